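"""End-to-end robustness evaluation: split, train a scorer, evaluate clean and
degraded test sets, and report metric deltas.

The protocol mirrors standard distribution-shift studies of screening
classifiers: a dataset is split 80/10/10 into train/validation/test; a scorer
is fit on the training split; the untouched test split is scored once
("in-distribution") and then re-scored after each fundus-specific degradation
is applied to its images (labels and membership unchanged). Robustness is the
signed difference clean - shifted for each metric, so a positive delta in
ROC-AUC means the degradation hurt discrimination.

Deep networks stay behind the :class:`ScorerContract`; the repository ships a
deterministic toy scorer (logistic regression on hand-crafted brightness/blob
features of the contrast-enhanced image) that detects the planted lesion
signal of the synthetic data well above chance, which is all the pipeline
contracts need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.linear_model import LogisticRegression

from .corruption import apply_shift
from .dataset import LabeledDataset
from .image import Image
from .metrics import PredictionSet, metric_records
from .preprocess import PreprocessConfig, graham_preprocess, resize_normalize
from .synthetic import SyntheticImageParams, synth_dataset


@dataclass(frozen=True)
class ScorerContract:
    """A named, deterministic mapping from preprocessed images to confidences.

    ``score_fn`` receives a list of preprocessed :class:`Image` objects and
    must return confidence scores in [0, 1], one per image.
    """

    name: str
    score_fn: Callable[[Sequence[Image]], np.ndarray]

    def __call__(self, images: Sequence[Image]) -> np.ndarray:
        scores = np.asarray(self.score_fn(images), dtype=np.float64)
        if scores.shape != (len(images),):
            raise ValueError("scorer must return one score per image")
        if scores.min() < 0.0 or scores.max() > 1.0:
            raise ValueError("scorer outputs must lie in [0, 1]")
        return scores


def split_dataset(ds: LabeledDataset, fractions: tuple[float, float, float],
                  seed: int) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Shuffled disjoint train/validation/test split.

    Validation and test sizes are round(n * frac); the remainder goes to
    train, so the three parts are exhaustive.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ValueError("split fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(ds)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = int(round(n * f_val))
    n_test = int(round(n * f_test))
    # salt the stream so a generator seeded identically elsewhere in the
    # pipeline cannot produce a correlated permutation
    perm = np.random.default_rng(
        np.random.SeedSequence([seed, 0x5917])).permutation(n)
    val_idx = perm[:n_val]
    test_idx = perm[n_val:n_val + n_test]
    train_idx = perm[n_val + n_test:]
    return (ds.subset(train_idx, split="train", split_seed=seed),
            ds.subset(val_idx, split="val", split_seed=seed),
            ds.subset(test_idx, split="test", split_seed=seed))


# ---------------------------------------------------------------------------
# toy scorer


@dataclass
class ToyScorer:
    """Logistic regression on three features of the contrast-enhanced image.

    Features (green channel inside the fundus mask, after preprocessing):
    mean intensity, a high percentile of intensity, and the count of bright
    connected blobs above a fixed threshold. The percentile is the one
    "decision-feature scaling" knob, selected on the validation split.
    """

    percentile: float
    blob_threshold: float
    feat_mean: np.ndarray
    feat_std: np.ndarray
    coef: np.ndarray
    intercept: float

    def features(self, images: Sequence[Image]) -> np.ndarray:
        rows = []
        for img in images:
            g = img.pixels[:, :, 1]
            inside = g[img.mask] if img.mask.any() else g.ravel()
            bright = (g > self.blob_threshold) & img.mask
            n_blobs = int(measure.label(bright).max()) if bright.any() else 0
            rows.append([float(inside.mean()),
                         float(np.percentile(inside, self.percentile)),
                         float(n_blobs)])
        return np.asarray(rows, dtype=np.float64)

    def __call__(self, images: Sequence[Image]) -> np.ndarray:
        z = (self.features(images) - self.feat_mean) / self.feat_std
        logit = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def to_dict(self) -> dict:
        return {"percentile": self.percentile,
                "blob_threshold": self.blob_threshold,
                "feat_mean": self.feat_mean.tolist(),
                "feat_std": self.feat_std.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept}

    @classmethod
    def from_dict(cls, d: dict) -> "ToyScorer":
        return cls(percentile=d["percentile"], blob_threshold=d["blob_threshold"],
                   feat_mean=np.asarray(d["feat_mean"]),
                   feat_std=np.asarray(d["feat_std"]),
                   coef=np.asarray(d["coef"]), intercept=float(d["intercept"]))


_PERCENTILE_GRID = (95.0, 99.0, 99.8)
_BLOB_THRESHOLD = 0.7


def _preprocess_for_scoring(images: Sequence[Image],
                            cfg: PreprocessConfig) -> list[Image]:
    # evaluation path: contrast enhancement + resize, never augmentation
    return [resize_normalize(graham_preprocess(img, cfg), cfg.target_size)
            for img in images]


def toy_scorer_train(train: LabeledDataset, val: LabeledDataset, seed: int,
                     preprocess_cfg: PreprocessConfig | None = None
                     ) -> ScorerContract:
    """Fit the toy scorer; the validation split picks the percentile feature.

    Deterministic given (data, seed). Raises on single-class training data.
    """
    from .metrics import roc_auc  # local import keeps module load cheap

    cfg = preprocess_cfg if preprocess_cfg is not None else PreprocessConfig()
    y_train = train.labels
    if y_train.min() == y_train.max():
        raise ValueError("toy scorer needs both classes in the training split")
    pp_train = _preprocess_for_scoring(train.images, cfg)
    pp_val = _preprocess_for_scoring(val.images, cfg)
    y_val = val.labels

    best = None
    for q in _PERCENTILE_GRID:
        model = _fit_logistic(pp_train, y_train, q, seed)
        if y_val.size and y_val.min() != y_val.max():
            score = roc_auc(PredictionSet(model(pp_val), y_val))
        else:  # degenerate validation split: fall back to training fit quality
            score = roc_auc(PredictionSet(model(pp_train), y_train))
        if best is None or score > best[0]:
            best = (score, model)
    scorer = best[1]
    return ScorerContract(name="toy-logistic", score_fn=scorer)


def _fit_logistic(pp_images: Sequence[Image], labels: np.ndarray,
                  percentile: float, seed: int) -> ToyScorer:
    probe = ToyScorer(percentile=percentile, blob_threshold=_BLOB_THRESHOLD,
                      feat_mean=np.zeros(3), feat_std=np.ones(3),
                      coef=np.zeros(3), intercept=0.0)
    feats = probe.features(pp_images)
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=500,
                             random_state=seed)
    clf.fit((feats - mean) / std, labels)
    return ToyScorer(percentile=percentile, blob_threshold=_BLOB_THRESHOLD,
                     feat_mean=mean, feat_std=std,
                     coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]))


# ---------------------------------------------------------------------------
# evaluation and robustness report


def evaluate(scorer: ScorerContract, test: LabeledDataset,
             preprocess_cfg: PreprocessConfig | None = None,
             fixed_bins: int = 15) -> tuple[PredictionSet, dict]:
    """Preprocess (no augmentation), score, and compute all metrics.

    Returns the prediction set and a JSON-ready record with ROC-AUC,
    fixed-bin ECE, sweep ECE (+ its chosen bin count) and provenance.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    cfg = preprocess_cfg if preprocess_cfg is not None else PreprocessConfig()
    preds = PredictionSet(scorer(_preprocess_for_scoring(test.images, cfg)),
                          test.labels)
    record = metric_records(preds, fixed_bins=fixed_bins)
    record["scorer"] = scorer.name
    record["provenance"] = {k: v for k, v in test.metadata.items()
                            if k != "per_image"}
    return preds, record


@dataclass(frozen=True)
class EvalRow:
    """One report row: a scorer evaluated under one (shift, severity) condition.

    ``shift='clean'`` rows hold the in-distribution reference; deltas are
    clean - shifted (positive delta_auc = discrimination degraded).
    """

    scorer: str
    shift: str
    severity: str
    n_test: int
    clean_auc: float
    clean_ece_sweep: float
    clean_ece_fixed: float
    shifted_auc: float | None = None
    shifted_ece_sweep: float | None = None
    shifted_ece_fixed: float | None = None
    delta_auc: float | None = None
    delta_ece_sweep: float | None = None
    delta_ece_fixed: float | None = None


@dataclass
class RobustnessReport:
    rows: list[EvalRow]
    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"rows": [vars(r) for r in self.rows],
                "seeds": self.seeds, "config": self.config}

    @classmethod
    def from_dict(cls, d: dict) -> "RobustnessReport":
        return cls(rows=[EvalRow(**r) for r in d["rows"]],
                   seeds=d["seeds"], config=d["config"])


DEFAULT_CONFIG: dict = {
    "synthetic": {"n": 300, "positive_frac": 0.35, "image": {}},
    "preprocess": {},
    "pipeline": {
        "seed": 0,
        "fractions": [0.8, 0.1, 0.1],
        "shifts": ["light", "blur", "artifact"],
        "severities": ["none", "low", "mid", "high"],
    },
    "metrics": {"fixed_bins": 15},
}


def _merge_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, values in (config or {}).items():
        if isinstance(values, dict) and isinstance(merged.get(section), dict):
            merged[section].update(values)
        else:
            merged[section] = values
    return merged


def robustness_run(config: dict | None = None,
                   dataset: LabeledDataset | None = None) -> RobustnessReport:
    """Run the full protocol: generate/split data, train the toy scorer,
    evaluate clean and under every configured (shift, severity) pair.

    ``dataset`` overrides the synthetic-generation section when the caller
    already holds labeled images (e.g. read from disk).
    """
    cfg = _merge_config(config)
    pl = cfg["pipeline"]
    seed = int(pl["seed"])
    pp_cfg = PreprocessConfig(**cfg["preprocess"])
    fixed_bins = int(cfg["metrics"]["fixed_bins"])

    # independent deterministic sub-seeds for each source of randomness
    data_seed, split_seed, train_seed, shift_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(4))

    if dataset is None:
        img_params = SyntheticImageParams(seed=data_seed, **cfg["synthetic"]["image"])
        dataset = synth_dataset(img_params, int(cfg["synthetic"]["n"]),
                                float(cfg["synthetic"]["positive_frac"]),
                                np.random.default_rng(data_seed))
    train, val, test = split_dataset(dataset, tuple(pl["fractions"]),
                                     seed=split_seed)
    scorer = toy_scorer_train(train, val, seed=train_seed, preprocess_cfg=pp_cfg)

    _, clean = evaluate(scorer, test, pp_cfg, fixed_bins)
    rows = [EvalRow(scorer=scorer.name, shift="clean", severity="none",
                    n_test=len(test), clean_auc=clean["roc_auc"],
                    clean_ece_sweep=clean["ece_sweep"],
                    clean_ece_fixed=clean["ece_fixed"])]

    for shift in pl["shifts"]:
        for severity in pl["severities"]:
            shifted_ds = apply_shift(test, shift, severity, seed=shift_seed)
            assert list(shifted_ds.labels) == list(test.labels)
            _, rec = evaluate(scorer, shifted_ds, pp_cfg, fixed_bins)
            rows.append(EvalRow(
                scorer=scorer.name, shift=shift, severity=severity,
                n_test=len(test),
                clean_auc=clean["roc_auc"],
                clean_ece_sweep=clean["ece_sweep"],
                clean_ece_fixed=clean["ece_fixed"],
                shifted_auc=rec["roc_auc"],
                shifted_ece_sweep=rec["ece_sweep"],
                shifted_ece_fixed=rec["ece_fixed"],
                delta_auc=clean["roc_auc"] - rec["roc_auc"],
                delta_ece_sweep=clean["ece_sweep"] - rec["ece_sweep"],
                delta_ece_fixed=clean["ece_fixed"] - rec["ece_fixed"]))
    return RobustnessReport(
        rows=rows,
        seeds={"pipeline": seed, "data": data_seed, "split": split_seed,
               "train": train_seed, "shift": shift_seed},
        config=cfg)


CSV_HEADER = ["scorer", "shift", "severity", "metric", "clean", "shifted", "delta"]
_METRIC_FIELDS = {
    "roc_auc": ("clean_auc", "shifted_auc", "delta_auc"),
    "ece_sweep": ("clean_ece_sweep", "shifted_ece_sweep", "delta_ece_sweep"),
    "ece_fixed": ("clean_ece_fixed", "shifted_ece_fixed", "delta_ece_fixed"),
}


def write_report(report: RobustnessReport, out_dir: str | Path,
                 figures: bool = False) -> dict[str, Path]:
    """Write report.json (machine-readable, byte-stable) and report.csv;
    optionally bar charts of the per-shift metric deltas."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"json": out / "report.json", "csv": out / "report.csv"}
    paths["json"].write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")

    rows = []
    for r in report.rows:
        for metric, (c, s, d) in _METRIC_FIELDS.items():
            rows.append({"scorer": r.scorer, "shift": r.shift,
                         "severity": r.severity, "metric": metric,
                         "clean": getattr(r, c), "shifted": getattr(r, s),
                         "delta": getattr(r, d)})
    pd.DataFrame(rows, columns=CSV_HEADER).to_csv(paths["csv"], index=False)

    if figures:
        paths["figures"] = _delta_figures(report, out)
    return paths


def read_report(path: str | Path) -> RobustnessReport:
    with open(Path(path) if Path(path).is_file() else Path(path) / "report.json") as fh:
        return RobustnessReport.from_dict(json.load(fh))


def _delta_figures(report: RobustnessReport, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for metric, (_, _, dfield) in _METRIC_FIELDS.items():
        rows = [r for r in report.rows if getattr(r, dfield) is not None]
        if not rows:
            continue
        labels = [f"{r.shift}\n{r.severity}" for r in rows]
        values = [getattr(r, dfield) for r in rows]
        fig, ax = plt.subplots(figsize=(max(4, 0.7 * len(rows)), 3.2))
        ax.bar(range(len(rows)), values, color="#4878b0")
        ax.set_xticks(range(len(rows)), labels, fontsize=7)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel(f"delta {metric} (clean - shifted)")
        ax.set_title(report.rows[0].scorer)
        fig.tight_layout()
        p = out / f"delta_{metric}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
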