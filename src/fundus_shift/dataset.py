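"""Labeled image dataset container shared by the generation, corruption and
evaluation stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .image import Image


class LabeledItem(NamedTuple):
    id: str
    image: Image
    label: int


@dataclass
class LabeledDataset:
    """Ordered collection of (id, image, binary label) with provenance metadata.

    ``metadata`` records where the data came from (source, shift applied,
    severity, seed) so every report row is traceable.
    """

    items: list[LabeledItem]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset ids must be unique")
        for it in self.items:
            if it.label not in (0, 1):
                raise ValueError(f"labels must be binary, got {it.label!r}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[LabeledItem]:
        return iter(self.items)

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def labels(self) -> np.ndarray:
        return np.array([it.label for it in self.items], dtype=np.int64)

    @property
    def images(self) -> list[Image]:
        return [it.image for it in self.items]

    def subset(self, indices: np.ndarray | list[int], **metadata) -> "LabeledDataset":
        meta = dict(self.metadata)
        meta.update(metadata)
        return LabeledDataset([self.items[int(i)] for i in indices], metadata=meta)
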