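"""Shared data containers.

Expression matrices are plain :class:`pandas.DataFrame` objects (genes in the
index, samples in the columns); the containers here cover the objects that do
not map onto a DataFrame naturally: gene sets, image tiles, per-slide patch
bags and slide-level embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EMBED_DIM = 768  #: width of patch-level feature vectors

LABEL_HIGH = "LAC_H"
LABEL_LOW = "LAC_L"
LABEL_MID = "MID"


@dataclass
class GeneSet:
    """A named collection of unique gene identifiers.

    Parameters
    ----------
    name
        Gene-set name (e.g. ``"LACTATE"``).
    genes
        Gene identifiers, order preserved, duplicates not allowed.
    description
        Free-text description (second GMT column).
    relevance
        Optional per-gene relevance scores (e.g. database relevance used to
        curate the set).
    """

    name: str
    genes: list[str]
    description: str = ""
    relevance: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate identifiers")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class Tile:
    """One non-overlapping square tile cut from an RGB image.

    ``x`` is the 0-based row offset and ``y`` the column offset of the
    top-left pixel; both are multiples of the tile size.
    """

    slide_id: str
    x: int
    y: int
    pixels: np.ndarray  # (edge, edge, 3) uint8

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("tile pixels must be a square (edge, edge, 3) array")


@dataclass
class PatchBag:
    """All patches of one slide, as embeddings and/or raw tile images.

    ``embeddings`` is an ``(n_patches, 768)`` float array; ``coords`` holds
    the per-patch pixel offsets. ``label`` is 1 for LAC_H-like slides, 0 for
    LAC_L-like, ``None`` when unknown.
    """

    slide_id: str
    embeddings: np.ndarray | None = None
    coords: np.ndarray | None = None
    label: int | None = None
    tiles: list[Tile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.embeddings is not None:
            e = np.asarray(self.embeddings)
            if e.ndim != 2 or e.shape[1] != EMBED_DIM:
                raise ValueError(
                    f"embeddings must be (n_patches, {EMBED_DIM}); got {e.shape}"
                )
            if e.shape[0] < 1:
                raise ValueError("a bag needs at least one patch")
            if not np.all(np.isfinite(e)):
                raise ValueError("embeddings contain non-finite values")

    @property
    def n_patches(self) -> int:
        if self.embeddings is not None:
            return int(np.asarray(self.embeddings).shape[0])
        return len(self.tiles)


@dataclass
class SlideEmbedding:
    """Slide-level representation: 512-d CLS vector, optionally reduced to 128-d."""

    slide_id: str
    vector: np.ndarray  # (512,)
    reduced: np.ndarray | None = None  # (<=128,)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples expression matrix.

    Requires unique gene identifiers and finite values; returns the frame
    unchanged so calls can be inlined.
    """
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    values = expr.to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    return expr
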