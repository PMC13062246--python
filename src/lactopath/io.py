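"""File I/O: per-slide HDF5 patch-embedding containers and table formats.

Each slide's embeddings live in one ``.h5`` file with datasets
``embeddings`` (n x 768 float32) and ``coords`` (n x 2 int32) and attributes
``slide_id`` and, when known, ``label``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import PatchBag

__all__ = [
    "write_bag_h5",
    "read_bag_h5",
    "write_expression_tsv",
    "read_expression_tsv",
]


def write_bag_h5(bag: PatchBag, path: str | Path) -> None:
    """Store one slide's patch embeddings and coordinates."""
    if bag.embeddings is None:
        raise ValueError(f"bag {bag.slide_id!r} has no embeddings to store")
    with h5py.File(path, "w") as fh:
        # track_times=False keeps files byte-identical across reruns
        fh.create_dataset(
            "embeddings", data=np.asarray(bag.embeddings, dtype=np.float32),
            compression="gzip", track_times=False,
        )
        coords = bag.coords
        if coords is None:
            coords = np.zeros((bag.n_patches, 2), dtype=np.int32)
        fh.create_dataset(
            "coords", data=np.asarray(coords, dtype=np.int32),
            compression="gzip", track_times=False,
        )
        fh.attrs["slide_id"] = bag.slide_id
        if bag.label is not None:
            fh.attrs["label"] = int(bag.label)


def read_bag_h5(path: str | Path) -> PatchBag:
    """Inverse of :func:`write_bag_h5`."""
    with h5py.File(path, "r") as fh:
        label = int(fh.attrs["label"]) if "label" in fh.attrs else None
        return PatchBag(
            slide_id=str(fh.attrs["slide_id"]),
            embeddings=fh["embeddings"][...].astype(np.float64),
            coords=fh["coords"][...],
            label=label,
        )


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as TSV with a 'gene' index column."""
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV written by :func:`write_expression_tsv`."""
    return pd.read_csv(path, sep="\t", index_col="gene")
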