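"""Patch featurization.

The featurizer interface is any callable mapping a list of RGB tile arrays
to an ``(n, 768)`` float array; an adapter for an external pretrained
backbone (e.g. a pathology foundation model) plugs in here. The default
:class:`HandcraftedFeaturizer` is a deterministic desk-scale backend:
color/texture summary statistics randomly projected to 768 dimensions with
a fixed seed. It is a pure per-tile function, so batch size cannot change
results.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..containers import EMBED_DIM, PatchBag, Tile

__all__ = ["HandcraftedFeaturizer", "featurize_patches"]

_GRAY = np.array([0.299, 0.587, 0.114])


def _tile_descriptor(pixels: np.ndarray) -> np.ndarray:
    """Raw color + texture descriptor of one RGB tile (fixed length)."""
    rgb = np.asarray(pixels, dtype=float)
    feats: list[np.ndarray] = []
    for c in range(3):
        hist, _ = np.histogram(rgb[..., c], bins=16, range=(0, 256))
        feats.append(hist / hist.sum())
        feats.append(np.array([rgb[..., c].mean() / 255.0, rgb[..., c].std() / 255.0]))
    gray = rgb @ _GRAY
    hist, _ = np.histogram(gray, bins=16, range=(0, 256))
    feats.append(hist / hist.sum())
    gx = ndimage.sobel(gray, axis=0)
    gy = ndimage.sobel(gray, axis=1)
    grad = np.hypot(gx, gy)
    feats.append(np.array([grad.mean() / 255.0, grad.std() / 255.0]))
    feats.append(np.percentile(gray, [10, 25, 50, 75, 90]) / 255.0)
    return np.concatenate(feats)


class HandcraftedFeaturizer:
    """Deterministic tile embedder: summary statistics -> random 768-d projection.

    The Gaussian projection matrix is generated once from ``seed``; two
    featurizers with the same seed produce identical embeddings for
    identical pixels.
    """

    #: descriptor length produced by :func:`_tile_descriptor`
    _RAW_DIM = 16 * 3 + 2 * 3 + 16 + 2 + 5

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((self._RAW_DIM, EMBED_DIM))
        self._projection /= np.sqrt(self._RAW_DIM)

    def __call__(self, tiles: list[np.ndarray]) -> np.ndarray:
        raw = np.stack([_tile_descriptor(t) for t in tiles])
        return (raw @ self._projection).astype(np.float32)


def featurize_patches(
    tiles: list[Tile],
    backend=None,
    batch_size: int = 256,
    seed: int = 0,
) -> PatchBag:
    """Embed a slide's tiles into a :class:`PatchBag` of 768-d vectors.

    ``backend`` is any callable from tile-pixel lists to ``(n, 768)``
    arrays; the default is :class:`HandcraftedFeaturizer` with ``seed``.
    Tiles are processed in batches of ``batch_size`` purely for memory;
    results are independent of the batch size.
    """
    if len(tiles) == 0:
        raise ValueError("cannot featurize an empty tile list")
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    if backend is None:
        backend = HandcraftedFeaturizer(seed=seed)
    chunks = []
    for start in range(0, len(tiles), batch_size):
        batch = [t.pixels for t in tiles[start : start + batch_size]]
        emb = np.asarray(backend(batch))
        if emb.shape != (len(batch), EMBED_DIM):
            raise ValueError(
                f"featurizer returned shape {emb.shape}, expected "
                f"({len(batch)}, {EMBED_DIM})"
            )
        chunks.append(emb)
    embeddings = np.vstack(chunks)
    coords = np.array([[t.x, t.y] for t in tiles], dtype=np.int32)
    return PatchBag(
        slide_id=tiles[0].slide_id, embeddings=embeddings, coords=coords
    )
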