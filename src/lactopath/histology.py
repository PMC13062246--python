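"""H&E tile extraction, background exclusion and stain normalization.

Slides are cut into non-overlapping square tiles (default 512x512 px);
near-white tiles are dropped with a brightness rule (default mean gray
> 216). Stain variability is corrected by estimating a two-stain
(hematoxylin/eosin) model via sparse non-negative matrix factorization of
the optical density — the Vahadane approach — and re-expressing a tile's
stain concentrations through a reference (target) stain model.

Optical density follows Beer–Lambert: ``OD = -ln((I + eps) / I0)`` with
``I0 = 255``; stain mixing is linear in OD, so a pixel's OD is approximately
``W @ c`` with ``W`` the 3x2 stain matrix (unit-norm, non-negative columns)
and ``c`` the two stain concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import Tile
from .errors import NoStainError

__all__ = [
    "tile_image",
    "is_background",
    "StainModel",
    "fit_stain_model",
    "normalize_tile",
]

#: ITU-R 601 luma weights used for the brightness rule
_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])
_I0 = 255.0
_EPS = 1.0
#: OD magnitude below which a pixel is treated as unstained background
_OD_TISSUE_THRESHOLD = 0.15


def tile_image(
    image: np.ndarray, slide_id: str = "slide", tile_size: int = 512
) -> list[Tile]:
    """Cut an RGB image into non-overlapping ``tile_size`` squares.

    Partial border tiles are discarded; tiles are returned in row-major
    order with 0-based (row, column) pixel offsets that are multiples of
    ``tile_size``. An image smaller than one tile yields an empty list with
    a warning.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w = img.shape[:2]
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"image {img.shape[:2]} smaller than one {tile_size}px tile; "
            "no tiles produced",
            stacklevel=2,
        )
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            x, y = r * tile_size, c * tile_size
            tiles.append(
                Tile(
                    slide_id=slide_id,
                    x=x,
                    y=y,
                    pixels=img[x : x + tile_size, y : y + tile_size],
                )
            )
    return tiles


def is_background(
    tile: Tile | np.ndarray,
    brightness_threshold: float = 216.0,
    method: str = "brightness",
    saturation_threshold: float = 0.08,
) -> bool:
    """Decide whether a tile is informationless (near-white) background.

    ``method="brightness"`` (default) flags a tile whose mean ITU-R 601 gray
    level exceeds ``brightness_threshold``. ``method="saturation"`` flags a
    tile whose mean HSV saturation falls below ``saturation_threshold``
    (white has zero saturation). Both are pure functions of the pixels.
    """
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    rgb = pixels.astype(float)
    if method == "brightness":
        gray = rgb @ _GRAY_WEIGHTS
        return bool(gray.mean() > brightness_threshold)
    if method == "saturation":
        mx = rgb.max(axis=2)
        mn = rgb.min(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
        return bool(sat.mean() < saturation_threshold)
    raise ValueError(f"unknown background method: {method!r}")


# ---------------------------------------------------------------------------
# Stain model
# ---------------------------------------------------------------------------

@dataclass
class StainModel:
    """Two-stain optical-density model of an H&E image.

    ``stain_matrix`` holds the hematoxylin and eosin OD color vectors as
    unit-norm non-negative columns (hematoxylin first — the column with the
    larger blue-channel OD loading). ``concentration_scale`` is the robust
    (99th percentile) concentration per stain, used to match intensity ranges
    between images.
    """

    stain_matrix: np.ndarray  # (3, 2)
    concentration_scale: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        w = np.asarray(self.stain_matrix, dtype=float)
        if w.shape != (3, 2):
            raise ValueError("stain matrix must be 3x2")
        if np.any(w < -1e-9):
            raise ValueError("stain matrix entries must be non-negative")
        norms = np.linalg.norm(w, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("stain matrix columns must have unit L2 norm")


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to optical density, flattened to (n_pixels, 3)."""
    rgb = np.asarray(pixels, dtype=float).reshape(-1, 3)
    return -np.log((rgb + _EPS) / (_I0 + _EPS))


def od_to_rgb(od: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to valid 8-bit range."""
    rgb = (_I0 + _EPS) * np.exp(-od) - _EPS
    return np.clip(rgb, 0, 255).round().astype(np.uint8).reshape(shape)


def fit_stain_model(
    tiles: Tile | np.ndarray | list,
    lambda_sparsity: float = 0.1,
    n_iter: int = 50,
    seed: int | None = 0,
    min_tissue_pixels: int = 100,
) -> StainModel:
    """Estimate a two-stain model by sparse NMF of the optical density.

    Tissue pixels (OD norm above a small threshold) are factorized as
    ``OD^T ~ W @ H`` with ``W`` the 3x2 non-negative stain matrix and ``H``
    the 2 x n_pixels non-negative concentrations carrying an L1 penalty
    (``lambda_sparsity``). Multiplicative updates run for ``n_iter``
    rounds from a seeded perturbation of canonical H&E vectors; columns of
    ``W`` are renormalized each round (concentration rows rescaled
    inversely, so the product is unchanged). Hematoxylin is identified as
    the column with the larger blue-channel loading.

    Raises :class:`NoStainError` when fewer than ``min_tissue_pixels``
    pixels carry appreciable optical density (e.g. a pure-white tile).
    """
    if isinstance(tiles, Tile):
        arrays = [tiles.pixels]
    elif isinstance(tiles, np.ndarray):
        arrays = [tiles]
    else:
        arrays = [t.pixels if isinstance(t, Tile) else np.asarray(t) for t in tiles]
    od = np.vstack([rgb_to_od(a) for a in arrays])
    mask = np.linalg.norm(od, axis=1) > _OD_TISSUE_THRESHOLD
    od = od[mask]
    if od.shape[0] < min_tissue_pixels:
        raise NoStainError(
            f"no stain content: only {od.shape[0]} tissue pixels "
            f"(need {min_tissue_pixels})"
        )
    # cap the pixel count for speed; seeded subsample keeps determinism
    rng = np.random.default_rng(seed)
    if od.shape[0] > 20000:
        od = od[rng.choice(od.shape[0], 20000, replace=False)]
    x = od.T  # (3, n)

    # canonical H&E OD vectors (Ruifrok) + seeded jitter as initialization
    w = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
    w = np.abs(w + 0.05 * rng.standard_normal(w.shape))
    w /= np.linalg.norm(w, axis=0, keepdims=True)
    h = np.maximum(np.linalg.lstsq(w, x, rcond=None)[0], 1e-8)

    tiny = 1e-12
    for _ in range(n_iter):
        # H update with L1 sparsity penalty
        h *= (w.T @ x) / (w.T @ w @ h + lambda_sparsity + tiny)
        h = np.maximum(h, tiny)
        # W update, then renormalize columns (rescale H to keep W@H fixed)
        w *= (x @ h.T) / (w @ h @ h.T + tiny)
        w = np.maximum(w, tiny)
        norms = np.linalg.norm(w, axis=0, keepdims=True)
        w /= norms
        h *= norms.T

    # hematoxylin = column with larger blue-channel OD loading
    if w[2, 0] < w[2, 1]:
        w = w[:, ::-1]
        h = h[::-1]
    scale = np.percentile(h, 99, axis=1)
    return StainModel(stain_matrix=w, concentration_scale=scale)


def _concentrations(od: np.ndarray, model: StainModel) -> np.ndarray:
    """Per-pixel stain concentrations: least squares in OD space, clipped >= 0."""
    c, *_ = np.linalg.lstsq(model.stain_matrix, od.T, rcond=None)
    return np.maximum(c, 0.0)


def normalize_tile(
    tile: Tile | np.ndarray, source: StainModel, target: StainModel
) -> Tile | np.ndarray:
    """Re-express a tile's stains through a target stain model.

    Source concentrations are rescaled per stain by the ratio of target to
    source concentration scales and recomposed through the target stain
    matrix; the result is mapped back from OD to 8-bit RGB with clipping.
    Returns the same type as the input (Tile in, Tile out).
    """
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    od = rgb_to_od(pixels)
    conc = _concentrations(od, source)
    ratio = target.concentration_scale / np.maximum(
        source.concentration_scale, 1e-12
    )
    od_new = (target.stain_matrix @ (conc * ratio[:, None])).T
    out = od_to_rgb(od_new, pixels.shape)
    if isinstance(tile, Tile):
        return Tile(slide_id=tile.slide_id, x=tile.x, y=tile.y, pixels=out)
    return out
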