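"""Principal-component reduction of slide embeddings.

Fit on training slides only and apply the fitted basis to held-out slides,
so no information leaks from test data into the representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["ComponentReducer", "reduce_components"]


@dataclass
class ComponentReducer:
    """Fitted centered PCA basis (orthonormal rows) with explained variance."""

    components: np.ndarray  # (k, p) orthonormal
    mean: np.ndarray  # (p,)
    explained_variance: np.ndarray  # (k,)
    explained_variance_ratio: np.ndarray  # (k,)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T


def reduce_components(
    slide_vectors: np.ndarray, k: int = 128
) -> tuple[np.ndarray, ComponentReducer]:
    """Project slide vectors onto their top-``k`` principal components.

    ``k`` is capped at ``min(k, m - 1, p)`` (with a warning when the cap
    bites); components are orthonormal and the explained variance is
    nonincreasing. Returns the reduced ``(m, k)`` matrix and the fitted
    :class:`ComponentReducer` for application to new slides.
    """
    x = np.asarray(slide_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 slides")
    m, p = x.shape
    k_eff = min(k, m - 1, p)
    if k_eff < k:
        warnings.warn(
            f"requested {k} components but only {k_eff} are identifiable "
            f"from {m} slides of width {p}; capping",
            stacklevel=2,
        )
    pca = PCA(n_components=k_eff, svd_solver="full")
    reduced = pca.fit_transform(x)
    reducer = ComponentReducer(
        components=pca.components_,
        mean=pca.mean_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    return reduced, reducer
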