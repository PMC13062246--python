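"""Synthetic data generators with the statistical structure the analysis assumes.

Every downstream stage is testable without controlled-access data:

* expression matrices with a latent lactate program positively coupled to a
  proliferation program and negatively to immune/stromal programs (the
  directions reported for high- vs low-lactate tumors);
* slide-level bags of patches whose class-conditional distributions differ —
  "compact/homogeneous" high-lactate-like slides vs "infiltrated/
  heterogeneous" low-lactate-like slides — in embedding space or as drawn
  tile images;
* proportional-hazards survival times tied to a continuous score;
* per-sample IHC intensity-class percentage tables with a group shift on the
  strong-intensity logit.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .containers import GeneSet, PatchBag, Tile
from .errors import ConfigurationError

__all__ = [
    "ExpressionSimConfig",
    "BagSimConfig",
    "SurvivalSimConfig",
    "simulate_expression",
    "simulate_bags",
    "simulate_survival",
    "simulate_ihc_table",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Generator settings for the expression matrix with a latent lactate axis.

    ``latent_effect`` is the mean shift (log-expression units) added to
    signature genes in latent-high samples; each coupled program
    ``(name, n_genes, sign)`` is shifted by ``sign * latent_effect``.
    Defaults: a 59-gene signature (the curated lactate set size) in a
    2000-gene background, a positively coupled proliferation program and
    negatively coupled immune and stromal programs, unit-SD noise and a
    1-SD latent effect.
    """

    n_genes: int = 2000
    n_samples: int = 200
    signature_size: int = 59
    latent_effect: float = 1.0
    coupled_programs: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("proliferation", 50, +1),
            ("immune", 50, -1),
            ("stromal", 50, -1),
        ]
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.signature_size) < 1:
            raise ConfigurationError("counts must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        program_total = sum(size for _, size, _ in self.coupled_programs)
        if self.signature_size + program_total > self.n_genes:
            raise ConfigurationError(
                "signature_size plus program sizes exceeds n_genes"
            )
        for name, size, sign in self.coupled_programs:
            if size < 1 or sign not in (-1, 1):
                raise ConfigurationError(
                    f"program {name!r}: size must be >= 1 and sign +/-1"
                )


@dataclass
class BagSimConfig:
    """Generator settings for per-slide patch bags.

    ``morphology_effect`` is the separation (in patch-noise SD units)
    between the class-conditional patch distributions; 0 removes all signal.
    ``patches_per_slide`` is an inclusive (low, high) range.
    """

    n_slides: int = 60
    patches_per_slide: tuple[int, int] = (80, 120)
    tile_edge: int = 512
    class_balance: float = 0.5
    morphology_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.patches_per_slide
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"patches_per_slide range ({lo}, {hi}) is empty"
            )
        if self.tile_edge <= 0:
            raise ConfigurationError("tile_edge must be > 0")
        if not 0 < self.class_balance < 1:
            raise ConfigurationError("class_balance must lie in (0, 1)")
        if self.morphology_effect < 0:
            raise ConfigurationError("morphology_effect must be >= 0")
        if self.n_slides < 2:
            raise ConfigurationError("need at least 2 slides")


@dataclass
class SurvivalSimConfig:
    """Exponential proportional-hazards survival with independent censoring.

    The hazard for a patient with score ``s`` is
    ``baseline_hazard * exp(log_hazard_ratio_per_unit_score * s)``. The
    default baseline corresponds to a ~2-year median survival at score 0
    with times measured in days.
    """

    n_patients: int = 300
    baseline_hazard: float = 0.001
    log_hazard_ratio_per_unit_score: float = 0.5
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, GeneSet, pd.Series]:
    """Simulate a genes x samples log-expression matrix with a latent axis.

    Returns ``(expression, signature_gene_set, latent_labels)`` where the
    labels (1 = latent-high) mark the samples whose signature-gene mean is
    elevated by ``latent_effect``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_g, n_s = cfg.n_genes, cfg.n_samples

    sig_genes = [f"LAC{i:04d}" for i in range(cfg.signature_size)]
    program_genes: list[str] = []
    program_shift: list[float] = []
    for name, size, sign in cfg.coupled_programs:
        program_genes += [f"{name.upper()}{i:04d}" for i in range(size)]
        program_shift += [sign * cfg.latent_effect] * size
    n_bg = n_g - len(sig_genes) - len(program_genes)
    bg_genes = [f"G{i:05d}" for i in range(n_bg)]
    genes = sig_genes + program_genes + bg_genes
    samples = [f"S{i:04d}" for i in range(n_s)]

    # balanced latent assignment, order shuffled by the seed
    labels = np.zeros(n_s, dtype=int)
    labels[: n_s // 2] = 1
    labels = labels[rng.permutation(n_s)]

    baseline = rng.normal(5.0, 1.0, size=n_g)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
    shift = np.zeros(n_g)
    shift[: len(sig_genes)] = cfg.latent_effect
    shift[len(sig_genes) : len(sig_genes) + len(program_genes)] = program_shift
    values += shift[:, None] * labels[None, :]

    expr = pd.DataFrame(values, index=genes, columns=samples)
    signature = GeneSet(name="LACTATE", genes=sig_genes, description="synthetic lactate program")
    return expr, signature, pd.Series(labels, index=samples, name="latent")


# ---------------------------------------------------------------------------
# patch bags
# ---------------------------------------------------------------------------

def _draw_high_tile(rng: np.random.Generator, edge: int, effect: float) -> np.ndarray:
    """Compact/homogeneous tile: dense uniform nucleus-like ellipses, pale bg."""
    img = np.full((edge, edge, 3), (236, 228, 238), dtype=float)
    n_nuclei = int((edge / 32) ** 2 * (1.0 + 0.4 * effect))
    r_base = max(2, edge // 40)
    for _ in range(n_nuclei):
        cx, cy = rng.integers(0, edge, size=2)
        r = r_base * rng.uniform(0.85, 1.15)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cx, cy, r, 1.4 * r, shape=(edge, edge), rotation=rot)
        img[rr, cc] = (96, 60, 150)  # uniform hematoxylin-dark nuclei
    return img.clip(0, 255).astype(np.uint8)


def _draw_low_tile(rng: np.random.Generator, edge: int, effect: float) -> np.ndarray:
    """Infiltrated/heterogeneous tile: small dark round cells + fibrous texture."""
    img = np.full((edge, edge, 3), (238, 222, 228), dtype=float)
    # fibrous eosin streaks
    rows = np.arange(edge)
    for _ in range(max(2, edge // 32)):
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(2, edge / 16)
        center = rng.integers(0, edge)
        cols = (center + amp * np.sin(rows / rng.uniform(8, 24) + phase)).astype(int)
        for wdt in range(-1, 2):
            cc = np.clip(cols + wdt, 0, edge - 1)
            img[rows, cc] = (222, 150, 170)
    # dense small lymphocyte-like cells
    n_cells = int((edge / 24) ** 2 * (1.0 + 0.4 * effect))
    r_cell = max(1, edge // 80)
    for _ in range(n_cells):
        cx, cy = rng.integers(0, edge, size=2)
        rr, cc = disk((cx, cy), r_cell * rng.uniform(0.8, 1.2), shape=(edge, edge))
        img[rr, cc] = (60, 45, 110)
    return img.clip(0, 255).astype(np.uint8)


def simulate_bags(cfg: BagSimConfig, mode: str = "embeddings") -> list[PatchBag]:
    """Simulate labeled slides as bags of patches.

    ``mode="embeddings"``: patch vectors are drawn from class-conditional
    768-d Gaussian mixtures (3 shared components, unit noise) whose class
    means are separated by ``morphology_effect`` along a fixed direction.
    ``mode="images"``: tiles are procedurally drawn — class 1 slides carry
    dense uniform nucleus-like ellipses on a pale background, class 0
    slides mix small dark round cells with fibrous texture; embeddings are
    left empty for the featurizer.
    """
    rng = np.random.default_rng(cfg.seed)
    n1 = int(round(cfg.class_balance * cfg.n_slides))
    n1 = min(max(n1, 1), cfg.n_slides - 1)
    labels = np.array([1] * n1 + [0] * (cfg.n_slides - n1))
    labels = labels[rng.permutation(cfg.n_slides)]
    lo, hi = cfg.patches_per_slide

    if mode == "embeddings":
        from .containers import EMBED_DIM

        component_means = rng.normal(0.0, 1.0, size=(3, EMBED_DIM))
        direction = rng.standard_normal(EMBED_DIM)
        direction /= np.linalg.norm(direction)
        delta = 0.5 * cfg.morphology_effect * direction
    elif mode != "images":
        raise ValueError(f"unknown bag mode: {mode!r}")

    bags: list[PatchBag] = []
    for i in range(cfg.n_slides):
        sid = f"slide{i:04d}"
        n_patch = int(rng.integers(lo, hi + 1))
        coords = (
            rng.integers(0, 64, size=(n_patch, 2)).astype(np.int64) * cfg.tile_edge
        ).astype(np.int32)
        if mode == "embeddings":
            comp = rng.integers(0, 3, size=n_patch)
            center = component_means[comp] + (delta if labels[i] == 1 else -delta)
            emb = center + rng.normal(0.0, 1.0, size=center.shape)
            bags.append(
                PatchBag(
                    slide_id=sid,
                    embeddings=emb,
                    coords=coords,
                    label=int(labels[i]),
                )
            )
        else:
            draw = _draw_high_tile if labels[i] == 1 else _draw_low_tile
            tiles = [
                Tile(
                    slide_id=sid,
                    x=int(coords[j, 0]),
                    y=int(coords[j, 1]),
                    pixels=draw(rng, cfg.tile_edge, cfg.morphology_effect),
                )
                for j in range(n_patch)
            ]
            bags.append(
                PatchBag(slide_id=sid, coords=coords, label=int(labels[i]), tiles=tiles)
            )
    return bags


# ---------------------------------------------------------------------------
# survival and IHC
# ---------------------------------------------------------------------------

def simulate_survival(
    cfg: SurvivalSimConfig, scores: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Exponential event times with hazard ∝ exp(log_HR * score).

    Censoring is independent of the score: each patient is censored with
    probability ``censoring_rate`` and then observed at a uniform fraction
    of the (unobserved) event time. Returns columns patient_id, time,
    event, score.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (cfg.n_patients,):
        raise ConfigurationError(
            f"need {cfg.n_patients} scores, got shape {scores.shape}"
        )
    if not np.all(np.isfinite(scores)):
        raise ConfigurationError("scores must be finite")
    rng = np.random.default_rng(cfg.seed)
    hazard = cfg.baseline_hazard * np.exp(
        cfg.log_hazard_ratio_per_unit_score * scores
    )
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(cfg.n_patients) < cfg.censoring_rate
    u = rng.random(cfg.n_patients)
    time = np.where(censored, u * t_event, t_event)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(cfg.n_patients)],
            "time": time,
            "event": (~censored).astype(int),
            "score": scores,
        }
    )


def simulate_ihc_table(
    n_per_group: int = 10, group_shift: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """Per-sample IHC intensity-class percentages with a group shift.

    Percentages for (negative, weak, moderate, strong) cells are a softmax
    of Gaussian logits scaled to 100, so each row satisfies
    ``p_weak + p_moderate + p_strong <= 100`` (the remainder is the
    negative fraction). The high group's strong-intensity logit is raised
    by ``group_shift``.
    """
    rng = np.random.default_rng(seed)
    base = np.array([1.2, 0.2, -0.2, -0.8])  # negative, weak, moderate, strong
    rows = []
    for group in ("high", "low"):
        logits = base + rng.normal(0.0, 0.7, size=(n_per_group, 4))
        if group == "high":
            logits[:, 3] += group_shift
        expd = np.exp(logits - logits.max(axis=1, keepdims=True))
        pct = 100.0 * expd / expd.sum(axis=1, keepdims=True)
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{group}{i:03d}",
                    "group": group,
                    "p_weak": pct[i, 1],
                    "p_moderate": pct[i, 2],
                    "p_strong": pct[i, 3],
                }
            )
    return pd.DataFrame(rows)
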