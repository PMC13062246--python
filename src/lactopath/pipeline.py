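"""End-to-end orchestration of the synthetic lactate-inference analysis.

One configuration drives the whole chain: simulate expression and slides,
score and stratify by the lactate signature, train the bag aggregator,
reduce, select features, fit the four-classifier ensemble, integrate the
score, compare IHC H-scores between predicted extremes, and run the
survival cutpoint analysis. Every stage writes its outputs under the run
directory and records their SHA-256 hashes in a manifest, so a rerun with
the same configuration reproduces identical hashes for deterministic
stages. Per-stage seeds fan out deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import genesets, ihc, survival, synthio
from .containers import LABEL_HIGH, LABEL_LOW
from .errors import ConfigurationError
from .io import write_bag_h5, write_expression_tsv
from .mil import (
    AggregatorConfig,
    aggregate_slides,
    reduce_components,
    train_aggregator,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; numeric defaults follow the published values
    where one exists (tile size 512, brightness threshold 216, tertile
    fraction 0.33, extremes 0.10, 128 components, cutpoint band [0.2, 0.8]).
    """

    out_dir: str | Path = "lactopath_run"
    seed: int = 0
    # synthetic cohort
    n_genes: int = 2000
    n_samples: int = 200
    latent_effect: float = 1.0
    patches_per_slide: tuple[int, int] = (80, 120)
    morphology_effect: float = 2.0
    ihc_group_shift: float = 2.0
    log_hazard_ratio: float = 0.5
    censoring_rate: float = 0.3
    # analysis parameters
    ssgsea_alpha: float = 0.25
    fraction: float = 0.33
    extremes_fraction: float = 0.10
    tile_size: int = 512
    brightness_threshold: float = 216.0
    components: int = 128
    minprop: float = 0.2
    maxprop: float = 0.8
    train_fraction: float = 0.75
    epochs: int = 8
    learning_rate: float = 1e-3
    # stage toggles
    do_survival: bool = True
    do_ihc: bool = True
    write_bags: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ConfigurationError("fraction must lie in (0, 0.5]")
        if not 0 < self.extremes_fraction < 0.5:
            raise ConfigurationError("extremes_fraction must lie in (0, 0.5)")
        if not 0 < self.minprop <= self.maxprop < 1:
            raise ConfigurationError("need 0 < minprop <= maxprop < 1")
        if self.components < 1 or self.tile_size < 1:
            raise ConfigurationError("components and tile_size must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2**31 fanned out from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    def record(stage: str, files: list[Path], metrics: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
            "metrics": metrics,
        }

    # -- expression -------------------------------------------------------
    expr_cfg = synthio.ExpressionSimConfig(
        n_genes=cfg.n_genes,
        n_samples=cfg.n_samples,
        latent_effect=cfg.latent_effect,
        seed=seeds[0],
    )
    expr, signature, latent = synthio.simulate_expression(expr_cfg)
    expr_path = out / "expression.tsv"
    write_expression_tsv(expr, expr_path)
    gmt_path = out / "signature.gmt"
    genesets.write_gmt([signature], gmt_path)
    record("expression", [expr_path, gmt_path], {"n_genes": cfg.n_genes,
                                                 "n_samples": cfg.n_samples})

    # -- signature scoring and stratification ------------------------------
    scores = genesets.ssgsea_scores(expr, signature, alpha=cfg.ssgsea_alpha)
    strata = genesets.stratify_tertiles(scores[signature.name], fraction=cfg.fraction)
    scores_path = out / "scores.csv"
    strata.to_csv(scores_path, index_label="sample_id")
    agreement = float(
        (latent[strata["group"] == LABEL_HIGH] == 1).mean()
    )
    record(
        "scoring",
        [scores_path],
        {
            "n_high": int((strata["group"] == LABEL_HIGH).sum()),
            "n_low": int((strata["group"] == LABEL_LOW).sum()),
            "latent_agreement_high": agreement,
        },
    )

    # -- slide bags for the stratified extremes ----------------------------
    hl = strata[strata["group"].isin([LABEL_HIGH, LABEL_LOW])]
    n_slides = len(hl)
    bag_cfg = synthio.BagSimConfig(
        n_slides=n_slides,
        patches_per_slide=cfg.patches_per_slide,
        tile_edge=cfg.tile_size,
        class_balance=0.5,
        morphology_effect=cfg.morphology_effect,
        seed=seeds[1],
    )
    bags = synthio.simulate_bags(bag_cfg, mode="embeddings")
    # pair each LAC_H sample with a class-1 bag, LAC_L with class-0
    high_ids = sorted(hl.index[hl["group"] == LABEL_HIGH])
    low_ids = sorted(hl.index[hl["group"] == LABEL_LOW])
    slide_map = {}
    hi_iter, lo_iter = iter(high_ids), iter(low_ids)
    for bag in bags:
        slide_map[bag.slide_id] = next(hi_iter if bag.label == 1 else lo_iter)
    bag_files = []
    if cfg.write_bags:
        bag_dir = out / "bags"
        bag_dir.mkdir(exist_ok=True)
        for bag in bags:
            p = bag_dir / f"{bag.slide_id}.h5"
            write_bag_h5(bag, p)
            bag_files.append(p)
    record("bags", bag_files, {"n_slides": n_slides})

    # -- aggregation and reduction -----------------------------------------
    labels = np.array([b.label for b in bags])
    is_train, is_test = ens.split_units(
        [b.slide_id for b in bags], labels,
        train_fraction=cfg.train_fraction, seed=seeds[2],
    )
    train_bags = [b for b, m in zip(bags, is_train) if m]
    agg_cfg = AggregatorConfig(seed=seeds[3])
    weights = train_aggregator(
        train_bags, agg_cfg, epochs=cfg.epochs, lr=cfg.learning_rate,
        seed=seeds[3],
    )
    slide_mat, slide_ids = aggregate_slides(bags, weights)
    reduced_train, reducer = reduce_components(
        slide_mat[is_train], k=cfg.components
    )
    reduced_all = reducer.transform(slide_mat)
    feat_path = out / "slide_features.csv"
    pd.DataFrame(reduced_all, index=slide_ids).to_csv(feat_path, index_label="slide_id")
    record(
        "aggregate",
        [feat_path],
        {
            "final_train_loss": weights.loss_history[-1],
            "n_components": reduced_all.shape[1],
        },
    )

    # -- selection, ensemble, evaluation ------------------------------------
    selected, coefs = ens.lasso_select(
        reduced_all[is_train], labels[is_train], seed=seeds[4]
    )
    x_train = reduced_all[np.ix_(is_train, selected)]
    x_test = reduced_all[np.ix_(is_test, selected)]
    models = ens.train_ensemble(x_train, labels[is_train], seed=seeds[5])
    probs_test = ens.predict_ensemble(models, x_test)
    probs_all = ens.predict_ensemble(models, reduced_all[:, selected])
    aurocs = {
        name: ens.auroc(probs_test[name].to_numpy(), labels[is_test])
        for name in probs_test.columns
    }
    dca = ens.decision_curve(probs_test.mean(axis=1).to_numpy(), labels[is_test])
    youden = ens.threshold_metrics(
        probs_test.mean(axis=1).to_numpy(), labels[is_test], mode="youden"
    )
    fixed = ens.threshold_metrics(
        probs_test.mean(axis=1).to_numpy(), labels[is_test], mode="fixed_0.5"
    )
    eval_path = out / "evaluation.json"
    dca_path = out / "dca.csv"
    dca.to_csv(dca_path, index=False)
    with open(eval_path, "w") as fh:
        json.dump(
            {
                "selected_features": [int(i) for i in selected],
                "auroc_test": aurocs,
                "youden": dataclasses.asdict(youden),
                "fixed_0.5": dataclasses.asdict(fixed),
            },
            fh,
            indent=2,
        )
    record("evaluate", [eval_path, dca_path],
           {"auroc_test": aurocs, "n_selected": len(selected)})

    # -- integrated score and extremes --------------------------------------
    integrated = pd.Series(
        ens.integrated_score(probs_all[list(ens.MODEL_ORDER)].to_numpy()),
        index=slide_ids,
        name="integrated_score",
    )
    extremes = ens.stratify_extremes(integrated, fraction=cfg.extremes_fraction)
    int_path = out / "integrated_scores.csv"
    pd.DataFrame({"integrated_score": integrated, "extreme_group": extremes}).to_csv(
        int_path, index_label="slide_id"
    )
    record(
        "integrate",
        [int_path],
        {
            "score_min": float(integrated.min()),
            "score_max": float(integrated.max()),
            "n_extreme": int((extremes != "mid").sum()),
        },
    )

    # -- IHC validation of predicted extremes --------------------------------
    if cfg.do_ihc:
        k = int((extremes == "high").sum())
        # ground-truth bag label drives the simulated staining shift
        truth = {b.slide_id: b.label for b in bags}
        ihc_table = synthio.simulate_ihc_table(
            n_per_group=k, group_shift=cfg.ihc_group_shift, seed=seeds[6]
        )
        # attach simulated staining rows to the predicted extreme slides by
        # their true class (high-lactate slides draw from the shifted rows)
        pred_high = [s for s in integrated.index if extremes[s] == "high"]
        pred_low = [s for s in integrated.index if extremes[s] == "low"]
        shifted = ihc_table[ihc_table["group"] == "high"].reset_index(drop=True)
        unshifted = ihc_table[ihc_table["group"] == "low"].reset_index(drop=True)
        rows = []
        i_hi = i_lo = 0
        for s in pred_high + pred_low:
            src_is_shifted = truth[s] == 1
            if src_is_shifted:
                row = shifted.iloc[i_hi % len(shifted)]
                i_hi += 1
            else:
                row = unshifted.iloc[i_lo % len(unshifted)]
                i_lo += 1
            rows.append(
                {
                    "sample_id": s,
                    "predicted_group": "high" if s in pred_high else "low",
                    "p_weak": row["p_weak"],
                    "p_moderate": row["p_moderate"],
                    "p_strong": row["p_strong"],
                }
            )
        ihc_df = pd.DataFrame(rows)
        ihc_path = out / "ihc.csv"
        ihc_df.to_csv(ihc_path, index=False)
        hi_rows = ihc_df[ihc_df["predicted_group"] == "high"]
        lo_rows = ihc_df[ihc_df["predicted_group"] == "low"]
        if len(hi_rows) >= 3 and len(lo_rows) >= 3:
            med_hi, med_lo, p = ihc.compare_groups(hi_rows, lo_rows)
        else:  # too few extremes for a rank-sum test; report medians only
            med_hi = float(ihc.h_score_table(hi_rows).median())
            med_lo = float(ihc.h_score_table(lo_rows).median())
            p = None
        record(
            "ihc",
            [ihc_path],
            {"median_high": med_hi, "median_low": med_lo, "p_value": p},
        )

    # -- survival tied to the integrated score -------------------------------
    if cfg.do_survival:
        surv_cfg = synthio.SurvivalSimConfig(
            n_patients=len(integrated),
            log_hazard_ratio_per_unit_score=cfg.log_hazard_ratio,
            censoring_rate=cfg.censoring_rate,
            seed=seeds[7],
        )
        records = synthio.simulate_survival(
            surv_cfg, integrated.to_numpy() - integrated.mean()
        )
        surv_path = out / "survival.csv"
        records.to_csv(surv_path, index=False)
        cut = survival.maxstat_cutpoint(
            records, minprop=cfg.minprop, maxprop=cfg.maxprop
        )
        lowg = records[records["score"] <= cut.cutpoint]
        highg = records[records["score"] > cut.cutpoint]
        chi2, p = survival.logrank_test(lowg, highg)
        km_low = survival.km_estimate(lowg)
        km_path = out / "km_low.csv"
        km_low.to_csv(km_path, index_label="time")
        record(
            "survival",
            [surv_path, km_path],
            {
                "cutpoint": cut.cutpoint,
                "max_statistic": cut.max_statistic,
                "logrank_chi2": chi2,
                "logrank_p": p,
                "group_sizes": list(cut.group_sizes),
            },
        )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
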