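"""Repeated-simulation studies of the pipeline's statistical behaviour.

Each function runs the full generator → analysis path across many seeds
and summarizes operating characteristics: type-I error calibration with
all generative mechanisms switched off, and directional effect recovery
with the default mechanisms on. These are the studies behind the package's
validation claims; they are deliberately thin loops over the public API.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distance import nn_distances, distance_to_front, front_distance_summary
from .hotspot import case_roi_summary, roi_correlation, roi_metrics, select_hotspots
from .io_tables import Phenotype
from .simulate import SyntheticConfig, generate_cohort, generate_tissue_pair
from .survival import cox_fit, logrank_test, mann_whitney_test
from .wta import median_split

_PRIME = 100_003


def _derive_seed(base: int, i: int) -> int:
    return (int(base) * _PRIME + i) % (2 ** 31)


def _null_config(seed: int, **overrides) -> SyntheticConfig:
    params = dict(exclusion_strength=0.0, front_gradient=0.0, gzmb_slope=0.0,
                  beta=0.0, seed=seed)
    params.update(overrides)
    return SyntheticConfig(**params)


def _case_ratio(per_case: list[dict]) -> pd.Series:
    df = pd.DataFrame(per_case).set_index("case_id")
    return df["cd8_density"] / df["ccr8_treg_density"].replace(0.0, np.nan)


def mw_null_calibration(n_runs: int = 200, seed: int = 0,
                        alpha: float = 0.05) -> float:
    """Rejection rate of the CCR8+/CCR8− NN-distance comparison under the null.

    All spatial mechanisms are off, so CCR8 labels are exchangeable among
    Tregs and the Mann-Whitney comparison should reject at ≈ alpha.
    """
    rejections = 0
    for i in range(n_runs):
        cfg = _null_config(_derive_seed(seed, i))
        tf, cg, _, _ = generate_tissue_pair(cfg, "c")
        pos = tf[tf["phenotype"] == Phenotype.TREG_CCR8POS.value]
        neg = tf[tf["phenotype"] == Phenotype.TREG_CCR8NEG.value]
        if len(pos) == 0 or len(neg) == 0 or len(cg) == 0:
            continue
        d_pos = nn_distances(pos, cg)
        d_neg = nn_distances(neg, cg)
        rejections += mann_whitney_test(d_pos, d_neg).p < alpha
    return rejections / n_runs


def logrank_null_calibration(n_runs: int = 200, seed: int = 0,
                             alpha: float = 0.05) -> float:
    """Rejection rate of the median-split ratio log-rank test when β = 0."""
    rejections = 0
    for i in range(n_runs):
        cfg = _null_config(_derive_seed(seed, i))
        cohort = generate_cohort(cfg, spatial=False)
        ratio = _case_ratio(cohort.ground_truth["per_case"])
        labels = median_split(ratio)
        clin = cohort.clinical.set_index("case_id")
        hi = clin.loc[labels.index[labels == "HIGH"]]
        lo = clin.loc[labels.index[labels == "LOW"]]
        res = logrank_test(hi["rfs_months"], hi["event"].astype(bool),
                           lo["rfs_months"], lo["event"].astype(bool))
        rejections += res.p < alpha
    return rejections / n_runs


def distance_direction_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Fraction of seeds reproducing the two spatial direction findings.

    At default mechanisms: (i) the median NN distance from CCR8+ Tregs to
    CD8+ T cells exceeds that from CCR8− Tregs (local exclusion), and
    (ii) CCR8+ Tregs sit closer to the invasion front than CCR8− Tregs
    (front enrichment). Both are evaluated on the same simulated tissues.
    """
    nn_hits = front_hits = n_used = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=_derive_seed(seed, i))
        tf, cg, region, _ = generate_tissue_pair(cfg, "c")
        pos = tf[tf["phenotype"] == Phenotype.TREG_CCR8POS.value]
        neg = tf[tf["phenotype"] == Phenotype.TREG_CCR8NEG.value]
        if len(pos) == 0 or len(neg) == 0 or len(cg) == 0:
            continue
        n_used += 1
        nn_hits += (np.median(nn_distances(pos, cg))
                    > np.median(nn_distances(neg, cg)))
        fd = distance_to_front(tf, region.invasion_front)
        summ = front_distance_summary(fd)
        front_hits += (summ.loc[Phenotype.TREG_CCR8POS.value, "median_um"]
                       < summ.loc[Phenotype.TREG_CCR8NEG.value, "median_um"])
    return {"nn_direction_fraction": nn_hits / n_used,
            "front_direction_fraction": front_hits / n_used,
            "n_seeds": n_used}


def hotspot_slope_recovery(n_seeds: int = 100, seed: int = 0,
                           n_cases: int = 80, top_n: int = 40) -> float:
    """Fraction of cohorts with a negative hotspot %GzmB+ regression slope."""
    negative = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=_derive_seed(seed, i), n_cases=n_cases)
        cohort = generate_cohort(cfg)
        groups = dict(iter(cohort.cells.groupby(["case_id", "panel"], sort=False)))
        empty = cohort.cells.iloc[:0]
        tables = []
        for case_id, region in cohort.regions.items():
            tf = groups.get((case_id, "CCR8_FOXP3"), empty)
            cg = groups.get((case_id, "CD8_GZMB"), empty)
            rois = select_hotspots(tf, region)
            if rois:
                tables.append(roi_metrics(rois, tf, cg))
        summary = case_roi_summary(pd.concat(tables, ignore_index=True))
        regs = roi_correlation(summary, top_n=top_n)
        negative += regs["pct_gzmb_in_cd8"].slope < 0
    return negative / n_seeds


def km_direction_recovery(n_seeds: int = 100, seed: int = 0) -> float:
    """Fraction of β = 1 cohorts where the LOW-ratio KM curve is lower at 60 m."""
    from .survival import km_estimate
    hits = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(seed=_derive_seed(seed, i))
        cohort = generate_cohort(cfg, spatial=False)
        ratio = _case_ratio(cohort.ground_truth["per_case"])
        labels = median_split(ratio)
        clin = cohort.clinical.set_index("case_id")
        hi = clin.loc[labels.index[labels == "HIGH"]]
        lo = clin.loc[labels.index[labels == "LOW"]]
        km_hi = km_estimate(hi["rfs_months"], hi["event"].astype(bool))
        km_lo = km_estimate(lo["rfs_months"], lo["event"].astype(bool))
        hits += km_lo.survival_at_60 < km_hi.survival_at_60
    return hits / n_seeds


def cox_coverage(n_runs: int = 500, seed: int = 0,
                 n_cases: int = 200) -> float:
    """Wald 95% CI coverage of the true log-hazard coefficient (β = 1).

    Cohorts are generated at the count level; the Cox model is fitted on
    the generative risk covariate (the negated standardized log ratio) and
    coverage of the true β is reported as a percentage.
    """
    covered = total = 0
    for i in range(n_runs):
        cfg = SyntheticConfig(seed=_derive_seed(seed, i), n_cases=n_cases)
        cohort = generate_cohort(cfg, spatial=False)
        per_case = pd.DataFrame(cohort.ground_truth["per_case"]).set_index("case_id")
        df = cohort.clinical.set_index("case_id")
        df["risk"] = per_case["risk"]
        df = df.reset_index()[["rfs_months", "event", "risk"]]
        df["event"] = df["event"].astype(bool)
        res = cox_fit(df, "risk")
        if not res.converged:
            continue
        beta, se = res.extra["beta"], res.extra["se"]
        total += 1
        covered += (beta - 1.959963984540054 * se <= cfg.beta
                    <= beta + 1.959963984540054 * se)
    return 100.0 * covered / total
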