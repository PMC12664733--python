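"""Synthetic paired-section tissue and cohort generator with known ground truth.

The generator encodes, as explicit switchable mechanisms, the statistical
structure the analysis pipeline assumes about tumor tissue:

* Tregs (FOXP3+) follow a homogeneous Poisson process over the tumor
  region; each is CCR8+ with a base probability that is multiplicatively
  enriched (``front_gradient``) within a band along the invasion front.
* CD8+ candidate cells follow an independent Poisson process and are
  thinned near CCR8+ Tregs: a candidate at distance d from its nearest
  CCR8+ Treg is retained with probability 1 − s·exp(−d/τ)
  (``exclusion_strength`` s, ``exclusion_decay`` τ).
* Each retained CD8 cell is GzmB+ with probability
  logistic(a − b·ρ) where ρ is the number of CCR8+ Tregs within 100 µm
  (``gzmb_base`` a, ``gzmb_slope`` b) — local suppression of cytotoxicity.
* The CD8/GZMB panel observes the same cells on a consecutive section:
  positions carry isotropic Gaussian jitter ``section_jitter``.
* Recurrence-free survival is exponential with hazard
  h0·exp(β·risk), risk = −z where z is the cohort-standardized
  log(CD8 density / CCR8+ Treg density); β > 0 makes low-ratio cases
  recur sooner, administratively censored at 60 months.

Setting s = b = g = 0 and β = 0 turns every mechanism off, giving the
calibration null. Identical (config, seed) reproduce outputs bit-exactly;
per-case substreams are derived by stable hashing of the case id.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon

from .exceptions import UsageError
from .io_tables import Panel, RegionAnnotation, classify_phenotypes


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic tissue and cohort generator.

    Intensities are in cells/mm², lengths in µm, hazards per month.
    Defaults describe a moderately infiltrated tumor: a 4×4 mm tumor
    region whose bottom edge is the invasion front, Treg intensity
    150/mm² with 35% CCR8 positivity (enriched 2.5-fold within 500 µm of
    the front), CD8 intensity 300/mm² with strong short-range exclusion
    (s = 1, τ = 20 µm), a granzyme-B logistic with mild local suppression,
    15 µm section-to-section jitter, and an exponential recurrence hazard
    giving roughly an 80% five-year recurrence-free fraction at β = 1.
    """

    seed: int = 0
    n_cases: int = 80
    region_um: tuple[float, float] = (4000.0, 4000.0)
    lambda_treg: float = 150.0
    p_ccr8: float = 0.35
    lambda_cd8: float = 300.0
    front_gradient: float = 1.5
    front_band_um: float = 500.0
    exclusion_strength: float = 1.0
    exclusion_decay_um: float = 20.0
    gzmb_base: float = 0.5
    gzmb_slope: float = 0.25
    gzmb_radius_um: float = 100.0
    section_jitter_um: float = 15.0
    case_effect_sd: float = 0.4
    p_ccr8_logit_sd: float = 0.5
    baseline_hazard: float = 0.004
    beta: float = 1.0
    censor_months: float = 60.0

    def __post_init__(self):
        if not (0.0 <= self.exclusion_strength <= 1.0):
            raise UsageError("exclusion_strength must lie in [0, 1]")
        if self.exclusion_decay_um <= 0:
            raise UsageError("exclusion_decay_um must be positive")
        if self.section_jitter_um < 0 or self.front_gradient < 0:
            raise UsageError("section_jitter_um and front_gradient must be ≥ 0")
        if self.baseline_hazard <= 0:
            raise UsageError("baseline_hazard must be positive")
        if min(self.lambda_treg, self.lambda_cd8) < 0:
            raise UsageError("intensities must be ≥ 0")

    @property
    def area_mm2(self) -> float:
        return self.region_um[0] * self.region_um[1] / 1e6


@dataclass
class SyntheticCohort:
    """A generated cohort: cell tables, annotations, clinical data, truth."""

    cells: pd.DataFrame
    regions: dict[str, RegionAnnotation]
    clinical: pd.DataFrame
    ground_truth: dict = field(repr=False, default_factory=dict)


def _case_rng(seed: int, case_id: str) -> np.random.Generator:
    # stable per-case substream: crc32 keeps the entropy below 2^32
    return np.random.default_rng([int(seed) % (2 ** 31), zlib.crc32(case_id.encode())])


def make_region(config: SyntheticConfig, case_id: str) -> RegionAnnotation:
    """Rectangular tumor region whose bottom edge is the invasion front."""
    w, h = config.region_um
    poly = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    front = LineString([(0, 0), (w, 0)])
    return RegionAnnotation(tumor_polygons=[poly], invasion_front=front,
                            case_id=case_id)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_tissue_pair(config: SyntheticConfig, case_id: str = "case_000",
                         rng: np.random.Generator | None = None,
                         treg_multiplier: float = 1.0,
                         cd8_multiplier: float = 1.0,
                         p_ccr8: float | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, RegionAnnotation, dict]:
    """Generate paired-panel cell tables for one case.

    Returns ``(cells_treg_panel, cells_cd8_panel, region, bookkeeping)``
    where both tables are phenotype-classified and the bookkeeping dict
    records the CD8 thinning balance (candidates = retained + removed).

    Raises
    ------
    UsageError
        Expected cell count above 10⁶ (shrink the region or intensities).
    """
    if rng is None:
        rng = _case_rng(config.seed, case_id)
    region = make_region(config, case_id)
    w, h = config.region_um
    area = config.area_mm2
    lam_treg = config.lambda_treg * treg_multiplier
    lam_cd8 = config.lambda_cd8 * cd8_multiplier
    if (lam_treg + lam_cd8) * area > 1e6:
        raise UsageError("expected cell count exceeds 1e6; reduce region size "
                         "or intensities")
    p_base = config.p_ccr8 if p_ccr8 is None else p_ccr8

    # Tregs: homogeneous Poisson, CCR8 label enriched near the front
    n_treg = rng.poisson(lam_treg * area)
    txy = rng.uniform([0, 0], [w, h], size=(n_treg, 2))
    front_d = txy[:, 1]  # front is the y = 0 edge
    p = np.where(front_d <= config.front_band_um,
                 p_base * (1.0 + config.front_gradient), p_base)
    p = np.clip(p, 0.0, 1.0)
    ccr8 = rng.uniform(size=n_treg) < p

    # CD8 candidates thinned near CCR8+ Tregs
    n_cand = rng.poisson(lam_cd8 * area)
    cxy = rng.uniform([0, 0], [w, h], size=(n_cand, 2))
    if ccr8.any() and n_cand:
        d, _ = cKDTree(txy[ccr8]).query(cxy, k=1)
        p_remove = config.exclusion_strength * np.exp(-d / config.exclusion_decay_um)
    else:
        p_remove = np.zeros(n_cand)
    keep = rng.uniform(size=n_cand) >= p_remove
    rxy = cxy[keep]
    n_ret = int(keep.sum())

    # GzmB positivity: logistic in the local CCR8+ Treg count
    if ccr8.any() and n_ret:
        rho = np.array([len(nb) for nb in
                        cKDTree(txy[ccr8]).query_ball_point(rxy,
                                                            r=config.gzmb_radius_um)])
    else:
        rho = np.zeros(n_ret)
    gzmb = rng.uniform(size=n_ret) < _sigmoid(config.gzmb_base
                                              - config.gzmb_slope * rho)

    # consecutive-section jitter on the CD8/GZMB panel positions
    oxy = rxy + rng.normal(scale=config.section_jitter_um, size=rxy.shape) \
        if config.section_jitter_um > 0 else rxy.copy()

    cells_tf = pd.DataFrame({
        "case_id": case_id, "panel": Panel.CCR8_FOXP3.value,
        "x_um": txy[:, 0], "y_um": txy[:, 1],
        "CCR8": ccr8, "FOXP3": np.ones(n_treg, bool),
    })
    cells_cg = pd.DataFrame({
        "case_id": case_id, "panel": Panel.CD8_GZMB.value,
        "x_um": oxy[:, 0], "y_um": oxy[:, 1],
        "CD8": np.ones(n_ret, bool), "GZMB": gzmb,
    })
    book = {"n_cd8_candidates": int(n_cand), "n_cd8_retained": n_ret,
            "n_cd8_removed": int(n_cand - n_ret),
            "n_treg": int(n_treg), "n_ccr8_treg": int(ccr8.sum())}
    return classify_phenotypes(cells_tf), classify_phenotypes(cells_cg), region, book


def _draw_survival(rng: np.random.Generator, risk: np.ndarray,
                   config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    rate = config.baseline_hazard * np.exp(config.beta * risk)
    t = rng.exponential(1.0 / rate)
    event = t <= config.censor_months
    return np.minimum(t, config.censor_months), event


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    # group-independent clinicopathological covariates (null by construction)
    return pd.DataFrame({
        "stage": rng.choice(["I", "II", "III"], size=n, p=[0.55, 0.25, 0.20]),
        "sex": rng.choice(["F", "M"], size=n, p=[0.4, 0.6]),
        "histology": rng.choice(["differentiated", "undifferentiated"],
                                size=n, p=[0.55, 0.45]),
        "vascular_invasion": rng.choice(["present", "absent"], size=n,
                                        p=[0.35, 0.65]),
        "lymphatic_invasion": rng.choice(["present", "absent"], size=n,
                                         p=[0.55, 0.45]),
        "preop_chemo": rng.choice(["treated", "not_treated"], size=n,
                                  p=[0.2, 0.8]),
    })


def generate_cohort(config: SyntheticConfig, spatial: bool = True,
                    ) -> SyntheticCohort:
    """Generate a full cohort: tissue pairs, clinical table, ground truth.

    Per case, intensities carry lognormal random effects
    (``case_effect_sd``) and the CCR8 fraction a logit-normal effect. The
    survival covariate is the cohort-standardized log CD8/CCR8+Treg density
    ratio; hazard follows the model in the module docstring.

    With ``spatial=False`` only per-case Poisson counts (no positions) are
    drawn — a fast count-level mode for survival simulation studies where
    cell positions are irrelevant; spatial mechanisms (s, g, b) do not act
    in this mode.

    Raises
    ------
    UsageError
        ``n_cases < 2``.
    """
    if config.n_cases < 2:
        raise UsageError("cohort generation requires n_cases ≥ 2")
    master = np.random.default_rng(int(config.seed) % (2 ** 31))
    case_ids = [f"case_{i:03d}" for i in range(config.n_cases)]
    cells_frames = []
    regions: dict[str, RegionAnnotation] = {}
    rows = []
    area = config.area_mm2
    for case_id in case_ids:
        rng = _case_rng(config.seed, case_id)
        m_treg = float(np.exp(rng.normal(0.0, config.case_effect_sd)))
        m_cd8 = float(np.exp(rng.normal(0.0, config.case_effect_sd)))
        logit = np.log(config.p_ccr8 / (1 - config.p_ccr8))
        p_ccr8 = float(_sigmoid(rng.normal(logit, config.p_ccr8_logit_sd)))
        if spatial:
            tf, cg, region, book = generate_tissue_pair(
                config, case_id, rng=rng, treg_multiplier=m_treg,
                cd8_multiplier=m_cd8, p_ccr8=p_ccr8)
            cells_frames += [tf, cg]
            regions[case_id] = region
            n_ccr8, n_cd8 = book["n_ccr8_treg"], book["n_cd8_retained"]
        else:
            n_treg = rng.poisson(config.lambda_treg * m_treg * area)
            n_ccr8 = rng.binomial(n_treg, p_ccr8) if n_treg else 0
            n_cd8 = rng.poisson(config.lambda_cd8 * m_cd8 * area)
            book = {"n_treg": int(n_treg), "n_ccr8_treg": int(n_ccr8),
                    "n_cd8_candidates": int(n_cd8), "n_cd8_retained": int(n_cd8),
                    "n_cd8_removed": 0}
        rows.append({"case_id": case_id, "m_treg": m_treg, "m_cd8": m_cd8,
                     "p_ccr8": p_ccr8, **book,
                     "ccr8_treg_density": n_ccr8 / area,
                     "cd8_density": n_cd8 / area})
    truth = pd.DataFrame(rows).set_index("case_id")

    # standardized log ratio; degenerate denominators fall back to 0.5 cells
    num = truth["cd8_density"].to_numpy().copy()
    den = truth["ccr8_treg_density"].to_numpy().copy()
    num[num == 0] = 0.5 / area
    den[den == 0] = 0.5 / area
    log_ratio = np.log(num / den)
    sd = log_ratio.std(ddof=1)
    z = (log_ratio - log_ratio.mean()) / (sd if sd > 0 else 1.0)
    risk = -z

    surv_rng = np.random.default_rng([int(config.seed) % (2 ** 31), 0xC0FFEE])
    rfs, event = _draw_survival(surv_rng, risk, config)
    if not event.any():
        import warnings
        warnings.warn("no events in generated cohort; survival analyses will "
                      "be underpowered")
    clinical = pd.DataFrame({"case_id": case_ids,
                             "rfs_months": rfs, "event": event.astype(int)})
    clinical = pd.concat([clinical,
                          _covariates(master, config.n_cases)], axis=1)
    cells = (pd.concat(cells_frames, ignore_index=True) if cells_frames
             else pd.DataFrame())
    ground_truth = {
        "config": asdict(config),
        "beta": config.beta,
        "exclusion_strength": config.exclusion_strength,
        "exclusion_decay_um": config.exclusion_decay_um,
        "front_gradient": config.front_gradient,
        "gzmb_slope": config.gzmb_slope,
        "per_case": truth.assign(z=z, risk=risk).reset_index().to_dict("records"),
    }
    return SyntheticCohort(cells=cells, regions=regions, clinical=clinical,
                           ground_truth=ground_truth)


def fixture_suite() -> dict:
    """Small deterministic datasets with hand-checkable answers.

    * ``nn345`` — one index cell at the origin, targets at (30, 40) and
      (100, 0): nearest-neighbor distance 50 (3-4-5 triangle).
    * ``hotspot1`` — 50 CCR8+ Tregs inside the single 500 µm window
      anchored at (500, 500) of a 2000×2000 µm region.
    * ``km4`` — survival times {6, 7, 10+, 15} with censoring at 10:
      S(7) = (3/4)·(2/3) = 0.5.
    """
    rng = np.random.default_rng(20_16)
    xy = 500.0 + rng.uniform(0.0, 499.0, size=(50, 2))
    hotspot_cells = classify_phenotypes(pd.DataFrame({
        "case_id": "hotspot1", "panel": Panel.CCR8_FOXP3.value,
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "CCR8": True, "FOXP3": True,
    }))
    region = RegionAnnotation(
        tumor_polygons=[Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])],
        case_id="hotspot1")
    return {
        "nn345": {"index": np.array([[0.0, 0.0]]),
                  "targets": np.array([[30.0, 40.0], [100.0, 0.0]])},
        "hotspot1": {"cells": hotspot_cells, "region": region,
                     "anchor": (500.0, 500.0), "count": 50},
        "km4": {"times": np.array([6.0, 7.0, 10.0, 15.0]),
                "events": np.array([True, True, False, True])},
    }
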