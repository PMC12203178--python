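"""Synthetic three-visit cohort generator.

Emulates the statistical structure the longitudinal analysis assumes: for
each region and modality, a subject's measurement at follow-up time ``t``
(years since baseline) is

    y = mu[group, roi] + b_subject + slope[group, roi] * t
        + beta_age * (age - mean age) + beta_sex * 1[male] + eps,

with a Gaussian random intercept ``b ~ N(0, sigma_b^2)`` shared across a
subject's visits and i.i.d. residuals ``eps ~ N(0, sigma_e^2)``.  Visit
times are drawn per design (default 2.1 +/- 0.2 y and 2.2 +/- 0.4 y
intervals); attrition keeps a nested random subset of subjects at later
visits.  Left/right hemisphere values decompose the subject-visit value
symmetrically (``L = y + d/2, R = y - d/2``) so that the reported
left-right average equals the latent value exactly while the two sides have
a configurable offset and cross-sectional correlation.  QSM and R2* for the
same region share correlated subject intercepts and residuals.

The shipped defaults (``cohort_defaults.yaml``) are paper-derived: group
sizes, ages, sex proportions and baseline QSM means/SDs per nigral territory
follow the published visit-1 cohort table, and the only nonzero annual
slopes are the Parkinson-group posteroventral ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = ["GroupSpec", "MeasureSpec", "CohortDesign", "default_design", "simulate_cohort"]

GROUPS = ("HV", "iRBD", "PD")
MODALITIES = ("qsm_ppm", "r2s_hz")


@dataclass
class GroupSpec:
    name: str
    n_per_visit: tuple[int, ...]
    age_mean: float
    age_sd: float
    male_prop: float

    def __post_init__(self) -> None:
        ns = tuple(int(n) for n in self.n_per_visit)
        if any(b > a for a, b in zip(ns, ns[1:])):
            raise ValueError(f"group {self.name}: sample sizes must be non-increasing")
        if not 0.0 <= self.male_prop <= 1.0:
            raise ValueError(f"group {self.name}: sex proportion must be in [0, 1]")
        if self.age_sd < 0:
            raise ValueError(f"group {self.name}: age SD must be >= 0")
        self.n_per_visit = ns


@dataclass
class MeasureSpec:
    """Baseline mean/SD and annual slope per group for one (roi, modality)."""

    roi: str
    modality: str
    mean: dict[str, float]
    sd: dict[str, float]
    slope: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd.values()):
            raise ValueError(f"{self.roi}/{self.modality}: SDs must be >= 0")


@dataclass
class CohortDesign:
    groups: list[GroupSpec]
    measures: list[MeasureSpec]
    visit_intervals: tuple[tuple[float, float], ...] = ((2.1, 0.2), (2.2, 0.4))
    between_subject_fraction: float = 0.8
    modality_corr: float = 0.88
    beta_age: float = 0.0
    beta_sex_male: dict[str, float] = field(default_factory=lambda: {"qsm_ppm": 0.0, "r2s_hz": 0.0})
    lateral_offset: float = 0.0
    lateral_corr: float = 0.85
    age_range: tuple[float, float] = (18.0, 80.0)
    covariates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        unknown = set(names) - set(GROUPS)
        if unknown:
            raise ValueError(f"inconsistent group labels: {sorted(unknown)} (expect {GROUPS})")
        if not 0.0 < self.between_subject_fraction <= 1.0:
            raise ValueError("between_subject_fraction must be in (0, 1]")
        if not 0.0 < self.lateral_corr <= 1.0:
            raise ValueError("lateral correlation must be in (0, 1]")


def default_design(seed: int = 0, rois: list[str] | None = None) -> CohortDesign:
    """Load the shipped paper-derived default design."""
    with resources.files("nigraq.data").joinpath("cohort_defaults.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    return design_from_config(cfg, seed=seed, rois=rois)


def design_from_config(cfg: dict, seed: int = 0, rois: list[str] | None = None) -> CohortDesign:
    groups = [
        GroupSpec(
            name,
            tuple(g["n_per_visit"]),
            float(g["age_mean"]),
            float(g["age_sd"]),
            float(g["male_prop"]),
        )
        for name, g in cfg["groups"].items()
    ]
    measures = []
    for modality in MODALITIES:
        block = cfg.get(modality)
        if not block:
            continue
        for roi, means in block["mean"].items():
            if rois is not None and roi not in rois:
                continue
            measures.append(
                MeasureSpec(
                    roi,
                    modality,
                    {k: float(v) for k, v in means.items()},
                    {k: float(v) for k, v in block["sd"][roi].items()},
                    {
                        k: float(v)
                        for k, v in block.get("slope_per_year", {}).get(roi, {}).items()
                    },
                )
            )
    cov_eff = cfg.get("covariate_effects", {})
    lat = cfg.get("lateral", {})
    return CohortDesign(
        groups=groups,
        measures=measures,
        visit_intervals=tuple((v["mean"], v["sd"]) for v in cfg["visit_intervals"]),
        between_subject_fraction=float(cfg.get("between_subject_fraction", 0.8)),
        modality_corr=float(cfg.get("modality_corr", 0.88)),
        beta_age=float(cov_eff.get("beta_age", 0.0)),
        beta_sex_male={k: float(v) for k, v in cov_eff.get("beta_sex_male", {}).items()},
        lateral_offset=float(lat.get("offset", 0.0)),
        lateral_corr=float(lat.get("correlation", 0.85)),
        age_range=tuple(cfg.get("age_range", (18.0, 80.0))),
        covariates=cfg.get("covariates", {}),
        seed=seed,
    )


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    tries = 0
    while bad.any() and tries < 100:
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
        tries += 1
    return np.clip(out, lo, hi)


def simulate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format cohort table and the generating-truth record.

    One row per (subject, visit, roi, side) with side in {left, right, mean};
    the side == "mean" value is the exact left-right average.  Deterministic
    given ``design.seed``.
    """
    fb = design.between_subject_fraction
    frac_e = float(np.sqrt(max(1.0 - fb * fb, 0.0)))
    if design.measures and all(
        all(s == 0 for s in m.sd.values()) for m in design.measures
    ):
        warnings.warn("all measure variance components are zero; trajectories are deterministic")
    rng = np.random.default_rng(design.seed)
    n_visits = len(design.visit_intervals) + 1

    pooled_age = np.average(
        [g.age_mean for g in design.groups], weights=[g.n_per_visit[0] for g in design.groups]
    )

    # correlated standard deviates across the two modalities of the same ROI
    rho_m = design.modality_corr
    rois = sorted({m.roi for m in design.measures})
    by_key = {(m.roi, m.modality): m for m in design.measures}

    rows: list[dict] = []
    truth: dict = {
        "seed": design.seed,
        "pooled_age_mean": float(pooled_age),
        "measures": {
            f"{m.roi}:{m.modality}": {"mean": m.mean, "sd": m.sd, "slope": m.slope}
            for m in design.measures
        },
        "beta_age": design.beta_age,
        "beta_sex_male": dict(design.beta_sex_male),
        "between_subject_fraction": fb,
    }

    sid = 0
    for g in design.groups:
        n1 = g.n_per_visit[0]
        ages = _truncnorm(rng, g.age_mean, g.age_sd, *design.age_range, size=n1)
        male = rng.random(n1) < g.male_prop
        # nested attrition: a fixed random order; later visits keep a prefix
        order = rng.permutation(n1)
        rank = np.empty(n1, dtype=int)
        rank[order] = np.arange(n1)

        times = np.zeros((n1, n_visits))
        for v, (mu_iv, sd_iv) in enumerate(design.visit_intervals, start=1):
            times[:, v] = times[:, v - 1] + np.maximum(rng.normal(mu_iv, sd_iv, n1), 0.1)

        # per-(subject, roi): correlated modality deviates for intercept...
        zb = {}
        ze = {}
        for roi in rois:
            z1 = rng.standard_normal(n1)
            z2 = rho_m * z1 + np.sqrt(max(1 - rho_m**2, 0.0)) * rng.standard_normal(n1)
            zb[roi] = {"qsm_ppm": z1, "r2s_hz": z2}
            e1 = rng.standard_normal((n1, n_visits))
            e2 = rho_m * e1 + np.sqrt(max(1 - rho_m**2, 0.0)) * rng.standard_normal(
                (n1, n_visits)
            )
            ze[roi] = {"qsm_ppm": e1, "r2s_hz": e2}

        # covariates linked to the posteroventral QSM subject deviate
        link_z = zb.get("posteroventral", {}).get("qsm_ppm", rng.standard_normal(n1))
        cov_vals: dict[str, np.ndarray] = {}
        for cname, cspec in design.covariates.items():
            spec_g = cspec.get("groups", {}).get(g.name)
            if spec_g is None:
                cov_vals[cname] = np.full(n1, np.nan)
                continue
            rho_c = float(cspec.get("corr_with_posteroventral_qsm", 0.0))
            z = rho_c * link_z + np.sqrt(max(1 - rho_c**2, 0.0)) * rng.standard_normal(n1)
            val = spec_g["mean"] + spec_g["sd"] * z
            if "min" in cspec:
                val = np.maximum(val, float(cspec["min"]))
            cov_vals[cname] = val

        for i in range(n1):
            subj = f"{g.name}{sid:04d}"
            sid += 1
            for v in range(n_visits):
                if rank[i] >= g.n_per_visit[v]:
                    continue  # dropped out from this visit on (nested subset)
                t = 0.0 if v == 0 else float(times[i, v])
                for roi in rois:
                    rec = {
                        "subject_id": subj,
                        "group": g.name,
                        "visit_index": v + 1,
                        "time_years": t,
                        "age_baseline": float(ages[i]),
                        "sex": "M" if male[i] else "F",
                        "roi_name": roi,
                    }
                    vals = {}
                    for modality in MODALITIES:
                        ms = by_key.get((roi, modality))
                        if ms is None or g.name not in ms.mean:
                            vals[modality] = (np.nan, np.nan, np.nan)
                            continue
                        sd_tot = ms.sd[g.name]
                        sigma_b = fb * sd_tot
                        sigma_e = frac_e * sd_tot
                        y = (
                            ms.mean[g.name]
                            + sigma_b * zb[roi][modality][i]
                            + ms.slope.get(g.name, 0.0) * t
                            + design.beta_age * (ages[i] - pooled_age)
                            + design.beta_sex_male.get(modality, 0.0) * (1.0 if male[i] else 0.0)
                            + sigma_e * ze[roi][modality][i, v]
                        )
                        var_y = sd_tot**2
                        sd_d = np.sqrt(
                            4.0 * var_y * (1 - design.lateral_corr) / (1 + design.lateral_corr)
                        )
                        d = design.lateral_offset + sd_d * rng.standard_normal()
                        vals[modality] = (y + d / 2.0, y - d / 2.0, y)
                    for cname, arr in cov_vals.items():
                        cval = arr[i]
                        if cname == "disease_duration_years" and np.isfinite(cval):
                            cval = cval + t  # duration advances with follow-up time
                        rec[cname] = float(cval) if np.isfinite(cval) else np.nan
                    for si, side in enumerate(("left", "right", "mean")):
                        row = dict(rec)
                        row["side"] = side
                        for modality in MODALITIES:
                            row[modality] = float(vals[modality][si])
                        rows.append(row)

    table = pd.DataFrame(rows)
    keys = ["subject_id", "visit_index", "roi_name", "side"]
    if table.duplicated(subset=keys).any():
        raise AssertionError("duplicated (subject, visit, roi, side) keys")
    return table, truth
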