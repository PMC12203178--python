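"""Cohort statistics for nigral iron measures.

Mirrors the standard longitudinal-biomarker analysis stack:

* baseline per-ROI ordinary least squares ``value ~ Group + age + sex`` with
  a partial F-test for Group and Tukey-adjusted pairwise contrasts on
  estimated marginal means (covariates held at their sample means);
* linear mixed-effects models with fixed Group, Visit (years), Group x Visit,
  age and sex, and a per-subject random intercept, tested by type-II Wald
  chi-square statistics; per-group time slopes with delta-method CIs and
  Tukey-adjusted pairwise slope contrasts;
* Pearson correlation families with Benjamini-Hochberg FDR adjustment within
  each declared family, plus leave-one-out influence analysis;
* left-right symmetry checks (exact Wilcoxon signed-rank for n <= 25,
  normal approximation with tie/continuity correction above) and Pearson
  correlation between hemispheres;
* demographics: one-way ANOVA (classic or Welch) with Tukey HSD, and k-group
  chi-square with Holm- or Bonferroni-corrected pairwise proportion tests.

statsmodels provides the underlying OLS/MixedLM fits and p-value adjustment;
the marginal-means, type-II Wald and slope-contrast layer is computed here
from the fitted coefficient covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .roi import pct_rate_change

__all__ = [
    "BaselineResult",
    "LongitudinalResult",
    "baseline_group_model",
    "fit_longitudinal_lmm",
    "estimate_group_slopes",
    "correlation_family",
    "loo_sensitivity",
    "lateral_symmetry_check",
    "demographics_tests",
    "benjamini_hochberg",
    "tukey_pvalue",
]

GROUP_ORDER = ("HV", "iRBD", "PD")


def tukey_pvalue(t_stat: float, n_groups: int, df: float) -> float:
    """Tukey (studentized-range) adjusted p for a pairwise contrast t statistic.

    For two groups the studentized-range law collapses to the t law, so the
    exact two-sided t-test p is returned (avoids the quadrature error of the
    general routine on a case with a closed form).
    """
    t = abs(float(t_stat))
    if n_groups <= 2:
        return float(2.0 * sps.t.sf(t, df))
    return float(np.clip(sps.studentized_range.sf(t * np.sqrt(2.0), n_groups, df), 0.0, 1.0))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Baseline cross-sectional model
# ---------------------------------------------------------------------------


@dataclass
class BaselineResult:
    roi: str
    modality: str
    f_stat: float
    df_num: int
    df_den: int
    p_group: float
    emmeans: dict[str, float]
    contrasts: pd.DataFrame  # difference, SE, t, p_tukey, pct_vs columns
    covariate_tests: dict[str, tuple[float, float]]  # name -> (F, p)
    n: int


def _design_matrix(df: pd.DataFrame, groups: list[str], with_group: bool = True):
    """Treatment-coded design: intercept, group dummies (ref = first), age, sexM."""
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    if with_group:
        for g in groups[1:]:
            cols.append((df["group"] == g).astype(float).to_numpy())
            names.append(f"group[{g}]")
    cols.append(df["age_baseline"].to_numpy(dtype=float))
    names.append("age")
    cols.append((df["sex"] == "M").astype(float).to_numpy())
    names.append("sexM")
    return np.column_stack(cols), names


def baseline_group_model(
    table: pd.DataFrame,
    roi: str,
    modality: str = "qsm_ppm",
    side: str = "mean",
) -> BaselineResult:
    """Cross-sectional group comparison at visit 1 for one ROI and modality.

    OLS of ``value ~ Group + age + sex``; the group effect is a partial
    F-test; pairwise contrasts are formed on estimated marginal means
    (covariates at sample means, which leaves contrasts equal to coefficient
    differences) with Tukey adjustment; percent differences versus the
    reference group use the shared percentage-rate-of-change code path.
    """
    d = table[
        (table["visit_index"] == 1)
        & (table["roi_name"] == roi)
        & (table["side"] == side)
    ].dropna(subset=[modality, "age_baseline", "sex"])
    groups = [g for g in GROUP_ORDER if g in set(d["group"])]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups at baseline")
    y = d[modality].to_numpy(dtype=float)
    x_full, names = _design_matrix(d, groups, with_group=True)
    n, k = x_full.shape
    if n <= k + 2:
        raise ValueError(f"too few observations (n={n}) for {k} parameters")
    rank = np.linalg.matrix_rank(x_full)
    if rank < k:
        # name the aliased column (first linearly dependent one)
        for j in range(1, k):
            if np.linalg.matrix_rank(x_full[:, : j + 1]) < j + 1:
                raise ValueError(f"rank-deficient design: column {names[j]!r} is aliased")
        raise ValueError("rank-deficient design")

    full = sm.OLS(y, x_full).fit()
    x_red, _ = _design_matrix(d, groups, with_group=False)
    red = sm.OLS(y, x_red).fit()
    df_num = len(groups) - 1
    df_den = int(full.df_resid)
    f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p_group = float(sps.f.sf(f_stat, df_num, df_den))

    beta = full.params
    cov = full.cov_params()
    age_mean = float(d["age_baseline"].mean())
    sexm_mean = float((d["sex"] == "M").mean())
    idx = {nm: j for j, nm in enumerate(names)}
    base = beta[idx["Intercept"]] + beta[idx["age"]] * age_mean + beta[idx["sexM"]] * sexm_mean
    emm = {groups[0]: float(base)}
    for g in groups[1:]:
        emm[g] = float(base + beta[idx[f"group[{g}]"]])

    # contrast vectors in coefficient space (covariates cancel)
    def cvec(g):
        v = np.zeros(len(names))
        if g != groups[0]:
            v[idx[f"group[{g}]"]] = 1.0
        return v

    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            c = cvec(gb) - cvec(ga)
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = diff / se
            rows.append(
                {
                    "contrast": f"{gb} - {ga}",
                    "difference": diff,
                    "se": se,
                    "t": t,
                    "p_tukey": tukey_pvalue(t, len(groups), df_den),
                }
            )
    contrasts = pd.DataFrame(rows)

    cov_tests = {}
    for nm in ("age", "sexM"):
        j = idx[nm]
        t = beta[j] / np.sqrt(cov[j, j])
        cov_tests[nm] = (float(t**2), float(2 * sps.t.sf(abs(t), df_den)))

    ref = groups[0]
    pct = {g: pct_rate_change(emm[ref], emm[g]) for g in groups if g != ref}
    contrasts["pct_vs_ref"] = [
        pct[r["contrast"].split(" - ")[0]]
        if r["contrast"].endswith(f"- {ref}")
        else np.nan
        for _, r in contrasts.iterrows()
    ]
    return BaselineResult(
        roi, modality, float(f_stat), df_num, df_den, p_group, emm, contrasts, cov_tests, n
    )


# ---------------------------------------------------------------------------
# Longitudinal mixed model
# ---------------------------------------------------------------------------


@dataclass
class LongitudinalResult:
    roi: str
    modality: str
    wald: dict[str, tuple[float, int, float]]  # term -> (chi2, df, p)
    slopes: pd.DataFrame  # group, slope, se, ci_low, ci_high, p
    slope_contrasts: pd.DataFrame
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_b2: float
    sigma_e2: float
    n_subjects: int
    n_obs: int
    n_singleton_excluded: int
    converged: bool
    boundary: bool = False


def _lmm_design(d: pd.DataFrame, groups: list[str], interaction: bool):
    cols = [np.ones(len(d))]
    names = ["Intercept"]
    for g in groups[1:]:
        cols.append((d["group"] == g).astype(float).to_numpy())
        names.append(f"group[{g}]")
    cols.append(d["time_years"].to_numpy(dtype=float))
    names.append("time")
    if interaction:
        for g in groups[1:]:
            cols.append(
                ((d["group"] == g).astype(float) * d["time_years"]).to_numpy(dtype=float)
            )
            names.append(f"group[{g}]:time")
    cols.append(d["age_baseline"].to_numpy(dtype=float))
    names.append("age")
    cols.append((d["sex"] == "M").astype(float).to_numpy())
    names.append("sexM")
    return np.column_stack(cols), names


def _fit_mixed(y, x, names, subjects):
    last_err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                model = sm.MixedLM(y, x, groups=subjects)
                return model.fit(reml=True, method=method, maxiter=300)
            except np.linalg.LinAlgError as e:  # optimizer walked into a singular V
                last_err = e
    raise RuntimeError(f"mixed model fit failed with all optimizers: {last_err}")


def fit_longitudinal_lmm(
    table: pd.DataFrame,
    roi: str,
    modality: str = "qsm_ppm",
    side: str = "mean",
) -> LongitudinalResult:
    """Random-intercept LMM of one ROI/modality over follow-up time.

    Subjects with a single visit are excluded (count recorded).  Type-II
    Wald chi-square tests respect marginality: Group and Visit are tested in
    the additive model (other main effect and covariates present, no
    interaction), the Group x Visit interaction in the full model.  Per-group
    slopes and their Tukey-adjusted pairwise contrasts come from the full
    model's coefficients and covariance (delta method; asymptotic normal).
    """
    d = table[(table["roi_name"] == roi) & (table["side"] == side)].dropna(
        subset=[modality, "age_baseline", "sex", "time_years"]
    )
    visits_per_subject = d.groupby("subject_id")["visit_index"].nunique()
    keep = visits_per_subject[visits_per_subject >= 2].index
    n_singleton = int((visits_per_subject < 2).sum())
    d = d[d["subject_id"].isin(keep)]
    if d.empty:
        raise ValueError("no subjects with >= 2 visits")
    groups = [g for g in GROUP_ORDER if g in set(d["group"])]
    d = d.copy()
    d["age_baseline"] = d["age_baseline"] - d["age_baseline"].mean()
    y_raw = d[modality].to_numpy(dtype=float)
    # standardize the response for optimizer conditioning; estimates are
    # transformed back (Wald statistics are invariant to this rescaling)
    y_loc = float(y_raw.mean())
    y_scale = float(y_raw.std()) or 1.0
    y = (y_raw - y_loc) / y_scale
    subjects = d["subject_id"].to_numpy()

    x_full, names_full = _lmm_design(d, groups, interaction=True)
    res_full = _fit_mixed(y, x_full, names_full, subjects)
    x_add, names_add = _lmm_design(d, groups, interaction=False)
    res_add = _fit_mixed(y, x_add, names_add, subjects)

    k_fe_full = len(names_full)
    beta_full = np.asarray(res_full.fe_params) * y_scale
    beta_full[0] += y_loc
    cov_full = np.asarray(res_full.cov_params())[:k_fe_full, :k_fe_full] * y_scale**2
    k_fe_add = len(names_add)
    beta_add = np.asarray(res_add.fe_params) * y_scale
    beta_add[0] += y_loc
    cov_add = np.asarray(res_add.cov_params())[:k_fe_add, :k_fe_add] * y_scale**2

    def wald_block(beta, cov, names, block):
        jj = [names.index(nm) for nm in block]
        b = beta[jj]
        v = cov[np.ix_(jj, jj)]
        chi2 = float(b @ np.linalg.solve(v, b))
        df = len(jj)
        return chi2, df, float(sps.chi2.sf(chi2, df))

    wald = {
        "Group": wald_block(beta_add, cov_add, names_add, [f"group[{g}]" for g in groups[1:]]),
        "Visit": wald_block(beta_add, cov_add, names_add, ["time"]),
        "Group:Visit": wald_block(
            beta_full, cov_full, names_full, [f"group[{g}]:time" for g in groups[1:]]
        ),
        "age": wald_block(beta_add, cov_add, names_add, ["age"]),
        "sexM": wald_block(beta_add, cov_add, names_add, ["sexM"]),
    }

    # per-group slope = d E[y] / d t: reference slope + interaction coefficient
    idx = {nm: j for j, nm in enumerate(names_full)}
    z = sps.norm.ppf(0.975)
    slope_rows = []
    cvecs = {}
    for g in groups:
        c = np.zeros(k_fe_full)
        c[idx["time"]] = 1.0
        if g != groups[0]:
            c[idx[f"group[{g}]:time"]] = 1.0
        cvecs[g] = c
        s = float(c @ beta_full)
        se = float(np.sqrt(c @ cov_full @ c))
        slope_rows.append(
            {
                "group": g,
                "slope": s,
                "se": se,
                "ci_low": s - z * se,
                "ci_high": s + z * se,
                "p": float(2 * sps.norm.sf(abs(s / se))),
            }
        )
    slopes = pd.DataFrame(slope_rows)

    df_approx = len(y) - k_fe_full
    contrast_rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            c = cvecs[gb] - cvecs[ga]
            diff = float(c @ beta_full)
            se = float(np.sqrt(c @ cov_full @ c))
            t = diff / se
            contrast_rows.append(
                {
                    "contrast": f"{gb} - {ga}",
                    "difference": diff,
                    "se": se,
                    "t": t,
                    "p_tukey": tukey_pvalue(t, len(groups), df_approx),
                }
            )

    sigma_b2 = (
        float(np.asarray(res_full.cov_re).ravel()[0]) * y_scale**2
        if res_full.cov_re.size
        else 0.0
    )
    sigma_e2 = float(res_full.scale) * y_scale**2
    boundary = sigma_b2 <= 1e-10
    if not res_full.converged:
        grad = getattr(res_full, "score_norm", None)
        raise RuntimeError(f"mixed model did not converge (gradient norm: {grad})")
    return LongitudinalResult(
        roi,
        modality,
        wald,
        slopes,
        pd.DataFrame(contrast_rows),
        pd.Series(beta_full, index=names_full),
        pd.DataFrame(cov_full, index=names_full, columns=names_full),
        sigma_b2,
        sigma_e2,
        int(d["subject_id"].nunique()),
        len(y),
        n_singleton,
        bool(res_full.converged),
        boundary,
    )


def estimate_group_slopes(fit: LongitudinalResult) -> pd.DataFrame:
    """Slope table (per-group annual change, CI, p) of a fitted mixed model."""
    out = fit.slopes.copy()
    out["roi"] = fit.roi
    out["modality"] = fit.modality
    return out


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def correlation_family(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    group_by: str | None = "group",
    family_id: str = "family",
) -> pd.DataFrame:
    """Pearson correlations for a family of (x, y) pairs with BH adjustment.

    Complete cases per pair; pairs with zero variance (or n < 3) are
    reported as undefined and excluded from the family size used by the
    Benjamini-Hochberg step-up.
    """
    rows = []
    frames = [("all", table)] if group_by is None else list(table.groupby(group_by))
    for gname, gdf in frames:
        for x, y in pairs:
            sub = gdf[[x, y]].dropna()
            n = len(sub)
            if n < 3 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
                rows.append(
                    {"family": family_id, "group": gname, "x": x, "y": y, "n": n,
                     "r": np.nan, "p": np.nan, "defined": False}
                )
                continue
            r, p = sps.pearsonr(sub[x], sub[y])
            rows.append(
                {"family": family_id, "group": gname, "x": x, "y": y, "n": n,
                 "r": float(r), "p": float(p), "defined": True}
            )
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    ok = out["defined"].to_numpy()
    if ok.any():
        out.loc[ok, "p_bh"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out


def loo_sensitivity(x, y, threshold: float = 0.1):
    """Leave-one-out influence of single points on a Pearson correlation.

    Returns ``(influential_index, r_full, r_without, p_without, influences)``
    where ``influential_index`` is the point whose removal changes r the most
    (None when no removal changes r by more than ``threshold``).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    r_full, _ = sps.pearsonr(x, y)
    influences = np.zeros(n)
    r_loo = np.zeros(n)
    p_loo = np.zeros(n)
    for i in range(n):
        xi = np.delete(x, i)
        yi = np.delete(y, i)
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            influences[i] = np.nan
            r_loo[i] = np.nan
            p_loo[i] = np.nan
            continue
        r, p = sps.pearsonr(xi, yi)
        influences[i] = abs(r_full - r)
        r_loo[i] = r
        p_loo[i] = p
    if np.all(np.isnan(influences)):
        return None, float(r_full), float("nan"), float("nan"), influences
    j = int(np.nanargmax(influences))
    if influences[j] <= threshold:
        return None, float(r_full), float(r_loo[j]), float(p_loo[j]), influences
    return j, float(r_full), float(r_loo[j]), float(p_loo[j]), influences


# ---------------------------------------------------------------------------
# Left-right symmetry
# ---------------------------------------------------------------------------


def lateral_symmetry_check(
    table: pd.DataFrame,
    roi: str,
    modality: str = "qsm_ppm",
    visit: int = 1,
    group: str | None = None,
):
    """Wilcoxon signed-rank p for left vs right plus the inter-side Pearson r.

    Exact signed-rank distribution for n <= 25 pairs (zeros dropped, the
    Wilcoxon convention), normal approximation with continuity and tie
    correction above.  All-zero differences give p = 1 with a flag.
    """
    d = table[
        (table["roi_name"] == roi)
        & (table["visit_index"] == visit)
        & (table["side"].isin(["left", "right"]))
    ]
    if group is not None:
        d = d[d["group"] == group]
    wide = d.pivot_table(index="subject_id", columns="side", values=modality)
    wide = wide.dropna()
    if len(wide) < 5:
        raise ValueError("need >= 5 complete left/right pairs")
    left = wide["left"].to_numpy()
    right = wide["right"].to_numpy()
    diffs = left - right
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return {"p_wilcoxon": 1.0, "r_sides": float(sps.pearsonr(left, right)[0]),
                "n_pairs": len(wide), "all_zero": True}
    if nz.size <= 25:
        p = wilcoxon_signed_rank_exact(nz)
    else:
        p = float(
            sps.wilcoxon(nz, zero_method="wilcox", correction=True, method="approx").pvalue
        )
    return {
        "p_wilcoxon": float(p),
        "r_sides": float(sps.pearsonr(left, right)[0]),
        "n_pairs": len(wide),
        "all_zero": False,
    }


def wilcoxon_signed_rank_exact(diffs) -> float:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Handles tied absolute differences through midranks; the distribution of
    W+ is built by dynamic programming on doubled midranks (always integer),
    which is equivalent to full enumeration of the sign flips.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks2 = np.rint(2.0 * sps.rankdata(np.abs(d))).astype(int)
    w_plus2 = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    counts /= 2.0**n
    p_le = float(counts[: w_plus2 + 1].sum())
    p_ge = float(counts[w_plus2:].sum())
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------


def welch_anova(samples: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df1, df2, p)."""
    k = len(samples)
    ns = np.array([len(s) for s in samples], float)
    means = np.array([np.mean(s) for s in samples])
    variances = np.array([np.var(s, ddof=1) for s in samples])
    w = ns / variances
    sw = w.sum()
    mw = (w * means).sum() / sw
    a = ((w * (means - mw) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / sw) ** 2 / (ns - 1)).sum() / (k**2 - 1)
    f = a / (1 + 2 * lam * (k - 2) / 3)
    df1 = k - 1
    df2 = 1.0 / lam
    return float(f), float(df1), float(df2), float(sps.f.sf(f, df1, df2))


def demographics_tests(
    table: pd.DataFrame,
    continuous: list[str] = ("age_baseline",),
    categorical: list[str] = ("sex",),
    visit: int = 1,
    anova: str = "classic",
    proportion_adjust: str = "holm",
) -> dict:
    """Group comparisons of demographic variables at one visit.

    Continuous variables: one-way ANOVA (``anova`` in {"classic", "welch"})
    with Tukey HSD pairwise tests.  Categorical variables: k-group chi-square
    plus pairwise 2x2 chi-square tests adjusted by Holm (default) or
    Bonferroni.  Expected cell counts below 1 trigger a warning recommending
    an exact test.
    """
    subj = table
    if "visit_index" in table:
        subj = table[table["visit_index"] == visit]
    subj = subj.drop_duplicates("subject_id")
    groups = [g for g in GROUP_ORDER if g in set(subj["group"])]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    out: dict = {"groups": groups, "continuous": {}, "categorical": {}}

    for var in continuous:
        samples = [subj.loc[subj["group"] == g, var].dropna().to_numpy() for g in groups]
        if anova == "welch":
            f, df1, df2, p = welch_anova(samples)
        else:
            f, p = sps.f_oneway(*samples)
            df1 = len(groups) - 1
            df2 = sum(len(s) for s in samples) - len(groups)
        tk = sps.tukey_hsd(*samples)
        pairs = {}
        for i, ga in enumerate(groups):
            for j in range(i + 1, len(groups)):
                pairs[f"{groups[j]} - {ga}"] = float(tk.pvalue[i, j])
        out["continuous"][var] = {
            "anova": anova, "F": float(f), "df": (float(df1), float(df2)),
            "p": float(p), "tukey_pairwise": pairs,
        }

    for var in categorical:
        tab = pd.crosstab(subj["group"], subj[var]).reindex(groups)
        chi2, p, dof, expected = sps.chi2_contingency(tab.to_numpy())
        if (expected < 1).any():
            warnings.warn(
                f"{var}: expected cell count < 1; an exact test is recommended",
                stacklevel=2,
            )
        raw = []
        labels = []
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                sub = tab.loc[[ga, gb]].to_numpy()
                c2, pp, _, _ = sps.chi2_contingency(sub)
                raw.append(pp)
                labels.append(f"{gb} - {ga}")
        adj = multipletests(raw, method=proportion_adjust)[1] if raw else []
        out["categorical"][var] = {
            "chi2": float(chi2), "df": int(dof), "p": float(p),
            "pairwise": dict(zip(labels, [float(a) for a in adj])),
            "adjust": proportion_adjust,
        }
    return out
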