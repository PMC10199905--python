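"""Tracking capacity and the behavioral statistical battery.

The multiple-object-tracking capacity statistic corrects the proportion of
correctly identified targets for guessing: with n targets among d discs the
success model is p = n/d (m/n + d/2), which rearranges to m = n (d p - d/2),
bounded by [-d/2, d/2]; m is affinely rescaled to m' in [-1, 1] so 4-disc
and 8-disc conditions are comparable. The battery around it: mixed / fully
repeated-measures two-way ANOVA with sphericity handling (Mauchly,
Greenhouse-Geisser) and generalized eta squared, Tukey-style post-hocs,
1.5 x IQR outlier sensitivity reruns, Cronbach's alpha, and a BIC-based
approximation of the Bayes factor in favor of the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TrackingRecord:
    """Per subject x condition tracking summary."""

    subject_id: str
    condition: str
    n: int
    d: int
    p: float
    m: float
    m_prime: float


def proportion_correct(trials: pd.DataFrame) -> float:
    """Mean of the correct flags for one subject x condition."""
    if len(trials) == 0:
        raise ValueError("no trials supplied")
    return float(trials["correct"].mean())


def tracking_capacity(p: float, n: int = 1, d: int = 4) -> float:
    """Effective number of targets tracked: m = n (d p - d/2)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("proportion correct must lie in [0, 1]")
    return float(n * (d * p - d / 2.0))


def rescale_capacity(m: float, d: int) -> float:
    """Affine map of [-d/2, d/2] onto [-1, 1]: m' = -1 + 2 (m - min) / (max - min)."""
    lo, hi = -d / 2.0, d / 2.0
    if not (lo - 1e-12 <= m <= hi + 1e-12):
        raise ValueError(f"m must lie in [{lo}, {hi}] for d = {d}")
    return float(-1.0 + 2.0 * (m - lo) / (hi - lo))


def tracking_records(behavior: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial table into per subject x condition (p, m, m')."""
    rows = []
    for (sid, cond), grp in behavior.groupby(["subject_id", "condition"], sort=False):
        n = int(grp["n"].iloc[0])
        d = int(grp["d"].iloc[0])
        p = proportion_correct(grp)
        m = tracking_capacity(p, n, d)
        rows.append({"subject_id": sid,
                     "group": grp["group"].iloc[0] if "group" in grp else "",
                     "condition": cond, "n": n, "d": d, "p": p, "m": m,
                     "m_prime": rescale_capacity(m, d)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA battery

@dataclass
class RmAnovaResult:
    """Two-way (mixed or fully repeated) ANOVA with diagnostics."""

    effects: dict                    # name -> {F, df, p, ng2, np2, p_gg}
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    shapiro_w: float
    shapiro_p: float
    tukey: pd.DataFrame
    sensitivity: dict | None = None


def _safe_shapiro(resid: np.ndarray):
    """Shapiro-Wilk, degenerate (near-constant residuals) reported as (1, 1)."""
    if resid.std() < 1e-12:
        return 1.0, 1.0
    w, p = stats.shapiro(resid)
    return float(w), float(p)


def _mixed_anova_ss(wide: np.ndarray, groups: np.ndarray):
    """Split-plot sums of squares; wide is subjects x within-levels."""
    n, k = wide.shape
    glabels = np.unique(groups)
    grand = wide.mean()
    m_s = wide.mean(axis=1)
    m_c = wide.mean(axis=0)
    ss_between_subj = k * ((m_s - grand) ** 2).sum()
    ss_group = sum(k * (groups == g).sum() * (wide[groups == g].mean() - grand) ** 2
                   for g in glabels)
    ss_sw = ss_between_subj - ss_group          # subjects within groups
    ss_within = ((wide - m_s[:, None]) ** 2).sum()
    ss_cond = n * ((m_c - grand) ** 2).sum()
    ss_int = 0.0
    for g in glabels:
        sel = groups == g
        m_gc = wide[sel].mean(axis=0)
        m_g = wide[sel].mean()
        ss_int += sel.sum() * ((m_gc - m_g - m_c + grand) ** 2).sum()
    ss_ew = ss_within - ss_cond - ss_int        # condition x subjects(group)
    ngroups = len(glabels)
    return {
        "group": (ss_group, ngroups - 1, ss_sw, n - ngroups),
        "within": (ss_cond, k - 1, ss_ew, (n - ngroups) * (k - 1)),
        "interaction": (ss_int, (ngroups - 1) * (k - 1), ss_ew,
                        (n - ngroups) * (k - 1)),
        "_ss_sw": ss_sw, "_ss_ew": ss_ew,
    }


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-level covariance matrix."""
    k = wide.shape[1]
    if k == 2:
        return 1.0
    s = np.cov(wide, rowvar=False)
    # double-centered covariance
    dc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    num = np.trace(dc) ** 2
    den = (k - 1) * (dc ** 2).sum()
    return float(num / den)


def _mauchly(wide: np.ndarray):
    """Mauchly's sphericity test on the orthonormal-contrast covariance."""
    n, k = wide.shape
    if k == 2:
        return 1.0, 1.0
    import pingouin as pg

    spher, w, chi2, dof, p = pg.sphericity(pd.DataFrame(wide), method="mauchly")
    return float(w), float(p)


def rm_two_way_anova(table: pd.DataFrame, value: str, subject: str,
                     within: str, between: str | None = None,
                     factor_b: str | None = None) -> RmAnovaResult:
    """Two-way ANOVA on a long-format table.

    With ``between`` set: mixed (split-plot) design -- one repeated factor
    and one group factor; with ``factor_b``: fully within-subject two
    repeated factors. Requires complete, balanced cells. Reports per effect
    F, df, p, generalized eta squared (Olejnik-Algina: effect SS over effect
    SS plus every subject-related error SS), Mauchly's W, the
    Greenhouse-Geisser epsilon with the corrected p when sphericity is
    violated (epsilon = 1 with two within levels), Shapiro-Wilk on
    residuals, and Tukey-type post-hocs.
    """
    if (between is None) == (factor_b is None):
        raise ValueError("specify exactly one of `between` or `factor_b`")
    if table[[subject, within] + ([between] if between else [factor_b])
             ].duplicated().any():
        raise ValueError("duplicate cells in table")
    if between is not None:
        return _mixed_two_way(table, value, subject, within, between)
    return _within_two_way(table, value, subject, within, factor_b)


def _mixed_two_way(table, value, subject, within, between):
    wide_df = table.pivot(index=subject, columns=within, values=value)
    if wide_df.isna().any().any():
        raise ValueError("missing cells: design must be complete")
    groups = table.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[wide_df.index].to_numpy()
    wide = wide_df.to_numpy(dtype=float)
    n, k = wide.shape
    ss = _mixed_anova_ss(wide, groups)
    eps = _gg_epsilon(wide)
    w, w_p = _mauchly(wide)

    effects = {}
    for name in ("group", "within", "interaction"):
        ss_eff, df1, ss_err, df2 = ss[name]
        if ss_err <= 0 or df1 == 0:
            f = 0.0
            p = 1.0
        else:
            f = (ss_eff / df1) / (ss_err / df2)
            p = float(stats.f.sf(f, df1, df2))
        denom = ss_eff + ss["_ss_sw"] + ss["_ss_ew"]
        ng2 = float(ss_eff / denom) if denom > 0 else 0.0
        np2 = float(ss_eff / (ss_eff + ss_err)) if (ss_eff + ss_err) > 0 else 0.0
        entry = {"F": float(f), "df": (df1, df2), "p": p, "ng2": ng2, "np2": np2}
        # GG correction applies to effects involving the repeated factor
        if name in ("within", "interaction") and w_p < 0.05 and ss_err > 0:
            entry["p_gg"] = float(stats.f.sf(f, eps * df1, eps * df2))
            entry["gg_df"] = (eps * df1, eps * df2)
        effects[name] = entry

    # residuals: cell-mean + subject deviation removed
    resid = np.empty_like(wide)
    for g in np.unique(groups):
        sel = groups == g
        cell = wide[sel].mean(axis=0)
        subj_dev = wide[sel].mean(axis=1) - wide[sel].mean()
        resid[sel] = wide[sel] - cell[None, :] - subj_dev[:, None]
    sw_w, sw_p = _safe_shapiro(resid.ravel())

    tukey = _tukey_table(wide, wide_df.columns, groups, ss)
    return RmAnovaResult(effects, w, w_p, eps, float(sw_w), float(sw_p), tukey)


def _within_two_way(table, value, subject, factor_a, factor_b):
    from .cluster_stats import _rm_twoway_f

    a_levels = sorted(table[factor_a].unique())
    b_levels = sorted(table[factor_b].unique())
    subjects = sorted(table[subject].unique())
    arr = np.full((len(subjects), len(a_levels), len(b_levels)), np.nan)
    for row in table.itertuples():
        arr[subjects.index(getattr(row, subject)),
            a_levels.index(getattr(row, factor_a)),
            b_levels.index(getattr(row, factor_b))] = getattr(row, value)
    if np.isnan(arr).any():
        raise ValueError("missing cells: design must be complete")
    maps = _rm_twoway_f(arr)
    s = len(subjects)
    effects = {}
    for name, (f, df) in maps.items():
        f = float(f)
        effects[name] = {"F": f, "df": df, "p": float(stats.f.sf(f, *df))}
    wide_a = arr.mean(axis=2)
    eps = _gg_epsilon(wide_a)
    w, w_p = _mauchly(wide_a)
    grand = arr.mean()
    resid = (arr - arr.mean(axis=(1, 2), keepdims=True)
             - arr.mean(axis=0, keepdims=True) + grand)
    sw_w, sw_p = _safe_shapiro(resid.ravel())
    return RmAnovaResult(effects, w, w_p, eps, float(sw_w), float(sw_p),
                         pd.DataFrame())


def _tukey_table(wide, level_names, groups, ss) -> pd.DataFrame:
    """Pairwise comparisons with studentized-range p (Tukey procedure).

    Within-level pairs use the repeated-measures error term; group pairs use
    the subjects-within-groups term. The z column is the plain
    difference/SE statistic, mirroring marginal-means style output.
    """
    n, k = wide.shape
    rows = []
    _, _, ss_ew, df_ew = ss["within"]
    ms_ew = ss_ew / df_ew if df_ew > 0 else 0.0
    m_c = wide.mean(axis=0)
    for i, j in combinations(range(k), 2):
        diff = m_c[i] - m_c[j]
        se = np.sqrt(2 * ms_ew / n) if ms_ew > 0 else np.inf
        q = abs(diff) / (np.sqrt(ms_ew / n)) if ms_ew > 0 else 0.0
        p = float(stats.studentized_range.sf(q, k, df_ew)) if k > 1 and ms_ew > 0 else 1.0
        rows.append({"contrast": f"{level_names[i]} - {level_names[j]}",
                     "type": "within", "estimate": float(diff),
                     "z": float(diff / se) if np.isfinite(se) else 0.0,
                     "p": min(1.0, p)})
    glabels = list(np.unique(groups))
    _, _, ss_sw, df_sw = ss["group"]
    ms_sw = ss_sw / df_sw if df_sw > 0 else 0.0
    for gi, gj in combinations(glabels, 2):
        mi = wide[groups == gi].mean()
        mj = wide[groups == gj].mean()
        ni = (groups == gi).sum() * k
        nj = (groups == gj).sum() * k
        diff = mi - mj
        se = np.sqrt(ms_sw / k * (1 / (ni / k) + 1 / (nj / k)))
        q = abs(diff) / (se / np.sqrt(2)) if se > 0 else 0.0
        p = float(stats.studentized_range.sf(q, len(glabels), df_sw)) \
            if se > 0 and len(glabels) > 1 else 1.0
        rows.append({"contrast": f"{gi} - {gj}", "type": "group",
                     "estimate": float(diff),
                     "z": float(diff / se) if se > 0 else 0.0,
                     "p": min(1.0, p)})
    return pd.DataFrame(rows)


def outlier_sensitivity(table: pd.DataFrame, value: str, subject: str,
                        within: str, between: str | None = None,
                        iqr_factor: float = 1.5) -> dict:
    """1.5 x IQR outlier flagging per cell and a complete-case ANOVA rerun.

    Values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] within their design cell are
    flagged; subjects contributing a flagged value are dropped (keeping the
    repeated design balanced) and the ANOVA rerun. Reports whether each
    effect's significance decision (p < 0.05) changed.
    """
    cells = [within] + ([between] if between else [])
    flagged_idx = []
    for _, grp in table.groupby(cells):
        q1, q3 = grp[value].quantile([0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        flagged_idx.extend(grp.index[(grp[value] < lo) | (grp[value] > hi)])
    if len(flagged_idx) > 0.5 * len(table):
        import warnings

        warnings.warn("more than half the values flagged as outliers")
    full = rm_two_way_anova(table, value, subject, within, between=between)
    bad_subjects = table.loc[flagged_idx, subject].unique()
    reduced_tab = table[~table[subject].isin(bad_subjects)]
    if reduced_tab[subject].nunique() < 3 or len(bad_subjects) == 0:
        reduced = full
    else:
        reduced = rm_two_way_anova(reduced_tab, value, subject, within,
                                   between=between)
    agreement = {
        name: (full.effects[name]["p"] < 0.05) == (reduced.effects[name]["p"] < 0.05)
        for name in full.effects}
    return {"flagged_rows": sorted(flagged_idx),
            "excluded_subjects": list(bad_subjects),
            "full": full, "reduced": reduced,
            "decision_unchanged": agreement,
            "robust": all(agreement.values())}


def cronbach_alpha(items: np.ndarray) -> float:
    """Internal consistency: alpha = k/(k-1) (1 - sum(var_item)/var_total)."""
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[0] < 2 or items.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 items")
    k = items.shape[1]
    var_total = items.sum(axis=1).var(ddof=1)
    if var_total <= 0:
        raise ValueError("zero total variance: alpha undefined")
    return float(k / (k - 1) * (1 - items.var(axis=0, ddof=1).sum() / var_total))


# ---------------------------------------------------------------------------
# Bayes factor (BIC approximation)

@dataclass
class BayesResult:
    """BF01 with the conventional interpretation band."""

    bf01: float
    label: str = field(init=False)

    def __post_init__(self) -> None:
        b = self.bf01
        if b <= 0:
            raise ValueError("BF01 must be positive")
        if b >= 30 or b <= 1 / 30:
            strength = "very strong"
        elif b >= 10 or b <= 1 / 10:
            strength = "strong"
        elif b >= 3 or b <= 1 / 3:
            strength = "moderate"
        elif abs(np.log(b)) < 1e-12:
            self.label = "ambiguous"
            return
        else:
            strength = "anecdotal"
        side = "null" if b > 1 else "alternative"
        self.label = f"{strength} evidence for the {side} hypothesis"


def bf01_bic(y: np.ndarray, x_null: np.ndarray, x_alt: np.ndarray) -> BayesResult:
    """BF01 = exp((BIC_alt - BIC_null) / 2) from nested OLS fits.

    The null design must be nested in the alternative (checked by projecting
    its columns onto the alternative's column space). This is the BIC
    (unit-information prior) approximation; it tracks, but does not equal,
    default-prior Bayes factors.
    """
    y = np.asarray(y, dtype=float)
    x0 = np.atleast_2d(np.asarray(x_null, dtype=float))
    x1 = np.atleast_2d(np.asarray(x_alt, dtype=float))
    if x0.shape[0] != len(y) or x1.shape[0] != len(y):
        raise ValueError("design rows must match observations")
    proj, *_ = np.linalg.lstsq(x1, x0, rcond=None)
    if not np.allclose(x1 @ proj, x0, atol=1e-8):
        raise ValueError("models are not nested")
    n = len(y)

    def bic(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ beta) ** 2).sum())
        k = np.linalg.matrix_rank(x)
        return n * np.log(max(rss, 1e-300) / n) + k * np.log(n)

    return BayesResult(float(np.exp((bic(x1) - bic(x0)) / 2.0)))


def bf01_condition_effect(table: pd.DataFrame, value: str, subject: str,
                          condition: str) -> BayesResult:
    """BF01 for a repeated condition effect: subject-only vs subject + condition."""
    subj_d = pd.get_dummies(table[subject], dtype=float).to_numpy()
    cond_d = pd.get_dummies(table[condition], drop_first=True, dtype=float).to_numpy()
    y = table[value].to_numpy(dtype=float)
    return bf01_bic(y, subj_d, np.hstack([subj_d, cond_d]))
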