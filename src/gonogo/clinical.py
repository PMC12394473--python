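"""HTQ scoring, responder classification, and univariate clinical statistics.

The Harvard Trauma Questionnaire total is the mean of the 16 DSM items
(1-4 scale, clinical cut-off 2.5).  A responder is a subject whose
total decreases by at least 0.5 points from pre- to post-treatment.
Group and pre/post contrasts use rank tests with Cohen's d and Cliff's
delta effect sizes, Bonferroni and Benjamini-Hochberg multiplicity
control, a baseline-severity regression, and a two-predictor
sensitivity model (responder status + medication status).

The 2x2 chi-square uses the Yates continuity correction with the
|O - E| - 0.5 term floored at zero; this is the variant that reproduces
the published contingency statistics of the study design this package
mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default 5-factor item map (dysphoric-arousal model).  The package
#: default; item assignments are configuration, not a fixed fact of the
#: instrument.
DEFAULT_SUBSCALES: dict[str, tuple[int, ...]] = {
    "Intrusions": (1, 2, 3, 16),
    "Avoidance": (11, 15),
    "Numbing": (4, 5, 12, 13, 14),
    "Dysphoric Arousal": (7, 8, 10),
    "Anxious Arousal": (6, 9),
}

HTQ_CUTOFF = 2.5
RESPONDER_DECREASE = 0.5


@dataclass
class HTQRecord:
    subject_id: str
    timepoint: str            # "pre" or "post"
    items: np.ndarray         # 16 ints in 1..4
    total: float              # mean of items
    subscales: dict[str, float]
    above_cutoff: bool


@dataclass
class EffectSizeReport:
    cohens_d: float
    cohens_d_ci: tuple[float, float]
    cliffs_delta: float
    cliffs_delta_ci: tuple[float, float]
    test_statistic: float
    p_raw: float
    p_bonferroni: float
    p_fdr: float


def score_htq(items, subject_id: str = "", timepoint: str = "",
              subscale_map: dict[str, tuple[int, ...]] | None = None) -> HTQRecord:
    """Score one 16-item HTQ administration (no imputation)."""
    items = np.asarray(items)
    if items.shape != (16,):
        raise ValueError(f"expected 16 items, got {items.shape}")
    if not np.all(np.isin(items, [1, 2, 3, 4])):
        bad = items[~np.isin(items, [1, 2, 3, 4])]
        raise ValueError(f"item scores must be integers in 1..4; got {bad}")
    items = items.astype(int)
    total = float(items.mean())
    sub_map = DEFAULT_SUBSCALES if subscale_map is None else subscale_map
    subscales = {name: float(items[[i - 1 for i in idx]].mean())
                 for name, idx in sub_map.items()}
    return HTQRecord(subject_id=subject_id, timepoint=timepoint, items=items,
                     total=total, subscales=subscales,
                     above_cutoff=total >= HTQ_CUTOFF)


def classify_responder(pre: HTQRecord, post: HTQRecord) -> str:
    """"responder" iff the total decreases by >= 0.5 points."""
    if pre.subject_id != post.subject_id:
        raise ValueError("pre and post records belong to different subjects")
    if pre.timepoint == post.timepoint:
        raise ValueError("need one pre and one post record")
    decrease = pre.total - post.total
    return "responder" if decrease >= RESPONDER_DECREASE else "non_responder"


# ---------------------------------------------------------------------------
# Rank tests

def mann_whitney_u(a, b):
    """Mann-Whitney U (reported for the first group) and two-sided p.

    Exact p for min(n1, n2) <= 8 without ties, normal approximation with
    tie correction otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(pre, post):
    """Paired signed-rank test on pre - post (shared z kernel).

    Returns ``(w_plus, w_minus, z, p)``; the normal-approximation p uses
    the same tie-corrected kernel as the cluster statistics.  All-zero
    differences give z = 0, p = 1.
    """
    from .cluster import signed_rank_ingredients, _z_from_signed, _two_sided_p

    d = (np.asarray(pre, float) - np.asarray(post, float))[:, None]
    signed, sigma, n_eff = signed_rank_ingredients(d)
    ranks = np.abs(signed[:, 0])
    w_plus = float(ranks[signed[:, 0] > 0].sum())
    w_minus = float(ranks[signed[:, 0] < 0].sum())
    z = float(_z_from_signed(signed.sum(axis=0), sigma)[0])
    p = float(_two_sided_p(np.array([z]))[0]) if n_eff[0] > 0 else 1.0
    return w_plus, w_minus, z, p


# ---------------------------------------------------------------------------
# Contingency tables

def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    return t


def chi_square_yates(table):
    """2x2 chi-square with Yates continuity correction floored at zero.

    chi2 = sum max(|O - E| - 0.5, 0)^2 / E over the four cells, df = 1.
    """
    t = _check_table(table)
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float((adj ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    t = _check_table(table)
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Effect sizes

def cohens_d(a, b, design: str = "independent"):
    """Cohen's d with a 95% CI (normal approximation to the d sampling SE).

    ``independent``: (mean a - mean b) / pooled SD.
    ``paired``: mean(a - b) / SD(a - b); a and b aligned by subject.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if design == "independent":
        n1, n2 = a.size, b.size
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ValueError("degenerate: zero pooled variance")
        d = (a.mean() - b.mean()) / np.sqrt(sp2)
        se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    elif design == "paired":
        if a.size != b.size:
            raise ValueError("paired design requires aligned samples")
        diff = a - b
        n = diff.size
        if n < 2:
            raise ValueError("need n >= 2 pairs")
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate: zero variance of differences")
        d = diff.mean() / sd
        se = np.sqrt(1.0 / n + d ** 2 / (2 * n))
    else:
        raise ValueError("design must be 'independent' or 'paired'")
    return float(d), (float(d - 1.959963984540054 * se), float(d + 1.959963984540054 * se))


def _cliffs_delta_brute(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / (a.size * b.size))


def _cliffs_delta_ranked(a: np.ndarray, b: np.ndarray) -> float:
    """O((n+m) log(n+m)) path via sorted counting; exact ties handling."""
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left").sum()     # b < a_i
    less = (b.size - np.searchsorted(bs, a, side="right")).sum()  # b > a_i
    return float((greater - less) / (a.size * b.size))


def cliffs_delta(a, b, max_pairs_brute: int = 10 ** 6):
    """Cliff's delta with a 95% CI (consistent variance estimate).

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (n_a n_b).  The all-pairs
    path is used up to ``max_pairs_brute`` pairwise comparisons; beyond
    that the rank-based path (identical result) takes over.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    if n * m <= max_pairs_brute:
        dmat = np.sign(a[:, None] - b[None, :])
        delta = float(dmat.mean())
        di = dmat.mean(axis=1)
        dj = dmat.mean(axis=0)
    else:
        delta = _cliffs_delta_ranked(a, b)
        bs, as_ = np.sort(b), np.sort(a)
        di = ((np.searchsorted(bs, a, "left") - (m - np.searchsorted(bs, a, "right"))) / m)
        dj = (((n - np.searchsorted(as_, b, "right")) - np.searchsorted(as_, b, "left")) / n)
    # Cliff's consistent variance estimate
    s_di = ((di - delta) ** 2).sum() / (n - 1) if n > 1 else 0.0
    s_dj = ((dj - delta) ** 2).sum() / (m - 1) if m > 1 else 0.0
    var = (m * s_di + n * s_dj) / (n * m) if n > 1 and m > 1 else 0.0
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    lo, hi = max(-1.0, delta - half), min(1.0, delta + half)
    return float(delta), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Multiplicity

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjust_pvalues(p, method: str = "bonferroni", m: int | None = None) -> np.ndarray:
    """Adjusted p-values by Bonferroni or Benjamini-Hochberg step-up.

    ``m`` may exceed ``len(p)`` (tests not reported but counted).
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError("m must be >= number of p-values")
    if method == "bonferroni":
        return np.minimum(p * m_eff, 1.0)
    if method == "fdr_bh":
        if m_eff == len(p):
            return multipletests(p, method="fdr_bh")[1]
        # pad with p = 1 placeholders for unreported tests
        padded = np.concatenate([p, np.ones(m_eff - len(p))])
        return multipletests(padded, method="fdr_bh")[1][: len(p)]
    raise ValueError("method must be 'bonferroni' or 'fdr_bh'")


# ---------------------------------------------------------------------------
# Regression models

def baseline_change_regression(htq_pre, htq_change):
    """OLS of change (post - pre; negative = improvement) on baseline severity.

    Returns ``(slope, intercept, r_squared, f_statistic, p_value)``.
    """
    import statsmodels.api as sm

    pre = np.asarray(htq_pre, float)
    change = np.asarray(htq_change, float)
    if pre.size < 3:
        raise ValueError("need n >= 3")
    if pre.std() == 0:
        raise ValueError("constant predictor: baseline has zero variance")
    if change.std() == 0:
        # degenerate: nothing to explain
        return 0.0, float(change[0]), 0.0, 0.0, 1.0
    model = sm.OLS(change, sm.add_constant(pre)).fit()
    return (float(model.params[1]), float(model.params[0]),
            float(model.rsquared), float(model.fvalue), float(model.f_pvalue))


def sensitivity_model(htq_change, responder_status, medication_status):
    """Two-predictor OLS with type-II F tests per predictor.

    Both predictors are binary (0/1).  Returns a DataFrame with one row
    per predictor: F, df_num, df_den, p.
    """
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm
    import statsmodels.formula.api as smf

    change = np.asarray(htq_change, float)
    resp = np.asarray(responder_status, int)
    med = np.asarray(medication_status, int)
    if change.size < 5:
        raise ValueError("need n >= 5")
    if change.std() == 0:
        raise ValueError("degenerate: outcome has zero variance")
    if np.array_equal(resp, med) or np.array_equal(resp, 1 - med):
        raise ValueError("collinear predictors: responder and medication "
                         "status are identical (or complementary)")
    if resp.std() == 0 or med.std() == 0:
        raise ValueError("constant predictor")
    df = pd.DataFrame({"change": change, "responder": resp, "medication": med})
    fit = smf.ols("change ~ responder + medication", data=df).fit()
    aov = anova_lm(fit, typ=2)
    df_den = float(aov.loc["Residual", "df"])
    rows = []
    for name in ("responder", "medication"):
        rows.append({"predictor": name, "F": float(aov.loc[name, "F"]),
                     "df_num": float(aov.loc[name, "df"]), "df_den": df_den,
                     "p": float(aov.loc[name, "PR(>F)"])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tidy comparison tables

def _safe(fn, *args, **kwargs):
    """NaN-filled fallback for degenerate inputs (e.g. zero-variance measures)."""
    try:
        return fn(*args, **kwargs)
    except ValueError:
        return np.nan, (np.nan, np.nan)


def _adjusted(p_raw: np.ndarray, method: str, m: int) -> np.ndarray:
    """Multiplicity adjustment tolerant of NaN entries (degenerate tests)."""
    p_raw = np.asarray(p_raw, dtype=float)
    ok = np.isfinite(p_raw)
    out = np.full(p_raw.shape, np.nan)
    if ok.any():
        out[ok] = adjust_pvalues(np.clip(p_raw[ok], 1e-300, 1.0), method, m)
    return out


def compare_groups(values: pd.DataFrame, group_col: str, value_cols: list[str],
                   group_a: str, group_b: str, alpha: float = 0.05,
                   m: int | None = None) -> pd.DataFrame:
    """Mann-Whitney + effect sizes for each measure, with corrections.

    Produces a tidy table (measure, medians, IQRs, U, p_raw, p_bonf,
    p_fdr, d, delta, CIs) mirroring a baseline-characteristics layout.
    """
    a_mask = values[group_col] == group_a
    b_mask = values[group_col] == group_b
    rows = []
    for col in value_cols:
        a = values.loc[a_mask, col].dropna().to_numpy(dtype=float)
        b = values.loc[b_mask, col].dropna().to_numpy(dtype=float)
        if np.concatenate([a, b]).std() > 0:
            u, p = mann_whitney_u(a, b)
        else:
            u, p = np.nan, np.nan  # all values identical: no test possible
        d, d_ci = _safe(cohens_d, a, b, "independent")
        delta, delta_ci = cliffs_delta(a, b)
        rows.append({
            "measure": col, "n_a": a.size, "n_b": b.size,
            "median_a": float(np.median(a)), "iqr_a_low": float(np.percentile(a, 25)),
            "iqr_a_high": float(np.percentile(a, 75)),
            "median_b": float(np.median(b)), "iqr_b_low": float(np.percentile(b, 25)),
            "iqr_b_high": float(np.percentile(b, 75)),
            "U": u, "p_raw": p, "cohens_d": d, "d_ci_low": d_ci[0], "d_ci_high": d_ci[1],
            "cliffs_delta": delta, "delta_ci_low": delta_ci[0],
            "delta_ci_high": delta_ci[1],
        })
    out = pd.DataFrame(rows)
    m_eff = m if m is not None else len(out)
    out["p_bonferroni"] = _adjusted(out["p_raw"], "bonferroni", m_eff)
    out["p_fdr"] = _adjusted(out["p_raw"], "fdr_bh", m_eff)
    return out


def prepost_table(pre: pd.DataFrame, post: pd.DataFrame, value_cols: list[str],
                  m: int | None = None) -> pd.DataFrame:
    """Within-group pre/post comparisons (signed-rank + paired effect sizes)."""
    rows = []
    for col in value_cols:
        a = pre[col].to_numpy(float)
        b = post[col].to_numpy(float)
        w_plus, w_minus, z, p = wilcoxon_signed_rank(a, b)
        d, d_ci = _safe(cohens_d, a, b, "paired")
        delta, delta_ci = cliffs_delta(a, b)
        rows.append({
            "measure": col,
            "median_pre": float(np.median(a)), "median_post": float(np.median(b)),
            "iqr_pre_low": float(np.percentile(a, 25)),
            "iqr_pre_high": float(np.percentile(a, 75)),
            "iqr_post_low": float(np.percentile(b, 25)),
            "iqr_post_high": float(np.percentile(b, 75)),
            "w_plus": w_plus, "w_minus": w_minus, "z": z, "p_raw": p,
            "cohens_d": d, "d_ci_low": d_ci[0], "d_ci_high": d_ci[1],
            "cliffs_delta": delta, "delta_ci_low": delta_ci[0],
            "delta_ci_high": delta_ci[1],
        })
    out = pd.DataFrame(rows)
    m_eff = m if m is not None else len(out)
    out["p_bonferroni"] = _adjusted(out["p_raw"], "bonferroni", m_eff)
    out["p_fdr"] = _adjusted(out["p_raw"], "fdr_bh", m_eff)
    return out
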