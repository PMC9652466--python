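"""Cohort hypothesis tests and correlations on effective-connectivity tables.

Covers the study-style statistical battery: the nonparametric (rank-based)
two-way mixed ANOVA on walking prefrontal EC, Wilcoxon signed-rank /
Mann-Whitney U / paired-t comparisons of resting-state ECs, the per-subject
session difference dEC = EC_baseline - EC_follow-up, Spearman correlations on
dEC, Shapiro-Wilk-gated Box-Cox + Pearson correlation for covariates, and
Benjamini-Hochberg FDR adjustment applied within each named battery (never
across batteries).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import TpdcError

logger = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# delta EC


def delta_ec(baseline: pd.DataFrame, followup: pd.DataFrame) -> pd.DataFrame:
    """Per-subject dEC = EC_baseline - EC_follow-up, per feature.

    Rows are matched on ``subject_id``; subjects present in only one session
    are excluded with a warning.
    """
    for df, name in ((baseline, "baseline"), (followup, "follow-up")):
        if "subject_id" not in df.columns:
            raise TpdcError(f"{name} table lacks a subject_id column")
    b = baseline.set_index("subject_id")
    f = followup.set_index("subject_id")
    common = b.index.intersection(f.index)
    dropped = set(b.index).symmetric_difference(f.index)
    if dropped:
        logger.warning(
            "subjects present in only one session excluded from dEC: %s",
            sorted(dropped),
        )
    feats = [
        c
        for c in baseline.columns
        if c not in ("subject_id", "group", "session", "response")
    ]
    out = b.loc[common, feats] - f.loc[common, feats]
    return out.reset_index()


# ---------------------------------------------------------------------------
# rank-based two-way mixed ANOVA


def np_two_way_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
    method: str = "rank",
) -> pd.DataFrame:
    """Nonparametric two-way ANOVA for the 2 x 2 mixed design.

    ``method='rank'`` (default) ranks the pooled response and runs a
    parametric mixed ANOVA on the ranks (the rank-transform procedure);
    ``method='art'`` uses the aligned-rank transform, aligning each effect
    before ranking so every effect is tested on its own aligned ranks.

    Returns a DataFrame with rows ``between``, ``within``, ``interaction``
    and columns ``F`` and ``p``.
    """
    df = data[[dv, between, within, subject]].dropna().copy()
    if df[between].nunique() != 2 or df[within].nunique() != 2:
        raise TpdcError("a 2 x 2 design is required")
    cells = df.groupby([between, within], observed=True)[dv].count()
    if len(cells) < 4 or (cells < 3).any():
        raise TpdcError("every design cell needs at least 3 observations")

    def _mixed(frame: pd.DataFrame, col: str) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pg.mixed_anova(
                data=frame, dv=col, within=within, between=between, subject=subject
            ).set_index("Source")

    if method == "rank":
        df["_r"] = sps.rankdata(df[dv])
        aov = _mixed(df, "_r")
        rows = {
            "between": aov.loc[between],
            "within": aov.loc[within],
            "interaction": aov.loc["Interaction"],
        }
        out = pd.DataFrame(
            {
                "F": [r["F"] for r in rows.values()],
                "p": [r["p_unc"] for r in rows.values()],
            },
            index=list(rows),
        )
    elif method == "art":
        out_rows = {}
        gm = df[dv].mean()
        cell_mean = df.groupby([between, within], observed=True)[dv].transform("mean")
        a_mean = df.groupby(between, observed=True)[dv].transform("mean")
        b_mean = df.groupby(within, observed=True)[dv].transform("mean")
        resid = df[dv] - cell_mean
        aligned = {
            "between": resid + a_mean - gm,
            "within": resid + b_mean - gm,
            "interaction": resid + cell_mean - a_mean - b_mean + gm,
        }
        src = {"between": between, "within": within, "interaction": "Interaction"}
        for effect, vals in aligned.items():
            frame = df.copy()
            frame["_r"] = sps.rankdata(vals)
            aov = _mixed(frame, "_r")
            row = aov.loc[src[effect]]
            out_rows[effect] = (row["F"], row["p_unc"])
        out = pd.DataFrame(out_rows, index=["F", "p"]).T
    else:
        raise TpdcError("method must be 'rank' or 'art'")
    logger.debug("nonparametric two-way ANOVA (%s):\n%s", method, out)
    return out


# ---------------------------------------------------------------------------
# rank tests and correlations (scipy-backed, exact small-sample nulls)


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired values (or on ``x - y``)."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.all(d == 0):
        raise TpdcError("all paired differences are zero: test degenerate")
    res = sps.wilcoxon(d, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; exact null for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise TpdcError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y) -> tuple[float, float]:
    """Two-tailed paired-samples t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise TpdcError("paired samples must have equal length")
    res = sps.ttest_rel(x, y)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical pairs: zero variance of differences
        return 0.0, 1.0
    return t, p


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise TpdcError("need equal-length samples of at least 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TpdcError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def power_transform_pearson(
    x, y, alpha: float = ALPHA, strict: bool = False
) -> dict:
    """Pearson correlation with a Shapiro-Wilk-gated Box-Cox transform.

    Each variable failing Shapiro-Wilk normality at ``alpha`` is Box-Cox
    transformed with the maximum-likelihood lambda before the correlation.
    Non-positive values are shifted (with the offset logged) unless
    ``strict`` is set, in which case they raise.

    Returns a dict with ``r``, ``p``, and per-variable ``lambda``/
    ``transformed``/``shift`` entries.
    """
    info: dict = {}
    arrs = []
    for name, arr in (("x", np.asarray(x, float)), ("y", np.asarray(y, float))):
        if np.ptp(arr) == 0:
            raise TpdcError("correlation undefined for constant input")
        sw_p = float(sps.shapiro(arr).pvalue)
        entry = {"shapiro_p": sw_p, "transformed": False, "lambda": None, "shift": 0.0}
        if sw_p < alpha:
            shifted = arr
            if arr.min() <= 0:
                if strict:
                    raise TpdcError(
                        f"{name} has non-positive values; Box-Cox requires > 0"
                    )
                shift = -float(arr.min()) + 1e-6
                shifted = arr + shift
                entry["shift"] = shift
                logger.info("shifted %s by %.3g before Box-Cox", name, shift)
            transformed, lam = sps.boxcox(shifted)
            entry.update(transformed=True, **{"lambda": float(lam)})
            logger.info("Box-Cox lambda for %s: %.4f", name, lam)
            arr = transformed
        info[name] = entry
        arrs.append(arr)
    r, p = sps.pearsonr(arrs[0], arrs[1])
    info.update(r=float(r), p=float(p))
    return info


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise TpdcError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# report batteries


@dataclass
class StatsReport:
    """Tidy battery report: one row per comparison with raw and adjusted p."""

    battery: str
    table: pd.DataFrame  # columns: test, effect, statistic, p_raw, p_fdr, n

    def __post_init__(self) -> None:
        t = self.table
        required = {"test", "effect", "statistic", "p_raw", "p_fdr", "n"}
        if not required.issubset(t.columns):
            raise TpdcError(f"report table must carry columns {sorted(required)}")
        if ((t["p_fdr"] + 1e-12) < t["p_raw"]).any():
            raise TpdcError("adjusted p-values must be >= raw p-values")


def _finish(battery: str, rows: list[dict]) -> StatsReport:
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    return StatsReport(battery=battery, table=table)


def battery_prefrontal_anova(
    walking: pd.DataFrame,
    dv: str = "prefrontal_ec",
    between: str = "group",
    within: str = "condition",
    subject: str = "subject_id",
    method: str = "rank",
) -> StatsReport:
    """Rank-based two-way mixed ANOVA on walking prefrontal EC."""
    aov = np_two_way_anova(walking, dv, between, within, subject, method=method)
    n = int(walking[subject].nunique())
    rows = [
        {
            "test": f"np-two-way-anova ({method})",
            "effect": effect,
            "statistic": float(aov.loc[effect, "F"]),
            "p_raw": float(aov.loc[effect, "p"]),
            "n": n,
        }
        for effect in aov.index
    ]
    return _finish("prefrontal-anova", rows)


def battery_resting_ec(cohort: pd.DataFrame, feature_cols=None) -> StatsReport:
    """Per-feature group and session contrasts on resting-state ECs.

    Mann-Whitney U compares PD vs HC at baseline; the Wilcoxon signed-rank
    test compares PD baseline vs follow-up (the paired-difference formulation
    of the one-sample signed-rank test on session changes).  FDR adjustment
    is applied within each contrast family of 20 features.
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in cohort.columns
            if c not in ("subject_id", "group", "session", "response")
        ]
    pd_base = cohort.query("group == 'PD' and session == 'baseline'").set_index(
        "subject_id"
    )
    hc_base = cohort.query("group == 'HC' and session == 'baseline'")
    pd_fu = cohort.query("group == 'PD' and session == 'follow-up'").set_index(
        "subject_id"
    )
    common = pd_base.index.intersection(pd_fu.index)

    mwu_rows, wsr_rows = [], []
    for f in feature_cols:
        u, p = mann_whitney_u(pd_base[f], hc_base[f])
        mwu_rows.append(
            {
                "test": "mann-whitney-u",
                "effect": f"{f}: PD-baseline vs HC",
                "statistic": u,
                "p_raw": p,
                "n": len(pd_base) + len(hc_base),
            }
        )
        try:
            w, p = wilcoxon_signed_rank(
                pd_base.loc[common, f].to_numpy(), pd_fu.loc[common, f].to_numpy()
            )
        except TpdcError:
            w, p = np.nan, 1.0
        wsr_rows.append(
            {
                "test": "wilcoxon-signed-rank",
                "effect": f"{f}: PD baseline vs follow-up",
                "statistic": w,
                "p_raw": p,
                "n": len(common),
            }
        )
    mwu = _finish("resting-ec", mwu_rows).table
    wsr = _finish("resting-ec", wsr_rows).table
    return StatsReport("resting-ec", pd.concat([mwu, wsr], ignore_index=True))


def battery_delta_corr(delta: pd.DataFrame, pairs) -> StatsReport:
    """Spearman correlations between named dEC feature pairs."""
    rows = []
    for fa, fb in pairs:
        rho, p = spearman_corr(delta[fa], delta[fb])
        rows.append(
            {
                "test": "spearman",
                "effect": f"dEC {fa} ~ dEC {fb}",
                "statistic": rho,
                "p_raw": p,
                "n": len(delta),
            }
        )
    return _finish("delta-corr", rows)


def battery_covariate_corr(
    cohort: pd.DataFrame,
    covariate: str,
    feature_cols=None,
    group: str = "PD",
    session: str = "baseline",
) -> StatsReport:
    """Shapiro-gated power-transform Pearson correlations of each EC feature
    against an external covariate column (e.g. a clinical score)."""
    sub = cohort.query("group == @group and session == @session")
    if covariate not in sub.columns:
        raise TpdcError(f"covariate column {covariate!r} not in table")
    if feature_cols is None:
        feature_cols = [
            c
            for c in sub.columns
            if c not in ("subject_id", "group", "session", "response", covariate)
        ]
    rows = []
    for f in feature_cols:
        res = power_transform_pearson(sub[f], sub[covariate])
        rows.append(
            {
                "test": "power-transform-pearson",
                "effect": f"{f} ~ {covariate}",
                "statistic": res["r"],
                "p_raw": res["p"],
                "n": len(sub),
            }
        )
    return _finish("covariate-corr", rows)
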