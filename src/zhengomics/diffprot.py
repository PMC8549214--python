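"""Proteomics QC, differential-protein calling and cohort statistics.

Differential proteins (DPs) between a syndrome group and healthy controls
are called with the classic volcano rule: raw-scale fold change FC > 1.1
combined with a Student (equal-variance) t-test p < 0.05 computed on log2
intensities.  Benjamini-Hochberg q-values are reported for information but
play no role in the significance flag.  Set algebra over DP lists
(:func:`venn_sets`) and the clinical-table statistics (one-way ANOVA from
summary statistics, chi-square homogeneity) live here as well.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from zhengomics.tables import OmicsTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# imputation and QC
# ---------------------------------------------------------------------------

def impute_missing(table: OmicsTable, policy: str = "half_min") -> OmicsTable:
    """Fill missing intensities; features with no observed value are dropped.

    The default ``half_min`` policy replaces each missing entry by half of
    the feature's minimum observed intensity, a standard left-censoring
    surrogate for below-detection-limit dropout.  ``min`` fills with the
    observed minimum itself.
    """
    if policy not in {"half_min", "min"}:
        raise ValueError(f"unknown imputation policy: {policy!r}")
    values = table.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d features with no observed values", int(all_missing.sum()))
        values = values.loc[~all_missing]
    if not values.isna().any().any():
        return OmicsTable(values, table.groups, table.feature_meta)
    fill = values.min(axis=1)
    if policy == "half_min":
        fill = fill / 2.0
    filled = values.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return OmicsTable(filled, table.groups, table.feature_meta)


def qc_cv(table: OmicsTable) -> pd.Series:
    """Per-feature coefficient of variation (sd/mean) over standard samples.

    Uses raw intensities and the sample standard deviation (ddof=1).
    Features with no observed standard-sample values are excluded.
    """
    std_samples = table.standard_samples()
    if len(std_samples) < 2:
        raise ValueError("need at least 2 standard samples for CV QC")
    sub = table.values[std_samples]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    ok = mean > 0
    if (~ok).any():
        logger.warning("excluding %d features with zero/absent standard mean", int((~ok).sum()))
    return (sd[ok] / mean[ok]).rename("cv")


def fraction_below(cv: pd.Series, threshold: float = 0.10) -> float:
    """Fraction of features whose CV is strictly below ``threshold``."""
    return float((cv < threshold).mean())


def qc_correlation(table: OmicsTable) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples on log2 intensities."""
    log2 = np.log2(table.values)
    corr = log2.corr(method="pearson")
    constant = log2.std(axis=0, ddof=1) == 0
    if constant.any():
        logger.warning("constant sample vectors: %s", list(constant.index[constant]))
    return corr


# ---------------------------------------------------------------------------
# differential proteins
# ---------------------------------------------------------------------------

def diff_proteins(
    table: OmicsTable,
    group_a: str,
    group_b: str,
    fc_thresh: float = 1.1,
    p_thresh: float = 0.05,
    welch: bool = False,
    fc_on_log: bool = False,
) -> pd.DataFrame:
    """Call differential proteins between ``group_a`` (disease) and ``group_b`` (control).

    Returns a DataFrame indexed 0..n-1 with columns ``protein``, ``mean_a``,
    ``mean_b``, ``fc`` (>= 1), ``log2fc`` (signed, a vs b), ``direction``,
    ``p``, ``q`` and ``significant``, ordered by (p ascending, protein id
    ascending).

    The t-test runs on log2 intensities.  By default the fold change is the
    ratio of raw-scale group means folded to >= 1; with ``fc_on_log`` the
    ratio of 2**(mean log2) values is used instead.
    """
    samples_a = table.samples_in_group(group_a)
    samples_b = table.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if table.has_missing():
        raise ValueError("table contains missing values; impute first")

    xa = table.values[samples_a].to_numpy(float)
    xb = table.values[samples_b].to_numpy(float)
    la, lb = np.log2(xa), np.log2(xb)

    tstat, p = stats.ttest_ind(la, lb, axis=1, equal_var=not welch)
    # zero variance in both groups with equal means -> 0/0; define p = 1
    p = np.where(np.isnan(p), 1.0, p)

    if fc_on_log:
        mean_a, mean_b = 2.0 ** la.mean(axis=1), 2.0 ** lb.mean(axis=1)
    else:
        mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ratio = mean_a / mean_b
    fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(mean_a > mean_b, "up", "down")

    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "protein": table.feature_ids,
            "mean_a": table.values[samples_a].mean(axis=1).to_numpy(),
            "mean_b": table.values[samples_b].mean(axis=1).to_numpy(),
            "fc": fc,
            "log2fc": np.log2(ratio),
            "direction": direction,
            "p": p,
            "q": q,
        }
    )
    out["significant"] = (out["fc"] > fc_thresh) & (out["p"] < p_thresh)
    out = out.sort_values(["p", "protein"], kind="mergesort").reset_index(drop=True)
    return out


def venn_sets(set_a, set_b) -> tuple[set, set, set]:
    """Two-way Venn partition: (common, a_only, b_only)."""
    a, b = set(set_a), set(set_b)
    common = a & b
    return common, a - common, b - common


# ---------------------------------------------------------------------------
# cohort (clinical table) statistics
# ---------------------------------------------------------------------------

def anova_from_summary(ns, means, sds) -> tuple[float, float]:
    """One-way ANOVA F and p from per-group (n, mean, sd).

    Equivalent to ANOVA on the raw vectors because between- and
    within-group sums of squares are functions of the summaries alone.
    """
    ns = np.asarray(ns, float)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2 for ANOVA")
    k = len(ns)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def chi_square_counts(events, ns) -> tuple[float, float]:
    """Pearson chi-square homogeneity test on a groups x {event, non-event} table.

    No continuity correction (matches the generic multi-group chi-square of
    clinical baseline tables).
    """
    events = np.asarray(events, float)
    ns = np.asarray(ns, float)
    if (events > ns).any():
        raise ValueError("event count exceeds group size")
    table = np.column_stack([events, ns - events])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def cohort_stats(cohort: pd.DataFrame) -> pd.Series:
    """Per-variable p-values for a clinical summary table.

    ``cohort`` has one row per variable with columns ``kind`` ("continuous"
    or "categorical") and per-group columns ``n_<g>``, plus ``mean_<g>`` /
    ``sd_<g>`` for continuous and ``events_<g>`` for categorical variables.
    Continuous variables get a one-way ANOVA; categorical variables a
    chi-square homogeneity test.
    """
    groups = sorted({c.split("_", 1)[1] for c in cohort.columns if c.startswith("n_")})
    pvals = {}
    for var, row in cohort.iterrows():
        ns = [row[f"n_{g}"] for g in groups]
        if row["kind"] == "continuous":
            means = [row[f"mean_{g}"] for g in groups]
            sds = [row[f"sd_{g}"] for g in groups]
            _, p = anova_from_summary(ns, means, sds)
        else:
            events = [row[f"events_{g}"] for g in groups]
            _, p = chi_square_counts(events, ns)
        pvals[var] = p
    return pd.Series(pvals, name="p")
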