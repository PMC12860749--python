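"""Cohort-level statistics.

Nonparametric correlation and association panel over per-patient,
per-timepoint records: Spearman rank correlation, Wilcoxon rank-sum for
two-group comparisons, Wilcoxon signed-rank for paired baseline/follow-up
contrasts, Kruskal-Wallis across k groups, Pearson chi-square association
for count tables, and Cohen's kappa for rater agreement.  Ties are handled
with midranks; exact p-values are used for small samples (n <= 25, no ties)
and the tie-corrected normal/chi-square approximations otherwise.  p-values
are reported unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError, InvalidInputError

EXACT_N_MAX = 25


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: Optional[float]
    n: int
    coefficient: Optional[float] = None
    group_labels: tuple = ()
    extras: dict = field(default_factory=dict)


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with midrank ties; two-sided p-value."""
    x, y = _clean_pairs(x, y)
    if len(x) < 3:
        raise InvalidInputError(f"need at least 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    return StatResult(
        test="spearman", statistic=float(r), coefficient=float(r), p_value=float(p), n=len(x)
    )


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def two_group_compare(values: Sequence[float], group: Sequence) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with group medians."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    keep = np.isfinite(values) & ~pd.isna(group)
    values, group = values[keep], group[keep]
    labels = pd.unique(group)
    if len(labels) != 2:
        raise InvalidInputError(f"need exactly 2 groups, got {len(labels)}")
    a = values[group == labels[0]]
    b = values[group == labels[1]]
    method = (
        "exact"
        if max(len(a), len(b)) <= EXACT_N_MAX and not _has_ties(np.concatenate([a, b]))
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult(
        test="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(values),
        group_labels=tuple(labels),
        extras={
            "median_" + str(labels[0]): float(np.median(a)),
            "median_" + str(labels[1]): float(np.median(b)),
            "method": method,
        },
    )


def paired_compare(before: Sequence[float], after: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon signed-rank; zero differences are dropped."""
    before, after = _clean_pairs(before, after)
    d = after - before
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        raise DegenerateDataError("all paired differences are zero; signed-rank undefined")
    method = "exact" if len(nonzero) <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided", method=method)
    return StatResult(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(before),
        extras={
            "n_nonzero": len(nonzero),
            "median_before": float(np.median(before)),
            "median_after": float(np.median(after)),
            "method": method,
        },
    )


def kruskal_wallis(values: Sequence[float], group: Sequence) -> StatResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    keep = np.isfinite(values)
    values, group = values[keep], group[keep]
    labels = pd.unique(group)
    if len(labels) < 2:
        raise InvalidInputError(f"need at least 2 groups, got {len(labels)}")
    samples = [values[group == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise InvalidInputError("every group must be nonempty")
    if np.ptp(values) == 0:
        raise DegenerateDataError("all values identical; Kruskal-Wallis H undefined")
    h, p = stats.kruskal(*samples)
    return StatResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        n=len(values),
        group_labels=tuple(labels),
        extras={"df": len(labels) - 1},
    )


def chi_square_association(table, correction: bool = False) -> StatResult:
    """Pearson chi-square of association on a 2-D count table.

    Continuity correction off by default (configurable).  Expected counts
    are reported in ``extras``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise InvalidInputError("contingency table must be 2-D")
    if (table < 0).any():
        raise InvalidInputError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("contingency table has a zero-margin row or column")
    res = stats.chi2_contingency(table, correction=correction)
    return StatResult(
        test="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(table.sum()),
        extras={"df": int(res.dof), "expected": res.expected_freq, "correction": correction},
    )


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> StatResult:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e) from the cross-tabulation."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise InvalidInputError("rating vectors must have equal length")
    if len(a) == 0:
        raise InvalidInputError("empty rating vectors")
    cats = pd.unique(np.concatenate([a, b]))
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    conf = np.zeros((k, k))
    for ai, bi in zip(a, b):
        conf[idx[ai], idx[bi]] += 1
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-12:
        raise DegenerateDataError("both raters constant on the same category; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return StatResult(
        test="cohens_kappa",
        statistic=float(kappa),
        coefficient=float(kappa),
        p_value=None,
        n=int(n),
        group_labels=tuple(cats),
        extras={"confusion": conf, "p_observed": float(p_o), "p_expected": p_e},
    )


# ---------------------------------------------------------------------------
# Panel runner


def _pivot_paired(df: pd.DataFrame, column: str):
    wide = df.pivot_table(index="patient_id", columns="timepoint", values=column, aggfunc="first")
    if "baseline" not in wide or "followup" not in wide:
        raise ConfigError("paired test needs 'baseline' and 'followup' timepoints")
    wide = wide.dropna(subset=["baseline", "followup"])
    return wide["baseline"].to_numpy(), wide["followup"].to_numpy()


def run_panel(
    cohort: pd.DataFrame, panel: Sequence[dict], alpha: float = 0.05
) -> pd.DataFrame:
    """Run a list of test specifications against a cohort table.

    Each entry is a dict with a ``test`` key (``spearman``, ``two_group``,
    ``paired``, ``kruskal``, ``chi_square`` or ``kappa``) plus the column
    names the test needs; optional ``timepoint`` restricts the rows first.
    Duplicate entries are dropped with a warning.  Results carry a
    ``significant`` flag at ``alpha`` with no multiplicity adjustment.
    """
    seen = set()
    rows = []
    for entry in panel:
        key = tuple(sorted((k, str(v)) for k, v in entry.items()))
        if key in seen:
            warnings.warn(f"duplicate panel entry dropped: {entry}", stacklevel=2)
            continue
        seen.add(key)
        test = entry.get("test")
        df = cohort
        if "timepoint" in entry:
            df = cohort[cohort["timepoint"] == entry["timepoint"]]
        try:
            if test == "spearman":
                _need(df, entry, "x", "y")
                res = spearman(df[entry["x"]], df[entry["y"]])
                desc = f"{entry['x']} ~ {entry['y']}"
            elif test == "two_group":
                _need(df, entry, "values", "group")
                res = two_group_compare(df[entry["values"]], df[entry["group"]])
                desc = f"{entry['values']} by {entry['group']}"
            elif test == "paired":
                _need(df, entry, "values")
                before, after = _pivot_paired(cohort, entry["values"])
                res = paired_compare(before, after)
                desc = f"{entry['values']} baseline vs followup"
            elif test == "kruskal":
                _need(df, entry, "values", "group")
                res = kruskal_wallis(df[entry["values"]], df[entry["group"]])
                desc = f"{entry['values']} across {entry['group']}"
            elif test == "chi_square":
                _need(df, entry, "x", "y")
                table = pd.crosstab(df[entry["x"]], df[entry["y"]]).to_numpy()
                res = chi_square_association(table)
                desc = f"{entry['x']} x {entry['y']}"
            elif test == "kappa":
                _need(df, entry, "a", "b")
                res = cohens_kappa(df[entry["a"]], df[entry["b"]])
                desc = f"{entry['a']} vs {entry['b']}"
            else:
                raise ConfigError(f"unknown panel test {test!r}")
        except (DegenerateDataError, InvalidInputError) as exc:
            rows.append(
                {
                    "test": test,
                    "description": _describe(entry),
                    "statistic": np.nan,
                    "coefficient": np.nan,
                    "p_value": np.nan,
                    "n": 0,
                    "significant": False,
                    "note": str(exc),
                }
            )
            continue
        rows.append(
            {
                "test": res.test,
                "description": desc,
                "statistic": res.statistic,
                "coefficient": res.coefficient,
                "p_value": res.p_value,
                "n": res.n,
                "significant": bool(res.p_value is not None and res.p_value < alpha),
                "note": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "test",
            "description",
            "statistic",
            "coefficient",
            "p_value",
            "n",
            "significant",
            "note",
        ],
    )


def _describe(entry: dict) -> str:
    return ", ".join(f"{k}={v}" for k, v in entry.items() if k != "test")


def _need(df: pd.DataFrame, entry: dict, *keys: str) -> None:
    for k in keys:
        if k not in entry:
            raise ConfigError(f"panel entry {entry} is missing key {k!r}")
        if entry[k] not in df.columns:
            raise ConfigError(f"unknown cohort variable {entry[k]!r}")
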