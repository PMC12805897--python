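"""Expression time-course summaries and normality-gated group comparisons.

Cumulative reporter output is summarized as an AUC -- by default the plain
sum of signal values over the sampled time points (the convention used for
the plate-reader readouts this package emulates), with trapezoidal
integration over minutes available when time grids differ between variants.
Per-variant AUCs are normalized to a reference variant as fold-changes.

Group comparison follows a normality gate: Shapiro-Wilk per group at
alpha = .05; if every group passes, one-way ANOVA with Tukey's HSD post hoc,
otherwise Kruskal-Wallis with Dunn's post hoc (Bonferroni-adjusted).
Significance is reported on the .05/.01/.001/.0001 ladder.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data import TimeCourse

__all__ = [
    "auc",
    "summarize_auc",
    "fold_vs_reference",
    "GroupComparison",
    "gated_comparison",
    "dunn_test",
    "significance_tier",
]

GATE_ALPHA = 0.05


def auc(tc: TimeCourse, method: str = "sum") -> float:
    """Area under one time course.

    ``sum`` adds the signal values at the sampled time points; ``trapezoid``
    integrates trapezoidally over time in minutes (needs >= 2 points).
    """
    if method == "sum":
        return float(np.sum(tc.signal))
    if method == "trapezoid":
        if tc.n_points < 2:
            raise ValueError("trapezoid AUC needs at least 2 time points")
        return float(np.trapezoid(tc.signal, tc.times))
    raise ValueError(f"unknown AUC method {method!r}; use 'sum' or 'trapezoid'")


def summarize_auc(
    courses: Iterable[TimeCourse], method: str = "sum"
) -> pd.DataFrame:
    """Per-replicate AUC table (cell_line, variant, replicate, auc, method)."""
    rows = [
        {
            "cell_line": tc.cell_line,
            "variant": tc.variant,
            "replicate": tc.replicate,
            "auc": auc(tc, method=method),
            "method": method,
        }
        for tc in courses
    ]
    if not rows:
        raise ValueError("no time courses to summarize")
    return pd.DataFrame(rows)


def fold_vs_reference(
    auc_table: pd.DataFrame, reference_variant: str
) -> pd.DataFrame:
    """Mean AUC per variant divided by the reference variant's, per cell line."""
    required = {"cell_line", "variant", "auc"}
    missing = required - set(auc_table.columns)
    if missing:
        raise ValueError(f"AUC table is missing columns: {sorted(missing)}")
    out = []
    for cell, grp in auc_table.groupby("cell_line", sort=True):
        means = grp.groupby("variant", sort=True)["auc"].agg(["mean", "std", "count"])
        if reference_variant not in means.index:
            raise ValueError(
                f"reference variant {reference_variant!r} absent in cell line {cell!r}"
            )
        ref_mean = float(means.loc[reference_variant, "mean"])
        if ref_mean <= 0:
            raise ValueError(
                f"reference variant {reference_variant!r} has non-positive mean AUC"
            )
        for variant, row in means.iterrows():
            out.append(
                {
                    "cell_line": cell,
                    "variant": variant,
                    "auc_mean": float(row["mean"]),
                    "auc_sd": float(row["std"]) if row["count"] > 1 else 0.0,
                    "n_replicates": int(row["count"]),
                    "fold_vs_reference": float(row["mean"]) / ref_mean,
                }
            )
    return pd.DataFrame(out)


def significance_tier(p: float) -> str:
    """The .05/.01/.001/.0001 significance ladder."""
    if not np.isfinite(p):
        return "ns"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def dunn_test(
    groups: Mapping[str, np.ndarray], p_adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc test with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))](1/n_i + 1/n_j))
    where T = sum(t^3 - t) over tie groups; two-sided p-values, adjusted by
    Bonferroni (default) or reported raw.
    """
    labels = sorted(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    all_values = np.concatenate(values)
    n_total = all_values.size
    ranks = stats.rankdata(all_values)
    mean_ranks = {}
    pos = 0
    for label, v in zip(labels, values):
        mean_ranks[label] = float(np.mean(ranks[pos : pos + v.size]))
        pos += v.size
    _, tie_counts = np.unique(all_values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for g1, g2 in pairs:
        n1, n2 = groups[g1], groups[g2]
        se = np.sqrt(var_factor * (1.0 / len(n1) + 1.0 / len(n2)))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        if p_adjust == "bonferroni" and np.isfinite(p):
            p = min(1.0, p * len(pairs))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_adj": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Gate decision plus adjusted pairwise p-values and significance tiers."""

    test_used: str  # "ANOVA+Tukey" or "KruskalWallis+Dunn"
    gate_pvalues: dict
    all_groups_normal: bool
    omnibus_pvalue: float
    pairwise: pd.DataFrame  # group1, group2, p_adj, significance


def gated_comparison(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Normality-gated comparison of per-variant replicate values.

    Shapiro-Wilk per group; every group must pass at alpha = .05 for the
    parametric branch (the stricter reading of a per-dataset gate, recorded
    in the output so the decision can be audited).
    """
    clean = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups to compare")
    for label, v in clean.items():
        if v.size < 3:
            raise ValueError(f"group {label!r} has < 3 values (Shapiro-Wilk minimum)")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {label!r} contains non-finite values")
    all_values = np.concatenate(list(clean.values()))
    if np.ptp(all_values) == 0:
        raise ValueError("constant data in all groups: tests undefined")

    labels = sorted(clean)
    gate_pvalues = {}
    for label in labels:
        v = clean[label]
        if np.ptp(v) == 0:
            gate_pvalues[label] = np.nan  # constant group cannot be normal-tested
            continue
        gate_pvalues[label] = float(stats.shapiro(v).pvalue)
    all_normal = all(
        np.isfinite(p) and p >= GATE_ALPHA for p in gate_pvalues.values()
    )

    if all_normal:
        test_used = "ANOVA+Tukey"
        omnibus = float(stats.f_oneway(*(clean[k] for k in labels)).pvalue)
        flat = np.concatenate([clean[k] for k in labels])
        tags = np.concatenate([[k] * clean[k].size for k in labels])
        tukey = pairwise_tukeyhsd(flat, tags, alpha=GATE_ALPHA)
        pairs = list(itertools.combinations(tukey.groupsunique, 2))
        pairwise = pd.DataFrame(
            {
                "group1": [p[0] for p in pairs],
                "group2": [p[1] for p in pairs],
                "p_adj": np.asarray(tukey.pvalues, dtype=float),
            }
        )
    else:
        test_used = "KruskalWallis+Dunn"
        omnibus = float(stats.kruskal(*(clean[k] for k in labels)).pvalue)
        pairwise = dunn_test(clean)[["group1", "group2", "p_adj"]].copy()
    pairwise["significance"] = [significance_tier(p) for p in pairwise["p_adj"]]
    return GroupComparison(
        test_used=test_used,
        gate_pvalues=gate_pvalues,
        all_groups_normal=all_normal,
        omnibus_pvalue=omnibus,
        pairwise=pairwise,
    )
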