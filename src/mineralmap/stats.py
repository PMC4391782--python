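"""Statistical comparisons between/within tissues and the summary report.

Paired and unpaired (Welch by default) t-tests compare mineral densities
between tissue groups; Bonferroni correction handles the multiple pairwise
dentin-zone comparisons; a median-based ANOVA (Mood's median test) compares
masked ROI pixel populations within a tissue. The report builder merges
segment mineral statistics with masked elemental-ratio statistics into one
table and flags statistically indistinguishable tissue pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ComparisonResult", "TissueReportRow", "t_test", "bonferroni",
    "median_anova", "build_report",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    groups: tuple[str, ...]
    test: str
    statistic: float
    p: float
    p_adjusted: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.p_adjusted is None:
            self.p_adjusted = self.p
        if self.significant is None:
            self.significant = self.p_adjusted < ALPHA


@dataclass
class TissueReportRow:
    tissue: str
    md_mean: float
    md_sd: float
    md_min: float
    md_max: float
    hu_mean: float | None = None
    n: int | None = None
    ca_p_mean: float | None = None
    ca_p_sd: float | None = None
    ca_zn_mean: float | None = None
    ca_zn_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.md_min - 1e-9 <= self.md_mean <= self.md_max + 1e-9:
            raise ValueError("md range must bracket the mean")


def t_test(group_a: np.ndarray, group_b: np.ndarray, paired: bool = False,
           names: tuple[str, str] = ("a", "b"), welch: bool = True) -> ComparisonResult:
    """Two-sided t-test between two samples.

    Unpaired comparisons use the Welch (unequal-variance) form by default;
    ``welch=False`` selects the pooled-variance form. Paired comparisons
    require equal sample sizes. Identical constant groups have no usable
    variance and raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal sample sizes")
        if np.ptp(a - b) == 0 and (a - b)[0] == 0:
            return ComparisonResult(groups=names, test="paired t",
                                    statistic=0.0, p=1.0)
        res = _sps.ttest_rel(a, b)
        test = "paired t"
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                return ComparisonResult(groups=names, test="unpaired t",
                                        statistic=0.0, p=1.0)
            raise ValueError("both groups are degenerate (zero variance)")
        res = _sps.ttest_ind(a, b, equal_var=not welch)
        test = "unpaired t (Welch)" if welch else "unpaired t (pooled)"
    return ComparisonResult(groups=names, test=test,
                            statistic=float(res.statistic), p=float(res.pvalue))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, m * p)`` each.

    ``m`` defaults to the number of tests and must be at least that number.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m_eff * p)


def median_anova(groups: Mapping[str, np.ndarray] | Sequence[np.ndarray],
                 ties: str = "below", method: str = "median") -> ComparisonResult:
    """Median-based ANOVA across two or more pixel populations.

    Implemented as Mood's median test: counts above/below the grand median
    per group. With exactly two groups the p-value is the two-sided Fisher
    exact probability of the resulting 2x2 table (an exact small-sample
    test); with more groups the chi-square form is used. ``method="kruskal"``
    switches to the Kruskal-Wallis rank test.
    """
    if isinstance(groups, Mapping):
        names = tuple(str(k) for k in groups)
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
        names = tuple(f"group{i + 1}" for i in range(len(samples)))
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    if method == "kruskal":
        res = _sps.kruskal(*samples)
        return ComparisonResult(groups=names, test="kruskal-wallis",
                                statistic=float(res.statistic), p=float(res.pvalue))
    if method != "median":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate(samples)
    grand = np.median(pooled)
    if np.all(pooled == grand):
        raise ValueError("all values equal the grand median; test undefined")
    above = np.array([(s > grand).sum() for s in samples])
    if ties == "below":
        below = np.array([(s <= grand).sum() for s in samples])
    elif ties == "above":
        above = np.array([(s >= grand).sum() for s in samples])
        below = np.array([(s < grand).sum() for s in samples])
    else:
        raise ValueError("ties must be 'below' or 'above'")
    if len(samples) == 2:
        table = np.array([above, below])
        odds, p = _sps.fisher_exact(table, alternative="two-sided")
        return ComparisonResult(groups=names, test="median (Fisher exact)",
                                statistic=float(odds), p=float(p))
    stat, p, _, _ = _sps.median_test(*samples, ties=ties)
    return ComparisonResult(groups=names, test="median (chi-square)",
                            statistic=float(stat), p=float(p))


def build_report(segment_stats: pd.DataFrame,
                 ratio_stats: pd.DataFrame | None = None,
                 comparisons: Sequence[ComparisonResult] = (),
                 ) -> tuple[pd.DataFrame, dict]:
    """Merge per-tissue mineral and elemental statistics into a report table.

    ``segment_stats`` needs columns ``tissue, mean_md, sd_md, md_min, md_max``
    (``mean_hu``/``n_voxels`` used when present). ``ratio_stats`` (optional)
    needs ``tissue, element_pair, mean, sd`` with pairs like ``"Ca/P"``.
    Comparisons whose adjusted p is not significant are flagged as
    statistically indistinguishable pairs. Tissues named by a comparison but
    absent from the table are listed under ``missing`` rather than fatal.
    """
    required = {"tissue", "mean_md", "sd_md", "md_min", "md_max"}
    if not required.issubset(segment_stats.columns):
        raise ValueError(f"segment_stats must have columns {sorted(required)}")
    rows = []
    for _, r in segment_stats.iterrows():
        row = TissueReportRow(
            tissue=str(r["tissue"]), md_mean=float(r["mean_md"]),
            md_sd=float(r["sd_md"]), md_min=float(r["md_min"]),
            md_max=float(r["md_max"]),
            hu_mean=float(r["mean_hu"]) if "mean_hu" in r else None,
            n=int(r["n_voxels"]) if "n_voxels" in r else None)
        rows.append(row)
    table = pd.DataFrame([vars(r) for r in rows])
    if ratio_stats is not None and len(ratio_stats):
        for pair, (mcol, scol) in (("Ca/P", ("ca_p_mean", "ca_p_sd")),
                                   ("Ca/Zn", ("ca_zn_mean", "ca_zn_sd"))):
            sub = ratio_stats[ratio_stats["element_pair"] == pair]
            for _, r in sub.iterrows():
                sel = table["tissue"] == r["tissue"]
                table.loc[sel, mcol] = float(r["mean"])
                table.loc[sel, scol] = float(r["sd"])
    known = set(table["tissue"])
    indistinct, missing = [], []
    for c in comparisons:
        absent = [g for g in c.groups if g not in known]
        missing.extend(absent)
        if not c.significant:
            indistinct.append(tuple(c.groups))
    summary = {
        "indistinguishable_pairs": indistinct,
        "missing": sorted(set(missing)),
        "comparisons": [vars(c) for c in comparisons],
    }
    return table, summary
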