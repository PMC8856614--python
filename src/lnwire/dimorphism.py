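"""Per-glomerulus group-frequency screening and correlation structure.

Compares innervation frequencies between two groups (sexes, mating states)
glomerulus by glomerulus with Pearson chi-square tests and family-wise
Bonferroni correction, restricted to glomeruli whose pooled two-group
frequency is strictly between 0 and 1 (a glomerulus innervated in every
neuron, or in none, carries no between-group information and would
degenerate the test). Also computes the pairwise Pearson correlation of
glomerulus columns across neurons.
"""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, SchemaError
from .profiles import ProfileCollection, frequency_table


@dataclass
class GroupContingency:
    """2x2 innervated/not-innervated counts for one glomerulus."""

    glomerulus: str
    a: int  # innervated, group 1
    b: int  # not innervated, group 1
    c: int  # innervated, group 2
    d: int  # not innervated, group 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d


def eligible_glomeruli(freq_g1: pd.DataFrame,
                       freq_g2: pd.DataFrame) -> list[str]:
    """Glomeruli whose pooled two-group innervation frequency is strictly
    inside (0, 1) — the testable family for the dimorphism screen."""
    g1 = freq_g1.set_index("glomerulus")
    g2 = freq_g2.set_index("glomerulus")
    if set(g1.index) != set(g2.index):
        raise SchemaError("frequency tables cover different glomerulus maps")
    out = []
    for name in freq_g1["glomerulus"]:
        pooled = g1.loc[name, "count_innervated"] + \
            g2.loc[name, "count_innervated"]
        total = g1.loc[name, "n"] + g2.loc[name, "n"]
        if 0 < pooled < total:
            out.append(name)
    return out


def frequency_chisq(table: GroupContingency,
                    yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table; returns (statistic, raw p).

    No continuity correction by default (``yates=True`` enables it). A
    zero expected cell raises :class:`DegenerateTableError`.
    """
    if table.n1 == 0 or table.n2 == 0:
        raise ValueError("both groups must be non-empty")
    obs = np.array([[table.a, table.b], [table.c, table.d]], float)
    if (obs.sum(axis=0) == 0).any():
        raise DegenerateTableError(
            f"{table.glomerulus}: expected cell of zero (pooled frequency "
            "0 or 1)")
    res = stats.chi2_contingency(obs, correction=yates)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(pvals: Sequence[float], m: int) -> list[float]:
    """Family-wise adjustment: each adjusted p = min(1, m * p)."""
    pvals = list(pvals)
    if m < len(pvals):
        raise ValueError("m must be >= number of p-values")
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in pvals]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def dimorphism_screen(collection: ProfileCollection, group_col: str = "sex",
                      yates: bool = False) -> pd.DataFrame:
    """Chi-square + Bonferroni screen of per-glomerulus frequencies
    between the two levels of ``group_col``.

    Only glomeruli with pooled frequency strictly in (0, 1) are tested;
    m for Bonferroni is the number of glomeruli actually tested. Returns
    one row per glomerulus with frequencies per group, ``tested`` flag,
    raw and adjusted p, ``m_tests`` and significance stars.
    """
    levels = sorted(collection.meta[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"screen requires exactly 2 levels in {group_col!r}, "
            f"got {levels}")
    freqs = frequency_table(collection, group_by=[group_col])
    f1 = freqs[freqs.group_label == levels[0]].reset_index(drop=True)
    f2 = freqs[freqs.group_label == levels[1]].reset_index(drop=True)
    eligible = set(eligible_glomeruli(f1, f2))
    m_tests = len(eligible)
    rows = []
    for r1, r2 in zip(f1.itertuples(), f2.itertuples()):
        name = r1.glomerulus
        tested = name in eligible
        raw_p = np.nan
        statistic = np.nan
        if tested:
            tab = GroupContingency(
                name, int(r1.count_innervated),
                int(r1.n - r1.count_innervated), int(r2.count_innervated),
                int(r2.n - r2.count_innervated))
            statistic, raw_p = frequency_chisq(tab, yates=yates)
        rows.append({
            "glomerulus": name,
            f"n_{levels[0]}": int(r1.n), f"n_{levels[1]}": int(r2.n),
            f"freq_{levels[0]}": float(r1.frequency),
            f"freq_{levels[1]}": float(r2.frequency),
            "tested": tested, "statistic": statistic, "raw_p": raw_p,
        })
    report = pd.DataFrame(rows)
    adj = np.full(len(report), np.nan)
    tested_mask = report["tested"].to_numpy()
    adj[tested_mask] = bonferroni_adjust(
        report.loc[tested_mask, "raw_p"].tolist(), m_tests)
    report["adjusted_p"] = adj
    report["m_tests"] = m_tests
    report["significance"] = [
        _stars(p) if np.isfinite(p) else "not tested" for p in adj]
    return report


def glomerulus_correlation(collection: ProfileCollection) -> pd.DataFrame:
    """Pairwise Pearson r between glomerulus columns (0/1 across neurons).

    r close to 1 means two glomeruli tend to be innervated by the same
    neurons; close to -1, by complementary neurons. Zero-variance columns
    (always or never innervated) have undefined correlation and are
    reported as NaN, never imputed.
    """
    if len(collection) < 2:
        raise ValueError("correlation needs at least two profiles")
    mat = collection.matrix.astype(float)
    names = list(collection.map.names)
    var = mat.var(axis=0)
    ok = var > 0
    out = np.full((len(names), len(names)), np.nan)
    if ok.sum() >= 2:
        out[np.ix_(ok, ok)] = np.corrcoef(mat[:, ok], rowvar=False)
    diag = np.where(ok, 1.0, np.nan)
    out[np.diag_indices_from(out)] = diag
    return pd.DataFrame(out, index=names, columns=names)
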