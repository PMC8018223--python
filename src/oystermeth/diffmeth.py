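"""Per-site differential methylation testing.

Implements the methylKit-style per-cytosine test: with replicated groups a
binomial logistic regression of methylated proportion on the group indicator
(likelihood-ratio chi-square, 1 df); without replicates a two-sided Fisher
exact test on pooled counts.  P values are adjusted by Benjamini-Hochberg
within each comparison, and differentially methylated cytosines (DMCs) are
those with pooled difference strictly greater than 25 percentage points and
q strictly below 0.05.

The logistic regression has a single binary covariate, so its maximum
likelihood fit is available in closed form (each group's fitted proportion is
its pooled proportion); the likelihood-ratio statistic is computed directly
and vectorised over sites.  Complete separation (one group fully methylated,
the other fully unmethylated) falls back to the Fisher test and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .calling import UnitedMatrix


@dataclass
class DMCSet:
    """DMCs of one pairwise comparison, plus the full per-site test table."""

    label: str
    group_a: list[str]
    group_b: list[str]
    diff_threshold: float
    q_threshold: float
    data: pd.DataFrame        # passing sites only
    all_sites: pd.DataFrame   # every tested site

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_hyper(self) -> int:
        return int((self.data["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.data["direction"] == "hypo").sum())


def methylation_difference(pooled_a: tuple[float, float],
                           pooled_b: tuple[float, float]) -> float:
    """Pooled percent methylation difference, group A minus group B.

    ``pooled_a`` and ``pooled_b`` are (methylated, unmethylated) read totals.
    Returns percentage points; raises on zero total coverage in either group.
    """
    ma, ua = pooled_a
    mb, ub = pooled_b
    if ma + ua <= 0 or mb + ub <= 0:
        raise ZeroDivisionError("zero total coverage in a group")
    return 100.0 * (ma / (ma + ua) - mb / (mb + ub))


def site_test_fisher(pooled_a: tuple[int, int], pooled_b: tuple[int, int]) -> float:
    """Two-sided Fisher exact p for one 2x2 table of pooled counts.

    Sums hypergeometric probabilities less than or equal to that of the
    observed table.  Degenerate margins (an all-zero row or column) give p=1.
    """
    table = np.array([pooled_a, pooled_b], dtype=np.int64)
    if table.min() < 0:
        raise ValueError("negative count")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _binomial_lrt(m_a, u_a, m_b, u_b):
    """Vectorised 1-df likelihood-ratio test of equal methylation proportions.

    Inputs are (n_sites, n_samples) count arrays per group.  Equivalent to a
    binomial logistic regression on the group indicator: the alternative fits
    one pooled proportion per group, the null a single pooled proportion.
    Returns (p, separated) where ``separated`` marks complete separation.
    """
    MA, UA = m_a.sum(axis=1), u_a.sum(axis=1)
    MB, UB = m_b.sum(axis=1), u_b.sum(axis=1)
    tA, tB = MA + UA, MB + UB
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = MA / tA
        pB = MB / tB
        p0 = (MA + MB) / (tA + tB)
        ll_alt = xlogy(MA, pA) + xlogy(UA, 1 - pA) + xlogy(MB, pB) + xlogy(UB, 1 - pB)
        ll_null = xlogy(MA + MB, p0) + xlogy(UA + UB, 1 - p0)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    at_bound_a = (pA == 0) | (pA == 1)
    at_bound_b = (pB == 0) | (pB == 1)
    separated = at_bound_a & at_bound_b & (pA != pB)
    return p, separated


def site_test_glm(group_a_counts, group_b_counts) -> tuple[float, bool]:
    """Replicated-design site test: logistic-regression LRT p for one site.

    ``group_a_counts`` / ``group_b_counts`` are sequences of per-sample
    (methylated, unmethylated) pairs, each group with >=2 samples.  Under
    complete separation the Fisher exact test on pooled counts is used
    instead; the returned flag is True when that fallback fired.
    """
    a = np.asarray(group_a_counts, dtype=float)
    b = np.asarray(group_b_counts, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("site_test_glm needs >=2 samples per group")
    p, sep = _binomial_lrt(a[None, :, 0], a[None, :, 1], b[None, :, 0], b[None, :, 1])
    if sep[0] or not np.isfinite(p[0]):
        pooled_a = (int(a[:, 0].sum()), int(a[:, 1].sum()))
        pooled_b = (int(b[:, 0].sum()), int(b[:, 1].sum()))
        return site_test_fisher(pooled_a, pooled_b), True
    return float(p[0]), False


def adjust_qvalues(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone in p-rank)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def get_methyl_diff(united: UnitedMatrix, group_a, group_b,
                    diff_threshold: float = 25.0, q_threshold: float = 0.05,
                    diff_mode: str = "pooled", label: str | None = None) -> DMCSet:
    """Test every site of a united matrix and apply the DMC filter.

    Uses the logistic-regression LRT when both groups are replicated, the
    Fisher exact test on pooled counts otherwise.  ``meth_diff`` is the
    pooled (coverage-weighted) percent difference A minus B by default;
    ``diff_mode='mean'`` uses the unweighted mean of per-sample fractions.
    Sites pass with |meth_diff| strictly > ``diff_threshold`` and q strictly
    < ``q_threshold``; hyper means A > B.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    for sid in group_a + group_b:
        if f"{sid}.M" not in united.data.columns:
            raise ValueError(f"sample {sid!r} absent from united matrix")
    if label is None:
        label = united.label or f"{'+'.join(group_a)} vs {'+'.join(group_b)}"
    df = united.data
    cols_m_a = [f"{s}.M" for s in group_a]
    cols_u_a = [f"{s}.U" for s in group_a]
    cols_m_b = [f"{s}.M" for s in group_b]
    cols_u_b = [f"{s}.U" for s in group_b]
    m_a = df[cols_m_a].to_numpy(dtype=float)
    u_a = df[cols_u_a].to_numpy(dtype=float)
    m_b = df[cols_m_b].to_numpy(dtype=float)
    u_b = df[cols_u_b].to_numpy(dtype=float)

    tot_a = (m_a + u_a).sum(axis=1)
    tot_b = (m_b + u_b).sum(axis=1)
    ok = (tot_a > 0) & (tot_b > 0)

    if diff_mode == "pooled":
        with np.errstate(invalid="ignore"):
            diff = 100.0 * (m_a.sum(axis=1) / tot_a - m_b.sum(axis=1) / tot_b)
    elif diff_mode == "mean":
        with np.errstate(invalid="ignore"):
            fa = m_a / (m_a + u_a)
            fb = m_b / (m_b + u_b)
        diff = 100.0 * (np.nanmean(fa, axis=1) - np.nanmean(fb, axis=1))
    else:
        raise ValueError(f"unknown diff_mode {diff_mode!r}")

    replicated = len(group_a) >= 2 and len(group_b) >= 2
    fallback = np.zeros(len(df), dtype=bool)
    if replicated:
        p, separated = _binomial_lrt(m_a, u_a, m_b, u_b)
        for i in np.nonzero(separated & ok)[0]:
            p[i] = site_test_fisher(
                (int(m_a[i].sum()), int(u_a[i].sum())),
                (int(m_b[i].sum()), int(u_b[i].sum())),
            )
            fallback[i] = True
    else:
        p = np.ones(len(df))
        for i in np.nonzero(ok)[0]:
            p[i] = site_test_fisher(
                (int(m_a[i].sum()), int(u_a[i].sum())),
                (int(m_b[i].sum()), int(u_b[i].sum())),
            )

    table = df[["scaffold", "pos", "strand"]].copy()
    if "context" in df.columns:
        table["context"] = df["context"]
    else:
        table["context"] = "CN/CHN"
    table["meth_diff"] = diff
    table["p"] = p
    table = table.loc[ok].reset_index(drop=True)
    fallback = fallback[ok]
    table["q"] = adjust_qvalues(table["p"].to_numpy()) if len(table) else []
    table["direction"] = np.where(table["meth_diff"] > 0, "hyper", "hypo")
    table["fisher_fallback"] = fallback
    passing = table[
        (table["meth_diff"].abs() > diff_threshold) & (table["q"] < q_threshold)
    ].reset_index(drop=True)
    return DMCSet(
        label=label, group_a=group_a, group_b=group_b,
        diff_threshold=diff_threshold, q_threshold=q_threshold,
        data=passing, all_sites=table,
    )


def write_dmcs_bed(dmcset: DMCSet, path) -> None:
    """Write passing DMCs as BED6-plus TSV (0-based half-open coordinates)."""
    df = dmcset.data
    out = pd.DataFrame(
        {
            "scaffold": df["scaffold"],
            "start": df["pos"] - 1,
            "end": df["pos"],
            "name": [f"{dmcset.label}|{i}" for i in range(len(df))],
            "meth_diff": df["meth_diff"],
            "strand": df["strand"],
            "p": df["p"],
            "q": df["q"],
            "direction": df["direction"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
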