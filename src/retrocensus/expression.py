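"""Expression profiling of LTR retroelements across tissues or stages.

Reads are matched to element sequences with a capped multi-hit policy: every
read may support up to ``max_hits`` elements (the best-scoring hits), and each
retained element's count is incremented by one — multi-mapping reads are the
norm for repeat families, and dropping or uniquely assigning them would
systematically hide recently proliferated elements.

Raw counts are normalized with the median-of-ratios size-factor estimator:
for sample j,

    s_j = median over elements i of  k_ij / (prod_j k_ij)^(1/m)

taken over elements with a positive geometric mean.  NRC_ij = k_ij / s_j is
the normalized read count, and NRC_rel divides each element's NRC by its
arithmetic mean across samples, so per-element profiles are comparable.

Per-element group comparisons use a transform-then-test battery: a Box–Cox
power transform (lambda by maximum likelihood on a grid over [-2, 2], step
0.01; lambda = 0 is the log), Shapiro–Wilk normality on residuals and Levene
variance homogeneity across groups; if both pass, a one-way ANOVA, otherwise
the rank-based Kruskal–Wallis test.  The full decision trail is returned.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def count_reads(
    reads: list[tuple[str, str]],
    element_seqs: dict[str, str],
    max_hits: int = 20,
    min_matchlen: int = 30,
    seed_len: int = 15,
    fractional: bool = False,
) -> pd.Series:
    """Count reads per element with the capped multi-hit policy.

    Matching is exact-seed + ungapped extension: a read hits an element if
    some shared ``seed_len``-mer extends (without gaps, along its diagonal) to
    at least ``min_matchlen`` matching bases; the hit score is the number of
    matching bases on the best diagonal.  The read's hit list is truncated to
    the ``max_hits`` best (score, then element input order) and each retained
    element is incremented by 1 — or by 1/len(hits) if ``fractional``.
    Both read orientations are tried.  Unmatched reads are ignored.
    """
    if not element_seqs:
        raise ValueError("no element sequences to count against")
    names = list(element_seqs)
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ei, name in enumerate(names):
        seq = element_seqs[name].upper()
        for pos in range(len(seq) - seed_len + 1):
            index[seq[pos:pos + seed_len]].append((ei, pos))
    counts = pd.Series(0.0, index=names)
    for _rid, read in reads:
        best_per_element: dict[int, int] = {}
        for oriented in (read.upper(), str(Seq(read).reverse_complement())):
            diagonals: set[tuple[int, int]] = set()
            for off in range(len(oriented) - seed_len + 1):
                for ei, pos in index.get(oriented[off:off + seed_len], ()):
                    diagonals.add((ei, pos - off))
            for ei, diag in diagonals:
                seq = element_seqs[names[ei]]
                lo = max(0, -diag)
                hi = min(len(oriented), len(seq) - diag)
                matches = sum(
                    1 for t in range(lo, hi) if oriented[t] == seq[t + diag]
                )
                if matches >= min_matchlen and matches > best_per_element.get(ei, 0):
                    best_per_element[ei] = matches
        if not best_per_element:
            continue
        hits = sorted(best_per_element.items(), key=lambda kv: (-kv[1], kv[0]))
        hits = hits[:max_hits]
        inc = 1.0 / len(hits) if fractional else 1.0
        for ei, _score in hits:
            counts.iloc[ei] += inc
    return counts if fractional else counts.astype(np.int64)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column)."""
    k = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.mean(np.log(k), axis=1)  # -inf for rows with any zero
    ref = np.isfinite(loggeo)
    if not ref.any():
        raise ValueError(
            "no element has all-positive counts; size factors are undefined"
        )
    logratios = np.log(k[ref, :]) - loggeo[ref, None]
    s = np.exp(np.median(logratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class NormalizedCounts:
    """Size factors plus NRC and NRC_rel matrices (elements x samples)."""

    size_factors: pd.Series
    nrc: pd.DataFrame
    nrc_rel: pd.DataFrame
    zero_elements: list[str]

    def __post_init__(self) -> None:
        expressed = ~self.nrc_rel.index.isin(self.zero_elements)
        means = self.nrc_rel.loc[expressed].mean(axis=1)
        if len(means) and not np.allclose(means, 1.0):
            raise AssertionError("NRC_rel rows of expressed elements must average 1")


def nrc_rel(row: np.ndarray | pd.Series) -> np.ndarray:
    """Divide a row of NRC values by its arithmetic mean (all-zero row -> zeros)."""
    arr = np.asarray(row, dtype=float)
    m = arr.mean()
    if m == 0:
        return np.zeros_like(arr)
    return arr / m


def normalize_counts(counts: pd.DataFrame) -> NormalizedCounts:
    """Counts -> size factors, NRC and NRC_rel, flagging all-zero elements."""
    s = size_factors(counts)
    nrc = counts.div(s, axis=1)
    zero = list(nrc.index[(nrc.mean(axis=1) == 0)])
    if zero:
        log.info("%d elements have zero counts everywhere; NRC_rel flagged 0", len(zero))
    rel = nrc.apply(nrc_rel, axis=1, result_type="broadcast")
    return NormalizedCounts(size_factors=s, nrc=nrc, nrc_rel=rel, zero_elements=zero)


# ---------------------------------------------------------------------------
# Transform-then-test battery
# ---------------------------------------------------------------------------

BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class TestResult:
    element: str
    boxcox_lambda: float
    shift: float
    shapiro_p: float
    levene_p: float
    test_used: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        for p in (self.shapiro_p, self.levene_p, self.p_value):
            if not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValueError("p-values must lie in [0, 1]")


def boxcox_transform(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Box–Cox transform with grid-MLE lambda; non-positive data are shifted.

    Returns (transformed, lambda, shift).  lambda = 0 applies the log.
    """
    x = np.asarray(values, dtype=float)
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - x.min()
        x = x + shift
    if np.allclose(x, x[0]):
        return x, 1.0, shift
    # profile log-likelihood over the whole grid at once:
    # llf(l) = (l - 1) * sum(log x) - n/2 * log(var_mle(y_l))
    logx = np.log(x)
    lams = BOXCOX_GRID[:, None]
    with np.errstate(over="ignore", invalid="ignore"):
        ys = np.where(lams == 0.0, logx[None, :], (x[None, :] ** lams - 1.0) / lams)
        var = ys.var(axis=1)
    llf = (BOXCOX_GRID - 1.0) * logx.sum() - 0.5 * len(x) * np.log(var)
    llf[~np.isfinite(llf)] = -np.inf
    lam = float(BOXCOX_GRID[int(np.argmax(llf))])
    y = np.log(x) if lam == 0.0 else (x**lam - 1.0) / lam
    return y, lam, shift


def test_element(
    values_by_group: dict[str, np.ndarray],
    alpha: float = 0.05,
    element: str = "",
) -> TestResult:
    """Transform-then-test one element's values across sample groups.

    Box–Cox first; Shapiro–Wilk on residuals and Levene across groups decide
    between one-way ANOVA (both p > alpha) and Kruskal–Wallis.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(list(groups.values()))
    transformed, lam, shift = boxcox_transform(pooled)
    tg: dict[str, np.ndarray] = {}
    at = 0
    for g, v in groups.items():
        tg[g] = transformed[at:at + len(v)]
        at += len(v)
    residuals = np.concatenate([v - v.mean() for v in tg.values()])
    if np.allclose(residuals, residuals[0]):
        shapiro_p = 1.0
    else:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
    if np.allclose(transformed, transformed[0]):
        levene_p = 1.0
    else:
        levene_p = float(stats.levene(*tg.values(), center="mean").pvalue)
    samples = list(tg.values())
    if shapiro_p > alpha and levene_p > alpha:
        if np.allclose(transformed, transformed[0]):
            stat, p = 0.0, 1.0
        else:
            res = stats.f_oneway(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
            if np.isnan(stat):  # zero between- and within-group variance
                stat, p = 0.0, 1.0
        used = "ANOVA"
    else:
        res = stats.kruskal(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
        used = "Kruskal-Wallis"
    return TestResult(
        element=element, boxcox_lambda=lam, shift=shift, shapiro_p=shapiro_p,
        levene_p=levene_p, test_used=used, statistic=stat, p_value=p,
    )


def test_all(
    values: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run the battery for every element (row) of a values matrix.

    ``groups`` maps sample name -> group label.  With ``bh_correct`` a
    Benjamini–Hochberg adjusted p-value column is appended.
    """
    groups = groups.loc[values.columns]
    rows = []
    for element, row in values.iterrows():
        by_group = {g: row[groups.index[groups == g]].to_numpy() for g in groups.unique()}
        r = test_element(by_group, alpha=alpha, element=str(element))
        rows.append(r.__dict__)
    out = pd.DataFrame(rows).set_index("element")
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Stage profiles
# ---------------------------------------------------------------------------

def stage_profile(nrc_by_type: pd.DataFrame, stage_order: list[str]) -> pd.DataFrame:
    """Per-stage share of total LTR RE expression for each element type.

    Input: NRC matrix with element types as rows and stages as columns.
    Output: stages (rows, in the given order) x types, each row summing to 1;
    an all-zero stage yields a zero row (flagged in the log).
    """
    missing = [s for s in stage_order if s not in nrc_by_type.columns]
    if missing:
        raise ValueError(f"stages not in matrix: {missing}")
    prof = nrc_by_type[stage_order].T
    sums = prof.sum(axis=1)
    zero_stages = list(prof.index[sums == 0])
    if zero_stages:
        log.warning("stages with zero total expression: %s", zero_stages)
    out = prof.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
    return out
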