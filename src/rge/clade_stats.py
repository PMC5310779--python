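"""Clade-level comparative statistics on gene x symbiont parameter tables.

Implements the comparative layer of the analysis: per-clade gene means,
round-robin paired-test matrices over every symbiont pair (with separate
all-gene and intact-gene halves), the degraded/intact clade-ratio analysis
with an exact Mann-Whitney U test, and pooled cross-parameter ordinary
least-squares regressions.

No multiple-testing correction is applied in any default output — the
matrices report raw round-robin p-values, with an optional Holm-adjusted
view available separately.  Significance is judged uniformly at 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ParameterTable

logger = logging.getLogger(__name__)

ALPHA = 0.05

TEN_GENES = [
    "uvrA",
    "uvrB",
    "uvrC",
    "uvrD",
    "uvrDp",
    "mfd",
    "mutY",
    "groEL",
    "groES",
    "galU",
]
INTACT_SIX = ["uvrA", "uvrDp", "mfd", "groEL", "groES", "galU"]
DEGRADED_IN_CLADE_I = ["uvrB", "uvrC", "mutY"]
RATIO_INTACT_SET = ["uvrA", "uvrD", "uvrDp", "mfd", "groEL", "groES", "galU"]


@dataclass
class TestResult:
    statistic: float
    p: float
    flag: str | None = None


@dataclass
class PairMatrix:
    """Round-robin paired-test p-values with two gene subsets.

    ``p_lower`` holds the all-genes half, ``p_upper`` the intact-genes
    half; both are full symmetric DataFrames indexed by symbiont.
    ``averages`` has one row per gene set with per-symbiont across-gene
    means.  ``flags`` marks degenerate cells.
    """

    symbiont_order: list[str]
    p_lower: pd.DataFrame
    p_upper: pd.DataFrame
    averages: pd.DataFrame
    flags_lower: pd.DataFrame
    flags_upper: pd.DataFrame
    gene_set_lower: list[str]
    gene_set_upper: list[str]


@dataclass
class RatioResult:
    """Clade I / clade II per-gene ratios split by degraded/intact group."""

    ratios_degraded: dict[str, float]
    ratios_intact: dict[str, float]
    degraded_mean: float
    degraded_sd: float
    intact_mean: float
    intact_sd: float
    u_statistic: float
    p: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int


def clade_summary(table: ParameterTable) -> pd.DataFrame:
    """Per-gene, per-clade NA-aware mean and sample SD (outgroup excluded)."""
    rows = []
    for clade in ("I", "II"):
        members = table.clade_members(clade)
        sub = table.values[members]
        for gene in table.genes:
            vals = sub.loc[gene].dropna()
            if vals.empty:
                logger.warning("all-NA cell: gene %s clade %s", gene, clade)
                rows.append((gene, clade, np.nan, np.nan, 0))
            else:
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                rows.append((gene, clade, float(vals.mean()), sd, len(vals)))
    return pd.DataFrame(rows, columns=["gene", "clade", "mean", "sd", "n"])


def _exact_mwu_applicable(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)


def two_sample_test(x, y=None, method: str = "welch", groups=None) -> TestResult:
    """Two-sided two-sample test (or one-way ANOVA over >= 2 groups).

    Mann-Whitney uses the exact null distribution when n1+n2 <= 12 with no
    ties, and the tie-corrected normal approximation otherwise.
    """
    if method == "anova":
        gs = [np.asarray(g, float) for g in (groups if groups is not None else [x, y])]
        if len(gs) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        if all(np.ptp(g) == 0 for g in gs) and len({g[0] for g in gs}) == 1:
            return TestResult(0.0, 1.0, flag="constant-data")
        f, p = stats.f_oneway(*gs)
        return TestResult(float(f), float(p))

    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if method == "mannwhitney":
        mode = "exact" if _exact_mwu_applicable(xa, ya) else "asymptotic"
        u, p = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=mode)
        return TestResult(float(u), float(p))
    if method not in {"student", "welch"}:
        raise ValueError(f"unknown test method {method!r}")
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("t-tests need n >= 2 per group")
    if xa.std(ddof=1) == 0 and ya.std(ddof=1) == 0:
        if xa.mean() == ya.mean():
            return TestResult(0.0, 1.0, flag="zero-variance")
        return TestResult(math.inf, 0.0, flag="zero-variance")
    t, p = stats.ttest_ind(xa, ya, equal_var=(method == "student"))
    return TestResult(float(t), float(p))


def _paired_p(diffs: np.ndarray) -> tuple[float, str | None]:
    """Two-sided paired-t p-value with defined degenerate behaviour."""
    if len(diffs) == 0:
        return 1.0, "self-pair"
    sd = diffs.std(ddof=1) if len(diffs) > 1 else 0.0
    if sd == 0.0:
        if diffs.mean() == 0.0:
            return 1.0, "degenerate-zero"
        return 0.0, "degenerate-shift"
    t = diffs.mean() / (sd / math.sqrt(len(diffs)))
    p = 2.0 * stats.t.sf(abs(t), df=len(diffs) - 1)
    return float(p), None


def round_robin_paired(
    table: ParameterTable, gene_set: list[str]
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Paired t-test over the shared genes of ``gene_set`` for every pair.

    Returns (p-value matrix, per-symbiont across-gene averages, flags).
    Genes NA in either member of a pair are dropped pairwise; pairs sharing
    fewer than 2 genes get NA with a warning; a symbiont paired with
    itself is reported as p=1 with a flag.
    """
    missing = [g for g in gene_set if g not in table.genes]
    if missing:
        raise ValueError(f"gene_set entries not in table: {missing}")
    symbionts = table.ingroup_symbionts()
    sub = table.values.loc[gene_set, symbionts]
    pvals = pd.DataFrame(np.nan, index=symbionts, columns=symbionts)
    flags = pd.DataFrame("", index=symbionts, columns=symbionts)
    for i, a in enumerate(symbionts):
        for b in symbionts[i:]:
            if a == b:
                pvals.at[a, b] = 1.0
                flags.at[a, b] = "self-pair"
                continue
            pair = sub[[a, b]].dropna()
            if len(pair) < 2:
                logger.warning(
                    "pair (%s, %s): only %d shared genes, p undefined", a, b, len(pair)
                )
                flags.at[a, b] = flags.at[b, a] = "too-few-genes"
                continue
            diffs = (pair[a] - pair[b]).to_numpy()
            p, flag = _paired_p(diffs)
            pvals.at[a, b] = pvals.at[b, a] = p
            if flag:
                flags.at[a, b] = flags.at[b, a] = flag
    averages = sub.mean(axis=0, skipna=True)
    return pvals, averages, flags


def pair_matrix(
    table: ParameterTable,
    all_genes: list[str] | None = None,
    intact_genes: list[str] | None = None,
) -> PairMatrix:
    """Two-halves probability matrix: all genes (lower) / intact genes (upper)."""
    all_genes = all_genes if all_genes is not None else list(table.genes)
    intact_genes = intact_genes if intact_genes is not None else INTACT_SIX
    p_lower, avg_a, flags_lower = round_robin_paired(table, all_genes)
    p_upper, avg_b, flags_upper = round_robin_paired(table, intact_genes)
    averages = pd.DataFrame([avg_a, avg_b], index=["all_genes", "intact_genes"])
    return PairMatrix(
        symbiont_order=list(p_lower.index),
        p_lower=p_lower,
        p_upper=p_upper,
        averages=averages,
        flags_lower=flags_lower,
        flags_upper=flags_upper,
        gene_set_lower=list(all_genes),
        gene_set_upper=list(intact_genes),
    )


def holm_adjust(pvals: pd.DataFrame) -> pd.DataFrame:
    """Holm-adjusted view of a symmetric p-value matrix (non-default output)."""
    from statsmodels.stats.multitest import multipletests

    syms = list(pvals.index)
    cells = [
        (a, b)
        for i, a in enumerate(syms)
        for b in syms[i + 1 :]
        if not pd.isna(pvals.at[a, b])
    ]
    raw = [pvals.at[a, b] for a, b in cells]
    out = pvals.copy()
    if raw:
        adj = multipletests(raw, method="holm")[1]
        for (a, b), q in zip(cells, adj):
            out.at[a, b] = out.at[b, a] = q
    return out


def _clade_gene_mean(
    table: ParameterTable, gene: str, clade: str, intact_only: bool
) -> float:
    members = table.clade_members(clade)
    vals = []
    for sym in members:
        v = table.values.at[gene, sym]
        if pd.isna(v):
            continue
        if intact_only and table.status is not None:
            if table.status.at[gene, sym] != "intact":
                continue
        vals.append(float(v))
    return float(np.mean(vals)) if vals else np.nan


def ratio_analysis(
    table: ParameterTable,
    degraded_genes: list[str] | None = None,
    intact_genes: list[str] | None = None,
) -> RatioResult:
    """Clade I / clade II per-gene ratios, compared between gene groups.

    For genes intact in both clades only intact cells enter the clade
    means (a gene degraded in a couple of taxa contributes its intact
    copies only); for the degraded-in-clade-I group all measured cells
    enter, since the clade I values are the remnants themselves.  The two
    ratio groups are compared with a two-sided exact Mann-Whitney U test.
    """
    degraded_genes = degraded_genes if degraded_genes is not None else DEGRADED_IN_CLADE_I
    intact_genes = intact_genes if intact_genes is not None else RATIO_INTACT_SET
    if not degraded_genes or not intact_genes:
        raise ValueError("both gene sets must be non-empty")
    overlap = set(degraded_genes) & set(intact_genes)
    if overlap:
        raise ValueError(f"gene sets overlap: {sorted(overlap)}")

    def ratios(genes: list[str], intact_only: bool) -> dict[str, float]:
        out = {}
        for gene in genes:
            m1 = _clade_gene_mean(table, gene, "I", intact_only=intact_only)
            m2 = _clade_gene_mean(table, gene, "II", intact_only=intact_only)
            if np.isnan(m1) or np.isnan(m2):
                continue
            if m2 == 0:
                raise ValueError(f"zero clade II mean for gene {gene!r}")
            out[gene] = m1 / m2
        return out

    r_deg = ratios(degraded_genes, intact_only=False)
    r_int = ratios(intact_genes, intact_only=True)
    if not r_deg or not r_int:
        raise ValueError("no computable ratios in one of the gene groups")
    deg = np.array(list(r_deg.values()))
    intact = np.array(list(r_int.values()))
    res = two_sample_test(deg, intact, method="mannwhitney")
    return RatioResult(
        ratios_degraded=r_deg,
        ratios_intact=r_int,
        degraded_mean=float(deg.mean()),
        degraded_sd=float(deg.std(ddof=1)) if len(deg) > 1 else 0.0,
        intact_mean=float(intact.mean()),
        intact_sd=float(intact.std(ddof=1)) if len(intact) > 1 else 0.0,
        u_statistic=res.statistic,
        p=res.p,
    )


def parameter_regression(
    x_param: ParameterTable, y_param: ParameterTable
) -> RegressionResult:
    """OLS of y on x over all matched (gene, symbiont) cells.

    Every cell is one point — genes and symbionts are pooled, mirroring a
    per-gene-per-symbiont scatter; phylogenetic non-independence of the
    points is accepted as part of the replicated design.
    """
    common_genes = [g for g in x_param.genes if g in set(y_param.genes)]
    common_syms = [s for s in x_param.symbionts if s in set(y_param.symbionts)]
    xs, ys = [], []
    for gene in common_genes:
        for sym in common_syms:
            xv = x_param.values.at[gene, sym]
            yv = y_param.values.at[gene, sym]
            if pd.isna(xv) or pd.isna(yv):
                continue
            xs.append(float(xv))
            ys.append(float(yv))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} paired cells; need >= 3 for regression")
    xs = np.array(xs)
    ys = np.array(ys)
    if xs.std() == 0:
        raise ValueError("zero variance in x; regression undefined")
    fit = stats.linregress(xs, ys)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(xs),
    )
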