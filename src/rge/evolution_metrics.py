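"""Pairwise genetic distances from the outgroup ortholog and NG86 dN/dS.

Distances come in four flavours: raw mismatch proportion (p), the JC69 and
K80 closed-form corrections, and a numerically maximised pairwise HKY
likelihood with empirical base frequencies.  Gap/N columns are removed
pairwise (pairwise deletion), because degraded remnants have gene-specific
deletion patterns and complete deletion would discard most sites.

dN/dS uses the Nei-Gojobori (1986) counting method: per-codon synonymous
site fractions from the standard genetic code, averaged over the two
sequences; equal-weight averaging over all mutational pathways for
codons differing at 2 or 3 positions; Jukes-Cantor correction applied to
pN and pS separately.  It is intended for intact coding genes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.linalg import expm
from scipy.optimize import minimize

from .sequence_io import GeneMatrix
from .tables import ParameterTable

_BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_CODON_TABLE.stop_codons)


class AlignmentError(ValueError):
    pass


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped DNA strings."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentError(
                f"aligned sequences differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )

    @property
    def comparable_sites(self) -> int:
        skip = set("N-")
        return sum(
            1 for a, b in zip(self.seq_a, self.seq_b) if a not in skip and b not in skip
        )


@dataclass
class DistanceResult:
    model: str
    t: float
    comparable_sites: int
    kappa_hat: float | None = None
    saturated: bool = False
    symbiont_id: str | None = None
    gene_id: str | None = None


@dataclass
class DnDsResult:
    N_sites: float
    S_sites: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: float | None  # None when dS == 0
    codons_compared: int
    symbiont_id: str | None = None
    gene_id: str | None = None


def pairwise_mask(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Drop columns where either sequence carries a gap or N."""
    skip = set("N-")
    kept_a = []
    kept_b = []
    for a, b in zip(aln.seq_a, aln.seq_b):
        if a in skip or b in skip:
            continue
        kept_a.append(a)
        kept_b.append(b)
    if not kept_a:
        raise AlignmentError("zero comparable sites after gap/N masking")
    return PairwiseAlignment("".join(kept_a), "".join(kept_b))


def _mismatch_fractions(aln: PairwiseAlignment) -> tuple[float, float, float, int]:
    """(p, P_transition, Q_transversion, n_sites) on a masked alignment."""
    n = len(aln.seq_a)
    ts = tv = 0
    for a, b in zip(aln.seq_a, aln.seq_b):
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return (ts + tv) / n, ts / n, tv / n, n


def _hky_rate_matrix(pi: np.ndarray, kappa: float) -> np.ndarray:
    """HKY rate matrix (A,C,G,T order), scaled to one expected sub/site."""
    Q = np.zeros((4, 4))
    for i, a in enumerate(_BASES):
        for j, b in enumerate(_BASES):
            if i == j:
                continue
            Q[i, j] = kappa * pi[j] if (a, b) in _TRANSITIONS else pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale


def _pattern_counts(aln: PairwiseAlignment) -> np.ndarray:
    idx = {b: i for i, b in enumerate(_BASES)}
    counts = np.zeros((4, 4))
    for a, b in zip(aln.seq_a, aln.seq_b):
        counts[idx[a], idx[b]] += 1
    return counts


def _hky_ml_distance(aln: PairwiseAlignment) -> tuple[float, float]:
    """Maximise the pairwise HKY likelihood over (t, kappa)."""
    counts = _pattern_counts(aln)
    # empirical base frequencies, pooled over both sequences
    pi = counts.sum(axis=1) + counts.sum(axis=0)
    pi = pi / pi.sum()
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()
    # symmetrise: the pairwise likelihood is reversible, direction carries
    # no information
    sym = (counts + counts.T) / 2.0

    def neg_loglik(params: np.ndarray) -> float:
        t = math.exp(params[0])
        kappa = math.exp(params[1])
        P = expm(_hky_rate_matrix(pi, kappa) * t)
        with np.errstate(divide="ignore"):
            logjoint = np.log(np.clip(pi[:, None] * P, 1e-300, None))
        return -float((sym * logjoint).sum())

    p0 = max(_mismatch_fractions(aln)[0], 1e-4)
    t0 = jc69_distance(p0) if p0 < 0.70 else 1.0
    res = minimize(
        neg_loglik,
        x0=np.log([max(t0, 1e-4), 2.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 4000},
    )
    return float(math.exp(res.x[0])), float(math.exp(res.x[1]))


def jc69_distance(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.inf
    return -0.75 * math.log(arg)


def k80_distance(P: float, Q: float) -> tuple[float, float]:
    """(t, kappa_hat) from transition/transversion proportions."""
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return math.inf, math.nan
    A = -math.log(a1)
    B = -math.log(a2)
    t = A / 2.0 + B / 4.0
    kappa = 2.0 * A / B - 1.0 if B > 0 else math.nan
    return t, kappa


def nucleotide_distance(
    aln: PairwiseAlignment,
    model: str = "k80",
    symbiont_id: str | None = None,
    gene_id: str | None = None,
) -> DistanceResult:
    """Pairwise nucleotide distance in substitutions/site."""
    model = model.lower().replace("-ml", "")
    if model not in {"p", "jc69", "k80", "hky"}:
        raise ValueError(f"unknown distance model {model!r}")
    masked = pairwise_mask(aln)
    p, P, Q, n = _mismatch_fractions(masked)
    kappa_hat = None
    saturated = False
    if model == "p":
        t = p
    elif model == "jc69":
        t = jc69_distance(p)
        saturated = math.isinf(t)
    elif model == "k80":
        t, kappa_hat = k80_distance(P, Q)
        saturated = math.isinf(t)
    else:  # hky, numeric ML
        t, kappa_hat = _hky_ml_distance(masked)
    return DistanceResult(
        model=model,
        t=t,
        comparable_sites=n,
        kappa_hat=kappa_hat,
        saturated=saturated,
        symbiont_id=symbiont_id,
        gene_id=gene_id,
    )


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, None for a stop codon."""
    return _CODON_TABLE.forward_table.get(codon)


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one codon.

    Each position contributes its fraction of synonymous single-base
    changes; changes to stop codons count as non-synonymous.  Counts are
    normalised so every codon carries exactly 3 sites.  ``kappa`` > 1
    weights transition changes more heavily (a transition-bias-aware
    variant; the classic method uses kappa = 1).
    """
    aa = _translate(codon)
    syn = non = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            w = kappa if (codon[pos], base) in _TRANSITIONS else 1.0
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if _translate(neighbour) == aa and neighbour not in _STOPS:
                syn += w
            else:
                non += w
    total = syn + non
    return 3.0 * syn / total, 3.0 * non / total


@lru_cache(maxsize=None)
def _codon_difference_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, non-synonymous) differences.

    All orderings of the differing positions get equal weight; a step is
    synonymous when both codons translate identically (stops translate to
    no amino acid, so any step into or out of a stop is non-synonymous
    unless both ends are stops).
    """
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = list(permutations(diff_pos))
    weight = 1.0 / len(paths)
    syn = non = 0.0
    for order in paths:
        current = codon1
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if _translate(current) == _translate(nxt):
                syn += weight
            else:
                non += weight
            current = nxt
    return syn, non


def _jc_correct(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.inf
    return -0.75 * math.log(arg)


def ng86_dn_ds(
    codon_aln: PairwiseAlignment,
    symbiont_id: str | None = None,
    gene_id: str | None = None,
    kappa: float = 1.0,
) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS for an aligned codon pair.

    The alignment length must be divisible by 3; codon pairs where either
    codon contains a gap or N, or is a stop codon, are excluded pairwise.
    ``kappa`` = 1 is the classic method; larger values weight transitions
    in the site counting only.
    """
    if len(codon_aln.seq_a) % 3 != 0:
        raise AlignmentError(
            f"codon alignment length {len(codon_aln.seq_a)} not divisible by 3"
        )
    bad = set("N-")
    pairs = []
    for i in range(0, len(codon_aln.seq_a), 3):
        c1 = codon_aln.seq_a[i : i + 3]
        c2 = codon_aln.seq_b[i : i + 3]
        if bad & set(c1) or bad & set(c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        pairs.append((c1, c2))
    if not pairs:
        raise AlignmentError("no comparable codons for dN/dS")
    S_sites = N_sites = Sd = Nd = 0.0
    for c1, c2 in pairs:
        s1, n1 = _codon_site_fractions(c1, kappa)
        s2, n2 = _codon_site_fractions(c2, kappa)
        S_sites += (s1 + s2) / 2.0
        N_sites += (n1 + n2) / 2.0
        sd, nd = _codon_difference_counts(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S_sites
    pN = Nd / N_sites
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    if dS == 0.0:
        ratio = None  # no synonymous signal: ratio undefined, not infinite
    elif math.isinf(dS) and math.isinf(dN):
        ratio = math.nan
    else:
        ratio = dN / dS  # finite/inf -> 0.0 (saturated dS dominates)
    return DnDsResult(
        N_sites=N_sites,
        S_sites=S_sites,
        pN=pN,
        pS=pS,
        dN=dN,
        dS=dS,
        ratio=ratio,
        codons_compared=len(pairs),
        symbiont_id=symbiont_id,
        gene_id=gene_id,
    )


# ---------------------------------------------------------------------------
# table-level wrappers
# ---------------------------------------------------------------------------


def pairwise_vs_outgroup(
    msa_records: list[tuple[str, str]],
    outgroup_id: str,
    delimiter: str = "|",
) -> dict[str, PairwiseAlignment]:
    """Project a per-gene MSA onto pairwise alignments against the outgroup.

    Columns where both members are gaps are dropped; everything else is
    kept (masking happens downstream).  Headers follow the
    "symbiont_id|gene_id" convention; the outgroup record is required.
    """
    seqs = {}
    for header, seq in msa_records:
        sym = header.split()[0].split(delimiter)[0]
        seqs[sym] = seq
    if outgroup_id not in seqs:
        raise AlignmentError(f"outgroup {outgroup_id!r} missing from alignment")
    out_seq = seqs[outgroup_id]
    result = {}
    for sym, seq in seqs.items():
        a_cols = []
        b_cols = []
        for a, b in zip(seq, out_seq):
            if a == "-" and b == "-":
                continue
            a_cols.append(a)
            b_cols.append(b)
        result[sym] = PairwiseAlignment("".join(a_cols), "".join(b_cols))
    return result


def distance_table(
    matrix: GeneMatrix,
    alignments: dict[str, dict[str, PairwiseAlignment]],
    model: str = "k80",
) -> ParameterTable:
    """Genes x symbionts table of distances to the outgroup ortholog."""
    values = pd.DataFrame(np.nan, index=matrix.gene_order, columns=matrix.symbiont_order)
    for gene in matrix.gene_order:
        if gene not in alignments:
            raise AlignmentError(f"no alignment provided for gene {gene!r}")
        per_sym = alignments[gene]
        for sym in matrix.symbiont_order:
            rec = matrix.get(gene, sym)
            if rec is None or rec.status == "absent":
                continue
            if sym not in per_sym:
                raise AlignmentError(f"gene {gene!r}: no aligned row for {sym!r}")
            res = nucleotide_distance(per_sym[sym], model, sym, gene)
            values.at[gene, sym] = res.t if math.isfinite(res.t) else np.nan
    return ParameterTable(
        parameter="distance",
        values=values,
        status=matrix.status_frame(),
        clade_map=matrix.clade_map(),
    )


def dnds_table(
    matrix: GeneMatrix,
    alignments: dict[str, dict[str, PairwiseAlignment]],
) -> ParameterTable:
    """dN/dS vs the outgroup for intact genes only (remnants -> NA)."""
    values = pd.DataFrame(np.nan, index=matrix.gene_order, columns=matrix.symbiont_order)
    for gene in matrix.gene_order:
        per_sym = alignments.get(gene, {})
        for sym in matrix.symbiont_order:
            rec = matrix.get(gene, sym)
            if rec is None or rec.status != "intact" or sym not in per_sym:
                continue
            try:
                res = ng86_dn_ds(per_sym[sym], sym, gene)
            except AlignmentError:
                continue
            if res.ratio is not None and math.isfinite(res.ratio):
                values.at[gene, sym] = res.ratio
    return ParameterTable(
        parameter="dnds",
        values=values,
        status=matrix.status_frame(),
        clade_map=matrix.clade_map(),
    )
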