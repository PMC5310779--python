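"""Two-clade sequence-evolution simulator with ground truth.

Generates gene x symbiont datasets with the statistical structure the
comparative analysis assumes: a rooted tree with an outgroup and two
in-group clades, per-clade substitution-rate multipliers and GC
equilibria, HKY substitution dynamics with purifying selection applied as
acceptance thinning of non-synonymous events, and pseudogenization
(selection release plus an internal-deletion process) on designated
branches.  Because only deletions are modelled, homology can be tracked
exactly through the run and true alignments are emitted without any
realignment.

Units: branch lengths are expected substitutions per site for a neutral
(omega = 1) sequence at equilibrium; omega < 1 slows the realised rate by
thinning non-synonymous events.  Deletion rates are expected deletion
events per site per branch (a separate clock from substitutions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .repeat_density import encode_sequence
from .sequence_io import GeneMatrix, GeneRecord, write_fasta

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")
_STOP_SET = frozenset(_STOP_CODONS)

CLADE_I_TIPS = ["Akaw_S", "Clau_S", "Pkil_S", "Psoy_S", "Vok"]
CLADE_II_TIPS = ["Cpac_S", "Cfau_S", "Cnau_S", "Pste_S", "Rma", "Ifos_S", "Apha_S"]
OUTGROUP_ID = "Bsep_S"


def default_tree() -> dict[str, list[tuple[str, float]]]:
    """Rooted default topology: outgroup + 5 clade I tips + 7 clade II tips.

    Branch lengths (neutral expected subs/site) place the in-group split
    well inside the tree and give clade I a longer stem, mirroring the
    deeper pre-radiation branch of that lineage.
    """
    return {
        "root": [(OUTGROUP_ID, 0.55), ("anc", 0.20)],
        "anc": [("cladeI", 0.35), ("cladeII", 0.10)],
        "cladeI": list(zip(CLADE_I_TIPS, [0.08, 0.09, 0.10, 0.11, 0.12])),
        "cladeII": list(zip(CLADE_II_TIPS, [0.08, 0.09, 0.10, 0.10, 0.11, 0.12, 0.10])),
    }


def node_clade(node: str) -> str | None:
    """Clade tag governing rate multiplier and GC equilibrium on a branch."""
    if node == "cladeI" or node in CLADE_I_TIPS:
        return "I"
    if node == "cladeII" or node in CLADE_II_TIPS:
        return "II"
    if node == OUTGROUP_ID:
        return "outgroup"
    return None  # root-side internal branches


@dataclass
class GeneSpec:
    """One simulated gene: id, internal (non start/stop) codons, omega."""

    gene_id: str
    n_codons: int
    omega: float

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError(f"{self.gene_id}: n_codons must be >= 1")
        if not (0.0 <= self.omega):
            raise ValueError(f"{self.gene_id}: omega must be >= 0")


@dataclass
class PseudogenizationSpec:
    """Selection release + deletions starting on the branch into ``branch``."""

    gene_id: str
    branch: str
    deletion_rate: float = 0.004  # expected deletion events / site / branch
    mean_del_len: float = 25.0

    def __post_init__(self) -> None:
        if self.deletion_rate < 0:
            raise ValueError("deletion_rate must be >= 0")
        if self.mean_del_len < 1:
            raise ValueError("mean deletion length must be >= 1")


def default_gene_specs() -> list[GeneSpec]:
    # codon counts follow the real panel's gene lengths (uvrA 2817 bp ...
    # groES ~230 bp); omegas follow the per-gene dN/dS scale of the system
    return [
        GeneSpec("uvrA", 937, 0.16),
        GeneSpec("uvrB", 663, 0.30),
        GeneSpec("uvrC", 593, 0.30),
        GeneSpec("uvrD", 719, 0.26),
        GeneSpec("uvrDp", 1051, 0.44),
        GeneSpec("mfd", 1140, 0.25),
        GeneSpec("mutY", 348, 0.30),
        GeneSpec("groEL", 546, 0.18),
        GeneSpec("groES", 75, 0.35),
        GeneSpec("galU", 298, 0.20),
    ]


def default_pseudogenization() -> list[PseudogenizationSpec]:
    # uvrB/uvrC/mutY lost on the clade I stem; uvrD lost independently in
    # the two clade II tips that lack it in the real panel
    return [
        PseudogenizationSpec("uvrB", "cladeI"),
        PseudogenizationSpec("uvrC", "cladeI"),
        PseudogenizationSpec("mutY", "cladeI"),
        PseudogenizationSpec("uvrD", "Ifos_S"),
        PseudogenizationSpec("uvrD", "Apha_S"),
    ]


@dataclass
class SimulationConfig:
    tree: dict[str, list[tuple[str, float]]] = field(default_factory=default_tree)
    rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"I": 1.5, "II": 1.0}
    )
    gc_equilibrium: dict[str, float] = field(
        default_factory=lambda: {"I": 0.32, "II": 0.38}
    )
    root_gc: float = 0.38
    kappa: float = 4.0
    gene_specs: list[GeneSpec] = field(default_factory=default_gene_specs)
    pseudogenization: list[PseudogenizationSpec] = field(
        default_factory=default_pseudogenization
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for node, children in self.tree.items():
            for child, bl in children:
                if bl < 0:
                    raise ValueError(f"negative branch length into {child!r}")
        for key, gc in list(self.gc_equilibrium.items()) + [("root", self.root_gc)]:
            if not (0.0 < gc < 1.0):
                raise ValueError(f"GC equilibrium for {key!r} must be in (0,1)")
        gene_ids = [g.gene_id for g in self.gene_specs]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in gene_specs")
        known = set(gene_ids)
        nodes = set(self.tree) | {c for ch in self.tree.values() for c, _ in ch}
        for ev in self.pseudogenization:
            if ev.gene_id not in known:
                raise ValueError(f"pseudogenization of unknown gene {ev.gene_id!r}")
            if ev.branch not in nodes:
                raise ValueError(f"pseudogenization on unknown branch {ev.branch!r}")

    def tips(self) -> list[str]:
        children = {c for ch in self.tree.values() for c, _ in ch}
        return [c for c in children if c not in self.tree]


@dataclass
class SimulationTruth:
    """Generating parameters and realised events for recovery tests."""

    config: SimulationConfig
    substitutions: dict[str, dict[str, int]]  # gene -> child node -> accepted subs
    tip_gc: dict[str, dict[str, float]]  # gene -> tip -> realised GC fraction
    deletions: dict[str, dict[str, list[dict]]]  # gene -> node -> event log


@dataclass
class SimulationResult:
    matrix: GeneMatrix
    alignments: dict[str, list[tuple[str, str]]]  # gene -> [(taxon, gapped seq)]
    truth: SimulationTruth


def _equilibrium_freqs(gc: float) -> np.ndarray:
    # A, C, G, T with A=T and C=G (the GC/AT balance is the only free axis)
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _codon_probs(gc: float) -> tuple[list[str], np.ndarray]:
    pi = _equilibrium_freqs(gc)
    codons = []
    probs = []
    for i, a in enumerate(_BASES):
        for j, b in enumerate(_BASES):
            for k, c in enumerate(_BASES):
                codon = a + b + c
                if codon in _STOP_SET:
                    continue
                codons.append(codon)
                probs.append(pi[i] * pi[j] * pi[k])
    p = np.array(probs)
    return codons, p / p.sum()


def simulate_root_sequence(length_codons: int, gc_equilibrium: float, seed) -> str:
    """ATG + ``length_codons`` iid non-stop codons + one stop codon.

    Codon base frequencies are position-independent with the requested GC
    (A=T=(1-pi_GC)/2, G=C=pi_GC/2); stop codons are rejected.  The stop
    codon is drawn with probability proportional to its base frequencies
    (uniformly when the composition gives all stops zero weight).
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if length_codons == 1:
        logger.info("minimal gene: single internal codon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons, probs = _codon_probs(gc_equilibrium)
    body = "".join(rng.choice(codons, size=length_codons, p=probs))
    pi = _equilibrium_freqs(gc_equilibrium)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    stop_w = np.array(
        [math.prod(pi[base_idx[c]] for c in stop) for stop in _STOP_CODONS]
    )
    if stop_w.sum() == 0:
        stop = _STOP_CODONS[0]
    else:
        stop = _STOP_CODONS[int(rng.choice(3, p=stop_w / stop_w.sum()))]
    return "ATG" + body + stop


_GENCODE: dict[str, str | None] = {}


def _build_gencode() -> None:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                codon = a + b + c
                _GENCODE[codon] = table.forward_table.get(codon)


_build_gencode()


def _hky_proposal(kappa: float, gc: float) -> tuple[np.ndarray, np.ndarray]:
    """(per-base total rate, per-base cumulative target probabilities).

    Rates are scaled so a neutral sequence at equilibrium accumulates one
    expected substitution per site per unit branch length.
    """
    pi = _equilibrium_freqs(gc)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = kappa * pi[j] if (i, j) in transitions else pi[j]
    leave = Q.sum(axis=1)
    scale = float(pi @ leave)
    Q /= scale
    leave = Q.sum(axis=1)
    cum_targets = np.cumsum(Q / leave[:, None], axis=1)
    return leave, cum_targets


def evolve_sequence(
    seq: str,
    branch_length: float,
    kappa: float,
    gc_equilibrium: float,
    omega: float,
    seed,
    return_events: bool = False,
):
    """Evolve a sequence for ``branch_length`` expected neutral subs/site.

    Substitutions are proposed per site at HKY rates with equilibrium
    frequencies set by ``gc_equilibrium`` and accepted with probability 1
    when synonymous and ``omega`` when non-synonymous (Gillespie event
    sampling with acceptance thinning).  When omega < 1 the sequence is
    treated as a frame-1 ORF and proposals creating an internal stop codon
    are rejected outright (nonsense changes are never tolerated by
    purifying selection here); when omega >= 1 every proposal is accepted,
    with no reading-frame bookkeeping — that is the pseudogene regime.
    """
    if branch_length < 0:
        raise ValueError("negative branch length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if branch_length == 0 or not seq:
        return (seq, 0) if return_events else seq
    codes = encode_sequence(seq)
    leave, cum_targets = _hky_proposal(kappa, gc_equilibrium)
    rates = leave[codes]
    total = float(rates.sum())
    cum = np.cumsum(rates)
    n_codons_full = len(codes) // 3
    neutral = omega >= 1.0
    n_sub = 0
    t = 0.0
    while True:
        t += rng.exponential(1.0 / total)
        if t >= branch_length:
            break
        site = int(np.searchsorted(cum, rng.random() * total, side="right"))
        site = min(site, len(codes) - 1)
        old = codes[site]
        new = int(np.searchsorted(cum_targets[old], rng.random(), side="right"))
        new = min(new, 3)
        accept = True
        if not neutral:
            ci = site // 3
            if ci < n_codons_full:
                start = 3 * ci
                codon = _BASES[codes[start]] + _BASES[codes[start + 1]] + _BASES[codes[start + 2]]
                mutated = codon[: site - start] + _BASES[new] + codon[site - start + 1 :]
                if _GENCODE[mutated] is None and ci < n_codons_full - 1:
                    accept = False  # internal nonsense change
                elif _GENCODE[mutated] != _GENCODE[codon]:
                    accept = rng.random() < omega
        if accept:
            codes[site] = new
            n_sub += 1
            rates[site] = leave[new]
            total = float(rates.sum())
            cum = np.cumsum(rates)
    out = "".join(_BASES[c] for c in codes)
    return (out, n_sub) if return_events else out


def apply_pseudogenization(
    seq: str,
    deletion_rate: float,
    mean_len: float,
    seed,
    coords: np.ndarray | None = None,
):
    """Poisson deletion process along the sequence with geometric lengths.

    Returns (degraded sequence, event log[, coords]) — ``coords`` is an
    optional parallel array of ancestral coordinates that is cut the same
    way, used to carry true homology through the run.  Deletions running
    past the sequence end are truncated and logged as such.
    """
    if deletion_rate < 0:
        raise ValueError("deletion_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[dict] = []
    n_events = int(rng.poisson(deletion_rate * len(seq)))
    for _ in range(n_events):
        if not seq:
            break
        start = int(rng.integers(0, len(seq)))
        length = int(rng.geometric(1.0 / mean_len))
        deleted = min(length, len(seq) - start)
        events.append(
            {
                "start": start + 1,
                "requested": length,
                "deleted": deleted,
                "truncated": deleted < length,
            }
        )
        seq = seq[:start] + seq[start + deleted :]
        if coords is not None:
            coords = np.delete(coords, slice(start, start + deleted))
    if coords is not None:
        return seq, events, coords
    return seq, events


def simulate_dataset(config: SimulationConfig | None = None) -> SimulationResult:
    """Evolve every gene down the tree and assemble the full data model.

    Pseudogenized genes switch to omega = 1 and pick up the deletion
    process on the configured branch and every branch below it.  True
    alignments are emitted in root coordinates (deletion-only evolution
    keeps every surviving base at its ancestral column).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    pseudo_at: dict[tuple[str, str], PseudogenizationSpec] = {
        (ev.gene_id, ev.branch): ev for ev in config.pseudogenization
    }
    tips = set(config.tips())
    clade_of_tip = {t: node_clade(t) for t in tips}

    records: dict[tuple[str, str], GeneRecord] = {}
    alignments: dict[str, list[tuple[str, str]]] = {}
    substitutions: dict[str, dict[str, int]] = {}
    tip_gc: dict[str, dict[str, float]] = {}
    deletions: dict[str, dict[str, list[dict]]] = {}

    for gene in config.gene_specs:
        root_seq = simulate_root_sequence(gene.n_codons, config.root_gc, rng)
        root_len = len(root_seq)
        substitutions[gene.gene_id] = {}
        deletions[gene.gene_id] = {}
        tip_gc[gene.gene_id] = {}
        tip_rows: list[tuple[str, str, np.ndarray, bool]] = []

        # iterative preorder walk; state = (seq, coords, pseudogenized, spec)
        stack = [("root", root_seq, np.arange(root_len), False, None)]
        while stack:
            node, seq, coords, pseudo, pspec = stack.pop()
            for child, bl in reversed(config.tree.get(node, [])):
                clade = node_clade(child)
                mult = config.rate_multiplier.get(clade, 1.0) if clade else 1.0
                gc = config.gc_equilibrium.get(clade, config.root_gc) if clade else config.root_gc
                c_pseudo, c_pspec = pseudo, pspec
                if (gene.gene_id, child) in pseudo_at:
                    c_pseudo = True
                    c_pspec = pseudo_at[(gene.gene_id, child)]
                omega = 1.0 if c_pseudo else gene.omega
                c_seq, n_sub = evolve_sequence(
                    seq, bl * mult, config.kappa, gc, omega, rng, return_events=True
                )
                substitutions[gene.gene_id][child] = n_sub
                c_coords = coords
                if c_pseudo and c_pspec is not None:
                    c_seq, events, c_coords = apply_pseudogenization(
                        c_seq, c_pspec.deletion_rate, c_pspec.mean_del_len, rng, coords
                    )
                    if events:
                        deletions[gene.gene_id][child] = events
                if child in tips:
                    tip_rows.append((child, c_seq, c_coords, c_pseudo))
                else:
                    stack.append((child, c_seq, c_coords, c_pseudo, c_pspec))

        aln_rows = []
        tip_order = {t: i for i, t in enumerate([OUTGROUP_ID] + CLADE_I_TIPS + CLADE_II_TIPS)}
        for taxon, seq, coords, pseudo in sorted(
            tip_rows, key=lambda r: tip_order.get(r[0], 99)
        ):
            gapped = np.full(root_len, "-", dtype="U1")
            gapped[coords] = list(seq)
            aln_rows.append((f"{taxon}|{gene.gene_id}", "".join(gapped)))
            status = "degraded" if pseudo else "intact"
            clade = clade_of_tip[taxon]
            records[(gene.gene_id, taxon)] = GeneRecord(
                symbiont_id=taxon,
                gene_id=gene.gene_id,
                sequence=seq,
                status=status,
                clade=clade,
            )
            gc_bases = sum(1 for c in seq if c in "GC")
            tip_gc[gene.gene_id][taxon] = gc_bases / len(seq) if seq else float("nan")
        alignments[gene.gene_id] = aln_rows

    symbiont_order = [OUTGROUP_ID] + CLADE_I_TIPS + CLADE_II_TIPS
    matrix = GeneMatrix(
        records=records,
        gene_order=[g.gene_id for g in config.gene_specs],
        symbiont_order=[s for s in symbiont_order if s in {r[1] for r in records}],
        outgroup_id=OUTGROUP_ID,
    )
    truth = SimulationTruth(
        config=config,
        substitutions=substitutions,
        tip_gc=tip_gc,
        deletions=deletions,
    )
    return SimulationResult(matrix=matrix, alignments=alignments, truth=truth)


def write_dataset(result: SimulationResult, outdir) -> None:
    """Write genes.fa, aln/<gene>.fa, meta.tsv and truth.json."""
    os.makedirs(os.path.join(outdir, "aln"), exist_ok=True)
    fasta = [
        (f"{rec.symbiont_id}|{rec.gene_id}", rec.sequence)
        for rec in result.matrix.records.values()
        if rec.sequence
    ]
    fasta.sort()
    write_fasta(fasta, os.path.join(outdir, "genes.fa"))
    for gene, rows in result.alignments.items():
        write_fasta(rows, os.path.join(outdir, "aln", f"{gene}.fa"))
    meta_lines = ["symbiont_id\tgene_id\tclade\tstatus"]
    for (gene, sym) in sorted(result.matrix.records):
        rec = result.matrix.records[(gene, sym)]
        meta_lines.append(f"{sym}\t{gene}\t{rec.clade}\t{rec.status}")
    with open(os.path.join(outdir, "meta.tsv"), "w") as fh:
        fh.write("\n".join(meta_lines) + "\n")
    truth = {
        "config": _config_to_jsonable(result.truth.config),
        "substitutions": result.truth.substitutions,
        "tip_gc": result.truth.tip_gc,
        "deletions": result.truth.deletions,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def _config_to_jsonable(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["tree"] = {k: [[c, float(b)] for c, b in v] for k, v in config.tree.items()}
    return out
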