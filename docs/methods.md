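# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Repeat sequence density

A window of length W = 200 bp is slid along each gap- and N-stripped gene
sequence in steps of s = 10 bp; windows start at positions 1, 1+s, 1+2s, …
and only full windows are scored (a trailing fragment shorter than W is
dropped, so a 230 bp gene yields exactly 4 windows).  Within a window, the
statistic counts the k-mer start positions (k = 5 by default) whose k-mer
occurs at one or more *other* start positions anywhere in the same window,
overlapping occurrences allowed.  Counting is occurrence-wise: a k-mer
present three times contributes 3 to the window count, not the 3 pairs it
forms.  The per-gene scalar is the mean of the window counts after an
optional centred moving average (span odd, in windows; edge windows clip to
the available values; the default span of 1 disables it, because no
particular span is canonical and the plain mean already matches the
"average ± SD" presentation this statistic is normally given).  The "±" SD
is the sample SD (n−1).

Two counting modes exist.  The default scores k-mers repeated *anywhere*
in the window.  A strictly tandem variant (`tandem_only`, counting only
positions with an immediately adjacent identical copy) is provided for
sensitivity analysis; it cannot reproduce the magnitudes this statistic is
known to take on real bacterial genes — a 200 bp window holds at most ~66
adjacent 3-mer copies, far below observed 3-mer densities near 188 — which
is why anywhere-in-window is the default.

Genes whose usable length falls below W (heavily deleted remnants) fall
back to a single whole-sequence window with a logged warning, rather than
being dropped: remnants are first-class measurement targets here.

For the compositional null, the expected count in an iid window is
approximated by m·(1 − (1 − q^k)^(m−1)), with m = W − k + 1 start positions
and q = Σ_b p_b² the per-base coincidence probability.  This treats
overlapping k-mers as independent; the approximation error is a systematic
few percent at AT-rich compositions (the Monte-Carlo companion estimate in
`expected_repeat_count` carries no such assumption, and tests compare the
two at the width of the count distribution, not at the SE of the mean).
Because q is minimised at uniform composition, any GC shift away from 50%
raises q and with it the expected repeat count — the mechanism by which an
AT-biased mutational spectrum inflates repeat density.

## GC content

GC is (#G + #C)/(#A + #C + #G + #T) per (gene, symbiont) cell, computed on
the stored sequence with N and gap characters excluded from both numerator
and denominator, so remnants are measured only on their determined bases.
Tables report percent; the per-cell API carries both fraction and percent.

## Genetic distance

Distances are pairwise against the outgroup ortholog on user-supplied (or
simulator-emitted) alignments; columns where either sequence has a gap or N
are removed pairwise.  Models: p-distance; JC69, t = −(3/4)·ln(1 − 4p/3);
K80 from transition/transversion proportions P and Q,
t = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q) with κ̂ = 2A/B − 1 for
A = −ln(1 − 2P − Q), B = −ln(1 − 2Q); and a pairwise HKY maximum
likelihood, which maximises Σ n_xy·ln(π_x P_xy(t)) over (t, κ) with
empirical base frequencies, the rate matrix scaled to one expected
substitution per site, transition probabilities via the matrix exponential,
and Nelder–Mead on log-parameters to |ΔlogL| < 1e-9.  Saturated closed
forms (log argument ≤ 0) return +inf with a flag and become NA in tables.
K80 is the table default: closed-form, transition-aware, and adequate at
the divergences this design produces; HKY-ML is available where
composition bias matters.  No claim of parity with codon-model ML
(CodeML-style) distances is made — comparisons against numbers produced by
such software carry a model-choice tolerance.

## dN/dS (NG86)

For intact genes only, dN/dS follows Nei–Gojobori (1986): per-codon
synonymous/non-synonymous site fractions from the standard genetic code
(changes to stop codons count as non-synonymous; each codon normalised to
3 sites), averaged over the two sequences; differences counted with
equal-weight averaging over all orderings of the differing positions (2 or
6 pathways); Jukes–Cantor correction applied separately to pN and pS.
Codon pairs containing a gap, N or a stop codon are excluded pairwise.
Degenerate outcomes are defined rather than left to float arithmetic:
dS = 0 gives an undefined (None) ratio, not infinity; a saturated dS with
finite dN gives ratio 0.

The classic method counts sites as if transitions and transversions were
equally likely; under strong transition bias it therefore overestimates
synonymous divergence and deflates dN/dS (with κ = 4 the deflation is
roughly 40% in our simulations).  An optional transition-weighted site
counting (`kappa` argument) is provided, but the classic κ = 1 counting is
the default everywhere so that reported values mean what NG86 values
conventionally mean.

## Clade statistics

Clade summaries are NA-aware means and sample SDs per (gene, clade), with
the outgroup excluded.  The round-robin matrix runs a classical two-sided
paired t-test for every unordered symbiont pair, paired across the genes of
the chosen set and dropping genes NA in either member; two gene sets are
carried (all genes including remnants, and the intact-in-all subset),
mirroring the two halves of a paired-comparison table, together with
per-symbiont across-gene averages.  Degenerate pairs are defined: a
self-pair or a zero-mean/zero-variance difference vector reports p = 1,
a constant non-zero shift reports p = 0, each with a flag.  Remnant values
enter the all-genes half (the comparison is of genes *and their remnants*);
cells can be excluded only by being NA.

The ratio analysis divides each gene's clade I mean by its clade II mean
and compares the ratio group of genes degraded in clade I (default uvrB,
uvrC, mutY) against the group intact in both clades (default uvrA, uvrD,
uvrDp, mfd, groEL, groES, galU) with a two-sided Mann–Whitney U test —
exact when the pooled sample is ≤ 12 with no ties, tie-corrected normal
approximation otherwise.  For the intact group only intact cells enter the
clade means, so a gene degraded in a minority of taxa (uvrD in two clade II
symbionts) contributes its intact copies only; for the degraded group all
measured cells enter, since the clade I values are the remnants themselves.

Regressions are ordinary least squares over all matched (gene, symbiont)
cells, each cell one point.  The points are phylogenetically
non-independent — symbionts share ancestry — and the pooled-regression
design accepts that deliberately, as replication of the comparative
protocol it mirrors; no independent-contrasts correction is applied.
Raw p-values are reported throughout (no multiple-testing correction in
any default output; a Holm-adjusted view of a matrix is available as a
clearly separate function), and significance statements use α = 0.05.

## Synthetic data

The generator emulates the study design: a rooted tree with an outgroup
stem, a clade I stem with 5 tips and a clade II stem with 7 tips (tip
labels follow the real panel's abbreviations), ~10 genes with the real
panel's lengths (231 bp to 3.4 kb) and per-gene ω on the scale of that
system's dN/dS values (0.16–0.44), clade I evolving at 1.5× the clade II
rate toward a lower GC equilibrium (0.32 vs 0.38, the root at 0.38), and
κ = 4.

Substitution: per-site HKY proposals (equilibrium frequencies A = T,
G = C set by the branch's GC target, scaled so branch length = expected
neutral substitutions per site) sampled by Gillespie events; a proposal
that changes the amino acid is accepted with probability ω, a synonymous
one always.  When ω < 1 the sequence is treated as a frame-1 ORF and
proposals creating an internal stop are rejected outright; at ω = 1 (the
pseudogene regime) there is no reading-frame bookkeeping at all.  ω thus
acts as acceptance thinning, making the realised rate of a gene
(1 − fraction of rejected proposals) an explicit function of its
constraint — which is exactly what lets one pseudogenization event
simultaneously raise a gene's distance, accelerate its compositional
convergence, and through composition its repeat density.

Pseudogenization on a configured branch switches the gene to ω = 1 from
that branch down and adds a deletion process on that branch and every
descendant branch: a Poisson number of events (rate 0.004 per site per
branch — a clock deliberately separate from the substitution clock) with
geometric lengths (mean 25 bp), truncated at the sequence end and logged.
Only deletions are modelled, no insertions, so every surviving base keeps
its ancestral coordinate and true alignments are emitted without
realignment.  Defaults pseudogenize uvrB, uvrC and mutY on the clade I
stem and uvrD on the two clade II tips that lack it in the real panel.

Branch lengths are free design parameters (no published values exist for
this panel at neutral scale).  They were fixed once — outgroup stem 0.55,
root→ingroup 0.20, clade I stem 0.35, clade II stem 0.10, tips 0.08–0.12 —
so that the generator robustly embodies the mechanism it is meant to
express: with these values the full pipeline recovers all the expected
directional contrasts (clade I higher distance, lower GC, higher repeat
density; degraded/intact ratio orderings; negative repeat-vs-GC slope) in
roughly 19 of 20 seeds.  A consequence worth knowing: the clade I stem
long enough to move composition visibly also makes the simulated
clade I/clade II distance ratios (≈2.3 degraded / ≈1.5 intact) larger than
the ≈1.5/≈1.1 regime of the real system, whose clades share a much longer
history relative to the post-split divergence.  The simulator expresses
the mechanism's directions faithfully; it is not calibrated to reproduce
the real system's ratio magnitudes, and passing direction tests on it says
nothing about effect sizes in real data.

What the generator does not model: insertions, rearrangements,
within-gene rate heterogeneity, codon-usage selection, any explicit
repair-pathway biochemistry (repair-gene loss is represented only as the
rate multiplier and GC-equilibrium shift), and genome-scale context.

## Numerical and interface conventions

All coordinates in reports are 1-based inclusive.  Sequences are DNA over
{A, C, G, T, N, -}; ambiguity codes beyond N are rejected at parse time to
keep counting semantics clean.  Clade and status always come from the
metadata table, never from sequence inspection.  Parameter tables are TSV
with genes as rows, symbionts as columns, NA for missing cells, values at
full repr precision (read-back is bit-exact), and "#"-prefixed metadata
lines carrying the config hash and seed.  Every randomised component takes
a single integer seed; a dataset is byte-reproducible from its config.

Problem sizes in the test suite and the acceptance script (window counts
per gene, 100 kb estimator-recovery pairs, 20-seed mechanism replication,
10 kb ω-recovery sequences) were chosen as the smallest sizes at which the
corresponding statistical bounds (3 SE bands, ±0.05 on ω, 18/20 seeds) are
comfortably non-flaky.

## Known limitations

* The repeat counter's anywhere-in-window semantics is one reading of a
  statistic whose published description ("tandem repeats") is looser than
  its published calibration; the tandem-only variant is kept for
  sensitivity analysis, and per-window counts are emitted so users can
  re-summarise.
* NG86 dN/dS and closed-form distances are counting methods, not codon-ML;
  absolute values differ from CodeML-style estimates by method, most
  visibly under transition bias.
* Pairwise-vs-outgroup dN/dS averaged within a clade is one reading of
  "per-clade dN/dS"; branch-model estimates would differ.
* The ratio analysis and regressions treat genes and symbionts as
  exchangeable replicates; no phylogenetic correction is attempted.
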