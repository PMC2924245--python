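# Methods

## The assay and the bias being corrected

MethylSeq digests genomic DNA with HpaII, which cleaves `C^CGG` only when
the internal CG is unmethylated on both strands, size-selects fragments
(default 50–300 bp), and sequences fragment ends. Reads therefore begin
with `CGG` as sequenced and map to cut coordinates. The informative unit
is the CCGG site, but the read depth observed at a site is a function of
the whole neighborhood: a fragment copy exists in the library only if both
bounding sites were cut, no interior site was, and the length passed the
gel. The inference problem is to invert this many-to-one map from local
methylation configurations to end depths.

## Model structure

Per region, hidden variables are placed on every CG of the reference in
genomic order. HpaII CGs carry a joint state (methylation U/P/M × island
I/O); other CGs carry island status only. Internally each HpaII site is
factored into a 2-state island variable and a 3-state methylation variable
tied by the island-conditional methylation distribution; this is exactly
equivalent to the 6-state joint formulation but keeps elimination cliques
small, because fragment factors then touch only 3-state axes. Posteriors
are reported jointly over the pair, so the 6-state semantics are
preserved.

Consecutive CG variables are linked by the distance-dependent transition

    N(d) ∝ (T·D)^(d−1) · T · E

with per-base island transitions `T = [[1−b, b], [a, 1−a]]` (rows I, O;
a = 0.00031434 per-base entry, b = 0.0257 per-base exit), `D` the diagonal
of per-base no-CG probabilities and `E` of CG probabilities (0.10178
inside, 0.01298 outside). This conditions the island chain on the observed
CG landscape: seeing a CG after a short gap is evidence for an island,
a long CG-free gap evidence against. The first variable of a region uses
the initial island probability 0.013 reweighted by the CG emission. The
matrix power is computed by binary exponentiation with scalar rescaling,
so arbitrarily large gaps are handled without underflow; rows are
normalized at the end.

Methylation given island status uses P(U,P,M|I) = (0.7231, 0.05, 0.2269)
and P(U,P,M|O) = (0.1413, 0.05, 0.8087). The role assignment of these
printed triples over (U, P, M) is pinned by an internal identity: the
outside-island prior score p(U) + ½·p(P) must equal the documented prior
threshold 0.1663, which holds only for U = 0.1413 outside (0.1413 +
0.5·0.05 = 0.1663), and matches the biology (islands are
unmethylation-enriched). This identity is asserted in the test suite and
is the package's keystone parameter check.

Every candidate fragment — any ordered pair of HpaII sites whose
cut-to-cut distance lies in the size window, not only adjacent pairs — is
an observed variable. Its factor connects the methylation variables of its
two ends and at most three interior sites (chosen uniformly at random with
a recorded seed when more exist; wider subsets change the factor scope
exponentially for negligible information). The per-allele production rate
ρ = c(m_left)·c(m_right)·∏(1−c(m_q)) with c(U,P,M) = (1, ½, 0) determines
an equivalence class: ρ = 0 is class 0, and classes 1–4 bin ρ into
(0,.25], (.25,.5], (.5,.75], (.75,1]. The class-conditional distribution
over the ten observed count states is a 5×10 row-stochastic table; the
default table is Binomial(9, ρ̄) with class rates ρ̄ = (0, .125, .375,
.625, .875) — monotone in class, saturating, and matched to the capped
count scale — and any externally fitted 5×10 table can be loaded instead
(`metmap.params.load_fragment_table`).

## Observed states and k_max

Fragment read counts are capped to ten states by f = min(9, ⌊10·r/k_max⌋),
a monotone uniform binning that saturates at the capping value. k_max is
estimated from a low-bias reference set — fragments of 50–80 bp with no
interior restriction site lying fully inside CpG islands — as the mean
count plus two Poisson standard deviations (mean + 2√mean), which keeps
PCR-jackpot outliers from dictating the scale. For single-end data the
paired-fragment count is approximated by the symmetric mean of the two
end counts (reads starting exactly at the left cut on the forward strand;
reads whose 5′ end sits one base past the right cut on the reverse strand,
reflecting the two-base 5′-CG overhang left by double-strand cleavage),
rounded half-up; the approximation is exact when no two candidate
fragments share a cut position and unbiased under symmetric end sampling.
A configurable ±1 bp end-matching slack accommodates aligner off-by-one
conventions.

On simulated experiments the island-based reference set can be empty (see
"Limitations"); simulation drivers then use k_max = depth + 2√depth, the
population value the estimator targets (the Poisson mean of an unbiased,
fully unmethylated fragment is the design depth).

## Inference

Inference is exact. Variables are eliminated in genomic order; the
frontier after each step is the set of variables still referenced by a
factor anchored further right, so the induced junction tree is a chain of
cliques (previous frontier plus one variable). Two passes of sum-product
messages give every marginal, including the island×methylation pair
marginal per HpaII site. Messages are renormalized after every step, which
keeps linear-domain arithmetic stable across megabase regions while
preserving exact structural zeros (an observed count is impossible under
class 0 configurations, and renormalized linear messages propagate that
impossibility exactly); log-domain message passing was considered and
rejected as it gains nothing once messages are renormalized but forces
−∞ handling.

Clique sizes are bounded in practice by the number of pending fragment
memberships within one window length. If a clique would exceed 2²⁰ joint
states (CG-dense clusters with many overlapping candidate fragments), the
interior links of the widest fragments intersecting the oversized cliques
are dropped — their factors rebuilt end-only — with a warning; inference
remains exact for the reduced model, and the reduction is refused (an
error) rather than ever approximating silently.

Per-site outputs are p(island), p(U), p(P), p(M) and the score
p(U) + ½·p(P), the inferred fraction of unmethylated alleles. Only CCGG
sites in the scope of the experiment (on ≥ 1 size-passing fragment, as
end or interior) are reported.

## Region segmentation

Chromosomes are segmented into non-overlapping 0.5 Mbp core regions, each
modeled with two fragment-lengths (2·l_max) of context sequence on both
sides; posteriors are reported only for core-owned sites and every
fragment is owned by the region whose core contains its left cut. Two
window lengths of context guarantee that any fragment excluded from a
region's model ends at least l_max from the core, where the conditioned
island chain has forgotten it: the per-base evidence-decay rate through a
CG-free gap is the eigenvalue ratio of T·D (≈ 0.887/base under the default
parameters), so influence at 300 bp is below 10⁻¹⁵. The test suite checks
segmented runs against whole-chromosome runs at 10⁻⁶.

## SUMI annotation

SUMIs are the union of two region sets, both requiring direct experimental
support (≥ 2 candidate fragments with raw read count ≥ 1 lying fully
inside; threshold configurable):

* Set 1 — maximal runs of consecutive CG variables (either kind) with
  p(island) > 0.1, delimited by the first and last CG of the run (a
  conservative boundary; no extension to inter-CG midpoints).
* Set 2 — 600 bp windows (±300 around the cut) on HpaII sites with
  p(island) < 0.1 but score above the outside-island prior 0.1663,
  merged, and kept when ≥ 30% of the merged window's HpaII sites beat the
  score threshold. The score scale is used for both thresholds since the
  0.1663 constant is a score-scale quantity.

Overlapping results merge; each SUMI is scored by the mean score of its
HpaII sites. Outputs are BED (score scaled 0–1000) plus a full-precision
TSV with a provenance column (set1/set2/both).

## The simulator

The generator mirrors the model's own generative story so every module can
be tested against planted truth. Island state follows the per-base chain
(stationary start); CGs are planted per eligible position with the
island-conditional probabilities; a configurable fraction of CGs
(default 0.15, between the genome-wide and island-local CCGG/CG ratios of
human sequence) extends to CCGG. Background bases follow configurable GC
fractions (0.65 in islands, 0.38 outside, vertebrate-like), and assembly
is patched so that scanning the sequence recovers exactly the planted
CG/CCGG sites — no accidental motifs. Methylation draws per HpaII site
from the island-conditional distribution; U gives allele fraction u = 1,
M gives u = 0, and P draws u uniformly on (0.1, 0.9) as a simple
heterogeneity model. Reads: every size-passing candidate fragment draws a
Poisson(depth·ρ) count with ρ its production rate under the planted u;
optional single-end alignments emit one forward read at the left cut and
one reverse read per copy (a paired run collapsed to single-end), plus
optional non-`CGG`-prefix contaminants and a PCR-jackpot spike (one
count ×100) for robustness tests.

What the simulator does not emulate: sequencing error, mapping ambiguity,
GC/PCR coverage bias beyond the jackpot spike, incomplete digestion, and
chromosome-scale heterogeneity of CG density. Passing tests on simulated
data therefore demonstrate correctness of the inference given the model's
own assumptions, not robustness to real-library artifacts.

Calibration estimators reported by `calibration_summary`: the island base
fraction is compared with a/(a+b) ≈ 0.01208 using the two-state-chain
standard error (variance inflation (1+ρ₁)/(1−ρ₁) with lag-one
autocorrelation ρ₁ = 1−a−b), and the in-island CG frequency is the number
of planted CG starts per eligible island position (positions not interior
to an already-planted motif), a binomial estimator of p_cg_in.

## Problem sizes used in the test and acceptance runs

Simulation-based checks run at 2 Mb (bias correction, ten seeds; island
recovery) and 10 Mb (generator calibration); the oracle-equivalence check
enumerates 200 random graphs of up to 10 CG sites. These sizes give
standard errors comfortably inside the asserted bounds while keeping the
default suite fast on a single CPU.

## Known limitations

* The default island-chain parameters imply geometrically distributed
  unmethylated islands with mean length 1/b ≈ 39 bp. Real CpG islands are
  hundreds of bp; the short prior memory means posterior island runs track
  local CG clustering rather than island-scale structure. Two consequences
  on self-consistent simulations (genome drawn from the same chain): most
  planted islands are shorter than the minimum fragment length, so the
  SUMI support rule (two fragments fully inside) cannot hold for them, and
  island-concentrated size-selection bias is rare, so the advantage of
  model scores over raw counts, while systematic (the model wins on every
  tested seed), is modest in magnitude. With realistic island geometry and
  a matched prior (`SimParams(island_mean_length=800, island_spacing=20000)`
  and the corresponding chain rates) planted islands are recovered at
  base-level Jaccard ≥ 0.7 at 30×.
* The island-based k_max reference set is empty on default-geometry
  simulations for the same reason; pipelines accept an explicit k_max.
* The fragment observation table is a documented default, not the
  original fitted table; it is pluggable.
* Methylation values of neighboring sites are conditionally independent
  given island status; no learning of the fixed parameters is provided.
* No aligner integration, no GC/mappability normalization, no
  annotation-database comparisons.
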