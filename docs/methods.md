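# Methods

This note documents the models behind each stage, the defaults that matter,
what the synthetic generator does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Family identification

Membership is decided by domain architecture, not by sequence similarity
alone. An NBD (nucleotide-binding domain) is called where a Walker A motif
(`G..G.GK[ST]`) co-occurs with an ABC signature (`[LIVMFY]S[SG]G.[QRKE]`,
the LSGGQ consensus) or a Walker B (`[RK].{3}G.{3}[LIVMF]{3}`, hydrophobic
set LIVMF) within a 250-residue window. The ABC signature is spelled from
its canonical consensus; the Walker B hydrophobic set is a choice, exposed
in `motifs.MOTIF_PATTERNS`. `X` never matches. A TMD is a cluster of ≥ 4
predicted transmembrane helices spanning ≤ 350 residues, matching the 4–6
helices of a transporter membrane domain.

Helices come from windowed Kyte–Doolittle hydropathy (window 19, threshold
1.6): maximal runs of qualifying window centers become segments, widened to
at least 15 residues (a membrane-spanning helix cannot be shorter) and
split evenly when longer than 30. These four numbers (19 / 1.6 / 15 / 30)
are the standard desk-scale choices for single-sequence TM prediction; they
are parameters, not claims — real surveys would use a profile-HMM stack,
and this module deliberately trades that external dependency for a
self-contained, testable architecture rule that plays the same validation
role (presence of the conserved domains).

A protein with ≥ 1 NBD is accepted. TMD-only proteins (an architecture that
occurs in ABCI-type aluminum-tolerance transporters) are accepted only when
their nearest panel reference is a subfamily-I protein at ≥ 40% identity,
so the rare topology cannot become a background-acceptance loophole.

Topology classes map segment order to
`full_forward (TMD-NBD-TMD-NBD) / full_reverse / half_forward / half_reverse
/ soluble (NBD only) / tmd_only`; non-canonical arrangements fall back to
the nearest class by content, and a flag records disagreement with the
assigned subfamily's canonical topology.

## Subfamily assignment and naming

All pairwise comparisons in the package use one scoring scheme: global
alignment, BLOSUM62, gap open 10, extend 0.5 (Biopython's PairwiseAligner).
A candidate takes the subfamily of its nearest reference by p-distance
(1 − fractional identity over alignment columns); ties break toward the
earlier panel entry and are flagged. A neighbor-joining tree (Saitou–Nei,
implemented here; exact on additive matrices, verified against scikit-bio)
over candidates + references is written as Newick. Maximum-likelihood
phylogeny with bootstrap, used by full-scale surveys, is out of scope: NJ
on alignment distances is deterministic and sufficient for
nearest-reference classification, and no support values are reported.

Names number members within each subfamily 1..n by (natural chromosome
order, start coordinate) — `famB1` is the leftmost subfamily-B gene on the
lowest-numbered chromosome — independent of input order.

## Protein properties

Molecular weight sums ExPASy average residue masses plus one water
(18.0153 Da); `X` contributes the mean residue mass. pI solves
net-charge(pH) = 0 by bisection on [0, 14] with the EMBOSS pKa set
(N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1); the charge is strictly decreasing in pH, and the returned root
nulls it to < 10⁻⁴ charge units.

## Duplicate typing and collinearity

Homolog pairs: all-vs-all global alignment; per gene, up to `top_k = 5`
partners at ≥ `min_identity = 40%`. Anchors are expressed in gene-rank
coordinates (ordinal position along the chromosome); rank distance, not
base-pair distance, defines tandem/proximal, which makes the classifier
robust to intergenic length. Self-hits and same-chromosome anchors within
the tandem gap are removed before chaining.

Blocks: per chromosome pair, the longest anchor chain with strictly
monotone ranks on both axes (increasing, or decreasing on the second axis
for inverted blocks) and rank gaps ≤ `max_gap = 25`, found by O(n²) DP;
chains with ≥ `min_anchors = 5` anchors are emitted greedily best-first,
each anchor joining at most one block. The DP equals exhaustive best-chain
search (tested on instances up to 30 anchors).

Typing precedence is WGD/segmental > tandem > proximal > dispersed >
singleton: block anchor → `wgd_segmental`; else nearest same-chromosome
homolog at rank distance ≤ 1 → `tandem`, ≤ `proximal_window = 10` →
`proximal`; any homolog at all → `dispersed`. The defaults are the MCScanX
conventions; all are exposed because published surveys rarely state them.
Gene-level type counts and pair-level tallies (tandem pairs, in-block
pairs) are reported separately — the two bookkeepings differ and are not
reconciled.

Interspecies synteny runs the same chaining across two genomes and reports
family pairs inside blocks with one-to-one / one-to-many / many-to-one
cardinality ("many" counted on the genome-A side: several A genes anchoring
one B gene is many-to-one).

## Ka/Ks and divergence time

Nei–Gojobori (1986), implemented from the definition: per codon, each
position contributes the fraction of its three possible changes that are
synonymous (stop-creating changes count as nonsynonymous — the common
convention, fixed in `_codons.py`); S averages the two sequences and
N = 3L − S. Differences average Sd/Nd over all minimal mutational pathways
with equal weight (2 pathways for 2-position differences, 6 for 3),
excluding pathways through stop codons unless every pathway passes one.
pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −¾·ln(1 − 4p/3); p ≥ ¾ raises a saturation error distinct from the
Ks > 2 discard flag. Sd/Nd equal exhaustive pathway enumeration on all
61 × 61 sense-codon pairs (tested), and S + N = 3 × columns exactly.

Codon alignment is protein-level alignment back-translated; columns with a
gap in either row are dropped whole. Below roughly 50% protein identity the
aligner begins to introduce spurious gaps that scramble codon
correspondence and inflate distances, so for pairs known to be co-linear
(e.g. simulator output, which introduces no indels) `kaks_pair(...,
align=False)` pairs codons positionally; recovery statistics use that
route. This is an aligner limitation, not an estimator property.

Divergence time: T(years) = Ks/(2λ), reported in MYA, λ = 6.5×10⁻⁹
substitutions per synonymous site per year by default (the clock commonly
applied to legume nuclear genes). The printed formula in survey papers,
"T = Ks/(2λ × 10⁻⁶)", is dimensionally ambiguous; this package adopts the
reading that reproduces those papers' own endpoints (Ks 1.57 ↔ ~120.5 MYA,
Ks 0.07 ↔ ~5.3 MYA). Pairs with Ks > 2 stay in the output table flagged
`discarded` and are excluded from every summary statistic.

## Expression classification

"Expressed in tissue t" means median TPM > τ, with τ = 0 by default — the
only rule consistent with "not expressed" meaning an all-zero row; τ is a
CLI flag because the underlying surveys never state their cutoff.
Categories (ubiquitous = all tissues, silent = none, tissue-specific =
exactly one, other) are disjoint and exhaustive; raising τ can only shrink
a gene's expression breadth (tested as a monotonicity property).
log2(TPM+1) is computed for display export only; classification always
runs on raw TPM.

## qPCR analysis

ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt subtracts the mean
control ΔCt at the same timepoint (a time-zero baseline is available via
`baseline="time_zero"`); fold = 2^−ΔΔCt, mean ± SD over replicates.
Amplification efficiency is fixed at 2 — the assumption embedded in the
formula; no efficiency correction is attempted. Letters come from one-way
ANOVA + Tukey HSD with a Piepho-style insert-and-absorb compact letter
display: two groups share a letter iff Tukey p ≥ α (verified exhaustively
for up to 6 groups); when every group has zero variance, letters fall back
to exact equality of means. Because bar-plot letter conventions are
ambiguous, the output table carries both the across-timepoint letters and
a per-timepoint Welch t-test of treatment vs control.

## The synthetic generator

`simulate.generate_genome` builds `chr01..chrNN` with background genes
(uniform random sense codons — no homology, no motifs) and planted
duplication events. Family proteins are partially mutated copies (40% of
non-motif residues kept) of one deterministic template per subfamily, with
real motif content and the subfamily's canonical topology; motif codons
are frozen against nonsynonymous change during evolution, the in-silico
analogue of the purifying selection that makes these motifs diagnostic.
The identity ladder this produces — duplicates ≈ 75–90%, same-subfamily
non-duplicates ≈ 30–37%, cross-subfamily/background ≈ 15–25% — is what
lets a single 40% homology threshold separate descent from family
resemblance.

Codon evolution draws Poisson(Ks·S) synonymous and Poisson(ω·Ks·N)
nonsynonymous events (S, N = NG86 site counts of the ancestor) and applies
each uniformly over the current single-nucleotide opportunities of its
class via rejection sampling, so multiple hits and reversions occur and
JC correction is the matching inverse; stop-creating changes are redrawn.
No rate heterogeneity across sites and no indels are simulated — enough
for NG86 recovery tests (estimated Ks unbiased within 10% at
Ks ∈ {0.1, 0.5, 1.0}, ω ∈ {0.2, 1.0}), but real duplicate pairs also carry
indels, rate variation and GC/codon-usage bias that these tests do not
probe.

Gene models get 1–8 exons, introns of 80–500 bp, UTRs of 60–300 bp (an
opt-out count reproduces UTR-less genes), random strand, and non-adjacent
placement with 1–5 kb intergenic gaps. Tandem copies occupy adjacent ranks;
proximal copies are separated by the requested background genes; dispersed
copies land on different chromosomes; segmental events duplicate an ordered
run of ≥ 5 distinct family genes onto another chromosome so default block
detection recovers them. Everything derives from one integer seed through
a single numpy Generator; equal seed + config means byte-identical files.
Not emulated: intergenic sequence, transposons, isoforms, assembly gaps,
cross-family chimeras.

Expression matrices draw log-normal TPMs (log-mean 2, log-sd 1) into the
requested category pattern; Ct tables follow
Ct = Ct_ref + ΔCt_base − log2(fold)·[treatment] + N(0, σ) with reference
rows per sample, so the ΔΔCt analysis inverts the generator exactly at
σ = 0 and within 15% (mean over 100 seeds) at σ = 0.2 with triplicates.

## Problem sizes and determinism

The test-suite genome is ~490 genes (450 background + 34 planted across 5
chromosomes) — the size at which all-vs-all candidate alignment and NJ stay
in seconds while every duplication type, including a 9-gene segmental
block, is represented at a 1/10-scale version of a published survey's type
mix. Recovery statistics use 100 replicates per condition. The survey
report is audited at construction (all shares recompute from counts,
half-up decimal rounding at fixed precision) and re-running with the same
inputs is byte-identical.

## Known limitations

- Motif regexes approximate profile HMMs; divergent family members with
  degenerate Walker A motifs would be missed (sensitivity on real genomes
  is necessarily below the synthetic 100%).
- TM prediction is single-sequence hydropathy; signal anchors and
  amphipathic helices confound it.
- The codon aligner inherits global-alignment fragility below ~50% protein
  identity (see Ka/Ks section).
- NJ gives no branch support; the tree is an assignment aid, not a
  publishable phylogeny.
- Divergence times inherit every caveat of a strict clock and of the chosen
  λ; they are comparable within an analysis, not absolute ages.
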