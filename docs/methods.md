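# Methods

This note records the models, conventions and numerical choices behind
haplocase, and what the synthetic-data tests do and do not demonstrate.

## Coordinate system and variant nomenclature

All positions are 1-based on the rCRS (16,569 bp, circular; the historical
placeholder 'N' at 3107 is never a variant site). Variant tokens are parsed
in three dialects — HGVS-like (`m.11778G>A`, `m.249delA`), ref-position-alt
(`A14978G`), and control-region shorthand (`16223T`, `249d`, `309.1C`) —
because published mtDNA tables mix them freely (the same event appears as
both `m.14978A>G` and `m.A14978G` in the literature). Output defaults to
shorthand inside the control region and HGVS-like elsewhere. A lowercase
derived base or an IUPAC ambiguity code flags heteroplasmy; the flag never
affects variant identity, so a heteroplasmic carrier counts as a carrier.

The gene map is the standard rCRS annotation (13 protein genes, 2 rRNAs,
22 tRNAs, control region split 16024–16569 ∪ 1–576). MT-ND6 and eight tRNAs
are light-strand encoded; their codons are read on the reverse complement.
Translation uses the vertebrate mitochondrial code. A 3'-terminal incomplete
codon (completed by polyadenylation in vivo) is treated as stop and excluded
from synonymous/nonsynonymous calling. Indels inside protein genes are
reported as `frameshift-unsupported` rather than annotated.

## Variant calling

Sequences are aligned to the linearised target region (default 16033–16569 ∪
1–850: control region, MT-TF, and the 5' part of MT-RNR1, mirroring a
typical ~1.4 kb Sanger fragment) with an affine-gap global alignment
(match +1, mismatch −1, gap open −4, gap extend −1; `Bio.Align`). End gaps
are free, so primer slack and truncated reads do not generate spurious
calls; uncovered flanks are recorded on the profile. Indels are normalised
to their 3'-most equivalent placement before reporting. Length variants of
the C-tracts (windows 302–316 and 16183–16194, C bases only) are suppressed,
as is conventional in mtDNA haplotyping; point substitutions inside those
windows are still reported. The suppression windows are configurable at the
call site (`mask_ctracts`).

Calling is validated as the left inverse of profile application: random
synthetic profiles (60 per run, drawn across haplogroup backgrounds with two
private variants each on average) are applied to the reference, re-called,
and must reproduce exactly.

## Haplogroup classification

The classifier walks every node of a motif tree and scores the fraction of
the node's root-path defining variants present in the profile, after
collapsing the path per site (a back-mutation token `X!` cancels the
ancestral expectation of X and expects the reference state). When the
profile covers only the control region, motifs outside it are not scored at
all — the control-region-only situation in which real studies fall back on
coding-region RFLP checks for ambiguous clades. Insertion motifs are skipped
by default because they overlap the masked C-tracts.

Ranking is (score, number of matched variants, depth, name). The
matched-count criterion is deliberate: with region filtering, a deep clade
whose extra motifs are all coding ties shallower classes at score 1.0, and
depth alone would assign every near-empty profile to the deepest such chain.
Preferring more matched sites mirrors manual practice and makes the
end-to-end recovery invariant hold. Ties that survive all four keys are
byte-deterministic. A profile matching nothing classifies to the root with
score 0.

Nested class aggregation counts a sample toward class C when its assignment
is C or any descendant — published tables double-count nested rows (F inside
R9) by design, and the invariant count(ancestor) ≥ count(descendant) is
property-tested. Rare-class lumping into "others" is defined only for a
disjoint display partition.

The packaged tree covers the 26 classes of the bundled count tables plus the
M7b subclades, with representative motifs (control-region-weighted so that
the simulated terminal classes are separable from control-region data). It
is a test fixture, not a redistribution of any published phylogeny.

## Association statistics

Each class yields the 2×2 table (a, b; c, d) = (cases with, cases without,
controls with, controls without). The nominal test is Pearson's χ² with
1 df, X² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); the two-tailed Fisher exact
test (point-probability definition: sum of hypergeometric probabilities of
tables no more probable than observed) replaces it when any **observed**
cell is below five. Published nominal p-values are inconsistent about the
Yates continuity correction — one table row reproduces only with it, another
only without — so both settings are exposed (`continuity=`) and neither is
declared canonical; the packaged-fixture survey found 72/76 printed p-values
match one of the three settings.

Odds ratios use Woolf's log-scale CI with z = 1.959964. A single zero cell
makes the OR degenerate; such rows reproduce the source's observed fallback:
the cohort relative risk of control-group membership, e.g. for a = 0,
RR = (d/(b+d)) / (c/c) = d/(b+d) with SE √(1/d − 1/(b+d)) (the zero-count
terms cancel); analogous formulas apply by symmetry for the other single-zero
patterns. Fallback rows are always flagged so consumers can filter. Two or
more zero cells report NA.

Multiplicity is adjusted by single-step min-p permutation: cohort labels are
permuted with sizes fixed; each permutation recomputes every class's nominal
p under the same χ²/Fisher selection rule; adjusted_p = (1 + #{b : min_j
p_jb ≤ p_obs}) / (B + 1). The implementation precomputes, per class, the
p-value for every achievable carrier split (the permutation statistic is the
case-carrier count), so B = 100,000 over ~25 classes and ~2,000 samples runs
in ~10 s. Adjusted p-values are clipped from below at the nominal p so the
monotonicity invariant holds exactly; values at the estimator floor
1/(B + 1) are displayed as `<1e-05` (B = 100,000). One numerical caveat: in
the extreme tail the χ² approximation is anticonservative, so a permuted
family minimum can occasionally undercut an observed Fisher p in the 1e-9
range; the floor is therefore a statement about the headline ~1e-17 signals,
not about every sub-1e-5 row.

Counts-level permutation reconstructs a per-sample membership matrix from
published class counts through the tree's nesting structure (exact for count
purposes, which is all label permutation needs).

Power is estimated by Monte Carlo: binomial carrier counts at the stated
class frequencies, the same test-selection rule, rejection rate at α = 0.05.
It is checked against the closed-form two-proportion normal approximation
and calibrated at the null.

## Private variants and conservation

Complete genomes classified within one haplogroup are arranged in a
classification tree whose topology follows the backbone's named clades.
Haplogroup-defining variants stay on their clade's branch; every other
variant is pushed to the deepest branch all of whose samples carry it, so
the union along any root-to-leaf path reconstructs that sample's profile
exactly (C-tract length variants excluded). Variants forced onto more than
one branch are flagged recurrent. Branch lists are position-ascending for
reproducible rendering; coding variants carry `/s`, `/ns`, `/r`, `/t`
suffixes in the text output.

The conservation index of a position is the fraction of non-human species in
an ortholog alignment whose state equals the human reference state, computed
over species with a non-gap state at that column (the denominator is
reported alongside; gap handling is our stated convention). Indices are
rounded to 3 decimals for reporting. The "haplogroup-specific elsewhere"
annotation is a lookup against the loaded motif tree only — no external
searches.

## Synthetic cohorts

The generator's defaults are the study conditions: control frequencies are
the general Han Chinese haplogroup distribution (n = 1,689) resolved to the
terminal classes of the packaged tree, with the untabulated remainder
(98/1,689) drawn as "other" (tree root). Case draws multiply the odds of
selected classes by configured factors, holding each target's marginal odds
ratio exact and rescaling the remaining mass. Each sample's profile is its
clade's defining path restricted to the sequenced region, plus
Poisson(λ = 1 by default) private substitutions drawn only at positions no
motif uses (so classification truth is well defined), avoiding 3107 and the
C-tract windows. Sequence emission optionally adds C-tract length noise
(probability 0.2) that calling is expected to mask. Everything is
reproducible from the config seed.

What passing tests show: the pipeline's operations are internally consistent
(apply→call→classify round trips at 100%), the statistics are calibrated,
and injected effects are recovered with nominal CI coverage (~95% measured).
What they do not show: robustness to real Sanger artifacts (mixed traces,
phantom indels), saturation/recurrence at hypervariable sites, heteroplasmy
dynamics, or population substructure — real data violate the generator's
clean clade-plus-noise model in all these ways.

## Problem sizes and tolerances

Default test problem sizes were chosen to keep the suite fast while leaving
Monte-Carlo error far below the asserted margins: 60-profile calling round
trips, 150-sample end-to-end recovery, B = 100,000 for the permutation floor
(B = 10,000 for the monotonicity sweep), 500 replicates for CI coverage
(true coverage ≈ 95%; at 100 replicates the ≥93% bound would fail roughly
one run in ten by the meta-test's own noise), 4,000 replicates for type-I
calibration. Fisher's test is verified against exhaustive hypergeometric
enumeration for all tables with n ≤ 18 and against 250 random tables with
margins ≤ 40. Published odds ratios and CIs are asserted at the printed
3-decimal precision; three CI bounds that the source itself rounded
differently by one final-digit unit get a one-ulp tolerance, and four rows
whose printed OR/CI are not derivable from their own printed counts (a
nested-row block in one table; back-solving shows they were computed from
different counts) are tracked as documented source inconsistencies rather
than asserted.
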