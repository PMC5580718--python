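# Methods

## The phasing model

The central object is the *bubbled scaffold*: the backbone sequence a
diploid assembler emits for one individual, with heterozygous sites
retained as biallelic bubbles `[LEFT|RIGHT]`. The backbone is defined as
the body with every bubble collapsed to its LEFT allele; the allele
order within a bubble is arbitrary (the assembler does not know phase),
so the backbone is an arbitrary mosaic of the two underlying haplotypes.

Phasing rests on two sources of information:

* **Anchoring by unique exact matching.** Each bubble's 40-bp upstream
  flanking sequence (UFS) is searched, exactly, in all three trio
  members. A site is usable only when the UFS hits exactly one position
  in every individual; multiple hits within an individual discard the
  site there, and two different sites' flanks landing on the same
  position discard both. Reverse-complement (RUFS) hits are recorded as
  putative inversions and excluded from phasing. Because a 40-mer flank
  may straddle a neighbouring heterozygous site, both the search index
  and the query set enumerate the local allele paths (combinations of
  bubble alleles within a window of ±100 bp, capped at 8 bubbles per
  cluster); a flank is therefore matched under every spelling the
  individual's two haplotypes can produce.

* **Mendelian transmission.** At an anchored, fully genotyped, biallelic
  site, the child's allele pair must split into one paternal and one
  maternal allele. If exactly one split is consistent with the parental
  genotypes, the site is phased — this simultaneously fixes the child's
  parent-of-origin and each parent's transmitted allele. Two consistent
  splits (all three members heterozygous) leave the site unphased; zero
  marks a Mendelian violation. Sites with missing data in any individual
  are excluded, as are sites with more than two alleles across the trio.

Triple heterozygotes are a hard information-theoretic boundary for this
scheme: no transmission logic can resolve them, and under a neutral
site-frequency spectrum they are roughly 9–11% of the variant sites
ascertainable in a trio. Resolving them requires an orthogonal signal
(e.g. read-backed phasing), which is outside this package's scope; they
are emitted N-masked.

## Haplotype emission, consensus, iteration

The six per-trio haplotypes (father transmitted/nontransmitted, mother
transmitted/nontransmitted, child paternal/maternal) are the backbone
with each phased bubble replaced by its resolved allele. Unphased or
uncalled bubbles become an N-run of the backbone allele's length — this
keeps coordinates stable while marking uncertainty rather than
inventing phase. Length-changing substitutions (indels) shift all
downstream coordinates; a per-sequence coordinate map tracks the
cumulative shift, and every call position is updated through it.

Parent–child consensus sequences are built per transmitted pair: the
sequences are partitioned at the phased sites (whose resolved alleles
are identical in both frames by construction) and each inter-site
segment pair is globally aligned (edlib, Needleman–Wunsch-equivalent
unit costs). Consensus columns: agreement keeps the base; an N on one
side takes the other side's base; a true mismatch takes the child base
and is logged as a disagreement. A segment pair whose lengths differ by
more than 2× signals structural disagreement and is replaced by Ns.

Iteration replaces the original study design's read-backed refinement
with what the assembled sequence itself supports: before each re-run,
every N-run (injected gaps and the single-N scaffold joins) is closed by
unique exact matching of its two 40-bp flanks in the other two trio
members, donating the intervening sequence — a join between truly
abutting fragments is thereby deleted. Re-anchoring then rescues sites
whose flanks previously crossed missing sequence. Calls from earlier
rounds are carried forward (coordinate-translated through the gap-fill
shift maps), so the phased fraction — reported as the share of the final
call set resolved by the end of each round — is nondecreasing.
Positions of phased variants are finally mapped onto the nontransmitted
haplotypes by unique exact matching of the transmitted-haplotype flank.

## The simulator and what it does (not) emulate

`simdata` generates a founder panel from one random ancestral sequence:

* **Rates.** SNVs at 1/150 bp and indels (1–50 bp, geometric-free
  uniform length) at 1/1500 bp by default — the density regime of a
  highly polymorphic human locus. Variant reference spans are kept
  disjoint. Rates implying >10% divergence are rejected.
* **Frequencies.** Background variants draw their minor-allele count
  from the panel's folded neutral spectrum, P(j) ∝ 1/j + 1/(n−j). Near
  designated "classical" loci, variants instead tag subsets of 8 deep
  allelic lineages (an independent random partition of the founders per
  locus) with probability 0.5·exp(−d/20 kb) at distance d. This yields
  the two balancing-selection signatures at once: intermediate
  frequencies clustered near the loci (mean MAF ≈ 0.25 at a locus edge
  vs ≈ 0.13 in the background, matching the magnitude of the decline
  reported for classical HLA genes) and long-range LD among the tagging
  variants. Five loci per region keep per-trio phasability an average
  over independent partitions, as it is over the real MHC's nine
  classical genes. With `maf_gradient=0` the footprint vanishes and the
  panel is exchangeable across positions.
* **Panel size.** 50 founders by default, mirroring a 25-trio parental
  panel; a trio draws four distinct founders.
* **Assembler emulation.** Heterozygous sites become bubbles with
  probability 1 − `bubble_loss` (default 0.05 — a placeholder for the
  assembler's haplotype-collapse rate, sensitivity-tested in the suite);
  a lost bubble collapses to one random allele, which is the main source
  of downstream genotyping errors and Mendelian violations. Scaffolds
  are cut into 1–8 fragments (each ≥ 55 kb when the region allows, so
  all pieces clear the 50-kb selection threshold), reverse-complemented
  with probability 0.5, and peppered with short N-gaps (runs of 1–20 bp
  at 2×10⁻⁵/bp). Synthetic reference-frame alignments (with occasional
  sub-half-length noise blocks) are emitted for scaffold ordering.

Not emulated: read-level error models, coverage and insert-size
structure, repetitive-element content, and assembler-specific artifacts
beyond bubble loss and fragmentation. Passing tests therefore
demonstrate the correctness of the anchoring/phasing/consensus logic
and realistic sensitivity to fragmentation, strand flips, missing
sequence and haplotype collapse — not robustness to repeat-induced
misassembly or to systematic sequencing error.

## Population-genetic statistics

π is the mean pairwise difference per bp (per-site n·(n−c)·c pairwise
accounting, missing genotypes excluded pairwise). Tajima's *D* uses the
standard 1989 constants (a1…e2, unit-tested against closed forms);
windows with fewer than three segregating sites are reported NaN.
Defaults follow the study layout: π/D in 5-kb windows with 1-kb steps
(1-kb windows exposed for locus zooms), variant densities in 50-kb
windows with 10-kb steps, pairwise-difference profiles in 10-kb bins.
pN/pS divides class counts by fixed site fractions 0.73/0.27. The
MAF–distance analysis measures distance to the nearest classical-locus
edge (0 inside; such variants excluded), fits the regression on
nonbinned data and reports 25-variant bins (final partial bin dropped)
for display. r² is computed from phased haplotype frequencies, restricted
to SNVs with MAF ≥ 0.05, and averaged arithmetically in 10-kb distance
bins; a genotype-based mode is not provided since panels here are phased.

## Evaluation

`phase_accuracy` aligns the two truth haplotypes to find their
substitution columns (*informative positions*), lets each assembled
haplotype vote at every informative position for the truth base it
carries, and picks the global label permutation maximizing correct
votes. The headline accuracy is base-weighted over *assigned* votes
(N-masked or mismatching bases are unassigned and reported separately);
runs of constant vote become segments, vote changes are switch errors,
and uninformative positions inherit the flanking assignment.
`difference_profile` rejects comparisons whose reference is >20%
unaligned and masks bins with >50% N.

## Numerical and design choices

* Exact matching is string equality; no mismatches are tolerated
  anywhere in anchoring (the method's defining property).
* Non-unique flank matches are optionally disambiguated (on by default)
  by preferring the candidate position that carries a bubble — resolving
  the coordinate ambiguity an indel inside a short repeat produces — and
  otherwise by requiring the bubble's downstream 40-bp flank nearby.
* Scaffold ordering uses the lower median of retained block starts (ties
  and even counts resolved deterministically); the half-max block filter
  is applied per scaffold. Orientation ties keep the plus strand and are
  logged.
* Anchor-gene trimming locates anchors by banded infix alignment
  allowing up to 15% divergence; a missing anchor leaves that end
  untrimmed with a warning.
* Genotype lookup for bubble-less individuals tests candidate alleles
  longest-first, so a deletion allele is preferred over its own prefix.
* Segment-pair consensus alignment is skipped (Ns emitted) when the
  length ratio exceeds 2, signalling structural disagreement.
* All randomness flows from explicit integer seeds; identical seeds give
  byte-identical outputs.

## Known limitations

* Triple heterozygotes and Mendelian-violating sites remain unphased;
  with the default simulation conditions this caps the phased fraction
  of called variants near 0.87–0.91 after iteration. The bubble-level
  phased fraction and the accuracy of what *is* phased are unaffected.
* Putative inversions (RUFS-only anchors) are detected and counted but
  not phased or reoriented.
* The gap filler assumes the donor individual is collinear with the
  target across the gap; a structural difference spanning a gap would be
  filled with the donor's allele.
* Sites within 40 bp of a region scaffold's start cannot be anchored.
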