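# Methods

## Scope and model

`mircomp` treats a clade's miRNA repertoire as a set of *families* that
arise once on a branch of a rooted, time-calibrated species tree and can
be lost independently along descendant branches.  This single-gain
assumption reflects the strong asymmetry of miRNA evolution — new
miRNAs appear readily from hairpin-forming loci, while convergent
re-invention of the same mature sequence is implausible — and it makes
the parsimony optimum unique: for any presence/absence pattern the gain
sits on the branch above the MRCA of the present tips and the losses are
exactly the maximal subtrees below it that contain no present tip.  We
verified this against exhaustive enumeration of all single-gain
placements on all presence patterns of 5- and 6-tip trees.

Within a family, a *gene* is a (family, seed) pair, the seed being
nucleotides 2–8 from the 5′ end.  IsomiRs — 3′-length or non-seed
substitution variants sharing the seed — collapse into one gene;
5′-length variants are not treated as isomiRs because trimming the 5′
end shifts the seed itself.

## Family construction

Families are single-linkage components over pairwise optimal local
alignments (Smith–Waterman, affine gaps, scores match/mismatch/open/extend
= 5/−4/−10/−4 via Biopython's `PairwiseAligner`).  An edge requires
identity ≥ 0.85 over ≥ 16 aligned columns (both configurable).  The
threshold was calibrated against the behaviour of single linkage on
unrelated sequences: under the looser setting of 0.75 identity over 14
columns, about 1.1% of *random* 22-mer pairs qualify as edges (measured
on 245k pairs), which is enough to collapse a thousand matures into a
few giant components; at 0.85/16 the random edge rate drops to ~4×10⁻⁵
while genuine family members (≤ 2 seed substitutions plus a ≤ 2-nt
variant edit, i.e. ≥ 0.9 identity over ≥ 20 columns) always qualify.

Two provably lossless prefilters speed up the O(n²) comparison without
changing the result: a qualifying alignment must share an exact k-mer
(k computed from the thresholds by the pigeonhole bound over admissible
column counts; k = 5 at the defaults), and — when the worst per-column
score of a qualifying alignment is positive — must reach a score linear
in the minimum column count.  A test compares the pruned implementation
against unpruned all-pairs alignment.

`annotate_known` labels a gene *known* when any member aligns to any
reference mature with identities covering ≥ 90% of the shorter
sequence.

## Cluster detection

Precursors on the same scaffold and strand are sorted by start and
chained while the gap to the running maximum end of the open chain is
below `max_gap` (default 5 000 bp; 50 000 available).  Using the running
maximum end rather than the previous element's end makes the output
identical to the connected components of the pairwise "gap < max_gap"
relation even for nested intervals — the property the oracle test
asserts on random interval sets.  Chains may span more than `max_gap`
overall (polycistron chaining).  Gap is measured end-to-start
(intergenic separation); for ~70-nt precursors the distinction from
start-to-start is negligible.  A cluster's class label is its members'
shared conservation class or `mixed`; mixed clusters are excluded from
the density comparison.

## Target sites and spatial statistics

The matcher implements the canonical seed-site hierarchy.  Writing the
target 5′→3′, the 6mer core is the reverse complement of miRNA positions
2–7; an m8 pair prepends one base, an A opposite position 1 appends one,
and both give the 8mer.  Each matching core locus yields exactly one
site of the strongest supported type (8mer > 7mer-m8 > 7mer-A1 > 6mer);
distinct loci may overlap.  Thermodynamic or context scoring and
ORF/5′-UTR sites are out of scope.  Site strings depend only on the
seed, so any isomiR is a valid representative of its gene.

A site is *conserved* when every species in the gene's alignment has a
same-gene site overlapping it by ≥ 6 alignment columns — one column of
alignment jitter cannot break a call, and the site type is allowed to
differ between species.

Relative position uses the site midpoint: (start + (length−1)/2) /
(utr_length−1), 0 at the stop codon.  The spatial profile is a Gaussian
KDE with R's reference bandwidth bw = 0.9·min(s, IQR/1.34)·n^(−1/5),
evaluated on an even 512-point grid on [0, 1] (no tail extension — the
regression window [0.1, 0.9] makes edge treatment irrelevant), and the
reported statistic is the OLS slope of density on position in that
window.

The per-gene *emergence rate* divides the count of species-specific
sites (summed over species) by the summed ungapped UTR length over
species; the top ceil(0.05·N) genes by rate (ties broken by gene id)
enter GO enrichment, which uses the hypergeometric upper tail per term
and Benjamini–Hochberg q-values.  BH was chosen as the correction
because it is standard and closed-form; the output records the method.

## Expression

Small-RNA libraries are normalized to reads per million, mRNA libraries
to transcripts per million; both normalizations are invariant to
positive scaling of a sample and their columns sum to 10⁶ exactly.
Pairwise association uses Pearson's r on log2(x+1) values across
individuals (the transform is configurable, `none|log2p1`); p-values use
the t distribution with n−2 df and no multiple-testing correction, since
downstream inference uses only the sign counts.  Pairs are restricted to
miRNA–gene combinations with a predicted site in every species.

Across-species correlation first reduces each gene to per-species means
of log2(x+1) expression — contrasts assume Brownian change on a roughly
additive scale — then computes Felsenstein's independent contrasts
(standard pruning: contrast (x₁−x₂)/√(b₁+b₂), precision-weighted
ancestral values, branch extension b₁b₂/(b₁+b₂)) and correlates the two
contrast sets through the origin.  The implementation is checked against
the closed form for two tips (to 10⁻¹²), against R's `ape::pic`, against
the unit-variance property of standardized contrasts under simulated
Brownian motion, and against ordinary Pearson correlation in the star
limit.  The sign-bias test is a df-1 goodness of fit of (n⁻, n⁺) against
50:50 without continuity correction; NAs and exact zeros are excluded,
and by default all non-NA pairs count (a `significant_only` flag with
α = 0.05 is available).

## Synthetic study generator

The generator emulates an eight-species, two-clade study on a fixed
ultrametric tree (depth 5 relative time units).  Defaults: 200 families;
a family is root-origin with probability 0.4, otherwise gains uniformly
on one of the 14 non-root branches; per-branch loss probability 0.15;
per-branch seed-mutation probability 0.02 (root-origin) or 0.2
(lineage-specific), capped at 2 events per family; isomiR variant
probability 0.45 / 0.05; 22-nt matures; 300 target genes with lognormal
(μ=7, σ=0.5) UTR lengths; Poisson(12) planted sites per conserved miRNA
at Beta(1,3)-distributed (5′-skewed) relative positions and Poisson(3)
per species-specific miRNA at uniform positions; 6 individuals per
species.  The spec-level knobs `n_families` and a per-branch gain rate
cannot both be honoured exactly; the total is taken as primary and gains
are spread uniformly.

Design choices that make recovery exact rather than probable:

- Each drafted family is checked against every previously emitted mature
  under the family-edge criterion and redrafted on any hit, so the
  single-linkage graph can never bridge families.
- True alignments are emitted directly (no aligner run): UTRs evolve
  along the tree with substitutions and short indels while alignment
  columns carry stable keys, so homology is known exactly.
- Planted site windows (plus one flanking base on each side, adjusted so
  the site scans as exactly its planted type) are protected from
  mutation; biological site turnover is out of scope.
- Coordinates follow an open-chain process: a precursor joins the open
  chain with its origin-dependent cluster probability at a gap uniform
  in [200, 4000) bp, otherwise the chain closes and a new one starts
  ≥ 100 kb away.  Planted chains of ≥ 2 members are therefore exactly
  the detectable clusters.
- mRNA repression is driven by the standardized log of the *realized*
  miRNA counts (after Poisson sampling), not the latent expression: a
  cell responds to the miRNA molecules actually present, and at low
  biological noise the latent signal would otherwise be buried in
  counting noise that no analysis could see through.

What the generator does **not** emulate: rate heterogeneity or codon
structure in UTR evolution, hairpin secondary structure, site turnover,
read-level artifacts, or mapping error.  Passing recovery tests
therefore shows the pipeline's logic is correct on data satisfying its
assumptions, not that real repertoires are this clean — real families
blur at the similarity threshold, and real target sites are gained and
lost.

## Problem sizes and determinism

The default synthetic study (200 families → ~850 matures and ~240
genes, 300 genes × 8 species alignments, 48 expression samples) runs the
full pipeline in well under a minute; oracle tests use up to 10-kb UTRs,
200 random intervals and exhaustive enumerations on ≤ 6-tip trees.  A
single integer seed drives every stochastic stage; identical config and
seed reproduce every output byte-for-byte (asserted in the CLI test).
Degenerate inputs error explicitly: empty FASTA, non-positive intervals,
trees with missing branch lengths, zero-variance positions for the KDE,
all-zero expression columns, singleton clusters for density.

## Known limitations

- The family-edge threshold is a calibration, not an inference; clades
  with highly diverged paralogs may need a looser setting plus manual
  review of component sizes.
- Site conservation requires presence in *all* aligned species; a
  partial-conservation tier is not implemented.
- Emergence rates pool sites across species in both numerator and
  denominator; a per-species-mean variant is available via configuration
  but not separately tested.
- GO annotation is taken as flat and pre-propagated; no ontology-graph
  propagation is performed.
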