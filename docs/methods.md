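# Methods

This note documents the models, conventions, numerical choices and
limitations behind `mito_orfan`, in the order a typical analysis runs.

## Genome model and unassigned regions

Coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention exists only at the I/O boundary.  A feature on a
circular genome may wrap the origin (`end > length`); GenBank output
renders it as a `join()` location.  Overlapping annotated genes are
permitted — common in animal mtDNA — and an unassigned region (UR) is
defined as a maximal interval covered by **zero** features.  URs are
numbered from 1 starting with the UR whose end abuts (or, failing an
exact abutment, lies nearest upstream of) *cox1*'s start on the
forward strand, proceeding in ascending-coordinate (clockwise) order;
the numbering is invariant under rotation of the sequence origin.
Gene labels are normalized through a shipped synonym table
(`data/gene_synonyms.tsv`); unknown labels are retained with kind
`other` and a warning rather than rejected.

## ORF census

ORFs are called in URs only, on both strands and all three frames,
under NCBI translation table 5.  The default definition is
getorf-like *start-to-stop*: from the first start codon
(ATG/ATA/ATT/ATC/GTG/TTG) after the previous in-frame stop to the
nearest in-frame stop, both inside the UR, with nested ORFs sharing a
stop suppressed (longest kept).  The minimum is 10 sense codons plus
the stop (33 nt).  A *stop-to-stop* mode is available behind a flag for
data annotated with the alternative getorf convention.  Codons
containing N translate to X (or their unique resolution); an ORF
containing a codon that *could* be a stop under some N-resolution is
rejected outright rather than called optimistically.  Each ORF carries
two translations — as coded, and with the first residue forced to
methionine — which differ at most at position 1.

The homology screen replaces profile/database searches with local
alignment (Smith–Waterman, BLOSUM62, gap open 11 / extend 1, a gap of
length L costing 11 + (L−1)).  The default acceptance score is 50:
measured against the null (best score of a random 30-aa protein
screened against a full set of 13 mitochondrial proteins) the 95th and
99th percentiles are ≈ 40 and ≈ 44, so 50 keeps the per-ORF
false-positive rate well below 5%, while genuine homologies (an exact
ATP8 copy scores ≈ 270) are never near the boundary.  The dynamic
programming is delegated to Biopython's `PairwiseAligner`; the test
suite checks it against an exhaustive alignment-enumeration oracle on
short sequences.

## Divergence statistics

*p-distance* is the proportion of differing sites among compared
columns, with gap/N (nt) or gap/X (aa) columns excluded pairwise — for
two sequences this equals complete deletion.

*Nei–Gojobori (1986)* is implemented in its conventional form.
Synonymous sites per codon: at each position, the fraction of the three
single-nucleotide changes that are synonymous, with changes creating a
stop codon excluded from the fraction's denominator, so sites always
total three per codon.  Differences: codon pairs differing at k
positions are averaged over all k! mutational pathways, pathways
through stop codons excluded; in the (rare) case that every pathway
passes through a stop, the pair falls back to an unweighted average
over all pathways and the result is flagged.  Site totals are averaged
over the two sequences.  Jukes–Cantor correction
`d = −(3/4)·ln(1 − (4/3)p)` is undefined at `p ≥ 3/4` and flagged; ω is
undefined when `dS` is 0 or undefined.  An exhaustive test compares
every statistic against an independent enumeration oracle over all
62 × 62 sense-codon pairs of table 5.

For accession-style inputs, codon alignments are built by globally
aligning the two proteins (BLOSUM62, 11/1, end gaps free, so the
3′-extended M-type *cox2* aligns as an overhang) and threading codons
back through the gaps.  MUSCLE-style multiple alignment is out of
scope; for diverged real data the alignment choice can shift per-gene
values slightly.  The headline "overall" F-vs-M statistics are computed
on the **concatenation** of the 13 per-gene codon alignments; a
per-gene mean is emitted alongside, since the two summaries can differ.
12S/16S rRNA genes receive nucleotide p-distances only.

*RSCU* is observed codon count × family size / family total, families
grouped by amino acid under the chosen code, stop codons excluded, with
unused families reported as zeros and flagged.

## Consensus masking

Masks are boolean keep-vectors per column; `combine_masks` keeps a
column iff at least k of n sources keep it (default k = 3, the
three-of-four consensus).  k = 1 is the union, k = n the intersection,
and raising k never adds columns.  Two built-in maskers (gap fraction
≤ 0.5 and column Shannon entropy ≤ 1.5 bits by default) stand in for
external maskers so the pipeline is self-contained; mask files are a
0/1 string per column or a list of kept 1-based indices.

## Gene order, TDRL, repeats, fragments

Gene orders are signed circular permutations of copy-indexed tokens in
ascending start order.  Breakpoint distance counts signed adjacencies
of one order absent from the other, on the shared token set, with
(x, y) identified with (−y, −x); it is symmetric and
rotation-invariant.

**TDRL.** Replaying a tandem duplication–random loss shows that the
survivors read as the genes retained from copy 1 (in source order)
followed by those retained from copy 2 — a *concatenation* of two
source-ordered subsequences, i.e. at most one descent in the block's
relative order.  (An arbitrary interleaving — equivalently, longest
decreasing subsequence ≤ 2 — is a strictly weaker condition:
(3,1,4,2) satisfies it but is not reachable by one TDRL.)  Feasibility
is decided by scanning every circular block and split point; block
ranks are taken within the block itself so origin-wrapping blocks are
handled.  The witness records the block and each gene's retained copy;
replay is exact and is asserted exhaustively against a brute-force
duplication/loss oracle for ≤ 6 tokens and on 1,000 random 10-token
instances.  TDRL cannot invert genes, so any sign mismatch is
infeasible by definition.

**Pseudogene fragments** are found by nucleotide Smith–Waterman
(+1/−1, gap −2) of reference genes against URs on both strands, with
iterative masking so multiple decayed copies of one gene are all
reported and overlapping hits merged.  The default score threshold is
22: the null distribution of best local scores on random AT-rich 500-nt
URs has 95th/99th percentiles of 15/17, so 22 holds the per-UR
false-positive rate under 5%, while a 15%-decayed tRNA-sized fragment
scores ≈ 46 and an *atp8*-sized one ≈ 100.  References should be the
*same genome's* genes — a remnant is a decayed copy of its own
genome's gene, and using a 40%-diverged ortholog halves the signal.

**Tandem repeats** are found by a periodicity scan: for each candidate
period p, positions whose p-window matches the next p-window at the
identity threshold (default 0.8) are merged into runs; region edges are
trimmed to the matching core (windowed support bleeds up to
(1 − min_identity)·p into random flanks), smallest periods are scanned
first, and larger-period harmonics overlapping an accepted region are
suppressed.  Reported unit lengths are accurate to a few percent;
boundaries carry O(p·(1−identity)) uncertainty, which is why planted
repeats are asserted with ±10% period tolerance.

## Trees and transmission patterns

Distance matrices support raw p-distances (nt/aa) and Jukes–Cantor
corrected nucleotide distances.  **Tree building uses the JC mode**: at
the ~0.4 F-vs-M divergences typical of DUI comparisons, raw
p-distances saturate and compress the deepest pairs, which can collapse
a true taxon-joining configuration into a spurious gender-joining
topology under neighbor joining; the JC transform restores approximate
additivity.  Neighbor joining is the standard Saitou–Nei algorithm with
the Q-criterion, exact on additive matrices (verified against every
4–6-taxon topology and cross-checked against scikit-bio), with negative
branch lengths clamped to zero with a warning.

Classification is topological only.  Gender-joining: some edge
bipartition separates all M tips from all F/H tips (H genomes are
F-derived, hence grouped with F).  Taxon-joining: every species' tips
have a private edge — the cherry criterion, which is this package's
operationalization of "clustering by species" and is labelled as such
in output.  The bipartition test runs first; failing both yields
`mixed` with the violating species named.  The call is invariant under
tip reordering and re-rooting.

## Synthetic data generator

The generator's defaults are the study conditions: target F-vs-M
concatenated PCG p-distance 0.40 with dN/dS 0.33, AT fraction 0.60,
~17 kb circular genomes with the 37 standard genes in a unionid-like
order, a 501-bp in-frame M-*cox2* 3′ extension (within the observed
1.27–1.38 kb M-cox2 range for a ~0.7 kb core), an M-orf between
*nad4L* and tRNA-Asp, a TDRL of the tRNA-Asp/*atp8* block with 15%
pseudogene decay, three ~320-bp tandem repeat copies at 2% inter-copy
decay, and three species at 0.03 between-species divergence per branch.

*Substitution machinery.*  One seeded generator is threaded through
every step.  Coding genes evolve by uniform per-site proposals
(transition/transversion ratio κ configurable) with nonsynonymous
changes accepted with probability ω, stop codons never created and
start codons protected; divergence targets are enforced by
construction — mutation continues until the observed PCG p-distance
against the reference reaches the target, so realized p is within
sampling error of the target by design.  The default κ is 1: the
Nei–Gojobori estimator assumes no transition bias, and with κ = 1 the
estimate recovers the generating ω within ±0.1 at 10⁴ codons for
ω ∈ {0.1, 0.33, 1.0} (a seeded test); with κ > 1 the estimator is
biased low, which is a property of the estimator, not the generator.
rRNA/tRNA sequences evolve without codon constraints via per-site
Poisson substitution counts.

*Gender- vs taxon-joining truth.*  Gender-joining studies evolve one
deep M ancestor shared by all species (undershooting the pairwise
target slightly, with a per-species top-up driving each F/M pair to the
target exactly); taxon-joining studies derive each species' M from its
own F independently.

*Known-truth unassigned regions.*  UR spacer sequence is constructed
ORF-free (stop-seeded chunks, verified as the spacer grows inside a
guard context) and regenerated per genome rather than evolved, since
UR sequence is unalignable noise in real F/M comparisons.  Planted
ORFs, decayed pseudogene copies and the repeat region are wrapped in
15-nt guard motifs (`TAGCTAGCTAGCTAG`: stop codons in all six
frame/strand combinations, no start codon in any), which makes each
block's ORF inventory a purely local, deterministic function of the
block — enumerated at plant time and recorded as truth, mirroring real
mitogenomes where census ORFs arise inside repeats over pseudogenized
gene fragments.  Any residual boundary-crossing reading frame is
disrupted with an in-frame premature stop.  The census therefore
matches the planted inventory *exactly*, which is the generator's
end-to-end acceptance property.

*What the generator does not emulate* — and hence what passing tests do
not show about real data: indels and alignment uncertainty,
among-site rate variation and conservative-substitution bias (realized
protein p-distance ≈ 0.57 at the default settings, somewhat above the
0.48–0.49 seen empirically), strand-asymmetric composition, tRNA/rRNA
structure, and recombination.  Taxon-joining recovery by NJ is ≈ 90–95%
rather than 100% at the default 0.03 species divergence: the codon
model's site-class rate heterogeneity leaves residual long-branch
compression that the JC correction cannot fully undo.

## Problem sizes and determinism

The default test suite runs in about 40 s: oracle checks are exhaustive
where the space is small (all sense-codon pairs; all permutations of
≤ 6 tokens; all 4–6-taxon topologies) and seeded Monte-Carlo at 300–500
draws where it is not (screen and fragment false-positive rates,
noisy-matrix NJ recovery at 100–200 replicates).  The acceptance script
simulates one full three-species study plus eight two-species
replicates (~10 s).  Every stochastic step draws from a single seeded
`numpy` generator; identical configs produce byte-identical files
(GenBank records carry a fixed date stamp for this reason).
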