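# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Family identification

A candidate protein enters the roster when at least one kinase-domain hit
satisfies all of: full-sequence E-value ≤ `evalue_cutoff` (default 1e-10),
model coverage (model_to − model_from + 1)/model_length ≥
`domain_completeness_fraction` (default 0.8), and protein length ≥
`min_protein_length` (default 100 aa). "Complete domain" has no universal
quantitative definition; the coverage fraction is this package's
operationalisation and is configurable. With several hits per protein the
best qualifying hit decides, which makes the filter monotone in the
E-value cutoff. One isoform per locus is retained — the greatest summed
CDS length, ties broken by lexicographically smallest transcript id so
re-runs are stable. Renaming orders genes by chromosome in natural order
(chr2 before chr10), then start coordinate, then gene id, and pads the
index to the digit count of the family size so names sort correctly.

## Gene structure

Metrics are computed on the retained transcript only: introns are the
gaps between consecutive exons, the total intron length is the transcript
span minus the summed exon lengths, and the amino-acid length is the CDS
length / 3, minus one when the supplied CDS ends in a stop codon. Group
differences use the two-sided Wilcoxon rank-sum test: exact enumeration
when both groups have n ≤ 8, the tie-corrected normal approximation
otherwise. The rank-sum (not signed-rank) form is used because the
compared groups (subfamilies, conservation classes) are unpaired. No
multiple-testing correction is applied across panels; each comparison is
reported as-is.

## Subfamily and cluster assignment

Unknown members inherit labels from reference proteins of known
subfamily. The protein alignment (an input; this package does not build
multiple alignments) is trimmed by the gap-threshold rule — a column is
kept iff its non-gap fraction is ≥ the threshold (default 0.2, boundary
inclusive) — then p-distances are taken over columns where neither
sequence is gapped (pairs with no comparable columns get distance 1 with
a warning). The tree is Saitou–Nei neighbor joining with two determinism
rules: Q-matrix ties resolve to the smallest label pair, and a negative
branch length is clamped to zero with the deficit moved to its sister so
the cherry's summed length is preserved. NJ is exact on additive
matrices, which is what the additivity tests assert. Each query leaf then
takes the labels of its nearest reference by patristic distance (ties to
the smallest reference id). Nearest-reference propagation was chosen over
smallest-monophyletic-clade labelling because it degrades gracefully when
the distance tree differs locally from a likelihood tree. Cluster labels
obey the family convention: clusters 1–5 are MEKK, 6–7 ZIK, 8–14 RAF.

## Orthogroups

Reciprocal best hits per species pair (per gene the top-scoring partner
in the other species, ties to the smallest id; an edge survives only if
mutual), then connected components. Genes without surviving edges are
singleton OGGs. With N species: conserved = present in all N, variable =
exactly N − 1 (one loss tolerated), rare = 1..N − 2. Copy number per
species is recorded so presence matrices show amplification, not just
occupancy. Percentages of the roster per class are reported half-up to
two decimals. Recovery of a planted grouping by RBH is guaranteed only at
copy number one: a duplicate copy shares its source's group in the truth
tables but cannot win a reciprocal edge against the source, so it
surfaces as a singleton; orthogroup-recovery checks therefore run on
duplication-free configurations.

## Ka/Ks (NG86)

Sites: for each codon and each of its nine one-step changes, changes
creating stops are excluded and the synonymous fraction is renormalised
over the remaining changes; per-codon fractions sum over the three
positions and are averaged between the two sequences, so S + N = 3 ×
(compared codon columns). Differences: codon pairs differing at k
positions are counted by averaging the synonymous/nonsynonymous step
classification over all k! orderings of single steps, discarding
pathways through stops (if every pathway is blocked, all steps count as
nonsynonymous — a conservative convention for a case the generator never
produces). Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p) maps ps and
pn to Ks and Ka; ω = Ka/Ks is undefined when Ks = 0 or either proportion
reaches 3/4. Aggregation is two-level and follows the arithmetic-mean
convention: OGG mean over pairs with defined ω, cluster mean unweighted
over its OGG means. When precomputed pairwise protein alignments are not
supplied, equal-length proteins are paired positionally and only
unequal-length pairs go through global alignment (BLOSUM62, gap open
−10 / extend −1); a gapped alignment of equal-length diverged sequences
would otherwise shift codon pairings it has no evidence for.

## Duplication modes and collinearity

Anchors are homologous gene pairs located by per-chromosome rank (the
gene's 1-based position by start coordinate among all annotated genes).
Blocks are longest strictly monotone chains — increasing on both sides
(same orientation) or increasing/decreasing (inverted) — with
consecutive-anchor rank gaps ≤ 25 on both sides, found by longest-chain
dynamic programming; 25 follows the spirit of standard collinearity
tools, while the 10-anchor minimum is the study's stated threshold.
Anchors join at most one block: chains are extracted greedily by length,
ties by leftmost start, same orientation before inverted. Duplication
modes are assigned by priority: WGD (anchored in an intra-species block),
tandem (homolog at rank distance 1 on the same chromosome), proximal
(rank distance 2–10), transposed (the copy of a homolog pair lacking
outgroup synteny while its partner retains it; the syntenic partner falls
through to a later mode), dispersed (any other homolog-bearing gene),
singleton (no homolog). The synteny–conservation table pools the unique
genes anchored per species pair and reports class percentages half-up to
two decimals.

## Promoters

The promoter is the 2000 bp immediately 5′ of the translation start
(first CDS base): plus strand [cds_start − w, cds_start − 1], minus
strand the reverse complement of [cds_end + 1, cds_end + w], truncated at
chromosome edges. The packaged library holds the high-frequency plant
elements (ABRE, CGTCA/TGACG motifs, as-1, ERE, MYC, MYB, MYB-like, ARE,
STRE, AAGAA motif, Box-4, G-box, GT1 motif) plus two development-class
elements (CAT-box, O2-site) so that all four functional classes are
populated; it is a TSV users can extend. Scanning reports every
overlapping IUPAC match on both strands; a minus-strand hit is placed at
the plus-strand start of its window, an element matching one window on
both strands (palindrome) is reported once on the plus strand, and N
bases never match. Frequencies are normalised within group (species,
subfamily or OGG) so rows sum to 1; column z-scores use the population
standard deviation with constant columns set to zero. Class-level shares
are reported half-up to one decimal.

## Expression

FPKM = count × 10⁹ / (transcript length × mapped library size); the
library size is taken from a `total_mapped` column when the table
provides one (summing counts over a gene-family subset would mistake the
family's aggregate induction for a library-size shift). The screen
compares condition means of FPKM with a pseudocount (default 1.0):
log₂FC = log₂((t + c₀)/(c + c₀)), responsive iff strictly |log₂FC| > 1.
qPCR: ΔCt = Ct_target − Ct_reference per replicate, ΔΔCt subtracts the
mean control (0 h) ΔCt, fold = 2^−ΔΔCt, reported as mean ± sample sd over
replicate folds. Letter displays run one-way ANOVA on log₂ folds and,
when significant, Tukey HSD at α = 0.05; letters come from the
insert-and-absorb construction ordered from the highest mean, so a group
indistinguishable from two separated groups shows both letters. The
ANOVA/Tukey choice is a documented stand-in — the original figure
convention does not name its test.

## Synthetic data

The generator emulates the study design, not real genomes. Each
orthogroup gets a random ancestor CDS (150–220 codons, ATG start, no
stops); members are the ancestor mutated with planted synonymous and
nonsynonymous counts, at most one substitution per codon and never in the
start codon, with substitution positions drawn only from codons that
admit the requested change so no stop can arise. This makes the planted
Sd/Nd exact integers — the point of the design, trading realism
(no multiple hits per codon) for an exact oracle. Planted counts aim at
the configured ω targets through the approximation Nd ≈ ω·3·Sd; the truth
tables record the exact counts, and recovery is judged against those, not
against the ω targets. Defaults mirror the ten-species study design:
10 species, 50 orthogroups in a 0.3/0.5/0.2 conserved/variable/rare mix,
blocks of ≥ 12 anchors, and one WGD plus a handful of small-scale events.

Gene layout is slot-based: each chromosome has `genes_per_chromosome`
slots, each slot one gene, so rank = slot + 1. Planted collinear runs
(cross-species, WGD, outgroup) occupy consecutive slots in identical
order; all other family genes are placed at random slots at least one
`max_rank_gap` window away from any run and at low density, so planted
chains are recovered with their exact anchor sets and no spurious chain
reaches the block minimum. Tandem pairs sit in adjacent slots, proximal
pairs three slots apart, dispersed/transposed copies on another
chromosome; the transposed event's ancestral copy keeps outgroup synteny
and is therefore planted (and classified) as dispersed, matching the
classifier's priority semantics. An outgroup pseudo-genome mirrors the
cross-run region; its genes carry no orthogroup membership — truth tables
are scoped to the focal roster. Decoy homology rows (scores 30–60 versus
90–100 for true pairs) are only drawn between genes whose orthogroups are
present in each other's species, so a decoy never becomes a best hit by
forfeit.

Promoter backgrounds are random sequence scrubbed of every library motif
on both strands before the planned instances are inserted at
non-overlapping positions and random strands; the finished promoter is
re-scanned and must contain exactly the planted hits (plans whose
elements embed in one another are rejected). Expression counts come from
baseline FPKM 10–100 with planted log₂ fold changes from
{0, ±0.5, ±1.5, 2, −2, 3} and small multiplicative noise (σ = 0.05 in
log₂), so the screen's margin to the |log₂FC| = 1 boundary is wide; qPCR
Ct values encode planted induction curves against a reference gene at
Ct ≈ 20 with σ = 0.05 cycles. Subfamily signal is planted as 120-aa
signature rows: three base sequences ~50% divergent, members within a
subfamily 5% divergent from their base, with sparse columns forced mostly
to gaps to exercise trimming — an emulated alignment, not an alignment of
the generated CDS translations. Domain tables give family proteins
passing hits and plant three violators per species (high E-value, half
model coverage, short protein), one per filter.

All randomness derives from one master seed through named sub-streams
(one per file kind), so equal configurations are byte-identical and
regenerating one file kind leaves the bytes of the others unchanged.

What passing tests on this generator do **not** show: robustness to
multiple substitutions per codon (real Ka/Ks saturation), alignment
error, fragmented assemblies, tandem arrays longer than two, overlapping
block structure, PlantCARE's full matrix library, or count overdispersion
in real RNA-seq. These are properties of real data the study conditions
deliberately abstract away.

## Problem sizes

The test suite exercises a four-species dataset (36 orthogroups, 160
genes per chromosome) for end-to-end recovery and a ten-species,
duplication-free dataset for orthogroup recovery; the acceptance script
additionally measures 100 coding pairs of 500 codons, 50 random additive
8-taxon matrices, and 20 anchor sets of 5 planted blocks with 200 noise
anchors. These sizes were chosen so the whole validation runs in minutes
on one core while every recovery criterion is still measured at its
stated scale.

## Known limitations

Neighbor joining replaces likelihood tree inference, so bootstrap support
and model selection are out of scope, and the 14-cluster partition is
taken from the reference panel rather than inferred from tree shape. The
NG86 estimator deliberately differs from modified-Yang–Nielsen
implementations (no transition/transversion or codon-frequency
weighting), so absolute Ka/Ks values are not comparable to tools using
those models; within-package comparisons and planted-truth recovery are.
Orthogrouping has no tree-reconciliation step and does not separate
in-paralogs. The motif library covers 16 named elements, not the full
cis-element universe, so absolute element totals are library-relative.
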