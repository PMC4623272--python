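# Methods

## The analysis in brief

ere-scout reimplements, as a tested library, a genome-wide SINE survey
workflow: (1) discover consensus-matching loci in an assembly and filter
them into a clean catalog; (2) detect empty (uninserted) alleles of those
loci from unassembled trace reads of the reference individual; (3)
classify loci relative to genes and resolve the target-site duplication
(TSD) of individual insertions; (4) compute the population and
evolutionary statistics that relate identity class, polymorphism and
insertion age.  A synthetic-data generator stands in for the genome
assembly and trace archive and carries complete ground truth.

## Discovery

The scan seeds exact k-mers (default word size 11) between the consensus
and every contig, on both strands, clusters seeds into candidate regions,
and resolves each region with an infix alignment (edlib).  Identity is
matches / alignment-columns with gap columns counted as errors — BLAST
hit-table semantics.  Overlapping hits keep the highest score
(2·matches − errors), then the leftmost.

*Boundary canonicalization.*  Unit-cost (edit-distance) alignment trades
substitutions for indels freely; near hit ends this can shift the
reported interval by a few bases among co-optimal paths, and at 84 %
identity a gapped path can even beat the ungapped one by an edit or two.
Because hit reporting should follow megablast-like scoring, where a gap
costs more than a mismatch, any gapped hit whose span is within 12 bp of
the query length is replaced by the best full-length ungapped placement
whenever that placement costs at most 2 extra mismatches per gap run
(i.e. the gap-opening penalty).  On substitution-only data this makes
reported coordinates exact, which the recovery tests assert.

Filters, in order, each recorded as a `filter_status` so counts always
reconcile: length within consensus ± 10 bp; identity ≥ 84.0 (inclusive;
`strict_gt` excludes the boundary — the two published phrasings of this
threshold differ, and the inclusive reading is the operative one);
contig→chromosome lifting through a placement table (reverse-oriented
contigs flip coordinates and strand; absent contigs are `dropped_unplaced`);
overlap of ≥ 1 bp with a non-ERE repeat annotation (`min_repeat_overlap`
is configurable; the published rule says only "interrupts").

Identity classes are eight 2-point bins over [84, 100], top bin closed.

## Empty-allele detection

Each kept locus yields a window of the element plus 1 kb flanks
(~2.2 kb).  Traces from the reference sequencing project are matched by a
seeded split alignment: exact 15-mers between trace and window are
grouped by diagonal; the dominant chain plus at most one colinear
continuation per side defines the alignment, and a diagonal shift of
≥ 50 bp is a large deletion.  Per-segment identities come from global
alignment of the matched slices.

A deliberate design point: plain edit-distance alignment *cannot* find
these deletions.  For a gap of g bp followed by f ≥ g bp of flank, the
mismatch path costs ≈ 0.75 g (expected, random DNA) versus g for the gap
path, so the optimal unit-cost alignment hides the deletion.  The
diagonal-chain formulation sidesteps gap penalties entirely and is exact
on the substitution-only reads the generator emits; it replaces a
two-piece gap-penalty DP that would add cost without adding power here.

Evidence requires: reference project id; exactly one deletion, of length
element ± 10 bp, overlapping the element interval; both flank identities
≥ 98 %; both anchors ≥ 50 bp (the published procedure does not state an
anchor minimum; 50 bp prevents spurious few-base anchors).  Flank
identity is computed per segment, both sides required — the published
phrasing is ambiguous between joint and per-flank identity, and the
per-flank reading is the stricter one.

The gap band has a consequence worth stating: the trace gap at a true
empty allele equals element + TSD length, so the element ± 10 rule can
only detect insertions with TSDs ≤ 10 bp.  This is the method's
sensitivity envelope, not an implementation artifact — insertions with
longer TSDs (such as a 14-bp-TSD promoter insertion) are invisible to
trace screening and must be found by PCR.  The generator therefore draws
TSDs of 5–10 bp for the loci it designates heterozygous, and 5–20 bp
elsewhere.

Multicopy screening masks the element, re-aligns each flank genome-wide
(plus its 80 % prefix/suffix, since the infix aligner consumes the whole
query and a partial duplication would otherwise hide), and flags a locus
when a second location matches at ≥ 95 %.  A locus is called heterozygous
iff it is unique and has ≥ 1 evidence trace (`min_traces` configurable).

## Gene context and TSD anatomy

Classification precedence is exon > intron > distance bins.  "Intron"
requires full containment within one intron; distance is from the nearest
locus boundary to the strand-aware 5' end of the nearest gene
(midpoint-based distance available behind a flag); ties go to the
lexicographically smaller gene id.  Validated and putative gene sets are
taken as a union.

`detect_tsd` scans repeat lengths t from 30 down to 0.  For each t the
admissible nick positions are bounded by the longest common prefix/suffix
of the filled and empty alleles, and a candidate is confirmed by exact
equality of the two direct-repeat copies; the maximal t wins, leftmost
nick on ties, and when the element sequence is supplied the inserted
segment must match it at ≥ 90 % identity.  Length conservation
(len(filled) − len(empty) = element + TSD) is asserted on every report.
TSD copies must match exactly; a mismatch-tolerant mode is out of scope.
Microhomology is the longest k with the element ending in A^k and the
empty allele carrying A^k immediately 3' of the nick (a T-run on the
bottom strand — the TPRT annealing substrate); it is reported as the
T-run string.

The generator guarantees decomposition uniqueness at planted sites by
requiring the base after the cut to differ from the element's first base
and the base left of the TSD to differ from the element's last base; any
longer spurious direct repeat would force one of those equalities, so
these two conditions make exact recovery well-defined.  Real allele pairs
can be genuinely ambiguous at the ±1 bp level when the insertion
boundaries share sequence with the flanks; the detector then still
returns the canonical (maximal-repeat, leftmost-nick) decomposition.

## Population statistics

Percentages in frequency reports are rounded half-up to one decimal (the
convention of the survey tables they mirror).  χ² statistics are Pearson
sums without continuity correction — with Yates' correction the
goodness-of-fit p on the packaged survey counts would be ≈ 1.3×10⁻⁵
instead of the published ≈ 9.3×10⁻⁶, which settles the choice.  p-values
use the χ² and t survival functions from scipy; the statistics themselves
are computed from their defining formulas and cross-checked against
scipy's full implementations to 10⁻¹⁰ in tests.

The identity/polymorphism correlation uses class midpoints as the x
variable (lower bounds behind a flag), ln(polymorphic fraction) as y;
classes with zero polymorphic loci are dropped because ln 0 is undefined
(whether the original analysis included them is not stated), and ≥ 3
usable classes are required.

Insertion-age classification is a pure function of the per-species
presence pattern: present everywhere → inserted before the equid
radiation (all_equus); present in both horse species only →
horse_lineage; domestic horse only → caballus_only; patterns violating
the tree → unresolved.  Presence at any allele frequency counts, and
per-species polymorphism flags are carried alongside.

Linkage disequilibrium between two unphased loci uses EM over the nine
two-locus genotype cells (only the double heterozygote is
phase-ambiguous), r² = D²/(p_A p_a p_B p_b).  When no double
heterozygotes are present the EM estimate equals direct haplotype
counting, which a test asserts.  Monomorphic loci report r² as undefined
rather than zero.

ΔΔCq: ΔCq = mean Cq(target) − mean Cq(control) per condition, ΔΔCq taken
against a reference condition, fold change 2^(−ΔΔCq) (reference ≡ 1).

## The generative model

Per locus, age T ~ Uniform(0, 32) My.  Identity decays linearly,
100·(1 − μT) with μ = 0.005 /site/My, clamped to [84, 100] — so 2
identity points ≈ 4 My and the clamp meets the catalog floor at 32 My.
Polymorphism decays exponentially, P(polymorphic) = p₀·exp(−T/τ) with
p₀ = 0.06 and τ = 7.33 My, calibrated so the youngest identity class is
~5 % polymorphic and the oldest ~0.1 % — the qualitative law the analysis
is built to recover.  (A pure exp(−T/τ) cannot produce a ~5 % ceiling at
T = 0; the p₀ prefactor absorbs detection incompleteness from screening a
single diploid genome.)  Species presence follows the tree: T ≥ 3.8 My →
present in all eight equid tips; 0.12 ≤ T < 3.8 → both horse species;
T < 0.12 → domestic horse only.  The 0.12 My horse/Przewalski split is a
free tree parameter.  Polymorphic loci draw an ERE1+ frequency from
Uniform(0.05, 0.95) and genotypes are Hardy-Weinberg draws per
individual; sample sizes default to 30 domestic horses, 20 Przewalski's
horses and six single/small other-equid samples.

Insertions are planted with TPRT geometry (TSD duplicated 5' of the cut).
Divergence is substitution-only so planted loci sit inside the ± 10 bp
length filter by construction; an indel-bearing locus is deliberately an
out-of-filter case.  Recovery-experiment datasets additionally designate
disjoint locus sets: heterozygous in the reference individual (default
30; empty-haplotype reads are emitted spanning the junction with ≥ 120 bp
anchors), embedded in another repeat's annotation (default 10), and
window-duplicated (default 5; the duplicate is pasted into a reserved
genome tail and is itself a catalog-eligible locus, and these loci also
carry empty alleles so that the uniqueness screen — not missing evidence —
is what excludes them from the calls).  Traces default to 700 bp, 4 reads
per haplotype per locus, plus decoy-project reads that the project filter
must ignore; half of all reads are reverse-complemented.

What the generator does not emulate: sequencing errors and quality
values, paired-end structure, read-depth heterogeneity, genuine segmental
duplication divergence, indel divergence within elements, realistic equid
demography or linkage.  Passing recovery tests therefore demonstrate
correctness of the algorithms under the stated model — exact coordinate
recovery, exact heterozygote calling — not robustness to base-call noise,
which the real procedure absorbed through manual curation.

## Problem sizes and numerics

The recovery experiment runs on a 2 Mb genome with 200 planted loci — the
same locus density (one per 10 kb) as a ~2.4 Gb genome with ~27 k
catalog loci, kept small enough that the whole experiment completes in
seconds.  The statistical-law simulation uses 2000 loci so that each
identity class holds ~250.  All randomness flows from a single seed
through named substreams; identical configuration and seed reproduce
bit-identical datasets, which a test asserts.  Tolerances: planted
identity is recovered within ±0.5 points (co-optimal alignments can
differ in how they count a tied column); statistic oracles match scipy to
10⁻¹⁰ relative; EM r² converges to 10⁻¹² in haplotype frequency.

## Known limitations

Discovery reports one locus per candidate region, so two inserts within
~225 bp of each other would merge; the generator never plants them that
close.  The trace matcher models exactly one large deletion; nested or
double events are out of scope.  The TSD detector requires exact direct
repeats.  The EM r² assumes random mating within the sample.  The CLI is
a thin veneer over the library and exposes only the common paths.
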