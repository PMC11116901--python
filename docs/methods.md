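# Methods

`translokit` models the genetics and genomics of balanced inter-chromosomal
translocations of the kind used to breed less-seed watermelon: a wild-type
line and a near-isogenic translocation line are compared at the assembly
level to find the breakpoints, the junctions are characterized at base
resolution, codominant PCR markers are designed across them, and the
meiotic consequences in heterozygotes (multivalents, semi-sterility,
Mendelian F2 ratios) are predicted and tested. Because real long-read
assemblies are far beyond desk scale, the package ships a first-class
synthetic-genome generator with exact ground truth; everything downstream
is validated against that truth.

## Synthetic genomes and translocation derivation

Wild-type chromosomes are i.i.d. nucleotide sequences with a configurable
GC content. Defaults emulate a watermelon-like karyotype at desk scale:
**11 chromosomes x 200 kb, GC 0.35** (the real genome is ~365 Mb at GC
~0.35; length-dependent behavior such as unique-anchor density saturates
well below 200 kb, so nothing in the analysis depends on the missing
scale). Chromosome lengths under 10 kb are rejected because they leave too
few unique anchors.

A reciprocal translocation is specified by one breakpoint per donor —
1-based position of the last base retained on the proximal segment — plus
per-junction NHEJ-style edits:

* **deletions** resect the bases nearest the break from either flank
  (defaults put the whole per-junction deletion on the proximal flank,
  the reading consistent with per-recombinant deletion sizes reported for
  real junctions);
* an optional **insertion** of arbitrary sequence at the join;
* an optional **micro-homology motif**: the motif is written into both
  wild-type flanks immediately at the (post-resection) break, and the
  derived junction retains exactly one copy spanning the join. The motif
  is rewritten into the wild type *before* derivation so that wild type
  and mutant are mutually consistent — matching the biological situation
  where the micro-homology pre-exists in the wild-type genome.

Complex (chained) events are built by applying reciprocal exchanges
sequentially; an exchange whose breakpoint falls inside an
already-rearranged chromosome splits it there, so a chain over three
donors yields three derived chromosomes carrying four junctions (one of
them with two junctions and three source segments). Disjoint exchanges
reduce to independent reciprocal events.

**Exact-homology guards.** A random junction carries, with probability
~7/16 per side, one or more bases of chance homology between the two
flanks, which makes the junction placement ambiguous. The generator
therefore adjusts single wild-type bases adjacent to each junction so the
realized micro-homology equals the requested motif exactly (zero when no
motif is requested). This is a deliberate design choice: generated
junctions *are* their specification, so recovery tests can demand
base-exact agreement rather than agreement up to an unmodeled ambiguity
interval. Real junctions do carry chance micro-homology; on real data the
caller reports the ambiguity interval and the leftmost canonical
coordinate (see below), and "exact recovery" must be read modulo that
interval. Guards are iterated to a fixed point because a guard base can
sit in another junction's flank; with an insertion abutting a motif the
ambiguity cannot always be removed and a warning is issued.

Every derivation emits a truth record: source segments per derived
chromosome (verified to tile the mutant byte-exactly), per-junction
canonical coordinates, edit sizes, and the per-donor deletion totals a
sequence-level analysis can observe. Because motif emulation rewrites
wild-type flanks, the truth record carries the adjusted wild-type genome;
comparisons must use it rather than the pre-derivation input.

## Anchor alignment

The aligner stands in for whole-genome alignment at desk scale. It indexes
every k-mer whose canonical (strand-collapsed) form occurs exactly once in
the wild-type genome (k odd to exclude reverse-complement palindromes;
default **k = 21**, where >95% of positions of a random 200 kb chromosome
are anchored), locates those k-mers in the mutant, and chains co-oriented
anchors into maximal colinear blocks. A chain breaks at a change of
wild-type chromosome or strand, a gap above **max_gap = 2 kb** on either
genome, or a diagonal shift above **indel_slack = 50 bp**; runs shorter
than **min_anchors = 10** are dropped. Unique-anchor density on random
sequence makes junction localization much finer than max_gap. Blocks are
0-based half-open, sorted and non-overlapping on the mutant; minus-strand
blocks are reported but never interpreted (inversion calling is out of
scope). Uniqueness is strand-collapsed, so a k-mer equal to the reverse
complement of another occurrence is excluded even if each strand reading
occurs once.

## Breakpoint calling and refinement

A junction candidate is any adjacency of two plus-strand blocks from
different wild-type chromosomes on one mutant chromosome (blocks under
1 kb are suppressed first; same-chromosome anomalies are logged, not
called). Candidates are grouped by connected components of the wild-type
chromosome adjacency graph: a two-chromosome component must be a mirrored
pair of calls (reciprocal); components over three or more chromosomes are
complex chains.

Refinement extends exact sequence match from the left block rightward and
from the right block leftward across the junction:

* overlapping extensions = micro-homology shared by both wild-type
  flanks; the junction is placed at the **leftmost** equivalent position
  on the mutant chromosome and the shared bases are attributed to the
  right-hand source (a fixed, documented convention — any position inside
  the overlap is sequence-equivalent);
* a gap between extensions = inserted sequence, reported verbatim with
  the residual ci_width;
* abutting extensions = a clean junction with ci_width 0.

The generator records truth coordinates under the same leftmost
convention, so synthetic recovery is exact at base precision.

## Junction characterization

Per junction the characterizer reports the deletion on each donor, the
insertion, and the micro-homology (exact match only, capped at 50 bp;
junctions are classed micro-homology-mediated at >= 2 bp shared — 1 bp is
uninformative — else blunt; the threshold is configurable). Deletions are
found by a probe search: the smallest shift at which a 40 bp window of
donor sequence beyond the refined junction reoccurs in the mutant genome.
Only per-donor totals are observable — how missing bases split between a
junction's proximal flank and the partner junction's distal flank is not
identifiable from sequence — so each donor's total is attributed to the
junction where that donor is proximal, which is how per-recombinant
deletion sizes are conventionally reported. The left-donor measurement
includes the micro-homology bases under the leftmost convention and is
corrected by the reported micro-homology length.

## Marker design and in-silico genotyping

For each junction the package designs a recombinant pair (one primer per
side of the junction, product spans the join) and a nonrecombinant pair on
the left donor spanning its breakpoint. The junction-side forward primer
is shared between the two pairs and translated to wild-type coordinates —
the classic multiplex layout — unless junction edits reach into its site,
in which case an independent primer is searched. Primer rules (defaults:
length 20 searched within 18–24, GC 40–60%, Wallace 2+4 Tm 55–65 °C,
amplicon 150–1000 bp, WT/MT size difference >= 100 bp) are deliberately
simple and fully configurable; uniqueness requires at most one exact
occurrence, either strand, within *each* genome — occurrence once "across
both genomes combined" is unattainable because breakpoint-flank sequence
is shared by wild type and mutant by construction. The PCR model is
exact-match, full-length annealing of convergent primers within a 2 kb
product cap; mismatch annealing, primer dimers and thermodynamic Tm are
out of scope. Specificity is validated at design time: the WT pair must
give exactly one product on the wild type and none on the mutant, and
vice versa, so presence/absence of the two amplicons maps bijectively
onto homozygous-WT / heterozygous / homozygous-translocated.

Populations can be genotyped either from diploid genome pairs (real PCR
simulation) or from truth genotypes (N/T alleles per event); individuals
whose markers disagree within one event are flagged
recombinant-discordant and excluded from counts.

## Meiosis model

Heterozygous reciprocal events form quadrivalents (2 chromosome pairs
each); heterozygous chains over c donors form one 2c-chromosome
multivalent; everything else is bivalents. Alternate segregation (freq
``a`` per multivalent, default 0.5 — the classical expectation, and close
to values back-estimated from observed semi-sterility) yields balanced
all-normal or all-translocated gametes with probability a/2 each;
adjacent-1 and adjacent-2 are lumped into a single unbalanced mass
because only balanced-vs-unbalanced is identifiable from fertility data.
Under balanced-only viability, selfing gives NN:NT:TT = 1:2:1 per event,
fully fertile fraction (1/2)^k for k independent events (normal :
semi-sterile = 1 : 2^k − 1), and pollen sterility 1 − prod(a_i); seed-set
reduction uses the same rule on the ovule side, with an independent
ovule alternate frequency as a configuration hook since published seed
reductions need not match pollen sterility. Chained multivalents have no
closed-form ratio; they require an explicit segregation table
(`uniform_chain_table` enumerates n:n disjunctions uniformly — 2 balanced
of C(2n, n) — and predictions made with it are flagged model-dependent).
The estimator inverts sterility as a_hat = (1 − s)^(1/k) with a
Wilson-interval-transformed CI. All stochastic operations take explicit
seeds; there is no hidden RNG state.

Observed diakinesis configurations of a chained heterozygote may resolve
as two quadrivalents rather than one hexavalent; the model reports the
strict chain prediction, and users modelling the observed configuration
should declare two reciprocal events instead.

## Segregation statistics

Pearson chi-square with expected counts total·r_i/Σr and **no continuity
correction** — back-computation of the published F2 tables (e.g. 112:125
vs 1:1 → 0.713) confirms the authors computed it uncorrected. df =
classes − 1; "conforms" is boundary-inclusive at the critical value
(α = 0.05 default). Percentages print with one decimal, half-up, to
mirror the published layout. The two published F2 count tables ship as
packaged TSV fixtures and their ten chi-square values are reproduced to
±0.001 in the acceptance suite.

## Pipeline, scales and determinism

`run_pipeline` chains all stages from one YAML config with explicit seeds
(missing seeds fail validation before any stage runs) and writes a
manifest with the truth-vs-called comparison, junction recovery, marker
specificity and the F2 chi-square table. Re-running a config reproduces
byte-identical artifacts; logging (timestamped, stage-scoped) goes to
stderr, never into artifacts.

Problem sizes used by the test and acceptance suites are the package's
standard desk scale: 11 x 200 kb genomes for breakpoint-recovery
(50 randomized events, 20 wild-type self-comparisons) and the
published-edit-size junction checks; 3 x 30 kb genomes for marker-design
properties; n = 237 F2 individuals (the published population size) with
100 seeded replicates for genotype-ratio checks; n = 1e5 offspring for
simulation-vs-theory agreement; 200 replicates at n = 1e4 pollen grains
for estimator coverage.

## What the synthetic data does and does not show

The generator reproduces the *logical* structure of the problem — exact
reciprocal/chained exchanges, NHEJ-style junction edits, known truth —
on i.i.d. random sequence. It does not model repeats, centromeres,
segmental duplications, assembly errors, or heterozygosity within a line,
all of which make anchor uniqueness and junction interpretation harder on
real assemblies. Passing tests therefore demonstrate correctness of the
algorithms under clean assembly conditions, not robustness to repetitive
genome structure. Read-level simulation and assembly are out of scope by
design.

## Known limitations

* Inversions and intra-chromosomal rearrangements are detected only as
  anomalies and never called.
* The PCR model ignores mismatch tolerance, so a single SNP in a primer
  site abolishes the product; real assays degrade more gracefully.
* Insertions combined with micro-homology motifs can leave junction
  ambiguity the guards cannot remove (warned at generation time).
* Chain-segregation predictions depend entirely on the supplied table;
  the uniform 3:3 default is a null model, not an empirical claim.
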