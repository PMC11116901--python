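# translokit

Detection and genetic analysis of balanced chromosomal translocations from
assembly comparison — with the meiosis model that explains why
translocation heterozygotes are semi-sterile.

## The problem

Reciprocal translocations — a mutual exchange of terminal segments between
two nonhomologous chromosomes — are agronomically useful in watermelon:
a plant heterozygous for a translocation forms a quadrivalent at meiosis,
half (or more) of its gametes are unbalanced and abort, and the fruit of
such heterozygotes is nearly seedless. Breeding with these lines requires
knowing exactly where the breakpoints are, what the junctions look like
(NHEJ repair leaves 1–25 bp deletions and sometimes micro-homology such as
a shared 5-nt `TTTAT`), and markers that distinguish homozygous wild-type,
heterozygous, and homozygous translocated plants in segregating
populations.

`translokit` implements that entire analysis as a tested pipeline on
synthetic data with exact ground truth: a generator for wild-type genomes
and derived translocation mutants (reciprocal, multi-event, and chained
complex configurations), a unique k-mer anchor aligner, a breakpoint
caller with base-resolution refinement, junction characterization,
codominant breakpoint-spanning PCR marker design with in-silico PCR, a
quadrivalent alternate/adjacent segregation model, and chi-square tests
of Mendelian segregation. It is aimed at plant-genetics researchers and
tool developers who need a fully controlled testbed for
translocation-calling and marker-assisted-selection workflows.

## The model in brief

* **Breakpoints.** A junction on a recombinant chromosome is the adjacency
  of synteny blocks from two wild-type chromosomes. Exact-match extension
  across the junction gives base resolution; micro-homology makes the
  placement ambiguous over the shared bases, and the leftmost equivalent
  coordinate is reported. Per junction, the donor deletions, any inserted
  bases, and the maximal micro-homology shared by both wild-type flanks
  are measured (`blunt` vs `microhomology_mediated` at a 2 bp threshold).
* **Meiosis.** A heterozygous reciprocal event forms one quadrivalent
  (9 bivalents + 1 quadrivalent in an 11-pair karyotype; 7 + 2 for two
  events). With alternate-segregation frequency *a*, pollen sterility is
  1 − ∏aᵢ; under balanced-only gamete viability, selfing gives per-event
  genotypes NN:NT:TT = 1:2:1 and a normal : semi-sterile phenotype ratio
  of 1 : 2ᵏ − 1 for k independent events (1:1 for one event, 1:3 for
  two). The estimator inverts sterility as â = (1 − s)^(1/k).
* **Segregation tests.** Pearson χ² against a ratio, expectedᵢ =
  total·rᵢ/Σr, no continuity correction, df = classes − 1.

## Worked example

Simulate a translocation line, call and characterize its breakpoints:

```python
from translokit import generate_wt_genome, reciprocal_junction_pair, simulate_mutant
from translokit.anchors import build_anchor_index, chain_anchors
from translokit.breakpoints import call_and_refine
from translokit.junctions import characterize_event

wt0 = generate_wt_genome(11, [200_000] * 11, gc_content=0.35, seed=7, name="WT-a")
pair = reciprocal_junction_pair(("Chr6", 110_000), ("Chr10", 90_000),
                                deletions=(3, 3), motifs=("TTTAT", ""))
wt, mt, truth = simulate_mutant(wt0, [pair], "MT-a")   # wt carries the motif flanks

events = call_and_refine(chain_anchors(build_anchor_index(wt, k=21), mt), wt, mt)
ev = events[0]
print(f"{ev.event_id}: {ev.kind} between {sorted(ev.chromosomes)}")
for rep in characterize_event(ev, wt, mt):
    print(f"  {rep.mt_chromosome}:{rep.position}  del=({rep.deletion_left},{rep.deletion_right})"
          f"  mh={rep.microhomology_seq or '-'}  class={rep.joining_class}")
```

prints

```
EV1: reciprocal between ['Chr10', 'Chr6']
  Chr10^6:89997  del=(3,3)  mh=-  class=blunt
  Chr6^10:109992  del=(3,3)  mh=TTTAT  class=microhomology_mediated
```

i.e. one reciprocal event between Chr6 and Chr10 was called; each
recombinant junction lost 3 bp, and the Chr6-derived junction carries the
5-nt `TTTAT` micro-homology — exactly the edits the mutant was built
with (the junction coordinates are the last Chr10/Chr6 base retained on
each recombinant chromosome: the 3 bp resections shift them from the
nominal 90,000/110,000 exchange positions, and the leftmost-placement
convention shifts the motif junction 5 bp further).

The same analysis from the shell, end to end:

```bash
translokit run-all --preset MT-a --seed 7 --outdir run_mta
translokit segregation-test --counts 112,125 --ratio 1:1
```

The second command tests a normal:sterile pollen count of 112:125 from a
segregating F2 against 1:1 and prints

```json
{"observed": [112, 125], "expected": [118.5, 118.5],
 "chi2": 0.713, "df": 1, "p_value": 0.398, "segregation": "mendelian"}
```

(abridged): the population segregates 1:1, i.e. the semi-sterile
phenotype behaves as a single dominant heterozygous condition. Other
subcommands: `simulate-genomes`, `align`, `call`, `junctions`,
`design-markers`, `meiosis-predict`, `simulate-cross`, `estimate-a`.

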