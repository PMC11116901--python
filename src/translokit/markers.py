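"""Codominant breakpoint-spanning PCR markers and in-silico genotyping.

For each translocation junction a marker set holds two primer pairs:

* the recombinant pair (MT-F/R): one primer on each side of the junction on
  the recombinant chromosome, so the product physically spans the join and
  can only amplify from a recombinant template (on the wild type the two
  primers sit on different chromosomes);
* the nonrecombinant pair (WT-F/R): both primers on the wild-type donor
  chromosome, spanning the breakpoint position, so the product is lost on
  the recombinant template where the downstream binding site has moved to
  another chromosome (or was resected).

Scoring both pairs on one template class gives a codominant assay: WT band
only = homozygous wild type, both bands = heterozygous, MT band only =
homozygous translocation — the three-class readout used to follow a
translocation through segregating populations.

The PCR model is exact-match, full-length annealing of convergent primer
pairs within a product-size cap; melting temperatures use the Wallace 2+4
rule.  Mismatch-tolerant annealing, primer dimers and thermodynamic Tm are
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breakpoints import BreakpointCall
from .genomes import Genome, revcomp
from .kmers import canonical_codes, canonical_kmer_code

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """No primer satisfying the rules exists in the search window."""


@dataclass(frozen=True)
class PrimerRules:
    """Primer and amplicon constraints.

    Lengths are searched from ``length`` outward within ``length_range``;
    Tm is the Wallace rule 2*(A+T) + 4*(G+C) in deg C; uniqueness requires
    at most one exact occurrence (either strand) within each genome.
    ``min_size_diff`` keeps the WT and MT amplicons gel-resolvable.
    """

    length: int = 20
    length_range: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (55.0, 65.0)
    amplicon_range: tuple[int, int] = (150, 1000)
    min_size_diff: int = 100
    min_junction_margin: int = 50
    max_product: int = 2000


def wallace_tm(seq: str) -> float:
    gc = seq.count("G") + seq.count("C")
    return 2.0 * (len(seq) - gc) + 4.0 * gc


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str          # 5'->3'
    chromosome: str        # binding chromosome in its design genome
    start: int             # 1-based binding-site start on the + strand
    end: int               # 1-based inclusive end
    strand: str            # "+": sequence == template slice; "-": revcomp
    tm: float
    gc: float


@dataclass
class MarkerSet:
    """Codominant marker for one breakpoint: WT pair + MT pair."""

    name: str
    event_id: str | None
    breakpoint: BreakpointCall
    wt_pair: tuple[Primer, Primer]
    mt_pair: tuple[Primer, Primer]
    wt_amplicon: int
    mt_amplicon: int

    @property
    def expected_sizes(self) -> dict[str, list[int]]:
        return {
            "homozygous_WT": [self.wt_amplicon],
            "heterozygous_TL": sorted([self.wt_amplicon, self.mt_amplicon]),
            "homozygous_TL": [self.mt_amplicon],
        }


@dataclass
class GenotypeCall:
    individual: str
    marker: str
    wt_amplicon: bool
    mt_amplicon: bool

    @property
    def call(self) -> str:
        if self.wt_amplicon and self.mt_amplicon:
            return "heterozygous_TL"
        if self.wt_amplicon:
            return "homozygous_WT"
        if self.mt_amplicon:
            return "homozygous_TL"
        return "no_amplification"


# ---------------------------------------------------------------------------
# primer uniqueness
# ---------------------------------------------------------------------------


class _UniquenessScreen:
    """Exact occurrence counts (canonical, both strands) per genome, lazily
    built per primer length."""

    def __init__(self, genomes: tuple[Genome, ...]):
        self.genomes = genomes
        self._tables: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}

    def _table(self, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
        if k not in self._tables:
            per_genome = []
            for g in self.genomes:
                codes = np.concatenate(
                    [canonical_codes(seq, k)[0] for seq in g.chromosomes.values()]
                )
                uniq, counts = np.unique(codes, return_counts=True)
                per_genome.append((uniq, counts))
            self._tables[k] = per_genome
        return self._tables[k]

    def occurrences(self, seq: str) -> list[int]:
        out = []
        code = canonical_kmer_code(seq)
        for uniq, counts in self._table(len(seq)):
            i = np.searchsorted(uniq, code)
            out.append(int(counts[i]) if i < uniq.size and uniq[i] == code else 0)
        return out

    def is_unique(self, seq: str) -> bool:
        return all(c <= 1 for c in self.occurrences(seq))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def _candidate_lengths(rules: PrimerRules) -> list[int]:
    lo, hi = rules.length_range
    out = [rules.length]
    for d in range(1, hi - lo + 1):
        for L in (rules.length + d, rules.length - d):
            if lo <= L <= hi and L not in out:
                out.append(L)
    return out


def _passes(seq: str, rules: PrimerRules) -> bool:
    return (
        rules.gc_range[0] <= gc_fraction(seq) <= rules.gc_range[1]
        and rules.tm_range[0] <= wallace_tm(seq) <= rules.tm_range[1]
    )


def _find_forward(template: str, chrom: str, end_from: int, end_to: int,
                  rules: PrimerRules, screen: _UniquenessScreen,
                  name: str) -> Primer:
    """First acceptable forward primer with 3' end scanning end_from->end_to
    (1-based); scan direction follows the sign of the range."""
    step = 1 if end_to >= end_from else -1
    for e in range(end_from, end_to + step, step):
        for L in _candidate_lengths(rules):
            s = e - L + 1
            if s < 1 or e > len(template):
                continue
            seq = template[s - 1 : e]
            if _passes(seq, rules) and screen.is_unique(seq):
                return Primer(name, seq, chrom, s, e, "+", wallace_tm(seq), gc_fraction(seq))
    raise DesignError(
        f"no unique primer with GC {rules.gc_range} and Tm {rules.tm_range} "
        f"found for {name} with 3' end in {chrom}:{end_from}-{end_to}"
    )


def _find_reverse(template: str, chrom: str, start_from: int, start_to: int,
                  rules: PrimerRules, screen: _UniquenessScreen,
                  name: str) -> Primer:
    """First acceptable reverse primer whose binding site starts (on the +
    strand) in the given scan range."""
    step = 1 if start_to >= start_from else -1
    for s in range(start_from, start_to + step, step):
        for L in _candidate_lengths(rules):
            e = s + L - 1
            if s < 1 or e > len(template):
                continue
            site = template[s - 1 : e]
            if _passes(site, rules) and screen.is_unique(site):
                seq = revcomp(site)
                return Primer(name, seq, chrom, s, e, "-", wallace_tm(seq), gc_fraction(seq))
    raise DesignError(
        f"no unique primer with GC {rules.gc_range} and Tm {rules.tm_range} "
        f"found for {name} with binding start in {chrom}:{start_from}-{start_to}"
    )


def design_breakpoint_markers(
    wt_genome: Genome,
    mt_genome: Genome,
    breakpoint: BreakpointCall,
    rules: PrimerRules = PrimerRules(),
) -> MarkerSet:
    """Design the codominant WT/MT primer pairs for one refined breakpoint.

    The MT pair spans the junction on the recombinant chromosome; the WT
    pair spans the corresponding breakpoint position on the left donor
    chromosome.  Raises :class:`DesignError` with the limiting constraint
    when the junction geometry or sequence admits no valid panel.
    """
    if not breakpoint.refined:
        raise DesignError("breakpoint must be refined before marker design")
    j = breakpoint.mt_junction_position
    mt_chrom = breakpoint.mt_chromosome
    a_chrom, a_pos = breakpoint.left_source[0], breakpoint.left_source[1]
    M = mt_genome.chromosomes[mt_chrom]
    A = wt_genome.chromosomes[a_chrom]

    lo, hi = rules.amplicon_range
    # keep room for the primers themselves so the minimum amplicon is reachable
    margin = max(rules.min_junction_margin, lo // 2 - rules.length + 5)
    if min(j, len(M) - j) < lo // 2:
        raise DesignError(
            f"junction {mt_chrom}:{j} is {min(j, len(M) - j)} bp from a "
            f"chromosome end; minimum amplicon {lo} bp cannot span it"
        )
    screen = _UniquenessScreen((wt_genome, mt_genome))

    # recombinant pair: F upstream of the junction, R downstream
    mt_f = _find_forward(M, mt_chrom, j - margin, max(j - margin - 400, 1),
                         rules, screen, f"{mt_chrom}-MT-F")
    mt_r = _find_reverse(M, mt_chrom, j + margin, min(j + margin + 400, len(M)),
                         rules, screen, f"{mt_chrom}-MT-R")
    mt_len = mt_r.end - mt_f.start + 1
    if not lo <= mt_len <= hi:
        raise DesignError(f"recombinant amplicon {mt_len} bp outside {lo}-{hi}")

    # Nonrecombinant pair on the left donor, spanning its breakpoint.  The
    # forward primer is shared with the recombinant pair (the sequence
    # upstream of the junction is identical in both genomes), translated to
    # wild-type coordinates — the classic shared-primer multiplex layout.
    wt_f_start = a_pos - (j - mt_f.start)
    wt_f = Primer(f"{a_chrom}-WT-F", mt_f.sequence, a_chrom,
                  wt_f_start, wt_f_start + len(mt_f.sequence) - 1, "+",
                  mt_f.tm, mt_f.gc)
    if A[wt_f.start - 1 : wt_f.end] != wt_f.sequence:
        # junction edits reached into the primer site; design independently
        wt_f = _find_forward(A, a_chrom, a_pos - margin, max(a_pos - margin - 400, 1),
                             rules, screen, f"{a_chrom}-WT-F")
    min_end = wt_f.start + mt_len + rules.min_size_diff - 1  # required WT-R 3' reach
    wt_r = _find_reverse(A, a_chrom,
                         max(a_pos + margin, min_end - rules.length_range[0] + 1),
                         min(a_pos + margin + 600, len(A)),
                         rules, screen, f"{a_chrom}-WT-R")
    wt_len = wt_r.end - wt_f.start + 1
    if not lo <= wt_len <= hi:
        raise DesignError(f"nonrecombinant amplicon {wt_len} bp outside {lo}-{hi}")
    if abs(wt_len - mt_len) < rules.min_size_diff:
        raise DesignError(
            f"amplicon sizes {wt_len}/{mt_len} differ by less than "
            f"{rules.min_size_diff} bp"
        )

    marker = MarkerSet(
        name=f"{a_chrom}+{mt_chrom}",
        event_id=breakpoint.event_id,
        breakpoint=breakpoint,
        wt_pair=(wt_f, wt_r),
        mt_pair=(mt_f, mt_r),
        wt_amplicon=wt_len,
        mt_amplicon=mt_len,
    )
    _validate_specificity(marker, wt_genome, mt_genome, rules)
    return marker


def _validate_specificity(marker: MarkerSet, wt: Genome, mt: Genome,
                          rules: PrimerRules) -> None:
    wt_on_wt = insilico_pcr(wt, marker.wt_pair, rules.max_product)
    wt_on_mt = insilico_pcr(mt, marker.wt_pair, rules.max_product)
    mt_on_wt = insilico_pcr(wt, marker.mt_pair, rules.max_product)
    mt_on_mt = insilico_pcr(mt, marker.mt_pair, rules.max_product)
    if len(wt_on_wt) != 1 or wt_on_mt or mt_on_wt or len(mt_on_mt) != 1:
        raise DesignError(
            f"marker {marker.name} failed specificity validation: "
            f"WT pair {len(wt_on_wt)}/{len(wt_on_mt)} products on WT/MT, "
            f"MT pair {len(mt_on_wt)}/{len(mt_on_mt)}"
        )


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def _find_all(template: str, query: str) -> list[int]:
    out, i = [], template.find(query)
    while i != -1:
        out.append(i)
        i = template.find(query, i + 1)
    return out


def insilico_pcr(
    template: Genome | tuple[Genome, Genome],
    primer_pair: tuple[Primer, Primer],
    max_product: int = 2000,
) -> list[tuple[str, int, int, int]]:
    """Exact-match PCR products of a convergent primer pair.

    Returns (chromosome, start, end, length) with 1-based inclusive
    coordinates, deduplicated and sorted.  ``template`` may be a single
    (haploid) genome or a diploid pair of genomes; for a pair, chromosome
    names are prefixed with the haplotype index.
    """
    genomes = template if isinstance(template, tuple) else (template,)
    f, r = (p.sequence for p in primer_pair)
    products: set[tuple[str, int, int, int]] = set()
    for gi, genome in enumerate(genomes):
        prefix = f"hap{gi + 1}:" if len(genomes) > 1 else ""
        for chrom, seq in genome.chromosomes.items():
            for fwd, rev in ((f, r), (r, f)):
                starts = _find_all(seq, fwd)
                ends = _find_all(seq, revcomp(rev))
                if not starts or not ends:
                    continue
                for s in starts:
                    for e in ends:
                        end = e + len(rev)  # 0-based exclusive
                        if end - s >= max(len(fwd), len(rev)) and end - s <= max_product:
                            products.add((prefix + chrom, s + 1, end, end - s))
    return sorted(products)


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------


def _truth_presence(genotype: str) -> tuple[bool, bool]:
    if genotype not in ("NN", "NT", "TN", "TT"):
        raise DesignError(f"unknown truth genotype {genotype!r}")
    return "N" in genotype, "T" in genotype


def genotype_individual(
    individual: tuple[Genome, Genome] | dict[str, str],
    marker: MarkerSet,
    max_product: int = 2000,
) -> tuple[bool, bool]:
    """Presence of the WT and MT amplicons for one individual.

    ``individual`` is either a diploid pair of haplotype genomes (scored by
    in-silico PCR) or a truth genotype map event_id -> NN/NT/TT (scored
    directly; an N allele carries the nonrecombinant configuration, a T
    allele the recombinant one).
    """
    if isinstance(individual, dict):
        genotype = individual.get(marker.event_id or "", "NN")
        return _truth_presence(genotype)
    wt_products = insilico_pcr(individual, marker.wt_pair, max_product)
    mt_products = insilico_pcr(individual, marker.mt_pair, max_product)
    return bool(wt_products), bool(mt_products)


GENOTYPE_CLASSES = ["homozygous_WT", "heterozygous_TL", "homozygous_TL"]


def genotype_population(
    individuals: list,
    markers: list[MarkerSet],
    ids: list[str] | None = None,
    max_product: int = 2000,
) -> tuple[list[GenotypeCall], pd.DataFrame]:
    """Score every individual against every marker; tabulate per-marker
    three-class counts.

    Individuals whose markers for one reciprocal event disagree are flagged
    recombinant-discordant, logged, and excluded from that event's counts.
    """
    ids = ids or [f"ind{i + 1}" for i in range(len(individuals))]
    calls: list[GenotypeCall] = []
    for ind_id, ind in zip(ids, individuals):
        for m in markers:
            wt_amp, mt_amp = genotype_individual(ind, m, max_product)
            calls.append(GenotypeCall(ind_id, m.name, wt_amp, mt_amp))

    by_event: dict[str | None, list[MarkerSet]] = {}
    for m in markers:
        by_event.setdefault(m.event_id, []).append(m)
    call_map = {(c.individual, c.marker): c for c in calls}

    discordant: set[tuple[str, str]] = set()
    for event_id, ms in by_event.items():
        if event_id is None or len(ms) < 2:
            continue
        for ind_id in ids:
            got = {call_map[(ind_id, m.name)].call for m in ms}
            if len(got) > 1:
                discordant.update((ind_id, m.name) for m in ms)
                logger.warning(
                    "individual %s recombinant-discordant for event %s (%s); "
                    "excluded from counts", ind_id, event_id, sorted(got))

    rows = []
    for m in markers:
        counted = [
            call_map[(i, m.name)].call
            for i in ids
            if (i, m.name) not in discordant
        ]
        row = {"marker": m.name, "event_id": m.event_id, "n": len(counted)}
        for cls in GENOTYPE_CLASSES:
            row[cls] = counted.count(cls)
        row["no_amplification"] = counted.count("no_amplification")
        row["n_discordant_excluded"] = sum(1 for i in ids if (i, m.name) in discordant)
        rows.append(row)
    return calls, pd.DataFrame(rows)


def markers_to_dataframe(markers: list[MarkerSet]) -> pd.DataFrame:
    rows = []
    for m in markers:
        for role, primer in zip(
            ("WT-F", "WT-R", "MT-F", "MT-R"), (*m.wt_pair, *m.mt_pair)
        ):
            rows.append({
                "marker": m.name,
                "event_id": m.event_id,
                "role": role,
                "name": primer.name,
                "sequence": primer.sequence,
                "chromosome": primer.chromosome,
                "start": primer.start,
                "end": primer.end,
                "strand": primer.strand,
                "tm": primer.tm,
                "gc": round(primer.gc, 3),
                "wt_amplicon": m.wt_amplicon,
                "mt_amplicon": m.mt_amplicon,
            })
    return pd.DataFrame(rows)
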