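"""Synthetic genomes carrying chromosomal translocations with exact truth.

This module generates wild-type multi-chromosome genomes and derives mutant
genomes by reciprocal or complex (chained) inter-chromosomal translocations
with NHEJ-style junction edits: flank deletions, insertions, and
micro-homology motifs shared by both wild-type breakpoint flanks.  Every
derivation is recorded in a :class:`TruthRecord` that maps each mutant
chromosome back to its source segments and gives the exact junction
coordinates, so downstream callers can be validated at base resolution.

Coordinate conventions
----------------------
Breakpoints are 1-based positions of the last base retained on the proximal
segment of a donor chromosome.  Junction coordinates on mutant chromosomes
are reported under the *leftmost placement* convention: when the join is
ambiguous because of micro-homology, the canonical coordinate is the
leftmost equivalent placement (micro-homology bases are attributed to the
right-hand source).  BED output is 0-based half-open.

Micro-homology emulation rewrites the wild-type flanks *before* derivation,
so the returned truth record carries the adjusted wild-type genome
(``TruthRecord.wt_genome``); use it, not the input genome, when comparing
wild type against mutant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class GenomeError(ValueError):
    """Invalid genome or translocation specification."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome container
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """Named chromosome sequences (A/C/G/T upper case).

    ``chromosomes`` preserves insertion order; ``name`` is an optional label
    (e.g. "WT-a") propagated into alignment outputs.
    """

    chromosomes: dict[str, str]
    name: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chromosomes:
            raise GenomeError("genome has no chromosomes")
        for cid, seq in self.chromosomes.items():
            if not seq:
                raise GenomeError(f"chromosome {cid!r} is empty")
            if set(seq) - set(ALPHABET):
                bad = sorted(set(seq) - set(ALPHABET))
                raise GenomeError(f"chromosome {cid!r} contains non-ACGT symbols {bad}")

    @property
    def karyotype(self) -> list[tuple[str, int]]:
        return [(cid, len(seq)) for cid, seq in self.chromosomes.items()]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return list(self.chromosomes.items()) == list(other.chromosomes.items())

    def gc_fraction(self, chromosome: str | None = None) -> float:
        seqs = [self.chromosomes[chromosome]] if chromosome else self.chromosomes.values()
        gc = sum(s.count("G") + s.count("C") for s in seqs)
        return gc / sum(len(s) for s in seqs)


def random_chromosome(length: int, gc_content: float, rng: np.random.Generator) -> str:
    """Draw an i.i.d. nucleotide sequence with expected GC ``gc_content``."""
    if length <= 0:
        raise GenomeError(f"chromosome length must be positive, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise GenomeError(f"gc_content must be in (0, 1), got {gc_content}")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")
    ).decode()


def generate_wt_genome(
    n_chromosomes: int,
    lengths: Sequence[int],
    gc_content: float = 0.35,
    seed: int = 0,
    name: str | None = None,
) -> Genome:
    """Generate a wild-type genome of random sequence.

    Deterministic for a fixed ``seed``.  Chromosomes are named Chr1..ChrN.
    Lengths below 10 kb are rejected: at the scales this generator targets,
    shorter chromosomes leave too few unique anchors for alignment.
    """
    if n_chromosomes < 1:
        raise GenomeError("n_chromosomes must be >= 1")
    if len(lengths) != n_chromosomes:
        raise GenomeError("lengths must have one entry per chromosome")
    for L in lengths:
        if L < 10_000:
            raise GenomeError(f"chromosome length {L} < 10 kb")
    if not 0.0 < gc_content < 1.0:
        raise GenomeError(f"gc_content must be in (0, 1), got {gc_content}")
    rng = np.random.default_rng(seed)
    chroms = {
        f"Chr{i + 1}": random_chromosome(L, gc_content, rng)
        for i, L in enumerate(lengths)
    }
    return Genome(chroms, name=name)


# ---------------------------------------------------------------------------
# Translocation specification and truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionSpec:
    """One recombinant junction: proximal ``donor_a`` joined to the distal
    part of ``donor_b``.

    ``deletion_a`` bases are resected from the a-side (proximal) flank and
    ``deletion_b`` from the b-side (distal) flank before joining; the bases
    nearest the break are lost.  A non-empty ``microhomology_motif`` is
    written into both wild-type flanks adjacent to the (post-resection)
    break, and one copy is retained at the mutant junction.
    """

    donor_a: tuple[str, int]
    donor_b: tuple[str, int]
    deletion_a: int = 0
    deletion_b: int = 0
    insertion: str = ""
    microhomology_motif: str = ""

    def __post_init__(self) -> None:
        if self.deletion_a < 0 or self.deletion_b < 0:
            raise GenomeError("deletions must be >= 0")
        for s in (self.insertion, self.microhomology_motif):
            if set(s) - set(ALPHABET):
                raise GenomeError(f"non-ACGT symbols in junction edit {s!r}")
        if self.insertion and self.microhomology_motif:
            warnings.warn(
                "insertion combined with a micro-homology motif can leave the "
                "junction placement ambiguous; detected micro-homology may "
                "exceed the motif length",
                stacklevel=2,
            )


ExchangePair = tuple[JunctionSpec, JunctionSpec]


def reciprocal_junction_pair(
    donor_a: tuple[str, int],
    donor_b: tuple[str, int],
    deletions: tuple[int, int] = (0, 0),
    insertions: tuple[str, str] = ("", ""),
    motifs: tuple[str, str] = ("", ""),
) -> ExchangePair:
    """Build the mirrored pair of junction specs of one reciprocal exchange.

    The first spec describes the junction on the derived chromosome keeping
    ``donor_a``'s proximal segment; the second the mirror junction.  Each
    junction's deletion is taken from its proximal flank.
    """
    j1 = JunctionSpec(donor_a, donor_b, deletion_a=deletions[0],
                      insertion=insertions[0], microhomology_motif=motifs[0])
    j2 = JunctionSpec(donor_b, donor_a, deletion_a=deletions[1],
                      insertion=insertions[1], microhomology_motif=motifs[1])
    return (j1, j2)


@dataclass
class TranslocationEvent:
    event_id: str
    kind: str  # "reciprocal" | "complex_chain"
    junctions: list[JunctionSpec]

    def __post_init__(self) -> None:
        if self.kind not in ("reciprocal", "complex_chain"):
            raise GenomeError(f"unknown event kind {self.kind!r}")
        donors = {self.junctions[0].donor_a[0]} if self.junctions else set()
        for j in self.junctions:
            donors.add(j.donor_a[0])
            donors.add(j.donor_b[0])
        if self.kind == "reciprocal" and len(donors) != 2:
            raise GenomeError("reciprocal event must involve exactly 2 donors")
        if self.kind == "complex_chain" and len(donors) < 3:
            raise GenomeError("complex_chain event must involve >= 3 donors")


@dataclass(frozen=True)
class Segment:
    """1-based inclusive source interval of a mutant chromosome segment."""

    source: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthJunction:
    """Ground truth for one junction on a mutant chromosome.

    ``position`` is the canonical (leftmost-placement) 1-based coordinate of
    the last left-attributed base; ``boundary`` is the construction boundary
    (end of the left segment, including any retained motif copy).
    ``deletion_left``/``deletion_right`` are the per-donor totals a
    sequence-level characterizer can recover (see junction analysis docs).
    """

    mt_chromosome: str
    position: int
    boundary: int
    left_source: tuple[str, int]      # last retained base of left donor
    right_source: tuple[str, int]     # first right-attributed base (incl. motif)
    deletion_left: int
    deletion_right: int
    spec_deletion_a: int
    spec_deletion_b: int
    insertion: str
    microhomology: str

    def to_dict(self) -> dict:
        return {
            "mt_chromosome": self.mt_chromosome,
            "position": self.position,
            "boundary": self.boundary,
            "left_source": list(self.left_source),
            "right_source": list(self.right_source),
            "deletion_left": self.deletion_left,
            "deletion_right": self.deletion_right,
            "spec_deletion_a": self.spec_deletion_a,
            "spec_deletion_b": self.spec_deletion_b,
            "insertion": self.insertion,
            "microhomology": self.microhomology,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthJunction":
        d = dict(d)
        d["left_source"] = tuple(d["left_source"])
        d["right_source"] = tuple(d["right_source"])
        return cls(**d)


@dataclass
class TruthRecord:
    event: TranslocationEvent
    derived_chromosome_map: dict[str, list[Segment]]
    junctions: list[TruthJunction]
    wt_genome: Genome | None = field(default=None, compare=False, repr=False)

    @property
    def junction_coordinates(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j in self.junctions:
            out.setdefault(j.mt_chromosome, []).append(j.position)
        return {c: sorted(v) for c, v in out.items()}

    def junctions_on(self, chrom: str) -> list[TruthJunction]:
        return [j for j in self.junctions if j.mt_chromosome == chrom]

    def reconstruct(self, wt: Genome | None = None) -> Genome:
        """Rebuild the mutant genome from segments + junction insertions.

        Used as the tiling invariant: the reconstruction must be byte-equal
        to the derived genome.
        """
        wt = wt or self.wt_genome
        if wt is None:
            raise GenomeError("need a wild-type genome to reconstruct from")
        chroms: dict[str, str] = {}
        for cid, segs in self.derived_chromosome_map.items():
            juncs = sorted(self.junctions_on(cid), key=lambda j: j.boundary)
            if len(juncs) != len(segs) - 1:
                raise GenomeError(f"{cid}: junction count does not tile segments")
            parts: list[str] = []
            for i, seg in enumerate(segs):
                parts.append(wt.chromosomes[seg.source][seg.start - 1 : seg.end])
                if i < len(juncs):
                    parts.append(juncs[i].insertion)
            chroms[cid] = "".join(parts)
        return Genome(chroms)

    def to_dict(self) -> dict:
        return {
            "event": {
                "event_id": self.event.event_id,
                "kind": self.event.kind,
                "junctions": [
                    {
                        "donor_a": list(j.donor_a),
                        "donor_b": list(j.donor_b),
                        "deletion_a": j.deletion_a,
                        "deletion_b": j.deletion_b,
                        "insertion": j.insertion,
                        "microhomology_motif": j.microhomology_motif,
                    }
                    for j in self.event.junctions
                ],
            },
            "derived_chromosome_map": {
                cid: [[s.source, s.start, s.end, s.strand] for s in segs]
                for cid, segs in self.derived_chromosome_map.items()
            },
            "junctions": [j.to_dict() for j in self.junctions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        ev = d["event"]
        event = TranslocationEvent(
            event_id=ev["event_id"],
            kind=ev["kind"],
            junctions=[
                JunctionSpec(
                    donor_a=tuple(j["donor_a"]),
                    donor_b=tuple(j["donor_b"]),
                    deletion_a=j["deletion_a"],
                    deletion_b=j["deletion_b"],
                    insertion=j["insertion"],
                    microhomology_motif=j["microhomology_motif"],
                )
                for j in ev["junctions"]
            ],
        )
        segmap = {
            cid: [Segment(s[0], s[1], s[2], s[3]) for s in segs]
            for cid, segs in d["derived_chromosome_map"].items()
        }
        juncs = [TruthJunction.from_dict(j) for j in d["junctions"]]
        return cls(event=event, derived_chromosome_map=segmap, junctions=juncs)


# ---------------------------------------------------------------------------
# Derivation engine
# ---------------------------------------------------------------------------


def _superscript(chrom: str) -> str:
    return chrom.removeprefix("Chr")


@dataclass
class _Junction:
    """Internal junction bookkeeping in original (wild-type) coordinates."""

    left: tuple[str, int]          # (chrom, last retained base)
    right_attrib: tuple[str, int]  # first right-attributed base (motif start if any)
    motif: str
    insertion: str
    spec_deletion_a: int
    spec_deletion_b: int

    @property
    def right_seq_start(self) -> int:
        return self.right_attrib[1] + len(self.motif)


class _Derivation:
    """Applies a sequence of reciprocal exchanges, tracking segments and
    junctions in original coordinates; materializes mutant sequences last."""

    def __init__(self, genome: Genome, enforce_exact_homology: bool = True):
        self.wt = {cid: bytearray(seq, "ascii") for cid, seq in genome.chromosomes.items()}
        self.order = list(genome.chromosomes)
        # each current chromosome: (segments, junctions between them)
        self.chroms: dict[str, tuple[list[Segment], list[_Junction]]] = {
            cid: ([Segment(cid, 1, len(seq))], []) for cid, seq in genome.chromosomes.items()
        }
        self.enforce = enforce_exact_homology
        self._rewrites: list[tuple[str, int, str]] = []  # (chrom, 1-based start, text)

    # -- locating and splitting -------------------------------------------

    def _locate(self, donor: tuple[str, int]) -> tuple[str, int]:
        src, pos = donor
        if src not in self.wt:
            raise GenomeError(f"unknown donor chromosome {src!r}")
        L = len(self.wt[src])
        if not (2 <= pos <= L - 1):
            raise GenomeError(
                f"breakpoint {src}:{pos} not strictly inside the chromosome (length {L})"
            )
        for cid, (segs, _) in self.chroms.items():
            for i, seg in enumerate(segs):
                if seg.source == src and seg.start <= pos <= seg.end:
                    return cid, i
        raise GenomeError(
            f"position {src}:{pos} is not available in any current chromosome "
            "(conflicting or overlapping exchange specifications)"
        )

    def _split(self, cid: str, seg_idx: int, pos: int):
        segs, juncs = self.chroms[cid]
        seg = segs[seg_idx]
        if pos == seg.end:
            raise GenomeError(
                f"breakpoint {seg.source}:{pos} coincides with an existing "
                "segment boundary; nested exchanges must not share junctions"
            )
        head = (segs[:seg_idx] + [Segment(seg.source, seg.start, pos)], juncs[:seg_idx])
        tail = ([Segment(seg.source, pos + 1, seg.end)] + segs[seg_idx + 1 :], juncs[seg_idx:])
        return head, tail

    # -- one exchange -------------------------------------------------------

    def exchange(self, pair: ExchangePair) -> None:
        j1, j2 = pair
        if j1.donor_a != j2.donor_b or j1.donor_b != j2.donor_a:
            raise GenomeError(
                "exchange pair must mirror each other's donors: "
                f"{j1.donor_a}/{j1.donor_b} vs {j2.donor_a}/{j2.donor_b}"
            )
        cid1, i1 = self._locate(j1.donor_a)
        cid2, i2 = self._locate(j1.donor_b)
        if cid1 == cid2:
            raise GenomeError(
                f"both breakpoints of an exchange resolve to {cid1!r}; "
                "inter-chromosomal exchange required"
            )
        head1, tail1 = self._split(cid1, i1, j1.donor_a[1])
        head2, tail2 = self._split(cid2, i2, j1.donor_b[1])

        new1 = self._join(head1, tail2, j1)
        new2 = self._join(head2, tail1, j2)

        # replace in insertion order
        for old, (name, payload) in zip((cid1, cid2), (new1, new2)):
            idx = self.order.index(old)
            del self.chroms[old]
            self.order[idx] = name
            self.chroms[name] = payload
        self.chroms = {cid: self.chroms[cid] for cid in self.order}

    def _join(self, head, tail, spec: JunctionSpec):
        (hsegs, hjuncs), (tsegs, tjuncs) = head, tail
        if not hsegs or not tsegs:
            raise GenomeError("exchange would create an empty chromosome arm")
        last = hsegs[-1]
        if last.end - spec.deletion_a < last.start:
            raise GenomeError(
                f"deletion_a={spec.deletion_a} spans past the proximal segment "
                f"{last.source}:{last.start}-{last.end}"
            )
        first = tsegs[0]
        if first.start + spec.deletion_b > first.end:
            raise GenomeError(
                f"deletion_b={spec.deletion_b} spans past the distal segment "
                f"{first.source}:{first.start}-{first.end}"
            )
        last = replace(last, end=last.end - spec.deletion_a)
        first = replace(first, start=first.start + spec.deletion_b)

        motif = spec.microhomology_motif
        m = len(motif)
        if m:
            if last.length < m or first.length < m:
                raise GenomeError("micro-homology motif longer than flanking segment")
            self._rewrites.append((last.source, last.end - m + 1, motif))
            self._rewrites.append((first.source, first.start, motif))
        junction = _Junction(
            left=(last.source, last.end),
            right_attrib=(first.source, first.start),
            motif=motif,
            insertion=spec.insertion,
            spec_deletion_a=spec.deletion_a,
            spec_deletion_b=spec.deletion_b,
        )
        first = replace(first, start=first.start + m)
        if first.start > first.end:
            raise GenomeError("motif consumed the entire distal segment")

        segs = hsegs[:-1] + [last] + [first] + tsegs[1:]
        juncs = hjuncs + [junction] + tjuncs
        name = f"{hsegs[0].source}^{_superscript(junction.right_attrib[0])}"
        return name, (segs, juncs)

    # -- flank rewriting and homology guards --------------------------------

    def _apply_rewrites(self) -> None:
        written: dict[tuple[str, int], str] = {}
        for chrom, start, text in self._rewrites:
            seq = self.wt[chrom]
            if start < 1 or start + len(text) - 1 > len(seq):
                raise GenomeError(
                    f"motif rewrite at {chrom}:{start} exceeds chromosome bounds"
                )
            for off, base in enumerate(text):
                key = (chrom, start + off)
                prev = written.get(key)
                if prev is not None and prev != base:
                    raise GenomeError(
                        f"conflicting flank rewrites at {chrom}:{start + off}"
                    )
                written[key] = base
                seq[start + off - 1] = ord(base)

    def _guard(self, chrom: str, pos: int, avoid: str) -> bool:
        """Set wt[chrom][pos] to a base != avoid; returns True if mutated."""
        seq = self.wt[chrom]
        if pos < 1 or pos > len(seq):
            return False
        if chr(seq[pos - 1]) != avoid:
            return False
        for b in ALPHABET:
            if b != avoid:
                seq[pos - 1] = ord(b)
                return True
        return True

    def _motif_positions(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for chrom, start, text in self._rewrites:
            out.update((chrom, start + i) for i in range(len(text)))
        return out

    def _apply_guards(self) -> None:
        """Adjust single flank bases so each junction's realized
        micro-homology equals the requested motif exactly.

        Iterated to a fixed point because a guard on one junction can sit in
        another junction's flank.
        """
        protected = self._motif_positions()
        all_juncs = [j for _, (_, js) in self.chroms.items() for j in js]
        for _ in range(10):
            mutated = False
            for j in all_juncs:
                c1, e1 = j.left
                c2, s2 = j.right_attrib
                m = len(j.motif)
                # rightward-matching stop: base preceding the right-attributed run
                if j.insertion:
                    if m == 0:
                        tgt = (c2, s2 - 1)
                        if tgt not in protected and self._chr(c2, s2 - 1) == j.insertion[-1]:
                            mutated |= self._guard(c2, s2 - 1, j.insertion[-1])
                    elif self._chr(c2, s2 + m - 1) == j.insertion[-1]:
                        warnings.warn(
                            "insertion abuts micro-homology motif with matching "
                            "base; junction ambiguity may exceed the motif",
                            stacklevel=2,
                        )
                else:
                    a, b = (c1, e1 - m), (c2, s2 - 1)
                    if (
                        a not in protected
                        and self._chr(*a) is not None
                        and self._chr(*a) == self._chr(*b)
                    ):
                        mutated |= self._guard(a[0], a[1], self._chr(*b))
                # leftward-matching stop: base following the left flank
                nxt = j.insertion[0] if j.insertion else self._chr(c2, j.right_seq_start)
                tgt = (c1, e1 + 1) if j.insertion else (c2, j.right_seq_start)
                if nxt is not None and self._chr(c1, e1 + 1) == nxt:
                    if j.insertion:
                        if tgt not in protected:
                            mutated |= self._guard(c1, e1 + 1, j.insertion[0])
                    else:
                        if tgt not in protected:
                            mutated |= self._guard(c2, j.right_seq_start, self._chr(c1, e1 + 1))
            if not mutated:
                return
        warnings.warn("homology guards did not converge; junctions may carry "
                      "chance micro-homology", stacklevel=2)

    def _chr(self, chrom: str, pos: int) -> str | None:
        seq = self.wt.get(chrom)
        if seq is None or pos < 1 or pos > len(seq):
            return None
        return chr(seq[pos - 1])

    # -- materialization -----------------------------------------------------

    def finish(self, event: TranslocationEvent, wt_name: str | None, mt_name: str | None):
        self._apply_rewrites()
        if self.enforce:
            self._apply_guards()
        wt_genome = Genome(
            {cid: self.wt[cid].decode() for cid in self.wt}, name=wt_name
        )
        chroms: dict[str, str] = {}
        segmap: dict[str, list[Segment]] = {}
        truth_juncs: list[TruthJunction] = []
        for cid, (segs, juncs) in self.chroms.items():
            parts: list[str] = []
            offset = 0
            boundaries: list[int] = []
            for i, seg in enumerate(segs):
                parts.append(wt_genome.chromosomes[seg.source][seg.start - 1 : seg.end])
                offset += seg.length
                if i < len(juncs):
                    boundaries.append(offset)
                    parts.append(juncs[i].insertion)
                    offset += len(juncs[i].insertion)
            chroms[cid] = "".join(parts)
            segmap[cid] = list(segs)
            for boundary, j in zip(boundaries, juncs):
                m = len(j.motif)
                truth_juncs.append(
                    TruthJunction(
                        mt_chromosome=cid,
                        position=boundary - m,
                        boundary=boundary,
                        left_source=j.left,
                        right_source=j.right_attrib,
                        deletion_left=0,
                        deletion_right=0,
                        spec_deletion_a=j.spec_deletion_a,
                        spec_deletion_b=j.spec_deletion_b,
                        insertion=j.insertion,
                        microhomology=j.motif,
                    )
                )
        self._fill_donor_gaps(truth_juncs)
        mutant = Genome(chroms, name=mt_name)
        truth = TruthRecord(
            event=event,
            derived_chromosome_map=segmap,
            junctions=truth_juncs,
            wt_genome=wt_genome,
        )
        # tiling invariant: reconstruction must be byte-exact
        assert truth.reconstruct(wt_genome) == mutant
        return mutant, truth

    def _fill_donor_gaps(self, juncs: list[TruthJunction]) -> None:
        """Per-donor missing-base totals, attributed per the convention
        documented in the junction-analysis module."""
        for j in juncs:
            c1, e1 = j.left_source
            m = len(j.microhomology)
            resumes = [
                o.right_source[1]
                for o in juncs
                if o.right_source[0] == c1 and o.right_source[1] > e1 - m
            ]
            j.deletion_left = (min(resumes) - e1 - 1) if resumes else 0
            c2, s2 = j.right_source
            ends = [
                o.left_source[1]
                for o in juncs
                if o.left_source[0] == c2 and o.left_source[1] < s2
            ]
            j.deletion_right = (s2 - max(ends) - 1) if ends else 0


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def apply_reciprocal_translocation(
    genome: Genome,
    specs: ExchangePair,
    event_id: str,
    enforce_exact_homology: bool = True,
) -> tuple[Genome, TruthRecord]:
    """Replace two donor chromosomes by their reciprocal-exchange products.

    Returns the mutant genome and a truth record whose ``wt_genome`` field
    holds the (possibly flank-rewritten) wild type consistent with the
    mutant.
    """
    if len(specs) != 2:
        raise GenomeError("reciprocal translocation needs exactly 2 junction specs")
    event = TranslocationEvent(event_id, "reciprocal", list(specs))
    d = _Derivation(genome, enforce_exact_homology)
    d.exchange(tuple(specs))
    return d.finish(event, genome.name, f"{genome.name or 'MT'}:{event_id}")


def apply_complex_translocation(
    genome: Genome,
    exchanges: Sequence[ExchangePair],
    event_id: str,
    enforce_exact_homology: bool = True,
) -> tuple[Genome, TruthRecord]:
    """Apply >=2 reciprocal exchanges sequentially (chained or disjoint).

    A chained pair of exchanges sharing a donor chromosome produces the
    composite configuration: three donors replaced by three derived
    chromosomes carrying four junctions in total.  Two disjoint exchanges
    are equivalent to two independent reciprocal applications.
    """
    exchanges = [tuple(e) for e in exchanges]
    if len(exchanges) < 2:
        raise GenomeError(
            "complex translocation needs >= 2 exchanges; use "
            "apply_reciprocal_translocation for a single exchange"
        )
    flat = [s for pair in exchanges for s in pair]
    donors: list[str] = []
    for s in flat:
        donors.extend((s.donor_a[0], s.donor_b[0]))
    if len(set(donors)) < 3:
        raise GenomeError("complex translocation must involve >= 3 donor chromosomes")
    event = TranslocationEvent(event_id, "complex_chain", flat)
    d = _Derivation(genome, enforce_exact_homology)
    for pair in exchanges:
        d.exchange(pair)
    return d.finish(event, genome.name, f"{genome.name or 'MT'}:{event_id}")


def apply_translocations(
    genome: Genome,
    exchanges: Sequence[ExchangePair],
    event_prefix: str = "EV",
    enforce_exact_homology: bool = True,
) -> tuple[Genome, Genome, list[TruthRecord]]:
    """Apply any number of exchanges and split the truth into events.

    Exchanges sharing donor chromosomes are chained into one complex event;
    disjoint exchanges become independent reciprocal events.  Returns
    (adjusted wild type, mutant, truth records, one per event).
    """
    exchanges = [tuple(e) for e in exchanges]
    if not exchanges:
        raise GenomeError("no exchanges supplied")
    d = _Derivation(genome, enforce_exact_homology)
    for pair in exchanges:
        d.exchange(pair)
    flat = [s for pair in exchanges for s in pair]
    donors = sorted({c for s in flat for c in (s.donor_a[0], s.donor_b[0])})
    kind = "reciprocal" if len(donors) == 2 else "complex_chain"
    mutant, combined = d.finish(
        TranslocationEvent(f"{event_prefix}*", kind, flat), genome.name,
        f"{genome.name or 'MT'}:{event_prefix}*",
    )
    wt_adj = combined.wt_genome

    # connected components of donors over exchanges
    parent = {c: c for c in donors}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in exchanges:
        a, b = pair[0].donor_a[0], pair[0].donor_b[0]
        parent[find(a)] = find(b)
    comp_of = {c: find(c) for c in donors}
    roots = sorted({comp_of[c] for c in donors},
                   key=lambda r: min(c for c in donors if comp_of[c] == r))

    truths: list[TruthRecord] = []
    for i, root in enumerate(roots, start=1):
        comp = {c for c in donors if comp_of[c] == root}
        specs = [s for s in flat if s.donor_a[0] in comp]
        juncs = [j for j in combined.junctions if j.left_source[0] in comp]
        segmap = {
            cid: segs
            for cid, segs in combined.derived_chromosome_map.items()
            if {s.source for s in segs} & comp and len(segs) > 1
        }
        kind = "reciprocal" if len(comp) == 2 else "complex_chain"
        truths.append(
            TruthRecord(
                event=TranslocationEvent(f"{event_prefix}{i}", kind, specs),
                derived_chromosome_map=segmap,
                junctions=juncs,
                wt_genome=wt_adj,
            )
        )
    return wt_adj, mutant, truths


def simulate_mutant(
    genome: Genome,
    exchanges: Sequence[ExchangePair],
    event_id: str,
    enforce_exact_homology: bool = True,
) -> tuple[Genome, Genome, TruthRecord]:
    """Convenience wrapper returning (adjusted WT, mutant, truth)."""
    if len(exchanges) == 1:
        mt, truth = apply_reciprocal_translocation(
            genome, exchanges[0], event_id, enforce_exact_homology
        )
    else:
        mt, truth = apply_complex_translocation(
            genome, exchanges, event_id, enforce_exact_homology
        )
    return truth.wt_genome, mt, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    """Write FASTA with 60-column wrapping."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_genome_fasta(path: str | Path, name: str | None = None) -> Genome:
    chroms: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            chroms[rec.id] = str(rec.seq).upper()
    except ValueError as exc:  # malformed input surfaced by the parser
        raise GenomeError(f"malformed FASTA {path}: {exc}") from exc
    if not chroms:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    raise GenomeError(
                        f"malformed FASTA {path}: line {lineno} is not a FASTA header"
                    )
        raise GenomeError(f"malformed FASTA {path}: empty file")
    return Genome(chroms, name=name)


def write_truth(truth: TruthRecord, json_path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write the truth record as JSON, and junctions as BED (0-based half-open)."""
    with open(json_path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if bed_path is not None:
        lines = []
        for i, j in enumerate(truth.junctions):
            name = f"{truth.event.event_id}.J{i + 1}"
            lines.append(f"{j.mt_chromosome}\t{j.position - 1}\t{j.position}\t{name}")
        Path(bed_path).write_text("\n".join(lines) + "\n")


def read_truth(json_path: str | Path) -> TruthRecord:
    with open(json_path) as fh:
        return TruthRecord.from_dict(json.load(fh))
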