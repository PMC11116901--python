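"""Translocation calling and base-resolution breakpoint refinement.

A candidate junction is emitted wherever two adjacent synteny blocks on one
mutant chromosome descend from different wild-type chromosomes.  Candidates
are grouped into events via the graph of wild-type chromosome adjacencies:
a two-chromosome component is a reciprocal translocation, a component over
three or more chromosomes a complex chain.

Refinement extends exact sequence match from the flanking blocks up to and
across the junction.  When the left and right extensions overlap, the
junction placement is ambiguous over the overlap (micro-homology shared by
both wild-type flanks); the canonical coordinate is the **leftmost**
equivalent placement on the mutant chromosome, with the shared bases
attributed to the right-hand source.  When the extensions leave a gap, the
intervening mutant bases are reported as an insertion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .anchors import SyntenyBlock
from .genomes import Genome

logger = logging.getLogger(__name__)


class CallError(ValueError):
    pass


@dataclass
class BreakpointCall:
    """One junction on a mutant chromosome (1-based coordinates).

    ``mt_junction_position`` is the last base attributed to the left source
    under the leftmost-placement convention; ``left_source``/``right_source``
    give the matching wild-type coordinates (last left-attributed base and
    first right-attributed base).  ``ci_width`` is 0 once refined, unless
    unmatched junction bases remain (reported in ``insertion_seq``).
    """

    call_id: str
    mt_chromosome: str
    mt_junction_position: int
    left_source: tuple[str, int, str]
    right_source: tuple[str, int, str]
    ci_width: int
    refined: bool = False
    mh_len: int = 0
    mh_seq: str = ""
    insertion_seq: str = ""
    event_id: str | None = None
    paired_with: "BreakpointCall | None" = field(default=None, repr=False, compare=False)


@dataclass
class EventCall:
    event_id: str
    kind: str  # "reciprocal" | "complex_chain"
    breakpoints: list[BreakpointCall]
    chromosomes: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind == "reciprocal":
            if len(self.breakpoints) != 2 or len(self.chromosomes) != 2:
                raise CallError("reciprocal event must have 2 breakpoints on 2 chromosomes")
            a, b = self.breakpoints
            if not (
                a.left_source[0] == b.right_source[0]
                and a.right_source[0] == b.left_source[0]
            ):
                raise CallError("reciprocal breakpoints must exchange sources symmetrically")
        elif self.kind == "complex_chain":
            if len(self.chromosomes) < 3:
                raise CallError("complex_chain event must involve >= 3 wild-type chromosomes")
        else:
            raise CallError(f"unknown event kind {self.kind!r}")


def call_translocations(
    blocks: list[SyntenyBlock],
    min_block_len: int = 1000,
) -> list[EventCall]:
    """Group adjacent-block junction candidates into translocation events."""
    genomes = {b.mt_genome for b in blocks if b.mt_genome is not None}
    if len(genomes) > 1:
        raise CallError(f"blocks from multiple mutant genomes mixed: {sorted(genomes)}")

    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        if b.mt_span < min_block_len:
            logger.debug("suppressing short block %s:%d-%d (<%d bp)",
                         b.mt_chromosome, b.mt_start, b.mt_end, min_block_len)
            continue
        by_chrom.setdefault(b.mt_chromosome, []).append(b)

    candidates: list[BreakpointCall] = []
    n = itertools.count(1)
    for chrom, bl in by_chrom.items():
        bl.sort(key=lambda b: b.mt_start)
        for lb, rb in zip(bl, bl[1:]):
            if lb.strand == "-" or rb.strand == "-":
                logger.warning(
                    "minus-strand block adjacency on %s ignored (inversions "
                    "are not interpreted)", chrom)
                continue
            if lb.wt_chromosome == rb.wt_chromosome:
                logger.warning(
                    "intra-chromosomal anomaly on %s: %s blocks end %d / start %d "
                    "(not called as translocation)",
                    chrom, lb.wt_chromosome, lb.wt_end, rb.wt_start)
                continue
            candidates.append(
                BreakpointCall(
                    call_id=f"BP{next(n)}",
                    mt_chromosome=chrom,
                    mt_junction_position=lb.mt_end,
                    left_source=(lb.wt_chromosome, lb.wt_end, "+"),
                    right_source=(rb.wt_chromosome, rb.wt_start + 1, "+"),
                    ci_width=rb.mt_start - lb.mt_end,
                )
            )

    # connected components over wild-type chromosome adjacency
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in candidates:
        ra, rb_ = find(c.left_source[0]), find(c.right_source[0])
        if ra != rb_:
            parent[ra] = rb_

    groups: dict[str, list[BreakpointCall]] = {}
    for c in candidates:
        groups.setdefault(find(c.left_source[0]), []).append(c)

    events: list[EventCall] = []
    for i, (_, calls) in enumerate(sorted(groups.items()), start=1):
        chroms = frozenset(
            c.left_source[0] for c in calls) | frozenset(c.right_source[0] for c in calls)
        kind = "reciprocal" if len(chroms) == 2 else "complex_chain"
        event_id = f"EV{i}"
        for c in calls:
            c.event_id = event_id
        if kind == "reciprocal":
            if len(calls) != 2:
                raise CallError(
                    f"{event_id}: {len(calls)} junction candidates between "
                    f"{sorted(chroms)}; expected a reciprocal pair")
            calls[0].paired_with = calls[1]
            calls[1].paired_with = calls[0]
        events.append(EventCall(event_id, kind, calls, chroms))
    return events


def refine_breakpoint(
    call: BreakpointCall,
    wt_genome: Genome,
    mt_genome: Genome,
    window: int = 500,
) -> BreakpointCall:
    """Refine a candidate junction to base resolution by exact extension.

    Extends the left flank match rightward and the right flank match
    leftward; overlap of the extensions is micro-homology, a gap between
    them is an insertion.  The refined coordinate is the leftmost
    equivalent placement.
    """
    S = mt_genome.chromosomes[call.mt_chromosome]
    A = wt_genome.chromosomes[call.left_source[0]]
    B = wt_genome.chromosomes[call.right_source[0]]
    if window < call.ci_width:
        raise CallError(f"window {window} < ci_width {call.ci_width}")

    # 0-based index of last matched base on the left, and its wt mate
    L = call.mt_junction_position - 1
    a = call.left_source[1] - 1
    if S[L] != A[a]:
        raise CallError("left block correspondence is not exact at the block end")
    steps = 0
    while steps < window and L + 1 < len(S) and a + 1 < len(A) and S[L + 1] == A[a + 1]:
        L += 1
        a += 1
        steps += 1

    R = call.mt_junction_position + call.ci_width  # 0-based first right base
    b = call.right_source[1] - 1
    if S[R] != B[b]:
        raise CallError("right block correspondence is not exact at the block start")
    steps = 0
    while steps < window and R > 0 and b > 0 and S[R - 1] == B[b - 1]:
        R -= 1
        b -= 1
        steps += 1

    overlap = L - R + 1
    if overlap >= 0:
        junction = R  # 1-based last left-attributed base = 0-based R-1 + 1
        return replace(
            call,
            mt_junction_position=junction,
            left_source=(call.left_source[0], a + 1 - overlap, "+"),
            right_source=(call.right_source[0], b + 1, "+"),
            ci_width=0,
            refined=True,
            mh_len=overlap,
            mh_seq=S[R : R + overlap],
            insertion_seq="",
        )
    gap = R - L - 1
    return replace(
        call,
        mt_junction_position=L + 1,
        left_source=(call.left_source[0], a + 1, "+"),
        right_source=(call.right_source[0], b + 1, "+"),
        ci_width=gap,
        refined=True,
        mh_len=0,
        mh_seq="",
        insertion_seq=S[L + 1 : R],
    )


def refine_event(
    event: EventCall, wt_genome: Genome, mt_genome: Genome, window: int = 500
) -> EventCall:
    """Refine every breakpoint of an event, preserving reciprocal pairing."""
    refined = [refine_breakpoint(c, wt_genome, mt_genome, window) for c in event.breakpoints]
    if event.kind == "reciprocal":
        refined[0].paired_with = refined[1]
        refined[1].paired_with = refined[0]
    return EventCall(event.event_id, event.kind, refined, event.chromosomes)


def call_and_refine(
    blocks: list[SyntenyBlock],
    wt_genome: Genome,
    mt_genome: Genome,
    min_block_len: int = 1000,
    window: int = 500,
) -> list[EventCall]:
    return [
        refine_event(ev, wt_genome, mt_genome, window)
        for ev in call_translocations(blocks, min_block_len)
    ]
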