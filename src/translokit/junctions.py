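"""Junction sequence characterization: deletions, insertions, micro-homology.

For a refined breakpoint the characterizer measures, per junction:

* ``deletion_left`` — wild-type bases of the left (proximal) donor that are
  present in neither the junction flank nor anywhere else in the mutant
  genome, i.e. the bases resected between where the left flank match ends
  and where that donor's distal sequence resumes on another recombinant
  chromosome.
* ``deletion_right`` — the same quantity for the right donor's proximal
  side.
* ``insertion_seq`` — mutant junction bases matched to neither source.
* micro-homology — the maximal exact run at the join present at the
  breakpoint flank of **both** wild-type sources (capped at 50 bp).

Only per-donor totals are observable from sequence: how missing bases split
between a junction's proximal flank and its partner junction's distal flank
cannot be decided from the genomes alone.  The convention used throughout
is to attribute each donor's missing bases to the junction where that donor
contributes the proximal segment, which matches how per-recombinant
deletion sizes are reported in the literature (e.g. "a 25 nt deletion in
recombinant chromosome Chr1^5").

Deletions are located by a probe search: the smallest offset ``d`` at which
a probe of the donor sequence downstream (resp. upstream) of the refined
junction reoccurs exactly in the mutant genome.  Probes are long enough
(default 40 bp) that chance matches are negligible at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .breakpoints import BreakpointCall, EventCall
from .genomes import Genome

MH_CAP = 50


class JunctionError(ValueError):
    pass


@dataclass
class JunctionReport:
    event_id: str | None
    mt_chromosome: str
    position: int
    deletion_left: int
    deletion_right: int
    insertion_seq: str
    microhomology_len: int
    microhomology_seq: str
    joining_class: str  # "blunt" | "microhomology_mediated"
    left_source: tuple[str, int]
    right_source: tuple[str, int]

    def __post_init__(self) -> None:
        assert self.microhomology_len == len(self.microhomology_seq)


def _probe_in_genome(probe: str, genome: Genome) -> bool:
    return any(probe in seq for seq in genome.chromosomes.values())


def _search_resumption(
    donor_seq: str,
    start0: int,
    mt_genome: Genome,
    probe_len: int,
    max_deletion: int,
    direction: int,
) -> int:
    """Smallest d >= 0 such that the probe shifted by d reoccurs in the
    mutant.  direction=+1 probes rightward windows starting at start0+d;
    direction=-1 probes leftward windows ending at start0-d (0-based,
    exclusive end)."""
    for d in range(max_deletion + 1):
        if direction > 0:
            lo = start0 + d
            hi = min(lo + probe_len, len(donor_seq))
        else:
            hi = start0 - d
            lo = max(hi - probe_len, 0)
        if hi - lo < min(probe_len, 20):
            break
        if _probe_in_genome(donor_seq[lo:hi], mt_genome):
            return d
    raise JunctionError(
        "no donor-sequence resumption found within "
        f"{max_deletion} bp of the refined junction"
    )


def characterize_junction(
    refined: BreakpointCall,
    wt_genome: Genome,
    mt_genome: Genome,
    flank: int = 200,
    mh_threshold: int = 2,
    probe_len: int = 40,
    max_deletion: int = 200,
) -> JunctionReport:
    """Measure junction edits for one refined breakpoint call.

    Requires a refined call whose residual uncertainty, if any, is explained
    by an insertion; ``flank`` bounds the sequence context consulted and
    must be >= 50.
    """
    if flank < 50:
        raise JunctionError("flank must be >= 50 bp")
    if not refined.refined:
        raise JunctionError(f"{refined.call_id}: breakpoint has not been refined")
    if refined.ci_width > 0 and not refined.insertion_seq:
        raise JunctionError(
            f"{refined.call_id}: ci_width={refined.ci_width} with no insertion; "
            "refine the call before characterization"
        )
    mh_len = min(refined.mh_len, MH_CAP)
    mh_seq = refined.mh_seq[:mh_len]

    a_chrom, a_pos = refined.left_source[0], refined.left_source[1]
    b_chrom, b_pos = refined.right_source[0], refined.right_source[1]
    A = wt_genome.chromosomes[a_chrom]
    B = wt_genome.chromosomes[b_chrom]

    # left donor: first reoccurring window at/after the canonical flank end.
    # The measured offset includes the micro-homology bases (attributed to
    # the right source under the leftmost convention), so subtract them.
    d_left = _search_resumption(A, a_pos, mt_genome, probe_len, max_deletion + mh_len, +1)
    deletion_left = d_left - mh_len
    # right donor: first reoccurring window ending at/before the attributed start
    deletion_right = _search_resumption(B, b_pos - 1, mt_genome, probe_len, max_deletion, -1)
    if deletion_left < 0:
        raise JunctionError("inconsistent micro-homology vs donor resumption")

    joining_class = "microhomology_mediated" if mh_len >= mh_threshold else "blunt"
    return JunctionReport(
        event_id=refined.event_id,
        mt_chromosome=refined.mt_chromosome,
        position=refined.mt_junction_position,
        deletion_left=deletion_left,
        deletion_right=deletion_right,
        insertion_seq=refined.insertion_seq,
        microhomology_len=mh_len,
        microhomology_seq=mh_seq,
        joining_class=joining_class,
        left_source=(a_chrom, a_pos),
        right_source=(b_chrom, b_pos),
    )


def characterize_event(
    event: EventCall,
    wt_genome: Genome,
    mt_genome: Genome,
    **kwargs,
) -> list[JunctionReport]:
    return [characterize_junction(bp, wt_genome, mt_genome, **kwargs)
            for bp in event.breakpoints]


def reports_to_dataframe(reports: list[JunctionReport]) -> pd.DataFrame:
    cols = [
        "event_id", "mt_chromosome", "position", "deletion_left",
        "deletion_right", "insertion_seq", "microhomology_len",
        "microhomology_seq", "joining_class",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in reports], columns=cols)


def summarize_junctions(reports: list[JunctionReport]) -> pd.DataFrame:
    """Per-event deletion range and joining-class counts."""
    if not reports:
        raise JunctionError("no junction reports to summarize")
    df = reports_to_dataframe(reports)
    grouped = df.groupby("event_id", dropna=False)
    out = grouped.agg(
        n_junctions=("mt_chromosome", "size"),
        deletion_min=("deletion_left", "min"),
        deletion_max=("deletion_left", "max"),
        n_blunt=("joining_class", lambda s: int((s == "blunt").sum())),
        n_microhomology=("joining_class",
                         lambda s: int((s == "microhomology_mediated").sum())),
    ).reset_index()
    return out
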