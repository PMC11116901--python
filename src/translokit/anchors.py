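"""Colinear synteny blocks from unique k-mer anchors.

The aligner indexes every k-mer whose canonical form occurs exactly once in
the wild-type genome, finds the positions of those k-mers in a mutant
genome, and chains co-oriented anchors into maximal colinear blocks with a
bounded gap on both genomes and a consistent diagonal.  On genomes related
only by balanced rearrangement this localizes every junction to within a
few times k without base-level alignment.

Blocks are reported 0-based half-open, sorted and non-overlapping on the
mutant genome.  Minus-strand blocks (mutant k-mers matching the reverse
complement of an indexed wild-type k-mer) are reported and flagged but
never interpreted downstream; inversion calling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import Genome
from .kmers import canonical_codes


class AlignError(ValueError):
    pass


@dataclass
class AnchorIndex:
    """Sorted lookup of single-copy canonical k-mers of one genome."""

    k: int
    genome_name: str | None
    chrom_names: list[str]
    codes: np.ndarray        # sorted canonical codes, unique in the genome
    chrom_idx: np.ndarray    # per code: chromosome index
    pos: np.ndarray          # per code: 0-based offset
    fwd: np.ndarray          # per code: True if forward strand is canonical

    def __len__(self) -> int:
        return int(self.codes.size)

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices into the index for each query code; hit mask."""
        ix = np.searchsorted(self.codes, codes)
        ix_clipped = np.minimum(ix, len(self.codes) - 1)
        hit = (self.codes.size > 0) & (self.codes[ix_clipped] == codes)
        return ix_clipped, hit


def build_anchor_index(genome: Genome, k: int = 21) -> AnchorIndex:
    """Index all k-mers occurring exactly once (canonically) in the genome."""
    if k < 15:
        raise AlignError(f"k must be >= 15, got {k}")
    if k % 2 == 0:
        raise AlignError(f"k must be odd to avoid palindromic k-mers, got {k}")
    shortest = min(len(s) for s in genome.chromosomes.values())
    if k > shortest:
        raise AlignError(f"k={k} exceeds the shortest chromosome ({shortest} bp)")

    chrom_names = list(genome.chromosomes)
    all_codes, all_chrom, all_pos, all_fwd = [], [], [], []
    for ci, cname in enumerate(chrom_names):
        codes, fwd = canonical_codes(genome.chromosomes[cname], k)
        all_codes.append(codes)
        all_chrom.append(np.full(codes.size, ci, dtype=np.int32))
        all_pos.append(np.arange(codes.size, dtype=np.int64))
        all_fwd.append(fwd)
    codes = np.concatenate(all_codes)
    chrom = np.concatenate(all_chrom)
    pos = np.concatenate(all_pos)
    fwd = np.concatenate(all_fwd)

    order = np.argsort(codes, kind="stable")
    codes, chrom, pos, fwd = codes[order], chrom[order], pos[order], fwd[order]
    # keep codes whose run length is exactly 1
    is_new = np.empty(codes.size, dtype=bool)
    if codes.size:
        is_new[0] = True
        is_new[1:] = codes[1:] != codes[:-1]
        run_id = np.cumsum(is_new) - 1
        counts = np.bincount(run_id)
        keep = counts[run_id] == 1
    else:
        keep = is_new
    return AnchorIndex(
        k=k,
        genome_name=genome.name,
        chrom_names=chrom_names,
        codes=codes[keep],
        chrom_idx=chrom[keep],
        pos=pos[keep],
        fwd=fwd[keep],
    )


@dataclass
class SyntenyBlock:
    """A maximal colinear run of unique anchors (0-based half-open)."""

    mt_chromosome: str
    mt_start: int
    mt_end: int
    strand: str
    wt_chromosome: str
    wt_start: int
    wt_end: int
    anchor_count: int
    mt_genome: str | None = None

    @property
    def mt_span(self) -> int:
        return self.mt_end - self.mt_start

    @property
    def wt_span(self) -> int:
        return self.wt_end - self.wt_start


def chain_anchors(
    wt_index: AnchorIndex,
    mt_genome: Genome,
    max_gap: int = 2000,
    min_anchors: int = 10,
    indel_slack: int = 50,
) -> list[SyntenyBlock]:
    """Chain shared unique k-mers into colinear synteny blocks.

    Anchors are chained greedily along the mutant genome: a run breaks at a
    change of wild-type chromosome or relative strand, a gap > ``max_gap``
    on either genome, or a diagonal shift beyond ``indel_slack``.  Because
    anchors are genome-unique, each mutant position has at most one
    candidate chain, so the nearest-previous-anchor tie-break of ambiguous
    chaining never triggers in practice.
    """
    if max_gap <= wt_index.k:
        raise AlignError("max_gap must exceed k")
    k = wt_index.k
    blocks: list[SyntenyBlock] = []
    for mt_name, seq in mt_genome.chromosomes.items():
        if len(seq) < k:
            continue
        codes, mt_fwd = canonical_codes(seq, k)
        ix, hit = wt_index.lookup(codes)
        if not hit.any():
            continue
        mt_pos = np.flatnonzero(hit).astype(np.int64)
        ix = ix[hit]
        wt_chrom = wt_index.chrom_idx[ix]
        wt_pos = wt_index.pos[ix]
        same_strand = wt_index.fwd[ix] == mt_fwd[hit]

        if mt_pos.size == 1:
            breaks = np.empty(0, dtype=np.int64)
        else:
            d_mt = np.diff(mt_pos)
            d_wt = np.diff(wt_pos)
            chrom_change = np.diff(wt_chrom) != 0
            strand_change = same_strand[1:] != same_strand[:-1]
            plus = same_strand[:-1]
            ok_plus = (d_wt > 0) & (d_wt <= max_gap) & (np.abs(d_wt - d_mt) <= indel_slack)
            ok_minus = (d_wt < 0) & (-d_wt <= max_gap) & (np.abs(-d_wt - d_mt) <= indel_slack)
            ok = np.where(plus, ok_plus, ok_minus) & (d_mt <= max_gap)
            breaks = np.flatnonzero(chrom_change | strand_change | ~ok) + 1

        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [mt_pos.size]))
        for s, e in zip(starts, ends):
            n = int(e - s)
            if n < min_anchors:
                continue
            run_wt = wt_pos[s:e]
            strand = "+" if same_strand[s] else "-"
            blocks.append(
                SyntenyBlock(
                    mt_chromosome=mt_name,
                    mt_start=int(mt_pos[s]),
                    mt_end=int(mt_pos[e - 1]) + k,
                    strand=strand,
                    wt_chromosome=wt_index.chrom_names[int(wt_chrom[s])],
                    wt_start=int(run_wt.min()),
                    wt_end=int(run_wt.max()) + k,
                    anchor_count=n,
                    mt_genome=mt_genome.name,
                )
            )
    blocks.sort(key=lambda b: (b.mt_chromosome, b.mt_start))
    return _trim_overlaps(blocks)


def _trim_overlaps(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Enforce non-overlap on the mutant genome (overlaps are < k at block
    boundaries); the later block is trimmed on both genomes."""
    out: list[SyntenyBlock] = []
    for b in blocks:
        if out and b.mt_chromosome == out[-1].mt_chromosome and b.mt_start < out[-1].mt_end:
            delta = out[-1].mt_end - b.mt_start
            if b.mt_span <= delta:
                continue
            if b.strand == "+":
                b = replace(b, mt_start=b.mt_start + delta, wt_start=b.wt_start + delta)
            else:
                b = replace(b, mt_start=b.mt_start + delta, wt_end=b.wt_end - delta)
        out.append(b)
    return out


def coverage_fraction(blocks: list[SyntenyBlock], genome: Genome) -> float:
    """Fraction of mutant bases covered by at least one block."""
    covered = sum(b.mt_span for b in blocks)
    return covered / genome.total_length


def blocks_to_dataframe(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    cols = [
        "mt_chromosome", "mt_start", "mt_end", "strand",
        "wt_chromosome", "wt_start", "wt_end", "anchor_count",
    ]
    return pd.DataFrame([{c: getattr(b, c) for c in cols} for b in blocks], columns=cols)


def write_blocks_tsv(blocks: list[SyntenyBlock], path: str | Path) -> None:
    blocks_to_dataframe(blocks).to_csv(path, sep="\t", index=False)
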