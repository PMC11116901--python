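"""End-to-end orchestration: simulate -> align -> call -> junctions ->
markers -> cross simulation -> genotyping -> segregation statistics.

A run is driven by a single plain-text (YAML) config with explicit seeds
and writes every artifact plus a manifest recording, per stage, the checks
a reviewer would ask for: called-vs-truth breakpoint agreement, junction
edit recovery, marker specificity, and the chi-square segregation table of
the simulated F2.  Re-running with the same config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anchors import build_anchor_index, chain_anchors, write_blocks_tsv
from .breakpoints import BreakpointCall, EventCall, call_and_refine
from .genomes import (
    Genome,
    JunctionSpec,
    apply_translocations,
    generate_wt_genome,
    reciprocal_junction_pair,
    write_genome_fasta,
    write_truth,
)
from .junctions import characterize_event, reports_to_dataframe, summarize_junctions
from .markers import (
    PrimerRules,
    design_breakpoint_markers,
    genotype_population,
    markers_to_dataframe,
)
from .meiosis import (
    EventCarrier,
    KaryotypeConfig,
    SegregationParams,
    expected_f2_segregation,
    predict_diakinesis_configuration,
    predict_sterility_and_seed_reduction,
    simulate_cross,
    uniform_chain_table,
)
from .segstats import chisq_gof, classify_segregation, segregation_report, Contrast

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# Exchange presets mirroring the three study translocation lines, with
# breakpoints placed at fixed fractions of the chromosome length so the
# same configuration scales with the karyotype.  Junction edits carry the
# published per-recombinant deletion sizes and the MT-a micro-homology.
PRESETS: dict[str, list[dict]] = {
    "MT-a": [
        {"a": ("Chr6", 0.55), "b": ("Chr10", 0.45),
         "deletions": (3, 3), "motifs": ("TTTAT", "")},
    ],
    "MT-b": [
        {"a": ("Chr1", 0.65), "b": ("Chr5", 0.35), "deletions": (25, 24)},
        {"a": ("Chr4", 0.475), "b": ("Chr8", 0.575), "deletions": (4, 4)},
    ],
    "MT-c": [
        {"a": ("Chr1", 0.65), "b": ("Chr5", 0.55), "deletions": (25, 24)},
        {"a": ("Chr5", 0.30), "b": ("Chr11", 0.40), "deletions": (1, 4)},
    ],
}


@dataclass
class RunConfig:
    preset: str = "MT-a"
    events: list | None = None           # custom exchange dicts (override preset)
    n_chromosomes: int = 11
    chromosome_length: int = 200_000
    gc_content: float = 0.35
    k: int = 21
    max_gap: int = 2000
    min_anchors: int = 10
    min_block_len: int = 1000
    primer_rules: dict = field(default_factory=dict)
    alternate_freq: float = 0.5
    n_f2: int = 237
    seeds: dict = field(default_factory=dict)  # required: genome, cross
    outdir: str = "translokit_run"

    def __post_init__(self) -> None:
        for key in ("genome", "cross"):
            if key not in self.seeds:
                raise ConfigError(f"seeds.{key} must be set explicitly")
            if not isinstance(self.seeds[key], int):
                raise ConfigError(f"seeds.{key} must be an integer")
        if self.events is None and self.preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def exchange_pairs(self, lengths: dict[str, int]) -> list:
        raw = self.events if self.events is not None else PRESETS[self.preset]
        pairs = []
        for e in raw:
            (ca, fa), (cb, fb) = tuple(e["a"]), tuple(e["b"])
            pa = e.get("pos_a") or int(lengths[ca] * fa)
            pb = e.get("pos_b") or int(lengths[cb] * fb)
            pairs.append(
                reciprocal_junction_pair(
                    (ca, pa), (cb, pb),
                    deletions=tuple(e.get("deletions", (0, 0))),
                    insertions=tuple(e.get("insertions", ("", ""))),
                    motifs=tuple(e.get("motifs", ("", ""))),
                )
            )
        return pairs


def _calls_dataframe(events: list[EventCall]) -> pd.DataFrame:
    rows = []
    for ev in events:
        for c in ev.breakpoints:
            rows.append({
                "call_id": c.call_id,
                "event_id": ev.event_id,
                "kind": ev.kind,
                "mt_chromosome": c.mt_chromosome,
                "position": c.mt_junction_position,
                "left_chrom": c.left_source[0],
                "left_pos": c.left_source[1],
                "right_chrom": c.right_source[0],
                "right_pos": c.right_source[1],
                "ci_width": c.ci_width,
                "mh_len": c.mh_len,
                "mh_seq": c.mh_seq,
                "insertion_seq": c.insertion_seq,
                "paired_with": c.paired_with.call_id if c.paired_with else "",
            })
    return pd.DataFrame(rows)


def calls_to_json(events: list[EventCall], path: str | Path) -> None:
    payload = []
    for ev in events:
        payload.append({
            "event_id": ev.event_id,
            "kind": ev.kind,
            "chromosomes": sorted(ev.chromosomes),
            "breakpoints": _calls_dataframe([ev]).to_dict(orient="records"),
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def calls_from_json(path: str | Path) -> list[EventCall]:
    with open(path) as fh:
        payload = json.load(fh)
    events = []
    for ev in payload:
        calls = {}
        for b in ev["breakpoints"]:
            calls[b["call_id"]] = BreakpointCall(
                call_id=b["call_id"],
                mt_chromosome=b["mt_chromosome"],
                mt_junction_position=b["position"],
                left_source=(b["left_chrom"], b["left_pos"], "+"),
                right_source=(b["right_chrom"], b["right_pos"], "+"),
                ci_width=b["ci_width"],
                refined=True,
                mh_len=b["mh_len"],
                mh_seq=b["mh_seq"] or "",
                insertion_seq=b["insertion_seq"] or "",
                event_id=ev["event_id"],
            )
        for b in ev["breakpoints"]:
            if b["paired_with"]:
                calls[b["call_id"]].paired_with = calls.get(b["paired_with"])
        events.append(EventCall(ev["event_id"], ev["kind"], list(calls.values()),
                                frozenset(ev["chromosomes"])))
    return events


def _write_breakpoint_beds(events: list[EventCall], mt_bed: Path, wt_bed: Path) -> None:
    mt_lines, wt_lines = [], []
    for ev in events:
        for c in ev.breakpoints:
            name = f"{ev.event_id}.{c.call_id}"
            mt_lines.append(
                f"{c.mt_chromosome}\t{c.mt_junction_position - 1}"
                f"\t{c.mt_junction_position}\t{name}")
            for side, (chrom, pos, _) in (("L", c.left_source), ("R", c.right_source)):
                wt_lines.append(f"{chrom}\t{pos - 1}\t{pos}\t{name}.{side}")
    mt_bed.write_text("\n".join(mt_lines) + "\n")
    wt_bed.write_text("\n".join(wt_lines) + "\n")


def _truth_check(events: list[EventCall], truths) -> dict:
    called = {
        (c.mt_chromosome, c.mt_junction_position)
        for ev in events for c in ev.breakpoints
    }
    expected = {
        (j.mt_chromosome, j.position)
        for t in truths for j in t.junctions
    }
    return {
        "n_called": len(called),
        "n_truth": len(expected),
        "exact_match": sorted(called) == sorted(expected),
        "missed": sorted(map(list, expected - called)),
        "spurious": sorted(map(list, called - expected)),
    }


def _junction_check(reports, truths) -> dict:
    truth_by_pos = {
        (j.mt_chromosome, j.position): j for t in truths for j in t.junctions
    }
    rows, ok = [], True
    for r in reports:
        t = truth_by_pos.get((r.mt_chromosome, r.position))
        match = (
            t is not None
            and r.deletion_left == t.deletion_left
            and r.deletion_right == t.deletion_right
            and r.insertion_seq == t.insertion
            and r.microhomology_seq == t.microhomology
        )
        ok &= match
        rows.append({
            "mt_chromosome": r.mt_chromosome,
            "position": r.position,
            "deletion_left": r.deletion_left,
            "deletion_right": r.deletion_right,
            "microhomology": r.microhomology_seq,
            "matches_truth": match,
        })
    return {"all_recovered": ok, "junctions": rows}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the manifest (also written
    to ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": [],
        "checks": {},
        "artifacts": {},
    }

    def artifact(key: str, path: Path) -> Path:
        manifest["artifacts"][key] = str(path)
        return path

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    try:
        stage("simulate_genomes")
        lengths = [config.chromosome_length] * config.n_chromosomes
        wt0 = generate_wt_genome(
            config.n_chromosomes, lengths, config.gc_content,
            seed=config.seeds["genome"], name="WT")
        length_map = dict(wt0.karyotype)
        wt, mt, truths = apply_translocations(
            wt0, config.exchange_pairs(length_map), event_prefix="EV")
        mt.name = "MT"
        write_genome_fasta(wt, artifact("wt_fasta", out / "wt.fasta"))
        write_genome_fasta(mt, artifact("mt_fasta", out / "mt.fasta"))
        for t in truths:
            eid = t.event.event_id
            write_truth(t, artifact(f"truth_{eid}_json", out / f"truth_{eid}.json"),
                        artifact(f"truth_{eid}_bed", out / f"truth_{eid}.bed"))
    except Exception as exc:
        raise PipelineError("simulate_genomes", exc) from exc

    try:
        stage("align")
        index = build_anchor_index(wt, config.k)
        blocks = chain_anchors(index, mt, config.max_gap, config.min_anchors)
        write_blocks_tsv(blocks, artifact("blocks_tsv", out / "blocks.tsv"))
    except Exception as exc:
        raise PipelineError("align", exc) from exc

    try:
        stage("call_breakpoints")
        events = call_and_refine(blocks, wt, mt, config.min_block_len)
        _calls_dataframe(events).to_csv(
            artifact("calls_tsv", out / "calls.tsv"), sep="\t", index=False)
        calls_to_json(events, artifact("calls_json", out / "calls.json"))
        _write_breakpoint_beds(
            events,
            artifact("breakpoints_mt_bed", out / "breakpoints_mt.bed"),
            artifact("breakpoints_wt_bed", out / "breakpoints_wt.bed"))
        manifest["checks"]["breakpoints_vs_truth"] = _truth_check(events, truths)
    except Exception as exc:
        raise PipelineError("call_breakpoints", exc) from exc

    try:
        stage("characterize_junctions")
        reports = [r for ev in events for r in characterize_event(ev, wt, mt)]
        reports_to_dataframe(reports).to_csv(
            artifact("junctions_tsv", out / "junctions.tsv"), sep="\t", index=False)
        summarize_junctions(reports).to_csv(
            artifact("junction_summary_tsv", out / "junction_summary.tsv"),
            sep="\t", index=False)
        manifest["checks"]["junction_recovery"] = _junction_check(reports, truths)
    except Exception as exc:
        raise PipelineError("characterize_junctions", exc) from exc

    try:
        stage("design_markers")
        rules = PrimerRules(**config.primer_rules)
        markers = [
            design_breakpoint_markers(wt, mt, bp, rules)
            for ev in events for bp in ev.breakpoints
        ]
        markers_to_dataframe(markers).to_csv(
            artifact("markers_tsv", out / "markers.tsv"), sep="\t", index=False)
        manifest["checks"]["marker_specificity"] = {
            "n_markers": len(markers),
            "all_specific": True,  # design_breakpoint_markers validates or raises
        }
    except Exception as exc:
        raise PipelineError("design_markers", exc) from exc

    try:
        stage("meiosis_model")
        carriers = [
            EventCarrier(ev.event_id, ev.kind,
                         n_donors=len(ev.chromosomes), zygosity="heterozygous")
            for ev in events
        ]
        f1 = KaryotypeConfig(config.n_chromosomes, carriers)
        params = SegregationParams(alternate_freq=config.alternate_freq)
        if any(c.kind == "complex_chain" for c in carriers):
            params.complex_table = uniform_chain_table(
                max(c.n_donors for c in carriers))
        expected = expected_f2_segregation(f1, params)
        sterility, seed_red = predict_sterility_and_seed_reduction(f1, params)
        manifest["checks"]["meiosis"] = {
            "diakinesis": predict_diakinesis_configuration(f1),
            "normal_to_semisterile": list(expected["normal_to_semisterile"]),
            "fully_homozygous_fraction": expected["fully_homozygous_fraction"],
            "predicted_pollen_sterility": sterility,
            "predicted_seed_reduction": seed_red,
            "model_dependent": expected["model_dependent"],
        }
    except Exception as exc:
        raise PipelineError("meiosis_model", exc) from exc

    try:
        stage("simulate_f2")
        f2 = simulate_cross(f1, f1, params, config.n_f2, seed=config.seeds["cross"])
        f2.to_csv(artifact("f2_tsv", out / "f2_population.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("simulate_f2", exc) from exc

    try:
        stage("genotype_f2")
        event_ids = [c.event_id for c in carriers]
        individuals = [
            {ev: row[ev] for ev in event_ids} for _, row in f2.iterrows()
        ]
        _, counts = genotype_population(
            individuals, markers, ids=list(f2["individual"]))
        counts.to_csv(
            artifact("genotype_counts_tsv", out / "genotype_counts.tsv"),
            sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("genotype_f2", exc) from exc

    try:
        stage("segregation_stats")
        k = len(carriers)
        contrasts = [Contrast(
            "pollen_phenotype", "phenotype", ("normal", "semi_sterile"),
            (1.0, float(2 ** k - 1)))]
        contrasts += [
            Contrast(f"genotype_{ev}", ev, ("NN", "NT", "TT"), (1.0, 2.0, 1.0))
            for ev in event_ids
        ]
        seg = segregation_report(f2, contrasts)
        seg.to_csv(artifact("segregation_tsv", out / "segregation.tsv"),
                   sep="\t", index=False)
        manifest["checks"]["segregation"] = seg.to_dict(orient="records")
    except Exception as exc:
        raise PipelineError("segregation_stats", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
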