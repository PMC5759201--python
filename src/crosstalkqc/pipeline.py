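"""End-to-end orchestration: simulate -> demux -> cross-talk -> consensus -> call -> evaluate.

Each stage consumes only the previous stage's declared outputs; simulation
truth is read exclusively by the evaluation/auditing steps, never by
demultiplexing, consensus calling or variant calling.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import yaml

from . import consensus as cons
from . import demux as dx
from . import simulate as sim
from . import stats, variants
from .plates import (
    AdapterPlate,
    SampleSheet,
    UNIQUE_DUAL,
    default_combinatorial_plate,
    default_unique_dual_plate,
    read_plate_csv,
    read_sample_sheet,
    sheet_for_samples,
    write_plate_csv,
    write_sample_sheet,
)
from .simulate import ConfigError, SimConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    plate: AdapterPlate
    sheet: SampleSheet
    sim: SimConfig
    max_mismatches: int = 0
    filter_params: cons.ConsensusFilterParams = field(default_factory=cons.ConsensusFilterParams)
    threshold: float = 0.002
    oxoG_threshold: float = 0.003
    min_depth: int = 100
    seed: int | None = None  # overrides sim.seed when given
    write_fastq: bool = True

    def resolved_sim(self) -> SimConfig:
        if self.seed is None:
            return self.sim
        from dataclasses import replace

        return replace(self.sim, seed=self.seed)


def _parse_sim(d: dict) -> SimConfig:
    d = dict(d)
    if "duplicate_family_size" in d:
        fs = d["duplicate_family_size"]
        d["duplicate_family_size"] = sim.FamilySizeSpec(fs["name"], float(fs["param"]))
    if "variants" in d:
        d["variants"] = tuple(
            sim.Variant(int(v["position"]), v["ref"], v["alt"], float(v["allele_fraction"]))
            for v in d["variants"]
        )
    if "contamination" in d:
        from .plates import Well

        d["contamination"] = tuple(
            sim.ContaminationEvent(
                Well.from_label(c["target"]), Well.from_label(c["source"]),
                float(c["rate"]), c.get("arm")
            )
            for c in d["contamination"]
        )
    try:
        return SimConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_run_config(path, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file (see README for the schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    pspec = doc.get("plate", {})
    if "file" in pspec:
        plate = read_plate_csv(pspec["file"])
    elif pspec.get("scheme") == UNIQUE_DUAL:
        plate = default_unique_dual_plate(
            n=int(pspec.get("n_indices", 35)),
            seed=int(pspec.get("seed", 0)),
            umi_length=int(pspec.get("umi_length", 6)),
        )
    else:
        plate = default_combinatorial_plate(seed=int(pspec.get("seed", 0)))
    if "sheet_file" in doc:
        sheet = read_sample_sheet(doc["sheet_file"], plate)
    else:
        samples = doc.get("samples") or ["S1"]
        sheet = sheet_for_samples(plate, list(samples))
    sim_cfg = _parse_sim(doc.get("sim", {}))
    sim_cfg.validate(plate)
    fp = doc.get("filter", {})
    params = cons.ConsensusFilterParams(**fp) if fp else cons.ConsensusFilterParams()
    calling = doc.get("calling", {})
    return RunConfig(
        plate=plate,
        sheet=sheet,
        sim=sim_cfg,
        max_mismatches=int(doc.get("max_mismatches", 0)),
        filter_params=params,
        threshold=float(calling.get("threshold", 0.002)),
        oxoG_threshold=float(calling.get("oxoG_threshold", 0.003)),
        min_depth=int(calling.get("min_depth", 100)),
        seed=seed,
        write_fastq=bool(doc.get("write_fastq", True)),
    )


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """Run every stage, writing all artifacts under ``out_dir``.

    Returns a manifest dict mapping artifact names to paths.  Deterministic
    given the seed: identical seeds produce byte-identical outputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    p = lambda name: os.path.join(out_dir, name)  # noqa: E731
    manifest: dict[str, str] = {}
    sim_cfg = config.resolved_sim()

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return deco

    @stage("simulate")
    def _sim():
        reads, truth = sim.simulate_experiment(config.plate, config.sheet, sim_cfg)
        write_plate_csv(config.plate, p("plate.csv"))
        write_sample_sheet(config.sheet, p("sample_sheet.csv"))
        if config.write_fastq:
            for path in sim.write_fastq(reads, p("reads")):
                manifest[os.path.basename(path)] = path
        sim.write_truth_tsv(truth, p("truth.tsv"))
        sim.write_reads_tsv(reads, p("reads.tsv"))
        with open(p("reference.fasta"), "w") as fh:
            fh.write(">ref\n")
            fh.write(reads.reference + "\n")
        return reads, truth

    reads, truth = _sim
    manifest.update(plate=p("plate.csv"), sample_sheet=p("sample_sheet.csv"),
                    truth=p("truth.tsv"), reads=p("reads.tsv"), reference=p("reference.fasta"))

    @stage("demux")
    def _demux():
        policy = dx.DemuxPolicy.for_plate(config.plate, config.max_mismatches)
        matrix = dx.build_crosstalk_matrix(reads, policy, used_wells=config.sheet.wells)
        matrix.write_tsv(p("crosstalk_matrix.tsv"))
        dx.assignments_dataframe(reads, policy, config.plate).to_csv(
            p("assignments.tsv"), sep="\t", index=False
        )
        return matrix

    matrix = _demux
    manifest.update(crosstalk_matrix=p("crosstalk_matrix.tsv"), assignments=p("assignments.tsv"))

    @stage("crosstalk")
    def _crosstalk():
        report = stats.misassignment_report(matrix, config.sheet.wells, config.plate)
        extra = {"seed": sim_cfg.seed}
        if config.plate.scheme == UNIQUE_DUAL:
            extra["mismatched_pair_rate"] = stats.mismatched_pair_rate(matrix)
            diag = stats.symmetry_diagnostic(matrix)
            extra["symmetry"] = {"score": diag.asymmetry_score, "verdict": diag.verdict}
        stats.write_report_json(report, p("crosstalk_report.json"), extra=extra)
        stats.plate_grid(matrix, config.plate).to_csv(p("plate_counts.tsv"), sep="\t")
        return report

    _crosstalk
    manifest.update(crosstalk_report=p("crosstalk_report.json"), plate_counts=p("plate_counts.tsv"))

    records = list(reads.records())

    if reads.umi_length > 0:
        @stage("consensus")
        def _consensus():
            kept, rejected = cons.consensus_pipeline(records, config.filter_params)
            cons.write_consensus_tsv(kept, p("consensus.tsv"))
            with open(p("consensus_rejects.tsv"), "w") as fh:
                fh.write("ref_start\tstrand\tumi\tfamily_size\treason\n")
                for rej in rejected:
                    c = rej.consensus
                    fh.write(f"{c.ref_start}\t{c.strand}\t{c.canonical_umi}\t"
                             f"{c.family_size}\t{rej.reason}\n")
            return kept

        calling_input = _consensus
        manifest.update(consensus=p("consensus.tsv"), consensus_rejects=p("consensus_rejects.tsv"))
    else:
        calling_input = cons.raw_duplicate_collapse(records)

    @stage("call")
    def _call():
        pileup = variants.build_pileup(calling_input, reads.reference)
        calls = variants.call_variants(
            pileup, threshold=config.threshold, oxoG_threshold=config.oxoG_threshold,
            min_depth=config.min_depth,
        )
        variants.write_variants_tsv(calls, p("variants.tsv"))
        return calls

    calls = _call
    manifest["variants"] = p("variants.tsv")

    @stage("evaluate")
    def _eval():
        report = variants.evaluate_calls(calls, list(truth.variants))
        variants.write_eval_json(report, p("eval.json"))
        return report

    _eval
    manifest["eval"] = p("eval.json")

    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
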