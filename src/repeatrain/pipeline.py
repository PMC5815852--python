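"""End-to-end orchestration: simulate → reference → assign → quantify → test.

A run is described by a single YAML/JSON configuration holding either a
simulation block (synthetic mode) or real input paths (genome, consensus,
instance BED, per-sample FASTQ), plus the assignment and quantification
parameter blocks. Outputs are written in a fixed layout under the output
directory, and a JSON run manifest records the configuration hash, a SHA-256
checksum of every stage output, and per-stage read accounting, so identical
configurations reproduce identical checksums and count reconciliation can be
audited (assigned = input − skipped − discarded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assign import AssignParams, assign_all, read_fastq, summary_frame
from .differential import differential_table
from .quant import QuantConfig, quantify, read_abundance, write_abundance
from .reference import build_combined_reference, load_annotation, write_reference
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RealInputs:
    genome: str
    consensus: str
    instances: str
    samples: dict[str, dict]  # name -> {"fastq": path, "condition": "control"|"treated"}


@dataclass
class RunConfig:
    seed: int = 0
    read_length: int = 26
    outdir: str = "repeatrain_out"
    simulation: SimulationConfig | None = None
    inputs: RealInputs | None = None
    assign: AssignParams = field(default_factory=AssignParams)
    quant: QuantConfig = field(default_factory=QuantConfig)

    def validate(self) -> None:
        errors = []
        if (self.simulation is None) == (self.inputs is None):
            errors.append("config: exactly one of 'simulation' and 'inputs' must be present")
        if self.quant.k > self.read_length:
            errors.append(f"quant.k: k-mer size {self.quant.k} exceeds read_length "
                          f"{self.read_length}")
        if self.assign.k > self.read_length:
            errors.append(f"assign.k: k-mer size {self.assign.k} exceeds read_length "
                          f"{self.read_length}")
        if self.simulation is not None:
            try:
                self.simulation.validate()
                if self.simulation.read_length != self.read_length:
                    errors.append("simulation.read_length: must equal read_length")
            except ValueError as e:
                errors.append(f"simulation: {e}")
        if self.inputs is not None:
            for sname, spec in self.inputs.samples.items():
                cond = spec.get("condition")
                if cond not in ("control", "treated"):
                    errors.append(f"inputs.samples.{sname}.condition: must be "
                                  f"'control' or 'treated', got {cond!r}")
                for p in ("genome", "consensus", "instances"):
                    if not Path(getattr(self.inputs, p)).exists():
                        errors.append(f"inputs.{p}: file not found: {getattr(self.inputs, p)}")
                        break
                if "fastq" not in spec or not Path(spec["fastq"]).exists():
                    errors.append(f"inputs.samples.{sname}.fastq: file not found")
        try:
            self.quant.validate()
            self.assign.resolve_min_score(self.read_length)
        except ValueError as e:
            errors.append(str(e))
        if errors:
            raise ValueError("invalid run configuration:\n  " + "\n  ".join(errors))


def _pick(d: dict, cls, path: str, errors: list):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        errors.append(f"{path}: unknown keys {sorted(unknown)}")
    return {k: v for k, v in d.items() if k in known}


def validate_config(source) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration (path or mapping).

    Unknown keys are rejected (never silently ignored); every error names its
    path into the document. Defaults are filled for anything omitted
    (k = 17, read_length = 26, masking on, poly-A filter on, BH-FDR).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, dict):
        raise ValueError("config: top level must be a mapping")
    errors: list[str] = []
    top_known = {"seed", "read_length", "outdir", "simulation", "inputs", "assign", "quant"}
    unknown = set(doc) - top_known
    if unknown:
        errors.append(f"config: unknown keys {sorted(unknown)}")

    sim = None
    if isinstance(doc.get("simulation"), dict):
        sim_doc = dict(doc["simulation"])
        sim_doc.setdefault("seed", doc.get("seed", 0))
        sim_doc.setdefault("read_length", doc.get("read_length", 26))
        try:
            sim = SimulationConfig.from_dict(sim_doc)
        except (TypeError, ValueError) as e:
            errors.append(f"simulation: {e}")
    inputs = None
    if isinstance(doc.get("inputs"), dict):
        picked = _pick(doc["inputs"], RealInputs, "inputs", errors)
        try:
            inputs = RealInputs(**picked)
        except TypeError as e:
            errors.append(f"inputs: {e}")
    assign = AssignParams(**_pick(doc.get("assign", {}) or {}, AssignParams, "assign", errors))
    quant = QuantConfig(**_pick(doc.get("quant", {}) or {}, QuantConfig, "quant", errors))
    if errors:
        raise ValueError("invalid run configuration:\n  " + "\n  ".join(errors))
    cfg = RunConfig(
        seed=int(doc.get("seed", 0)),
        read_length=int(doc.get("read_length", 26)),
        outdir=str(doc.get("outdir", "repeatrain_out")),
        simulation=sim, inputs=inputs, assign=assign, quant=quant)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(str(type(o)))
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # output location is not part of the analysis
    blob = json.dumps(d, sort_keys=True, default=enc)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON).

    On stage failure a ``FAILED`` marker naming the stage is left in the
    output directory and the exception propagates; partial outputs remain.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "repeatrain", "version": __version__,
        "config_hash": _config_hash(config),
        "parameters": {
            "read_length": config.read_length,
            "flank": config.read_length // 2,
            "assign": dataclasses.asdict(config.assign),
            "assign_min_score": config.assign.resolve_min_score(config.read_length),
            "quant": dataclasses.asdict(config.quant),
            "fdr_method": "benjamini-hochberg",
        },
        "stages": {}, "checksums": {}, "counts": {},
    }
    stage = "setup"
    try:
        if config.simulation is not None:
            stage = "simulate"
            logger.info("stage %s: seed=%d", stage, config.simulation.seed)
            simdir = outdir / "sim"
            paths = simulate_dataset(config.simulation, simdir)
            genome_fa = paths["genome"]
            consensus_fa = paths["consensus"]
            instances_bed = paths["instances"]
            sample_specs = {
                s: {"fastq": str(paths[f"fastq_{s}"]),
                    "condition": config.simulation.condition_of(s)}
                for s in config.simulation.sample_names}
            manifest["checksums"]["simulate"] = {
                k: _sha256(p) for k, p in sorted(paths.items())}
        else:
            genome_fa = config.inputs.genome
            consensus_fa = config.inputs.consensus
            instances_bed = config.inputs.instances
            sample_specs = config.inputs.samples

        stage = "build-ref"
        logger.info("stage %s: flank=%d", stage, config.read_length // 2)
        annotation, genome = load_annotation(consensus_fa, instances_bed, genome_fa)
        ref = build_combined_reference(annotation, genome, config.read_length)
        ref_paths = write_reference(ref, outdir / "ref")
        manifest["checksums"]["build-ref"] = {k: _sha256(p) for k, p in sorted(ref_paths.items())}

        stage = "assign+quant"
        counts: dict[str, dict] = {}
        lib_sizes: dict[str, int] = {}
        conditions: dict[str, str] = {}
        abundance_files: dict[str, Path] = {}
        for sample in sorted(sample_specs):
            spec = sample_specs[sample]
            reads = read_fastq(spec["fastq"])
            table = assign_all(reads, ref, config.assign)
            adir = outdir / "samples" / sample
            adir.mkdir(parents=True, exist_ok=True)
            table.to_tsv(adir / "assignments.tsv")
            summary_frame(table).to_csv(adir / "summary.tsv", sep="\t", index=False)
            ab = quantify(table, reads, ref, config.quant)
            write_abundance(ab, adir / "abundance.tsv")
            abundance_files[sample] = adir / "abundance.tsv"
            conditions[sample] = spec["condition"]
            lib_sizes[sample] = int(ab.attrs["library_size"])
            manifest["counts"][sample] = {
                "input": table.n_input,
                "skipped": table.n_skipped,
                "discarded": table.reason_counts,
                "assigned": table.n_assigned,
                "quantified": lib_sizes[sample],
                "dropped_in_quant": int(ab.attrs["n_dropped"]),
            }
            counts[sample] = dict(zip(ab["family"], ab["count"]))
            manifest["checksums"].setdefault("samples", {})[sample] = {
                "assignments": _sha256(adir / "assignments.tsv"),
                "abundance": _sha256(adir / "abundance.tsv"),
            }
            logger.info("sample %s: %d/%d reads assigned (%d quantified)",
                        sample, table.n_assigned, table.n_input, lib_sizes[sample])

        stage = "differential"
        count_mat = pd.DataFrame(counts)
        diff = differential_table(count_mat, lib_sizes, conditions)
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False,
                    float_format="%.6g")
        manifest["checksums"]["differential"] = _sha256(outdir / "differential.tsv")
        n_ctrl = sum(1 for c in conditions.values() if c == "control")
        n_trt = sum(1 for c in conditions.values() if c == "treated")
        manifest["stages"] = {
            "mode": "simulation" if config.simulation is not None else "real",
            "test": "baggerly" if (n_ctrl >= 2 and n_trt >= 2) else "kal_z",
            "samples": sorted(sample_specs),
        }
    except Exception as e:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def differential_from_abundance(control_files, treated_files) -> pd.DataFrame:
    """Differential table straight from per-sample abundance TSVs."""
    counts = {}
    lib = {}
    cond = {}
    for label, files in (("control", control_files), ("treated", treated_files)):
        for i, f in enumerate(files, 1):
            name = f"{label}_{i}"
            ab = read_abundance(f)
            counts[name] = dict(zip(ab["family"], ab["count"]))
            lib[name] = int(ab.attrs["library_size"])
            cond[name] = label
    return differential_table(pd.DataFrame(counts), lib, cond)
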