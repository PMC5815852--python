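"""Synthetic genomes, repeat annotations and RNA-seq reads.

The generator emulates the data regime the repeatome pipeline is built for: a
small multi-contig genome carrying tandem satellite arrays (major/minor
satellite analogues), interspersed LINE/SINE-like retroelement copies diverged
from their family consensus, and background protein-coding-like genes, a
configurable fraction of which embed a SINE fragment to act as decoy
multi-mapping sources. Two conditions (control vs treated) are sampled with
per-family multiplicative derepression fold changes, mimicking drug-induced
loss of heterochromatic silencing. A ground-truth table records the transcript
fractions and realized read counts behind every sample so that downstream
estimates can be scored against what was actually simulated.

Randomness flows from a single master seed through named
``numpy.random.SeedSequence`` child streams (one for the genome, one per
sample), so any sample can be regenerated in isolation and identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, encode, mutate, random_seq, revcomp

logger = logging.getLogger(__name__)

BACKGROUND = "background"

_CONDITIONS = ("control", "treated")


@dataclass
class FamilySpec:
    """One repeat family of the synthetic repeatome.

    Parameters
    ----------
    name:
        Family identifier (e.g. ``"SATMIN-like"``).
    consensus_length:
        Length of the family consensus sequence in bases.
    copy_number:
        Number of genomic instances. Tandem families place all copies as one
        adjacent array on a single contig; interspersed families scatter them.
    divergence:
        Per-base substitution rate of each instance relative to the consensus,
        applied independently per instance. Must lie in [0, 0.3].
    tandem:
        Satellite-style tandem array when True.
    baseline_expression:
        Relative weight of the family in the control read pool (arbitrary
        units, compared against other families and ``background_expression``).
    strand_symmetric:
        Emit reads from both strands with equal probability (satellite
        transcription is bidirectional and produces dsRNA).
    """

    name: str
    consensus_length: int
    copy_number: int
    divergence: float = 0.05
    tandem: bool = False
    baseline_expression: float = 1.0
    strand_symmetric: bool = False

    def validate(self) -> None:
        if not self.name or self.name == BACKGROUND:
            raise ValueError(f"invalid family name {self.name!r}")
        if self.consensus_length < 1:
            raise ValueError(f"{self.name}: consensus_length must be >= 1")
        if self.copy_number < 0:
            raise ValueError(f"{self.name}: copy_number must be >= 0")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError(f"{self.name}: divergence must be in [0, 0.3]")
        if self.baseline_expression < 0:
            raise ValueError(f"{self.name}: baseline_expression must be >= 0")


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset.

    ``read_length`` defaults to 26 bp, the regime in which half-read-length
    flanks are 13 bp; all half-read quantities downstream are computed as
    ``floor(L/2)``, never hard-coded. Two biological replicates per condition
    is the default replication level.
    """

    seed: int = 0
    contig_lengths: list[int] = field(default_factory=lambda: [60_000, 60_000, 40_000])
    repeat_families: list[FamilySpec] = field(default_factory=list)
    n_background_genes: int = 20
    read_length: int = 26
    reads_per_sample: int = 50_000
    error_rate: float = 0.005
    replicates_per_condition: int = 2
    condition_fold_changes: dict[str, float] = field(default_factory=dict)
    background_gene_length: int = 1_000
    background_expression: float = 10.0
    sine_embed_fraction: float = 0.2
    sine_embed_family: str | None = None
    sine_embed_length: int = 100

    def validate(self) -> None:
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if not self.contig_lengths:
            raise ValueError("at least one contig required")
        for length in self.contig_lengths:
            if length <= 0:
                raise ValueError("zero-length contig rejected")
        names = [f.name for f in self.repeat_families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")
        for fam in self.repeat_families:
            fam.validate()
        for name, fc in self.condition_fold_changes.items():
            if name not in names:
                raise ValueError(f"fold change for unknown family {name!r}")
            if not np.isfinite(fc) or fc < 0:
                raise ValueError(f"fold change for {name!r} must be finite and >= 0")
        if not 0.0 <= self.sine_embed_fraction <= 1.0:
            raise ValueError("sine_embed_fraction must be in [0, 1]")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{cond}_{rep + 1}"
            for cond in _CONDITIONS
            for rep in range(self.replicates_per_condition)
        ]

    def condition_of(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        fams = [
            f if isinstance(f, FamilySpec) else FamilySpec(**f)
            for f in d.pop("repeat_families", [])
        ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(repeat_families=fams, **d)
        cfg.validate()
        return cfg


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard study conditions: four repeat families on a ~160 kb genome.

    Satellites (GSAT-like major, SATMIN-like minor) are tandem and
    strand-symmetric; LINE1-like and SINE-B1-like copies are interspersed and
    diverged from their consensus. Background genes dominate the read pool so
    that repeat-derived reads are a realistic minority (~30%).
    """
    cfg = SimulationConfig(
        seed=seed,
        repeat_families=[
            FamilySpec("GSAT-like", 234, 40, divergence=0.02, tandem=True,
                       baseline_expression=1.0, strand_symmetric=True),
            FamilySpec("SATMIN-like", 120, 30, divergence=0.02, tandem=True,
                       baseline_expression=0.08, strand_symmetric=True),
            FamilySpec("LINE1-like", 1_500, 8, divergence=0.10,
                       baseline_expression=1.5),
            FamilySpec("SINE-B1-like", 150, 40, divergence=0.08,
                       baseline_expression=1.6),
        ],
        **overrides,
    )
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """What was actually simulated, for parameter-recovery scoring.

    ``per_sample`` has one row per (sample, source) with the source's true
    fraction of the read pool and the realized read count; sources are repeat
    family names plus ``"background"``. ``fold_change`` maps every repeat
    family to its configured treated/control fold change (1.0 when absent from
    the configuration).
    """

    per_sample: pd.DataFrame
    fold_change: dict[str, float]

    def to_tsv(self, path) -> None:
        df = self.per_sample.copy()
        df["configured_fold_change"] = [
            self.fold_change.get(f, float("nan")) for f in df["family"]
        ]
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class _Transcript:
    name: str
    source: str  # family name or BACKGROUND
    sequence: str
    weight: float
    strand_symmetric: bool


@dataclass
class _World:
    genome: dict[str, str]
    annotation: "RepeatAnnotation"
    transcripts: list[_Transcript]


def _genome_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 0]))


def _sample_rng(config: SimulationConfig, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1, sample_index]))


def _place_block(rng, free: list[tuple[int, int, int]], size: int):
    """Pick a free segment (contig, start, end) that fits ``size`` and split it.

    The segment is chosen with probability proportional to the number of valid
    offsets it offers, so placement is uniform over all admissible positions.
    """
    fits = [i for i, (_, a, b) in enumerate(free) if b - a >= size]
    if not fits:
        raise ValueError(
            "repeat/gene footprint does not fit the genome; "
            "increase contig_lengths or reduce copy numbers"
        )
    slots = np.array([free[i][2] - free[i][1] - size + 1 for i in fits], dtype=float)
    pick = fits[rng.choice(len(fits), p=slots / slots.sum())]
    contig, a, b = free.pop(pick)
    start = a + int(rng.integers(0, b - a - size + 1))
    if start > a:
        free.append((contig, a, start))
    if start + size < b:
        free.append((contig, start + size, b))
    return contig, start


def _build_world(config: SimulationConfig) -> _World:
    from .reference import Instance, RepeatAnnotation  # local to avoid cycle

    config.validate()
    rng = _genome_rng(config)
    total = sum(config.contig_lengths)
    repeat_footprint = sum(f.consensus_length * f.copy_number for f in config.repeat_families)
    if repeat_footprint > 0.8 * total:
        raise ValueError(
            f"repeat footprint {repeat_footprint} bp exceeds 80% of the "
            f"{total} bp genome; enlarge contigs or reduce copy numbers"
        )
    gene_footprint = config.n_background_genes * config.background_gene_length
    if repeat_footprint + gene_footprint > 0.95 * total:
        raise ValueError("combined repeat+gene footprint leaves too little background")

    contig_names = [f"ctg{i + 1}" for i in range(len(config.contig_lengths))]
    contigs = {
        name: encode(random_seq(rng, length)).copy()
        for name, length in zip(contig_names, config.contig_lengths)
    }
    free: list[tuple[int, int, int]] = [
        (name, 0, length) for name, length in zip(contig_names, config.contig_lengths)
    ]

    consensus = {f.name: random_seq(rng, f.consensus_length) for f in config.repeat_families}
    instances: list[Instance] = []
    transcripts: list[_Transcript] = []

    # tandem satellite arrays: all copies adjacent on one contig, plus-strand;
    # transcripts are read-through concatemers of 1-3 adjacent units
    for fam in config.repeat_families:
        if not fam.tandem or fam.copy_number == 0:
            continue
        size = fam.consensus_length * fam.copy_number
        contig, start = _place_block(rng, free, size)
        unit_starts = []
        for i in range(fam.copy_number):
            s = start + i * fam.consensus_length
            unit = mutate(rng, consensus[fam.name], fam.divergence)
            contigs[contig][s:s + fam.consensus_length] = encode(unit)
            instances.append(Instance(fam.name, contig, s, s + fam.consensus_length, "+"))
            unit_starts.append(s)
        i = 0
        while i < fam.copy_number:
            run = int(rng.integers(1, 4))
            run = min(run, fam.copy_number - i)
            a = unit_starts[i]
            b = unit_starts[i] + run * fam.consensus_length
            seq = decode(contigs[contig][a:b])
            transcripts.append(_Transcript(
                f"{fam.name}|{contig}:{a}-{b}", fam.name, seq, 0.0, fam.strand_symmetric))
            i += run

    # interspersed families: scattered single copies, random strand
    for fam in config.repeat_families:
        if fam.tandem:
            continue
        for _ in range(fam.copy_number):
            contig, start = _place_block(rng, free, fam.consensus_length)
            inst_seq = mutate(rng, consensus[fam.name], fam.divergence)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = inst_seq if strand == "+" else revcomp(inst_seq)
            contigs[contig][start:start + fam.consensus_length] = encode(genomic)
            end = start + fam.consensus_length
            instances.append(Instance(fam.name, contig, start, end, strand))
            transcripts.append(_Transcript(
                f"{fam.name}|{contig}:{start}-{end}({strand})", fam.name,
                inst_seq, 0.0, fam.strand_symmetric))

    # background genes; a configurable fraction embed one SINE fragment
    embed_family = config.sine_embed_family
    if embed_family is None:
        interspersed = [f for f in config.repeat_families if not f.tandem and f.copy_number]
        if interspersed:
            embed_family = min(interspersed, key=lambda f: f.consensus_length).name
    for g in range(config.n_background_genes):
        contig, start = _place_block(rng, free, config.background_gene_length)
        seq = random_seq(rng, config.background_gene_length)
        if embed_family is not None and rng.random() < config.sine_embed_fraction:
            fam = next(f for f in config.repeat_families if f.name == embed_family)
            flen = min(config.sine_embed_length, fam.consensus_length,
                       config.background_gene_length)
            f0 = int(rng.integers(0, fam.consensus_length - flen + 1))
            frag = mutate(rng, consensus[embed_family][f0:f0 + flen], fam.divergence)
            pos = int(rng.integers(0, config.background_gene_length - flen + 1))
            seq = seq[:pos] + frag + seq[pos + flen:]
        contigs[contig][start:start + config.background_gene_length] = encode(seq)
        transcripts.append(_Transcript(f"gene{g + 1}", BACKGROUND, seq, 0.0, False))

    # weights: each family's baseline_expression is its share of the read
    # pool, split across its transcripts in proportion to length; background
    # genes share background_expression equally
    for fam in config.repeat_families:
        mine = [t for t in transcripts if t.source == fam.name]
        lens = np.array([len(t.sequence) for t in mine], dtype=float)
        if len(mine) and lens.sum() > 0:
            for t, frac in zip(mine, lens / lens.sum()):
                t.weight = fam.baseline_expression * frac
    genes = [t for t in transcripts if t.source == BACKGROUND]
    for t in genes:
        t.weight = config.background_expression / max(len(genes), 1)

    genome = {name: decode(arr) for name, arr in contigs.items()}
    annotation = RepeatAnnotation(families=consensus, instances=instances)
    return _World(genome=genome, annotation=annotation, transcripts=transcripts)


def generate_genome(config: SimulationConfig):
    """Build the synthetic genome and its repeat annotation.

    Returns ``(genome, annotation)`` where ``genome`` maps contig name to
    sequence and ``annotation`` is a :class:`~repeatrain.reference.RepeatAnnotation`
    with 0-based half-open instance intervals.
    """
    world = _build_world(config)
    return world.genome, world.annotation


def generate_reads(genome, annotation, config: SimulationConfig):
    """Sample per-condition FASTQ reads and the matching ground truth.

    The transcript pool is re-derived deterministically from ``config``; the
    supplied genome/annotation must come from :func:`generate_genome` with the
    same configuration (checked). Returns ``(reads, truth)`` where ``reads``
    maps sample name to a list of ``(read_name, sequence)`` pairs; read names
    carry a ``|src=<family|background>`` provenance tag used by oracle tests.
    """
    world = _build_world(config)
    if world.genome != dict(genome):
        raise ValueError("genome does not match the configuration it was paired with")

    L = config.read_length
    usable = [t for t in world.transcripts if len(t.sequence) >= L]
    dropped = len(world.transcripts) - len(usable)
    if dropped:
        logger.warning("%d transcripts shorter than read length %d excluded", dropped, L)
    if not usable and config.reads_per_sample > 0:
        raise ValueError("no transcript is long enough to sample reads from")

    sources = sorted({t.source for t in world.transcripts})
    seqs = [encode(t.sequence) for t in usable]
    lens = np.array([len(t.sequence) for t in usable], dtype=np.int64)
    sym = np.array([t.strand_symmetric for t in usable], dtype=bool)
    src_of = [t.source for t in usable]

    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for s_idx, sample in enumerate(config.sample_names):
        cond = config.condition_of(sample)
        weights = np.array([
            t.weight * (config.condition_fold_changes.get(t.source, 1.0)
                        if cond == "treated" and t.source != BACKGROUND else 1.0)
            for t in usable
        ])
        if weights.sum() <= 0:
            raise ValueError("all transcript weights are zero")
        probs = weights / weights.sum()
        rng = _sample_rng(config, s_idx)
        R = config.reads_per_sample
        sample_reads: list[tuple[str, str]] = []
        counts: dict[str, int] = {s: 0 for s in sources}
        if R > 0:
            idx = rng.choice(len(usable), size=R, p=probs)
            starts = (rng.random(R) * (lens[idx] - L + 1)).astype(np.int64)
            flip = (rng.random(R) < 0.5) & sym[idx]
            err = rng.random((R, L)) < config.error_rate
            n_err = int(err.sum())
            shifts = rng.integers(1, 4, size=n_err, dtype=np.uint8)
            e = 0
            for r in range(R):
                t = int(idx[r])
                arr = seqs[t][starts[r]:starts[r] + L]
                if flip[r]:
                    arr = arr[::-1].copy()
                    arr[arr < 4] = 3 - arr[arr < 4]
                else:
                    arr = arr.copy()
                row = err[r]
                k = int(row.sum())
                if k:
                    hit = arr[row]
                    ok = hit < 4
                    hit[ok] = (hit[ok] + shifts[e:e + k][ok]) % 4
                    arr[row] = hit
                    e += k
                src = src_of[t]
                counts[src] += 1
                sample_reads.append((f"{sample}.r{r + 1:07d}|src={src}", decode(arr)))
        reads[sample] = sample_reads
        fam_weight: dict[str, float] = {s: 0.0 for s in sources}
        for t, p in zip(usable, probs):
            fam_weight[t.source] += p
        for src in sources:
            truth_rows.append({
                "sample": sample, "condition": cond, "family": src,
                "true_fraction": fam_weight[src], "true_count": counts[src],
            })

    fold = {f.name: config.condition_fold_changes.get(f.name, 1.0)
            for f in config.repeat_families}
    truth = GroundTruth(per_sample=pd.DataFrame(truth_rows), fold_change=fold)
    return reads, truth


# ---------------------------------------------------------------------------
# writers

def write_fasta(path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path, reads: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_dataset(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Run the full generator and write all artifacts under ``outdir``.

    Writes ``genome.fa``, ``consensus.fa``, ``repeats.bed`` (BED6, name =
    family), one ``sample_<condition>_<replicate>.fastq`` per sample, and
    ``truth.tsv``. Returns a name → path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation = generate_genome(config)
    reads, truth = generate_reads(genome, annotation, config)

    paths = {
        "genome": outdir / "genome.fa",
        "consensus": outdir / "consensus.fa",
        "instances": outdir / "repeats.bed",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["genome"], genome)
    write_fasta(paths["consensus"], annotation.families)
    with open(paths["instances"], "w") as fh:
        for inst in annotation.instances:
            fh.write(f"{inst.contig}\t{inst.start}\t{inst.end}\t{inst.family}\t0\t{inst.strand}\n")
    truth.to_tsv(paths["truth"])
    for sample, recs in reads.items():
        p = outdir / f"sample_{sample}.fastq"
        write_fastq(p, recs)
        paths[f"fastq_{sample}"] = p
    return paths
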