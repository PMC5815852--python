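"""Combined repeat reference: canonical entries, flanked instances, genome mask.

The quantification reference for each repeat family holds (i) the family's
canonical (Repbase-style consensus) sequence and (ii) every annotated genomic
instance of the family extended by F = floor(L/2) bases of flanking genomic
sequence on each side, where L is the read length — so a read overlapping an
instance by at least one repeat base fits entirely inside the extended
interval. Minus-strand instances are reverse-complemented after extraction so
every record reads 5'→3' in repeat orientation; the read scorer matches both
strands of every record, which makes that choice observationally neutral.

The complement of the union of all flank-extended instance intervals is the
``mask partition``: the portion of the genome assembly not associated with any
annotated instance. It backs the optional masking criterion that discards
reads matching un-annotated genome as well as, or better than, their best
repeat family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ._seq import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Instance:
    """One annotated genomic copy of a repeat family (0-based half-open)."""

    family: str
    contig: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class RepeatAnnotation:
    """Repeat families (name → consensus) plus their genomic instances."""

    families: dict[str, str]
    instances: list[Instance]

    def validate(self, contig_lengths: dict[str, int] | None = None) -> None:
        for i, inst in enumerate(self.instances):
            if inst.family not in self.families:
                raise ValueError(f"instance row {i}: unknown family {inst.family!r}")
            if inst.strand not in "+-":
                raise ValueError(f"instance row {i}: bad strand {inst.strand!r}")
            if not 0 <= inst.start < inst.end:
                raise ValueError(
                    f"instance row {i} ({inst.family} {inst.contig}:"
                    f"{inst.start}-{inst.end}): interval must satisfy 0 <= start < end")
            if contig_lengths is not None:
                if inst.contig not in contig_lengths:
                    raise ValueError(f"instance row {i}: unknown contig {inst.contig!r}")
                if inst.end > contig_lengths[inst.contig]:
                    raise ValueError(
                        f"instance row {i}: end {inst.end} exceeds contig "
                        f"{inst.contig} length {contig_lengths[inst.contig]}")


@dataclass(frozen=True)
class RefRecord:
    """One target sequence of the combined reference."""

    record_id: str
    family: str | None  # None for mask-partition records
    sequence: str
    contig: str | None = None
    start: int | None = None  # flank-extended interval, 0-based half-open
    end: int | None = None
    strand: str = "+"
    is_canonical: bool = False


@dataclass
class CombinedReference:
    """Per-family canonical + flanked-instance records, plus the genome mask."""

    records: list[RefRecord]
    mask_records: list[RefRecord]
    flank: int
    read_length: int
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def type_index(self) -> dict[str, str]:
        return {r.record_id: r.family for r in self.records}

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.family)
        return list(seen)

    @property
    def mask_partition(self) -> list[tuple[str, int, int]]:
        return [(r.contig, r.start, r.end) for r in self.mask_records]

    def canonical_length(self, family: str) -> int:
        for r in self.records:
            if r.family == family and r.is_canonical:
                return len(r.sequence)
        raise KeyError(family)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def load_annotation(consensus_fasta, instances_bed, genome_fasta) -> tuple[RepeatAnnotation, dict[str, str]]:
    """Read consensus FASTA + BED6 instances + genome FASTA.

    Returns ``(annotation, genome)``. BED coordinates are native 0-based
    half-open; the name column is the family. Rows naming a family absent
    from the consensus FASTA, or with out-of-bounds or inverted intervals,
    are rejected with the offending row identified.
    """
    families = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(consensus_fasta), "fasta")}
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    lengths = {name: len(seq) for name, seq in genome.items()}
    instances = []
    with open(instances_bed) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{instances_bed}:{lineno}: need >= 4 BED columns")
            contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            if name not in families:
                raise ValueError(f"{instances_bed}:{lineno}: unknown family {name!r}")
            instances.append(Instance(name, contig, start, end, strand))
    ann = RepeatAnnotation(families=families, instances=instances)
    ann.validate(lengths)
    return ann, genome


def build_combined_reference(annotation: RepeatAnnotation, genome: dict[str, str],
                             read_length: int) -> CombinedReference:
    """Assemble the combined repeat reference for a given read length.

    Pure function of (annotation, genome, read_length): the flank is
    F = floor(read_length/2); instance intervals are extended by F and clipped
    to contig bounds; duplicate annotation rows are deduplicated (logged);
    records are ordered family-by-family (canonical first, then instances by
    coordinate). The mask partition complements the union of extended
    intervals over ALL families, so overlapping instances of different
    families both keep their shared bases while the mask keeps none.
    """
    lengths = {name: len(seq) for name, seq in genome.items()}
    annotation.validate(lengths)
    F = read_length // 2

    seen: set[Instance] = set()
    dups = 0
    per_family: dict[str, list[Instance]] = {name: [] for name in annotation.families}
    for inst in annotation.instances:
        if inst in seen:
            dups += 1
            continue
        seen.add(inst)
        per_family[inst.family].append(inst)
    if dups:
        logger.info("deduplicated %d duplicate annotation rows", dups)

    records: list[RefRecord] = []
    extended_by_contig: dict[str, list[tuple[int, int]]] = {name: [] for name in genome}
    for family in annotation.families:
        records.append(RefRecord(
            record_id=f"{family}|consensus", family=family,
            sequence=annotation.families[family], is_canonical=True))
        for inst in sorted(per_family[family], key=lambda x: (x.contig, x.start, x.end, x.strand)):
            a = max(inst.start - F, 0)
            b = min(inst.end + F, lengths[inst.contig])
            seq = genome[inst.contig][a:b]
            if inst.strand == "-":
                seq = revcomp(seq)
            records.append(RefRecord(
                record_id=f"{family}|{inst.contig}:{inst.start}-{inst.end}({inst.strand})",
                family=family, sequence=seq, contig=inst.contig,
                start=a, end=b, strand=inst.strand))
            extended_by_contig[inst.contig].append((a, b))

    mask_records: list[RefRecord] = []
    for contig in genome:
        covered = _merge(extended_by_contig[contig])
        pos = 0
        for a, b in covered + [(lengths[contig], lengths[contig])]:
            if pos < a:
                mask_records.append(RefRecord(
                    record_id=f"mask|{contig}:{pos}-{a}", family=None,
                    sequence=genome[contig][pos:a], contig=contig, start=pos, end=a))
            pos = max(pos, b)

    return CombinedReference(records=records, mask_records=mask_records,
                             flank=F, read_length=read_length,
                             contig_lengths=lengths)


def write_reference(ref: CombinedReference, outdir) -> dict[str, Path]:
    """Write combined_repeats.fa, mask.bed, mask.fa and manifest.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "combined": outdir / "combined_repeats.fa",
        "mask_bed": outdir / "mask.bed",
        "mask_fa": outdir / "mask.fa",
        "manifest": outdir / "manifest.tsv",
    }
    with open(paths["combined"], "w") as fh:
        for r in ref.records:
            fh.write(f">{r.record_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")
    with open(paths["mask_bed"], "w") as fh:
        for contig, a, b in ref.mask_partition:
            fh.write(f"{contig}\t{a}\t{b}\tmask\t0\t+\n")
    with open(paths["mask_fa"], "w") as fh:
        for r in ref.mask_records:
            fh.write(f">{r.record_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")
    with open(paths["manifest"], "w") as fh:
        fh.write("record_id\tfamily\tcanonical\tcontig\tstart\tend\tstrand\tlength\n")
        fh.write(f"#flank={ref.flank}\tread_length={ref.read_length}\t"
                 f"contigs={','.join(f'{c}:{n}' for c, n in ref.contig_lengths.items())}\n")
        for r in ref.records:
            fh.write(f"{r.record_id}\t{r.family}\t{int(r.is_canonical)}\t"
                     f"{r.contig or '.'}\t{'.' if r.start is None else r.start}\t"
                     f"{'.' if r.end is None else r.end}\t{r.strand}\t{len(r.sequence)}\n")
    return paths


def load_reference(refdir) -> CombinedReference:
    """Read back a reference written by :func:`write_reference`."""
    refdir = Path(refdir)
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(refdir / "combined_repeats.fa"), "fasta")}
    mask_seqs = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(refdir / "mask.fa"), "fasta")}
    records: list[RefRecord] = []
    flank = read_length = None
    contig_lengths: dict[str, int] = {}
    with open(refdir / "manifest.tsv") as fh:
        header = fh.readline()
        meta = fh.readline().lstrip("#").split("\t")
        flank = int(meta[0].split("=")[1])
        read_length = int(meta[1].split("=")[1])
        for part in meta[2].split("=")[1].strip().split(","):
            if part:
                c, n = part.rsplit(":", 1)
                contig_lengths[c] = int(n)
        for line in fh:
            rid, family, canon, contig, start, end, strand, _ = line.rstrip("\n").split("\t")
            records.append(RefRecord(
                record_id=rid, family=family, sequence=seqs[rid],
                contig=None if contig == "." else contig,
                start=None if start == "." else int(start),
                end=None if end == "." else int(end),
                strand=strand, is_canonical=canon == "1"))
    mask_records = []
    for rid, seq in mask_seqs.items():
        _, loc = rid.split("|", 1)
        contig, span = loc.rsplit(":", 1)
        a, b = span.split("-")
        mask_records.append(RefRecord(record_id=rid, family=None, sequence=seq,
                                      contig=contig, start=int(a), end=int(b)))
    mask_records.sort(key=lambda r: (r.contig, r.start))
    return CombinedReference(records=records, mask_records=mask_records,
                             flank=flank, read_length=read_length,
                             contig_lengths=contig_lengths)
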