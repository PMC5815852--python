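"""Read-to-repeat-type assignment under the three uniqueness criteria.

A read is associated with a repeat family only when

  (a) it aligns to one or more locations within that family's canonical
      sequence or flank-extended genomic instances,
  (b) no alignment of equal or better quality exists to any other family's
      canonical or instance sequences, and
  (c) optionally ("masking"), no alignment of equal or better quality exists
      to any portion of the genome not associated with annotated instances.

Alignment quality is operationalized as the ungapped matching-base count: the
score of a read against a target is the maximum, over every ungapped placement
of the read on the target in either orientation (placements may overhang the
target ends; overhanging bases score zero), of the number of matching bases.
"Equal or better quality" is ``>=`` on this integer score, so ties trigger
criteria (b)/(c) and the read is discarded. Multiple placements *within* the
winning family never discard.

Candidate placements are located through shared seed k-mers and then rescored
exactly. The seed length is chosen by a pigeonhole bound from ``min_score``:
any placement scoring at least ``min_score`` contains an exact match of at
least ``min_score // (L - min_score + 1)`` consecutive bases, so every
placement that can influence a verdict is guaranteed to be found and the
seeded verdicts provably equal exhaustive all-offset scoring. The configured
k-mer size (default 17) caps the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import SENTINEL, encode, kmer_codes, revcomp_arr
from .reference import CombinedReference, RefRecord

logger = logging.getLogger(__name__)

MASK = "__mask__"

REASONS = ("no_hit", "below_min_score", "cross_family_tie", "genome_tie")


@dataclass
class AssignParams:
    """Knobs of the assignment stage.

    ``min_score`` defaults to L - 2 (≈92% identity at L = 26); ``k`` is the
    seed k-mer cap; ``masking_enabled`` switches criterion (c).
    """

    k: int = 17
    min_score: int | None = None
    masking_enabled: bool = True

    def resolve_min_score(self, read_length: int) -> int:
        ms = read_length - 2 if self.min_score is None else self.min_score
        if not 1 <= ms <= read_length:
            raise ValueError(f"min_score {ms} outside [1, {read_length}]")
        if not 1 <= self.k:
            raise ValueError("k must be >= 1")
        return ms

    def seed_length(self, read_length: int) -> int:
        """Pigeonhole-complete seed length for the resolved ``min_score``."""
        ms = self.resolve_min_score(read_length)
        guarantee = max(1, ms // (read_length - ms + 1))
        return min(self.k, guarantee, read_length)


@dataclass(frozen=True)
class Verdict:
    read_id: str
    assigned: bool
    family: str | None
    reason: str | None
    best_score: int


@dataclass
class AssignmentTable:
    """Per-read verdicts plus per-family and per-reason summaries."""

    verdicts: pd.DataFrame  # read_id, assigned, family, reason, best_score
    masking_enabled: bool
    read_length: int
    n_input: int
    n_skipped: int

    @property
    def family_counts(self) -> dict[str, int]:
        sub = self.verdicts[self.verdicts["assigned"]]
        return sub.groupby("family", sort=True).size().to_dict()

    @property
    def reason_counts(self) -> dict[str, int]:
        sub = self.verdicts[~self.verdicts["assigned"]]
        return sub.groupby("reason", sort=True).size().to_dict()

    @property
    def n_assigned(self) -> int:
        return int(self.verdicts["assigned"].sum())

    def to_tsv(self, path) -> None:
        df = self.verdicts.copy()
        df.insert(1, "verdict", np.where(df.pop("assigned"), "assigned", "discarded"))
        df.to_csv(path, sep="\t", index=False)


def score_read(read: str, target: str) -> int:
    """Exact best ungapped score of ``read`` against ``target``.

    Maximum matching-base count over every placement (both orientations of
    the read; overhangs allowed and scored zero). Non-ACGT bases never match.
    """
    L = len(read)
    if L == 0 or len(target) == 0:
        return 0
    tarr = encode(target)
    pad = np.full(L - 1, SENTINEL, dtype=np.uint8)
    padded = np.concatenate([pad, tarr, pad])
    win = np.lib.stride_tricks.sliding_window_view(padded, L)
    fwd = encode(read)
    best = 0
    for arr in (fwd, revcomp_arr(fwd)):
        ok = arr < 4
        if ok.any():
            best = max(best, int(((win == arr) & ok).sum(axis=1).max()))
    return best


class _TargetIndex:
    """Seed-k-mer index over the concatenated reference (and mask) records."""

    def __init__(self, ref: CombinedReference, read_length: int, seed_k: int,
                 include_mask: bool):
        self.read_length = L = read_length
        self.seed_k = seed_k
        self.families = ref.families
        fam_id = {f: i for i, f in enumerate(self.families)}
        self.n_families = len(self.families)

        records: list[RefRecord] = list(ref.records)
        if include_mask:
            records += list(ref.mask_records)
        parts = [np.full(L, SENTINEL, dtype=np.uint8)]
        ends = []
        fams = []
        pos = L
        gap = np.full(L, SENTINEL, dtype=np.uint8)
        for r in records:
            arr = encode(r.sequence)
            parts.append(arr)
            pos += len(arr)
            ends.append(pos)
            fams.append(self.n_families if r.family is None else fam_id[r.family])
            parts.append(gap)
            pos += L
        self.cat = np.concatenate(parts) if records else np.full(2 * L, SENTINEL, np.uint8)
        self.record_ends = np.array(ends, dtype=np.int64)
        self.record_fam = np.array(fams, dtype=np.int64)

        codes, valid = kmer_codes(self.cat, seed_k)
        pos_all = np.flatnonzero(valid)
        c = codes[pos_all]
        order = np.argsort(c, kind="stable")
        self._codes = c[order]
        self._pos = pos_all[order]

    def best_scores(self, reads_enc: np.ndarray) -> np.ndarray:
        """(R, n_families + 1) matrix of best scores; last column is the mask."""
        R, L = reads_enc.shape
        nf = self.n_families + 1
        best = np.zeros((R, nf), dtype=np.int64)
        if R == 0 or len(self.record_ends) == 0:
            return best
        k = self.seed_k
        nk = L - k + 1
        for arr in (reads_enc, np.flip(3 - np.where(reads_enc < 4, reads_enc, -1), axis=1)):
            # revcomp lane encodes non-ACGT as 4 via the where/-1 trick
            arr = np.where((arr >= 0) & (arr < 4), arr, 4).astype(np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(arr, k, axis=1)
            powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
            qcodes = win.astype(np.int64) @ powers  # (R, nk)
            qvalid = (win < 4).all(axis=2)
            rid, off = np.nonzero(qvalid)
            qc = qcodes[rid, off]
            lo = np.searchsorted(self._codes, qc, side="left")
            hi = np.searchsorted(self._codes, qc, side="right")
            cnt = hi - lo
            keep = cnt > 0
            rid, off, lo, cnt = rid[keep], off[keep], lo[keep], cnt[keep]
            total = int(cnt.sum())
            if total == 0:
                continue
            cum = np.cumsum(cnt)
            flat = np.arange(total) - np.repeat(cum - cnt, cnt) + np.repeat(lo, cnt)
            tpos = self._pos[flat]
            pread = np.repeat(rid, cnt)
            diag = tpos - np.repeat(off, cnt)
            key = pread * np.int64(len(self.cat)) + diag
            key, first = np.unique(key, return_index=True)
            pread = pread[first]
            diag = diag[first]
            # exact rescoring of each unique (read, placement) pair, chunked
            rec = np.searchsorted(self.record_ends, diag, side="right")
            rec = np.minimum(rec, len(self.record_ends) - 1)
            fam = self.record_fam[rec]
            offs = np.arange(L, dtype=np.int64)
            for s in range(0, len(diag), 1_000_000):
                sl = slice(s, s + 1_000_000)
                window = self.cat[diag[sl, None] + offs[None, :]]
                q = arr[pread[sl]]
                scores = ((window == q) & (q < 4)).sum(axis=1)
                np.maximum.at(best, (pread[sl], fam[sl]), scores)
        return best


def _verdicts_from_scores(best: np.ndarray, min_score: int, masking: bool,
                          families: list[str]):
    """Apply criteria (a)-(c) to a (R, n_families+1) best-score matrix."""
    nf = len(families)
    fam_scores = best[:, :nf] if nf else np.zeros((len(best), 1), dtype=np.int64)
    s_star = fam_scores.max(axis=1) if nf else np.zeros(len(best), dtype=np.int64)
    winner = fam_scores.argmax(axis=1) if nf else np.zeros(len(best), dtype=np.int64)
    n_top = (fam_scores == s_star[:, None]).sum(axis=1) if nf else np.zeros(len(best))
    s_mask = best[:, nf]

    assigned = np.zeros(len(best), dtype=bool)
    family = np.full(len(best), None, dtype=object)
    reason = np.full(len(best), None, dtype=object)
    any_score = np.maximum(s_star, s_mask)

    low = s_star < min_score
    reason[low & (any_score == 0)] = "no_hit"
    reason[low & (any_score > 0)] = "below_min_score"
    tie = ~low & (n_top > 1)
    reason[tie] = "cross_family_tie"
    gmask = ~low & ~tie & masking & (s_mask >= s_star)
    reason[gmask] = "genome_tie"
    ok = ~low & ~tie & ~gmask
    assigned[ok] = True
    if nf:
        family[ok] = np.array(families, dtype=object)[winner[ok]]
    best_score = np.maximum(s_star, s_mask if masking else 0)
    return assigned, family, reason, best_score


def assign_read(read: str, ref: CombinedReference, params: AssignParams) -> Verdict:
    """Assign a single read by exhaustive scoring (reference semantics)."""
    L = len(read)
    min_score = params.resolve_min_score(L)
    families = ref.families
    best = np.zeros((1, len(families) + 1), dtype=np.int64)
    for r in ref.records:
        i = families.index(r.family)
        best[0, i] = max(best[0, i], score_read(read, r.sequence))
    if params.masking_enabled:
        for r in ref.mask_records:
            best[0, len(families)] = max(best[0, len(families)],
                                         score_read(read, r.sequence))
    assigned, family, reason, score = _verdicts_from_scores(
        best, min_score, params.masking_enabled, families)
    return Verdict("read", bool(assigned[0]), family[0], reason[0], int(score[0]))


def read_fastq(path) -> list[tuple[str, str]]:
    """Parse a (plain-text) FASTQ file into (name, sequence) pairs."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header[1:].strip(), seq.upper()))
    return out


def assign_all(reads, ref: CombinedReference, params: AssignParams | None = None) -> AssignmentTable:
    """Assign every read; reads whose length differs from the reference read
    length are skipped (logged), per the fixed-L criteria arithmetic.

    ``reads`` may be a FASTQ path, a list of FASTQ paths, or a list of
    ``(name, sequence)`` pairs. Verdict order follows input order but is
    independent of it read-by-read (each read is scored in isolation).
    """
    params = params or AssignParams()
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    elif reads and isinstance(reads[0], (str, Path)):
        merged = []
        for p in reads:
            merged.extend(read_fastq(p))
        reads = merged
    L = ref.read_length
    min_score = params.resolve_min_score(L)
    names = [n for n, _ in reads]
    seqs = [s for _, s in reads]
    ok = np.array([len(s) == L for s in seqs], dtype=bool)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d reads with length != %d", n_skipped, L)

    kept = [i for i in range(len(seqs)) if ok[i]]
    if kept:
        enc = np.stack([encode(seqs[i]) for i in kept])
        index = _TargetIndex(ref, L, params.seed_length(L), params.masking_enabled)
        best = index.best_scores(enc)
        assigned, family, reason, score = _verdicts_from_scores(
            best, min_score, params.masking_enabled, index.families)
    rows = {
        "read_id": names,
        "assigned": np.zeros(len(seqs), dtype=bool),
        "family": np.full(len(seqs), None, dtype=object),
        "reason": np.full(len(seqs), "skipped", dtype=object),
        "best_score": np.zeros(len(seqs), dtype=np.int64),
    }
    for j, i in enumerate(kept):
        rows["assigned"][i] = assigned[j]
        rows["family"][i] = family[j]
        rows["reason"][i] = reason[j]
        rows["best_score"][i] = score[j]
    table = AssignmentTable(
        verdicts=pd.DataFrame(rows), masking_enabled=params.masking_enabled,
        read_length=L, n_input=len(seqs), n_skipped=n_skipped)
    return table


def summary_frame(table: AssignmentTable) -> pd.DataFrame:
    """One-row-per-category accounting (assigned per family, discards per reason)."""
    rows = [{"category": f"assigned:{fam}", "count": n}
            for fam, n in sorted(table.family_counts.items())]
    rows += [{"category": f"discarded:{r}", "count": n}
             for r, n in sorted(table.reason_counts.items())]
    rows.append({"category": "input", "count": table.n_input})
    rows.append({"category": "skipped", "count": table.n_skipped})
    return pd.DataFrame(rows)
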