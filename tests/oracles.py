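"""Independent oracles used by the test suite.

Everything here is deliberately written from the definitions, by a different
route than the package: exhaustive all-offset scoring instead of seeded
search, plain standard EM instead of variational Bayes, direct arithmetic
instead of vectorized library calls. Oracles stay independent of the code
paths they check.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def brute_score_py(read: str, target: str) -> int:
    """Plain-Python exhaustive best ungapped score (tiny inputs only)."""
    L = len(read)
    best = 0
    for r in (read, rc(read)):
        for off in range(-(L - 1), len(target)):
            s = 0
            for i, c in enumerate(r):
                j = off + i
                if 0 <= j < len(target) and c in "ACGT" and target[j] == c:
                    s += 1
            best = max(best, s)
    return best


def brute_scores_np(reads: list[str], targets: list[str]) -> np.ndarray:
    """(n_reads, n_targets) exact best scores via windowed numpy comparison."""
    if not reads:
        return np.zeros((0, len(targets)), dtype=int)
    L = len(reads[0])
    enc = np.full(256, 9, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        enc[ord(b)] = i

    def e(s):
        return enc[np.frombuffer(s.encode(), dtype=np.uint8)]

    R = np.stack([e(r) for r in reads])
    Rrc = np.stack([e(rc(r)) for r in reads])
    out = np.zeros((len(reads), len(targets)), dtype=int)
    for t_i, t in enumerate(targets):
        padded = np.concatenate([np.full(L - 1, 8, np.uint8), e(t),
                                 np.full(L - 1, 8, np.uint8)])
        win = np.lib.stride_tricks.sliding_window_view(padded, L)
        for mat in (R, Rrc):
            sc = ((win[None, :, :] == mat[:, None, :]) & (mat[:, None, :] < 4)).sum(axis=2)
            out[:, t_i] = np.maximum(out[:, t_i], sc.max(axis=1))
    return out


def brute_verdicts(reads: list[str], ref, min_score: int, masking: bool):
    """Exhaustive-scoring verdicts under criteria (a)-(c).

    Returns a list of (assigned: bool, family: str | None, reason) tuples,
    derived from all-offset scores with no seeding involved.
    """
    fams = []
    for r in ref.records:
        if r.family not in fams:
            fams.append(r.family)
    fam_seqs = {f: [r.sequence for r in ref.records if r.family == f] for f in fams}
    mask_seqs = [r.sequence for r in ref.mask_records]
    all_targets = [s for f in fams for s in fam_seqs[f]] + mask_seqs
    owner = [f for f in fams for _ in fam_seqs[f]] + [None] * len(mask_seqs)
    scores = brute_scores_np(reads, all_targets)
    verdicts = []
    for row in scores:
        best_per = {f: 0 for f in fams}
        s_mask = 0
        for sc, f in zip(row, owner):
            if f is None:
                s_mask = max(s_mask, int(sc))
            else:
                best_per[f] = max(best_per[f], int(sc))
        s_star = max(best_per.values()) if fams else 0
        winners = [f for f in fams if best_per[f] == s_star]
        if s_star < min_score:
            # sub-threshold scores are not resolved exactly by seeded search,
            # so no_hit and below_min_score count as one category
            verdicts.append((False, None, "sub_threshold"))
        elif len(winners) > 1:
            verdicts.append((False, None, "cross_family_tie"))
        elif masking and s_mask >= s_star:
            verdicts.append((False, None, "genome_tie"))
        else:
            verdicts.append((True, winners[0], None))
    return verdicts


def random_instance(seed: int, max_reads: int = 80):
    """Random small reference + read set for seeded-vs-exhaustive checks.

    Reads mix exact copies of reference records, mutated copies (0-3
    substitutions), genomic background and reverse complements.
    """
    from repeatrain import Instance, RepeatAnnotation, build_combined_reference

    rng = np.random.default_rng(seed)

    def rand_seq(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    n_fam = int(rng.integers(2, 6))
    families = {}
    instances = []
    genome_parts = [rand_seq(150)]
    pos = 150
    for f in range(n_fam):
        cons = rand_seq(int(rng.integers(40, 120)))
        families[f"fam{f}"] = cons
        for _ in range(int(rng.integers(0, 3))):
            inst = "".join(
                c if rng.random() > 0.08 else "ACGT"[rng.integers(0, 4)] for c in cons)
            strand = "+" if rng.random() < 0.5 else "-"
            genome_parts.append(inst if strand == "+" else rc(inst))
            instances.append(Instance(f"fam{f}", "ctg", pos, pos + len(inst), strand))
            pos += len(inst)
            genome_parts.append(rand_seq(40))
            pos += 40
    genome_parts.append(rand_seq(150))
    genome = {"ctg": "".join(genome_parts)}
    ref = build_combined_reference(
        RepeatAnnotation(families=families, instances=instances), genome, 26)
    pool = [r.sequence for r in ref.records if len(r.sequence) >= 26]
    pool += [genome["ctg"]]
    reads = []
    for i in range(int(rng.integers(max(30, max_reads // 2), max_reads + 1))):
        src = pool[rng.integers(0, len(pool))]
        s = int(rng.integers(0, len(src) - 25))
        read = list(src[s:s + 26])
        for _ in range(int(rng.integers(0, 4))):
            read[rng.integers(0, 26)] = "ACGT"[rng.integers(0, 4)]
        read = "".join(read)
        if rng.random() < 0.5:
            read = rc(read)
        reads.append((f"r{i}", read))
    return ref, reads


def standard_em(classes, eff_lengths: dict[str, float], tol: float = 1e-12,
                max_iter: int = 100_000) -> dict[str, float]:
    """Classic EM fixed point over equivalence classes (maximum likelihood)."""
    fams = sorted(eff_lengths)
    idx = {f: i for i, f in enumerate(fams)}
    eff = np.array([max(eff_lengths[f], 1.0) for f in fams])
    theta = np.full(len(fams), 1.0 / len(fams))
    members = [[idx[f] for f in sorted(c.families)] for c in classes]
    counts = np.array([c.count for c in classes], dtype=float)
    total = counts.sum()
    for _ in range(max_iter):
        new = np.zeros(len(fams))
        for m, n in zip(members, counts):
            w = theta[m] / eff[m]
            new[np.array(m)] += n * w / w.sum()
        new /= total
        if np.abs(new - theta).max() < tol:
            theta = new
            break
        theta = new
    return {f: float(t) for f, t in zip(fams, theta)}


def bh_reference(p):
    """Step-up BH by direct definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(min(m * p[order[j - 1]] / j for j in range(rank, m + 1)), 1.0)
    return q
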