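"""Generator behaviour: determinism, ground-truth consistency, edge cases."""

import numpy as np
import pytest
from scipy import stats

from repeatrain import (
    FamilySpec,
    SimulationConfig,
    generate_genome,
    generate_reads,
    simulate_dataset,
)


def _cfg(**kw):
    base = dict(seed=5, contig_lengths=[50_000], n_background_genes=4,
                background_expression=2.0, reads_per_sample=500,
                error_rate=0.0, sine_embed_fraction=0.0)
    base.update(kw)
    return SimulationConfig(**base)


def test_zero_copy_family_gives_pure_background():
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 100, 0, tandem=True)])
    genome, ann = generate_genome(cfg)
    assert ann.instances == []
    assert len(genome["ctg1"]) == 50_000


def test_zero_divergence_instance_equals_consensus():
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 150, 1, divergence=0.0)])
    genome, ann = generate_genome(cfg)
    (inst,) = ann.instances
    seq = genome[inst.contig][inst.start:inst.end]
    if inst.strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        seq = seq.translate(comp)[::-1]
    assert seq == ann.families["SAT"]


def test_tandem_array_layout_and_divergence():
    """20 SATMIN-like units sit adjacently, covering 2,400 bp, and their
    pairwise Hamming distance to the consensus matches the configured
    divergence within 3 standard errors (direct comparison oracle)."""
    cfg = _cfg(seed=7, repeat_families=[
        FamilySpec("SATMIN-like", 120, 20, divergence=0.1, tandem=True)])
    genome, ann = generate_genome(cfg)
    rows = [i for i in ann.instances if i.family == "SATMIN-like"]
    assert len(rows) == 20
    starts = sorted(r.start for r in rows)
    assert all(b - a == 120 for a, b in zip(starts, starts[1:]))
    assert sum(r.end - r.start for r in rows) == 2_400
    cons = ann.families["SATMIN-like"]
    mism = [sum(a != b for a, b in zip(genome[r.contig][r.start:r.end], cons))
            for r in rows]
    frac = sum(mism) / 2_400
    se = np.sqrt(0.1 * 0.9 / 2_400)
    assert abs(frac - 0.1) <= 3 * se


def test_footprint_overflow_rejected():
    cfg = _cfg(contig_lengths=[1_000],
               repeat_families=[FamilySpec("SAT", 100, 9, tandem=True)])
    with pytest.raises(ValueError, match="footprint"):
        generate_genome(cfg)


def test_zero_length_contig_rejected():
    with pytest.raises(ValueError, match="contig"):
        _cfg(contig_lengths=[0]).validate()


def test_negative_fold_change_rejected():
    with pytest.raises(ValueError, match="fold change"):
        _cfg(repeat_families=[FamilySpec("SAT", 100, 2)],
             condition_fold_changes={"SAT": -1.0}).validate()


def test_zero_error_reads_are_exact_substrings():
    cfg = _cfg(repeat_families=[FamilySpec("LINE", 800, 1)],
               n_background_genes=0, background_expression=0.0)
    genome, ann = generate_genome(cfg)
    reads, _ = generate_reads(genome, ann, cfg)
    (inst,) = ann.instances
    seq = genome[inst.contig][inst.start:inst.end]
    comp = str.maketrans("ACGT", "TGCA")
    pool = seq + "#" + seq.translate(comp)[::-1]
    for name, r in reads["control_1"]:
        assert r in pool, name


def test_empty_fold_change_means_identical_pools():
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 120, 4, tandem=True)])
    genome, ann = generate_genome(cfg)
    _, truth = generate_reads(genome, ann, cfg)
    per = truth.per_sample.pivot_table(index="family", columns="sample",
                                       values="true_fraction")
    assert np.allclose(per.values, per.values[:, [0]] @ np.ones((1, per.shape[1])))


def test_truth_counts_conserve_reads_per_sample():
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 120, 4, tandem=True)],
               reads_per_sample=777, error_rate=0.01)
    genome, ann = generate_genome(cfg)
    reads, truth = generate_reads(genome, ann, cfg)
    sums = truth.per_sample.groupby("sample")["true_count"].sum()
    assert (sums == 777).all()
    for sample, recs in reads.items():
        assert len(recs) == 777
    fracs = truth.per_sample.groupby("sample")["true_fraction"].sum()
    assert np.allclose(fracs, 1.0)


def test_tagged_fraction_within_exact_binomial_interval():
    """At 50k reads and a 2% SATMIN-like weight the tagged-read count lands
    in the exact central 99% binomial interval (quantile oracle)."""
    cfg = _cfg(seed=11, contig_lengths=[60_000],
               repeat_families=[FamilySpec("SATMIN-like", 120, 10, tandem=True,
                                           baseline_expression=0.02)],
               n_background_genes=10, background_expression=0.98,
               reads_per_sample=50_000)
    genome, ann = generate_genome(cfg)
    reads, _ = generate_reads(genome, ann, cfg)
    n = sum(1 for name, _ in reads["control_1"] if name.endswith("src=SATMIN-like"))
    lo = stats.binom.ppf(0.005, 50_000, 0.02)
    hi = stats.binom.ppf(0.995, 50_000, 0.02)
    assert lo <= n <= hi


def test_zero_reads_gives_empty_fastq():
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 120, 2, tandem=True)],
               reads_per_sample=0)
    genome, ann = generate_genome(cfg)
    reads, truth = generate_reads(genome, ann, cfg)
    assert all(len(v) == 0 for v in reads.values())
    assert (truth.per_sample["true_count"] == 0).all()


def test_short_transcripts_excluded_with_warning(caplog):
    cfg = _cfg(repeat_families=[FamilySpec("TINY", 10, 2),
                                FamilySpec("SAT", 200, 2, tandem=True)])
    genome, ann = generate_genome(cfg)
    with caplog.at_level("WARNING"):
        reads, _ = generate_reads(genome, ann, cfg)
    assert "excluded" in caplog.text
    assert all("src=TINY" not in name for name, _ in reads["control_1"])


def test_simulate_dataset_is_byte_deterministic(tmp_path):
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 120, 4, tandem=True)],
               error_rate=0.01, reads_per_sample=300)
    p1 = simulate_dataset(cfg, tmp_path / "a")
    p2 = simulate_dataset(cfg, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_treated_pool_reflects_fold_change():
    cfg = _cfg(repeat_families=[FamilySpec("SAT", 120, 4, tandem=True,
                                           baseline_expression=1.0)],
               background_expression=9.0, reads_per_sample=20_000,
               condition_fold_changes={"SAT": 4.0})
    genome, ann = generate_genome(cfg)
    _, truth = generate_reads(genome, ann, cfg)
    t = truth.per_sample
    f_ctrl = t[(t["sample"] == "control_1") & (t["family"] == "SAT")]["true_fraction"].item()
    f_trt = t[(t["sample"] == "treated_1") & (t["family"] == "SAT")]["true_fraction"].item()
    assert f_ctrl == pytest.approx(0.1)
    assert f_trt == pytest.approx(4.0 / 13.0)
    assert truth.fold_change == {"SAT": 4.0}
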