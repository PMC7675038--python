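"""Simulator: capture model, read generation, scenario presets."""

import numpy as np
import pandas as pd
import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

import deldeck as dd
from deldeck.simulate import SCENARIO_NAMES, pair_weights
from conftest import make_manifest


@pytest.fixture(scope="module")
def manifest():
    return make_manifest(6, 8, with_properties=False)


# -- capture ---------------------------------------------------------------

def test_capture_uniform_expectation(manifest):
    """All folds 1, p0=1e-5, n0=1e7 -> every member's expected count is 100."""
    truth = dd.GroundTruth()
    cap = dd.simulate_capture(truth, dd.SelectionMode(), manifest, seed=3)
    assert len(cap) == manifest.n_members
    # mean of 96 iid Binomial(1e7, 1e-5) ~ 100 +- ~1 (5 sigma band)
    assert abs(cap.mean() - 100.0) < 5.1


def test_capture_planted_binder_scaling(manifest):
    """A fold-1000 binder has expected captured count n0*p0*1000 = 1e5."""
    truth = dd.GroundTruth()
    truth.plant("A2", "B3", 1000.0)
    cap = dd.simulate_capture(truth, dd.SelectionMode(), manifest, seed=5)
    sigma = np.sqrt(1e7 * 1e-3 * 0.999)
    for s in ("R", "S"):
        assert abs(cap.loc[(s, "A2", "B3")] - 1e5) < 5 * sigma
    assert abs(cap.loc[("R", "A1", "B1")] - 100) < 100


def test_capture_deterministic(manifest):
    truth = dd.GroundTruth()
    truth.plant("A1", "B1", 50.0)
    a = dd.simulate_capture(truth, dd.SelectionMode(), manifest, seed=9)
    b = dd.simulate_capture(truth, dd.SelectionMode(), manifest, seed=9)
    assert (a == b).all()


def test_capture_probability_capped_with_warning(manifest):
    truth = dd.GroundTruth(base_capture_prob=1e-2)
    truth.plant("A1", "B1", 500.0)  # p = 5 > 1
    with pytest.warns(UserWarning, match="capping"):
        cap = dd.simulate_capture(truth, dd.SelectionMode(), manifest, seed=1)
    assert cap.loc[("R", "A1", "B1")] == truth.copies_per_member


def test_ground_truth_invariants():
    with pytest.raises(ValueError):
        dd.GroundTruth(fold={("R", "A1", "B1"): 0.5})
    with pytest.raises(ValueError):
        dd.GroundTruth(base_capture_prob=0.0)
    with pytest.raises(ValueError):
        dd.GroundTruth(copies_per_member=0)


def test_dp_mode_requires_hit_label():
    with pytest.raises(ValueError, match="hit_label"):
        dd.SelectionMode(mode="DP")


def test_dp_multiplier_applied(manifest):
    """DP effective fold = f_m * multiplier, visible in expected counts."""
    truth = dd.GroundTruth()
    truth.plant("A2", "B3", 3.0)
    dp = dd.SelectionMode(mode="DP", hit_label="HIT1",
                          hit_fold_multiplier={(s, "A2", "B3"): 100.0 for s in "RS"})
    cap = dd.simulate_capture(truth, dp, manifest, seed=2)
    # expected 1e7 * 1e-5 * (3 * 100) = 30000
    assert abs(cap.loc[("R", "A2", "B3")] - 30000) < 5 * np.sqrt(30000)


# -- read generation -------------------------------------------------------

def _read_fastq(path):
    with open(path) as fh:
        return [(t, s, q) for t, s, q in FastqGeneralIterator(fh)]


def test_reads_error_free_match_codebooks(manifest, tmp_path):
    """depth=1000, error_rate=0: truth has 1000 rows; slots match codebooks exactly."""
    cap = dd.simulate_capture(dd.GroundTruth(), dd.SelectionMode(), manifest, seed=4)
    cfg = dd.SequencingConfig(depth=1000, error_rate=0.0, seed=4)
    truth = dd.sequence_reads(cap, manifest, cfg, tmp_path / "r.fastq", tmp_path / "t.tsv")
    assert len(truth) == 1000
    seq_a = {c.code_id: c.sequence for c in manifest.codebook_a}
    seq_b = {c.code_id: c.sequence for c in manifest.codebook_b}
    sa, sb = cfg.layout.slots(manifest.code_length_a, manifest.code_length_b)
    records = _read_fastq(tmp_path / "r.fastq")
    assert len(records) == 1000
    for (title, seq, qual), row in zip(records, truth.itertuples(index=False)):
        assert title == row.read_id
        assert seq[sa] == seq_a[row.code_a]
        assert seq[sb] == seq_b[row.code_b]
        assert set(qual) == {"I"}
    # truth table on disk equals the returned frame
    on_disk = pd.read_csv(tmp_path / "t.tsv", sep="\t")
    assert on_disk.equals(truth)


def test_read_error_fraction_closed_form(manifest, tmp_path):
    """At e=0.01, P(>=1 error in a 6-nt slot) = 1 - 0.99^6; observed matches."""
    cap = dd.simulate_capture(dd.GroundTruth(), dd.SelectionMode(), manifest, seed=6)
    n = 20000
    cfg = dd.SequencingConfig(depth=n, error_rate=0.01, seed=6)
    truth = dd.sequence_reads(cap, manifest, cfg, tmp_path / "r.fastq")
    seq_a = {c.code_id: c.sequence for c in manifest.codebook_a}
    sa, _ = cfg.layout.slots(manifest.code_length_a, manifest.code_length_b)
    errs = sum(
        seq[sa] != seq_a[row.code_a]
        for (t, seq, q), row in zip(_read_fastq(tmp_path / "r.fastq"), truth.itertuples(index=False))
    )
    p = 1 - 0.99 ** manifest.code_length_a
    assert abs(errs / n - p) < 5 * np.sqrt(p * (1 - p) / n)


def test_sequencing_zero_capture_is_error(manifest, tmp_path):
    zero = pd.Series(0, index=dd.simulate_capture(
        dd.GroundTruth(), dd.SelectionMode(), manifest, seed=0).index)
    with pytest.raises(ValueError, match="no molecules captured"):
        dd.sequence_reads(zero, manifest, dd.SequencingConfig(depth=10), tmp_path / "r.fastq")


def test_sequencing_depth_zero(manifest, tmp_path):
    cap = dd.simulate_capture(dd.GroundTruth(), dd.SelectionMode(), manifest, seed=0)
    truth = dd.sequence_reads(cap, manifest, dd.SequencingConfig(depth=0), tmp_path / "r.fastq")
    assert len(truth) == 0
    assert (tmp_path / "r.fastq").read_text() == ""


def test_pair_weights_sum_stereoisomers(manifest):
    cap = dd.simulate_capture(dd.GroundTruth(), dd.SelectionMode(), manifest, seed=8)
    w = pair_weights(cap)
    assert len(w) == manifest.n_pairs
    assert w.loc[("A1", "B1")] == cap.loc[("R", "A1", "B1")] + cap.loc[("S", "A1", "B1")]
    assert w.sum() == cap.sum()


def test_expected_count_monotone_in_fold(manifest, tmp_path):
    """Raising a member's fold never decreases its mean decoded count."""
    means = []
    for fold in (1.0, 5.0, 25.0, 125.0):
        counts = []
        for seed in (1, 2, 3):
            truth = dd.GroundTruth()
            if fold > 1:
                truth.plant("A3", "B5", fold)
            cap = dd.simulate_capture(truth, dd.SelectionMode(), manifest, seed=seed)
            cfg = dd.SequencingConfig(depth=5000, error_rate=0.0, seed=seed)
            tt = dd.sequence_reads(cap, manifest, cfg, tmp_path / "r.fastq")
            mat = dd.decode_fastq(tmp_path / "r.fastq", manifest, max_mismatch=0)
            counts.append(mat.counts[2, 4])  # A3 row, B5 column
        means.append(np.mean(counts))
    assert all(b >= a for a, b in zip(means, means[1:]))


# -- scenario presets ------------------------------------------------------

def test_unknown_scenario(manifest):
    with pytest.raises(ValueError, match="unknown scenario"):
        dd.scenario_presets("nope", manifest)


def test_unselected_preset(ref_manifest):
    sc = dd.scenario_presets("unselected", ref_manifest)
    assert sc.cfg.depth == 17_046_900
    assert sc.truth.fold == {}
    assert sc.sp_mode.mode == "SP"


def test_sp_selection_preset(ref_manifest):
    sc = dd.scenario_presets("sp_selection", ref_manifest)
    assert sc.cfg.depth == 232_900
    planted_pairs = {(a, b) for (_, a, b) in sc.truth.fold}
    assert 1 <= len(planted_pairs) <= 5
    assert sc.planted_pair in planted_pairs
    assert max(sc.truth.fold.values()) == 1000.0
    # folds planted on both stereoisomers (codes are shared)
    for (_, a, b), f in sc.truth.fold.items():
        assert sc.truth.fold[("R", a, b)] == sc.truth.fold[("S", a, b)] == f


def test_triplicate_preset(ref_manifest):
    sc = dd.scenario_presets("triplicate", ref_manifest, seed=10)
    assert sc.n_replicates == 3
    assert sc.replicate_seeds(10) == [10, 11, 12]


def test_dp_maturation_preset(ref_manifest):
    sc = dd.scenario_presets("dp_maturation", ref_manifest)
    assert sc.dp_mode is not None and sc.dp_mode.mode == "DP"
    (syn,) = sc.synergistic_pairs
    (ind,) = sc.independent_pairs
    # SP fold 3 boosted ~373x in DP -> DP-effective fold ~1119; independent
    # pair keeps fold 112 in both modes
    assert sc.truth.fold[("R", *syn)] == 3.0
    assert sc.truth.fold[("R", *ind)] == 112.0
    assert sc.dp_mode.hit_fold_multiplier[("R", *syn)] == 373.0
    assert ("R", *ind) not in sc.dp_mode.hit_fold_multiplier
    assert all(name in SCENARIO_NAMES for name in
               ("unselected", "sp_selection", "dp_maturation", "triplicate"))
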