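"""Recurrence scoring: G-scores, relocation null, q-values, regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from cnaconcord import (
    Chromosome,
    GenomeLayout,
    ProbeMap,
    SignificantRegion,
    arm_level,
    benjamini_hochberg,
    call_regions,
    classify_scope,
    gscore,
    marker_qvalues,
    permutation_null,
)
from cnaconcord.segmentation import MarkerLevelMatrix


def _ml(values, positions=None, chroms=None):
    values = np.asarray(values, float)
    n = values.shape[1]
    if positions is None:
        positions = np.arange(1, n + 1) * 1000
    if chroms is None:
        chroms = ["chr1"] * n
    pm = ProbeMap([f"m{i}" for i in range(n)], chroms, positions)
    return MarkerLevelMatrix(pm, [f"s{i}" for i in range(values.shape[0])], values)


def _uniform_segment_cohort(rng, n_samples=12, n_markers=400, n_segs=5):
    """Marker-level cohort whose aberrant segments sit at uniform random
    locations — matching the relocation null by construction."""
    v = np.zeros((n_samples, n_markers))
    for s in range(n_samples):
        for _ in range(n_segs):
            w = int(rng.integers(5, 30))
            start = int(rng.integers(0, n_markers - w))
            amp = float(rng.uniform(0.2, 1.0)) * (1 if rng.random() < 0.5 else -1)
            v[s, start : start + w] = amp
    return _ml(v)


# ---------------------------------------------------------------------------
# gscore
# ---------------------------------------------------------------------------

def test_gscore_formula_single_sample():
    track = gscore(_ml([[0.7, 0.05, -0.4]]), theta=0.1)
    np.testing.assert_allclose(track.g_amp, [0.6, 0.0, 0.0])
    np.testing.assert_allclose(track.g_del, [0.0, 0.0, 0.3])


def test_gscore_subthreshold_values_score_zero():
    rng = np.random.default_rng(0)
    track = gscore(_ml(rng.uniform(-0.09, 0.09, size=(5, 40))), theta=0.1)
    assert np.all(track.g_amp == 0.0)
    assert np.all(track.g_del == 0.0)


def test_gscore_additive_over_samples():
    rng = np.random.default_rng(1)
    v = rng.normal(scale=0.5, size=(6, 30))
    single = gscore(_ml(v), theta=0.1)
    doubled = gscore(_ml(np.vstack([v, v])), theta=0.1)
    np.testing.assert_allclose(doubled.g_amp, 2 * single.g_amp)
    np.testing.assert_allclose(doubled.g_del, 2 * single.g_del)


def test_gscore_monotone_in_theta():
    rng = np.random.default_rng(2)
    v = rng.normal(scale=0.5, size=(4, 50))
    lo = gscore(_ml(v), theta=0.1)
    hi = gscore(_ml(v), theta=0.3)
    assert np.all(hi.g_amp <= lo.g_amp)
    assert np.all(hi.g_del <= lo.g_del)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def test_null_degenerate_zero_offsets_reproduces_observed():
    rng = np.random.default_rng(3)
    ml = _uniform_segment_cohort(rng)
    track = gscore(ml, 0.1)
    null = permutation_null(ml, 0.1, n_perm=1,
                            offsets=np.zeros((1, len(ml.sample_ids)), dtype=int))
    np.testing.assert_allclose(np.sort(track.g_amp), null.null_amp)
    np.testing.assert_allclose(np.sort(track.g_del), null.null_del)


def test_null_shift_preserves_per_sample_value_multiset():
    rng = np.random.default_rng(4)
    ml = _uniform_segment_cohort(rng, n_samples=3)
    # one permutation, known offsets: reconstruct by hand and compare sums
    offs = np.array([[5, 17, 111]])
    null = permutation_null(ml, 0.1, n_perm=1, offsets=offs)
    amp = np.maximum(ml.values - 0.1, 0.0)
    manual = sum(np.roll(amp[s], int(offs[0, s])) for s in range(3))
    np.testing.assert_allclose(null.null_amp, np.sort(manual))
    # multiset conservation: pooled mass equals observed mass
    assert null.null_amp.sum() == pytest.approx(amp.sum())


def test_null_calibrated_on_uniformly_placed_segments():
    """When segment locations are uniform, observed G is itself a draw
    from the relocation null: its quantiles must sit where they should."""
    diffs = {("amp", 0.3): [], ("amp", 0.8): [], ("del", 0.3): [], ("del", 0.8): []}
    for seed in range(10):  # average out the cohort's own sampling noise
        rng = np.random.default_rng(seed)
        ml = _uniform_segment_cohort(rng, n_samples=15, n_markers=600)
        track = gscore(ml, 0.1)
        null = permutation_null(ml, 0.1, n_perm=100, seed=seed)
        for kind, g, null_g in (("amp", track.g_amp, null.null_amp),
                                ("del", track.g_del, null.null_del)):
            for t in (0.3, 0.8):
                diffs[(kind, t)].append(float(np.mean(g >= t)) - float(np.mean(null_g >= t)))
    for key, d in diffs.items():
        assert abs(np.mean(d)) < 0.08, (key, np.mean(d))


def test_null_deterministic_given_seed():
    rng = np.random.default_rng(7)
    ml = _uniform_segment_cohort(rng, n_samples=4, n_markers=100)
    a = permutation_null(ml, 0.1, 100, seed=9)
    b = permutation_null(ml, 0.1, 100, seed=9)
    np.testing.assert_array_equal(a.null_amp, b.null_amp)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_bh_hand_example():
    q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])


@given(seed=st.integers(0, 10_000), n=st.integers(1, 200))
@settings(max_examples=30)
def test_bh_matches_statsmodels(seed, n):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(benjamini_hochberg(p), ref, rtol=1e-12)


def test_bh_monotone_in_p_after_sorting():
    rng = np.random.default_rng(11)
    p = rng.uniform(size=50)
    q = benjamini_hochberg(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= 0)


def test_marker_qvalues_constant_track_all_equal():
    ml = _ml(np.full((3, 20), 0.5))
    track = gscore(ml, 0.1)
    null = permutation_null(ml, 0.1, 100, seed=0)
    q = marker_qvalues(track, null)
    assert np.all(q.q_amp == q.q_amp[0])


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def _call(ml, q_threshold=0.25, n_perm=100, layout=None, peel_off=False):
    track = gscore(ml, 0.1)
    null = permutation_null(ml, 0.1, n_perm, seed=13)
    q = marker_qvalues(track, null)
    return call_regions(track, q, q_threshold, ml.probe_map,
                        peel_off=peel_off, m=ml, null=null, layout=layout)


def test_call_regions_two_disjoint_events_two_regions():
    v = np.zeros((10, 300))
    v[:6, 50:60] = 1.0  # recurrent in 6/10
    v[:6, 200:215] = 1.2
    regs = _call(_ml(v))
    amps = [r for r in regs if r.kind == "amp"]
    assert len(amps) == 2
    assert amps[0].region_end_bp < amps[1].region_start_bp
    for r in amps:
        assert r.q <= 0.25
        assert r.peak_start_bp >= r.region_start_bp
        assert r.peak_end_bp <= r.region_end_bp


def test_call_regions_all_insignificant_empty():
    rng = np.random.default_rng(17)
    ml = _uniform_segment_cohort(rng, n_samples=4, n_segs=2)
    track = gscore(ml, 0.1)
    null = permutation_null(ml, 0.1, 100, seed=1)
    q = marker_qvalues(track, null)
    assert call_regions(track, q, 1e-6, ml.probe_map, peel_off=False) == []


def test_peel_off_reveals_secondary_peak():
    """Two distinct carrier groups at nearby loci inside one significant
    run: peel-off must emit a second peak after removing the first."""
    v = np.zeros((20, 200))
    v[:8, 80:100] = 1.0  # group A
    v[8:14, 100:120] = 0.9  # group B, adjacent so the q-run is contiguous
    ml = _ml(v)
    no_peel = _call(ml, peel_off=False)
    peel = _call(ml, peel_off=True)
    amps_no = [r for r in no_peel if r.kind == "amp"]
    amps = [r for r in peel if r.kind == "amp"]
    assert len(amps) > len(amps_no)
    peaks = {(r.peak_start_bp, r.peak_end_bp) for r in amps}
    assert len(peaks) >= 2


# ---------------------------------------------------------------------------
# scope classification
# ---------------------------------------------------------------------------

def _region(start, end, chrom="chr1"):
    return SignificantRegion("amp", chrom, start, end, start, end, 0.01, 1.0, None, 10)


def test_classify_scope_quarter_arm_rule():
    layout = GenomeLayout([Chromosome("chr1", 1000, 400)])
    # p arm = [1, 400]: 25% = 100 bp
    assert classify_scope(_region(1, 80), layout) == "focal"  # 20%
    assert classify_scope(_region(1, 100), layout) == "focal"  # exactly 25%
    assert classify_scope(_region(1, 104), layout) == "broad"  # 26%
    # q arm = [401, 1000], 600 bp: region of 150 = 25%
    assert classify_scope(_region(401, 550), layout) == "focal"
    assert classify_scope(_region(401, 556), layout) == "broad"


def test_classify_scope_centromere_spanning_uses_longer_overlap_arm():
    layout = GenomeLayout([Chromosome("chr1", 1000, 400)])
    # 300 bp on p, 10 bp on q -> classified against p (300 > 100 -> broad)
    assert classify_scope(_region(101, 410), layout) == "broad"
    # 30 bp on p, 20 bp on q -> p arm, 50 bp clipped to 30 <= 100 -> focal
    assert classify_scope(_region(371, 420), layout) == "focal"


# ---------------------------------------------------------------------------
# arm level
# ---------------------------------------------------------------------------

def test_arm_level_whole_arm_gain_frequency():
    layout = GenomeLayout([Chromosome("chr1", 100_000, 40_000)])
    pos = np.arange(1, 101) * 1000  # 40 markers on p, 60 on q
    v = np.zeros((10, 100))
    v[:5, :40] = 1.0  # p arm gained in half the samples
    pm = ProbeMap([f"m{i}" for i in range(100)], ["chr1"] * 100, pos)
    ml = MarkerLevelMatrix(pm, [f"s{i}" for i in range(10)], v)
    arms = arm_level(ml, layout, theta=0.1, n_perm=100, seed=0)
    byarm = {a.arm: a for a in arms}
    assert byarm["1p"].gain_freq == pytest.approx(0.5)
    assert byarm["1p"].loss_freq == 0.0
    for a in arms:
        assert a.gain_freq + a.loss_freq <= 1.0


def test_arm_level_null_cohort_rarely_significant():
    layout = GenomeLayout([Chromosome("chr1", 500_000, 200_000),
                           Chromosome("chr2", 400_000, 180_000)])
    pos = np.concatenate([np.arange(1, 251) * 2000, np.arange(1, 201) * 2000])
    chroms = ["chr1"] * 250 + ["chr2"] * 200
    pm = ProbeMap([f"m{i}" for i in range(450)], chroms, pos)
    clean = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        v = np.zeros((12, 450))
        for s in range(12):
            # focal-scale segments: far below half an arm, so arm-level
            # medians stay diploid and this is a true arm-level null
            for _ in range(4):
                w = int(rng.integers(5, 25))
                start = int(rng.integers(0, 450 - w))
                v[s, start : start + w] = rng.uniform(0.2, 0.8) * rng.choice([-1, 1])
        ml = MarkerLevelMatrix(pm, [f"s{i}" for i in range(12)], v)
        arms = arm_level(ml, layout, theta=0.1, n_perm=100, seed=seed)
        if all(a.q_gain > 0.25 and a.q_loss > 0.25 for a in arms):
            clean += 1
    assert clean >= 18


def test_empty_arm_skipped():
    layout = GenomeLayout([Chromosome("chr1", 100_000, 90_000)])
    pos = np.arange(1, 41) * 1000  # all markers on the p arm
    pm = ProbeMap([f"m{i}" for i in range(40)], ["chr1"] * 40, pos)
    ml = MarkerLevelMatrix(pm, ["s0", "s1"], np.zeros((2, 40)))
    arms = arm_level(ml, layout, theta=0.1, n_perm=100, seed=0)
    assert [a.arm for a in arms] == ["1p"]
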