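"""Segmentation engines vs independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cnaconcord import (
    CNMatrix,
    CohortSpec,
    PipelineParams,
    ProbeMap,
    TruthEvent,
    cbs_max_arc,
    cbs_segment,
    default_layout,
    pcf_cost,
    pcf_segment,
    segment_cohort,
    simulate_cohort,
    to_marker_level,
)
from cnaconcord.segmentation import winsorize

MB = 1_000_000


# ---------------------------------------------------------------------------
# independent oracles (plain Python, no package kernels)
# ---------------------------------------------------------------------------

def arc_scan_oracle(x):
    """Exhaustive double loop over arcs with the pooled two-sample t."""
    x = np.asarray(x, float)
    n = len(x)
    best = None
    for i in range(n - 1):
        for j in range(i + 2, n + 1):
            if n - (j - i) < 2:
                continue
            a = x[i:j]
            b = np.concatenate([x[:i], x[j:]])
            ssa = ((a - a.mean()) ** 2).sum()
            ssb = ((b - b.mean()) ** 2).sum()
            sp2 = (ssa + ssb) / (n - 2)
            d = a.mean() - b.mean()
            if sp2 <= 1e-13 * max(1.0, (x ** 2).sum()):
                t = 0.0 if d == 0 else np.inf
            else:
                t = abs(d) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
            if best is None or t > best[2]:
                best = (i, j, t)
    return best


def pcf_enumeration_oracle(x, gamma, kmin):
    """Enumerate every admissible segmentation; rank by (cost, n_segments,
    breakpoint vector)."""
    x = np.asarray(x, float)
    n = len(x)
    best = None
    for k in range(0, n // kmin):
        for bps in itertools.combinations(range(kmin, n - kmin + 1), k):
            edges = (0,) + bps + (n,)
            if any(b - a < kmin for a, b in zip(edges, edges[1:])):
                continue
            cost = pcf_cost(x, list(bps), gamma)
            key = (cost, len(bps), bps)
            if best is None or key < best:
                best = key
    return best


# ---------------------------------------------------------------------------
# cbs_max_arc
# ---------------------------------------------------------------------------

def test_max_arc_step_example():
    arc = cbs_max_arc(np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0.0]))
    assert (arc.i, arc.j) == (4, 8)


def test_max_arc_constant_vector_scores_zero():
    arc = cbs_max_arc(np.full(20, 3.7))
    assert arc.t == 0.0


def test_max_arc_location_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    a = cbs_max_arc(x)
    b = cbs_max_arc(x + 17.5)
    assert (a.i, a.j) == (b.i, b.j)
    assert a.t == pytest.approx(b.t, rel=1e-9)


def test_max_arc_short_vector_sentinel():
    arc = cbs_max_arc(np.array([1.0, 2.0, 3.0]))
    assert arc.t == 0.0


@given(seed=st.integers(0, 10_000), n=st.integers(6, 40))
@settings(max_examples=30)
def test_max_arc_matches_exhaustive_oracle(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    got = cbs_max_arc(x)
    i, j, t = arc_scan_oracle(x)
    assert (got.i, got.j) == (i, j)
    assert got.t == pytest.approx(t, rel=1e-6)


def test_pooled_t_matches_scipy():
    rng = np.random.default_rng(3)
    x = rng.normal(size=25)
    arc = cbs_max_arc(x)
    a = x[arc.i : arc.j]
    b = np.concatenate([x[: arc.i], x[arc.j :]])
    t_ref = stats.ttest_ind(a, b, equal_var=True).statistic
    assert arc.t == pytest.approx(abs(t_ref), rel=1e-9)


# ---------------------------------------------------------------------------
# cbs_segment
# ---------------------------------------------------------------------------

def test_cbs_noiseless_step_single_breakpoint():
    x = np.zeros(40)
    x[20:] = 1.0
    assert cbs_segment(x, alpha=0.01, n_perm=100, seed=0) == [20]


def test_cbs_constant_vector_never_splits():
    x = np.full(60, 0.5)
    for alpha in (0.01, 0.5, 1.0):
        assert cbs_segment(x, alpha=alpha, n_perm=100, seed=0) == []


def test_cbs_alpha_one_splits_to_min_width_exhaustion():
    rng = np.random.default_rng(4)
    x = rng.normal(size=64)
    bps = cbs_segment(x, alpha=1.0, n_perm=100, seed=0)
    assert bps  # noise alone splits when every split is accepted
    edges = [0] + bps + [64]
    widths = np.diff(edges)
    assert widths.min() >= 2
    # every remaining window is too short to split further
    assert all(w < 4 for w in widths)


def test_cbs_breakpoints_nested_in_alpha():
    """Raising alpha can only add breakpoints (same seed)."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=300)
    x[100:140] += 0.8
    grids = [0.005, 0.01, 0.02, 0.05]
    sets = [set(cbs_segment(x, alpha=a, n_perm=200, seed=5)) for a in grids]
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger


def test_cbs_deterministic_given_seed():
    rng = np.random.default_rng(1)
    x = rng.normal(size=120)
    x[50:70] += 1.0
    a = cbs_segment(x, alpha=0.05, n_perm=200, seed=3)
    b = cbs_segment(x, alpha=0.05, n_perm=200, seed=3)
    assert a == b


# ---------------------------------------------------------------------------
# pcf
# ---------------------------------------------------------------------------

def test_pcf_cost_examples():
    x = np.array([1.0, 1.0, 5.0, 5.0])
    assert pcf_cost(x, [2], 3.0) == pytest.approx(3.0)
    assert pcf_cost(x, [], 12345.0) == pytest.approx(16.0)  # mean 3, +-2 x 4
    with pytest.raises(ValueError):
        pcf_cost(x, [0], 1.0)
    with pytest.raises(ValueError):
        pcf_cost(x, [4], 1.0)


def test_pcf_cost_monotone_in_gamma():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    costs = [pcf_cost(x, [5, 10], g) for g in (0.0, 1.0, 2.0, 10.0)]
    assert costs == sorted(costs)


def test_pcf_segment_examples():
    assert pcf_segment(np.array([1.0, 1.0, 5.0, 5.0]), gamma=3.0, kmin=2) == [2]
    rng = np.random.default_rng(0)
    assert pcf_segment(rng.normal(size=50), gamma=1e6, kmin=2) == []


def test_pcf_tie_prefers_fewer_segments():
    # splitting saves exactly gamma: no-split SSE 1.0, split cost gamma=1.0
    x = np.array([0.0, 0.0, 1.0, 1.0])
    assert pcf_segment(x, gamma=1.0, kmin=2) == []


@given(
    seed=st.integers(0, 10_000),
    n=st.integers(5, 12),
    kmin=st.integers(1, 3),
    gamma=st.floats(0.0, 5.0),
)
@settings(max_examples=40)
def test_pcf_matches_enumeration_oracle(seed, n, kmin, gamma):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    got = pcf_segment(x, gamma=gamma, kmin=kmin)
    cost_best, _, _ = pcf_enumeration_oracle(x, gamma, kmin)
    assert pcf_cost(x, got, gamma) == pytest.approx(cost_best, abs=1e-9)


def test_pcf_breakpoint_count_nonincreasing_in_gamma():
    rng = np.random.default_rng(2)
    x = rng.normal(size=300, scale=0.25)
    x[60:100] += 1.0
    x[200:230] -= 0.8
    counts = [len(pcf_segment(x, gamma=g, kmin=5)) for g in (0.5, 1.0, 2.5, 6.0, 14.0, 25.0)]
    assert counts == sorted(counts, reverse=True)


def test_pcf_location_invariance():
    rng = np.random.default_rng(5)
    x = rng.normal(size=80)
    x[30:50] += 1.0
    assert pcf_segment(x, 2.0, 5) == pcf_segment(x + 100.0, 2.0, 5)


# ---------------------------------------------------------------------------
# cohort-level
# ---------------------------------------------------------------------------

def _toy_cohort(values):
    values = np.asarray(values, float)
    n = values.shape[1]
    pm = ProbeMap([f"m{i}" for i in range(n)], ["chr1"] * n,
                  np.arange(1, n + 1) * 1000)
    return CNMatrix(pm, [f"s{i}" for i in range(values.shape[0])], values)


def test_segment_cohort_noiseless_step_both_methods_agree():
    row = np.zeros(60)
    row[25:40] = 1.0
    m = _toy_cohort([row, row])
    params = PipelineParams(alpha=0.01, gamma=1.0, kmin=2, n_perm_cbs=200, seed=0)
    got = {}
    for method in ("cbs", "pcf"):
        segs = segment_cohort(m, method, params)
        got[method] = sorted(
            {(s.sample_id, s.start_marker, s.end_marker) for s in segs.segments}
        )
    assert got["cbs"] == got["pcf"]
    starts = {s for (_, s, _) in got["cbs"]}
    assert starts == {0, 25, 40}


def test_segment_cohort_constant_yields_single_segments():
    m = _toy_cohort(np.full((3, 30), 0.2))
    for method in ("cbs", "pcf"):
        segs = segment_cohort(m, method, PipelineParams(n_perm_cbs=100, seed=0))
        assert len(segs.segments) == 3
        assert all(s.n_markers == 30 for s in segs.segments)


@given(seed=st.integers(0, 5000))
@settings(max_examples=10)
def test_segment_cohort_partition_audit_on_random_cohorts(seed):
    layout = default_layout(2)
    spec = CohortSpec(
        layout=layout, n_samples=3, n_markers_per_chrom=60, noise_sd=0.3,
        events=[TruthEvent("focal_amp", "chr1", 40 * MB, 60 * MB, 1.0, 0.5)],
        seed=seed,
    )
    m, _ = simulate_cohort(spec)
    params = PipelineParams(alpha=0.05, gamma=2.5, n_perm_cbs=100, seed=seed)
    for method in ("cbs", "pcf"):
        segs = segment_cohort(m, method, params)
        segs.audit(m.probe_map, matrix=m)  # partition + exact means


def test_segment_cohort_imputes_nan():
    vals = np.full((2, 30), 0.1)
    vals[0, 5] = np.nan
    m = _toy_cohort(vals)
    segs = segment_cohort(m, "pcf", PipelineParams(seed=0))
    assert all(np.isfinite(s.mean) for s in segs.segments)


def test_to_marker_level_projection_and_conservation():
    row = np.concatenate([np.full(10, 0.7), np.full(20, -0.1)])
    m = _toy_cohort([row])
    segs = segment_cohort(m, "pcf", PipelineParams(gamma=0.5, kmin=2, seed=0))
    ml = to_marker_level(segs, m.probe_map)
    assert np.all(ml.values[0, :10] == pytest.approx(0.7))
    # conservation: marker-level sum equals sum of mean * n_markers
    total = sum(s.mean * s.n_markers for s in segs.segments)
    assert ml.values.sum() == pytest.approx(total)
    # round-trip: recomputing segment means from marker level is exact
    for s in segs.segments:
        assert ml.values[0, s.start_marker : s.end_marker].mean() == pytest.approx(s.mean)


def test_winsorize_clips_outliers():
    x = np.zeros(50)
    x[10] = 10.0
    w = winsorize(x)
    assert w[10] < 10.0
    assert np.all(w[np.arange(50) != 10] == 0.0)
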