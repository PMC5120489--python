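"""Recurrence analysis of segmented copy-number data.

Per-marker G-scores combine aberration amplitude and cross-sample
frequency: each sample contributes its excess over the call threshold,
``(v - theta)+`` for gains and ``(-v - theta)+`` for losses, summed over
samples. Significance comes from a segment-relocation permutation null —
each sample's genome-wide marker-level vector is circularly shifted by an
independent uniform offset, preserving segment lengths and values while
randomizing their locations — pooled over markers and permutations, with
Benjamini-Hochberg FDR control across markers. Maximal runs of
significant markers become regions; the maximal-G run inside a region is
its peak; peel-off optionally removes the segments explaining a peak and
re-tests the region for secondary peaks. Regions are classified focal
(span <= ``focal_fraction`` of their chromosome arm) or broad, and a
separate arm-level test compares per-arm gain/loss frequencies to the
same relocation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core_io import GenomeLayout, ProbeMap
from .segmentation import MarkerLevelMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GScoreTrack",
    "PermutationNull",
    "MarkerQValues",
    "SignificantRegion",
    "ArmSummary",
    "gscore",
    "permutation_null",
    "benjamini_hochberg",
    "marker_qvalues",
    "call_regions",
    "classify_scope",
    "arm_level",
    "region_to_dict",
    "region_from_dict",
]


@dataclass
class GScoreTrack:
    probe_map: ProbeMap
    g_amp: np.ndarray  # per-marker, nonnegative
    g_del: np.ndarray
    theta: float


@dataclass
class PermutationNull:
    """Pooled empirical null of per-marker G (sorted ascending)."""

    null_amp: np.ndarray
    null_del: np.ndarray
    n_perm: int
    theta: float


@dataclass
class MarkerQValues:
    p_amp: np.ndarray
    p_del: np.ndarray
    q_amp: np.ndarray
    q_del: np.ndarray


@dataclass
class SignificantRegion:
    kind: str  # amp | del
    chrom: str
    region_start_bp: int
    region_end_bp: int
    peak_start_bp: int
    peak_end_bp: int
    q: float
    g_peak: float
    scope: str | None  # focal | broad (None when no layout was supplied)
    n_markers: int


@dataclass
class ArmSummary:
    arm: str  # e.g. "8q"
    gain_freq: float
    loss_freq: float
    q_gain: float
    q_loss: float


def _excess(values: np.ndarray, theta: float) -> tuple[np.ndarray, np.ndarray]:
    amp = np.maximum(values - theta, 0.0)
    dele = np.maximum(-values - theta, 0.0)
    return amp, dele


def gscore(m: MarkerLevelMatrix, theta: float) -> GScoreTrack:
    """G(i) = sum over samples of the threshold excess at marker i."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    amp, dele = _excess(m.values, theta)
    return GScoreTrack(m.probe_map, amp.sum(axis=0), dele.sum(axis=0), theta)


def permutation_null(
    m: MarkerLevelMatrix,
    theta: float,
    n_perm: int,
    seed: int | tuple = 0,
    offsets: np.ndarray | None = None,
) -> PermutationNull:
    """Segment-relocation null: per permutation, circularly shift each
    sample's genome-wide vector by an independent uniform offset and
    recompute G; pool G over all markers x permutations.

    ``offsets`` (n_perm x n_samples) overrides the random offsets — used
    to pin degenerate cases in tests.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if offsets is None and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_s, n_m = m.values.shape
    rng = np.random.default_rng(seed)
    if offsets is None:
        offsets = rng.integers(0, n_m, size=(n_perm, n_s))
    offsets = np.asarray(offsets)
    if offsets.shape != (n_perm, n_s):
        raise ValueError("offsets must have shape (n_perm, n_samples)")
    amp, dele = _excess(m.values, theta)  # shifting v commutes with the excess
    null_amp = np.empty((n_perm, n_m))
    null_del = np.empty((n_perm, n_m))
    for p in range(n_perm):
        ga = np.zeros(n_m)
        gd = np.zeros(n_m)
        for s in range(n_s):
            off = int(offsets[p, s]) % n_m
            ga += np.roll(amp[s], off)
            gd += np.roll(dele[s], off)
        null_amp[p] = ga
        null_del[p] = gd
    return PermutationNull(
        np.sort(null_amp.ravel()), np.sort(null_del.ravel()), n_perm, theta
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


def _empirical_p(g: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    n = null_sorted.size
    ge = n - np.searchsorted(null_sorted, g, side="left")
    return (1.0 + ge) / (1.0 + n)


def marker_qvalues(track: GScoreTrack, null: PermutationNull) -> MarkerQValues:
    """Empirical p per marker against the pooled null, BH per kind."""
    if null.null_amp.size == 0 or null.null_del.size == 0:
        raise ValueError("empty permutation null")
    p_amp = _empirical_p(track.g_amp, null.null_amp)
    p_del = _empirical_p(track.g_del, null.null_del)
    return MarkerQValues(p_amp, p_del, benjamini_hochberg(p_amp), benjamini_hochberg(p_del))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _peak_run(g: np.ndarray, a: int, b: int) -> tuple[int, int]:
    """Contiguous run of markers attaining max G inside [a, b)."""
    seg = g[a:b]
    k = a + int(np.argmax(seg))
    gmax = g[k]
    lo = k
    while lo > a and g[lo - 1] == gmax:
        lo -= 1
    hi = k + 1
    while hi < b and g[hi] == gmax:
        hi += 1
    return lo, hi


def _segment_run(row: np.ndarray, k: int, a: int, b: int) -> tuple[int, int]:
    """Run of identical values around marker k within [a, b) — the piece
    of the sample's segment visible inside the window."""
    v = row[k]
    lo = k
    while lo > a and row[lo - 1] == v:
        lo -= 1
    hi = k + 1
    while hi < b and row[hi] == v:
        hi += 1
    return lo, hi


def call_regions(
    track: GScoreTrack,
    qvals: MarkerQValues,
    q_threshold: float,
    pm: ProbeMap,
    peel_off: bool = True,
    m: MarkerLevelMatrix | None = None,
    null: PermutationNull | None = None,
    layout: GenomeLayout | None = None,
    focal_fraction: float = 0.25,
    max_peel: int = 5,
) -> list[SignificantRegion]:
    """Call significant regions and their peaks per kind.

    Maximal runs of markers with q <= ``q_threshold`` (within one
    chromosome) become regions; the maximal-G run inside each region is
    its peak. With ``peel_off`` (requires ``m`` and ``null``), the
    segments of the samples explaining a peak are removed, G is
    recomputed inside the region against the same null, and secondary
    peaks are emitted while significance persists *at the genome-wide
    level* — a peeled marker must still beat the largest empirical p
    that Benjamini-Hochberg accepted genome-wide for that kind (at most
    ``max_peel`` secondary peaks per region).
    """
    regions: list[SignificantRegion] = []
    for kind, g, p, q in (
        ("amp", track.g_amp, qvals.p_amp, qvals.q_amp),
        ("del", track.g_del, qvals.p_del, qvals.q_del),
    ):
        sig_mask = q <= q_threshold
        p_cut = float(p[sig_mask].max()) if sig_mask.any() else 0.0
        for chrom in pm.chrom_names:
            lo, hi = pm.chrom_slice(chrom)
            for a, b in _runs(sig_mask[lo:hi]):
                a += lo
                b += lo
                pa, pb = _peak_run(g, a, b)
                first = SignificantRegion(
                    kind=kind,
                    chrom=chrom,
                    region_start_bp=int(pm.pos[a]),
                    region_end_bp=int(pm.pos[b - 1]),
                    peak_start_bp=int(pm.pos[pa]),
                    peak_end_bp=int(pm.pos[pb - 1]),
                    q=float(np.min(q[pa:pb])),
                    g_peak=float(g[pa:pb].max()),
                    scope=None,
                    n_markers=b - a,
                )
                regions.append(first)
                if peel_off and m is not None and null is not None:
                    regions.extend(
                        _peel(first, kind, m, null, p_cut, q, pm, a, b, pa, pb, max_peel)
                    )
    if layout is not None:
        for r in regions:
            r.scope = classify_scope(r, layout, focal_fraction)
    regions.sort(key=lambda r: (r.kind, list(pm.chrom_names).index(r.chrom), r.region_start_bp))
    return regions


def _peel(
    region: SignificantRegion,
    kind: str,
    m: MarkerLevelMatrix,
    null: PermutationNull,
    p_cut: float,
    q_genome: np.ndarray,
    pm: ProbeMap,
    a: int,
    b: int,
    pa: int,
    pb: int,
    max_peel: int,
) -> list[SignificantRegion]:
    sign = 1.0 if kind == "amp" else -1.0
    null_sorted = null.null_amp if kind == "amp" else null.null_del
    theta = null.theta
    V = (sign * m.values[:, a:b]).copy()  # oriented window copy
    extra: list[SignificantRegion] = []
    cur = (pa - a, pb - a)
    for _ in range(max_peel):
        # remove the segments of samples supporting the current peak
        k = cur[0] + int(np.argmax(np.maximum(V[:, cur[0] : cur[1]] - theta, 0.0).sum(axis=0)))
        for s in range(V.shape[0]):
            if V[s, k] > theta:
                lo_s, hi_s = _segment_run(V[s], k, 0, b - a)
                V[s, lo_s:hi_s] = 0.0
        g = np.maximum(V - theta, 0.0).sum(axis=0)
        p = _empirical_p(g, null_sorted)
        sig = p <= p_cut  # significance persists at the genome-wide level
        if not sig.any():
            break
        # secondary peak: maximal-G run around the best remaining
        # significant marker
        best = int(np.flatnonzero(sig)[np.argmax(g[sig])])
        run_a, run_b = best, best + 1
        while run_a > 0 and sig[run_a - 1]:
            run_a -= 1
        while run_b < sig.size and sig[run_b]:
            run_b += 1
        pa2, pb2 = _peak_run(g, run_a, run_b)
        extra.append(
            replace(
                region,
                peak_start_bp=int(pm.pos[a + pa2]),
                peak_end_bp=int(pm.pos[a + pb2 - 1]),
                q=float(q_genome[a + pa2 : a + pb2].min()),
                g_peak=float(g[pa2:pb2].max()),
            )
        )
        cur = (pa2, pb2)
    return extra


def classify_scope(
    r: SignificantRegion, layout: GenomeLayout, focal_fraction: float = 0.25
) -> str:
    """Focal iff the region (clipped to its arm) spans no more than
    ``focal_fraction`` of the containing chromosome arm.

    A region spanning the centromere is classified against the arm with
    the longer overlap (warning logged).
    """
    c = layout[r.chrom]
    cen = c.centromere
    if r.region_start_bp <= cen < r.region_end_bp:
        p_ov = cen - r.region_start_bp + 1
        q_ov = r.region_end_bp - cen
        arm = "p" if p_ov >= q_ov else "q"
        log.warning(
            "region %s:%d-%d spans the centromere; classified against arm %s",
            r.chrom,
            r.region_start_bp,
            r.region_end_bp,
            arm,
        )
    else:
        arm = layout.arm_of(r.chrom, (r.region_start_bp + r.region_end_bp) // 2)
    a, b = layout.arm_bounds(r.chrom, arm)
    clipped = min(r.region_end_bp, b) - max(r.region_start_bp, a) + 1
    return "focal" if clipped <= focal_fraction * (b - a + 1) else "broad"


def _arm_marker_weights(pm: ProbeMap, chrom: str, a: int, b: int) -> tuple[slice, np.ndarray]:
    """Markers inside arm [a, b] and the bp extent each one represents
    (midpoint rule, clipped to the arm)."""
    lo, hi = pm.chrom_slice(chrom)
    pos = pm.pos[lo:hi]
    inside = np.nonzero((pos >= a) & (pos <= b))[0]
    if inside.size == 0:
        return slice(0, 0), np.empty(0)
    i0, i1 = inside[0], inside[-1] + 1
    p = pos[i0:i1].astype(np.float64)
    left = np.empty(p.size)
    right = np.empty(p.size)
    left[0] = a
    left[1:] = (p[:-1] + p[1:]) / 2.0
    right[-1] = b
    right[:-1] = (p[:-1] + p[1:]) / 2.0
    return slice(lo + i0, lo + i1), right - left


def _weighted_median(v: np.ndarray, w: np.ndarray) -> float:
    o = np.argsort(v, kind="stable")
    cw = np.cumsum(w[o])
    k = int(np.searchsorted(cw, 0.5 * cw[-1], side="left"))
    return float(v[o][min(k, v.size - 1)])


def arm_level(
    m: MarkerLevelMatrix,
    layout: GenomeLayout,
    theta: float,
    n_perm: int,
    seed: int | tuple = 0,
) -> list[ArmSummary]:
    """Arm-level (broad) significance.

    A sample-arm is called gained (lost) iff the bp-length-weighted
    median of its marker-level values is > theta (< -theta). Observed
    per-arm frequencies are compared with the frequencies obtained under
    the same genome-wide circular-shift permutations:
    p = (1 + #{null freq >= observed}) / (1 + n_perm), BH-adjusted
    across arms x {gain, loss}. Arms without markers are skipped.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pm = m.probe_map
    n_s, n_m = m.values.shape
    arms = []
    for chrom, arm, a, b in layout.arms():
        if chrom not in pm.chrom_names:
            continue
        sl, w = _arm_marker_weights(pm, chrom, a, b)
        if w.size == 0:
            log.warning("arm %s%s contains no markers; skipped", chrom, arm)
            continue
        arms.append((layout.arm_id(chrom, arm), sl, w))

    def freqs(values: np.ndarray) -> np.ndarray:
        out = np.empty((len(arms), 2))
        for k, (_, sl, w) in enumerate(arms):
            med = np.array([_weighted_median(values[s, sl], w) for s in range(n_s)])
            out[k, 0] = np.mean(med > theta)
            out[k, 1] = np.mean(med < -theta)
        return out

    obs = freqs(m.values)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((len(arms), 2))
    shifted = np.empty_like(m.values)
    for _ in range(n_perm):
        offs = rng.integers(0, n_m, size=n_s)
        for s in range(n_s):
            shifted[s] = np.roll(m.values[s], int(offs[s]))
        exceed += freqs(shifted) >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = benjamini_hochberg(p.ravel()).reshape(p.shape)
    return [
        ArmSummary(
            arm=arms[k][0],
            gain_freq=float(obs[k, 0]),
            loss_freq=float(obs[k, 1]),
            q_gain=float(q[k, 0]),
            q_loss=float(q[k, 1]),
        )
        for k in range(len(arms))
    ]


# ---------------------------------------------------------------------------
# (de)serialization for the CLI / cross-cohort comparison
# ---------------------------------------------------------------------------

def region_to_dict(r: SignificantRegion) -> dict:
    return {
        "kind": r.kind,
        "chrom": r.chrom,
        "region_start_bp": r.region_start_bp,
        "region_end_bp": r.region_end_bp,
        "peak_start_bp": r.peak_start_bp,
        "peak_end_bp": r.peak_end_bp,
        "q": r.q,
        "g_peak": r.g_peak,
        "scope": r.scope,
        "n_markers": r.n_markers,
    }


def region_from_dict(d: dict) -> SignificantRegion:
    return SignificantRegion(**d)
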