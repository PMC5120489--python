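"""Two independent segmentation engines for marker-level log2 ratios.

**CBS** (circular binary segmentation): recursively finds the arc of the
chromosome maximizing the pooled two-sample t-statistic between the arc
and its complement, accepts the split when a full-permutation p-value is
at most ``alpha``, and recurses into the resulting sub-windows. The
circular statistic is evaluated on the linear window — the arc is an
interior interval; wrap-around arcs are covered by the complement and
need no separate enumeration. No hybrid tail approximation and no
post-hoc pruning are applied: the permutation test is exact (with early
termination only once the exceedance count already forces p > alpha,
which cannot change the decision).

**PCF** (piecewise constant fit): the exact global minimizer of the sum
of within-segment squared deviations plus ``gamma`` per breakpoint,
subject to a minimum segment length ``kmin``, via O(n^2) dynamic
programming. Ties resolve to fewer segments, then the lexicographically
smallest breakpoint vector.

Determinism: each CBS recursion window draws its permutations from an
RNG stream keyed on (seed, window bounds). Decisions on a given window
therefore do not depend on alpha-dependent early stopping elsewhere,
which makes the breakpoint set exactly nested in alpha: raising alpha
can only add breakpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import max_arc_crit, max_arc_full, pcf_dp
from .core_io import CNMatrix, PipelineParams, ProbeMap, Segment, SegmentSet

log = logging.getLogger(__name__)

__all__ = [
    "ArcStat",
    "MarkerLevelMatrix",
    "cbs_max_arc",
    "cbs_segment",
    "pcf_cost",
    "pcf_segment",
    "segment_cohort",
    "to_marker_level",
    "winsorize",
]


@dataclass(frozen=True)
class ArcStat:
    """Best arc (i, j] (half-open marker indices into the window) with
    its max |t|; ``p`` is filled by the permutation test when run."""

    i: int
    j: int
    t: float
    p: float | None = None


@dataclass
class MarkerLevelMatrix:
    """samples x markers matrix where each marker carries the mean of
    its enclosing segment — the input contract of recurrence scoring."""

    probe_map: ProbeMap
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), self.probe_map.n_markers):
            raise ValueError("marker-level matrix shape mismatch")


def cbs_max_arc(x: np.ndarray) -> ArcStat:
    """Exhaustive max-|t| arc of ``x``; min width 2 on arc and complement.

    Returns a no-split sentinel (t=0 over the first admissible arc) for
    vectors shorter than 4 markers or with zero pooled variance.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < 4:
        return ArcStat(0, min(2, x.size), 0.0)
    i, j, _, t = max_arc_full(x, 1)
    return ArcStat(int(i), int(j), float(t))


def _window_rng(seed, lo: int, hi: int) -> np.random.Generator:
    if isinstance(seed, (tuple, list)):
        key = [int(v) for v in seed] + [lo, hi]
    else:
        key = [int(seed), lo, hi]
    return np.random.default_rng(key)


def cbs_segment(
    x: np.ndarray,
    alpha: float,
    n_perm: int = 1000,
    seed: int | tuple = 0,
    min_width: int = 2,
) -> list[int]:
    """Recursive CBS on one vector; returns sorted interior breakpoints.

    p = (1 + #{permuted max |t| >= observed}) / (1 + n_perm); the split
    is accepted when p <= alpha and the arc boundaries interior to the
    current window become breakpoints.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.size
    breakpoints: list[int] = []
    # exceedance count that already forces p > alpha
    stop_count = int(np.floor(alpha * (1 + n_perm)))

    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 4 or m < 2 * min_width:
            continue
        w = x[lo:hi]
        i, j, crit, t = max_arc_full(w, min_width)
        if t <= 0.0:
            continue
        if alpha < 1.0:  # at alpha = 1 every nonzero-t split is accepted
            rng = _window_rng(seed, lo, hi)
            exceed = 0
            for _ in range(n_perm):
                # max |t| comparison via the monotone split criterion
                if max_arc_crit(rng.permutation(w), min_width) >= crit:
                    exceed += 1
                    if exceed >= stop_count:
                        break
            p = (1 + exceed) / (1 + n_perm)
            if exceed >= stop_count or p > alpha:
                continue
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            continue
        breakpoints.extend(cuts)
        edges = [lo] + cuts + [hi]
        # push right-to-left so windows are processed left-to-right
        for a, b in zip(edges[:-1][::-1], edges[1:][::-1]):
            stack.append((a, b))
    return sorted(breakpoints)


def pcf_cost(x: np.ndarray, breakpoints, gamma: float) -> float:
    """Within-segment sum of squared deviations + gamma * n_breakpoints."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    bps = sorted(int(b) for b in breakpoints)
    if any(b <= 0 or b >= n for b in bps):
        raise ValueError(f"breakpoints must be interior to (0, {n})")
    if len(set(bps)) != len(bps):
        raise ValueError("duplicate breakpoints")
    edges = [0] + bps + [n]
    cost = gamma * len(bps)
    for a, b in zip(edges, edges[1:]):
        seg = x[a:b]
        cost += float(np.sum((seg - seg.mean()) ** 2))
    return cost


def pcf_segment(x: np.ndarray, gamma: float, kmin: int = 5) -> list[int]:
    """Exact penalized least-squares segmentation; sorted breakpoints."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < kmin:
        raise ValueError(f"need len(x) >= kmin ({x.size} < {kmin})")
    return [int(b) for b in pcf_dp(x, float(gamma), int(kmin))]


def winsorize(x: np.ndarray, k: float = 2.5) -> np.ndarray:
    """Clip at median +/- k * MAD (MAD scaled to sigma for a normal)."""
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:  # majority-constant vector: fall back to mean abs dev
        mad = 1.4826 * np.mean(np.abs(x - med))
        if mad == 0:
            return x.copy()
    return np.clip(x, med - k * mad, med + k * mad)


def _impute_nan(vec: np.ndarray, sample: str, chrom: str) -> np.ndarray:
    bad = np.isnan(vec)
    if bad.any():
        fill = float(np.nanmean(vec)) if not bad.all() else 0.0
        vec = np.where(bad, fill, vec)
        log.info("%s/%s: imputed %d NaN markers with chromosome mean", sample, chrom, int(bad.sum()))
    return vec


def segment_cohort(m: CNMatrix, method: str, params: PipelineParams) -> SegmentSet:
    """Segment every (sample, chromosome) vector independently.

    NaN markers are mean-imputed per (sample, chromosome) first. With
    ``params.winsorize`` and method ``pcf``, breakpoints are found on the
    winsorized vector but segment means always come from the (imputed)
    data. Provenance records the engine and its parameters.
    """
    if method not in ("cbs", "pcf"):
        raise ValueError(f"method must be 'cbs' or 'pcf', got {method!r}")
    pm = m.probe_map
    segments: list[Segment] = []
    for si, sample in enumerate(m.sample_ids):
        for ci, chrom in enumerate(pm.chrom_names):
            lo, hi = pm.chrom_slice(chrom)
            vec = _impute_nan(m.values[si, lo:hi].copy(), sample, chrom)
            try:
                if method == "cbs":
                    bps = cbs_segment(
                        vec,
                        alpha=params.alpha,
                        n_perm=params.n_perm_cbs,
                        seed=(params.seed, si, ci),
                    )
                else:
                    fit_vec = winsorize(vec) if params.winsorize else vec
                    if fit_vec.size < params.kmin:
                        bps = []
                    else:
                        bps = pcf_segment(fit_vec, gamma=params.gamma, kmin=params.kmin)
            except Exception as e:
                raise RuntimeError(f"segmentation failed for {sample}/{chrom}") from e
            edges = [0] + bps + [hi - lo]
            for a, b in zip(edges, edges[1:]):
                segments.append(
                    Segment(
                        sample_id=sample,
                        chrom=chrom,
                        start_marker=lo + a,
                        end_marker=lo + b,
                        start_bp=int(pm.pos[lo + a]),
                        end_bp=int(pm.pos[lo + b - 1]),
                        mean=float(vec[a:b].mean()),
                        n_markers=b - a,
                    )
                )
    prov = {
        "method": method,
        "alpha": params.alpha if method == "cbs" else None,
        "gamma": params.gamma if method == "pcf" else None,
        "kmin": params.kmin if method == "pcf" else None,
        "n_perm": params.n_perm_cbs if method == "cbs" else None,
        "winsorize": params.winsorize if method == "pcf" else None,
        "seed": params.seed,
    }
    segs = SegmentSet(segments, provenance=prov)
    segs.audit(pm)  # partition property checked after every call
    return segs


def to_marker_level(segs: SegmentSet, pm: ProbeMap) -> MarkerLevelMatrix:
    """Project segment means back onto markers (one value per marker)."""
    segs.audit(pm)
    samples = sorted({s.sample_id for s in segs.segments})
    index = {s: i for i, s in enumerate(samples)}
    values = np.full((len(samples), pm.n_markers), np.nan)
    for s in segs.segments:
        values[index[s.sample_id], s.start_marker : s.end_marker] = s.mean
    if np.isnan(values).any():
        raise ValueError("segments do not cover every marker for every sample")
    return MarkerLevelMatrix(pm, samples, values)
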