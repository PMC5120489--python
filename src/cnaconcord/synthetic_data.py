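"""Synthetic copy-number cohorts with planted, known aberrations.

The generator produces the statistical structure the downstream analysis
assumes: per-marker log2 ratios equal to a sum of planted event
amplitudes over carrier samples, an optional per-sample baseline shift,
optional private "passenger" segments, and i.i.d. Gaussian marker noise.
With noise and shifts off, every non-carrier marker value is exactly
zero, so ground truth is unambiguous and every pipeline stage can be
tested end-to-end without external data.

Named presets emulate four array-CGH/SNP cohorts of differing probe
density and size at one-tenth scale (11/7/8/8 samples on 10932 / 1798 /
11478 / 26053 markers) on a shared synthetic 8-chromosome, 1.36 Gb
genome. The comparison presets plant one amplification locus common to
all four cohorts plus cohort-private events, the study design used by
the cross-cohort recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_io import (
    Chromosome,
    CNMatrix,
    Cytoband,
    GenomeLayout,
    ProbeMap,
    map_bp_to_marker_index,
)

__all__ = [
    "TruthEvent",
    "CohortSpec",
    "default_layout",
    "synthetic_cytobands",
    "make_probe_map",
    "markers_by_length",
    "simulate_cohort",
    "truth_to_bed",
    "read_truth_bed",
    "cohort_preset",
    "comparison_presets",
    "three_event_spec",
    "focal_recovery_spec",
    "null_cohort_spec",
    "PRESET_NAMES",
]

EVENT_KINDS = ("focal_amp", "focal_del", "broad_amp", "broad_del")


@dataclass
class TruthEvent:
    """A planted aberration with known locus, amplitude and carriers."""

    kind: str  # focal_amp | focal_del | broad_amp | broad_del
    chrom: str
    start_bp: int
    end_bp: int
    amplitude: float  # log2 ratio; > 0 for amp, < 0 for del
    carrier_frequency: float
    carriers: list[str] | None = None  # resolved sample ids

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.amplitude == 0:
            raise ValueError("event amplitude must be nonzero")
        if self.kind.endswith("amp") and self.amplitude < 0:
            raise ValueError("amp event with negative amplitude")
        if self.kind.endswith("del") and self.amplitude > 0:
            raise ValueError("del event with positive amplitude")
        if not (0 <= self.carrier_frequency <= 1):
            raise ValueError("carrier_frequency must be in [0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("event start_bp > end_bp")


@dataclass
class CohortSpec:
    """Everything needed to simulate one cohort reproducibly."""

    layout: GenomeLayout
    n_samples: int
    n_markers_per_chrom: int | dict[str, int] = 500
    noise_sd: float = 0.25  # log2 units, i.i.d. per marker
    sample_shift_sd: float = 0.0  # per-sample baseline offset
    events: list[TruthEvent] = field(default_factory=list)
    passenger_rate: float = 0.0  # expected private segments per sample
    seed: int = 0
    probe_map: ProbeMap | None = None  # pre-resolved marker positions
    focal_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_layout(n_chromosomes: int = 8) -> GenomeLayout:
    """Synthetic genome: chr1..chrN with lengths 240, 220, ... Mb and
    centromeres at 40-48% of the length (so p and q arms differ)."""
    if not (1 <= n_chromosomes <= 8):
        raise ValueError("n_chromosomes must be in 1..8")
    mb = 1_000_000
    lengths = [240, 220, 200, 180, 160, 140, 120, 100]
    cen_frac = [0.46, 0.43, 0.45, 0.44, 0.42, 0.48, 0.40, 0.45]
    chroms = [
        Chromosome(f"chr{i + 1}", lengths[i] * mb, int(lengths[i] * mb * cen_frac[i]))
        for i in range(n_chromosomes)
    ]
    return GenomeLayout(chroms)


def synthetic_cytobands(layout: GenomeLayout, band_mb: int = 10) -> GenomeLayout:
    """Return a copy of ``layout`` with evenly spaced synthetic cytobands
    (p11, p12, ... outward from the centromere), used for labeling."""
    bands: list[Cytoband] = []
    size = band_mb * 1_000_000
    for c in layout.chromosomes:
        # p arm: bands run from centromere toward pter, named p11, p12, ...
        edges = list(range(c.centromere, 0, -size)) + [0]
        p_bands = [
            Cytoband(c.name, lo + 1, hi, f"p1{k + 1}")
            for k, (hi, lo) in enumerate(zip(edges, edges[1:]))
        ]
        bands.extend(sorted(p_bands, key=lambda b: b.start))
        edges = list(range(c.centromere, c.length, size)) + [c.length]
        edges = sorted(set(edges))
        bands.extend(
            Cytoband(c.name, lo + 1, hi, f"q1{k + 1}")
            for k, (lo, hi) in enumerate(zip(edges, edges[1:]))
        )
    return GenomeLayout(layout.chromosomes, bands)


def markers_by_length(layout: GenomeLayout, total: int) -> dict[str, int]:
    """Apportion ``total`` markers over chromosomes proportionally to
    length (largest-remainder rounding, ties to earlier chromosomes)."""
    L = sum(c.length for c in layout.chromosomes)
    raw = [(c.name, total * c.length / L) for c in layout.chromosomes]
    base = {name: int(math.floor(x)) for name, x in raw}
    short = total - sum(base.values())
    rema = sorted(raw, key=lambda t: t[1] - math.floor(t[1]), reverse=True)
    for name, _ in rema[:short]:
        base[name] += 1
    return base


def make_probe_map(
    layout: GenomeLayout, n_markers_per_chrom: int | dict[str, int], seed: int
) -> ProbeMap:
    """Draw marker positions uniformly without replacement per
    chromosome, sorted; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    chroms: list[str] = []
    pos: list[np.ndarray] = []
    for c in layout.chromosomes:
        n = (
            n_markers_per_chrom[c.name]
            if isinstance(n_markers_per_chrom, dict)
            else n_markers_per_chrom
        )
        if n < 2:
            raise ValueError(f"{c.name}: need >= 2 markers per chromosome")
        if n > c.length:
            raise ValueError(f"{c.name}: {n} markers exceed chromosome length")
        draw = np.unique(rng.integers(1, c.length + 1, size=n))
        while draw.size < n:  # resolve duplicate positions by topping up
            extra = rng.integers(1, c.length + 1, size=n - draw.size)
            draw = np.unique(np.concatenate([draw, extra]))
        p = np.sort(draw[:n])
        pos.append(p)
        chroms.extend([c.name] * n)
        ids.extend(f"{c.name}_m{k}" for k in range(n))
    return ProbeMap(ids, chroms, np.concatenate(pos) if pos else np.array([], dtype=int))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _validate_events(spec: CohortSpec) -> None:
    layout = spec.layout
    for ev in spec.events:
        if ev.chrom not in layout:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        c = layout[ev.chrom]
        if ev.start_bp < 1 or ev.end_bp > c.length:
            raise ValueError(f"event {ev.chrom}:{ev.start_bp}-{ev.end_bp} outside layout")
        arm = layout.arm_of(ev.chrom, (ev.start_bp + ev.end_bp) // 2)
        a, b = layout.arm_bounds(ev.chrom, arm)
        if ev.kind.startswith("broad"):
            if (ev.start_bp, ev.end_bp) != (a, b):
                raise ValueError(
                    f"broad event {ev.chrom}:{ev.start_bp}-{ev.end_bp} must span "
                    f"arm {arm} exactly ({a}-{b})"
                )
        else:
            span = ev.end_bp - ev.start_bp + 1
            if span > spec.focal_fraction * (b - a + 1):
                raise ValueError(
                    f"focal event {ev.chrom}:{ev.start_bp}-{ev.end_bp} spans more than "
                    f"{spec.focal_fraction:.0%} of arm {arm}"
                )
    # overlapping same-kind events make the truth ambiguous -> reject
    for i, a in enumerate(spec.events):
        for b in spec.events[i + 1 :]:
            same_sign = (a.amplitude > 0) == (b.amplitude > 0)
            if (
                same_sign
                and a.chrom == b.chrom
                and a.start_bp <= b.end_bp
                and b.start_bp <= a.end_bp
            ):
                raise ValueError(
                    f"overlapping same-kind truth events at {a.chrom}:"
                    f"{a.start_bp}-{a.end_bp} / {b.start_bp}-{b.end_bp}"
                )


def simulate_cohort(spec: CohortSpec) -> tuple[CNMatrix, list[TruthEvent]]:
    """Simulate one cohort; fully reproducible from ``spec.seed``.

    value(s, i) = sum of amplitudes of events covering marker i with s a
    carrier, + baseline shift(s), + passengers, + N(0, noise_sd^2).
    """
    _validate_events(spec)
    rng = np.random.default_rng(spec.seed)
    pm = spec.probe_map
    if pm is None:
        pm = make_probe_map(
            spec.layout, spec.n_markers_per_chrom, seed=int(rng.integers(0, 2**31))
        )
    n_s, n_m = spec.n_samples, pm.n_markers
    sample_ids = [f"S{i:03d}" for i in range(n_s)]
    values = np.zeros((n_s, n_m))

    if spec.sample_shift_sd > 0:
        values += rng.normal(0.0, spec.sample_shift_sd, size=n_s)[:, None]

    resolved: list[TruthEvent] = []
    for ev in spec.events:
        k = _round_half_up(ev.carrier_frequency * n_s)
        carriers = sorted(rng.choice(n_s, size=k, replace=False).tolist())
        a, b = map_bp_to_marker_index(pm, ev.chrom, ev.start_bp, ev.end_bp)
        for s in carriers:
            values[s, a:b] += ev.amplitude
        resolved.append(replace(ev, carriers=[sample_ids[s] for s in carriers]))

    if spec.passenger_rate > 0:
        for s in range(n_s):
            for _ in range(rng.poisson(spec.passenger_rate)):
                c = spec.layout.chromosomes[rng.integers(len(spec.layout.chromosomes))]
                lo, hi = pm.chrom_slice(c.name)
                width = int(rng.integers(5, 51))
                if hi - lo <= width:
                    continue
                start = int(rng.integers(lo, hi - width))
                amp = float(rng.uniform(0.3, 1.0)) * (1 if rng.random() < 0.5 else -1)
                values[s, start : start + width] += amp

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=(n_s, n_m))

    return CNMatrix(pm, sample_ids, values), resolved


# ---------------------------------------------------------------------------
# truth BED round-trip
# ---------------------------------------------------------------------------

def truth_to_bed(events: list[TruthEvent], path: str | Path) -> None:
    """Write truth events as BED: name = kind|amplitude|frequency|carriers,
    score = round(1000*|amplitude|) clipped to BED's 0-1000."""
    with open(path, "w") as fh:
        for ev in events:
            name = (
                f"{ev.kind}|{ev.amplitude:g}|{ev.carrier_frequency:g}|"
                + (",".join(ev.carriers) if ev.carriers else ".")
            )
            score = min(1000, int(round(abs(ev.amplitude) * 1000)))
            fh.write(f"{ev.chrom}\t{ev.start_bp - 1}\t{ev.end_bp}\t{name}\t{score}\n")


def read_truth_bed(path: str | Path) -> list[TruthEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name, _score = line.split("\t")
            kind, amp, freq, carriers = name.split("|")
            events.append(
                TruthEvent(
                    kind=kind,
                    chrom=chrom,
                    start_bp=int(start) + 1,
                    end_bp=int(end),
                    amplitude=float(amp),
                    carrier_frequency=float(freq),
                    carriers=None if carriers == "." else carriers.split(","),
                )
            )
    return events


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

MB = 1_000_000

# (n_samples, total markers) at one-tenth of the emulated cohorts
_PRESET_SHAPE = {
    "breast_like": (11, 10932),
    "ovarian_like": (7, 1798),
    "endometrial_like": (8, 11478),
    "cervix_like": (8, 26053),
}
PRESET_NAMES = tuple(_PRESET_SHAPE)

# One amplification locus common to all four cohorts (distal chr8q) plus
# two private amps and two private dels per cohort, all 12 Mb wide so the
# sparsest probe map still covers them with ~15 markers, all within 25%
# of their arm. Loci are pairwise separated by >= 15 Mb.
_SHARED_AMP = ("chr8", 86 * MB, 98 * MB)

_PRIVATE_EVENTS = {
    "breast_like": [
        ("focal_amp", "chr1", 20 * MB, 32 * MB, 1.0),
        ("focal_amp", "chr2", 20 * MB, 32 * MB, 1.0),
        ("focal_del", "chr3", 20 * MB, 32 * MB, -1.0),
        ("focal_del", "chr4", 20 * MB, 32 * MB, -1.0),
    ],
    "ovarian_like": [
        ("focal_amp", "chr1", 60 * MB, 72 * MB, 1.0),
        ("focal_amp", "chr2", 60 * MB, 72 * MB, 1.0),
        ("focal_del", "chr3", 60 * MB, 72 * MB, -1.0),
        ("focal_del", "chr4", 50 * MB, 62 * MB, -1.0),
    ],
    "endometrial_like": [
        ("focal_amp", "chr1", 130 * MB, 142 * MB, 1.0),
        ("focal_amp", "chr2", 120 * MB, 132 * MB, 1.0),
        ("focal_del", "chr3", 110 * MB, 122 * MB, -1.0),
        ("focal_del", "chr4", 100 * MB, 112 * MB, -1.0),
    ],
    "cervix_like": [
        ("focal_amp", "chr1", 180 * MB, 192 * MB, 1.0),
        ("focal_amp", "chr2", 170 * MB, 182 * MB, 1.0),
        ("focal_del", "chr3", 160 * MB, 172 * MB, -1.0),
        ("focal_del", "chr4", 140 * MB, 152 * MB, -1.0),
    ],
}


def cohort_preset(
    name: str,
    seed: int,
    noise_sd: float = 0.25,
    passenger_rate: float = 0.0,
    carrier_frequency: float = 0.4,
) -> CohortSpec:
    """One of the four emulated cohorts, with its planted study design."""
    if name not in _PRESET_SHAPE:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    layout = default_layout(8)
    n, total = _PRESET_SHAPE[name]
    events = [
        TruthEvent("focal_amp", *_SHARED_AMP, amplitude=1.0, carrier_frequency=carrier_frequency)
    ]
    for kind, chrom, s, e, amp in _PRIVATE_EVENTS[name]:
        events.append(
            TruthEvent(kind, chrom, s, e, amplitude=amp, carrier_frequency=carrier_frequency)
        )
    return CohortSpec(
        layout=layout,
        n_samples=n,
        n_markers_per_chrom=markers_by_length(layout, total),
        noise_sd=noise_sd,
        events=events,
        passenger_rate=passenger_rate,
        seed=seed,
    )


def comparison_presets(seed: int) -> dict[str, CohortSpec]:
    """The four cohorts of the cross-cohort comparison design, each with
    its own sub-seed derived from ``seed``."""
    return {
        name: cohort_preset(name, seed=int(np.random.default_rng([seed, i]).integers(0, 2**31)))
        for i, name in enumerate(PRESET_NAMES)
    }


def three_event_spec(seed: int, n_samples: int = 40) -> CohortSpec:
    """Calibration benchmark: three focal amplifications on a 4-chromosome
    genome, 2000 markers, sigma = 0.25."""
    layout = default_layout(4)
    return CohortSpec(
        layout=layout,
        n_samples=n_samples,
        n_markers_per_chrom=500,
        noise_sd=0.25,
        events=[
            TruthEvent("focal_amp", "chr1", 30 * MB, 42 * MB, 1.0, 0.30),
            TruthEvent("focal_amp", "chr2", 120 * MB, 132 * MB, 0.9, 0.40),
            TruthEvent("focal_amp", "chr3", 110 * MB, 122 * MB, 1.1, 0.35),
        ],
        seed=seed,
    )


def focal_recovery_spec(seed: int) -> CohortSpec:
    """Detection-power benchmark: one focal amplification of amplitude
    1.0 covering exactly 12 markers, carried by 30% of 40 samples, on a
    4-chromosome genome with 10,000 markers and sigma = 0.25.

    The probe map is resolved first so the event can be placed on exactly
    12 consecutive markers (bp bounds equal the flanking marker positions).
    """
    layout = default_layout(4)
    pm = make_probe_map(
        layout,
        markers_by_length(layout, 10_000),
        seed=int(np.random.default_rng([seed, 9151]).integers(0, 2**31)),
    )
    lo, hi = pm.chrom_slice("chr2")
    # place the event on the q arm of chr2, ~60% into the chromosome block
    k = lo + int(0.6 * (hi - lo))
    event = TruthEvent(
        "focal_amp",
        "chr2",
        int(pm.pos[k]),
        int(pm.pos[k + 11]),
        amplitude=1.0,
        carrier_frequency=0.30,
    )
    return CohortSpec(
        layout=layout,
        n_samples=40,
        n_markers_per_chrom=markers_by_length(layout, 10_000),
        noise_sd=0.25,
        events=[event],
        seed=seed,
        probe_map=pm,
    )


def null_cohort_spec(seed: int) -> CohortSpec:
    """Same shape as :func:`focal_recovery_spec` but with no events."""
    spec = focal_recovery_spec(seed)
    spec.events = []
    return spec
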