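"""Domain types, coordinate conventions and on-disk formats.

Conventions used throughout the package:

* base-pair coordinates are **1-based inclusive** (the SEG convention);
  UCSC-style inputs (0-based half-open) are converted at the boundary by
  the readers;
* marker (probe) indices are **0-based half-open** ``[start, end)`` into
  the genome-wide probe map;
* chromosomes are kept in natural order (1..22, then X as 23, Y as 24).

The types here carry the data between the pipeline stages: a
:class:`GenomeLayout` (chromosome lengths, centromeres, optional
cytobands), a :class:`ProbeMap` of ordered markers, the
:class:`CNMatrix` of per-sample log2 ratios, and :class:`Segment` /
:class:`SegmentSet` for segmentation output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Chromosome",
    "Cytoband",
    "GenomeLayout",
    "ProbeMap",
    "CNMatrix",
    "Segment",
    "SegmentSet",
    "GeneModel",
    "PipelineParams",
    "chrom_sort_key",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_genome_layout",
    "write_genome_layout",
    "read_seg_file",
    "write_seg_file",
    "read_genes_bed",
    "map_bp_to_marker_index",
]


def chrom_sort_key(name: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X=23, Y=24, others after."""
    s = name[3:] if name.lower().startswith("chr") else name
    u = s.upper()
    if u == "X":
        return (23, "")
    if u == "Y":
        return (24, "")
    try:
        return (int(s), "")
    except ValueError:
        return (1000, u)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int  # bp, positions run 1..length
    centromere: int  # bp, 1-based; p arm = [1, centromere], q arm = (centromere, length]

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"{self.name}: centromere {self.centromere} outside (0, {self.length})"
            )


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    name: str  # e.g. "q24.3"


class GenomeLayout:
    """Chromosome lengths, centromere positions and optional cytobands.

    Derives chromosome arms: the p arm covers ``[1, centromere]`` and the
    q arm ``[centromere+1, length]``, so p + q tile the chromosome.
    """

    def __init__(
        self,
        chromosomes: Sequence[Chromosome],
        cytobands: Sequence[Cytoband] | None = None,
    ) -> None:
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes: list[Chromosome] = list(chromosomes)
        self._by_name = {c.name: c for c in self.chromosomes}
        self.cytobands: list[Cytoband] | None = list(cytobands) if cytobands else None
        if self.cytobands is not None:
            self._check_cytobands()

    def _check_cytobands(self) -> None:
        assert self.cytobands is not None
        by_chrom: dict[str, list[Cytoband]] = {}
        for b in self.cytobands:
            by_chrom.setdefault(b.chrom, []).append(b)
        for name, bands in by_chrom.items():
            if name not in self._by_name:
                raise ValueError(f"cytoband on unknown chromosome {name}")
            bands.sort(key=lambda b: b.start)
            expect = 1
            for b in bands:
                if b.start != expect:
                    raise ValueError(
                        f"cytobands on {name} leave a gap/overlap at {expect}"
                    )
                expect = b.end + 1
            if expect != self._by_name[name].length + 1:
                raise ValueError(f"cytobands on {name} do not reach chromosome end")

    # -- lookup ---------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    # -- arms -----------------------------------------------------------
    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        c = self._by_name[chrom]
        if arm == "p":
            return (1, c.centromere)
        if arm == "q":
            return (c.centromere + 1, c.length)
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")

    def arm_of(self, chrom: str, pos: int) -> str:
        return "p" if pos <= self._by_name[chrom].centromere else "q"

    def arm_length(self, chrom: str, arm: str) -> int:
        a, b = self.arm_bounds(chrom, arm)
        return b - a + 1

    def arm_id(self, chrom: str, arm: str) -> str:
        s = chrom[3:] if chrom.lower().startswith("chr") else chrom
        return f"{s}{arm}"

    def arms(self) -> Iterable[tuple[str, str, int, int]]:
        """Yield (chrom, arm, start, end) over all arms in genome order."""
        for c in self.chromosomes:
            yield (c.name, "p", 1, c.centromere)
            yield (c.name, "q", c.centromere + 1, c.length)

    # -- cytobands ------------------------------------------------------
    def cytoband_label(self, chrom: str, pos: int) -> str | None:
        if self.cytobands is None:
            return None
        for b in self.cytobands:
            if b.chrom == chrom and b.start <= pos <= b.end:
                s = chrom[3:] if chrom.lower().startswith("chr") else chrom
                return f"{s}{b.name}"
        return None

    def cytoband_labels_in(self, chrom: str, start: int, end: int) -> list[str]:
        if self.cytobands is None:
            return []
        out = []
        s = chrom[3:] if chrom.lower().startswith("chr") else chrom
        for b in self.cytobands:
            if b.chrom == chrom and b.start <= end and b.end >= start:
                out.append(f"{s}{b.name}")
        return out


class ProbeMap:
    """Ordered genomic markers: ids, chromosome and 1-based position.

    Markers are sorted by (natural chromosome order, position) with
    strictly increasing positions within a chromosome; marker ids are
    unique. Violations raise ``ValueError`` naming the offending marker.
    """

    def __init__(
        self,
        marker_ids: Sequence[str],
        chrom: Sequence[str],
        pos: Sequence[int],
    ) -> None:
        self.marker_ids = np.asarray(marker_ids, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        n = len(self.marker_ids)
        if not (len(self.chrom) == len(self.pos) == n):
            raise ValueError("marker_ids, chrom, pos must have equal length")
        if len(set(self.marker_ids)) != n:
            seen: set[str] = set()
            for m in self.marker_ids:
                if m in seen:
                    raise ValueError(f"duplicate marker id {m!r}")
                seen.add(m)
        self._blocks: dict[str, tuple[int, int]] = {}
        prev_key = None
        block_start = 0
        for i in range(n):
            c = self.chrom[i]
            if c not in self._blocks and (i == 0 or self.chrom[i - 1] != c):
                if i > 0:
                    self._blocks[self.chrom[i - 1]] = (block_start, i)
                block_start = i
                key = chrom_sort_key(c)
                if prev_key is not None and key <= prev_key:
                    raise ValueError(
                        f"chromosome {c} out of order (marker {self.marker_ids[i]!r})"
                    )
                prev_key = key
            elif i > 0 and self.chrom[i - 1] == c:
                if self.pos[i] <= self.pos[i - 1]:
                    raise ValueError(
                        f"non-increasing position at marker {self.marker_ids[i]!r} "
                        f"({c}:{self.pos[i]} after {self.pos[i - 1]})"
                    )
            else:  # chromosome re-appears after a different one
                raise ValueError(f"chromosome {c} appears in two separate blocks")
        if n:
            self._blocks[self.chrom[n - 1]] = (block_start, n)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._blocks)

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        """Half-open global marker-index range of one chromosome."""
        if chrom not in self._blocks:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._blocks[chrom]

    def __len__(self) -> int:
        return self.n_markers

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.marker_ids == other.marker_ids))
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
        )


def map_bp_to_marker_index(
    pm: ProbeMap, chrom: str, start_bp: int, end_bp: int
) -> tuple[int, int]:
    """Half-open global marker-index interval of markers with
    ``start_bp <= pos <= end_bp``. The interval may be empty."""
    if start_bp > end_bp:
        raise ValueError(f"start_bp {start_bp} > end_bp {end_bp}")
    lo, hi = pm.chrom_slice(chrom)
    p = pm.pos[lo:hi]
    a = lo + int(np.searchsorted(p, start_bp, side="left"))
    b = lo + int(np.searchsorted(p, end_bp, side="right"))
    return (a, b)


@dataclass
class CNMatrix:
    """samples x markers log2-ratio matrix bound to a probe map."""

    probe_map: ProbeMap
    sample_ids: list[str]
    values: np.ndarray  # (n_samples, n_markers) float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), self.probe_map.n_markers):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.probe_map.n_markers} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_nan(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class Segment:
    """One constant-mean segment of one sample's chromosome.

    ``start_marker``/``end_marker`` are half-open global marker indices;
    ``start_bp``/``end_bp`` are 1-based inclusive; ``mean`` is the
    arithmetic mean of the member marker values.
    """

    sample_id: str
    chrom: str
    start_marker: int
    end_marker: int
    start_bp: int
    end_bp: int
    mean: float
    n_markers: int


@dataclass
class SegmentSet:
    segments: list[Segment]
    provenance: dict = field(default_factory=dict)

    def audit(self, pm: ProbeMap, matrix: CNMatrix | None = None, atol: float = 1e-8) -> None:
        """Verify the partition property: per (sample, chromosome) the
        segments tile the chromosome's marker range with no gaps or
        overlaps. With ``matrix`` given, also verify segment means."""
        groups: dict[tuple[str, str], list[Segment]] = {}
        for s in self.segments:
            if s.n_markers != s.end_marker - s.start_marker or s.n_markers < 1:
                raise ValueError(f"bad n_markers on segment {s}")
            groups.setdefault((s.sample_id, s.chrom), []).append(s)
        for (sample, chrom), segs in groups.items():
            lo, hi = pm.chrom_slice(chrom)
            segs.sort(key=lambda s: s.start_marker)
            if segs[0].start_marker != lo or segs[-1].end_marker != hi:
                raise ValueError(
                    f"{sample}/{chrom}: segments do not span marker range [{lo},{hi})"
                )
            for a, b in zip(segs, segs[1:]):
                if a.end_marker != b.start_marker:
                    raise ValueError(
                        f"{sample}/{chrom}: gap/overlap between markers "
                        f"{a.end_marker} and {b.start_marker}"
                    )
            if matrix is not None:
                row = matrix.sample_ids.index(sample)
                for s in segs:
                    m = float(np.mean(matrix.values[row, s.start_marker : s.end_marker]))
                    if abs(m - s.mean) > atol:
                        raise ValueError(
                            f"{sample}/{chrom}: segment mean {s.mean} != data mean {m}"
                        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Sample": [s.sample_id for s in self.segments],
                "Chromosome": [s.chrom for s in self.segments],
                "Start": [s.start_bp for s in self.segments],
                "End": [s.end_bp for s in self.segments],
                "Num_Probes": [s.n_markers for s in self.segments],
                "Segment_Mean": [s.mean for s in self.segments],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class PipelineParams:
    """Shared tuning knobs for the whole pipeline.

    ``alpha`` is the CBS change-point significance level, ``gamma`` the
    PCF per-breakpoint penalty (raw residual scale), ``theta`` the
    log2-ratio threshold for calling gain/loss (0.1 by convention),
    ``focal_fraction`` the focal/broad boundary as a fraction of the
    chromosome arm.
    """

    alpha: float = 0.01
    gamma: float = 2.5
    kmin: int = 5
    theta: float = 0.1
    q_threshold: float = 0.25
    n_perm_cbs: int = 1000
    n_perm_gistic: int = 1000
    focal_fraction: float = 0.25
    seed: int = 0
    winsorize: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")
        if not (0 < self.focal_fraction <= 1):
            raise ValueError("focal_fraction must be in (0, 1]")
        if self.kmin < 1:
            raise ValueError("kmin must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_marker_matrix(path: str | Path) -> tuple[ProbeMap, CNMatrix]:
    """Read a tab-delimited marker matrix.

    Expected header: ``marker  chrom  pos  <sample1> ... <sampleN>``.
    Markers must already satisfy the probe-map ordering invariants.
    NaN cells are kept (and counted in the log); they are imputed later,
    just before segmentation.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=0,
            dtype={"marker": str, "chrom": str},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise ValueError(f"{path}: parse error: {e}") from e
    required = ["marker", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}, got {list(df.columns[:3])}")
    sample_ids = [str(c) for c in df.columns[3:]]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    pm = ProbeMap(df["marker"].tolist(), df["chrom"].tolist(), df["pos"].to_numpy())
    values = df[df.columns[3:]].to_numpy(dtype=np.float64).T
    m = CNMatrix(pm, sample_ids, values)
    if m.n_nan:
        log.warning("%s: %d NaN cells flagged for imputation", path, m.n_nan)
    return pm, m


def write_marker_matrix(m: CNMatrix, path: str | Path) -> None:
    pm = m.probe_map
    df = pd.DataFrame({"marker": pm.marker_ids, "chrom": pm.chrom, "pos": pm.pos})
    for i, s in enumerate(m.sample_ids):
        df[s] = m.values[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_seg_file(segs: SegmentSet, path: str | Path) -> None:
    """Write segments in SEG format (1-based inclusive bp, mean to 6 dp)."""
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for s in segs.segments:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                f"{s.n_markers}\t{s.mean:.6f}\n"
            )


def read_seg_file(path: str | Path, probe_map: ProbeMap | None = None) -> SegmentSet:
    """Read a SEG file. With a probe map, marker indices are
    reconstructed from the bp bounds; without one they are left as -1
    sentinels and the partition audit is unavailable."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"Sample": str, "Chromosome": str})
    segments = []
    for row in df.itertuples(index=False):
        start_m = end_m = -1
        if probe_map is not None:
            start_m, end_m = map_bp_to_marker_index(
                probe_map, row.Chromosome, int(row.Start), int(row.End)
            )
        segments.append(
            Segment(
                sample_id=row.Sample,
                chrom=row.Chromosome,
                start_marker=start_m,
                end_marker=end_m,
                start_bp=int(row.Start),
                end_bp=int(row.End),
                mean=float(row.Segment_Mean),
                n_markers=int(row.Num_Probes),
            )
        )
    return SegmentSet(segments, provenance={"source": str(path)})


def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Read a genome layout.

    Two dialects are accepted, distinguished by column count:

    * UCSC cytoBand: ``chrom  start  end  band  stain`` (0-based
      half-open). Chromosome length is the maximum end; the centromere
      is the midpoint of the ``acen`` band pair. A chromosome without
      ``acen`` rows is an error.
    * 3-column fallback: ``chrom  length  centromere`` (values taken
      as-is, 1-based).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rows.append((ln, parts))
    if not rows:
        raise ValueError(f"{path}: empty layout file")
    ncol = len(rows[0][1])
    if any(len(p) != ncol for _, p in rows):
        bad = next(ln for ln, p in rows if len(p) != ncol)
        raise ValueError(f"{path}: inconsistent column count at line {bad}")

    if ncol == 3:
        chroms = [
            Chromosome(name=p[0], length=int(p[1]), centromere=int(p[2]))
            for _, p in rows
        ]
        chroms.sort(key=lambda c: chrom_sort_key(c.name))
        return GenomeLayout(chroms)

    if ncol != 5:
        raise ValueError(f"{path}: expected 3 or 5 columns, got {ncol}")

    by_chrom: dict[str, list[tuple[int, int, str, str]]] = {}
    for _, p in rows:
        chrom, start, end, band, stain = p
        by_chrom.setdefault(chrom, []).append((int(start), int(end), band, stain))
    chroms = []
    bands: list[Cytoband] = []
    for name, rs in by_chrom.items():
        rs.sort()
        length = max(e for _, e, _, _ in rs)
        acen = [(s, e) for s, e, _, st in rs if st == "acen"]
        if not acen:
            raise ValueError(f"{path}: chromosome {name} has no acen (centromere) rows")
        cen0 = (min(s for s, _ in acen) + max(e for _, e in acen)) // 2
        chroms.append(Chromosome(name=name, length=length, centromere=cen0 + 1))
        for s, e, band, _ in rs:
            bands.append(Cytoband(chrom=name, start=s + 1, end=e, name=band))
    chroms.sort(key=lambda c: chrom_sort_key(c.name))
    return GenomeLayout(chroms, bands)


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    """Write the 3-column layout dialect (chrom, length, centromere)."""
    with open(path, "w") as fh:
        for c in layout.chromosomes:
            fh.write(f"{c.name}\t{c.length}\t{c.centromere}\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open -> 1-based inclusive).

    Columns: chrom start end name [score strand]."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 4:
                raise ValueError(f"{path}: line {ln}: need >= 4 BED columns")
            strand = p[5] if len(p) >= 6 else "+"
            genes.append(
                GeneModel(
                    gene_id=p[3],
                    symbol=p[3],
                    chrom=p[0],
                    start=int(p[1]) + 1,
                    end=int(p[2]),
                    strand=strand,
                )
            )
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start))
    return genes
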