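"""Cross-cohort comparison of significant copy-number regions.

Cohorts sit on different probe maps, so "shared" is defined by bp-
interval intersection in genomic coordinates, never by band-name
equality; cytoband labels are annotation only. Per cohort the consensus
region set is the pairwise intersection of the regions found on the CBS
and PCF branches; sharing across cohorts is computed by an endpoint
sweep that stacks each cohort's merged intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

from .core_io import GeneModel, GenomeLayout, chrom_sort_key
from .gistic_scoring import SignificantRegion

__all__ = [
    "CohortPeaks",
    "SharedInterval",
    "OverlapReport",
    "consensus_regions",
    "shared_regions",
    "specificity_summary",
    "genes_in_regions",
    "venn_counts",
    "export_links",
    "build_overlap_report",
]


@dataclass
class CohortPeaks:
    name: str
    regions: list[SignificantRegion]
    provenance: dict = field(default_factory=dict)

    def of_kind(self, kind: str, include_broad: bool = False) -> list[SignificantRegion]:
        return [
            r
            for r in self.regions
            if r.kind == kind and (include_broad or r.scope != "broad")
        ]


@dataclass
class SharedInterval:
    chrom: str
    start_bp: int
    end_bp: int
    kind: str
    cohorts: list[str]
    cytobands: list[str] = field(default_factory=list)

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)


@dataclass
class OverlapReport:
    """Shared/specific region summaries and gene-set overlaps."""

    pairwise: dict[str, dict[tuple[str, str], list[SharedInterval]]]
    kway: dict[str, list[SharedInterval]]
    specificity: dict[str, tuple[int, int, int]]  # kind -> (n_unique, n_total, percent)
    gene_sets: dict[str, set[str]]
    venn: dict[tuple[str, ...], int]


def _round_half_up_percent(num: int, den: int) -> int:
    return int(math.floor(100.0 * num / den + 0.5)) if den else 0


def consensus_regions(
    cbs_regions: list[SignificantRegion],
    pcf_regions: list[SignificantRegion],
    kind: str,
) -> list[SignificantRegion]:
    """Pairwise intersections of overlapping same-kind region intervals
    from the two branches — the cohort's consensus set.

    The consensus peak is the intersection of the two peaks when they
    intersect, else the intersection of the regions; q is the larger
    (more conservative) of the two, g_peak the smaller.
    """
    A = [r for r in cbs_regions if r.kind == kind]
    B = [r for r in pcf_regions if r.kind == kind]
    out = []
    seen: set[tuple] = set()
    for a in A:
        for b in B:
            if a.chrom != b.chrom:
                continue
            s = max(a.region_start_bp, b.region_start_bp)
            e = min(a.region_end_bp, b.region_end_bp)
            if s > e:
                continue
            ps = max(a.peak_start_bp, b.peak_start_bp)
            pe = min(a.peak_end_bp, b.peak_end_bp)
            if ps > pe:
                ps, pe = s, e
            key = (a.chrom, s, e, ps, pe)
            if key in seen:  # identical intersections (e.g. peel-off twins)
                continue
            seen.add(key)
            scope = "focal" if a.scope == "focal" and b.scope == "focal" else (
                "broad" if a.scope == "broad" or b.scope == "broad" else None
            )
            out.append(
                SignificantRegion(
                    kind=kind,
                    chrom=a.chrom,
                    region_start_bp=s,
                    region_end_bp=e,
                    peak_start_bp=ps,
                    peak_end_bp=pe,
                    q=max(a.q, b.q),
                    g_peak=min(a.g_peak, b.g_peak),
                    scope=scope,
                    n_markers=min(a.n_markers, b.n_markers),
                )
            )
    out.sort(key=lambda r: (chrom_sort_key(r.chrom), r.region_start_bp))
    return out


def _merged_intervals(regions: list[SignificantRegion]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.region_start_bp, r.region_end_bp))
    out = {}
    for c, iv in by_chrom.items():
        iv.sort()
        merged = [list(iv[0])]
        for s, e in iv[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[c] = [(s, e) for s, e in merged]
    return out


def shared_regions(
    cohorts: list[CohortPeaks],
    kind: str,
    min_cohorts: int = 2,
    layout: GenomeLayout | None = None,
    include_broad: bool = False,
) -> list[SharedInterval]:
    """Genomic intervals where >= ``min_cohorts`` cohorts' same-kind
    region intervals stack, via a sweep over interval endpoints.

    Each cohort's intervals are merged first, so a cohort counts at most
    once per bp. Intervals are annotated with the contributing cohorts
    and, when a layout with cytobands is supplied, band labels.
    """
    if min_cohorts < 2:
        raise ValueError("min_cohorts must be >= 2")
    per_cohort = {
        c.name: _merged_intervals(c.of_kind(kind, include_broad)) for c in cohorts
    }
    chroms = sorted(
        {c for iv in per_cohort.values() for c in iv}, key=chrom_sort_key
    )
    out: list[SharedInterval] = []
    for chrom in chroms:
        events: list[tuple[int, int, str]] = []  # (pos, +1/-1, cohort)
        for name, iv in per_cohort.items():
            for s, e in iv.get(chrom, []):
                events.append((s, +1, name))
                events.append((e + 1, -1, name))
        events.sort(key=lambda t: (t[0], t[1]))
        active: set[str] = set()
        prev_pos: int | None = None
        for pos, delta, name in events:
            if prev_pos is not None and pos > prev_pos and len(active) >= min_cohorts:
                out.append(
                    SharedInterval(
                        chrom=chrom,
                        start_bp=prev_pos,
                        end_bp=pos - 1,
                        kind=kind,
                        cohorts=sorted(active),
                    )
                )
            if delta > 0:
                active.add(name)
            else:
                active.discard(name)
            prev_pos = pos
    # merge sweep fragments with identical cohort sets that abut
    merged: list[SharedInterval] = []
    for si in out:
        if (
            merged
            and merged[-1].chrom == si.chrom
            and merged[-1].cohorts == si.cohorts
            and si.start_bp <= merged[-1].end_bp + 1
        ):
            merged[-1].end_bp = si.end_bp
        else:
            merged.append(si)
    if layout is not None:
        for si in merged:
            si.cytobands = layout.cytoband_labels_in(si.chrom, si.start_bp, si.end_bp)
    return merged


def specificity_summary(
    cohorts: list[CohortPeaks], kind: str, include_broad: bool = False
) -> tuple[int, int, int]:
    """(n_unique, n_total, percent): a region is cohort-specific iff it
    overlaps no same-kind region of any other cohort; percent is
    round-half-up of 100 * n_unique / n_total."""
    if len(cohorts) < 2:
        raise ValueError("need >= 2 cohorts")
    n_total = 0
    n_unique = 0
    for c in cohorts:
        mine = c.of_kind(kind, include_broad)
        others = [
            o
            for other in cohorts
            if other.name != c.name
            for o in other.of_kind(kind, include_broad)
        ]
        for r in mine:
            n_total += 1
            hit = any(
                o.chrom == r.chrom
                and o.region_start_bp <= r.region_end_bp
                and r.region_start_bp <= o.region_end_bp
                for o in others
            )
            if not hit:
                n_unique += 1
    return (n_unique, n_total, _round_half_up_percent(n_unique, n_total))


def genes_in_regions(
    regions: list[SignificantRegion], genes: list[GeneModel]
) -> list[GeneModel]:
    """Genes whose span intersects (>= 1 bp) any region interval,
    deduplicated by gene_id, in genome order."""
    hit: dict[str, GeneModel] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in regions:
        for g in by_chrom.get(r.chrom, []):
            if g.start <= r.region_end_bp and r.region_start_bp <= g.end:
                hit.setdefault(g.gene_id, g)
    return sorted(hit.values(), key=lambda g: (chrom_sort_key(g.chrom), g.start, g.gene_id))


def venn_counts(gene_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive counts per nonempty subset of cohorts (genes belonging
    to exactly that subset). Subset keys are sorted cohort-name tuples;
    counts over all classes sum to |union|."""
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 gene sets")
    names = sorted(gene_sets)
    out: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(names, k):
            inside = set.intersection(*(gene_sets[n] for n in subset))
            outside = set.union(
                *(gene_sets[n] for n in names if n not in subset), set()
            )
            out[subset] = len(inside - outside)
    return out


def export_links(shared: list[SharedInterval], path: str | Path) -> int:
    """Write a Circos-style link table: one row per cohort pair per
    shared interval (``chrom start end chrom start end kind cohortA
    cohortB``). Returns the number of rows written."""
    n = 0
    with open(path, "w") as fh:
        for si in shared:
            for a, b in itertools.combinations(sorted(si.cohorts), 2):
                fh.write(
                    f"{si.chrom}\t{si.start_bp}\t{si.end_bp}\t"
                    f"{si.chrom}\t{si.start_bp}\t{si.end_bp}\t"
                    f"{si.kind}\t{a}\t{b}\n"
                )
                n += 1
    return n


def build_overlap_report(
    cohorts: list[CohortPeaks],
    genes: list[GeneModel] | None = None,
    layout: GenomeLayout | None = None,
    include_broad_genes: bool = True,
) -> OverlapReport:
    """Assemble the full comparison: pairwise and k-way shared intervals,
    specificity per kind, per-cohort gene sets and Venn counts.

    Gene extraction includes broad regions by default while peak sharing
    and specificity use focal regions only, mirroring the separate
    treatment of the two scopes in recurrence reporting.
    """
    kinds = ("amp", "del")
    pairwise: dict[str, dict[tuple[str, str], list[SharedInterval]]] = {}
    kway: dict[str, list[SharedInterval]] = {}
    spec: dict[str, tuple[int, int, int]] = {}
    for kind in kinds:
        pairwise[kind] = {}
        for a, b in itertools.combinations([c.name for c in cohorts], 2):
            sub = [c for c in cohorts if c.name in (a, b)]
            pairwise[kind][(a, b)] = shared_regions(sub, kind, 2, layout)
        kway[kind] = shared_regions(cohorts, kind, 2, layout)
        spec[kind] = specificity_summary(cohorts, kind)
    gene_sets: dict[str, set[str]] = {}
    venn: dict[tuple[str, ...], int] = {}
    if genes is not None:
        for c in cohorts:
            rs = [
                r
                for r in c.regions
                if include_broad_genes or r.scope != "broad"
            ]
            gene_sets[c.name] = {g.gene_id for g in genes_in_regions(rs, genes)}
        venn = venn_counts(gene_sets)
    return OverlapReport(pairwise, kway, spec, gene_sets, venn)
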