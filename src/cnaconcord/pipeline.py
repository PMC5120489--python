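"""One-call convenience wrapper: segmentation branch -> recurrence calls.

Chains segment_cohort, to_marker_level, gscore, permutation_null,
marker_qvalues and call_regions with a shared parameter record. This is
the unit the calibration grid and the cross-cohort comparison repeat per
branch.
"""

from __future__ import annotations

from .core_io import CNMatrix, GenomeLayout, PipelineParams
from .gistic_scoring import (
    SignificantRegion,
    call_regions,
    gscore,
    marker_qvalues,
    permutation_null,
)
from .segmentation import segment_cohort, to_marker_level

__all__ = ["score_branch"]


def score_branch(
    m: CNMatrix,
    method: str,
    params: PipelineParams,
    layout: GenomeLayout | None = None,
    null_seed: int | tuple | None = None,
    peel_off: bool = True,
) -> list[SignificantRegion]:
    """Segment with one engine and call significant recurrence regions.

    ``null_seed`` defaults to ``params.seed``; pass a shared value when
    several branches must see the same permutation null.
    """
    segs = segment_cohort(m, method, params)
    ml = to_marker_level(segs, m.probe_map)
    track = gscore(ml, params.theta)
    null = permutation_null(
        ml,
        params.theta,
        params.n_perm_gistic,
        seed=params.seed if null_seed is None else null_seed,
    )
    q = marker_qvalues(track, null)
    return call_regions(
        track,
        q,
        params.q_threshold,
        m.probe_map,
        peel_off=peel_off,
        m=ml,
        null=null,
        layout=layout,
        focal_fraction=params.focal_fraction,
    )
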