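"""Bow-tie / center-circle region classification of the two-axis scatter.

Each merged site has coordinates (x, y) = (mean log2 fold change under ATR
inhibition, mean log2 fold change under RAD1 knockout). Sites within a circle
of radius ``center_radius`` of the origin are unregulated CENTER sites. The
bow-tie wedge is the region between the two lines through the origin with
slopes ``bowtie_fold`` and ``1/bowtie_fold``: points there move concordantly
on both axes within the stated fold interval of correlation. Concordant
decreases in the wedge are Q2 (dependent on both perturbations), concordant
increases Q4. Decreases outside the wedge are dominated by one axis:
knockout-dominant decreases are Q1 (RAD1-dependent, ATR-independent) and
inhibitor-dominant decreases are Q3 (ATR-dependent, RAD1-independent).
Discordant or increase-only points outside the wedge stay UNCLASSIFIED.

Boundary convention (fixed for determinism): the center circle and the wedge
lines are inclusive; x = 0 with y < 0 falls in Q1, y = 0 with x < 0 in Q3.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, List, Sequence, Tuple

from .model import (
    QUADRANTS,
    Axis,
    MergedSite,
    PipelineError,
    PipelineParameters,
    Region,
    RegionAssignment,
)


def assign_region(x: float, y: float, params: PipelineParameters) -> Region:
    """Classify one (x, y) point; see the module docstring for the geometry."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise PipelineError(f"non-finite coordinates ({x}, {y})")
    if math.hypot(x, y) <= params.center_radius:
        return Region.CENTER
    fold = params.bowtie_fold
    if x != 0 and y != 0 and (x < 0) == (y < 0):
        ratio = y / x
        if 1.0 / fold <= ratio <= fold:
            return Region.Q2 if x < 0 else Region.Q4
    if y < 0 and (x >= 0 or y / x > fold):
        return Region.Q1
    if x < 0 and (y >= 0 or 0 < y / x < 1.0 / fold):
        return Region.Q3
    return Region.UNCLASSIFIED


# per quadrant: the axes whose per-replicate ratios carry an expected sign
_EXPECTED_SIGNS: Dict[Region, Tuple[Tuple[Axis, int], ...]] = {
    Region.Q2: ((Axis.ATRI, -1), (Axis.CKO, -1)),
    Region.Q4: ((Axis.ATRI, +1), (Axis.CKO, +1)),
    Region.Q1: ((Axis.CKO, -1),),
    Region.Q3: ((Axis.ATRI, -1),),
}


def consistency_filter(
    site: MergedSite, region: Region, params: PipelineParameters
) -> Tuple[bool, Tuple[Tuple[Axis, str, float], ...]]:
    """Flag quadrant sites with an inverted replicate ratio of magnitude >= threshold.

    An offender is a per-replicate log2 ratio on a sign-constrained axis whose
    sign opposes the quadrant's expectation with |value| at or above
    ``inversion_magnitude``. Returns (passed, offenders).
    """
    if region not in _EXPECTED_SIGNS:
        raise PipelineError(f"consistency filter does not apply to {region.value}")
    offenders: List[Tuple[Axis, str, float]] = []
    per_axis = {Axis.ATRI: site.ratios_atri, Axis.CKO: site.ratios_cko}
    for axis, expected_sign in _EXPECTED_SIGNS[region]:
        for rep, value in per_axis[axis].items():
            inverted = (value > 0 and expected_sign < 0) or (value < 0 and expected_sign > 0)
            if inverted and abs(value) >= params.inversion_magnitude:
                offenders.append((axis, rep, value))
    return (len(offenders) == 0, tuple(offenders))


def classify_sites(
    merged_sites: Sequence[MergedSite], params: PipelineParameters
) -> List[RegionAssignment]:
    """Assign every merged site a region; quadrant sites also get the consistency verdict."""
    assignments: List[RegionAssignment] = []
    for site in merged_sites:
        region = assign_region(site.x, site.y, params)
        if region in _EXPECTED_SIGNS:
            passed, offenders = consistency_filter(site, region, params)
            assignments.append(RegionAssignment(region, passed, offenders))
        else:
            assignments.append(RegionAssignment(region, None, ()))
    return assignments


def summarize_regions(assignments: Sequence[RegionAssignment]) -> Dict[str, Dict[str, int]]:
    """Region counts before and after the consistency filter.

    ``pre`` counts every assignment; ``post`` keeps only quadrant sites that
    passed the filter (CENTER/UNCLASSIFIED counts are unchanged).
    """
    pre = Counter(a.region for a in assignments)
    post = Counter(
        a.region
        for a in assignments
        if a.region not in QUADRANTS or a.passed_consistency
    )
    order = [Region.CENTER, *QUADRANTS, Region.UNCLASSIFIED]
    return {
        "pre": {r.value: int(pre.get(r, 0)) for r in order},
        "post": {r.value: int(post.get(r, 0)) for r in order},
    }
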