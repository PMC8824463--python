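"""Cross-experiment merge of the two perturbation axes.

Sites quantified on both the inhibitor axis and the knockout axis, in at
least ``min_replicates_per_axis`` independent replicates on each, are merged;
their per-axis mean log2 fold changes become the scatter coordinates used for
region classification. Clusters are matched across replicates by their
representative position (member sets can differ between replicates when the
localization ambiguity differs spectrum to spectrum).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

from .model import Axis, ExperimentRatio, MergedSite, PipelineError

DropLog = List[Tuple[Tuple[str, int], int, int, str]]


def merge_datasets(
    ratios_atri: Sequence[ExperimentRatio],
    ratios_cko: Sequence[ExperimentRatio],
    min_replicates_per_axis: int = 2,
) -> Tuple[List[MergedSite], DropLog]:
    """Join the two axes on site key, enforcing the per-axis replicate minimum.

    Returns the merged sites (sorted by protein then position) and a drop log
    listing every site key failing the requirement with its per-axis counts.
    Duplicate (site, axis, replicate) entries are an error: spectra of one
    site must be combined upstream.
    """
    per_axis: Dict[Axis, Dict[Tuple[str, int], Dict[str, float]]] = {
        Axis.ATRI: defaultdict(dict),
        Axis.CKO: defaultdict(dict),
    }
    members: Dict[Tuple[str, int], set] = defaultdict(set)
    for ratios, axis in ((ratios_atri, Axis.ATRI), (ratios_cko, Axis.CKO)):
        for r in ratios:
            if r.perturbation_axis != axis:
                raise PipelineError(
                    f"ratio for {r.site_key} carries axis {r.perturbation_axis}, expected {axis}"
                )
            bucket = per_axis[axis][r.site_key]
            if r.replicate_id in bucket:
                raise PipelineError(
                    f"duplicate ratio for site {r.site_key}, axis {axis.value}, "
                    f"replicate {r.replicate_id!r}"
                )
            bucket[r.replicate_id] = r.log2_fc
            members[r.site_key].update(r.member_positions)

    merged: List[MergedSite] = []
    drop_log: DropLog = []
    all_keys = set(per_axis[Axis.ATRI]) | set(per_axis[Axis.CKO])
    for key in sorted(all_keys):
        atri = per_axis[Axis.ATRI].get(key, {})
        cko = per_axis[Axis.CKO].get(key, {})
        if len(atri) >= min_replicates_per_axis and len(cko) >= min_replicates_per_axis:
            merged.append(
                MergedSite(
                    protein_accession=key[0],
                    representative_position=key[1],
                    clustered_positions=tuple(sorted(members[key])),
                    ratios_atri=dict(sorted(atri.items())),
                    ratios_cko=dict(sorted(cko.items())),
                )
            )
        else:
            drop_log.append(
                (key, len(atri), len(cko), f"fewer than {min_replicates_per_axis} replicates on an axis")
            )
    return merged, drop_log
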