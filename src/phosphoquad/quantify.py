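"""Reporter-ratio computation: missing-value elimination, median log2 fold
changes between treated and control channels, and per-replicate
median-centering normalization."""

from __future__ import annotations

import statistics
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .model import Arm, ChannelDesign, PhosphopeptideRecord, PipelineError


def _observed(intensities: Mapping[str, Optional[float]], channels: Sequence[str]) -> List[float]:
    return [intensities[c] for c in channels if intensities.get(c) is not None]


def arm_observable(record: PhosphopeptideRecord, design: ChannelDesign) -> bool:
    """True when each arm retains at least one observed intensity."""
    return all(
        len(_observed(record.reporter_intensities, design.channels(arm))) > 0
        for arm in (Arm.TREATED, Arm.CONTROL)
    )


def eliminate_missing(
    records: Sequence[PhosphopeptideRecord],
    designs_by_experiment: Mapping[str, ChannelDesign],
) -> List[PhosphopeptideRecord]:
    """Drop peptides whose reporter intensities cannot yield a ratio.

    A record is removed when either condition arm has no observed channel at
    all; a usable treated/control ratio then cannot be formed. Survivors have
    at least one observed intensity in each arm.
    """
    return [r for r in records if arm_observable(r, designs_by_experiment[r.experiment_id])]


def compute_log2_ratio(
    intensities: Mapping[str, Optional[float]], design: ChannelDesign
) -> float:
    """log2(median treated / median control), medians over observed channels only."""
    treated = _observed(intensities, design.channels(Arm.TREATED))
    control = _observed(intensities, design.channels(Arm.CONTROL))
    if not treated or not control:
        raise PipelineError("an arm is fully missing; record should have been eliminated")
    return float(np.log2(statistics.median(treated) / statistics.median(control)))


def record_log2_ratio(record: PhosphopeptideRecord, design: ChannelDesign) -> float:
    return compute_log2_ratio(record.reporter_intensities, design)


def normalize_ratios(ratios: Sequence[float]) -> List[float]:
    """Median-center the log2 ratios of one experiment replicate.

    Subtracting the replicate-wide median puts the bulk of (unregulated)
    sites at zero; the operation is idempotent.
    """
    if len(ratios) == 0:
        raise PipelineError("cannot normalize an empty replicate")
    med = float(np.median(np.asarray(ratios, dtype=float)))
    return [float(r) - med for r in ratios]


def combine_intensities(
    intensity_maps: Sequence[Mapping[str, Optional[float]]], channels: Sequence[str]
) -> Dict[str, Optional[float]]:
    """Sum channel intensities over spectra of the same site cluster.

    Spectra of one site in one replicate must not be double counted as
    separate sites, so their reporter intensities are pooled per channel
    before the median ratio. A channel observed in no contributing spectrum
    stays missing.
    """
    out: Dict[str, Optional[float]] = {}
    for c in channels:
        vals = [m[c] for m in intensity_maps if m.get(c) is not None]
        out[c] = float(sum(vals)) if vals else None
    return out
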