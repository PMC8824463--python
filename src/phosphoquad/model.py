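"""Core record types shared across the pipeline.

Coordinates are 1-based and inclusive throughout: a site's protein position
is ``peptide_start + site_offset - 1``, matching the convention used to name
sites in the proteomics literature (e.g. "serine 353").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple

#: residues that can carry a phosphate group
PHOSPHO_RESIDUES = frozenset("STY")

#: sentinel for a non-detected reporter intensity (empty/zero/non-numeric cell)
MISSING = None

#: pad character used when a motif window overhangs a protein terminus
PAD = "-"


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class SchemaError(PipelineError):
    """A required column or config key is missing or malformed."""


class RecordValidationError(PipelineError):
    """A single input row violates a record invariant (row-level, not fatal)."""


class Arm(str, Enum):
    TREATED = "TREATED"
    CONTROL = "CONTROL"


class Axis(str, Enum):
    """The two perturbation axes: chemical ATR inhibition and genetic RAD1 loss."""

    ATRI = "ATRI"
    CKO = "CKO"


class Region(str, Enum):
    CENTER = "CENTER"
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"
    UNCLASSIFIED = "UNCLASSIFIED"


QUADRANTS = (Region.Q1, Region.Q2, Region.Q3, Region.Q4)


class MotifClass(str, Enum):
    STQ = "STQ"
    STPXK = "STPXK"
    STP_OTHER = "STP_OTHER"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ChannelDesign:
    """Maps the reporter channels of one TMT experiment to treated/control arms.

    One experiment corresponds to one biological replicate of one perturbation
    axis (a sixplex typically carries 3 treated + 3 control channels).
    """

    experiment_id: str
    perturbation_axis: Axis
    replicate_id: str
    channel_to_arm: Mapping[str, Arm]

    def __post_init__(self) -> None:
        arms = set(self.channel_to_arm.values())
        if Arm.TREATED not in arms or Arm.CONTROL not in arms:
            raise SchemaError(
                f"experiment {self.experiment_id!r}: at least one channel must be "
                "mapped to each of TREATED and CONTROL"
            )

    def channels(self, arm: Arm) -> Tuple[str, ...]:
        return tuple(c for c, a in self.channel_to_arm.items() if a == arm)


@dataclass
class PhosphopeptideRecord:
    """One quantified phosphopeptide observation from one experiment.

    ``site_offsets`` are 1-based offsets within the peptide;
    ``site_probabilities`` are the localization probabilities (from an
    upstream localization tool) parallel to the offsets.
    ``reporter_intensities`` maps channel label to a nonnegative float, or
    ``MISSING`` (None) for a non-detection.
    """

    peptide_sequence: str
    protein_accession: str
    peptide_start: int
    site_offsets: Sequence[int]
    site_probabilities: Sequence[float]
    reporter_intensities: Mapping[str, Optional[float]]
    experiment_id: str
    replicate_id: str

    def validate(self) -> None:
        pep = self.peptide_sequence
        if not pep or pep != pep.upper():
            raise RecordValidationError("peptide sequence must be non-empty uppercase")
        if self.peptide_start < 1:
            raise RecordValidationError("peptide_start must be >= 1")
        if len(self.site_offsets) != len(self.site_probabilities):
            raise RecordValidationError("site offsets and probabilities differ in length")
        if not self.site_offsets:
            raise RecordValidationError("record carries no phosphosite")
        for off in self.site_offsets:
            if not 1 <= off <= len(pep):
                raise RecordValidationError(f"site offset {off} outside peptide of length {len(pep)}")
            if pep[off - 1] not in PHOSPHO_RESIDUES:
                raise RecordValidationError(
                    f"residue {pep[off - 1]!r} at offset {off} is not phosphorylatable (S/T/Y)"
                )
        for p in self.site_probabilities:
            if not (0.0 <= p <= 1.0):
                raise RecordValidationError(f"localization probability {p} outside [0, 1]")
        for group in self._ambiguity_groups():
            s = sum(self.site_probabilities[i] for i in group)
            if s > 1.0 + 1e-6:
                raise RecordValidationError(
                    f"probabilities of ambiguity group {group} sum to {s:.6f} > 1"
                )
        for channel, v in self.reporter_intensities.items():
            if v is not None and (not math.isfinite(v) or v < 0):
                raise RecordValidationError(f"channel {channel}: intensity {v!r} invalid")

    def _ambiguity_groups(self) -> list[list[int]]:
        """Indices of sites grouped by contiguous runs of phosphorylatable residues."""
        order = sorted(range(len(self.site_offsets)), key=lambda i: self.site_offsets[i])
        groups: list[list[int]] = []
        for i in order:
            off = self.site_offsets[i]
            if groups:
                prev = self.site_offsets[groups[-1][-1]]
                between = self.peptide_sequence[prev : off - 1]  # residues strictly between
                if all(c in PHOSPHO_RESIDUES for c in between):
                    groups[-1].append(i)
                    continue
            groups.append([i])
        return groups


@dataclass(frozen=True)
class PipelineParameters:
    """Tunable thresholds of the classification pipeline (log2 units unless noted)."""

    localization_threshold: float = 0.85
    center_radius: float = 0.7
    bowtie_fold: float = 5.0
    inversion_magnitude: float = 0.25
    min_replicates_per_axis: int = 2
    motif_flank: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.localization_threshold <= 1.0:
            raise SchemaError("localization_threshold must lie in (0, 1]")
        for name in ("center_radius", "inversion_magnitude"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be strictly positive")
        if self.bowtie_fold <= 1:
            raise SchemaError("bowtie_fold must exceed 1")
        if self.min_replicates_per_axis < 1:
            raise SchemaError("min_replicates_per_axis must be >= 1")
        if self.motif_flank < 1:
            raise SchemaError("motif_flank must be >= 1")


@dataclass(frozen=True)
class SiteCluster:
    """A group of adjacent candidate phosphosites treated as one site.

    Ambiguous localizations across a contiguous run of S/T/Y residues are
    collapsed; the member probabilities are summed into
    ``cumulative_probability`` and the highest-probability member (ties to the
    smallest position) becomes the representative coordinate.
    """

    protein_accession: str
    member_positions: Tuple[int, ...]
    member_probabilities: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.member_positions:
            raise ValueError("cluster must have at least one member")
        if list(self.member_positions) != sorted(set(self.member_positions)):
            raise ValueError("member positions must be strictly ascending")
        if len(self.member_positions) != len(self.member_probabilities):
            raise ValueError("positions and probabilities differ in length")

    @property
    def cumulative_probability(self) -> float:
        return float(sum(self.member_probabilities))

    @property
    def representative_position(self) -> int:
        best = max(self.member_probabilities)
        for pos, p in zip(self.member_positions, self.member_probabilities):
            if p == best:
                return pos
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ExperimentRatio:
    """Normalized log2 fold change of one site cluster in one replicate."""

    protein_accession: str
    representative_position: int
    member_positions: Tuple[int, ...]
    perturbation_axis: Axis
    replicate_id: str
    log2_fc: float

    @property
    def site_key(self) -> Tuple[str, int]:
        return (self.protein_accession, self.representative_position)


@dataclass(frozen=True)
class MergedSite:
    """One phosphosite observed on both perturbation axes.

    ``x`` is the mean log2 fold change over the ATR-inhibitor replicates,
    ``y`` over the knockout replicates; the per-replicate ratios are kept for
    the downstream consistency filter.
    """

    protein_accession: str
    representative_position: int
    clustered_positions: Tuple[int, ...]
    ratios_atri: Mapping[str, float]
    ratios_cko: Mapping[str, float]

    @property
    def site_key(self) -> Tuple[str, int]:
        return (self.protein_accession, self.representative_position)

    @property
    def x(self) -> float:
        return float(sum(self.ratios_atri.values()) / len(self.ratios_atri))

    @property
    def y(self) -> float:
        return float(sum(self.ratios_cko.values()) / len(self.ratios_cko))

    @property
    def n_atri(self) -> int:
        return len(self.ratios_atri)

    @property
    def n_cko(self) -> int:
        return len(self.ratios_cko)


@dataclass(frozen=True)
class RegionAssignment:
    """Region label of a merged site plus its consistency-filter outcome.

    ``passed_consistency`` is None for CENTER/UNCLASSIFIED sites, where the
    filter does not apply.
    """

    region: Region
    passed_consistency: Optional[bool] = None
    offending_replicates: Tuple[Tuple[Axis, str, float], ...] = ()


@dataclass(frozen=True)
class MotifWindow:
    """±flank sequence context around a phosphosite, '-'-padded at termini."""

    window: str
    center_residue: str
    motif_class: MotifClass

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError("window length must be odd")
        mid = self.window[len(self.window) // 2]
        if mid != self.center_residue:
            raise ValueError("center residue does not match window center")


@dataclass(frozen=True)
class EnrichmentResult:
    """Foreground-vs-background enrichment of one motif class (Fisher's exact)."""

    motif_class: str
    foreground_count: int
    foreground_total: int
    background_count: int
    background_total: int
    odds_ratio: float
    p_value: float
    adjusted_p: float = float("nan")
    degenerate: bool = False

    @property
    def foreground_fraction(self) -> float:
        return self.foreground_count / self.foreground_total

    @property
    def background_fraction(self) -> float:
        return self.background_count / self.background_total
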