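"""Synthetic two-perturbation TMT phosphoproteomics data with planted truth.

The generator emulates the statistical structure of a deposited testes
phosphoproteomic dataset at desk scale: log-normal reporter intensities on
six channels (3 treated + 3 control), per-class log2 fold-change shifts on
the two perturbation axes, per-channel noise and dropout, localization
ambiguity split across adjacent S/T residues, and class-dependent motif
composition of the ±6 site windows. Defaults mirror the study design: five
inhibitor-axis replicates and three knockout-axis replicates, strong
concordant decreases for the doubly dependent class (log2 effect ~
N(-1.5, 0.3)), and S/T-P-X-K planted at 15% in Q2 versus 3% in CENTER.

Every planted site is recorded in a truth table so each pipeline stage is
testable without downloading the real deposit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pq_io
from .model import (
    Arm,
    Axis,
    ChannelDesign,
    PipelineError,
    PipelineParameters,
    Region,
)
from .regions import assign_region

# approximate vertebrate proteome residue frequencies (UniProt-style background)
BACKGROUND_COMPOSITION: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

CLASSES = ("Q2", "Q1", "Q3", "Q4", "CENTER")

_DEFAULT_PROPORTIONS = {"Q2": 0.16, "Q1": 0.08, "Q3": 0.08, "Q4": 0.08, "CENTER": 0.60}

# per class: ((mean, sd) of the ATRi-axis log2 effect, (mean, sd) of the cKO-axis effect)
_DEFAULT_EFFECTS = {
    "Q2": ((-1.5, 0.3), (-1.5, 0.3)),
    "Q1": ((0.0, 0.1), (-1.5, 0.3)),
    "Q3": ((-1.5, 0.3), (0.0, 0.1)),
    "Q4": ((1.5, 0.3), (1.5, 0.3)),
    "CENTER": ((0.0, 0.05), (0.0, 0.05)),
}

# per class: probability that the site window realizes each named motif;
# the remainder gets a non-Q/non-P residue at +1 (class OTHER)
_DEFAULT_MOTIF_RATES = {
    "Q2": {"STQ": 0.15, "STPXK": 0.15, "STP_OTHER": 0.27},
    "default": {"STQ": 0.05, "STPXK": 0.03, "STP_OTHER": 0.22},
}

TREATED_CHANNELS = ("126", "127", "128")
CONTROL_CHANNELS = ("129", "130", "131")

# minimum spacing between planted sites so their ±6 windows never overlap
_SITE_SPACING = 16
_EDGE_MARGIN = 10


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the simulator; defaults follow the study design."""

    n_proteins: int = 150
    protein_length: Tuple[int, int] = (300, 800)
    n_sites: int = 1000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    effect_sizes: Mapping[str, Tuple[Tuple[float, float], Tuple[float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    n_replicates_atri: int = 5
    n_replicates_cko: int = 3
    base_intensity_mu: float = 11.5  # natural-log mean of the site base intensity
    base_intensity_sigma: float = 1.0
    noise_sd: float = 0.2  # per-channel log2 noise
    dropout: float = 0.05  # independent per-channel missingness
    ambiguity_prob: float = 0.2  # chance a site's probability splits with an adjacent S/T
    localization_floor: float = 0.9  # cumulative prob = floor + (1-floor) * Beta(a, b)
    localization_beta: Tuple[float, float] = (2.0, 2.0)
    low_confidence_fraction: float = 0.0  # sites planted below the 0.85 threshold
    inverted_replicate_fraction: float = 0.0  # Q2 sites given one inverted ATRi replicate
    inverted_magnitude: float = 0.5
    motif_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MOTIF_RATES.items()}
    )
    motif_flank: int = 6
    #: planted effects are resampled until the true (x, y) lies inside the
    #: planted region with this margin (log2 units) to every region boundary,
    #: so the class label is geometrically self-consistent
    class_margin: float = 0.15

    def __post_init__(self) -> None:
        props = dict(self.class_proportions)
        if set(props) - set(CLASSES):
            raise PipelineError(f"unknown classes {set(props) - set(CLASSES)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise PipelineError("class proportions must sum to 1")
        for p in (
            self.dropout,
            self.ambiguity_prob,
            self.low_confidence_fraction,
            self.inverted_replicate_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise PipelineError(f"probability {p} outside [0, 1]")
        if self.noise_sd < 0 or self.base_intensity_sigma < 0:
            raise PipelineError("standard deviations must be nonnegative")
        if self.protein_length[0] < 2 * _EDGE_MARGIN + _SITE_SPACING:
            raise PipelineError("proteins too short to place any site")
        for cls in CLASSES:
            rates = self.rates_for(cls)
            if sum(rates.values()) > 1.0 + 1e-9:
                raise PipelineError(f"motif rates for {cls} exceed 1")

    def rates_for(self, cls: str) -> Mapping[str, float]:
        return self.motif_rates.get(cls, self.motif_rates.get("default", {}))


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted truth."""

    proteome: Dict[str, str]
    designs: List[ChannelDesign]
    quant_tables: Dict[str, pd.DataFrame]  # experiment_id -> table
    truth: pd.DataFrame
    config: GeneratorConfig
    seed: int


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_residue(rng: np.random.Generator, exclude: Sequence[str] = ()) -> str:
    residues = [r for r in BACKGROUND_COMPOSITION if r not in exclude]
    probs = np.array([BACKGROUND_COMPOSITION[r] for r in residues])
    return str(rng.choice(residues, p=probs / probs.sum()))


def generate_proteome(
    config: GeneratorConfig, seed
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random proteome with planted sites; returns (proteome, placements).

    Placement columns: protein, position, true_class, motif_planted, window,
    ambiguous, partner_position, prob_site, prob_partner, cumulative_prob,
    low_confidence. Site windows are overwritten to realize the planted motif;
    sites are spaced so windows never collide.
    """
    rng = _rng(seed)
    residues = list(BACKGROUND_COMPOSITION)
    probs = np.array(list(BACKGROUND_COMPOSITION.values()))
    probs = probs / probs.sum()

    lengths = rng.integers(config.protein_length[0], config.protein_length[1] + 1, config.n_proteins)
    sequences = {
        f"SYN{i:04d}": list(rng.choice(residues, size=int(L), p=probs))
        for i, L in enumerate(lengths)
    }

    slots: List[Tuple[str, int]] = []
    for acc, seq in sequences.items():
        pos = _EDGE_MARGIN + 1
        while pos <= len(seq) - _EDGE_MARGIN:
            slots.append((acc, pos))
            pos += _SITE_SPACING
    if config.n_sites > len(slots):
        raise PipelineError(
            f"cannot place {config.n_sites} sites: only {len(slots)} slots available; "
            "increase n_proteins or protein lengths"
        )
    chosen = [slots[i] for i in rng.permutation(len(slots))[: config.n_sites]]

    class_names = list(CLASSES)
    class_probs = np.array([config.class_proportions.get(c, 0.0) for c in class_names])
    site_classes = rng.choice(class_names, size=config.n_sites, p=class_probs)

    a, b = config.localization_beta
    flank = config.motif_flank
    rows = []
    for (acc, pos), cls in zip(chosen, site_classes):
        seq = sequences[acc]
        seq[pos - 1] = "S" if rng.random() < 0.5 else "T"

        rates = config.rates_for(cls)
        names = ["STQ", "STPXK", "STP_OTHER"]
        p_named = [rates.get(n, 0.0) for n in names]
        motif = str(rng.choice(names + ["OTHER"], p=p_named + [1.0 - sum(p_named)]))
        if motif == "STQ":
            seq[pos] = "Q"
        elif motif == "STPXK":
            seq[pos] = "P"
            seq[pos + 2] = "K"
        elif motif == "STP_OTHER":
            seq[pos] = "P"
            seq[pos + 2] = _draw_residue(rng, exclude=("K",))
        else:
            seq[pos] = _draw_residue(rng, exclude=("Q", "P"))

        ambiguous = bool(rng.random() < config.ambiguity_prob)
        low_conf = bool(rng.random() < config.low_confidence_fraction)
        if low_conf:
            cumulative = float(rng.uniform(0.3, 0.8))
        else:
            cumulative = config.localization_floor + (1 - config.localization_floor) * float(
                rng.beta(a, b)
            )
        if ambiguous:
            # partner on the -1 side keeps the motif-bearing +1/+3 positions free
            seq[pos - 2] = "S" if rng.random() < 0.5 else "T"
            share = float(rng.uniform(0.55, 0.9))
            prob_site = cumulative * share
            prob_partner = cumulative - prob_site
            partner_position: Optional[int] = pos - 1
        else:
            prob_site, prob_partner, partner_position = cumulative, 0.0, None

        window = "".join(seq[pos - 1 - flank : pos + flank])
        rows.append(
            {
                "protein": acc,
                "position": pos,
                "true_class": cls,
                "motif_planted": motif,
                "window": window,
                "ambiguous": ambiguous,
                "partner_position": -1 if partner_position is None else partner_position,
                "prob_site": prob_site,
                "prob_partner": prob_partner,
                "cumulative_prob": cumulative,
                "low_confidence": low_conf,
            }
        )

    proteome = {acc: "".join(seq) for acc, seq in sequences.items()}
    placements = (
        pd.DataFrame(rows)
        .sort_values(["protein", "position"], kind="mergesort")
        .reset_index(drop=True)
    )
    return proteome, placements


def default_designs(config: GeneratorConfig) -> List[ChannelDesign]:
    designs = []
    for axis, n in ((Axis.ATRI, config.n_replicates_atri), (Axis.CKO, config.n_replicates_cko)):
        for r in range(1, n + 1):
            channel_to_arm = {c: Arm.TREATED for c in TREATED_CHANNELS}
            channel_to_arm.update({c: Arm.CONTROL for c in CONTROL_CHANNELS})
            designs.append(
                ChannelDesign(
                    experiment_id=f"{axis.value}_{r}",
                    perturbation_axis=axis,
                    replicate_id=f"r{r}",
                    channel_to_arm=channel_to_arm,
                )
            )
    return designs


def _draw_class_effects(
    rng: np.random.Generator, cls: str, config: GeneratorConfig
) -> Tuple[float, float]:
    """Draw (ATRi, cKO) log2 effects whose point lies in the planted region.

    The point and the four corners of a ``class_margin`` box around it must
    all classify to the planted region under the default geometry, so small
    normalization shifts cannot move a zero-noise site across a boundary.
    """
    (mx, sx), (my, sy) = config.effect_sizes[cls]
    params = PipelineParameters()
    target = Region(cls)
    m = config.class_margin
    for _ in range(1000):
        ex = float(rng.normal(mx, sx))
        ey = float(rng.normal(my, sy))
        probes = ((ex, ey), (ex - m, ey - m), (ex - m, ey + m), (ex + m, ey - m), (ex + m, ey + m))
        if all(assign_region(px, py, params) is target for px, py in probes):
            return ex, ey
    raise PipelineError(
        f"effect distribution for class {cls} is incompatible with its region geometry"
    )


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticDataset:
    """Generate the full synthetic study: proteome, designs, quant tables, truth."""
    ss = np.random.SeedSequence(seed)
    rng_prot, rng_effects, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    proteome, placements = generate_proteome(config, rng_prot)
    designs = default_designs(config)
    n = len(placements)

    effects = {Axis.ATRI: np.zeros(n), Axis.CKO: np.zeros(n)}
    for i, cls in enumerate(placements["true_class"]):
        effects[Axis.ATRI][i], effects[Axis.CKO][i] = _draw_class_effects(
            rng_effects, cls, config
        )

    # optionally plant one inverted ATRi replicate per selected Q2 site
    inverted_rep = np.full(n, -1)
    q2_idx = np.flatnonzero((placements["true_class"] == "Q2").to_numpy())
    for i in q2_idx:
        if rng_effects.random() < config.inverted_replicate_fraction:
            inverted_rep[i] = int(rng_effects.integers(0, config.n_replicates_atri))

    quant_tables: Dict[str, pd.DataFrame] = {}
    for design in designs:
        axis = design.perturbation_axis
        rep_index = int(design.replicate_id[1:]) - 1
        rows = []
        for i, site in enumerate(placements.itertuples(index=False)):
            base = math.exp(rng_noise.normal(config.base_intensity_mu, config.base_intensity_sigma))
            effect = effects[axis][i]
            if axis is Axis.ATRI and inverted_rep[i] == rep_index:
                effect = config.inverted_magnitude
            intensities = {}
            for channel in (*TREATED_CHANNELS, *CONTROL_CHANNELS):
                shift = effect if channel in TREATED_CHANNELS else 0.0
                eps = rng_noise.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                value = base * 2.0 ** (shift + eps)
                if config.dropout > 0 and rng_noise.random() < config.dropout:
                    intensities[channel] = ""
                else:
                    intensities[channel] = f"{value:.4f}"

            pos = site.position
            pep_start = max(1, pos - 7)
            pep_end = min(len(proteome[site.protein]), pos + 7)
            peptide = proteome[site.protein][pep_start - 1 : pep_end]
            offsets = [pos - pep_start + 1]
            probs = [site.prob_site]
            if site.ambiguous:
                offsets.insert(0, site.partner_position - pep_start + 1)
                probs.insert(0, site.prob_partner)
            rows.append(
                {
                    "experiment_id": design.experiment_id,
                    "replicate_id": design.replicate_id,
                    "peptide": peptide,
                    "protein": site.protein,
                    "peptide_start": pep_start,
                    "site_offsets": ";".join(str(o) for o in offsets),
                    "site_probs": ";".join(f"{p:.6f}" for p in probs),
                    **intensities,
                }
            )
        quant_tables[design.experiment_id] = pd.DataFrame(rows)

    truth = placements.copy()
    truth["effect_atri"] = effects[Axis.ATRI]
    truth["effect_cko"] = effects[Axis.CKO]
    truth["inverted_atri_replicate"] = [
        f"r{r + 1}" if r >= 0 else "" for r in inverted_rep
    ]
    truth["seed"] = seed
    return SyntheticDataset(
        proteome=proteome,
        designs=designs,
        quant_tables=quant_tables,
        truth=truth,
        config=config,
        seed=seed,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Dict[str, Path]:
    """Emit FASTA, per-experiment quant TSVs, design/parameter YAML and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    fasta = out / "proteome.fasta"
    with open(fasta, "w") as fh:
        for acc in sorted(dataset.proteome):
            seq = dataset.proteome[acc]
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["proteome"] = fasta

    for exp_id, table in dataset.quant_tables.items():
        p = out / f"quant_{exp_id}.tsv"
        table.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths[f"quant_{exp_id}"] = p

    from .model import PipelineParameters

    config_path = out / "config.yaml"
    pq_io.write_config(
        dataset.designs,
        PipelineParameters(),
        config_path,
        generator={"seed": dataset.seed, "n_sites": dataset.config.n_sites},
    )
    paths["config"] = config_path

    truth_path = out / "truth.tsv"
    dataset.truth.to_csv(
        truth_path, sep="\t", index=False, float_format="%.6f", lineterminator="\n"
    )
    paths["truth"] = truth_path
    return paths


@dataclass
class RecoveryReport:
    confusion: pd.DataFrame  # rows: truth classes; columns: predicted regions + MISSING
    precision: Dict[str, float]
    recall: Dict[str, float]


def evaluate_recovery(
    assignments: Mapping[Tuple[str, int], str | Region],
    truth: pd.DataFrame,
) -> RecoveryReport:
    """Confusion matrix plus per-class precision/recall of planted classes.

    ``assignments`` maps (protein, representative position) to the predicted
    region; truth sites missing from the assignments are tallied in the
    MISSING column and count against recall.
    """
    pred_labels = [r.value for r in Region] + ["MISSING"]
    confusion = pd.DataFrame(0, index=list(CLASSES), columns=pred_labels)
    normalized = {
        key: (r.value if isinstance(r, Region) else str(r)) for key, r in assignments.items()
    }
    truth_keys = set()
    for site in truth.itertuples(index=False):
        key = (site.protein, int(site.position))
        truth_keys.add(key)
        predicted = normalized.get(key, "MISSING")
        confusion.loc[site.true_class, predicted] += 1
    extra = set(normalized) - truth_keys
    if extra:
        raise PipelineError(f"assignments carry {len(extra)} site keys absent from truth")

    precision: Dict[str, float] = {}
    recall: Dict[str, float] = {}
    for cls in CLASSES:
        tp = int(confusion.loc[cls, cls])
        n_true = int(confusion.loc[cls].sum())
        n_pred = int(confusion[cls].sum())
        recall[cls] = tp / n_true if n_true else float("nan")
        precision[cls] = tp / n_pred if n_pred else float("nan")
    return RecoveryReport(confusion=confusion, precision=precision, recall=recall)


def config_from_dict(overrides: Mapping) -> GeneratorConfig:
    """Build a GeneratorConfig from a (YAML-derived) mapping of overrides."""
    kwargs = dict(overrides)
    kwargs.pop("seed", None)
    if "protein_length" in kwargs:
        kwargs["protein_length"] = tuple(kwargs["protein_length"])
    if "localization_beta" in kwargs:
        kwargs["localization_beta"] = tuple(kwargs["localization_beta"])
    if "effect_sizes" in kwargs:
        kwargs["effect_sizes"] = {
            cls: (tuple(v[0]), tuple(v[1])) for cls, v in kwargs["effect_sizes"].items()
        }
    valid = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(kwargs) - valid
    if unknown:
        raise PipelineError(f"unknown generator option(s) {sorted(unknown)}")
    return GeneratorConfig(**kwargs)
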