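"""Readers and writers for the tab-separated tables, FASTA and YAML config.

The pipeline starts at the quantified-phosphopeptide level: one row per
phosphopeptide-spectrum group with six reporter-channel intensities. Raw and
search-engine formats (mzML, pepXML) are out of scope.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .model import (
    MISSING,
    Arm,
    Axis,
    ChannelDesign,
    MergedSite,
    PhosphopeptideRecord,
    PipelineParameters,
    RecordValidationError,
    RegionAssignment,
    SchemaError,
)

REQUIRED_COLUMNS = (
    "experiment_id",
    "replicate_id",
    "peptide",
    "protein",
    "peptide_start",
    "site_offsets",
    "site_probs",
)

RESULT_COLUMNS = (
    "protein",
    "site_position",
    "clustered_positions",
    "mean_log2fc_atri",
    "mean_log2fc_cko",
    "n_reps_atri",
    "n_reps_cko",
    "region",
    "passed_consistency",
    "motif_class",
    "window",
)


def _parse_intensity(cell: object) -> Optional[float]:
    """Empty, zero and non-numeric cells are all non-detections."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return MISSING
    s = str(cell).strip()
    if not s:
        return MISSING
    try:
        v = float(s)
    except ValueError:
        return MISSING
    if v <= 0 or not math.isfinite(v):
        return MISSING
    return v


def read_quant_table(
    path: str | Path,
    designs: Sequence[ChannelDesign],
) -> Tuple[List[PhosphopeptideRecord], List[Tuple[int, str]]]:
    """Read a quantification table; returns (records, rejections).

    Rejections are (0-based row index, reason) pairs for rows violating the
    record invariants; accepted + rejected always equals the input row count.
    Raises :class:`SchemaError` when a required column is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s) {missing_cols}")
    by_exp = {d.experiment_id: d for d in designs}
    all_channels = sorted({c for d in designs for c in d.channel_to_arm})
    missing_channels = [c for c in all_channels if c not in df.columns]
    if missing_channels:
        raise SchemaError(f"{path}: missing intensity column(s) {missing_channels}")

    records: List[PhosphopeptideRecord] = []
    rejections: List[Tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            exp_id = row_d["experiment_id"]
            design = by_exp.get(exp_id)
            if design is None:
                raise RecordValidationError(f"unknown experiment_id {exp_id!r}")
            offsets = [int(t) for t in str(row_d["site_offsets"]).split(";") if t.strip()]
            probs = [float(t) for t in str(row_d["site_probs"]).split(";") if t.strip()]
            record = PhosphopeptideRecord(
                peptide_sequence=str(row_d["peptide"]).strip(),
                protein_accession=str(row_d["protein"]).strip(),
                peptide_start=int(row_d["peptide_start"]),
                site_offsets=offsets,
                site_probabilities=probs,
                reporter_intensities={
                    c: _parse_intensity(row_d[c]) for c in design.channel_to_arm
                },
                experiment_id=exp_id,
                replicate_id=str(row_d["replicate_id"]).strip(),
            )
            record.validate()
        except (RecordValidationError, ValueError) as exc:
            rejections.append((i, str(exc)))
            continue
        records.append(record)
    return records, rejections


def _parse_accession(header: str, uniprot_headers: bool) -> str:
    token = header.split()[0]
    if uniprot_headers and token.count("|") >= 2:
        parts = token.split("|")
        if parts[0] in ("sp", "tr") and parts[1]:
            return parts[1]
    return token


def read_proteome(path: str | Path, uniprot_headers: bool = False) -> dict[str, str]:
    """Read a FASTA proteome into {accession: uppercase sequence}.

    The accession is the first whitespace-delimited header token; with
    ``uniprot_headers=True``, ``sp|ACC|NAME`` headers are parsed to ``ACC``.
    Duplicate accessions, digits in sequences and empty files are errors
    ('X' is tolerated as an unknown residue).
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _parse_accession(rec.description or rec.id, uniprot_headers)
        seq = str(rec.seq).upper()
        if acc in proteome:
            raise SchemaError(f"duplicate accession {acc!r} in {path}")
        if any(ch.isdigit() for ch in seq):
            raise SchemaError(f"sequence of {acc!r} contains digits")
        proteome[acc] = seq
    if not proteome:
        raise SchemaError(f"{path}: no FASTA records found")
    return proteome


def results_frame(
    merged_sites: Sequence[MergedSite],
    assignments: Sequence[RegionAssignment],
    motif_classes: Optional[Sequence[str]] = None,
    windows: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble the results table (one row per merged site), deterministically sorted."""
    if len(merged_sites) != len(assignments):
        raise ValueError("assignments must be parallel to merged_sites")
    n = len(merged_sites)
    motif_classes = list(motif_classes) if motif_classes is not None else [""] * n
    windows = list(windows) if windows is not None else [""] * n
    rows = []
    for site, asg, mc, win in zip(merged_sites, assignments, motif_classes, windows):
        rows.append(
            {
                "protein": site.protein_accession,
                "site_position": site.representative_position,
                "clustered_positions": ";".join(str(p) for p in site.clustered_positions),
                "mean_log2fc_atri": site.x,
                "mean_log2fc_cko": site.y,
                "n_reps_atri": site.n_atri,
                "n_reps_cko": site.n_cko,
                "region": asg.region.value,
                "passed_consistency": "" if asg.passed_consistency is None else str(asg.passed_consistency),
                "motif_class": mc,
                "window": win,
            }
        )
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return df.sort_values(["protein", "site_position"], kind="mergesort").reset_index(drop=True)


def write_results(
    merged_sites: Sequence[MergedSite],
    assignments: Sequence[RegionAssignment],
    path: str | Path,
    motif_classes: Optional[Sequence[str]] = None,
    windows: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Write the results table as TSV; floats carry 6 decimals so a round trip is exact."""
    df = results_frame(merged_sites, assignments, motif_classes, windows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing result column(s) {missing}")
    for col in ("mean_log2fc_atri", "mean_log2fc_cko"):
        df[col] = df[col].astype(float)
    for col in ("site_position", "n_reps_atri", "n_reps_cko"):
        df[col] = df[col].astype(int)
    return df


def write_drop_log(drop_log: Iterable[Tuple[Tuple[str, int], int, int, str]], path: str | Path) -> None:
    """Write the merge drop log: site, per-axis replicate counts, reason."""
    rows = [
        {"site": f"{key[0]}:{key[1]}", "n_atri": na, "n_cko": nc, "reason": reason}
        for key, na, nc, reason in drop_log
    ]
    pd.DataFrame(rows, columns=["site", "n_atri", "n_cko", "reason"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def _parse_design_entry(entry: Mapping) -> ChannelDesign:
    try:
        return ChannelDesign(
            experiment_id=str(entry["experiment_id"]),
            perturbation_axis=Axis(str(entry["perturbation_axis"]).upper()),
            replicate_id=str(entry["replicate_id"]),
            channel_to_arm={str(c): Arm(str(a).upper()) for c, a in entry["channels"].items()},
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"invalid experiment design entry {entry!r}: {exc}") from exc


def read_config(path: str | Path) -> Tuple[List[ChannelDesign], PipelineParameters, dict]:
    """Read the YAML config: experiment designs, pipeline parameters and
    (optionally) generator settings. Returns (designs, parameters, generator_dict)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "experiments" not in raw:
        raise SchemaError(f"{path}: config must list 'experiments'")
    designs = [_parse_design_entry(e) for e in raw["experiments"]]
    if len({d.experiment_id for d in designs}) != len(designs):
        raise SchemaError("experiment_id values must be unique")
    params = PipelineParameters(**(raw.get("parameters") or {}))
    return designs, params, dict(raw.get("generator") or {})


def write_config(
    designs: Sequence[ChannelDesign],
    params: PipelineParameters,
    path: str | Path,
    generator: Optional[Mapping] = None,
) -> None:
    doc = {
        "experiments": [
            {
                "experiment_id": d.experiment_id,
                "perturbation_axis": d.perturbation_axis.value,
                "replicate_id": d.replicate_id,
                "channels": {c: a.value for c, a in d.channel_to_arm.items()},
            }
            for d in designs
        ],
        "parameters": {
            "localization_threshold": params.localization_threshold,
            "center_radius": params.center_radius,
            "bowtie_fold": params.bowtie_fold,
            "inversion_magnitude": params.inversion_magnitude,
            "min_replicates_per_axis": params.min_replicates_per_axis,
            "motif_flank": params.motif_flank,
        },
    }
    if generator:
        doc["generator"] = dict(generator)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
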