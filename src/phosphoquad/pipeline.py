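"""End-to-end orchestration: quantify -> cluster -> merge -> classify -> motif.

Ratios are computed at the clustered-site level: within one experiment
replicate, all spectra mapping to the same site cluster have their reporter
intensities summed per channel before the median ratio, so one site is never
counted twice. Log2 ratios are then median-centered within each replicate.

Every stage reports its in/out record counts so the filtering funnel (missing
values, localization, replicates, region, consistency) can be reconstructed
from the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import io as pq_io
from .clustering import cluster_adjacent_sites, filter_localization
from .merge import DropLog, merge_datasets
from .model import (
    Axis,
    ChannelDesign,
    ExperimentRatio,
    MergedSite,
    PhosphopeptideRecord,
    PipelineParameters,
    Region,
    RegionAssignment,
)
from .motifs import STP, MotifClass, enrichment_frame, extract_window, motif_enrichment
from .quantify import combine_intensities, compute_log2_ratio, eliminate_missing, normalize_ratios
from .regions import classify_sites, summarize_regions


@dataclass
class PipelineResult:
    ratios: List[ExperimentRatio]
    merged_sites: List[MergedSite]
    assignments: List[RegionAssignment]
    drop_log: DropLog
    funnel: Dict[str, int] = field(default_factory=dict)


def quantify_replicates(
    records: Sequence[PhosphopeptideRecord],
    designs: Sequence[ChannelDesign],
    proteome: Mapping[str, str],
    params: PipelineParameters,
) -> Tuple[List[ExperimentRatio], Dict[str, int]]:
    """Per-replicate normalized log2 ratios at the clustered-site level.

    Stages: missing-value elimination; adjacency clustering of each record's
    sites with the cumulative localization filter (> threshold); per-channel
    summing of spectra sharing a cluster within a replicate; median treated /
    median control log2 ratio; median-centering within each replicate.
    """
    by_exp = {d.experiment_id: d for d in designs}
    funnel = {"records_in": len(records)}
    kept = eliminate_missing(records, by_exp)
    funnel["records_after_missing_filter"] = len(kept)

    # Spectra of the same site in the same replicate are pooled. Clusters are
    # reconciled by representative position (member sets can differ spectrum
    # to spectrum when localization ambiguity differs).
    groups: Dict[Tuple[Axis, str, str, int], List[Mapping]] = defaultdict(list)
    members: Dict[Tuple[Axis, str, str, int], set] = defaultdict(set)
    n_clusters = 0
    n_localized = 0
    for record in kept:
        design = by_exp[record.experiment_id]
        clusters = cluster_adjacent_sites(record, proteome)
        n_clusters += len(clusters)
        valid = filter_localization(clusters, params.localization_threshold)
        n_localized += len(valid)
        for cluster in valid:
            key = (
                design.perturbation_axis,
                design.replicate_id,
                cluster.protein_accession,
                cluster.representative_position,
            )
            groups[key].append(record.reporter_intensities)
            members[key].update(cluster.member_positions)
    funnel["clusters_total"] = n_clusters
    funnel["clusters_localized"] = n_localized

    prelim: Dict[Tuple[Axis, str], List[Tuple[str, int, Tuple[int, ...], float]]] = defaultdict(list)
    for (axis, rep, protein, rep_pos), intensity_maps in sorted(
        groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2], kv[0][3])
    ):
        design = next(
            d for d in designs if d.perturbation_axis == axis and d.replicate_id == rep
        )
        combined = combine_intensities(intensity_maps, list(design.channel_to_arm))
        log2_fc = compute_log2_ratio(combined, design)
        positions = tuple(sorted(members[(axis, rep, protein, rep_pos)]))
        prelim[(axis, rep)].append((protein, rep_pos, positions, log2_fc))

    ratios: List[ExperimentRatio] = []
    for (axis, rep), entries in sorted(prelim.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        centered = normalize_ratios([e[3] for e in entries])
        for (protein, rep_pos, positions, _), fc in zip(entries, centered):
            ratios.append(
                ExperimentRatio(
                    protein_accession=protein,
                    representative_position=rep_pos,
                    member_positions=positions,
                    perturbation_axis=axis,
                    replicate_id=rep,
                    log2_fc=fc,
                )
            )
    funnel["replicate_site_ratios"] = len(ratios)
    return ratios, funnel


def run_pipeline(
    records: Sequence[PhosphopeptideRecord],
    designs: Sequence[ChannelDesign],
    proteome: Mapping[str, str],
    params: PipelineParameters,
) -> PipelineResult:
    """Records -> per-replicate ratios -> merged sites -> region assignments."""
    ratios, funnel = quantify_replicates(records, designs, proteome, params)
    atri = [r for r in ratios if r.perturbation_axis is Axis.ATRI]
    cko = [r for r in ratios if r.perturbation_axis is Axis.CKO]
    merged, drop_log = merge_datasets(atri, cko, params.min_replicates_per_axis)
    funnel["merged_sites"] = len(merged)
    funnel["dropped_by_replicate_rule"] = len(drop_log)
    assignments = classify_sites(merged, params)
    funnel["passed_consistency"] = sum(
        1 for a in assignments if a.passed_consistency is True
    )
    return PipelineResult(
        ratios=ratios,
        merged_sites=merged,
        assignments=assignments,
        drop_log=drop_log,
        funnel=funnel,
    )


def ratios_frame(ratios: Sequence[ExperimentRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "axis": r.perturbation_axis.value,
                "replicate_id": r.replicate_id,
                "protein": r.protein_accession,
                "representative_position": r.representative_position,
                "member_positions": ";".join(str(p) for p in r.member_positions),
                "log2_fc": r.log2_fc,
            }
            for r in ratios
        ]
    )


def motif_tables(
    result: PipelineResult,
    proteome: Mapping[str, str],
    params: PipelineParameters,
) -> Dict[str, pd.DataFrame]:
    """Motif outputs: Q2 (consistency-passing) foreground vs CENTER background.

    Returns the per-class enrichment table, the +1-position distribution of
    the foreground, and the foreground/background relative-proportion matrix.
    """
    from .motifs import frequency_matrix, plus_one_distribution, relative_proportion_matrix

    fg_windows, bg_windows = [], []
    for site, asg in zip(result.merged_sites, result.assignments):
        w = extract_window(
            proteome, site.protein_accession, site.representative_position, params.motif_flank
        )
        if asg.region is Region.Q2 and asg.passed_consistency:
            fg_windows.append(w)
        elif asg.region is Region.CENTER:
            bg_windows.append(w)
    tables: Dict[str, pd.DataFrame] = {}
    if fg_windows and bg_windows:
        results = motif_enrichment(
            fg_windows,
            bg_windows,
            (MotifClass.STQ.value, MotifClass.STPXK.value, MotifClass.STP_OTHER.value, STP),
        )
        tables["enrichment"] = enrichment_frame(results)
        dist = plus_one_distribution(fg_windows)
        tables["plus_one"] = pd.DataFrame(
            {"residue": list(dist), "count": list(dist.values())}
        )
        tables["relative_proportion"] = relative_proportion_matrix(
            fg_windows, bg_windows, params.motif_flank
        )
        tables["frequency_fg"] = frequency_matrix(fg_windows, params.motif_flank)
    return tables


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config_path: str | Path,
    out_dir: str | Path,
    seed: Optional[int] = None,
    quant_paths: Optional[Sequence[str | Path]] = None,
    fasta_path: Optional[str | Path] = None,
) -> Dict:
    """Run the whole pipeline from a YAML config; returns the run manifest.

    When the config carries a ``generator`` section and no quant tables are
    given, a synthetic dataset is generated (and written) first; otherwise
    the provided quant tables and FASTA are used.
    """
    from .simulate import config_from_dict, generate_dataset, write_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    designs, params, generator = pq_io.read_config(config_path)
    t0 = time.time()
    timings: Dict[str, float] = {}
    input_hashes: Dict[str, str] = {str(config_path): _sha256(Path(config_path))}

    if quant_paths is None:
        if not generator:
            raise pq_io.SchemaError(
                "config has no 'generator' section and no quant tables were given"
            )
        gen_seed = seed if seed is not None else int(generator.get("seed", 0))
        dataset = generate_dataset(config_from_dict(generator), gen_seed)
        data_dir = out / "data"
        paths = write_dataset(dataset, data_dir)
        designs = dataset.designs
        quant_paths = [paths[k] for k in sorted(paths) if k.startswith("quant_")]
        fasta_path = paths["proteome"]
        timings["generate"] = time.time() - t0

    if fasta_path is None:
        raise pq_io.SchemaError("a proteome FASTA is required")
    proteome = pq_io.read_proteome(fasta_path)
    input_hashes[str(fasta_path)] = _sha256(Path(fasta_path))

    records: List[PhosphopeptideRecord] = []
    n_rejected = 0
    for qp in quant_paths:
        recs, rejections = pq_io.read_quant_table(qp, designs)
        records.extend(recs)
        n_rejected += len(rejections)
        input_hashes[str(qp)] = _sha256(Path(qp))
    t1 = time.time()
    timings["read"] = t1 - t0

    result = run_pipeline(records, designs, proteome, params)
    result.funnel["rows_rejected_on_read"] = n_rejected
    timings["pipeline"] = time.time() - t1

    motif_classes, windows = [], []
    for site in result.merged_sites:
        w = extract_window(
            proteome, site.protein_accession, site.representative_position, params.motif_flank
        )
        motif_classes.append(w.motif_class.value)
        windows.append(w.window)

    outputs: Dict[str, str] = {}
    results_path = out / "results.tsv"
    pq_io.write_results(
        result.merged_sites, result.assignments, results_path, motif_classes, windows
    )
    outputs["results"] = str(results_path)

    ratios_path = out / "ratios.tsv"
    ratios_frame(result.ratios).to_csv(
        ratios_path, sep="\t", index=False, float_format="%.6f", lineterminator="\n"
    )
    outputs["ratios"] = str(ratios_path)

    drop_path = out / "drop_log.tsv"
    pq_io.write_drop_log(result.drop_log, drop_path)
    outputs["drop_log"] = str(drop_path)

    summary_path = out / "region_summary.json"
    summary = summarize_regions(result.assignments)
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    outputs["region_summary"] = str(summary_path)

    for name, table in motif_tables(result, proteome, params).items():
        p = out / f"motif_{name}.tsv"
        table.to_csv(p, sep="\t", float_format="%.6f", lineterminator="\n")
        outputs[f"motif_{name}"] = str(p)

    manifest = {
        "parameters": {
            "localization_threshold": params.localization_threshold,
            "center_radius": params.center_radius,
            "bowtie_fold": params.bowtie_fold,
            "inversion_magnitude": params.inversion_magnitude,
            "min_replicates_per_axis": params.min_replicates_per_axis,
            "motif_flank": params.motif_flank,
        },
        "seed": seed,
        "input_hashes": input_hashes,
        "output_hashes": {k: _sha256(Path(v)) for k, v in outputs.items()},
        "outputs": outputs,
        "funnel": result.funnel,
        "region_summary": summary,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
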