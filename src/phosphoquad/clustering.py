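"""Phosphosite localization clustering.

An upstream localization tool may split one phosphate's probability across
neighbouring S/T/Y residues. Sites localized to *adjacent phosphorylatable
residues* — a contiguous run of S/T/Y in the protein with no other residue
between them — are collapsed into one cluster whose localization
probabilities are summed; clusters whose cumulative probability stays above
the threshold are kept as valid sites.
"""

from __future__ import annotations

from typing import List, Mapping, Sequence

from .model import PHOSPHO_RESIDUES, PhosphopeptideRecord, PipelineError, SiteCluster


def map_sites_to_protein(
    record: PhosphopeptideRecord, proteome: Mapping[str, str]
) -> List[tuple[int, float]]:
    """(protein position, probability) pairs for a record, 1-based, ascending."""
    seq = proteome.get(record.protein_accession)
    if seq is None:
        raise PipelineError(f"unknown protein {record.protein_accession!r}")
    pairs = []
    for off, prob in zip(record.site_offsets, record.site_probabilities):
        pos = record.peptide_start + off - 1
        if pos > len(seq):
            raise PipelineError(
                f"site position {pos} exceeds length {len(seq)} of {record.protein_accession}"
            )
        if seq[pos - 1] not in PHOSPHO_RESIDUES:
            raise PipelineError(
                f"{record.protein_accession} position {pos}: residue {seq[pos - 1]!r} "
                "is not phosphorylatable; peptide-to-protein mapping is inconsistent"
            )
        pairs.append((pos, float(prob)))
    return sorted(pairs)


def cluster_adjacent_sites(
    record: PhosphopeptideRecord, proteome: Mapping[str, str]
) -> List[SiteCluster]:
    """Merge a record's sites into maximal runs of adjacent phosphorylatable residues.

    Two sites belong to the same cluster iff every protein residue between
    them is itself S/T/Y (a contiguous phosphorylatable run). Isolated sites
    become singleton clusters; every input site lands in exactly one cluster.
    """
    seq = proteome[record.protein_accession]
    pairs = map_sites_to_protein(record, proteome)
    runs: List[List[tuple[int, float]]] = []
    for pos, prob in pairs:
        if runs:
            prev_pos = runs[-1][-1][0]
            between = seq[prev_pos : pos - 1]  # residues strictly between, 0-based slice
            if all(c in PHOSPHO_RESIDUES for c in between):
                runs[-1].append((pos, prob))
                continue
        runs.append([(pos, prob)])
    return [
        SiteCluster(
            protein_accession=record.protein_accession,
            member_positions=tuple(p for p, _ in run),
            member_probabilities=tuple(q for _, q in run),
        )
        for run in runs
    ]


def filter_localization(
    clusters: Sequence[SiteCluster], localization_threshold: float
) -> List[SiteCluster]:
    """Keep clusters whose summed localization probability is strictly above threshold."""
    return [c for c in clusters if c.cumulative_probability > localization_threshold]
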