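"""Phosphorylation-motif analysis around site windows.

Windows of ±flank residues around each representative site position are
classified into the kinase-substrate motif classes relevant to checkpoint
signaling: S/T-Q (the preferred direct substrate motif of the apical
checkpoint kinases), S/T-P-X-K (a proline-directed, CDK-type motif) and the
remaining proline-directed S/T-P sites. Foreground (e.g. Q2) versus
background (CENTER) enrichment uses Fisher's exact test with
Benjamini-Hochberg adjustment across the classes tested in one batch.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import PAD, EnrichmentResult, MotifClass, MotifWindow, PipelineError

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: composite class: every proline-directed site (S/T-P-X-K plus the rest)
STP = "STP"


def extract_window(
    proteome: Mapping[str, str], protein: str, position: int, flank: int = 6
) -> MotifWindow:
    """±flank window centered at a 1-based protein position, '-'-padded at termini."""
    seq = proteome.get(protein)
    if seq is None:
        raise PipelineError(f"unknown protein {protein!r}")
    if not 1 <= position <= len(seq):
        raise PipelineError(f"position {position} outside protein {protein!r} (length {len(seq)})")
    chars = [
        seq[i - 1] if 1 <= i <= len(seq) else PAD
        for i in range(position - flank, position + flank + 1)
    ]
    window = "".join(chars)
    return MotifWindow(window=window, center_residue=seq[position - 1], motif_class=classify_motif(window))


def _at(window: str, offset: int) -> str:
    """Character at signed offset from the window center; pad if out of range."""
    mid = len(window) // 2
    i = mid + offset
    return window[i] if 0 <= i < len(window) else PAD


def classify_motif(window: str) -> MotifClass:
    """Mutually exclusive motif class of a window (S/T center required for the named classes)."""
    if len(window) % 2 != 1:
        raise PipelineError(f"window length {len(window)} is not odd")
    center = _at(window, 0)
    if center not in ("S", "T"):
        return MotifClass.OTHER
    plus1 = _at(window, 1)
    if plus1 == "Q":
        return MotifClass.STQ
    if plus1 == "P":
        return MotifClass.STPXK if _at(window, 3) == "K" else MotifClass.STP_OTHER
    return MotifClass.OTHER


def _as_window_strings(windows: Iterable[Union[str, MotifWindow]]) -> List[str]:
    return [w.window if isinstance(w, MotifWindow) else w for w in windows]


def plus_one_distribution(windows: Sequence[Union[str, MotifWindow]]) -> Dict[str, int]:
    """Counts of the residue immediately following the site (pad bucket included)."""
    ws = _as_window_strings(windows)
    if not ws:
        raise PipelineError("no windows given")
    counts = Counter(_at(w, 1) for w in ws)
    out = {res: counts.pop(res, 0) for res in AMINO_ACIDS}
    out[PAD] = counts.pop(PAD, 0)
    out.update(counts)  # non-standard residues such as 'X'
    return out


def frequency_matrix(windows: Sequence[Union[str, MotifWindow]], flank: int) -> pd.DataFrame:
    """Per-position residue proportions (rows = residues, columns = -flank..+flank).

    Pad characters are excluded from the denominators so terminus windows do
    not dilute the proportions; each column with any non-pad character sums to 1.
    """
    ws = _as_window_strings(windows)
    if not ws:
        raise PipelineError("no windows given")
    positions = list(range(-flank, flank + 1))
    residues = sorted(set("".join(ws)) - {PAD} | set(AMINO_ACIDS))
    mat = pd.DataFrame(0.0, index=residues, columns=positions)
    for pos in positions:
        col = Counter(_at(w, pos) for w in ws)
        col.pop(PAD, None)
        total = sum(col.values())
        if total:
            for res, n in col.items():
                mat.loc[res, pos] = n / total
    return mat


def relative_proportion_matrix(
    foreground_windows: Sequence[Union[str, MotifWindow]],
    background_windows: Sequence[Union[str, MotifWindow]],
    flank: int,
) -> pd.DataFrame:
    """Fold difference of per-position residue proportions, foreground over background.

    Proportions are smoothed with a pseudo-count of 0.5 per residue so
    residues absent from one set still yield finite ratios; identical sets
    give a matrix of exact ones.
    """
    fg = _as_window_strings(foreground_windows)
    bg = _as_window_strings(background_windows)
    if not fg or not bg:
        raise PipelineError("both window sets must be non-empty")
    positions = list(range(-flank, flank + 1))
    residues = sorted(set("".join(fg) + "".join(bg)) - {PAD} | set(AMINO_ACIDS))
    k = len(residues)

    def smoothed(ws: List[str]) -> pd.DataFrame:
        out = pd.DataFrame(0.0, index=residues, columns=positions)
        for pos in positions:
            col = Counter(_at(w, pos) for w in ws)
            col.pop(PAD, None)
            total = sum(col.values())
            for res in residues:
                out.loc[res, pos] = (col.get(res, 0) + 0.5) / (total + 0.5 * k)
        return out

    return smoothed(fg) / smoothed(bg)


def _in_class(window: str, motif_class: str) -> bool:
    cls = classify_motif(window)
    if motif_class == STP:
        return cls in (MotifClass.STPXK, MotifClass.STP_OTHER)
    return cls == MotifClass(motif_class)


def motif_enrichment(
    foreground_windows: Sequence[Union[str, MotifWindow]],
    background_windows: Sequence[Union[str, MotifWindow]],
    motif_classes: Union[str, Sequence[str]] = (
        MotifClass.STQ.value,
        MotifClass.STPXK.value,
        MotifClass.STP_OTHER.value,
        STP,
    ),
) -> Union[EnrichmentResult, List[EnrichmentResult]]:
    """Fisher's exact enrichment of motif classes, foreground versus background.

    ``motif_classes`` may be a single class name (returns one result) or a
    sequence (returns a list; BH adjustment is applied across the batch). A
    2x2 table with an empty margin is flagged ``degenerate`` and its odds
    ratio reported as NaN.
    """
    single = isinstance(motif_classes, str)
    classes = [motif_classes] if single else list(motif_classes)
    fg = _as_window_strings(foreground_windows)
    bg = _as_window_strings(background_windows)
    if not fg or not bg:
        raise PipelineError("both window sets must be non-empty")

    results: List[EnrichmentResult] = []
    for cls in classes:
        a = sum(_in_class(w, cls) for w in fg)
        b = sum(_in_class(w, cls) for w in bg)
        table = np.array([[a, len(fg) - a], [b, len(bg) - b]])
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(
                motif_class=cls,
                foreground_count=int(a),
                foreground_total=len(fg),
                background_count=int(b),
                background_total=len(bg),
                odds_ratio=float("nan") if degenerate else float(odds),
                p_value=float(p),
                degenerate=bool(degenerate),
            )
        )
    adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            motif_class=r.motif_class,
            foreground_count=r.foreground_count,
            foreground_total=r.foreground_total,
            background_count=r.background_count,
            background_total=r.background_total,
            odds_ratio=r.odds_ratio,
            p_value=r.p_value,
            adjusted_p=float(q),
            degenerate=r.degenerate,
        )
        for r, q in zip(results, adjusted)
    ]
    return results[0] if single else results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_class": r.motif_class,
                "fg_count": r.foreground_count,
                "fg_total": r.foreground_total,
                "fg_fraction": r.foreground_fraction,
                "bg_count": r.background_count,
                "bg_total": r.background_total,
                "bg_fraction": r.background_fraction,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
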