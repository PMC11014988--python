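"""Sliding-window Kyte–Doolittle hydropathy profiles.

A protein's local hydrophobicity is summarized by the mean hydropathy of
each w-residue window (default w = 20, roughly one transmembrane helix);
the maximum over windows ("max peak of local hydrophobicity", Φ_max) is a
simple scalar that separates membrane-embedded proteins from soluble ones
and is the statistic used to characterize proteins that relocalize from
mitochondria to the ER when contact sites are lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import HydropathyScale, ProteinRecord, kd_scale
from .statsutils import KsResult, QuartileSummary, ks_two_sample, quartile_summary

DEFAULT_WINDOW = 20


@dataclass
class HydrophobicityProfile:
    """Windowed hydropathy scores for one protein.

    ``scores[i]`` is the mean scale value over residues ``i+1 .. i+w``
    (1-based inclusive window coordinates); there are ``L − w + 1`` windows.
    """

    id: str
    window_length: int
    scores: np.ndarray

    @property
    def max_phi(self) -> float:
        return float(np.max(self.scores))

    @property
    def argmax_position(self) -> int:
        """1-based start coordinate of the highest-scoring window."""
        return int(np.argmax(self.scores)) + 1


def kd_profile(
    record: ProteinRecord,
    scale: HydropathyScale | None = None,
    w: int = DEFAULT_WINDOW,
    statistic: str = "mean",
) -> HydrophobicityProfile:
    """Compute the sliding-window hydropathy profile of one protein.

    Parameters
    ----------
    record : ProteinRecord
    scale : HydropathyScale, optional
        Defaults to the Kyte–Doolittle scale.
    w : int
        Window length in residues; the sequence must be at least this long
        (shorter sequences are rejected, not padded — padding would
        fabricate hydropathy where there is no sequence).
    statistic : {"mean", "sum"}
        Window aggregation; the conventional profile uses the mean.
    """
    scale = scale or kd_scale()
    if w < 1:
        raise ValueError("window length must be >= 1")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    seq = record.sequence
    if len(seq) < w:
        raise ValueError(
            f"protein {record.id!r}: sequence length {len(seq)} < window {w}"
        )
    try:
        residue_scores = np.array([scale.values[r] for r in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(
            f"protein {record.id!r}: residue {exc.args[0]!r} not in scale"
        ) from exc
    window_sums = np.convolve(residue_scores, np.ones(w), mode="valid")
    scores = window_sums / w if statistic == "mean" else window_sums
    return HydrophobicityProfile(id=record.id, window_length=w, scores=scores)


def max_local_hydrophobicity(
    records: list[ProteinRecord],
    scale: HydropathyScale | None = None,
    w: int = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, list[str]]:
    """Max-peak hydropathy table for a catalog.

    Returns ``(table, skipped_ids)`` where the table has one row per
    protein of length >= w (columns: id, length, n_windows, max_phi,
    argmax_position) and ``skipped_ids`` lists proteins too short to hold
    a single window.
    """
    if not records:
        raise ValueError("empty catalog")
    scale = scale or kd_scale()
    rows = []
    skipped: list[str] = []
    for rec in records:
        if len(rec.sequence) < w:
            skipped.append(rec.id)
            continue
        prof = kd_profile(rec, scale, w)
        rows.append(
            {
                "id": rec.id,
                "length": len(rec.sequence),
                "n_windows": len(prof.scores),
                "max_phi": prof.max_phi,
                "argmax_position": prof.argmax_position,
            }
        )
    table = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=["length", "n_windows", "max_phi", "argmax_position"]
    )
    return table, skipped


@dataclass
class SubclassComparison:
    """KS comparison of max-peak hydropathy between a subclass and background."""

    ks: KsResult
    subclass_summary: QuartileSummary
    background_summary: QuartileSummary
    n_subclass: int
    n_background: int


def subclass_hydrophobicity_comparison(
    max_phi: pd.Series,
    subclass_ids,
    background_ids=None,
) -> SubclassComparison:
    """Compare Φ_max of a protein subclass against a background set.

    ``max_phi`` is indexed by protein id (e.g. the ``max_phi`` column of
    :func:`max_local_hydrophobicity`). ``background_ids`` defaults to all
    other proteins in the table; an explicit background must be disjoint
    from the subclass.
    """
    subclass_ids = set(subclass_ids)
    if not subclass_ids:
        raise ValueError("subclass is empty")
    if background_ids is None:
        background_ids = set(max_phi.index) - subclass_ids
    else:
        background_ids = set(background_ids)
        overlap = subclass_ids & background_ids
        if overlap:
            raise ValueError(
                f"subclass and background overlap: {sorted(overlap)[:5]}..."
            )
    sub = max_phi.loc[max_phi.index.intersection(subclass_ids)].to_numpy(float)
    bg = max_phi.loc[max_phi.index.intersection(background_ids)].to_numpy(float)
    if len(sub) == 0 or len(bg) == 0:
        raise ValueError("subclass or background has no proteins in the table")
    ks = ks_two_sample(sub, bg)
    return SubclassComparison(
        ks=ks,
        subclass_summary=quartile_summary(sub),
        background_summary=quartile_summary(bg),
        n_subclass=len(sub),
        n_background=len(bg),
    )
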