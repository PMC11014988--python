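"""ER-vs-mitochondria enrichment ratios, shift classification, composition.

The dual-bait design purifies mitochondria (Tom20 bait) and ER (Rtn1 or
Sec63 bait) from the same lysate. Per protein and genotype, the
log2(Mito/ER) ratio of normalized intensities locates the protein on a
mitochondria↔ER axis. Plotting wild-type against mutant ratios, proteins
unaffected by contact-site loss sit on the diagonal; proteins that move
toward the ER in the mutant fall below it. The classifier flags proteins
whose deviation from the diagonal (wt − mut, in log2 units) exceeds 0.5
while the wild-type ratio is positive, i.e. genuinely mitochondrial
proteins that shift toward the ER when ER–mitochondria tethering is lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import IntensityMatrix
from .reference import MITO_COMPARTMENTS

DEV_THRESHOLD = 0.5
WT_THRESHOLD = 0.0

#: Default class grouping for fraction-composition summaries.
COMPOSITION_CLASSES = {
    "mitochondria": list(MITO_COMPARTMENTS),
    "ER+nucleus": ["ER", "nucleus"],
    "peroxisome": ["peroxisome"],
}


class CompartmentError(ValueError):
    pass


def compute_mito_er_ratio(
    matrix: IntensityMatrix,
    genotype: str,
    mito_bait: str = "Tom20",
    er_bait="Rtn1",
) -> pd.Series:
    """Per-protein log2(Mito/ER) enrichment ratio for one genotype.

    ``matrix`` must hold normalized log2-scale values. The ratio is the
    mean over the genotype's mito-bait runs minus the mean over its
    ER-bait runs; ``er_bait`` may be a tuple (e.g. ``("Rtn1", "Sec63")``)
    in which case the per-bait means are averaged. Proteins with no
    quantification in either side are NaN.
    """
    er_baits = (er_bait,) if isinstance(er_bait, str) else tuple(er_bait)
    known = set(matrix.samples["bait"])
    for bait in (mito_bait, *er_baits):
        if bait not in known:
            raise CompartmentError(f"bait {bait!r} not in sample metadata")
    if genotype not in set(matrix.samples["genotype"]):
        raise CompartmentError(f"genotype {genotype!r} not in sample metadata")

    def bait_mean(bait: str) -> pd.Series:
        cols = matrix.condition_samples(bait, genotype)
        if len(cols) < 2:
            raise CompartmentError(
                f"bait {bait!r}, genotype {genotype!r}: need >=2 runs, "
                f"found {len(cols)}"
            )
        return matrix.values[cols].mean(axis=1)  # skips NaN; all-NaN -> NaN

    mito = bait_mean(mito_bait)
    er = pd.concat([bait_mean(b) for b in er_baits], axis=1).mean(axis=1)
    ratio = mito - er
    ratio.name = f"log2_mito_er[{genotype}]"
    return ratio


@dataclass
class ShiftScore:
    """Diagonal-deviation classification of one protein."""

    id: str
    wt_mito_er: float
    mut_mito_er: float
    deviation: float
    classified: bool
    compartment: str = "unannotated"


def classify_er_surf_dependent(
    wt_scores: pd.Series,
    mut_scores: pd.Series,
    dev_threshold: float = DEV_THRESHOLD,
    wt_threshold: float = WT_THRESHOLD,
    annotation: pd.Series | None = None,
    deviation_mode: str = "axis",
) -> pd.DataFrame:
    """Classify proteins shifted from mitochondria toward the ER.

    A protein is classified when deviation > ``dev_threshold`` and its
    wild-type log2(Mito/ER) > ``wt_threshold``. Deviation is the signed
    axis-wise vertical distance wt − mut by default (the companion
    wild-type criterion is axis-wise, so 0.5 log2 units reads on the same
    scale); ``deviation_mode="perpendicular"`` divides by √2 to measure
    distance perpendicular to the diagonal instead.

    Returns a DataFrame indexed by protein id, sorted by deviation
    descending, with columns ``wt_mito_er, mut_mito_er, deviation,
    classified, compartment``. Proteins with a NaN ratio on either axis
    keep NaN deviation and are never classified (they are candidates for
    the separate missingness-based "depleted from mitochondria" report).
    """
    if set(wt_scores.index) != set(mut_scores.index):
        diff = set(wt_scores.index) ^ set(mut_scores.index)
        raise CompartmentError(
            f"wt/mut id sets differ; symmetric difference: {sorted(diff)[:10]}"
        )
    if deviation_mode not in ("axis", "perpendicular"):
        raise CompartmentError("deviation_mode must be 'axis' or 'perpendicular'")
    mut = mut_scores.reindex(wt_scores.index)
    dev = wt_scores - mut
    if deviation_mode == "perpendicular":
        dev = dev / np.sqrt(2.0)
    classified = (dev > dev_threshold) & (wt_scores > wt_threshold)
    classified &= dev.notna() & wt_scores.notna()
    table = pd.DataFrame(
        {
            "wt_mito_er": wt_scores,
            "mut_mito_er": mut,
            "deviation": dev,
            "classified": classified.fillna(False).astype(bool),
        }
    )
    table["compartment"] = (
        annotation.reindex(table.index).fillna("unannotated")
        if annotation is not None
        else "unannotated"
    )
    return table.sort_values("deviation", ascending=False, kind="mergesort")


def mito_depleted_candidates(
    matrix: IntensityMatrix,
    wt_genotype: str,
    mut_genotype: str,
    mito_bait: str = "Tom20",
    min_wt_runs: int = 2,
) -> list[str]:
    """Proteins quantified in the wild-type mito bait but absent from the
    mutant mito bait — the missingness-based "depleted from mitochondria"
    complement to the ratio classifier."""
    wt_cols = matrix.condition_samples(mito_bait, wt_genotype)
    mut_cols = matrix.condition_samples(mito_bait, mut_genotype)
    present = matrix.values.notna()
    wt_ok = present[wt_cols].sum(axis=1) >= min_wt_runs
    mut_absent = present[mut_cols].sum(axis=1) == 0
    return list(matrix.values.index[wt_ok & mut_absent])


def fraction_composition(
    matrix: IntensityMatrix,
    annotation: pd.Series,
    sample_names,
    classes: dict[str, list[str]] | None = None,
) -> dict[str, float]:
    """Relative intensity share of compartment classes in one fraction.

    ``matrix`` must hold raw-scale intensities (shares of summed signal
    are only meaningful there). Per class, the mean raw intensity of each
    protein across the fraction's replicate runs is summed; shares are
    normalized by the grand total, with every protein not in a listed
    class counted under ``"other"``. Shares sum to 1.
    """
    classes = dict(classes or COMPOSITION_CLASSES)
    sample_names = list(sample_names)
    missing = [s for s in sample_names if s not in matrix.values.columns]
    if missing:
        raise CompartmentError(f"unknown samples: {missing}")
    mean_int = matrix.values[sample_names].mean(axis=1).fillna(0.0)
    comp = annotation.reindex(mean_int.index).fillna("unannotated")

    assigned = set()
    sums: dict[str, float] = {}
    for cls, labels in classes.items():
        sel = comp.isin(labels)
        sums[cls] = float(mean_int[sel].sum())
        assigned |= set(labels)
        if not sel.any():
            warnings.warn(f"composition class {cls!r} has no proteins", stacklevel=2)
    sums["other"] = float(mean_int[~comp.isin(assigned)].sum())
    total = sum(sums.values())
    if total == 0:
        raise CompartmentError("no intensity in the selected samples")
    return {cls: v / total for cls, v in sums.items()}
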