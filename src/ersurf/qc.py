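"""Protein-level quantification tables and quality-control filters.

The pipeline starts from MaxQuant-style ``proteinGroups`` tables: one row
per protein group with an experiment-wide "Unique peptides" count, one
intensity column per MS run, and "+"-flagged "Reverse" / "Potential
contaminant" rows. Two filters mirror standard practice for such data:
proteins must be quantified with at least two unique peptides, and must
be identified in at least two of the (typically three) MS runs of a
biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class QcError(ValueError):
    pass


#: Sample-metadata columns required by the pipeline.
SAMPLE_COLUMNS = ("bait", "genotype", "replicate", "batch")


@dataclass
class IntensityMatrix:
    """Proteins × samples intensity matrix with sample metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Intensities, indexed by protein id, one column per sample (one
        sample = one MS run). Missing values are NaN; zero intensities
        from MaxQuant mean "not quantified" and are mapped to NaN on read.
    samples : pandas.DataFrame
        Indexed by sample name; columns ``bait, genotype, replicate,
        batch`` (plus optional ``run``).
    unique_peptides : pandas.Series
        Experiment-wide unique-peptide count per protein.
    log : dict
        Counters accumulated by the reader and filters.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unique_peptides: pd.Series
    log: dict = field(default_factory=dict)
    scale: str = "raw"  # "raw" intensities or "log2"-like transformed values

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise QcError("sample columns of values and metadata rows disagree")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise QcError(f"sample metadata lacks columns {missing_cols}")
        if not self.unique_peptides.index.equals(self.values.index):
            self.unique_peptides = self.unique_peptides.reindex(self.values.index)
        if self.scale == "raw":
            with np.errstate(invalid="ignore"):
                if np.nanmin(self.values.to_numpy(float), initial=0.0) < 0:
                    raise QcError("negative intensities")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset(self, protein_ids) -> "IntensityMatrix":
        """Row-subset preserving order; values are never mutated."""
        return IntensityMatrix(
            values=self.values.loc[protein_ids],
            samples=self.samples,
            unique_peptides=self.unique_peptides.loc[protein_ids],
            log=dict(self.log),
            scale=self.scale,
        )

    def replicate_groups(self) -> dict[tuple, list[str]]:
        """Sample names grouped by (bait, genotype, replicate).

        One group = the MS runs of one biological replicate of one
        condition; this is the grouping the run-presence filter uses.
        """
        groups: dict[tuple, list[str]] = {}
        for name, row in self.samples.iterrows():
            key = (row["bait"], row["genotype"], row["replicate"])
            groups.setdefault(key, []).append(name)
        return groups

    def condition_samples(self, bait: str, genotype: str) -> list[str]:
        sel = (self.samples["bait"] == bait) & (self.samples["genotype"] == genotype)
        return list(self.samples.index[sel])


def read_protein_groups(path, metadata_path) -> IntensityMatrix:
    """Read a proteinGroups-dialect TSV plus its sample-metadata TSV.

    Rows flagged "+" in "Reverse" or "Potential contaminant" (or with ids
    prefixed ``REV__``/``CON__``) are dropped and counted in ``log``.
    Intensity 0 or empty is recorded as missing.
    """
    table = pd.read_csv(path, sep="\t", dtype={"Protein IDs": str})
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise QcError("sample metadata must have a 'sample' column")
    missing_meta = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise QcError(f"sample metadata lacks columns {missing_meta}")
    meta = meta.set_index("sample")

    if "Protein IDs" not in table.columns:
        raise QcError("table lacks a 'Protein IDs' column")
    ids = table["Protein IDs"].astype(str)

    n0 = len(table)
    keep = pd.Series(True, index=table.index)
    for flag_col in ("Reverse", "Potential contaminant"):
        if flag_col in table.columns:
            keep &= table[flag_col].astype(str).str.strip() != "+"
    keep &= ~ids.str.startswith(("REV__", "CON__"))
    dropped_flagged = int(n0 - keep.sum())
    table, ids = table[keep], ids[keep]

    intensity_cols = {}
    for sample in meta.index:
        for candidate in (f"Intensity {sample}", sample):
            if candidate in table.columns:
                intensity_cols[sample] = candidate
                break
        else:
            raise QcError(
                f"no intensity column found for sample {sample!r} "
                f"(looked for 'Intensity {sample}' and {sample!r})"
            )
    if not intensity_cols:
        raise QcError("no intensity columns found")

    values = table[list(intensity_cols.values())].apply(
        pd.to_numeric, errors="coerce"
    )
    values.columns = list(intensity_cols)
    values.index = ids.to_numpy()
    values = values.mask(values == 0)  # MaxQuant writes 0 for "not quantified"

    if "Unique peptides" in table.columns:
        peptides = pd.to_numeric(table["Unique peptides"], errors="coerce").fillna(0)
    else:
        raise QcError("table lacks a 'Unique peptides' column")
    peptides.index = values.index
    peptides.name = "unique_peptides"

    return IntensityMatrix(
        values=values,
        samples=meta,
        unique_peptides=peptides.astype(int),
        log={"input_rows": n0, "dropped_reverse_contaminant": dropped_flagged},
    )


def filter_min_unique_peptides(matrix: IntensityMatrix, k: int = 2) -> IntensityMatrix:
    """Keep proteins quantified with at least ``k`` unique peptides."""
    if k < 1:
        raise QcError("k must be >= 1")
    keep = matrix.unique_peptides >= k
    out = matrix.subset(matrix.values.index[keep])
    out.log["dropped_min_unique_peptides"] = int((~keep).sum())
    return out


def filter_min_runs(
    matrix: IntensityMatrix, m: int = 2, n: int = 3, scope: str = "any"
) -> IntensityMatrix:
    """Keep proteins identified in at least ``m`` of the ``n`` MS runs of a
    biological replicate.

    Presence is evaluated within each (bait, genotype, replicate) group.
    With ``scope="any"`` (default) a protein is kept if some replicate
    group of some condition satisfies the rule — quantification that is
    reliable anywhere preserves condition-specific proteins. With
    ``scope="all"`` every replicate group in which the protein appears at
    all must satisfy it, and a protein absent everywhere is dropped.
    """
    if m > n:
        raise QcError(f"m={m} exceeds runs per replicate n={n}")
    if m < 1:
        raise QcError("m must be >= 1")
    if scope not in ("any", "all"):
        raise QcError("scope must be 'any' or 'all'")
    present = matrix.values.notna()
    groups = matrix.replicate_groups()
    counts = pd.DataFrame(
        {key: present[cols].sum(axis=1) for key, cols in groups.items()}
    )
    if scope == "any":
        keep = (counts >= m).any(axis=1)
    else:
        seen = counts > 0
        keep = ((counts >= m) | ~seen).all(axis=1) & seen.any(axis=1)
    out = matrix.subset(matrix.values.index[keep])
    out.log["dropped_min_runs"] = int((~keep).sum())
    return out
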