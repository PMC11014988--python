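"""Synthetic dual-bait affinity-purification experiments with ground truth.

The generator emulates the structure of a dual-organelle AP-MS study:
tagged baits on the mitochondrial outer membrane (Tom20) and the ER
membrane (Rtn1, Sec63) capture their cognate organelle efficiently and
everything else at a low contamination level. Each protein p has a true
abundance A_p (log-normal) and an ER-partition fraction f_p(genotype):
the fraction of its population residing on the ER. Mitochondrial
proteins sit near f ≈ 0.1 at baseline; for a planted set of
contact-site-dependent proteins, loss of ER–mitochondria tethering moves
the partition toward the ER by a fixed effect on the log2 partition-odds
scale (so f stays in [0, 1] for any effect size). Observed intensity is

    I_ps = A_p · [f_p(g_s)·mix(bait_s, ER) + (1−f_p(g_s))·mix(bait_s, c_p)]
           · batch_s · exp(ε),   ε ~ N(0, noise_sd²)

with intensity-dependent logistic dropout. Matching protein sequences
are generated so hydropathy profiling is testable: inner-membrane (and
ER) proteins carry at least one contiguous 21-residue stretch of strongly
hydrophobic residues, soluble compartments draw from a hydrophilic-biased
residue distribution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import IntensityMatrix
from .reference import COMPARTMENTS, MITO_COMPARTMENTS, ProteinRecord

GENOTYPES = ("WT_EV", "WT_MDM34KD", "TOM70D_EV", "TOM70D_MDM34KD")

#: Hydrophobic residues used for planted transmembrane-like stretches.
TM_RESIDUES = tuple("ILVFAM")

# Hydrophilic-biased background residue frequencies (soluble proteins).
_BACKGROUND_FREQS = {
    "A": 0.07, "R": 0.05, "N": 0.05, "D": 0.06, "C": 0.01, "Q": 0.05,
    "E": 0.08, "G": 0.06, "H": 0.02, "I": 0.03, "L": 0.06, "K": 0.09,
    "M": 0.02, "F": 0.03, "P": 0.05, "S": 0.12, "T": 0.07, "W": 0.01,
    "Y": 0.03, "V": 0.04,
}

DEFAULT_PROPORTIONS = {
    "matrix": 0.16,
    "inner_membrane": 0.14,
    "IMS": 0.03,
    "outer_membrane": 0.04,
    "ER": 0.22,
    "peroxisome": 0.03,
    "nucleus": 0.20,
    "other": 0.18,
}

#: Compartments whose proteins carry a planted hydrophobic stretch.
_MEMBRANE_COMPARTMENTS = ("inner_membrane", "ER")


class SimulationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Forward-model parameters of the synthetic experiment.

    Defaults define the package's standard study conditions: 2000
    proteins, 200 planted contact-site-dependent proteins shifted by 1.5
    log2 partition-odds units, log-normal measurement noise of 0.3
    natural-log units, 3 biological replicates of 3 MS runs each.
    """

    n_proteins: int = 2000
    compartment_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_shifted: int = 200
    shift_effect: float = 1.5  # log2 partition-odds units
    er_partition_baseline: float = 0.15  # f for mitochondrial proteins in WT
    abundance_log_mean: float = 16.0  # ln units
    abundance_log_sd: float = 2.0
    noise_sd: float = 0.3  # ln units
    batch_effects: dict[str, float] = field(
        default_factory=lambda: {"b1": 0.0, "b2": 0.25}
    )  # multiplicative ln offsets
    dropout_midpoint: float = 0.1  # missingness rate at the median ln-intensity
    dropout_steepness: float = 0.8  # per ln-intensity unit
    replicates: int = 3
    runs_per_replicate: int = 3
    genotypes: tuple[str, ...] = ("WT_EV", "WT_MDM34KD")
    shifted_genotypes: tuple[str, ...] = ("WT_MDM34KD",)
    min_length: int = 200
    max_length: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.compartment_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"compartment proportions sum to {total}, not 1")
        unknown = set(self.compartment_proportions) - set(COMPARTMENTS)
        if unknown:
            raise SimulationError(f"unknown compartments {sorted(unknown)}")
        if self.n_shifted > self.n_proteins:
            raise SimulationError("n_shifted exceeds n_proteins")
        if self.replicates < 2:
            raise SimulationError("need at least 2 replicates")
        for name in ("abundance_log_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0.0 < self.er_partition_baseline < 1.0:
            raise SimulationError("er_partition_baseline must be in (0, 1)")
        if not 0.0 <= self.dropout_midpoint < 1.0:
            raise SimulationError("dropout_midpoint is a probability in [0, 1)")


@dataclass
class ContaminationMatrix:
    """Capture efficiency of each bait for each true compartment.

    ``mix[bait][compartment]`` ∈ [0, 1]; each bait must capture its
    cognate compartment with the largest efficiency. ``er_compartment``
    names the compartment whose efficiency applies to the ER-partitioned
    population of a protein.
    """

    mix: dict[str, dict[str, float]]
    cognate: dict[str, str]
    er_compartment: str = "ER"

    def __post_init__(self) -> None:
        for bait, row in self.mix.items():
            for comp, v in row.items():
                if not 0.0 <= v <= 1.0:
                    raise SimulationError(
                        f"capture efficiency out of [0,1]: {bait}/{comp}={v}"
                    )
            cog = self.cognate.get(bait)
            if cog is None:
                raise SimulationError(f"no cognate compartment for bait {bait!r}")
            if row[cog] < max(row.values()):
                raise SimulationError(
                    f"bait {bait!r} must capture its cognate {cog!r} best"
                )

    def efficiency(self, bait: str, compartment: str) -> float:
        return self.mix[bait][compartment]

    @property
    def baits(self) -> tuple[str, ...]:
        return tuple(self.mix)


def default_contamination() -> ContaminationMatrix:
    """Cognate capture 0.9; non-cognate 0.05 for the mito bait and 0.1
    for the ER baits (membrane IPs of ER origin carry somewhat more
    off-target material)."""
    def row(cognate_set, cognate_eff, other_eff):
        return {
            comp: (cognate_eff if comp in cognate_set else other_eff)
            for comp in COMPARTMENTS
        }

    mito = set(MITO_COMPARTMENTS)
    return ContaminationMatrix(
        mix={
            "Tom20": row(mito, 0.9, 0.05),
            "Rtn1": row({"ER"}, 0.9, 0.1),
            "Sec63": row({"ER"}, 0.9, 0.1),
        },
        cognate={"Tom20": "outer_membrane", "Rtn1": "ER", "Sec63": "ER"},
    )


@dataclass
class SampleDescriptor:
    name: str
    bait: str
    genotype: str
    replicate: int
    run: int
    batch: str


@dataclass
class GroundTruth:
    """Planted truth of one simulated experiment."""

    shifted_ids: list[str]
    compartments: dict[str, str]
    er_fraction: dict[str, dict[str, float]]  # id -> genotype -> f
    abundance: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _random_sequence(rng, length, letters, probs) -> str:
    return "".join(rng.choice(letters, size=length, p=probs))


def generate_catalog(config: GeneratorConfig, rng) -> list[ProteinRecord]:
    """Generate protein records with compartments and sequences.

    Membrane compartments (inner membrane, ER) are guaranteed at least
    one contiguous 21-residue stretch drawn from {I,L,V,F,A,M}, so their
    20-residue max hydropathy window is high by construction; all other
    compartments draw every residue from a hydrophilic-biased
    distribution.
    """
    letters = np.array(sorted(_BACKGROUND_FREQS))
    probs = np.array([_BACKGROUND_FREQS[r] for r in letters])
    probs = probs / probs.sum()
    tm = np.array(TM_RESIDUES)
    tm_probs = np.full(len(tm), 1.0 / len(tm))

    comps = sorted(config.compartment_proportions)
    comp_probs = np.array([config.compartment_proportions[c] for c in comps])
    assignments = [str(c) for c in rng.choice(comps, size=config.n_proteins, p=comp_probs)]

    width = len(str(config.n_proteins))
    records = []
    for i, comp in enumerate(assignments):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        seq = list(_random_sequence(rng, length, letters, probs))
        if comp in _MEMBRANE_COMPARTMENTS:
            start = int(rng.integers(0, length - 21 + 1))
            seq[start : start + 21] = _random_sequence(rng, 21, tm, tm_probs)
        records.append(
            ProteinRecord(
                id=f"SYN{i + 1:0{width}d}", sequence="".join(seq), compartment=comp
            )
        )
    return records


def default_design(config: GeneratorConfig, baits=("Tom20", "Rtn1", "Sec63")) -> list[SampleDescriptor]:
    """Full factorial design: bait × genotype × replicate × run.

    Batches rotate over biological replicates (a replicate is processed
    in one batch), matching how batch structure enters real experiments.
    """
    batch_names = sorted(config.batch_effects)
    design = []
    for bait in baits:
        for genotype in config.genotypes:
            for rep in range(1, config.replicates + 1):
                batch = batch_names[(rep - 1) % len(batch_names)]
                for run in range(1, config.runs_per_replicate + 1):
                    design.append(
                        SampleDescriptor(
                            name=f"{bait}_{genotype}_r{rep}_run{run}",
                            bait=bait,
                            genotype=genotype,
                            replicate=rep,
                            run=run,
                            batch=batch,
                        )
                    )
    return design


def _logit2(f: float) -> float:
    return float(np.log2(f / (1.0 - f)))


def _inv_logit2(o: float) -> float:
    return float(2.0**o / (1.0 + 2.0**o))


def generate_experiment(
    catalog: list[ProteinRecord],
    config: GeneratorConfig,
    contamination: ContaminationMatrix | None = None,
    design: list[SampleDescriptor] | None = None,
    rng=None,
) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate the intensity table for a catalog under the forward model.

    Returns the (raw-scale) intensity matrix with missingness applied and
    the ground-truth manifest. The planted shifted set is drawn from
    inner-membrane and matrix proteins; in ``shifted_genotypes`` their
    ER-partition odds increase by ``shift_effect`` log2 units.
    """
    contamination = contamination or default_contamination()
    design = design or default_design(config, baits=contamination.baits)
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    baits = {d.bait for d in design}
    genotypes = {d.genotype for d in design}
    missing_baits = baits - set(contamination.baits)
    if missing_baits:
        raise SimulationError(f"design baits absent from contamination: {missing_baits}")
    if len(baits) < 2 or len(genotypes) < 2:
        raise SimulationError("design must cover >=2 baits and >=2 genotypes")
    if max(d.replicate for d in design) < 2:
        raise SimulationError("design must cover >=2 replicates")
    unknown_geno = genotypes - set(GENOTYPES)
    if unknown_geno:
        raise SimulationError(f"unknown genotypes {sorted(unknown_geno)}")

    ids = [r.id for r in catalog]
    comp = {r.id: r.compartment for r in catalog}
    eligible = [r.id for r in catalog if r.compartment in ("inner_membrane", "matrix")]
    if config.n_shifted > len(eligible):
        raise SimulationError(
            f"n_shifted={config.n_shifted} exceeds eligible pool {len(eligible)}"
        )
    shifted = sorted(
        str(x) for x in rng.choice(eligible, size=config.n_shifted, replace=False)
    )
    shifted_set = set(shifted)

    abundance = {
        pid: float(
            np.exp(rng.normal(config.abundance_log_mean, config.abundance_log_sd))
        )
        for pid in ids
    }

    # ER-partition fraction per protein per genotype
    base_odds = _logit2(config.er_partition_baseline)
    er_fraction: dict[str, dict[str, float]] = {}
    for pid in ids:
        c = comp[pid]
        per_geno = {}
        for g in sorted(genotypes):
            if c == "ER":
                f = 1.0
            elif c in MITO_COMPARTMENTS:
                odds = base_odds
                if pid in shifted_set and g in config.shifted_genotypes:
                    odds += config.shift_effect
                f = _inv_logit2(odds)
            else:
                f = 0.0
            per_geno[g] = f
        er_fraction[pid] = per_geno

    n_p, n_s = len(ids), len(design)
    intensity = np.empty((n_p, n_s))
    for j, d in enumerate(design):
        batch_factor = float(np.exp(config.batch_effects[d.batch]))
        mix_er = contamination.efficiency(d.bait, contamination.er_compartment)
        for i, pid in enumerate(ids):
            f = er_fraction[pid][d.genotype]
            capture = f * mix_er + (1.0 - f) * contamination.efficiency(
                d.bait, comp[pid]
            )
            intensity[i, j] = abundance[pid] * capture * batch_factor
    if config.noise_sd > 0:
        intensity *= np.exp(rng.normal(0.0, config.noise_sd, size=intensity.shape))

    # intensity-dependent logistic dropout
    if config.dropout_midpoint > 0:
        with np.errstate(divide="ignore"):
            log_i = np.log(intensity)
        ref = float(np.median(log_i))
        logit_mid = np.log(config.dropout_midpoint / (1.0 - config.dropout_midpoint))
        p_miss = 1.0 / (
            1.0 + np.exp(-(logit_mid - config.dropout_steepness * (log_i - ref)))
        )
        dropped = rng.random(size=intensity.shape) < p_miss
        intensity = np.where(dropped, np.nan, intensity)

    lengths = np.array([len(r.sequence) for r in catalog], dtype=float)
    unique_peptides = rng.poisson(1.0 + lengths / 100.0)

    values = pd.DataFrame(intensity, index=ids, columns=[d.name for d in design])
    samples = pd.DataFrame(
        {
            "bait": [d.bait for d in design],
            "genotype": [d.genotype for d in design],
            "replicate": [d.replicate for d in design],
            "run": [d.run for d in design],
            "batch": [d.batch for d in design],
        },
        index=[d.name for d in design],
    )
    matrix = IntensityMatrix(
        values=values,
        samples=samples,
        unique_peptides=pd.Series(unique_peptides, index=ids, name="unique_peptides"),
        log={"simulated": True, "seed": config.seed},
    )
    truth = GroundTruth(
        shifted_ids=list(shifted),
        compartments=dict(comp),
        er_fraction=er_fraction,
        abundance=abundance,
    )
    return matrix, truth


def write_protein_groups(matrix: IntensityMatrix, path) -> None:
    """Write the matrix as a MaxQuant proteinGroups-dialect TSV.

    Missing values become empty cells (MaxQuant writes 0 for "not
    quantified"; the reader maps both to missing). Round-trips through
    :func:`ersurf.qc.read_protein_groups` exactly for ids and within
    float-repr precision for intensities.
    """
    table = pd.DataFrame({"Protein IDs": matrix.values.index})
    table["Unique peptides"] = matrix.unique_peptides.to_numpy()
    for col in matrix.values.columns:
        table[f"Intensity {col}"] = matrix.values[col].to_numpy()
    table["Reverse"] = ""
    table["Potential contaminant"] = ""
    table.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def write_sample_metadata(design: list[SampleDescriptor], path) -> None:
    pd.DataFrame(
        {
            "sample": [d.name for d in design],
            "bait": [d.bait for d in design],
            "genotype": [d.genotype for d in design],
            "replicate": [d.replicate for d in design],
            "run": [d.run for d in design],
            "batch": [d.batch for d in design],
        }
    ).to_csv(path, sep="\t", index=False)
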