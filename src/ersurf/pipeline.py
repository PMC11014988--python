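"""End-to-end pipeline: QC → normalize → differential → shift → hydropathy.

``run_pipeline`` executes the full analysis on either a simulated
experiment (the default, with ground-truth evaluation) or user-supplied
files (proteinGroups TSV, sample metadata, FASTA, annotation TSV), and
writes a deterministic report bundle: a JSON report plus TSV tables for
the differential contrasts, shift scores and hydropathy statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments, differential, hydropathy, normalization, qc
from .reference import (
    MITO_COMPARTMENTS,
    annotation_map,
    load_annotation,
    load_fasta,
)
from .simulate import (
    GeneratorConfig,
    default_contamination,
    default_design,
    generate_catalog,
    generate_experiment,
)

class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; validated before any compute."""

    simulate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # file-mode inputs
    protein_groups: str | None = None
    sample_metadata: str | None = None
    fasta: str | None = None
    annotation: str | None = None
    # analysis parameters
    min_unique_peptides: int = 2
    min_runs: int = 2
    runs_per_group: int = 3
    run_filter_scope: str = "any"
    wt_genotype: str = "WT_EV"
    mut_genotype: str = "WT_MDM34KD"
    mito_bait: str = "Tom20"
    er_bait: str | tuple[str, ...] = ("Rtn1", "Sec63")
    dev_threshold: float = compartments.DEV_THRESHOLD
    wt_threshold: float = compartments.WT_THRESHOLD
    window: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate:
            required = {
                "protein_groups": self.protein_groups,
                "sample_metadata": self.sample_metadata,
                "fasta": self.fasta,
                "annotation": self.annotation,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise PipelineError(f"config lacks input paths: {missing}")
            absent = [k for k, v in required.items() if v and not Path(v).exists()]
            if absent:
                raise PipelineError(f"input files not found: {absent}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(generator=gen, **raw)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns the report dict. Given identical (inputs, config, seed) the
    bundle is byte-identical across runs: no timestamps, sorted JSON
    keys, fixed float formatting.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _jsonable(_config_dict(config))}

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        gen = config.generator
        rng = np.random.default_rng(gen.seed)
        catalog = generate_catalog(gen, rng)
        contamination = default_contamination()
        design = default_design(gen, baits=contamination.baits)
        raw, truth = generate_experiment(catalog, gen, contamination, design, rng)
    else:
        raw = qc.read_protein_groups(config.protein_groups, config.sample_metadata)
        catalog = load_fasta(config.fasta)
        load_annotation(config.annotation, catalog)
    annotation = annotation_map(catalog)
    report["catalog"] = {
        "n_proteins": len(catalog),
        "by_compartment": {
            str(k): int(v) for k, v in sorted(annotation.value_counts().items())
        },
    }

    # --- QC ---------------------------------------------------------------
    filtered = qc.filter_min_unique_peptides(raw, k=config.min_unique_peptides)
    filtered = qc.filter_min_runs(
        filtered, m=config.min_runs, n=config.runs_per_group,
        scope=config.run_filter_scope,
    )
    report["qc"] = {
        "input_proteins": raw.n_proteins,
        "retained_proteins": filtered.n_proteins,
        **{k: v for k, v in filtered.log.items() if k.startswith("dropped")},
    }

    # --- normalization ----------------------------------------------------
    vsn, model = normalization.vsn_transform(filtered)
    vsn = normalization.remove_batch_effects(vsn, model=model)
    diag = normalization.variance_stabilization_diagnostic(vsn)
    sds = diag["replicate_sd"].dropna()
    report["normalization"] = {
        "vsn_iterations": model.iterations,
        "vsn_converged": model.converged,
        "decile_sd_ratio": float(sds.max() / sds.min()) if len(sds) else None,
    }
    diag.to_csv(out / "vsn_diagnostic.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / "normalization_model.json", "w") as fh:
        json.dump(_jsonable(model.to_dict()), fh, indent=1, sort_keys=True)

    # --- differential abundance (mutant vs WT, per bait) ------------------
    report["differential"] = {}
    for bait in sorted(set(vsn.samples["bait"])):
        cols = [
            s for s in vsn.values.columns
            if vsn.samples.at[s, "bait"] == bait
            and vsn.samples.at[s, "genotype"] in (config.wt_genotype, config.mut_genotype)
        ]
        sub = vsn.values[cols]
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "mutant": [
                    float(vsn.samples.at[s, "genotype"] == config.mut_genotype)
                    for s in cols
                ],
            },
            index=cols,
        )
        table, d0, s0_sq = differential.differential_table(sub, design, [0.0, 1.0])
        table.to_csv(
            out / f"differential_{bait}.tsv", sep="\t", float_format="%.6g"
        )
        report["differential"][bait] = {
            "d0": d0,
            "s0_sq": s0_sq,
            "n_tested": int((table["reason"] == "").sum()),
            "n_significant_q05": int((table["q"] < 0.05).sum()),
        }

    # --- shift classification --------------------------------------------
    wt_ratio = compartments.compute_mito_er_ratio(
        vsn, config.wt_genotype, config.mito_bait, config.er_bait
    )
    mut_ratio = compartments.compute_mito_er_ratio(
        vsn, config.mut_genotype, config.mito_bait, config.er_bait
    )
    scores = compartments.classify_er_surf_dependent(
        wt_ratio, mut_ratio,
        dev_threshold=config.dev_threshold,
        wt_threshold=config.wt_threshold,
        annotation=annotation,
    )
    depleted = compartments.mito_depleted_candidates(
        vsn, config.wt_genotype, config.mut_genotype, config.mito_bait
    )
    classified_ids = sorted(scores.index[scores["classified"]])
    shifted_union = sorted(set(classified_ids) | set(depleted))
    scores.to_csv(out / "shift_scores.tsv", sep="\t", float_format="%.6g")
    subclass_counts = (
        scores.loc[scores["classified"], "compartment"].value_counts().to_dict()
    )
    report["shift"] = {
        "n_scored": int(scores["deviation"].notna().sum()),
        "n_classified": len(classified_ids),
        "n_mito_depleted": len(depleted),
        "n_contact_site_dependent": len(shifted_union),
        "classified_by_compartment": {k: int(v) for k, v in sorted(subclass_counts.items())},
    }

    if truth is not None:
        planted = set(truth.shifted_ids)
        found = set(shifted_union)
        tp = len(planted & found)
        report["shift"]["ground_truth"] = {
            "n_planted": len(planted),
            "sensitivity": tp / len(planted) if planted else None,
            "false_discovery_proportion": (
                (len(found) - tp) / len(found) if found else 0.0
            ),
        }

    # --- fraction composition (raw scale, WT mito bait) -------------------
    comp_samples = raw.condition_samples(config.mito_bait, config.wt_genotype)
    composition = compartments.fraction_composition(
        raw.subset(filtered.values.index), annotation, comp_samples
    )
    report["composition"] = {k: v for k, v in sorted(composition.items())}

    # --- hydropathy -------------------------------------------------------
    phi_table, skipped = hydropathy.max_local_hydrophobicity(catalog, w=config.window)
    phi_table.to_csv(out / "max_phi.tsv", sep="\t", float_format="%.6g")
    max_phi = phi_table["max_phi"]
    mito_ids = set(annotation.index[annotation.isin(MITO_COMPARTMENTS)])
    comparisons = {}
    im_ids = set(annotation.index[annotation == "inner_membrane"])
    if im_ids and len(max_phi) > len(im_ids):
        comparisons["inner_membrane_vs_rest"] = hydropathy.subclass_hydrophobicity_comparison(
            max_phi, im_ids & set(max_phi.index)
        )
    shifted_in_table = set(shifted_union) & set(max_phi.index) & mito_ids
    other_mito = (mito_ids & set(max_phi.index)) - shifted_in_table
    if shifted_in_table and other_mito:
        comparisons["contact_site_dependent_vs_other_mito"] = (
            hydropathy.subclass_hydrophobicity_comparison(
                max_phi, shifted_in_table, other_mito
            )
        )
    report["hydropathy"] = {
        "n_profiled": int(len(max_phi)),
        "n_too_short": len(skipped),
    }
    for name, cmp_res in comparisons.items():
        report["hydropathy"][name] = {
            "ks_D": cmp_res.ks.D,
            "ks_p": cmp_res.ks.p,
            "n_subclass": cmp_res.n_subclass,
            "n_background": cmp_res.n_background,
            "subclass_median": cmp_res.subclass_summary.median,
            "background_median": cmp_res.background_summary.median,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report


def _config_dict(config: PipelineConfig) -> dict:
    import dataclasses

    d = dataclasses.asdict(config)
    d["er_bait"] = list(d["er_bait"]) if not isinstance(d["er_bait"], str) else d["er_bait"]
    return d
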