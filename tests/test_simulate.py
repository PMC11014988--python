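import json
import re

import numpy as np
import pandas as pd
import pytest

import ersurf as es
from ersurf.simulate import (
    ContaminationMatrix,
    GeneratorConfig,
    SimulationError,
    default_contamination,
    default_design,
    generate_catalog,
    generate_experiment,
    write_protein_groups,
    write_sample_metadata,
)

TM_STRETCH = re.compile(r"[ILVFAM]{21}")


class TestGeneratorConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum"):
            GeneratorConfig(compartment_proportions={"matrix": 0.5, "ER": 0.4})

    def test_unknown_compartment_rejected(self):
        with pytest.raises(SimulationError, match="unknown"):
            GeneratorConfig(compartment_proportions={"cytosol": 1.0})

    def test_shifted_count_bounded_by_catalog(self):
        with pytest.raises(SimulationError):
            GeneratorConfig(n_proteins=10, n_shifted=11)

    def test_minimum_replication_enforced(self):
        with pytest.raises(SimulationError):
            GeneratorConfig(replicates=1)


class TestGenerateCatalog:
    def test_inner_membrane_proteins_carry_tm_stretch(self):
        cfg = GeneratorConfig(
            n_proteins=5, n_shifted=0,
            compartment_proportions={"inner_membrane": 1.0},
        )
        cat = generate_catalog(cfg, np.random.default_rng(0))
        assert len(cat) == 5
        assert all(TM_STRETCH.search(r.sequence) for r in cat)

    def test_same_seed_reproduces_catalog(self):
        cfg = GeneratorConfig(n_proteins=30, n_shifted=3)
        c1 = generate_catalog(cfg, np.random.default_rng(42))
        c2 = generate_catalog(cfg, np.random.default_rng(42))
        assert [(r.id, r.sequence, r.compartment) for r in c1] == [
            (r.id, r.sequence, r.compartment) for r in c2
        ]

    def test_lengths_within_configured_bounds(self):
        cfg = GeneratorConfig(n_proteins=50, n_shifted=0)
        cat = generate_catalog(cfg, np.random.default_rng(1))
        lens = [len(r.sequence) for r in cat]
        assert min(lens) >= cfg.min_length and max(lens) <= cfg.max_length

    def test_shifted_pool_must_be_large_enough(self):
        cfg = GeneratorConfig(
            n_proteins=20, n_shifted=15,
            compartment_proportions={"ER": 0.9, "matrix": 0.1},
        )
        rng = np.random.default_rng(3)
        cat = generate_catalog(cfg, rng)
        with pytest.raises(SimulationError, match="eligible"):
            generate_experiment(cat, cfg, rng=rng)


def noiseless_config(**kw):
    defaults = dict(
        n_proteins=40, n_shifted=4, noise_sd=0.0,
        batch_effects={"b1": 0.0}, dropout_midpoint=0.0, seed=9,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestGenerateExperiment:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_proteins=30, n_shifted=3, seed=4)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(cfg.seed)
            cat = generate_catalog(cfg, rng)
            mat, truth = generate_experiment(cat, cfg, rng=rng)
            out.append((mat.values, truth.shifted_ids))
        pd.testing.assert_frame_equal(out[0][0], out[1][0])
        assert out[0][1] == out[1][1]

    def test_noiseless_mito_er_ratio_constant_across_genotypes_without_shift(self):
        cfg = noiseless_config(n_shifted=0)
        rng = np.random.default_rng(cfg.seed)
        cat = generate_catalog(cfg, rng)
        mat, truth = generate_experiment(cat, cfg, rng=rng)
        v = np.log2(mat.values)
        for rec in cat:
            if rec.compartment not in ("matrix", "inner_membrane"):
                continue
            ratios = {}
            for g in cfg.genotypes:
                tom = [s for s in v.columns if mat.samples.at[s, "bait"] == "Tom20"
                       and mat.samples.at[s, "genotype"] == g]
                rtn = [s for s in v.columns if mat.samples.at[s, "bait"] == "Rtn1"
                       and mat.samples.at[s, "genotype"] == g]
                ratios[g] = v.loc[rec.id, tom].mean() - v.loc[rec.id, rtn].mean()
            vals = list(ratios.values())
            assert vals[0] == pytest.approx(vals[1], abs=1e-9)

    def test_noiseless_planted_shift_matches_partition_odds_closed_form(self):
        cfg = noiseless_config(shift_effect=2.0)
        rng = np.random.default_rng(cfg.seed)
        cat = generate_catalog(cfg, rng)
        mat, truth = generate_experiment(cat, cfg, rng=rng)
        mix = default_contamination()
        v = np.log2(mat.values)
        pid = truth.shifted_ids[0]
        comp = truth.compartments[pid]

        def expected_ratio(f):
            num = f * mix.efficiency("Tom20", "ER") + (1 - f) * mix.efficiency("Tom20", comp)
            den = f * mix.efficiency("Rtn1", "ER") + (1 - f) * mix.efficiency("Rtn1", comp)
            return np.log2(num / den)

        f_wt = truth.er_fraction[pid]["WT_EV"]
        f_mut = truth.er_fraction[pid]["WT_MDM34KD"]
        # partition odds moved by exactly shift_effect log2 units
        odds = lambda f: np.log2(f / (1 - f))
        assert odds(f_mut) - odds(f_wt) == pytest.approx(2.0, abs=1e-9)

        def observed_ratio(g):
            tom = [s for s in v.columns if mat.samples.at[s, "bait"] == "Tom20"
                   and mat.samples.at[s, "genotype"] == g]
            rtn = [s for s in v.columns if mat.samples.at[s, "bait"] == "Rtn1"
                   and mat.samples.at[s, "genotype"] == g]
            return v.loc[pid, tom].mean() - v.loc[pid, rtn].mean()

        assert observed_ratio("WT_EV") == pytest.approx(expected_ratio(f_wt), abs=1e-9)
        assert observed_ratio("WT_MDM34KD") == pytest.approx(
            expected_ratio(f_mut), abs=1e-9
        )

    def test_flat_dropout_rate_equals_midpoint_probability(self):
        cfg = GeneratorConfig(
            n_proteins=300, n_shifted=0, dropout_midpoint=0.2,
            dropout_steepness=0.0, seed=10,
        )
        rng = np.random.default_rng(cfg.seed)
        cat = generate_catalog(cfg, rng)
        mat, _ = generate_experiment(cat, cfg, rng=rng)
        rate = float(mat.values.isna().mean().mean())
        assert rate == pytest.approx(0.2, abs=0.01)

    def test_noiseless_bait_sum_conserves_abundance(self):
        cfg = noiseless_config()
        rng = np.random.default_rng(cfg.seed)
        cat = generate_catalog(cfg, rng)
        mat, truth = generate_experiment(cat, cfg, rng=rng)
        mix = default_contamination()
        baits = ("Tom20", "Rtn1", "Sec63")
        one_run = {
            b: [s for s in mat.values.columns
                if mat.samples.at[s, "bait"] == b
                and mat.samples.at[s, "genotype"] == "WT_EV"
                and mat.samples.at[s, "replicate"] == 1
                and mat.samples.at[s, "run"] == 1][0]
            for b in baits
        }
        for rec in cat:
            f = truth.er_fraction[rec.id]["WT_EV"]
            total = sum(mat.values.at[rec.id, one_run[b]] for b in baits)
            expected = truth.abundance[rec.id] * sum(
                f * mix.efficiency(b, "ER") + (1 - f) * mix.efficiency(b, rec.compartment)
                for b in baits
            )
            assert total == pytest.approx(expected, rel=1e-12)

    def test_design_must_cover_known_baits(self):
        cfg = noiseless_config()
        rng = np.random.default_rng(0)
        cat = generate_catalog(cfg, rng)
        design = default_design(cfg, baits=("Tom20", "UnknownBait"))
        with pytest.raises(SimulationError, match="UnknownBait"):
            generate_experiment(cat, cfg, design=design, rng=rng)


class TestContaminationMatrix:
    def test_cognate_must_dominate(self):
        with pytest.raises(SimulationError, match="cognate"):
            ContaminationMatrix(
                mix={"Tom20": {"ER": 0.9, "matrix": 0.5}},
                cognate={"Tom20": "matrix"},
            )

    def test_efficiencies_bounded(self):
        with pytest.raises(SimulationError, match="out of"):
            ContaminationMatrix(
                mix={"Tom20": {"ER": 1.2}}, cognate={"Tom20": "ER"}
            )

    def test_default_matrix_satisfies_invariants(self):
        mix = default_contamination()
        for bait in mix.baits:
            row = mix.mix[bait]
            assert all(0 <= v <= 1 for v in row.values())
            assert row[mix.cognate[bait]] == max(row.values())


class TestWriters:
    def test_protein_groups_round_trips(self, tmp_path, small_experiment):
        _, matrix, _ = small_experiment
        pg = tmp_path / "pg.txt"
        md = tmp_path / "md.tsv"
        write_protein_groups(matrix, pg)
        write_sample_metadata(
            default_design(GeneratorConfig(seed=7)), md
        )
        back = es.read_protein_groups(pg, md)
        assert list(back.values.index) == list(matrix.values.index)
        a, b = back.values.to_numpy(), matrix.values.to_numpy()
        assert (np.isnan(a) == np.isnan(b)).all()
        both = ~np.isnan(a)
        assert np.nanmax(np.abs(a[both] - b[both]) / np.abs(b[both])) < 1e-9
        assert back.unique_peptides.equals(matrix.unique_peptides)

    def test_missing_values_written_as_empty_cells(self, tmp_path):
        cfg = noiseless_config(n_proteins=3, n_shifted=0)
        rng = np.random.default_rng(1)
        cat = generate_catalog(cfg, rng)
        mat, _ = generate_experiment(cat, cfg, rng=rng)
        mat.values.iloc[0, 0] = np.nan
        path = tmp_path / "pg.txt"
        write_protein_groups(mat, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4  # header + 3 rows
        first_intensity = lines[1].split("\t")[2]
        assert first_intensity == ""

    def test_ground_truth_manifest_round_trips(self, tmp_path, small_experiment):
        _, _, truth = small_experiment
        p = tmp_path / "gt.json"
        truth.to_json(p)
        back = es.GroundTruth.from_json(p)
        assert back.shifted_ids == truth.shifted_ids
        assert back.compartments == truth.compartments
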