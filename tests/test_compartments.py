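import numpy as np
import pandas as pd
import pytest

import ersurf as es
from ersurf.compartments import (
    CompartmentError,
    classify_er_surf_dependent,
    compute_mito_er_ratio,
    fraction_composition,
    mito_depleted_candidates,
)
from tests.conftest import make_matrix


def dual_bait_matrix(rows, genotype="WT_EV"):
    """4 samples: Tom20 x2, Rtn1 x2, one genotype, log2 scale."""
    return make_matrix(
        rows,
        baits=["Tom20", "Tom20", "Rtn1", "Rtn1"],
        genotypes=[genotype] * 4,
        replicates=[1, 2, 1, 2],
        scale="log2",
    )


class TestMitoErRatio:
    def test_mean_difference_of_bait_means(self):
        m = dual_bait_matrix([[5.0, 5.0, 3.0, 3.0]])
        r = compute_mito_er_ratio(m, "WT_EV", "Tom20", "Rtn1")
        assert r.iloc[0] == pytest.approx(2.0)

    def test_protein_absent_from_er_bait_is_na(self):
        m = dual_bait_matrix([[5.0, 5.0, np.nan, np.nan]])
        r = compute_mito_er_ratio(m, "WT_EV", "Tom20", "Rtn1")
        assert np.isnan(r.iloc[0])

    def test_unknown_bait_or_genotype_rejected(self):
        m = dual_bait_matrix([[5.0, 5.0, 3.0, 3.0]])
        with pytest.raises(CompartmentError, match="bait"):
            compute_mito_er_ratio(m, "WT_EV", "Sec63", "Rtn1")
        with pytest.raises(CompartmentError, match="genotype"):
            compute_mito_er_ratio(m, "TOM70D_EV", "Tom20", "Rtn1")

    def test_zero_noise_fixture_matches_contamination_mixture(self):
        cfg = es.GeneratorConfig(
            n_proteins=60, n_shifted=0, noise_sd=0.0,
            batch_effects={"b1": 0.0}, dropout_midpoint=0.0, seed=2,
        )
        rng = np.random.default_rng(2)
        cat = es.generate_catalog(cfg, rng)
        mat, truth = es.generate_experiment(cat, cfg, rng=rng)
        log2 = mat.values.apply(np.log2)
        m = es.IntensityMatrix(
            values=log2, samples=mat.samples,
            unique_peptides=mat.unique_peptides, scale="log2",
        )
        r = compute_mito_er_ratio(m, "WT_EV", "Tom20", "Rtn1")
        mix = es.default_contamination()
        f0 = cfg.er_partition_baseline
        for rec in cat:
            if rec.compartment != "matrix":
                continue
            num = f0 * mix.efficiency("Tom20", "ER") + (1 - f0) * mix.efficiency(
                "Tom20", "matrix"
            )
            den = f0 * mix.efficiency("Rtn1", "ER") + (1 - f0) * mix.efficiency(
                "Rtn1", "matrix"
            )
            assert r[rec.id] == pytest.approx(np.log2(num / den), abs=1e-9)


class TestClassifier:
    def test_printed_rule_positive_case(self):
        wt = pd.Series({"P1": 2.0})
        mut = pd.Series({"P1": 1.0})
        out = classify_er_surf_dependent(wt, mut)
        assert bool(out.loc["P1", "classified"]) is True
        assert out.loc["P1", "deviation"] == pytest.approx(1.0)

    def test_printed_rule_requires_positive_wild_type_ratio(self):
        wt = pd.Series({"P1": -1.0})
        mut = pd.Series({"P1": -2.5})
        out = classify_er_surf_dependent(wt, mut)
        assert bool(out.loc["P1", "classified"]) is False
        assert out.loc["P1", "deviation"] == pytest.approx(1.5)

    def test_boundary_is_strict(self):
        wt = pd.Series({"P1": 1.0, "P2": 0.0})
        mut = pd.Series({"P1": 0.5, "P2": -1.0})
        out = classify_er_surf_dependent(wt, mut)
        assert not out["classified"].any()  # deviation == 0.5 and wt == 0

    def test_id_mismatch_lists_symmetric_difference(self):
        with pytest.raises(CompartmentError, match="P2"):
            classify_er_surf_dependent(
                pd.Series({"P1": 1.0}), pd.Series({"P2": 1.0})
            )

    def test_deviation_antisymmetric(self):
        wt = pd.Series({"P1": 2.0, "P2": -0.3})
        mut = pd.Series({"P1": 0.5, "P2": 0.8})
        fwd = classify_er_surf_dependent(wt, mut)["deviation"]
        rev = classify_er_surf_dependent(mut, wt)["deviation"]
        assert np.allclose(fwd.sort_index(), -rev.sort_index())

    def test_threshold_limits(self):
        rng = np.random.default_rng(4)
        wt = pd.Series(rng.normal(1, 1, 50), index=[f"p{i}" for i in range(50)])
        mut = pd.Series(rng.normal(0, 1, 50), index=wt.index)
        none = classify_er_surf_dependent(wt, mut, dev_threshold=np.inf)
        assert not none["classified"].any()
        allpos = classify_er_surf_dependent(
            wt, mut, dev_threshold=0.0, wt_threshold=-np.inf
        )
        assert set(allpos.index[allpos["classified"]]) == set(
            wt.index[(wt - mut) > 0]
        )

    def test_invariant_to_per_sample_constant_offsets(self):
        rows = np.random.default_rng(5).normal(5, 1, (30, 4))
        m1 = dual_bait_matrix(rows)
        m2 = dual_bait_matrix(rows + np.array([1.0, -0.5, 2.0, 0.25]))
        mut_rows = rows - 1.0
        mwt1 = compute_mito_er_ratio(m1, "WT_EV", "Tom20", "Rtn1")
        mwt2 = compute_mito_er_ratio(m2, "WT_EV", "Tom20", "Rtn1")
        # ratios shift by the same constant for every protein, so the
        # deviation (wt - mut computed under the same offsets) is unchanged
        assert np.allclose(mwt2 - mwt1, (mwt2 - mwt1).iloc[0])

    def test_perpendicular_mode_scales_by_sqrt2(self):
        wt = pd.Series({"P1": 2.0})
        mut = pd.Series({"P1": 1.0})
        axis = classify_er_surf_dependent(wt, mut)["deviation"]
        perp = classify_er_surf_dependent(wt, mut, deviation_mode="perpendicular")[
            "deviation"
        ]
        assert perp.iloc[0] == pytest.approx(axis.iloc[0] / np.sqrt(2))

    def test_sorted_by_deviation_descending(self):
        wt = pd.Series({"P1": 1.0, "P2": 3.0, "P3": 2.0})
        mut = pd.Series({"P1": 0.9, "P2": 0.0, "P3": 1.0})
        out = classify_er_surf_dependent(wt, mut)
        assert list(out.index) == ["P2", "P3", "P1"]


class TestMitoDepleted:
    def test_protein_vanishing_from_mutant_mito_bait_reported(self):
        vals = [[5.0, 5.0, 5.0, 5.0, np.nan, np.nan, 4.0, 4.0]]
        m = make_matrix(
            vals,
            baits=["Tom20"] * 2 + ["Rtn1"] * 2 + ["Tom20"] * 2 + ["Rtn1"] * 2,
            genotypes=["WT_EV"] * 4 + ["WT_MDM34KD"] * 4,
            replicates=[1, 2] * 4,
            scale="log2",
        )
        assert mito_depleted_candidates(m, "WT_EV", "WT_MDM34KD") == [0]


class TestFractionComposition:
    def test_pure_class_takes_full_share(self):
        m = make_matrix([[10.0, 10.0], [20.0, 20.0]])
        ann = pd.Series({0: "matrix", 1: "inner_membrane"})
        comp = fraction_composition(m, ann, m.values.columns)
        assert comp["mitochondria"] == pytest.approx(1.0)
        assert comp["other"] == pytest.approx(0.0)

    def test_equal_intensity_classes_split_evenly(self):
        m = make_matrix([[10.0, 10.0], [10.0, 10.0]])
        ann = pd.Series({0: "matrix", 1: "ER"})
        comp = fraction_composition(m, ann, m.values.columns)
        assert comp["mitochondria"] == pytest.approx(0.5)
        assert comp["ER+nucleus"] == pytest.approx(0.5)

    def test_shares_sum_to_one(self, small_experiment):
        catalog, matrix, _ = small_experiment
        ann = es.reference.annotation_map(catalog)
        cols = matrix.condition_samples("Tom20", "WT_EV")
        comp = fraction_composition(matrix, ann, cols)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_contaminated_pure_sample_matches_mixture_closed_form(self):
        # two proteins of equal abundance: one matrix (capture 0.9 by the
        # mito bait), one ER (capture f=1 -> mix(Tom20, ER)=0.05)
        m = make_matrix([[0.9], [0.05]], baits=["Tom20"])
        ann = pd.Series({0: "matrix", 1: "ER"})
        comp = fraction_composition(m, ann, m.values.columns)
        assert comp["ER+nucleus"] == pytest.approx(0.05 / 0.95)

    def test_empty_class_warns_with_zero_share(self):
        m = make_matrix([[10.0]], baits=["Tom20"])
        ann = pd.Series({0: "matrix"})
        with pytest.warns(UserWarning, match="peroxisome"):
            comp = fraction_composition(m, ann, m.values.columns)
        assert comp["peroxisome"] == 0.0
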