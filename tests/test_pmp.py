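import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pmpscan as ps
from pmpscan.pmp import PMPVector, StratumSpec
from pmpscan.simulate import SynthConfig, generate_methylome
from tests.conftest import TABLE1_SERIES


def _dataset(values, classes, series=None):
    n = len(classes)
    matrix = pd.DataFrame(np.asarray(values, dtype=float),
                          index=[f"cg{i}" for i in range(len(values))],
                          columns=[f"s{j}" for j in range(n)])
    samples = pd.DataFrame({
        "sample_id": matrix.columns,
        "series_id": series or ["A"] * n,
        "tissue": ["t"] * n,
        "cls": classes,
    })
    return matrix, samples


class TestBuildVector:
    def test_binary_assigns_zero_to_sperm_and_cancer(self):
        matrix, samples = _dataset([[0.1, 0.5, 0.9]],
                                   ["TUMOR", "SOMATIC_NORMAL", "GERMLINE"])
        vec = ps.build_pmp_vector(matrix, samples, mode="binary")
        assert list(vec.values) == [0.0, 1.0, 0.0]

    def test_minmax_takes_column_extremes(self):
        matrix, samples = _dataset([[0.1, 0.2], [0.4, 0.9]],
                                   ["TUMOR", "SOMATIC_NORMAL"])
        vec = ps.build_pmp_vector(matrix, samples, mode="minmax")
        assert vec.values["s0"] == pytest.approx(0.1)
        assert vec.values["s1"] == pytest.approx(0.9)

    def test_constant_matrix(self):
        matrix, samples = _dataset([[0.5, 0.5], [0.5, 0.5]],
                                   ["TUMOR", "SOMATIC_NORMAL"])
        vec = ps.build_pmp_vector(matrix, samples)
        assert (vec.values == 0.5).all()

    def test_all_missing_column_rejected(self):
        matrix, samples = _dataset([[np.nan, 0.2], [np.nan, 0.9]],
                                   ["TUMOR", "SOMATIC_NORMAL"])
        with pytest.raises(ValueError, match="s0"):
            ps.build_pmp_vector(matrix, samples, mode="minmax")


class TestPmpSim:
    def _vec(self, vals):
        return PMPVector(pd.Series(np.asarray(vals, dtype=float),
                                   index=[f"s{j}" for j in range(len(vals))]),
                         "binary")

    def test_self_correlation_is_one(self):
        matrix, _ = _dataset([[0.0, 1.0, 1.0, 0.0]], ["TUMOR"] * 4)
        sim = ps.pmp_sim(matrix, self._vec([0, 1, 1, 0]), min_samples=2)
        assert sim.loc["cg0", "sim"] == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self):
        matrix, _ = _dataset([[1.0, 0.0, 0.0, 1.0]], ["TUMOR"] * 4)
        sim = ps.pmp_sim(matrix, self._vec([0, 1, 1, 0]), min_samples=2)
        assert sim.loc["cg0", "sim"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # cov = 0.175, sd product = 0.5 * 0.35355; r = 0.98995
        matrix, _ = _dataset([[0.1, 0.8, 0.9, 0.2]], ["TUMOR"] * 4)
        sim = ps.pmp_sim(matrix, self._vec([0, 1, 1, 0]), min_samples=2)
        assert sim.loc["cg0", "sim"] == pytest.approx(0.98995, abs=1e-5)

    def test_zero_variance_row_is_missing(self):
        matrix, _ = _dataset([[0.5, 0.5, 0.5, 0.5]], ["TUMOR"] * 4)
        sim = ps.pmp_sim(matrix, self._vec([0, 1, 1, 0]), min_samples=2)
        assert np.isnan(sim.loc["cg0", "sim"])

    def test_min_samples_threshold(self):
        matrix, _ = _dataset([[0.1, 0.8, np.nan, np.nan]], ["TUMOR"] * 4)
        sim = ps.pmp_sim(matrix, self._vec([0, 1, 1, 0]), min_samples=3)
        assert np.isnan(sim.loc["cg0", "sim"])
        assert sim.loc["cg0", "n_used"] == 2

    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=8),
           st.floats(0.1, 5.0), st.floats(-2.0, 2.0))
    def test_invariant_under_affine_pmp_transform(self, row, scale, shift):
        n = len(row)
        base = np.arange(n, dtype=float) % 2
        matrix, _ = _dataset([row], ["TUMOR"] * n)
        s1 = ps.pmp_sim(matrix, self._vec(base), min_samples=2)
        s2 = ps.pmp_sim(matrix, self._vec(base * scale + shift),
                        min_samples=2)
        v1, v2 = s1.loc["cg0", "sim"], s2.loc["cg0", "sim"]
        if np.isnan(v1):
            assert np.isnan(v2)
        else:
            assert -1.0 <= v1 <= 1.0
            assert v1 == pytest.approx(v2, abs=1e-9)


def test_minmax_and_binary_sims_rank_concordant():
    """With mild noise and homogeneous tumors the two vector constructions
    order loci near-identically."""
    cfg = SynthConfig(seed=3, noise_sd=0.2, batch_shift_sd=0.0,
                      tumor_hypo_fraction=1.0, missing_rate=0.0)
    ds = generate_methylome(cfg)
    sim_mm = ps.pmp_sim(ds.matrix,
                        ps.build_pmp_vector(ds.matrix, ds.samples, "minmax"))
    sim_bin = ps.pmp_sim(ds.matrix,
                         ps.build_pmp_vector(ds.matrix, ds.samples, "binary"))
    joined = pd.DataFrame({"mm": sim_mm["sim"], "bin": sim_bin["sim"]}).dropna()
    rho = joined["mm"].corr(joined["bin"], method="spearman")
    assert rho > 0.99


class TestPermuteWithinSeries:
    def test_single_sample_series_unchanged(self):
        matrix, samples = _dataset([[0.1, 0.8, 0.9]],
                                   ["TUMOR", "SOMATIC_NORMAL", "GERMLINE"],
                                   series=["A", "B", "B"])
        out = ps.permute_within_series(matrix, samples, seed=0)
        assert out.loc["cg0", "s0"] == 0.1

    def test_multisets_preserved_per_locus_and_series(self, default_dataset):
        ds = default_dataset
        for seed in (1, 2):
            out = ps.permute_within_series(ds.matrix, ds.samples, seed=seed)
            for sid, grp in ds.samples.groupby("series_id"):
                cols = list(grp["sample_id"])
                orig = np.sort(ds.matrix[cols].to_numpy(), axis=1)
                perm = np.sort(out[cols].to_numpy(), axis=1)
                np.testing.assert_array_equal(orig, perm)

    def test_destroys_planted_signal_but_not_batch_structure(
            self, default_dataset, default_sim):
        ds = default_dataset
        perm = ps.permute_within_series(ds.matrix, ds.samples, seed=11)
        sim_perm = ps.pmp_sim(perm, ps.build_pmp_vector(perm, ds.samples))
        planted = list(ds.truth.planted_loci)
        before = default_sim.loc[planted, "sim"].mean()
        after = sim_perm.loc[planted, "sim"].mean()
        assert before > 0.5
        assert after < before / 3


class TestStratifiedSubsample:
    def test_requested_counts_returned(self, table1_samples):
        out = ps.stratified_subsample(
            table1_samples, [StratumSpec(count=2, cls="TUMOR")], seed=0)
        assert len(out) == 2
        assert (out["cls"] == "TUMOR").all()

    def test_deterministic_in_seed(self, table1_samples):
        spec = [StratumSpec(count=5, cls="TUMOR")]
        a = ps.stratified_subsample(table1_samples, spec, seed=3)
        b = ps.stratified_subsample(table1_samples, spec, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_stratum_names_it(self, table1_samples):
        with pytest.raises(ValueError, match="sperm"):
            ps.stratified_subsample(
                table1_samples,
                [StratumSpec(count=100, tissue="sperm")], seed=0)

    def test_seventy_sample_robustness_draw(self, table1_samples):
        """The published 70-sample stratified draw: 10 per tissue/condition,
        colorectal split across its two series."""
        spec = [
            StratumSpec(10, cls="SOMATIC_NORMAL", series_id="GSE26990"),
            StratumSpec(10, cls="TUMOR", series_id="GSE26990"),
            StratumSpec(10, cls="SOMATIC_NORMAL", series_id="GSE26126"),
            StratumSpec(10, cls="TUMOR", series_id="GSE26126"),
            StratumSpec(10, cls="GERMLINE", series_id="GSE26974"),
            StratumSpec(5, cls="SOMATIC_NORMAL", series_id="GSE17648"),
            StratumSpec(5, cls="SOMATIC_NORMAL", series_id="GSE25062"),
            StratumSpec(5, cls="TUMOR", series_id="GSE17648"),
            StratumSpec(5, cls="TUMOR", series_id="GSE25062"),
        ]
        out = ps.stratified_subsample(table1_samples, spec, seed=1)
        assert len(out) == 70
        assert out["sample_id"].is_unique


def test_compare_groups_on_planted_loci(default_dataset, default_sim):
    ds = default_dataset
    planted = set(ds.truth.planted_loci)
    cmp = ps.compare_groups(
        default_sim, ds.annotation,
        lambda df: pd.Series(df.index.isin(planted), index=df.index),
        lambda df: pd.Series(True, index=df.index))
    assert cmp.p < 1e-10
    assert cmp.mean_a > cmp.mean_b


def test_compare_groups_empty_selection_rejected(default_dataset,
                                                 default_sim):
    with pytest.raises(ValueError):
        ps.compare_groups(default_sim, default_dataset.annotation,
                          lambda df: pd.Series(False, index=df.index),
                          lambda df: pd.Series(True, index=df.index))
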