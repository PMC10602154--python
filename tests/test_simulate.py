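import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromdomains as cd


def test_identical_config_bit_identical_outputs():
    cfg = cd.SimConfig(n_samples=60, n_cases=25, peaks_per_chromosome=80,
                       crd_sizes=(8, 10), n_trds=2, n_cells=50,
                       n_variants=100, seed=5)
    p1, m1, t1 = cd.simulate_bulk(cfg)
    p2, m2, t2 = cd.simulate_bulk(cfg)
    pd.testing.assert_frame_equal(p1.table, p2.table)
    assert (m1.values.to_numpy() == m2.values.to_numpy()).all()
    assert t1.affected_peaks == t2.affected_peaks
    c1 = cd.simulate_single_cell(cfg, t1, p1)
    c2 = cd.simulate_single_cell(cfg, t2, p2)
    assert (c1.X != c2.X).nnz == 0


def test_copula_hits_within_crd_correlation_target():
    # one CRD of 10 peaks at rho=0.9, n=300: empirical mean pairwise r
    # must sit near the analytic copula target
    cfg = cd.SimConfig(n_samples=300, n_cases=150, n_chromosomes=1,
                       peaks_per_chromosome=60, crd_sizes=(10,), n_trds=1,
                       within_crd_correlation=0.9, disease_effect_size=0.0,
                       severity_prs_correlation=0.0,
                       covariate_effects={}, seed=3)
    peaks, m, truth = cd.simulate_bulk(cfg)
    members = truth.crd_members[0]
    X = m.values.loc[:, members].to_numpy()
    corr = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(len(members), 1)
    assert 0.8 < corr[iu].mean() < 0.95


def test_null_t_statistics_are_calibrated():
    # no disease effect: per-peak two-sample p-values ~ uniform
    cfg = cd.SimConfig(n_samples=200, n_cases=100, n_chromosomes=2,
                       peaks_per_chromosome=1000, crd_sizes=(),
                       n_trds=1, disease_effect_size=0.0,
                       severity_prs_correlation=0.0, covariate_effects={},
                       seed=7)
    peaks, m, truth = cd.simulate_bulk(cfg)
    case = (m.metadata["diagnosis"] == "case").to_numpy()
    X = m.values.to_numpy()
    p = stats.ttest_ind(X[case], X[~case]).pvalue
    assert 0.03 < (p < 0.05).mean() < 0.07


def test_case_severity_stochastically_dominates():
    cfg = cd.SimConfig(n_samples=200, n_cases=90, peaks_per_chromosome=60,
                       crd_sizes=(8,), n_trds=1, seed=9)
    _, m, truth = cd.simulate_bulk(cfg)
    case = m.metadata["diagnosis"] == "case"
    res = stats.mannwhitneyu(
        truth.sample_severity[case], truth.sample_severity[~case],
        alternative="greater",
    )
    assert res.pvalue < 1e-6


def test_realized_case_control_shift_matches_effect_size():
    cfg = cd.SimConfig(n_samples=400, n_cases=200, n_chromosomes=1,
                       peaks_per_chromosome=300, crd_sizes=(20, 20),
                       n_trds=1, disease_effect_size=1.0,
                       fraction_affected_peaks=0.1, covariate_effects={},
                       seed=13)
    _, m, truth = cd.simulate_bulk(cfg)
    case = (m.metadata["diagnosis"] == "case").to_numpy()
    diffs = []
    for p, sign in truth.affected_peaks.items():
        col = m.values[p].to_numpy()
        diffs.append(sign * (col[case].mean() - col[~case].mean()))
    assert np.mean(diffs) == pytest.approx(1.0, abs=0.1)


def test_prs_severity_correlation_target():
    cfg = cd.SimConfig(n_samples=500, n_cases=200, peaks_per_chromosome=60,
                       crd_sizes=(8,), n_trds=1,
                       severity_prs_correlation=0.5, seed=21)
    _, m, truth = cd.simulate_bulk(cfg)
    r = np.corrcoef(truth.sample_prs_true, truth.sample_severity)[0, 1]
    assert 0.4 < r < 0.6


def test_invalid_configs_name_the_field():
    with pytest.raises(ValueError, match="n_cases"):
        cd.SimConfig(n_samples=10, n_cases=10)
    with pytest.raises(ValueError, match="within_crd_correlation"):
        cd.SimConfig(within_crd_correlation=1.5)
    with pytest.raises(ValueError, match="crd_sizes"):
        cd.SimConfig(peaks_per_chromosome=10, crd_sizes=(8, 8, 8))


class TestSingleCell:
    def test_no_zero_depth_cells(self, small_cohort):
        cfg, peaks, m, truth = small_cohort
        cells = cd.simulate_single_cell(cfg, truth, peaks)
        depths = np.asarray(cells.X.sum(axis=1)).ravel()
        assert (depths > 0).all()
        assert set(cells.obs.columns) >= {"cell_type", "sample_id",
                                          "stage_group"}

    def test_planted_signal_elevates_type_mean(self):
        # planted 2x open probability: signal peaks' mean accessibility in
        # the focal type exceeds other types in nearly all seeds
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = cd.SimConfig(n_samples=40, n_cases=15,
                               peaks_per_chromosome=60, crd_sizes=(8,),
                               n_trds=1, n_cells=150, n_cell_types=3,
                               celltype_signal_fraction=0.15, n_variants=50,
                               seed=seed)
            peaks, m, truth = cd.simulate_bulk(cfg)
            cells = cd.simulate_single_cell(cfg, truth, peaks)
            sig = truth.celltype_signal_peaks["type_1"]
            cols = [cells.var_names.get_loc(p) for p in sig]
            depth = np.asarray(cells.X.sum(axis=1)).ravel()
            frac = np.asarray(cells.X[:, cols].sum(axis=1)).ravel() / depth
            is_a = (cells.obs["cell_type"] == "type_1").to_numpy()
            wins += frac[is_a].mean() > frac[~is_a].mean()
        assert wins >= 0.95 * n_seeds

    def test_no_planted_signal_means_comparable_type_means(self):
        cfg = cd.SimConfig(n_samples=40, n_cases=15, peaks_per_chromosome=60,
                           crd_sizes=(8,), n_trds=1, n_cells=400,
                           n_cell_types=2, celltype_signal_fraction=0.0,
                           n_variants=50, seed=2)
        peaks, m, truth = cd.simulate_bulk(cfg)
        cells = cd.simulate_single_cell(cfg, truth, peaks)
        depth = np.asarray(cells.X.sum(axis=1)).ravel()
        frac = np.asarray(cells.X[:, :30].sum(axis=1)).ravel() / depth
        is_a = (cells.obs["cell_type"] == "type_1").to_numpy()
        p = stats.ttest_ind(frac[is_a], frac[~is_a]).pvalue
        assert p > 0.001  # only sampling noise separates the types


class TestGenotypes:
    def test_dosage_support(self, small_cohort):
        cfg, peaks, m, truth = small_cohort
        dosages, weights = cd.simulate_genotypes(cfg, peaks, truth)
        assert set(np.unique(dosages.to_numpy())) <= {0, 1, 2}
        assert len(weights) == cfg.n_variants

    def test_weights_concentrate_in_affected_peaks(self, small_cohort):
        cfg, peaks, m, truth = small_cohort
        _, weights = cd.simulate_genotypes(cfg, peaks, truth)
        vt = truth._variant_table
        inside = vt["host_peak"].isin(truth.affected_peaks).to_numpy()
        w = vt["weight"].to_numpy()
        assert (w[inside] != 0).all()
        assert np.abs(w[inside]).mean() > 3 * np.abs(w[~inside]).mean()

    def test_zero_weights_give_zero_scores(self, small_cohort):
        cfg, peaks, m, truth = small_cohort
        dosages, weights = cd.simulate_genotypes(cfg, peaks, truth)
        weights = weights.assign(weight=0.0)
        scores = cd.score_samples(weights, dosages)
        assert (scores == 0).all()


def test_fold_change_generator_hits_target_spearman():
    a, b = cd.simulate_fold_changes(3000, 0.4, seed=0)
    rho = stats.spearmanr(a, b)[0]
    assert rho == pytest.approx(0.4, abs=0.05)
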