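import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import chromdomains as cd
from chromdomains.domains import CrdDifferential, DomainSet
from chromdomains.matrix import AccessibilityMatrix
from chromdomains.peaks import PeakSet


def _matrix_from_array(X, diagnosis=None):
    samples = [f"s{i}" for i in range(X.shape[0])]
    cols = [f"p{j:03d}" for j in range(X.shape[1])]
    meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    meta["diagnosis"] = diagnosis if diagnosis is not None else "control"
    return AccessibilityMatrix(
        pd.DataFrame(X, index=meta.index, columns=cols), meta
    )


def _peaks_for(n, chrom="chr1"):
    starts = np.arange(n) * 1000
    return PeakSet.from_arrays(
        [chrom] * n, starts, starts + 500, [f"p{j:03d}" for j in range(n)]
    )


# Naive, independent CRD oracle (pairwise pearsonr, double-loop merges,
# explicit acceptance checks) lives in chromdomains.validation; it shares
# no code with the optimized caller.
from chromdomains.validation import gamma_brute, naive_crd_intervals  # noqa: E402


def _called_intervals(dom, n):
    out = []
    for cid, mem in dom.members.items():
        out.append(tuple(sorted(int(p[1:]) for p in mem)))
    return sorted(out)


def _random_instance(seed):
    r = np.random.default_rng(seed)
    k = int(r.integers(3, 9))
    n = 60
    X = r.normal(size=(n, k))
    if seed % 2 == 0 and k >= 4:  # plant a correlated block half the time
        size = int(r.integers(3, min(k, 5) + 1))
        lo = int(r.integers(0, k - size + 1))
        f = r.normal(size=n)
        X[:, lo: lo + size] = (
            np.sqrt(0.6) * f[:, None]
            + np.sqrt(0.4) * r.normal(size=(n, size))
        )
    return X


@pytest.mark.parametrize("batch", range(8))
def test_crd_calls_equal_naive_oracle(batch):
    """200 random small instances: optimized caller == naive re-derivation."""
    for s in range(25):
        seed = batch * 25 + s
        X = _random_instance(seed)
        m = _matrix_from_array(X)
        dom = cd.build_crds(m, _peaks_for(X.shape[1]), r_threshold=0.3,
                            min_peaks=3)
        assert _called_intervals(dom, X.shape[1]) == naive_crd_intervals(
            X, 0.3, 3
        ), f"mismatch at seed {seed}"


def test_planted_block_recovered_exactly(rng):
    n, k = 300, 40
    f = rng.normal(size=n)
    X = rng.normal(size=(n, k))
    X[:, 10:20] = np.sqrt(0.9) * f[:, None] + np.sqrt(0.1) * rng.normal(
        size=(n, 10)
    )
    dom = cd.build_crds(_matrix_from_array(X), _peaks_for(k))
    assert len(dom) == 1
    assert sorted(dom.members[dom.crd_ids[0]]) == [
        f"p{j:03d}" for j in range(10, 20)
    ]


def test_independent_peaks_give_no_crds():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        X = r.normal(size=(300, 50))
        dom = cd.build_crds(_matrix_from_array(X), _peaks_for(50))
        hits += len(dom) > 0
    assert hits <= 2  # >= 90% of seeds yield zero CRDs


def test_build_crds_invariant_to_sample_order_and_affine_rescaling(rng):
    X = _random_instance(4)
    m1 = _matrix_from_array(X)
    perm = rng.permutation(X.shape[0])
    scale = rng.uniform(0.5, 3.0, size=X.shape[1])
    shift = rng.normal(size=X.shape[1])
    m2 = _matrix_from_array(X[perm] * scale + shift)
    p = _peaks_for(X.shape[1])
    d1, d2 = cd.build_crds(m1, p, 0.3, 3), cd.build_crds(m2, p, 0.3, 3)
    assert _called_intervals(d1, 0) == _called_intervals(d2, 0)


def test_crd_summaries_and_empty_error(small_cohort):
    cfg, peaks, m, truth = small_cohort
    dom = cd.domains_from_truth(truth, peaks, m)
    s = cd.crd_summaries(dom)
    assert s["mean_peaks_per_crd"] == pytest.approx(
        np.mean([len(v) for v in truth.crd_members.values()])
    )
    assert s["median_length_bp"] > 0
    empty = DomainSet(
        table=dom.table.iloc[:0], members={},
        signal=dom.signal.iloc[:, :0], peak_assignment=dom.peak_assignment,
    )
    with pytest.raises(ValueError, match="nonempty"):
        cd.crd_summaries(empty)


# ---------------------------------------------------------------------------
# Inside/outside GLM
# ---------------------------------------------------------------------------

def _fake_diff(t_values, ids):
    table = pd.DataFrame(
        {"log2fc": t_values, "t": t_values,
         "p": np.ones(len(ids)), "fdr": np.ones(len(ids)),
         "direction": "none"},
        index=pd.Index(ids, name="peak_id"),
    )
    return cd.DifferentialResult(table=table)


def _fake_domains(assignment: pd.Series):
    return DomainSet(
        table=pd.DataFrame({"crd_id": ["crd_1"], "chrom": ["chr1"],
                            "start": [0], "end": [1], "n_peaks": [1],
                            "mean_internal_correlation": [1.0]}),
        members={}, signal=pd.DataFrame(), peak_assignment=assignment,
    )


def test_inside_outside_glm_equals_contingency_cross_product():
    # binary |t|: logistic OR reduces to the 2x2 cross-product ratio
    ids, t_vals, inside = [], [], []
    spec = [(30, 1.0, "crd_1"), (10, 0.0, "crd_1"),
            (20, 1.0, None), (40, 0.0, None)]
    c = 0
    for count, t, a in spec:
        for _ in range(count):
            ids.append(f"p{c}")
            t_vals.append(t)
            inside.append(a)
            c += 1
    diff = _fake_diff(np.array(t_vals), ids)
    dom = _fake_domains(pd.Series(inside, index=ids, dtype=object))
    or_, p = cd.inside_outside_glm(diff, dom)
    assert or_ == pytest.approx((30 * 40) / (10 * 20), rel=1e-4)
    assert p < 0.01


def test_inside_outside_glm_null_and_separation(rng):
    ids = [f"p{i}" for i in range(400)]
    diff = _fake_diff(rng.normal(size=400), ids)
    assign = pd.Series(
        np.where(rng.random(400) < 0.5, "crd_1", None), index=ids, dtype=object
    )
    or_, p = cd.inside_outside_glm(diff, _fake_domains(assign))
    assert p > 0.001  # membership independent of |t|
    all_in = pd.Series(["crd_1"] * 400, index=ids, dtype=object)
    with pytest.raises(ValueError, match="separation"):
        cd.inside_outside_glm(diff, _fake_domains(all_in))


def test_inside_outside_enrichment_on_planted_simulation(small_cohort):
    cfg, peaks, m, truth = small_cohort
    mr = cd.residualize(m, ["age", "sex", "batch"])
    diff = cd.differential_peaks(mr)
    dom = cd.domains_from_truth(truth, peaks, mr)
    or_, p = cd.inside_outside_glm(diff, dom)
    assert or_ > 1.0 and p < 0.01  # affected peaks live inside CRDs


# ---------------------------------------------------------------------------
# Two-stage CRD test
# ---------------------------------------------------------------------------

class TestTwoStage:
    def test_invalid_alpha(self, small_cohort):
        cfg, peaks, m, truth = small_cohort
        dom = cd.domains_from_truth(truth, peaks, m)
        with pytest.raises(ValueError, match="alpha"):
            cd.two_stage_crd_test(dom, m, alpha=1.5)

    def test_single_crd_matches_plain_t_test_under_strong_signal(self, rng):
        n = 100
        labels = ["case"] * 50 + ["control"] * 50
        X = rng.normal(size=(n, 5))
        X[:50] += 1.0
        m = _matrix_from_array(X, labels)
        peaks = _peaks_for(5)
        dom = DomainSet(
            table=pd.DataFrame({"crd_id": ["crd_1"], "chrom": ["chr1"],
                                "start": [0], "end": [4500], "n_peaks": [5],
                                "mean_internal_correlation": [0.5]}),
            members={"crd_1": list(peaks.ids)},
            signal=pd.DataFrame({"crd_1": X.mean(axis=1)},
                                index=m.values.index),
            peak_assignment=pd.Series(["crd_1"] * 5, index=peaks.ids,
                                      dtype=object),
        )
        res = cd.two_stage_crd_test(dom, m)
        sig = X.mean(axis=1)
        t_p = stats.ttest_ind(sig[:50], sig[50:]).pvalue
        assert bool(res.table["significant"].iloc[0]) == (t_p < 0.05)
        assert res.table["direction"].iloc[0] == "up"

    def test_planted_shift_sensitivity(self):
        hits, total = 0, 0
        for seed in range(5):
            cfg = cd.SimConfig(
                n_samples=300, n_cases=150, n_chromosomes=2,
                peaks_per_chromosome=200, crd_sizes=tuple([8] * 15),
                n_trds=3, disease_effect_size=0.8,
                fraction_affected_peaks=0.1, seed=seed,
            )
            peaks, m, truth = cd.simulate_bulk(cfg)
            mr = cd.residualize(m, ["age", "sex", "batch"])
            dom = cd.domains_from_truth(truth, peaks, mr)
            res = cd.two_stage_crd_test(dom, mr)
            shifted = {
                f"crd_{truth.peak_to_crd[p] + 1:05d}"
                for p in truth.affected_peaks
                if truth.peak_to_crd[p] is not None
            }
            called = set(res.significant_ids())
            hits += len(called & shifted)
            total += len(shifted)
        assert hits / total >= 0.9

    def test_screening_pvalues_uniform_under_null(self):
        ps = []
        for seed in range(3):
            cfg = cd.SimConfig(
                n_samples=200, n_cases=100, n_chromosomes=2,
                peaks_per_chromosome=300, crd_sizes=tuple([5] * 60),
                n_trds=3, disease_effect_size=0.0,
                severity_prs_correlation=0.0, seed=seed,
            )
            peaks, m, truth = cd.simulate_bulk(cfg)
            mr = cd.residualize(m, ["age", "sex", "batch"])
            dom = cd.domains_from_truth(truth, peaks, mr)
            res = cd.two_stage_crd_test(dom, mr)
            ps.append(res.table["p_screen"].to_numpy())
        p = np.concatenate(ps)
        # exact-test p-values may be mildly conservative, never inflated
        assert (p < 0.05).mean() < 0.08
        assert (p < 0.001).mean() < 0.005


# ---------------------------------------------------------------------------
# Gamma statistic
# ---------------------------------------------------------------------------

class TestGamma:
    def test_separated_blobs_give_gamma_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                       rng.normal(10, 0.1, size=(10, 2))])
        labels = [0] * 10 + [1] * 10
        assert cd.gamma_statistic(pdist(X), labels) == 1.0

    def test_random_labels_give_gamma_near_zero(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 3))
            labels = r.integers(0, 4, size=40)
            vals.append(cd.gamma_statistic(pdist(X), labels))
        assert abs(np.mean(vals)) < 0.1

    @pytest.mark.parametrize("batch", range(4))
    def test_equals_brute_force_enumeration(self, batch):
        for s in range(50):
            r = np.random.default_rng(batch * 50 + s)
            n = int(r.integers(5, 16))
            X = r.normal(size=(n, 2))
            k = int(r.integers(2, max(3, n // 2)))
            labels = np.concatenate(
                [np.arange(k), r.integers(0, k, size=n - k)]
            )
            d = pdist(X)
            try:
                got = cd.gamma_statistic(d, labels)
            except ValueError:
                continue  # too few within/between pairs; contract tested below
            assert got == pytest.approx(gamma_brute(d, labels), abs=0)

    def test_degenerate_partitions_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="single cluster"):
            cd.gamma_statistic(pdist(X), [0] * 6)
        with pytest.raises(ValueError, match="pairs"):
            cd.gamma_statistic(pdist(X), [0, 1, 2, 3, 4, 5])


# ---------------------------------------------------------------------------
# TRD discovery
# ---------------------------------------------------------------------------

class TestBuildTrds:
    def _planted(self, seed, n_trds=3, crds_per_trd=15):
        cfg = cd.SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=3,
            peaks_per_chromosome=200,
            crd_sizes=tuple([10] * (n_trds * crds_per_trd)),
            n_trds=n_trds, trd_cross_correlation=0.6,
            disease_effect_size=0.0, severity_prs_correlation=0.0,
            seed=seed,
        )
        peaks, m, truth = cd.simulate_bulk(cfg)
        dom = cd.domains_from_truth(truth, peaks, m)
        return truth, dom

    def test_recovers_planted_trds(self):
        truth, dom = self._planted(seed=0)
        part = cd.build_trds(dom, k_range=range(2, 9))
        assert part.k == 3
        truth_lab = [truth.crd_to_trd[int(c.split("_")[1]) - 1]
                     for c in part.assignment.index]
        assert adjusted_rand_score(truth_lab, part.assignment) >= 0.9

    def test_forced_k_returns_that_k(self):
        truth, dom = self._planted(seed=1)
        part = cd.build_trds(dom, k_range=[3])
        assert part.k == 3 and set(part.gamma_trace) == {3}

    def test_independent_crds_score_below_planted_structure(self):
        # without trans modules the Gamma trace stays well below the planted
        # case and shows no early peak (chance pairings inflate Gamma at
        # large k, so the discriminating signal is the low-k regime)
        cfg = cd.SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=3,
            peaks_per_chromosome=150, crd_sizes=tuple([8] * 30), n_trds=30,
            trd_cross_correlation=0.0, disease_effect_size=0.0,
            severity_prs_correlation=0.0, seed=5,
        )
        peaks, m, truth = cd.simulate_bulk(cfg)
        dom = cd.domains_from_truth(truth, peaks, m)
        part = cd.build_trds(dom, k_range=range(2, 10))
        truth_s, dom_s = self._planted(seed=5)
        part_s = cd.build_trds(dom_s, k_range=range(2, 10))
        assert max(part.gamma_trace.values()) < 0.7
        assert max(part.gamma_trace[k] for k in (2, 3, 4)) < 0.5
        assert max(part_s.gamma_trace.values()) > 0.95  # planted contrast

    def test_restriction_to_significant_crds(self, small_cohort):
        cfg, peaks, m, truth = small_cohort
        mr = cd.residualize(m, ["age", "sex", "batch"])
        dom = cd.domains_from_truth(truth, peaks, mr)
        crd_diff = cd.two_stage_crd_test(dom, mr)
        n_sig = int(crd_diff.table["significant"].sum())
        if n_sig >= 4:
            part = cd.build_trds(dom, range(2, n_sig), crd_diff=crd_diff)
            assert set(part.assignment.index) <= set(
                crd_diff.significant_ids()
            )
        else:
            # too few significant CRDs: no valid partition exists
            with pytest.raises(ValueError):
                cd.build_trds(dom, range(2, 5), crd_diff=crd_diff)


class TestDirectionProfile:
    def _partition(self, crds):
        return cd.TrdPartition(
            assignment=pd.Series([1] * len(crds), index=crds), k=1
        )

    def _crd_diff(self, crds, directions):
        table = pd.DataFrame(
            {"log2fc": [1.0 if d == "up" else -1.0 for d in directions],
             "direction": directions, "significant": True},
            index=pd.Index(crds, name="crd_id"),
        )
        return CrdDifferential(table=table)

    def test_all_up_is_flagged(self):
        crds = [f"c{i}" for i in range(6)]
        prof = cd.trd_direction_profile(
            self._partition(crds), self._crd_diff(crds, ["up"] * 6)
        )
        assert bool(prof["predominantly_up"].iloc[0])

    def test_balanced_trd_not_flagged(self):
        crds = ["a", "b", "c", "d"]
        prof = cd.trd_direction_profile(
            self._partition(crds),
            self._crd_diff(crds, ["up", "up", "down", "down"]),
        )
        assert prof["up_fraction"].iloc[0] == 0.5
        assert not bool(prof["predominantly_up"].iloc[0])

    def test_planted_disease_trd_flagged(self):
        cfg = cd.SimConfig(
            n_samples=300, n_cases=150, n_chromosomes=2,
            peaks_per_chromosome=200, crd_sizes=tuple([8] * 15), n_trds=3,
            disease_effect_size=1.0, fraction_affected_peaks=0.15,
            affected_up_fraction=1.0, seed=3,
        )
        peaks, m, truth = cd.simulate_bulk(cfg)
        mr = cd.residualize(m, ["age", "sex", "batch"])
        dom = cd.domains_from_truth(truth, peaks, mr)
        crd_diff = cd.two_stage_crd_test(dom, mr)
        part = cd.build_trds(dom, range(2, 6), crd_diff=crd_diff)
        prof = cd.trd_direction_profile(part, crd_diff)
        assert prof["predominantly_up"].any()


class TestFoldChangeCorrelation:
    def test_identical_vectors_give_rho_one(self):
        a, _ = cd.simulate_fold_changes(100, 0.4, seed=0)
        rho, p, n = cd.fold_change_correlation(a, a)
        assert rho == pytest.approx(1.0) and n == 100

    def test_independent_vectors_near_zero(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            ids = [f"x{i}" for i in range(500)]
            a = pd.Series(r.normal(size=500), index=ids)
            b = pd.Series(r.normal(size=500), index=ids)
            rho, _, _ = cd.fold_change_correlation(a, b)
            hits += abs(rho) < 0.12
        assert hits >= 19

    def test_too_few_shared_peaks(self):
        a = pd.Series(np.arange(5.0), index=list("abcde"))
        with pytest.raises(ValueError, match=">= 10"):
            cd.fold_change_correlation(a, a)
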