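"""Mixture EM, information criteria, model vote and MQTL formation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from mastqtl.meta_analysis import (
    MixtureFit,
    _log_density,
    analyze_chromosome,
    compute_criteria,
    criteria_table,
    fit_gaussian_mixture,
    form_mqtls,
    select_model,
    sigma_from_ci,
)
from mastqtl.projection import ProjectedQTL
from mastqtl.qtl_data import QTLRecord


def brute_force_loglik(x, s, K):
    """Oracle: best mixture log-likelihood over all hard assignments with
    closed-form inverse-variance means and count weights."""
    best = -np.inf
    for z in itertools.product(range(K), repeat=len(x)):
        z = np.array(z)
        if len(set(z.tolist())) < K:
            continue
        mus, w = np.zeros(K), np.zeros(K)
        for k in range(K):
            idx = z == k
            iv = 1.0 / s[idx] ** 2
            mus[k] = np.sum(x[idx] * iv) / np.sum(iv)
            w[k] = idx.mean()
        lp = _log_density(x, s, mus) + np.log(w)[None, :]
        best = max(best, float(logsumexp(lp, axis=1).sum()))
    return best


def make_projected(qtl_id, study_id, peak, ci_width, stress="DS", chrom="1A", pve=10.0):
    rec = QTLRecord(
        qtl_id=qtl_id,
        study_id=study_id,
        population_type="RIL",
        population_size=150,
        stress=stress,
        trait="t",
        chromosome=chrom,
        left_marker="a",
        right_marker="b",
        peak_cm=peak,
        ci_start_cm=peak - ci_width / 2,
        ci_end_cm=peak + ci_width / 2,
        lod=4.0,
        pve=pve,
    )
    return ProjectedQTL(
        source=rec,
        consensus_chromosome=chrom,
        peak_cm=peak,
        ci_start_cm=peak - ci_width / 2,
        ci_end_cm=peak + ci_width / 2,
        status="projected",
    )


class TestFit:
    def test_identical_peaks_k1_closed_form(self):
        x = np.full(5, 12.0)
        s = np.array([1.0, 2.0, 0.5, 1.0, 1.5])
        fit = fit_gaussian_mixture(x, s, 1)
        assert fit.means[0] == pytest.approx(12.0)
        expected = sum(
            -0.5 * math.log(2 * math.pi) - math.log(si) for si in s
        )
        assert fit.loglik == pytest.approx(expected)

    def test_two_cluster_recovery(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(10, 1, 20), rng.normal(90, 1, 20)])
        s = np.ones(40)
        fit = fit_gaussian_mixture(x, s, 2, rng=0)
        # oracle: hard split at the midpoint, inverse-variance (= plain) means
        left, right = x[x < 50].mean(), x[x >= 50].mean()
        assert abs(fit.means[0] - left) < 0.5
        assert abs(fit.means[1] - right) < 0.5

    def test_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 5, 12)
        s = np.ones(12)
        lls = [fit_gaussian_mixture(x, s, K, seeds=8, rng=1).loglik for K in (1, 2, 3)]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_k_exceeding_n_raises(self):
        with pytest.raises(ValueError, match="K exceeds n"):
            fit_gaussian_mixture([1.0, 2.0], [1.0, 1.0], 3)

    @pytest.mark.parametrize("trial", range(5))
    def test_em_matches_brute_force_oracle(self, trial):
        """For n <= 8, K <= 2 the EM optimum matches exhaustive hard
        assignment + closed-form means to 1e-6."""
        rng = np.random.default_rng(100 + trial)
        K = 1 + trial % 2
        n = int(rng.integers(4, 9))
        centers = np.array([0.0, 30.0])[:K]
        z = rng.integers(K, size=n)
        if len(set(z.tolist())) < K:
            z[0] = 0
            z[-1] = K - 1
        s = rng.uniform(0.5, 1.5, n)
        x = centers[z] + rng.normal(0, s)
        fit = fit_gaussian_mixture(x, s, K, seeds=8, rng=7)
        assert fit.loglik == pytest.approx(brute_force_loglik(x, s, K), abs=1e-6)


class TestCriteria:
    def test_formula_arithmetic(self):
        # fabricated fit: logL = -100, K=2 (d=3), n=50
        fit = MixtureFit(
            K=2,
            weights=np.array([0.5, 0.5]),
            means=np.array([0.0, 10.0]),
            sigmas=np.ones(50),
            positions=np.concatenate([np.zeros(25), np.full(25, 10.0)]),
            loglik=-100.0,
            posteriors=np.tile([1.0, 0.0], (50, 1)),
        )
        row = compute_criteria(fit, 50)
        assert row["AIC"] == pytest.approx(206.0)
        assert row["AIC3"] == pytest.approx(209.0)
        assert row["BIC"] == pytest.approx(200.0 + 3 * math.log(50))
        assert row["AICc"] == pytest.approx(206.0 + 2 * 3 * 4 / (50 - 3 - 1))

    def test_aic_below_bic_for_large_n(self):
        fit = fit_gaussian_mixture(np.arange(30.0), np.ones(30), 1)
        row = compute_criteria(fit, 30)
        assert row["AIC"] - row["BIC"] == pytest.approx(2 * 1 - 1 * math.log(30))
        assert row["AIC"] < row["BIC"]

    def test_aicc_undefined_when_n_too_small(self):
        x = np.array([0.0, 1.0, 10.0])
        fit = fit_gaussian_mixture(x, np.ones(3), 2)
        row = compute_criteria(fit, 3)  # n - d - 1 = 3 - 3 - 1 < 0
        assert math.isnan(row["AICc"])

    def test_all_five_minimized_at_true_k(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(10, 1, 20), rng.normal(90, 1, 20)])
        s = np.ones(40)
        fits = [fit_gaussian_mixture(x, s, K, rng=2) for K in range(1, 7)]
        table = criteria_table(fits)
        for crit in ("AIC", "AICc", "AIC3", "BIC", "AWE"):
            assert int(table[crit].dropna().idxmin()) == 2


class TestSelectModel:
    def make_table(self, values):
        return pd.DataFrame(values).set_index("K")

    def test_majority_vote_three_of_five(self):
        # AIC, AICc, AIC3 minimal at K=2; BIC, AWE at K=1
        t = self.make_table(
            [
                {"K": 1, "AIC": 10, "AICc": 10, "AIC3": 10, "BIC": 5, "AWE": 5},
                {"K": 2, "AIC": 8, "AICc": 8, "AIC3": 8, "BIC": 6, "AWE": 6},
            ]
        )
        k, detail = select_model(t)
        assert k == 2 and detail["rule"] == "vote"

    def test_unanimous(self):
        t = self.make_table(
            [
                {"K": 1, "AIC": 1, "AICc": 1, "AIC3": 1, "BIC": 1, "AWE": 1},
                {"K": 2, "AIC": 2, "AICc": 2, "AIC3": 2, "BIC": 2, "AWE": 2},
            ]
        )
        assert select_model(t)[0] == 1

    def test_split_vote_falls_back_to_bic(self):
        t = self.make_table(
            [
                {"K": 1, "AIC": 3, "AICc": 1, "AIC3": 3, "BIC": 9, "AWE": 1},
                {"K": 2, "AIC": 1, "AICc": 3, "AIC3": 1, "BIC": 8, "AWE": 3},
                {"K": 3, "AIC": 4, "AICc": 4, "AIC3": 4, "BIC": 7, "AWE": 4},
            ]
        )
        k, detail = select_model(t)
        assert k == 3 and detail["rule"] == "bic_fallback"


class TestFormMqtls:
    def two_component_fixture(self):
        members = (
            [make_projected(f"a{i}", f"s{i % 3}", 10.0 + 0.1 * i, 4.0, pve=8.0) for i in range(6)]
            + [make_projected(f"b{i}", f"s{i % 3}", 90.0 + 0.1 * i, 4.0, pve=12.0) for i in range(6)]
        )
        x = np.array([m.peak_cm for m in members])
        s = np.array([sigma_from_ci(m.ci_width_cm) for m in members])
        return fit_gaussian_mixture(x, s, 2, rng=0), members

    def test_names_ascend_by_position(self):
        fit, members = self.two_component_fixture()
        mqtls, _ = form_mqtls(fit, members, "1A")
        assert [m.name for m in mqtls] == ["MQTL1A.1", "MQTL1A.2"]
        assert mqtls[0].position_cm < mqtls[1].position_cm

    def test_mean_lod_pve_are_arithmetic_means(self):
        fit, members = self.two_component_fixture()
        mqtls, _ = form_mqtls(fit, members, "1A")
        assert mqtls[0].mean_pve == pytest.approx(8.0)
        assert mqtls[1].mean_pve == pytest.approx(12.0)
        assert mqtls[0].mean_lod == pytest.approx(4.0)

    def test_position_within_member_peaks_and_ci_narrower(self):
        fit, members = self.two_component_fixture()
        mqtls, _ = form_mqtls(fit, members, "1A")
        for m in mqtls:
            peaks = [p.peak_cm for p in members if p.source.qtl_id in m.member_ids]
            assert min(peaks) <= m.position_cm <= max(peaks)
            widths = [p.ci_width_cm for p in members if p.source.qtl_id in m.member_ids]
            assert m.ci_width_cm <= min(widths)  # inverse-variance pooling never widens

    def test_single_study_component_discarded(self):
        members = [
            make_projected(f"a{i}", "only_study", 10.0 + 0.1 * i, 4.0) for i in range(5)
        ] + [make_projected(f"b{i}", f"s{i}", 90.0 + 0.1 * i, 4.0) for i in range(5)]
        x = np.array([m.peak_cm for m in members])
        s = np.array([sigma_from_ci(m.ci_width_cm) for m in members])
        fit = fit_gaussian_mixture(x, s, 2, rng=0)
        mqtls, discards = form_mqtls(fit, members, "1A")
        assert len(mqtls) == 1
        assert set(discards["single_study"]) == {f"a{i}" for i in range(5)}

    def test_singleton_component_reported(self):
        members = [make_projected("lone", "s1", 10.0, 2.0)] + [
            make_projected(f"b{i}", f"s{i}", 90.0 + 0.1 * i, 4.0) for i in range(5)
        ]
        x = np.array([m.peak_cm for m in members])
        s = np.array([sigma_from_ci(m.ci_width_cm) for m in members])
        fit = fit_gaussian_mixture(x, s, 2, rng=0)
        mqtls, discards = form_mqtls(fit, members, "1A")
        assert discards["singleton"] == ["lone"]
        assert len(mqtls) == 1

    def test_stress_tally_expands_combined_drought_heat(self):
        members = [
            make_projected("a0", "s0", 10.0, 4.0, stress="D+H"),
            make_projected("a1", "s1", 10.2, 4.0, stress="SS"),
        ]
        x = np.array([m.peak_cm for m in members])
        s = np.array([sigma_from_ci(m.ci_width_cm) for m in members])
        fit = fit_gaussian_mixture(x, s, 1)
        mqtls, _ = form_mqtls(fit, members, "2B")
        assert mqtls[0].stress_tally == {"DS": 1, "HS": 1, "SS": 1}
        assert mqtls[0].n_stress_classes == 3


def test_parameter_recovery_over_seeded_replicates():
    """On well-separated synthetic chromosomes (true K in {1,2,3}, separation
    >= 8 * max sigma, >= 15 QTLs per component, >= 3 studies), the 3-of-5
    vote recovers the true K in >= 90% of replicates with component means
    within 1 cM."""
    n_rep = 30
    ok = 0
    for rep in range(n_rep):
        rng = np.random.default_rng(2000 + rep)
        true_k = rep % 3 + 1
        sigma_max = 2.0
        means = 20.0 + np.arange(true_k) * (8 * sigma_max + 5)
        x, s = [], []
        for k in range(true_k):
            n_k = int(rng.integers(15, 22))
            sk = rng.uniform(0.5, sigma_max, n_k)
            x.append(rng.normal(means[k], sk))
            s.append(sk)
        x, s = np.concatenate(x), np.concatenate(s)
        fits = [fit_gaussian_mixture(x, s, K, rng=rng) for K in range(1, 7)]
        k_star, _ = select_model(criteria_table(fits))
        if k_star == true_k and np.abs(np.sort(fits[true_k - 1].means) - means).max() < 1.0:
            ok += 1
    assert ok / n_rep >= 0.9


def test_fold_reduction_greater_than_one(prepared_records, study_data, cmap):
    """Inverse-variance pooling shrinks the mean CI relative to members."""
    from mastqtl.pipeline import ci_fold_reduction
    from mastqtl.projection import project_all

    projected, _ = project_all(prepared_records, study_data.study_maps, cmap)
    mqtls = []
    for chrom in ("1A", "2B", "3D"):
        mqtls.extend(analyze_chromosome(projected, chrom, rng=0)["mqtls"])
    assert ci_fold_reduction(projected, mqtls) > 1.0
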