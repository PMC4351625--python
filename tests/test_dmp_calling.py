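import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix
from epidiff.dmp import (FdrPolicy, call_dmps, eligible_sites,
                         fisher_exact_2x2, fisher_exact_many, storey_pi0,
                         storey_qvalues)


def enumeration_p(ma, ua, mb, ub):
    """Independent oracle: exhaustive hypergeometric enumeration with
    integer binomial weights; two-sided by the point-probability rule with
    1e-7 relative tie tolerance."""
    n1, n2, k = ma + ua, mb + ub, ma + mb
    denom = math.comb(n1 + n2, k)
    weights = [math.comb(n1, a) * math.comb(n2, k - a)
               for a in range(max(0, k - n2), min(k, n1) + 1)]
    w_obs = math.comb(n1, ma) * math.comb(n2, mb)
    total = sum(w for w in weights if w <= w_obs * (1 + 1e-7))
    return total / denom


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_fully_separated_table(self):
        # only the observed table and its mirror are as extreme
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12)

    def test_worked_small_table(self):
        assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70,
                                                             rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_many(np.array([-1]), np.array([2]),
                              np.array([3]), np.array([4]))

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            ma, ua, mb, ub = (int(x) for x in rng.integers(0, 16, 4))
            if ma + ua + mb + ub == 0:
                continue
            expected = enumeration_p(ma, ua, mb, ub)
            assert fisher_exact_2x2(ma, ua, mb, ub) == pytest.approx(
                expected, rel=1e-9)

    def test_vectorised_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        ma, ua, mb, ub = (rng.integers(0, 60, 200) for _ in range(4))
        p_vec = fisher_exact_many(ma, ua, mb, ub)
        p_scalar = np.array([fisher_exact_2x2(*t)
                             for t in zip(ma, ua, mb, ub)])
        assert np.allclose(p_vec, p_scalar, rtol=1e-11)


class TestEligibility:
    @pytest.mark.parametrize("cov_a,cov_b,meth_a,meth_b,expect", [
        (4, 4, 2, 0, True),    # boundary of both rules
        (3, 100, 3, 50, False),  # coverage floor fails in one genotype
        (10, 10, 1, 1, False),   # no genotype reaches 2 methylated reads
        (4, 4, 0, 2, True),
        (50, 50, 0, 0, False),
    ])
    def test_coverage_rules(self, cov_a, cov_b, meth_a, meth_b, expect):
        m = make_matrix(
            [("Chr1", 1, "+", "CG", [(meth_a, cov_a), (meth_b, cov_b)])],
            ["a", "b"])
        assert eligible_sites(m, "a", "b")[0] == expect

    def test_unknown_sample_rejected(self):
        m = make_matrix([("Chr1", 1, "+", "CG", [(1, 4), (1, 4)])],
                        ["a", "b"])
        with pytest.raises(KeyError):
            eligible_sites(m, "a", "zzz")


class TestStoreyQvalues:
    def test_single_p_with_forced_pi0(self):
        q, pi0 = storey_qvalues(np.array([0.2]), pi0=1.0)
        assert q[0] == pytest.approx(0.2) and pi0 == 1.0

    def test_step_up_worked_example(self):
        q, _ = storey_qvalues(np.array([0.005, 0.01, 0.5, 1.0]), pi0=1.0)
        assert np.allclose(q, [0.02, 0.02, 2 / 3, 1.0], atol=5e-5)

    def test_pi0_near_one_on_uniform_nulls(self):
        rng = np.random.default_rng(2024)
        p = rng.uniform(size=10_000)
        assert 0.9 <= storey_pi0(p) <= 1.1

    def test_small_m_falls_back_to_one(self):
        assert storey_pi0(np.linspace(0.01, 0.99, 50)) == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        q, pi0 = storey_qvalues(p)
        assert ((q >= 0) & (q <= 1)).all() and 0 < pi0 <= 1
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([]))
        with pytest.raises(ValueError):
            storey_qvalues(np.array([1.5]))


def _null_matrix_with_spike(n_null=100, seed=0):
    """100 CG sites with identical proportions plus one fully separated
    site."""
    rng = np.random.default_rng(seed)
    rows = [("Chr1", 10_000, "+", "CG", [(12, 12), (0, 12)])]
    for i in range(n_null):
        cov = int(rng.integers(10, 30))
        meth = int(rng.integers(2, cov))
        rows.append(("Chr1", i + 1, "+", "CG", [(meth, cov), (meth, cov)]))
    return make_matrix(rows, ["a", "b"])


class TestCallDmps:
    def test_spiked_site_called_hyper(self):
        m = _null_matrix_with_spike()
        out = call_dmps(m, "a", "b")
        hit = out[out["pos"] == 10_000].iloc[0]
        assert hit["p"] == pytest.approx(2 / math.comb(24, 12), rel=1e-9)
        assert hit["q"] < 0.05 and hit["status"] == "DMP"
        assert hit["direction"] == "hyper"  # test sample more methylated

    def test_identical_samples_yield_no_dmps(self, tiny_study):
        _, matrix, _ = tiny_study
        out = call_dmps(matrix, "wildtype_1", "wildtype_1")
        assert (out.loc[out["status"] != "untested", "status"] == "NDMP").all()
        assert (out["direction"] != "none").sum() == 0

    def test_prefilter_blocks_weak_non_cg_sites(self):
        # CHH site with raw p about 0.2: never a DMP under the two-stage rule
        rows = [("Chr1", 1, "+", "CHH", [(8, 16), (13, 16)])]
        rows += [("Chr1", i + 10, "+", "CHH", [(2, 20), (18, 20)])
                 for i in range(30)]
        m = make_matrix(rows, ["a", "b"])
        out = call_dmps(m, "a", "b")
        weak = out[out["pos"] == 1].iloc[0]
        assert weak["p"] > 0.05 and weak["status"] == "NDMP"
        assert np.isnan(weak["q"])

    def test_every_site_in_exactly_one_state(self, tiny_study):
        _, matrix, _ = tiny_study
        out = call_dmps(matrix, "mutant_1", "wildtype_1")
        assert set(out["status"]) <= {"DMP", "NDMP", "untested"}
        assert len(out) == matrix.n_sites
        assert (out["status"].isin(["DMP", "NDMP"]) ==
                eligible_sites(matrix, "mutant_1", "wildtype_1")).all()

    def test_missing_policy_rejected(self):
        m = _null_matrix_with_spike()
        with pytest.raises(ValueError, match="policy"):
            call_dmps(m, "a", "b", {"CG": FdrPolicy("CG", 0.05)})

    def test_direction_follows_reference_choice(self):
        m = _null_matrix_with_spike()
        forward = call_dmps(m, "a", "b")
        reverse = call_dmps(m, "b", "a")
        assert forward[forward["pos"] == 10_000].iloc[0]["direction"] == "hyper"
        assert reverse[reverse["pos"] == 10_000].iloc[0]["direction"] == "hypo"
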