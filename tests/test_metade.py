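"""Moderated-t differential expression, Fisher combination, BH, and the
cross-study correlation analyses.

The moderated-t implementation is checked against an independent, literal
transcription of the empirical-Bayes recipe (log-variance moment matching
with digamma/trigamma, prior inversion by scipy root bracketing, posterior
variance, t on d0+d df) evaluated gene by gene.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

import panprost as pp
from panprost.metade import (
    estimate_variance_prior,
    moderated_t_table,
    posterior_variance,
    trigamma_inverse,
)


def two_group_frames(seed=0, n_genes=50, nh=6, nl=6, delta=0.0):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i}" for i in range(n_genes)], name="gene")
    sigma2 = 4 * 0.05 / rng.chisquare(4, size=n_genes)
    high = pd.DataFrame(
        delta + rng.normal(0, np.sqrt(sigma2)[:, None], (n_genes, nh)), index=genes
    )
    low = pd.DataFrame(
        rng.normal(0, np.sqrt(sigma2)[:, None], (n_genes, nl)), index=genes
    )
    return high, low


# ---------------------------------------------------------------------------
# Independent oracle: literal transcription of the moment-matching recipe


def oracle_moderated_t(high: pd.DataFrame, low: pd.DataFrame):
    logfc, s2, df, nh, nl = [], [], [], [], []
    for g in high.index:
        xh, xl = high.loc[g].to_numpy(), low.loc[g].to_numpy()
        logfc.append(xh.mean() - xl.mean())
        d = len(xh) + len(xl) - 2
        pooled = (np.sum((xh - xh.mean()) ** 2) + np.sum((xl - xl.mean()) ** 2)) / d
        s2.append(pooled)
        df.append(d)
        nh.append(len(xh))
        nl.append(len(xl))
    logfc, s2, df = np.array(logfc), np.array(s2), np.array(df, dtype=float)
    nh, nl = np.array(nh), np.array(nl)

    # moment-match log s2 to the scaled-F distribution implied by the prior
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = np.sum((e - e_mean) ** 2) / (len(e) - 1)
    excess = e_var - np.mean(special.polygamma(1, df / 2))
    if excess <= 0:
        d0, s0_2 = np.inf, np.exp(e_mean)
    else:
        # independent inversion: bracketed root of trigamma(x) - excess
        x = optimize.brentq(lambda v: special.polygamma(1, v) - excess, 1e-6, 1e8)
        d0 = 2 * x
        s0_2 = np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    t = logfc / np.sqrt(s2_post * (1 / nh + 1 / nl))
    if np.isinf(d0):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), d0 + df)
    return t, p, d0, s0_2


class TestModeratedT:
    def test_matches_literal_oracle_to_1e10(self):
        high, low = two_group_frames(seed=42)
        table, d0, s0_2 = moderated_t_table(high, low)
        t_o, p_o, d0_o, s0_o = oracle_moderated_t(high, low)
        assert d0 == pytest.approx(d0_o, abs=1e-8)
        assert s0_2 == pytest.approx(s0_o, abs=1e-10)
        np.testing.assert_allclose(table["t"].to_numpy(), t_o, atol=1e-10)
        np.testing.assert_allclose(table["p"].to_numpy(), p_o, atol=1e-10)

    def test_identical_groups_give_null_results(self):
        high, _ = two_group_frames(seed=1)
        table, _, _ = moderated_t_table(high, high.copy())
        assert np.allclose(table["logfc"], 0)
        assert np.allclose(table["t"], 0)
        assert np.allclose(table["p"], 1)

    def test_logfc_is_difference_of_group_means(self):
        genes = pd.Index(["A", "B"], name="gene")
        jitter = np.array([-0.1, 0.0, 0.1])
        high = pd.DataFrame([5.0 + jitter, 2.0 + jitter], index=genes)
        low = pd.DataFrame([3.0 + jitter, 2.0 + jitter], index=genes)
        table, _, _ = moderated_t_table(high, low)
        assert table.loc["A", "logfc"] == pytest.approx(2.0)
        assert table.loc["B", "logfc"] == pytest.approx(0.0)

    def test_posterior_variance_is_convex_combination(self):
        high, low = two_group_frames(seed=7)
        table, d0, s0_2 = moderated_t_table(high, low)
        lo = np.minimum(table["s2"], s0_2)
        hi = np.maximum(table["s2"], s0_2)
        assert ((table["s2_post"] >= lo - 1e-12) & (table["s2_post"] <= hi + 1e-12)).all()

    def test_prior_df_zero_recovers_ordinary_t(self):
        high, low = two_group_frames(seed=3)
        table, _, _ = moderated_t_table(high, low, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(high, low, axis=1)
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ref, atol=1e-10)

    def test_prior_df_infinite_gives_normal_test(self):
        high, low = two_group_frames(seed=3)
        table, d0, s0_2 = moderated_t_table(high, low, prior_df=np.inf)
        assert np.isinf(d0)
        se = np.sqrt(s0_2 * (1 / 6 + 1 / 6))
        t_ref = table["logfc"].to_numpy() / se
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(
            table["p"].to_numpy(), 2 * stats.norm.sf(np.abs(t_ref)), atol=1e-12
        )

    def test_trigamma_inverse_round_trip(self):
        for y in [1e-5, 0.01, 0.5, 2.0, 100.0, 1e6]:
            x = trigamma_inverse(y)
            assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_type_one_error_calibrated(self):
        """10,000 null genes, n=10/10, inverse-gamma variances: the fraction
        with p < 0.05 should sit in [0.04, 0.06]."""
        high, low = two_group_frames(seed=2024, n_genes=10_000, nh=10, nl=10, delta=0.0)
        table, _, _ = moderated_t_table(high, low)
        frac = float((table["p"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_study_level_wrapper(self, sim_bundles):
        studies, _ = sim_bundles
        de = pp.differential_expression(studies[0])
        assert de.d0 > 0
        assert ((de.table["p"] > 0) & (de.table["p"] <= 1)).all()
        assert (de.table["df"] == de.table["n_high"] + de.table["n_low"] - 2).all()

    def test_too_small_group_rejected(self, sim_bundles):
        studies, _ = sim_bundles
        with pytest.raises(ValueError, match=">= 2 samples"):
            pp.differential_expression(studies[0], high_label=">=8", low_label="nonexistent")


class TestFisherCombine:
    def test_all_ones(self):
        stat, p = pp.fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_k1_identity(self):
        for p_in in [0.001, 0.05, 0.5, 1.0]:
            _, p_out = pp.fisher_combine([p_in])
            assert p_out == pytest.approx(p_in, abs=1e-12)

    def test_two_p05_closed_form(self):
        stat, p = pp.fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(-4 * np.log(0.05), abs=1e-3)
        assert stat == pytest.approx(11.983, abs=1e-3)
        # chi-square with 4 df upper tail: exp(-x/2) * (1 + x/2)
        closed = np.exp(-stat / 2) * (1 + stat / 2)
        assert p == pytest.approx(closed, abs=1e-12)
        assert p == pytest.approx(0.01747, abs=5e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pp.fisher_combine([0.0, 0.5])

    @given(
        ps=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=6)
    )
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariant_and_monotone(self, ps):
        stat1, p1 = pp.fisher_combine(ps)
        stat2, p2 = pp.fisher_combine(list(reversed(ps)))
        assert stat1 == pytest.approx(stat2)
        assert p1 == pytest.approx(p2)
        smaller = list(ps)
        smaller[0] = smaller[0] / 2
        _, p3 = pp.fisher_combine(smaller)
        assert p3 <= p1 + 1e-15


class TestBH:
    def test_single_p(self):
        assert pp.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(pp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_capped_at_one(self):
        assert pp.bh_adjust([0.9, 0.95, 1.0]).max() <= 1.0

    def test_matches_brute_force_on_random_vectors(self):
        def brute_force_bh(p):
            p = np.asarray(p, dtype=float)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            running_min = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running_min = min(running_min, p[i] * n / rank)
                q[i] = running_min
            return q

        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(pp.bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestMetaDE:
    def test_mixed_sign_excluded_regardless_of_q(self):
        genes = pd.Index(["A"], name="gene")
        studies = []
        for i, sign in enumerate([+1, +1, +1, -1]):
            studies.append(
                pp.StudyDE(
                    study=f"s{i}",
                    table=pd.DataFrame(
                        {"logfc": [sign * 1.0], "p": [1e-6]}, index=genes
                    ),
                    d0=4.0,
                    s0_2=0.05,
                )
            )
        res = pp.meta_de(studies)
        assert res.table.loc["A", "sign_consistent"] == "mixed"
        assert res.up_genes == [] and res.down_genes == []

    def test_all_null_p_excluded(self):
        genes = pd.Index(["A", "B"], name="gene")
        studies = [
            pp.StudyDE(
                study=f"s{i}",
                table=pd.DataFrame({"logfc": [1.0, -1.0], "p": [1.0, 1.0]}, index=genes),
                d0=4.0,
                s0_2=0.05,
            )
            for i in range(2)
        ]
        res = pp.meta_de(studies)
        assert (res.table["q"] == 1.0).all()
        assert res.up_genes == [] and res.down_genes == []

    def test_empty_intersection_rejected(self):
        a = pp.StudyDE(
            study="a",
            table=pd.DataFrame({"logfc": [1.0], "p": [0.5]}, index=pd.Index(["A"])),
            d0=1.0, s0_2=1.0,
        )
        b = pp.StudyDE(
            study="b",
            table=pd.DataFrame({"logfc": [1.0], "p": [0.5]}, index=pd.Index(["B"])),
            d0=1.0, s0_2=1.0,
        )
        with pytest.raises(ValueError, match="intersection"):
            pp.meta_de([a, b])

    def test_planted_gene_recovery(self):
        """4 synthetic studies, 5,000 genes, 100 planted at |logFC|=1,
        n=30/30: >=90% of planted genes recovered at q<0.01 with sign
        consistency, <=1% null leakage."""
        cfg = pp.SimConfig(
            n_studies=4, n_samples=60, n_genes=5000, n_de_genes=100,
            de_logfc=1.0, grade_probs=(0.5, 0.0, 0.5), gene_overlap=1.0, seed=2,
        )
        studies, truth = pp.simulate_multistudy(cfg)
        des = [pp.differential_expression(b) for b in studies]
        res = pp.meta_de(des, q_threshold=0.01)
        planted = set(truth.de_genes_up) | set(truth.de_genes_down)
        selected = set(res.up_genes) | set(res.down_genes)
        correct_up = set(res.up_genes) & set(truth.de_genes_up)
        correct_down = set(res.down_genes) & set(truth.de_genes_down)
        assert len(correct_up) + len(correct_down) >= 90
        null_selected = selected - planted
        assert len(null_selected) <= 0.01 * (cfg.n_genes - len(planted))


class TestCorrelationAnalyses:
    def test_self_correlation_is_one(self, sim_bundles):
        studies, _ = sim_bundles
        de = pp.differential_expression(studies[0])
        r, p, n = pp.pairwise_logfc_correlation(de, de)
        assert r == pytest.approx(1.0)
        assert n == len(de.table)

    def test_hand_pearson(self):
        a = pp.StudyDE(
            study="a",
            table=pd.DataFrame({"logfc": [1.0, 2.0, 3.0], "p": [0.5] * 3},
                               index=pd.Index(["A", "B", "C"])),
            d0=1.0, s0_2=1.0,
        )
        b = pp.StudyDE(
            study="b",
            table=pd.DataFrame({"logfc": [1.0, 2.0, 4.0], "p": [0.5] * 3},
                               index=pd.Index(["A", "B", "C"])),
            d0=1.0, s0_2=1.0,
        )
        r, _, n = pp.pairwise_logfc_correlation(a, b)
        assert r == pytest.approx(0.98198, abs=1e-4)

    def test_disjoint_genes_rejected(self):
        a = pp.StudyDE(
            study="a", table=pd.DataFrame({"logfc": [1.0], "p": [0.5]}, index=pd.Index(["A"])),
            d0=1.0, s0_2=1.0,
        )
        b = pp.StudyDE(
            study="b", table=pd.DataFrame({"logfc": [1.0], "p": [0.5]}, index=pd.Index(["B"])),
            d0=1.0, s0_2=1.0,
        )
        with pytest.raises(ValueError, match="common genes"):
            pp.pairwise_logfc_correlation(a, b)

    def test_anchor_profile_extremes(self):
        df = pd.DataFrame(
            {
                "S1": [1.0, 1.0, -1.0, 5.0],
                "S2": [2.0, 2.0, -2.0, 5.0],
                "S3": [3.0, 3.0, -3.0, 5.0],
            },
            index=pd.Index(["AR", "SAME", "NEG", "CONST"], name="gene"),
        )
        prof = pp.anchor_correlation_profile(pp.ExpressionMatrix(data=df), "AR")
        assert "AR" not in prof.index
        assert prof["SAME"] == pytest.approx(1.0)
        assert prof["NEG"] == pytest.approx(-1.0)
        assert np.isnan(prof["CONST"])

    def test_anchor_absent_raises(self, tiny_expression):
        with pytest.raises(KeyError):
            pp.anchor_correlation_profile(tiny_expression, "NOPE")

    def test_cross_study_profiles(self):
        idx = pd.Index(["A", "B", "C", "D"])
        p1 = pd.Series([0.1, 0.5, -0.2, 0.9], index=idx)
        profiles = {
            "x": p1,
            "y": p1 ** 3,          # strictly monotone transform -> rho = 1
            "z": -p1,              # reversal -> rho = -1
        }
        mat = pp.cross_study_profile_correlation(profiles)
        assert np.allclose(np.diag(mat), 1.0)
        assert mat.loc["x", "y"] == pytest.approx(1.0)
        assert mat.loc["x", "z"] == pytest.approx(-1.0)
        assert mat.loc["y", "x"] == mat.loc["x", "y"]
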