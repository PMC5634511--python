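"""Three-level logit: oracle equivalences, invariances, ICC algebra,
subgroup machinery and the quartile/age-band variant.

Independent oracles used here: plain logistic regression in the collapse
limit, dense brute-force quadrature of the nested marginal likelihood on
tiny data, and lme4::glmer (via Rscript) for the Laplace objective.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logsumexp, roots_hermite

from watershed_health import model_fit as mf
from watershed_health.errors import SeparationError


def simulate_nested(seed, K=60, H=4, C=3, beta=(-1.0, 0.5, -0.3), sv=0.6, su=0.8):
    rng = np.random.default_rng(seed)
    n = K * H * C
    cl = np.repeat(np.arange(K), H * C)
    hh = np.repeat(np.arange(K * H), C)
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.normal(0, 1, n)
    v = sv * rng.standard_normal(K)
    u = su * rng.standard_normal(K * H)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2 + v[cl] + u[hh]
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {"diarrhea": y, "x1": x1, "x2": x2, "cluster_id": cl, "household_id": hh}
    )


SPEC_X1X2 = mf.ModelSpec(terms=("x1", "x2"))


def brute_force_loglik(df, beta, sv, su, n_nodes=80):
    """Dense (non-adaptive) Gauss-Hermite integration of the nested likelihood."""
    z, w = roots_hermite(n_nodes)
    lw = np.log(w)
    y = df["diarrhea"].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
    off = X @ np.asarray(beta)
    ll = 0.0
    for k, dk in df.groupby("cluster_id"):
        per_v = []
        for zv, lwv in zip(z, lw):
            v = np.sqrt(2) * sv * zv
            lp = 0.0
            for j, dj in dk.groupby("household_id"):
                rows = dj.index.to_numpy()
                etas = off[rows][None, :] + v + np.sqrt(2) * su * z[:, None]
                terms = (y[rows][None, :] * etas - np.logaddexp(0.0, etas)).sum(axis=1)
                lp += logsumexp(lw + terms) - 0.5 * np.log(np.pi)
            per_v.append(lwv + lp)
        ll += logsumexp(per_v) - 0.5 * np.log(np.pi)
    return ll


class TestLikelihoodOracles:
    @pytest.mark.parametrize(
        "sv,su", [(0.5, 0.8), (0.2, 0.4), (0.0, 0.8), (0.5, 0.0), (0.05, 1.2)]
    )
    def test_agq_converges_to_dense_quadrature(self, sv, su):
        df = simulate_nested(1, K=4, H=2, C=2)
        beta = np.array([-0.4, 0.3, -0.2])
        brute = brute_force_loglik(df, beta, sv, su)
        default = mf.evaluate_loglik(df, SPEC_X1X2, beta, sv, su, method="agq", n_quad=5)
        coarse = mf.evaluate_loglik(df, SPEC_X1X2, beta, sv, su, method="agq", n_quad=7)
        fine = mf.evaluate_loglik(df, SPEC_X1X2, beta, sv, su, method="agq", n_quad=21)
        assert default == pytest.approx(brute, abs=5e-3)
        assert coarse == pytest.approx(brute, abs=1e-3)
        assert fine == pytest.approx(brute, abs=1e-7)
        assert abs(fine - brute) <= abs(coarse - brute) + 1e-12

    def test_collapse_limit_matches_plain_logistic(self):
        # singleton households and clusters with pinned zero variances:
        # the marginal model IS ordinary logistic regression
        rng = np.random.default_rng(2)
        n = 800
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(-1.0 + 0.6 * x1 - 0.4 * x2)).astype(int)
        df = pd.DataFrame(
            {
                "diarrhea": y,
                "x1": x1,
                "x2": x2,
                "cluster_id": np.arange(n),
                "household_id": np.arange(n),
            }
        )
        spec = mf.ModelSpec(terms=("x1", "x2"), fix_sigma_cluster=0.0, fix_sigma_household=0.0)
        fit = mf.fit_three_level_logit(df, spec)
        ref = sm.Logit(y, np.column_stack([np.ones(n), x1, x2])).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-4)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=2e-2)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_laplace_matches_glmer(self, tmp_path):
        df = simulate_nested(7)
        csv = tmp_path / "nested.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(diarrhea ~ x1 + x2 + (1|cluster_id) + (1|household_id),
                       data = d, family = binomial, nAGQ = 1)
            cat(fixef(m), sqrt(unlist(VarCorr(m)))[["household_id"]],
                sqrt(unlist(VarCorr(m)))[["cluster_id"]], logLik(m), sep = "\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, b2, su_r, sv_r, ll_r = map(float, out.stdout.split())
        fit = mf.fit_three_level_logit(df, SPEC_X1X2, method="laplace")
        np.testing.assert_allclose(fit.beta, [b0, b1, b2], atol=1e-2)
        assert fit.sigma_household == pytest.approx(su_r, abs=2e-2)
        assert fit.sigma_cluster == pytest.approx(sv_r, abs=2e-2)
        assert fit.loglik == pytest.approx(ll_r, abs=5e-2)

    def test_optimum_beats_generating_parameters(self):
        df = simulate_nested(3)
        fit = mf.fit_three_level_logit(df, SPEC_X1X2)
        ll_true = mf.evaluate_loglik(
            df, SPEC_X1X2, np.array([-1.0, 0.5, -0.3]), 0.6, 0.8, method="agq"
        )
        assert fit.loglik >= ll_true - 1e-6


class TestInvariances:
    def test_row_permutation(self):
        df = simulate_nested(4)
        fit1 = mf.fit_three_level_logit(df, SPEC_X1X2)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit2 = mf.fit_three_level_logit(shuffled, SPEC_X1X2)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-6)
        assert fit1.sigma_household == pytest.approx(fit2.sigma_household, abs=1e-5)

    def test_id_relabeling(self):
        df = simulate_nested(4)
        fit1 = mf.fit_three_level_logit(df, SPEC_X1X2)
        relabeled = df.assign(
            cluster_id=df["cluster_id"].map(lambda k: f"CL-{997 - k}"),
            household_id=df["household_id"].map(lambda j: f"HH-{5000 - j}"),
        )
        fit2 = mf.fit_three_level_logit(relabeled, SPEC_X1X2)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-6)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)


class TestErrors:
    def test_single_class_outcome(self):
        df = simulate_nested(5)
        df["diarrhea"] = 0
        with pytest.raises(ValueError, match="both classes"):
            mf.fit_three_level_logit(df, SPEC_X1X2)

    def test_complete_separation(self):
        df = simulate_nested(5)
        df["diarrhea"] = (df["x1"] > 0).astype(int)
        with pytest.raises(SeparationError):
            mf.fit_three_level_logit(df, mf.ModelSpec(terms=("x1",)))

    def test_household_across_clusters_rejected(self):
        df = simulate_nested(5)
        df.loc[df.index[-1], "household_id"] = 0
        with pytest.raises(ValueError, match="more than one cluster"):
            mf.fit_three_level_logit(df, SPEC_X1X2)


class TestIcc:
    def _fit_with(self, sv, su):
        return mf.FitResult(
            names=["intercept"],
            beta=np.zeros(1),
            se=np.zeros(1),
            cov_beta=np.zeros((1, 1)),
            sigma_cluster=sv,
            sigma_household=su,
            loglik=0.0,
            n_children=0,
            n_households=0,
            n_clusters=0,
            converged=True,
            n_iter=0,
            message="",
        )

    def test_zero_variances(self):
        assert mf.icc(self._fit_with(0.0, 0.0)) == (0.0, 0.0)

    def test_cluster_half_when_variance_equals_logistic_residual(self):
        sv = np.pi / np.sqrt(3)
        icc_cl, icc_hh = mf.icc(self._fit_with(sv, 0.0))
        assert icc_cl == pytest.approx(0.5)
        assert icc_hh == pytest.approx(0.5)  # cumulative includes the cluster part

    def test_cumulative_vs_plain_convention(self):
        fit = self._fit_with(0.5, 0.9)
        denom = 0.25 + 0.81 + np.pi**2 / 3
        assert mf.icc(fit) == pytest.approx((0.25 / denom, (0.25 + 0.81) / denom))
        assert mf.icc(fit, cumulative=False)[1] == pytest.approx(0.81 / denom)


class TestSubgroups:
    def test_partition_of_rows(self):
        df = simulate_nested(6, K=40)
        res = mf.subgroup_fit(df, SPEC_X1X2, by="x1")
        assert res["0"].n_children + res["1"].n_children == len(df)

    def test_constant_split_column_errors(self):
        df = simulate_nested(6, K=20)
        df["always"] = 1
        with pytest.raises(ValueError, match="empty"):
            mf.subgroup_fit(df, SPEC_X1X2, by="always")

    def test_high_low_split_uses_subset_mean(self):
        df = simulate_nested(6, K=20)
        df["human_index"] = np.repeat(np.arange(20.0), len(df) // 20)
        mask = mf.split_high_low(df, "human_index")
        assert mask.equals(df["human_index"] > df["human_index"].mean())

    def test_nonbinary_column_rejected(self):
        df = simulate_nested(6, K=20)
        with pytest.raises(ValueError, match="not binary"):
            mf.subgroup_fit(df, SPEC_X1X2, by="x2")


class TestQuartileVariant:
    def test_uniform_tree_cover_cut_points(self):
        tree = np.linspace(0.0, 100.0, 4001)
        cols, names = mf._tree_quartile_dummies(tree)
        assert names == ["tree_q2", "tree_q3", "tree_q4"]
        # equal quarters under a uniform distribution
        np.testing.assert_allclose(cols.mean(axis=0), [0.25, 0.25, 0.25], atol=0.01)
        # boundaries: quartile bins are lower-inclusive
        q = np.quantile(tree, [0.25, 0.5, 0.75])
        exact = mf._tree_quartile_dummies(np.array([q[0], q[1], q[2], 0.0]))[0]
        np.testing.assert_array_equal(exact[0], [1, 0, 0])
        np.testing.assert_array_equal(exact[3], [0, 0, 0])

    def test_first_year_ages_are_reference_band(self):
        cols, _ = mf._age_band_dummies(np.arange(0, 12))
        assert cols.sum() == 0

    def test_degenerate_quartiles_rejected(self):
        df = simulate_nested(8, K=20)
        df["tree_index"] = 5.0
        df["age"] = 10
        with pytest.raises(ValueError):
            mf.quartile_variant_fit(df)

    def test_monotone_tree_effect_orders_quartile_odds(self):
        # strong protective tree effect; Q4 odds ratio must sit below 1
        # and below Q2's
        rng = np.random.default_rng(9)
        K, H, C = 300, 4, 2
        n = K * H * C
        cl = np.repeat(np.arange(K), H * C)
        hh = np.repeat(np.arange(K * H), C)
        tree = np.repeat(rng.uniform(0, 100, K), H * C)
        age = rng.integers(0, 60, n)
        eta = -0.8 - 0.025 * tree
        y = (rng.random(n) < expit(eta)).astype(int)
        df = pd.DataFrame(
            {
                "diarrhea": y,
                "age": age,
                "tree_index": tree,
                "cluster_id": cl,
                "household_id": hh,
            }
        )
        fit = mf.quartile_variant_fit(df, mf.ModelSpec(terms=("age", "tree_index")))
        ors = fit.odds_ratios()
        assert ors.loc["tree_q4", "odds_ratio"] < 1.0
        assert ors.loc["tree_q4", "odds_ratio"] < ors.loc["tree_q2", "odds_ratio"]
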