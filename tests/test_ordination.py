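import numpy as np
import pandas as pd
import pytest

from stemspat import (
    EnvDesign,
    anova_cca,
    backward_select,
    compare_with_without,
    fit_cca,
    variance_decomposition,
)


def brute_force_cca_eigenvalues(Y, X):
    """Independent dense-matrix evaluation: explicit hat matrix of the
    weighted design and eigen-decomposition of the projected cross-product."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    tot = Y.sum()
    P = Y / tot
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    Xw = np.sqrt(r)[:, None] * Xc
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    Qhat = H @ Q
    ev = np.linalg.eigvalsh(Qhat @ Qhat.T)[::-1]
    return ev[ev > 1e-12]


@pytest.fixture
def random_community(rng):
    Y = pd.DataFrame(
        rng.poisson(4, size=(20, 8)).astype(float),
        columns=[f"sp{j}" for j in range(8)],
    )
    X = pd.DataFrame(
        {
            "altitude": rng.normal(450, 10, 20),
            "dist_water": rng.uniform(0, 500, 20),
            "topo": rng.choice(["flat", "slope", "crest"], 20),
        }
    )
    return Y, X


class TestEnvDesign:
    def test_categorical_expansion_uses_flat_reference(self):
        env = pd.DataFrame(
            {"slope": [1.0, 2.0, 3.0, 4.0], "topo": ["flat", "slope", "crest", "shallow"]}
        )
        design = EnvDesign(env)
        assert design.terms == ["slope", "topo"]
        assert len(design.term_columns["topo"]) == 3  # 4 levels -> df 3
        assert "topo[flat]" not in design.columns

    def test_drop_term(self):
        env = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
        reduced = EnvDesign(env).drop("a")
        assert reduced.terms == ["b"]
        with pytest.raises(KeyError):
            EnvDesign(env).drop("zzz")


class TestFitCca:
    def test_inertia_conservation(self, random_community):
        Y, X = random_community
        m = fit_cca(Y, X)
        assert m.constrained_inertia_ + m.unconstrained_inertia_ == pytest.approx(
            m.total_inertia_, abs=1e-8
        )
        assert 0 <= m.proportion_constrained_ <= 1
        assert np.all(m.eigenvalues_ >= -1e-12)

    def test_toy_table_matches_brute_force(self):
        Y = pd.DataFrame(
            [[4.0, 1.0, 0.0], [2.0, 3.0, 1.0], [0.0, 2.0, 5.0], [1.0, 1.0, 3.0]]
        )
        X = pd.DataFrame({"grad": [0.0, 1.0, 2.0, 3.0]})
        m = fit_cca(Y, X)
        expected = brute_force_cca_eigenvalues(Y, X)
        np.testing.assert_allclose(
            m.eigenvalues_[: m.n_constrained_], expected, atol=1e-8
        )

    def test_matches_reference_implementation(self, random_community):
        """Cross-check eigenvalues and the constrained proportion against the
        independent scikit-bio implementation."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        Y, X = random_community
        design = EnvDesign(X)
        m = fit_cca(Y, design)
        ref = skbio_ord.cca(Y, pd.DataFrame(design.matrix, columns=design.columns))
        k = m.n_constrained_
        np.testing.assert_allclose(
            m.eigenvalues_[:k], ref.eigvals.values[:k], atol=1e-10
        )
        np.testing.assert_allclose(
            m.proportion_constrained_,
            ref.proportion_explained.values[:k].sum(),
            atol=1e-10,
        )

    def test_constant_predictor_explains_nothing(self, random_community):
        Y, _ = random_community
        m = fit_cca(Y, pd.DataFrame({"c": np.ones(len(Y))}))
        assert m.constrained_inertia_ == pytest.approx(0.0, abs=1e-12)
        assert m.proportion_constrained_ == 0.0

    def test_saturated_design_reproduces_plain_ca(self, rng):
        Y = pd.DataFrame(rng.poisson(5, size=(8, 5)).astype(float))
        X = pd.DataFrame(rng.normal(size=(8, 7)))  # full column rank n-1
        m = fit_cca(Y, X)
        assert m.proportion_constrained_ == pytest.approx(1.0, abs=1e-10)
        # CA eigenvalues = SVD of Qbar itself
        ca_ev = np.linalg.svd(m._Qbar, compute_uv=False) ** 2
        np.testing.assert_allclose(
            m.eigenvalues_[: m.n_constrained_], ca_ev[: m.n_constrained_], atol=1e-10
        )

    def test_scores_recover_eigenvalues(self, random_community):
        Y, X = random_community
        m = fit_cca(Y, X)
        k = m.n_constrained_
        site_w = np.sqrt(m.row_weights_)[:, None] * m.site_scores_
        spec_w = np.sqrt(m.col_weights_)[:, None] * m.species_scores_
        lam = site_w.T @ m._Qbar @ spec_w
        np.testing.assert_allclose(lam, np.diag(m.eigenvalues_[:k]), atol=1e-8)

    def test_zero_rows_dropped_with_count(self, random_community):
        Y, X = random_community
        Y2 = Y.copy()
        Y2.iloc[3] = 0.0
        m = fit_cca(Y2, X)
        assert m.n_dropped_sites_ == 1
        assert m.n_sites_ == len(Y) - 1

    def test_collinear_predictors_warn(self, random_community):
        Y, X = random_community
        X2 = X.assign(alt2=X["altitude"] * 2.0)
        with pytest.warns(UserWarning, match="collinear"):
            m = fit_cca(Y, X2)
        assert m.rank_ < len(EnvDesign(X2).columns)


class TestAnova:
    def test_joint_relabeling_invariance(self, random_community):
        """Permuting Y and X rows with the same permutation leaves the
        pseudo-F (inertia decomposition) unchanged."""
        Y, X = random_community
        m1 = fit_cca(Y, X)
        perm = np.random.default_rng(4).permutation(len(Y))
        m2 = fit_cca(Y.iloc[perm].reset_index(drop=True), X.iloc[perm].reset_index(drop=True))
        assert m1.constrained_inertia_ == pytest.approx(m2.constrained_inertia_, rel=1e-10)
        assert m1.total_inertia_ == pytest.approx(m2.total_inertia_, rel=1e-10)

    def test_null_pvalues_roughly_uniform(self, rng):
        """With X independent of Y the model p-value has ~uniform mean."""
        ps = []
        for s in range(40):
            r = np.random.default_rng(s)
            Y = pd.DataFrame(r.poisson(4, size=(15, 6)).astype(float))
            X = pd.DataFrame({"a": r.normal(size=15)})
            ps.append(anova_cca(fit_cca(Y, X), n_perm=99, seed=s)["p_perm"][0])
        assert 0.3 < np.mean(ps) < 0.7
        assert min(ps) < 0.3 and max(ps) > 0.7

    def test_strong_gradient_detected(self, rng):
        """A built-in abundance gradient gives a small marginal p."""
        grad = np.linspace(0, 1, 24)
        Y = pd.DataFrame(
            {
                "lover": rng.poisson(2 + 30 * grad),
                "hater": rng.poisson(2 + 30 * (1 - grad)),
                "neutral": rng.poisson(10, 24),
            }
        ).astype(float)
        X = pd.DataFrame({"grad": grad, "noise": rng.normal(size=24)})
        tab = anova_cca(fit_cca(Y, X), n_perm=199, seed=0, scope="margin")
        p_grad = tab.set_index("term").loc["grad", "p_perm"]
        assert p_grad <= 0.01

    def test_axes_scope_reports_each_axis(self, random_community):
        Y, X = random_community
        tab = anova_cca(fit_cca(Y, X), n_perm=99, seed=1, scope="axes")
        m = fit_cca(Y, X)
        assert len(tab) == m.n_constrained_
        assert tab["chi_square"].iloc[0] == pytest.approx(m.eigenvalues_[0])

    def test_reproducible_under_seed(self, random_community):
        Y, X = random_community
        m = fit_cca(Y, X)
        t1 = anova_cca(m, n_perm=99, seed=42, scope="margin")
        t2 = anova_cca(m, n_perm=99, seed=42, scope="margin")
        pd.testing.assert_frame_equal(t1, t2)


class TestBackwardSelect:
    def test_pure_noise_terms_mostly_eliminated(self):
        """Predictors independent of the community are usually pruned; the
        AIC penalty of 2 per df keeps a noise term at the usual AIC
        false-inclusion rate, so intercept-only is the modal outcome but
        not a near-certain one."""
        wins = 0
        kept = 0
        reps = 20
        for s in range(reps):
            r = np.random.default_rng(1000 + s)
            Y = pd.DataFrame(r.poisson(5, size=(30, 6)).astype(float))
            X = pd.DataFrame(r.normal(size=(30, 3)), columns=["n1", "n2", "n3"])
            final, _ = backward_select(Y, X)
            wins += len(final.design_.terms) == 0
            kept += len(final.design_.terms)
        assert wins >= reps / 2
        assert kept / reps < 1.0  # on average fewer than 1 of 3 noise terms survive

    def test_true_driver_retained(self, rng):
        grad = np.linspace(0, 1, 30)
        Y = pd.DataFrame(
            {
                "lover": rng.poisson(1 + 40 * grad),
                "hater": rng.poisson(1 + 40 * (1 - grad)),
                "bg": rng.poisson(8, 30),
            }
        ).astype(float)
        X = pd.DataFrame({"grad": grad, "noise": rng.normal(size=30)})
        final, trace = backward_select(Y, X)
        assert "grad" in final.design_.terms
        assert trace["aic"].is_monotonic_decreasing

    def test_single_term_trace_short(self, random_community):
        Y, _ = random_community
        X = pd.DataFrame({"a": np.random.default_rng(0).normal(size=len(Y))})
        final, trace = backward_select(Y, X)
        assert len(trace) <= 2


class TestVarianceDecomposition:
    def test_single_predictor_share_is_100(self, random_community):
        Y, X = random_community
        m = fit_cca(Y, X[["altitude"]])
        out = variance_decomposition(m)
        assert out["share_pct"].iloc[0] == pytest.approx(100.0)

    def test_orthogonal_predictors_sum_to_total(self, rng):
        """With orthogonal (weighted-centred) predictors marginal shares add
        to the full constrained inertia."""
        n = 16
        Y = pd.DataFrame(np.full((n, 4), 5.0))  # uniform masses
        Y += pd.DataFrame(rng.poisson(2, size=(n, 4)).astype(float))
        # equal row sums => weights equal; build exactly orthogonal contrasts
        Y.iloc[:, :] = 5.0
        Y.iloc[: n // 2, 0] = 7.0
        Y.iloc[n // 2 :, 1] = 7.0
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        m = fit_cca(Y, pd.DataFrame({"a": a, "b": b}))
        out = variance_decomposition(m)
        assert out["chi_square"].sum() == pytest.approx(m.constrained_inertia_, abs=1e-10)
        assert out["share_normalized_pct"].sum() == pytest.approx(100.0)


class TestCompareWithWithout:
    def test_redundant_focal_changes_nothing(self, rng):
        Y = pd.DataFrame(rng.poisson(5, size=(15, 4)).astype(float))
        Y["twin"] = Y[0]  # exact copy of another column
        X = pd.DataFrame({"a": rng.normal(size=15)})
        res = compare_with_without(Y, X, focal="twin")
        assert abs(res["delta_proportion"]) < 0.02

    def test_water_tied_focal_drives_association(self, rng):
        dist = np.linspace(0, 600, 24)
        Y = pd.DataFrame(
            {
                "water_lover": rng.poisson(30 * np.exp(-dist / 120)),
                "bg1": rng.poisson(5, 24),
                "bg2": rng.poisson(5, 24),
            }
        ).astype(float)
        X = pd.DataFrame({"dist_water": dist})
        res = compare_with_without(Y, X, focal="water_lover")
        assert res["proportion_with"] > res["proportion_without"]

    def test_unknown_focal_raises(self, random_community):
        Y, X = random_community
        with pytest.raises(KeyError, match="nope"):
            compare_with_without(Y, X, focal="nope")
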