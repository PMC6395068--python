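import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from factorde import linmod, simulate
from factorde.linmod import SignificanceCriteria
from factorde.types import ExpressionMatrix, SampleDesign, ValidationError


def normal_equations_oracle(X, y):
    """Explicit (X'X)^-1 X'y with textbook t-test p values, one gene."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    p = 2 * sps.t.sf(np.abs(beta / se), dof)
    return beta, p


def make_expr(design: SampleDesign, gene_values: dict[str, np.ndarray]):
    return ExpressionMatrix(
        list(gene_values),
        list(design.sample_ids),
        np.vstack(list(gene_values.values())),
    )


class TestEncodeDesign:
    def test_coding(self, small_design):
        X, names = linmod.encode_design(small_design)
        assert names == ["intercept", "exposure", "genotype", "sex"]
        for i, s in enumerate(small_design.sample_ids):
            assert X[i, 1] == (1.0 if small_design.exposure[i] == "smoke" else 0.0)
            assert X[i, 2] == (1.0 if small_design.genotype[i] == "bENaC" else 0.0)
            assert X[i, 3] == (1.0 if small_design.sex[i] == "male" else 0.0)

    def test_balanced_orthogonal_after_centering(self, small_design):
        X, _ = linmod.encode_design(small_design)
        C = X[:, 1:] - X[:, 1:].mean(axis=0)
        off = C.T @ C - np.diag(np.diag(C.T @ C))
        np.testing.assert_allclose(off, 0, atol=1e-12)

    def test_single_level_factor_named_in_error(self):
        d = SampleDesign(
            ["a", "b", "c", "d"],
            ["sham"] * 4,
            ["WT", "WT", "bENaC", "bENaC"],
            ["female", "male", "female", "male"],
            [1, 1, 1, 1],
        )
        with pytest.raises(ValidationError, match="exposure"):
            linmod.encode_design(d)

    def test_mixed_duration_rejected(self, both_durations_design):
        with pytest.raises(ValidationError, match="duration"):
            linmod.encode_design(both_durations_design)


class TestFitGeneModels:
    def test_zero_noise_exact_beta(self, small_design):
        x_exp = np.array(
            [1.0 if e == "smoke" else 0.0 for e in small_design.exposure]
        )
        expr = make_expr(small_design, {"gA": 7.0 + 1.5 * x_exp})
        eff = linmod.fit_gene_models(expr, small_design)
        assert eff.loc["gA", "beta_exposure"] == pytest.approx(1.5, abs=1e-12)
        assert eff.loc["gA", "beta_genotype"] == pytest.approx(0.0, abs=1e-10)
        assert eff.loc["gA", "beta_sex"] == pytest.approx(0.0, abs=1e-10)
        assert eff.loc["gA", "p_exposure"] == 0.0
        assert eff.loc["gA", "p_genotype"] == 1.0

    def test_constant_gene_degenerate_convention(self, small_design):
        expr = make_expr(
            small_design, {"gA": np.full(small_design.n_samples, 5.0)}
        )
        eff = linmod.fit_gene_models(expr, small_design)
        for f in ("exposure", "genotype", "sex"):
            assert eff.loc["gA", f"beta_{f}"] == pytest.approx(0.0, abs=1e-10)
            assert eff.loc["gA", f"p_{f}"] == 1.0

    def test_matches_normal_equations_oracle(self, noisy_dataset, small_design):
        eff = linmod.fit_gene_models(noisy_dataset, small_design)
        X, names = linmod.encode_design(small_design)
        for gi, gene in enumerate(noisy_dataset.gene_ids):
            beta, p = normal_equations_oracle(X, noisy_dataset.values[gi])
            for j, f in enumerate(names[1:], start=1):
                assert eff.loc[gene, f"beta_{f}"] == pytest.approx(
                    beta[j], abs=1e-9
                )
                assert eff.loc[gene, f"p_{f}"] == pytest.approx(p[j], abs=1e-9)

    def test_q_dominates_p(self, noisy_dataset, small_design):
        eff = linmod.fit_gene_models(noisy_dataset, small_design)
        for f in ("exposure", "genotype", "sex"):
            assert (eff[f"q_{f}"] >= eff[f"p_{f}"] - 1e-15).all()

    def test_gene_order_invariance(self, noisy_dataset, small_design, rng):
        perm = list(rng.permutation(noisy_dataset.gene_ids))
        a = linmod.fit_gene_models(noisy_dataset, small_design)
        b = linmod.fit_gene_models(
            noisy_dataset.subset_genes(perm), small_design
        )
        pd.testing.assert_frame_equal(a.loc[perm], b)

    def test_sample_order_invariance(self, noisy_dataset, small_design, rng):
        order = list(rng.permutation(small_design.sample_ids))
        a = linmod.fit_gene_models(noisy_dataset, small_design)
        b = linmod.fit_gene_models(
            noisy_dataset.subset_samples(order), small_design
        )
        pd.testing.assert_frame_equal(a, b)

    def test_adding_constant_shifts_only_intercept(
        self, noisy_dataset, small_design
    ):
        a = linmod.fit_gene_models(noisy_dataset, small_design)
        shifted = noisy_dataset.values.copy()
        shifted[3] += 2.5
        em = ExpressionMatrix(
            list(noisy_dataset.gene_ids), list(noisy_dataset.sample_ids), shifted
        )
        b = linmod.fit_gene_models(em, small_design)
        gene = noisy_dataset.gene_ids[3]
        assert b.loc[gene, "intercept"] - a.loc[gene, "intercept"] == pytest.approx(
            2.5, abs=1e-9
        )
        cols = [c for c in a.columns if c != "intercept"]
        pd.testing.assert_frame_equal(a[cols], b[cols])

    def test_too_few_samples(self):
        d = SampleDesign(
            ["a", "b", "c", "d"],
            ["sham", "smoke", "sham", "smoke"],
            ["WT", "WT", "bENaC", "bENaC"],
            ["female", "male", "male", "female"],
            [1] * 4,
        )
        expr = make_expr(d, {"g": np.arange(4.0)})
        with pytest.raises(ValidationError):
            linmod.fit_gene_models(expr, d)


class TestCallResponseGenes:
    def _table(self):
        return pd.DataFrame(
            {
                "beta_exposure": [0.50, 0.30, -1.2, -0.8],
                "q_exposure": [0.01, 0.001, 0.20, 0.04],
                "significant_exposure": [True, False, False, True],
            },
            index=pd.Index(["gUp", "gSmallBeta", "gBigQ", "gDown"], name="gene_id"),
        )

    def test_threshold_semantics(self):
        out = linmod.call_response_genes(self._table(), "exposure")
        assert set(out.index) == {"gUp", "gDown"}
        assert out.loc["gUp", "direction"] == "up"
        assert out.loc["gDown", "direction"] == "down"

    def test_ordering_by_abs_beta_then_id(self):
        out = linmod.call_response_genes(self._table(), "exposure")
        assert list(out.index) == ["gDown", "gUp"]

    def test_unknown_factor(self):
        with pytest.raises(KeyError):
            linmod.call_response_genes(self._table(), "duration")

    def test_significance_flag_definition(self, small_design, rng):
        """significant <=> q < thr and |beta| > log2(fc)."""
        values = rng.normal(8, 1, size=(40, small_design.n_samples))
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(40)], list(small_design.sample_ids), values
        )
        crit = SignificanceCriteria(q_threshold=0.5, fold_change_threshold=1.2)
        eff = linmod.fit_gene_models(expr, small_design, crit)
        for f in ("exposure", "genotype", "sex"):
            expected = (eff[f"q_{f}"] < 0.5) & (
                eff[f"beta_{f}"].abs() > np.log2(1.2)
            )
            assert (eff[f"significant_{f}"] == expected).all()


class TestInteractionModels:
    def _zero_noise_both(self, effect_day1, effect_day5):
        design = simulate.generate_design(2, durations=(1, 5))
        x_exp = np.array([1.0 if e == "smoke" else 0.0 for e in design.exposure])
        x_d5 = np.array([1.0 if d == 5 else 0.0 for d in design.duration_days])
        y = 6.0 + effect_day1 * x_exp * (1 - x_d5) + effect_day5 * x_exp * x_d5
        expr = ExpressionMatrix(["gA"], list(design.sample_ids), y[None, :])
        return expr, design

    def test_identical_effect_zero_interaction(self):
        expr, design = self._zero_noise_both(1.0, 1.0)
        t = linmod.fit_interaction_models(expr, design, ["gA"])
        assert t.loc["gA", "beta_interaction"] == pytest.approx(0.0, abs=1e-10)

    def test_sign_flip_coding_arithmetic(self):
        expr, design = self._zero_noise_both(1.0, -1.0)
        t = linmod.fit_interaction_models(expr, design, ["gA"])
        assert t.loc["gA", "beta_interaction"] == pytest.approx(-2.0, abs=1e-10)
        assert t.loc["gA", "beta_exposure"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_oracle_on_noisy_gene(self, rng):
        design = simulate.generate_design(3, durations=(1, 5))
        y = rng.normal(7, 1, size=design.n_samples)
        expr = ExpressionMatrix(["gA"], list(design.sample_ids), y[None, :])
        t = linmod.fit_interaction_models(expr, design, ["gA"])
        x_exp = np.array([1.0 if e == "smoke" else 0.0 for e in design.exposure])
        x_d5 = np.array([1.0 if d == 5 else 0.0 for d in design.duration_days])
        X = np.column_stack([np.ones(len(y)), x_exp, x_d5, x_exp * x_d5])
        beta, p = normal_equations_oracle(X, y)
        assert t.loc["gA", "beta_interaction"] == pytest.approx(beta[3], abs=1e-9)
        assert t.loc["gA", "p_interaction"] == pytest.approx(p[3], abs=1e-9)

    def test_absent_gene_named(self):
        expr, design = self._zero_noise_both(1.0, 1.0)
        with pytest.raises(KeyError, match="gMissing"):
            linmod.fit_interaction_models(expr, design, ["gMissing"])

    def test_q_over_listed_genes_only(self, rng):
        design = simulate.generate_design(3, durations=(1, 5))
        values = rng.normal(7, 1, size=(20, design.n_samples))
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(20)], list(design.sample_ids), values
        )
        sub = linmod.fit_interaction_models(expr, design, ["g0", "g1", "g2"])
        assert len(sub) == 3
        from factorde.stats import bh_adjust

        np.testing.assert_allclose(
            sub["q_interaction"], bh_adjust(sub["p_interaction"]), atol=1e-12
        )


class TestFoldChange:
    def test_paper_pairing(self):
        assert linmod.fold_change_to_beta(1.3) == pytest.approx(0.379, abs=5e-4)

    def test_exact_values(self):
        assert linmod.fold_change_to_beta(2.0) == pytest.approx(1.0)
        assert linmod.fold_change_to_beta(1.0) == pytest.approx(0.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            linmod.fold_change_to_beta(0.0)


def test_zero_noise_recovers_all_truth_betas():
    """Balanced zero-noise data: every estimated beta equals its truth."""
    design = simulate.generate_design(2, durations=(1,))
    expr, truth = simulate.generate_expression(
        design, 200, affected_fraction=0.2, noise_sd=0.0, seed=11
    )
    eff = linmod.fit_gene_models(expr, design)
    for f in ("exposure", "genotype", "sex"):
        np.testing.assert_allclose(
            eff[f"beta_{f}"].to_numpy(),
            truth.genes[f"beta_{f}"].to_numpy(),
            atol=1e-9,
        )
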