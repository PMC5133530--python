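"""Design construction, likelihood correctness, ML fitting, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from pedscan import (
    ModelSpec,
    SimSpec,
    TraitTable,
    build_design,
    prepare_model_data,
    loglikelihood,
    fit_null,
    pedigree_outlier_report,
    theoretical_kinship,
    simulate_study,
)
from pedscan.vcmodel import NonIdentifiableWarning

from conftest import ped_from


def _table(ped, traits, trait_names, covs=None, cov_names=()):
    n = ped.n
    covs = covs if covs is not None else np.zeros((n, 0))
    return TraitTable(
        ids=ped.person_id.copy(),
        trait_names=list(trait_names),
        traits=np.asarray(traits, dtype=float),
        covariate_names=list(cov_names),
        covariates=np.asarray(covs, dtype=float),
    )


class TestBuildDesign:
    @pytest.fixture()
    def table3(self, trio):
        covs = np.array([[1.0], [2.0], [3.0]])
        return _table(
            trio, np.ones((3, 3)), ["Y_1", "Y_2", "Y_3"], covs, ["x"]
        )

    def test_constrained_covariate_single_coefficient(self, table3):
        spec = ModelSpec.longitudinal(
            ("Y_1", "Y_2", "Y_3"), terms=("x",),
            trait_groups={"Y": ["Y_1", "Y_2", "Y_3"]},
        )
        info = build_design(spec, table3)
        assert info.n_coef == 1
        assert np.all(info.cell_coef == 0)

    def test_unconstrained_covariate_three_coefficients(self, table3):
        spec = ModelSpec(traits=("Y_1", "Y_2", "Y_3"), terms=("x",))
        info = build_design(spec, table3)
        assert info.n_coef == 3

    def test_constraint_reduces_free_coefficients_by_group_sizes(self, table3):
        free = build_design(
            ModelSpec(traits=("Y_1", "Y_2", "Y_3"), terms=("1", "x")), table3
        ).n_coef
        spec = ModelSpec(
            traits=("Y_1", "Y_2", "Y_3"),
            terms=("1", "x"),
            constraints=((("x", "Y_1"), ("x", "Y_2"), ("x", "Y_3")),),
        )
        constrained = build_design(spec, table3).n_coef
        assert free - constrained == 3 - 1

    def test_constrained_column_is_sum_of_member_columns(self, trio):
        covs = np.array([[1.0], [2.0], [3.0]])
        table = _table(trio, np.ones((3, 2)), ["Y_1", "Y_2"], covs, ["x"])
        spec = ModelSpec(
            traits=("Y_1", "Y_2"),
            terms=("x",),
            constraints=((("x", "Y_1"), ("x", "Y_2")),),
            components=("environmental",),
        )
        data = prepare_model_data(spec, trio, table, {})
        A = np.vstack([b.A for b in data.blocks])
        # trait-major cells: each individual appears once per trait, and the
        # single constrained column carries x in both slots
        assert A.shape == (6, 1)
        assert sorted(A[:, 0]) == [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]

    def test_interaction_and_unknown_covariate(self, trio):
        covs = np.array([[1.0, 2.0], [2.0, 1.0], [0.0, 5.0]])
        table = _table(trio, np.ones((3, 1)), ["Y"], covs, ["a", "b"])
        info = build_design(ModelSpec(traits=("Y",), terms=("a*b",)), table)
        assert np.allclose(info.term_values[:, 0], [2.0, 2.0, 0.0])
        with pytest.raises(ValueError, match="unknown covariate"):
            build_design(ModelSpec(traits=("Y",), terms=("zz",)), table)

    def test_mean_structure_one_estimate_per_covariate_per_trait_group(self):
        # 2 trait groups x 4 time points, 3 covariate terms + intercept:
        # the longitudinal constraint yields one coefficient per term per group
        ped = ped_from([(f"i{k}", None, None, "male", None) for k in range(3)])
        names = [f"{g}_{t}" for g in ("SBP", "DBP") for t in range(1, 5)]
        covs = np.arange(9.0).reshape(3, 3)
        table = _table(ped, np.ones((3, 8)), names, covs, ["sex", "age", "smoke"])
        spec = ModelSpec.longitudinal(
            tuple(names), terms=("1", "sex", "age", "smoke", "sex*age")
        )
        info = build_design(spec, table)
        assert info.n_coef == 5 * 2


class TestLoglikelihood:
    def test_standard_normal_at_its_mean(self):
        ped = ped_from([("a", None, None, "male", None)])
        table = _table(ped, [[5.0]], ["Y"])
        spec = ModelSpec(traits=("Y",), terms=("1",), components=("environmental",))
        data = prepare_model_data(spec, ped, table, {})
        ll = loglikelihood(np.array([5.0]), {"environmental": [[1.0]]}, data)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("T,seed", [(1, 0), (2, 1), (3, 2)])
    def test_matches_dense_mvn_oracle(self, T, seed):
        """Assembled per-pedigree likelihood equals a generic multivariate
        normal log-density, including missing-trait marginalization."""
        rng = np.random.default_rng(seed)
        traits = tuple(f"Y{t}" for t in range(T))
        A = rng.standard_normal((T, T))
        spec_sim = SimSpec(
            n_pedigrees=3,
            sibship_range=(2, 3),
            n_snps=2,
            traits=traits,
            beta={"1": rng.normal(0, 1, T)},
            components={
                "additive": A @ A.T + np.eye(T),
                "environmental": np.eye(T) * 2.0,
            },
            trait_missing=0.2,
            seed=seed,
        )
        ped, geno, table = simulate_study(spec_sim)
        spec = ModelSpec(traits=traits, terms=("1",))
        phi = theoretical_kinship(ped)
        data = prepare_model_data(spec, ped, table, {"additive": phi})
        beta = rng.standard_normal(data.design.n_coef)
        comps = {
            "additive": spec_sim.components["additive"],
            "environmental": spec_sim.components["environmental"],
        }
        ll = loglikelihood(beta, comps, data)
        oracle = sum(
            stats.multivariate_normal.logpdf(
                b.y, mean=b.A @ beta, cov=b.assemble_sigma(
                    {k: np.atleast_2d(v) for k, v in comps.items()}
                )
            )
            for b in data.blocks
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_block_additivity(self, small_study):
        ped, _, table = small_study
        spec = ModelSpec(traits=("SBP", "DBP"), terms=("1",))
        phi = theoretical_kinship(ped)
        fit = fit_null(spec, ped, table, {"additive": phi})
        assert sum(fit.loglik_by_pedigree.values()) == pytest.approx(
            fit.loglik, abs=1e-8
        )

    def test_invariant_to_within_pedigree_reordering(self, full_sibs):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(4, 2))
        spec = ModelSpec(traits=("A", "B"), terms=("1",))
        table = _table(full_sibs, Y, ["A", "B"])
        comps = {"additive": np.eye(2) * 0.5, "environmental": np.eye(2)}
        beta = np.array([0.1, -0.2])
        data = prepare_model_data(
            spec, full_sibs, table, {"additive": theoretical_kinship(full_sibs)}
        )
        ll1 = loglikelihood(beta, comps, data)
        # rebuild with siblings listed in the opposite order
        order = ["f", "m", "s2", "s1"]
        recs = []
        pos = {p: i for i, p in enumerate(full_sibs.person_id)}
        for p in order:
            i = pos[p]
            recs.append(
                (p,
                 full_sibs.person_id[full_sibs.father[i]] if full_sibs.father[i] >= 0 else None,
                 full_sibs.person_id[full_sibs.mother[i]] if full_sibs.mother[i] >= 0 else None,
                 full_sibs.sex[i], None)
            )
        ped2 = ped_from(recs)
        perm = [pos[p] for p in ped2.person_id]
        table2 = _table(ped2, Y[perm], ["A", "B"])
        data2 = prepare_model_data(
            spec, ped2, table2, {"additive": theoretical_kinship(ped2)}
        )
        assert loglikelihood(beta, comps, data2) == pytest.approx(ll1, abs=1e-10)


class TestFitNull:
    def test_ols_closed_form_for_unrelateds(self):
        rng = np.random.default_rng(8)
        n = 120
        spec_sim = SimSpec(
            n_unrelated=n, n_snps=2, traits=("Y",),
            beta={"1": [1.0], "age": [0.2]},
            components={"environmental": [[4.0]]},
            seed=8,
        )
        ped, _, table = simulate_study(spec_sim)
        spec = ModelSpec(
            traits=("Y",), terms=("1", "age"), components=("environmental",)
        )
        fit = fit_null(spec, ped, table, {})
        X = np.column_stack([np.ones(n), table.covariates[:, 1]])
        y = table.traits[:, 0]
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        sigma2_ml = resid @ resid / n
        assert fit.beta == pytest.approx(beta_ols, abs=1e-6)
        assert fit.components["environmental"][0, 0] == pytest.approx(
            sigma2_ml, rel=1e-6
        )
        # reported L equals the likelihood re-evaluated at the estimates
        assert fit.loglik == pytest.approx(
            loglikelihood(fit.beta, fit.components, fit.data), abs=1e-6
        )

    def test_monotone_trace(self, small_study):
        ped, _, table = small_study
        spec = ModelSpec(traits=("SBP", "DBP"), terms=("1", "sex", "age"))
        fit = fit_null(spec, ped, table, {"additive": theoretical_kinship(ped)})
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) >= -1e-7)
        assert fit.converged

    def test_zero_additive_component_detected(self):
        """Data simulated without polygenic signal: the fitted additive
        fraction stays small in median across replicates."""
        fractions = []
        for rep in range(15):
            spec_sim = SimSpec(
                n_pedigrees=10, sibship_range=(3, 3), n_snps=2, traits=("Y",),
                beta={"1": [0.0]},
                components={"additive": [[0.0]], "environmental": [[1.0]]},
                seed=300 + rep,
            )
            ped, _, table = simulate_study(spec_sim)
            spec = ModelSpec(traits=("Y",), terms=("1",))
            fit = fit_null(spec, ped, table, {"additive": theoretical_kinship(ped)})
            sa = fit.components["additive"][0, 0]
            se = fit.components["environmental"][0, 0]
            fractions.append(sa / (sa + se))
        assert np.median(fractions) < 0.05

    def test_missing_covariate_drops_individual(self, small_study):
        ped, _, table = small_study
        table = TraitTable(
            ids=table.ids, trait_names=table.trait_names,
            traits=table.traits.copy(),
            covariate_names=table.covariate_names,
            covariates=table.covariates.copy(),
        )
        table.covariates[5, 1] = np.nan
        spec = ModelSpec(traits=("SBP", "DBP"), terms=("1", "age"))
        data = prepare_model_data(
            spec, ped, table, {"additive": theoretical_kinship(ped)}
        )
        assert ped.person_id[5] not in data.ids
        dropped = data.dropped.set_index("person_id")
        assert dropped.loc[ped.person_id[5], "reason"] == "missing_covariate"

    def test_unrelateds_flag_additive_environment_confounding(self):
        spec_sim = SimSpec(
            n_unrelated=50, n_snps=2, traits=("Y",),
            beta={"1": [0.0]},
            components={"additive": [[0.5]], "environmental": [[1.0]]},
            seed=4,
        )
        ped, _, table = simulate_study(spec_sim)
        spec = ModelSpec(traits=("Y",), terms=("1",))
        with pytest.warns(NonIdentifiableWarning):
            fit = fit_null(spec, ped, table, {"additive": theoretical_kinship(ped)})
        assert fit.non_identifiable == ["additive~environmental"]


class TestOutlierReport:
    def test_planted_outlier_pedigree_ranked_first(self, small_study):
        ped, _, table = small_study
        table = TraitTable(
            ids=table.ids, trait_names=table.trait_names,
            traits=table.traits.copy(),
            covariate_names=table.covariate_names,
            covariates=table.covariates.copy(),
        )
        target = "P7"
        rows = ped.pedigree_id == target
        sd = np.nanstd(table.traits, axis=0)
        table.traits[rows] += 10.0 * sd
        spec = ModelSpec(traits=("SBP", "DBP"), terms=("1", "sex", "age"))
        fit = fit_null(spec, ped, table, {"additive": theoretical_kinship(ped)})
        ped_df, _ = pedigree_outlier_report(fit)
        assert ped_df.iloc[0]["pedigree_id"] == target
        assert ped_df.iloc[0]["p"] < 1e-10

    def test_planted_outlier_individual_ranked_first(self, small_study):
        # a single shifted individual is extreme in its conditional residual
        ped, _, table = small_study
        table = TraitTable(
            ids=table.ids, trait_names=table.trait_names,
            traits=table.traits.copy(),
            covariate_names=table.covariate_names,
            covariates=table.covariates.copy(),
        )
        sd = np.nanstd(table.traits, axis=0)
        table.traits[30] += 10.0 * sd
        spec = ModelSpec(traits=("SBP", "DBP"), terms=("1", "sex", "age"))
        fit = fit_null(spec, ped, table, {"additive": theoretical_kinship(ped)})
        _, ind_df = pedigree_outlier_report(fit)
        assert ind_df.iloc[0]["person_id"] == ped.person_id[30]

    def test_single_individual_zero_residual(self):
        ped = ped_from([("a", None, None, "male", None)])
        table = _table(ped, [[3.0]], ["Y"])
        spec = ModelSpec(traits=("Y",), terms=("1",), components=("environmental",))
        data = prepare_model_data(spec, ped, table, {})
        fit = fit_null(data, init_components={"environmental": [[1.0]]})
        ped_df, _ = pedigree_outlier_report(fit)
        assert ped_df.iloc[0]["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_null_statistics_chi_squared_calibrated(self):
        """Per-pedigree Mahalanobis statistics follow chi-square_m under the
        model: upper-tail probabilities look uniform."""
        spec_sim = SimSpec(
            n_pedigrees=100, generations=2, sibship_range=(3, 3), n_snps=2,
            traits=("Y",), beta={"1": [0.0]},
            components={"additive": [[1.0]], "environmental": [[1.0]]},
            seed=17,
        )
        ped, _, table = simulate_study(spec_sim)
        spec = ModelSpec(traits=("Y",), terms=("1",))
        fit = fit_null(spec, ped, table, {"additive": theoretical_kinship(ped)})
        ped_df, _ = pedigree_outlier_report(fit)
        ks = stats.kstest(ped_df["p"], "uniform")
        assert ks.pvalue > 0.01
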