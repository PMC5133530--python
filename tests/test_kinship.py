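"""Structure matrices: recursion oracles, enumeration oracles, estimators."""

from itertools import product

import numpy as np
import pytest

from pedscan import (
    Pedigree,
    SimSpec,
    theoretical_kinship,
    delta7_matrix,
    household_matrix,
    grm_kinship,
    mom_kinship,
    gene_drop,
    gene_drop_origins,
    empirical_ibd_kinship,
    simulate_pedigree,
)
from pedscan.pedio import PedigreeStructureError

from conftest import ped_from


def phi_of(ped, a, b):
    mat = theoretical_kinship(ped)
    ia = int(np.flatnonzero(mat.ids == a)[0])
    ib = int(np.flatnonzero(mat.ids == b)[0])
    return mat.values[ia, ib]


def enumerate_delta7(ped: Pedigree, i_id: str, j_id: str) -> float:
    """Independent oracle: exhaustive enumeration of parental transmissions.

    Iterates over every inheritance vector (4 choices per non-founder),
    tracking founder-allele labels, and counts the outcomes in condensed
    identity state 7 (neither individual autozygous, the two allele pairs
    IBD across individuals)."""
    i = int(np.flatnonzero(ped.person_id == i_id)[0])
    j = int(np.flatnonzero(ped.person_id == j_id)[0])
    nonf = [k for k in range(ped.n) if ped.father[k] >= 0]
    hits = 0
    combos = list(product(range(4), repeat=len(nonf)))
    for choices in combos:
        alleles: dict[int, tuple] = {}
        for k in range(ped.n):
            if ped.father[k] < 0:
                alleles[k] = (2 * k, 2 * k + 1)
        for k, ch in zip(nonf, choices):
            f, m = ped.father[k], ped.mother[k]
            alleles[k] = (alleles[f][ch & 1], alleles[m][(ch >> 1) & 1])
        a1, a2 = alleles[i]
        b1, b2 = alleles[j]
        if (
            a1 != a2
            and b1 != b2
            and ((a1 == b1 and a2 == b2) or (a1 == b2 and a2 == b1))
        ):
            hits += 1
    return hits / len(combos)


class TestTheoreticalKinship:
    def test_textbook_values(self, trio, full_sibs, half_sibs):
        assert phi_of(trio, "dad", "dad") == 0.5
        assert phi_of(trio, "dad", "kid") == 0.25
        assert phi_of(trio, "dad", "mom") == 0.0
        assert phi_of(full_sibs, "s1", "s2") == 0.25
        assert phi_of(half_sibs, "c1", "c2") == 0.125

    def test_inbred_self_kinship(self, inbred_ped):
        assert phi_of(inbred_ped, "k", "k") == 0.5 * (1 + 0.25)

    def test_permutation_invariance(self, double_first_cousins):
        base = theoretical_kinship(double_first_cousins)
        records = [
            {
                "pedigree_id": "P",
                "person_id": p,
                "father_id": (
                    double_first_cousins.person_id[double_first_cousins.father[i]]
                    if double_first_cousins.father[i] >= 0
                    else None
                ),
                "mother_id": (
                    double_first_cousins.person_id[double_first_cousins.mother[i]]
                    if double_first_cousins.mother[i] >= 0
                    else None
                ),
                "sex": double_first_cousins.sex[i],
                "household_id": None,
            }
            for i, p in enumerate(double_first_cousins.person_id)
        ]
        shuffled = Pedigree.from_records(records[::-1])
        mat2 = theoretical_kinship(shuffled)
        pos = {p: i for i, p in enumerate(mat2.ids)}
        perm = np.array([pos[p] for p in base.ids])
        assert np.allclose(base.values, mat2.values[np.ix_(perm, perm)])

    def test_psd(self, small_study):
        ped, _, _ = small_study
        w = np.linalg.eigvalsh(theoretical_kinship(ped).values)
        assert w.min() > -1e-12

    def test_gene_drop_monte_carlo_agrees(self, inbred_ped):
        # MC IBD frequency vs recursion, 2e4 loci, 3 standard errors
        rng = np.random.default_rng(7)
        origins = gene_drop_origins(inbred_ped, 20_000, rng)
        emp = empirical_ibd_kinship(origins)
        theo = theoretical_kinship(inbred_ped).values
        for i in range(inbred_ped.n):
            for j in range(i + 1):
                per_locus = np.zeros(origins.shape[2])
                for a in range(2):
                    for b in range(2):
                        per_locus += origins[i, a] == origins[j, b]
                per_locus /= 4.0
                se = per_locus.std(ddof=1) / np.sqrt(len(per_locus))
                if se == 0:
                    assert emp[i, j] == theo[i, j]
                else:
                    assert abs(emp[i, j] - theo[i, j]) < 3 * se


class TestDelta7:
    def test_parent_offspring_zero(self, trio):
        mat = delta7_matrix(trio)
        i = int(np.flatnonzero(mat.ids == "dad")[0])
        j = int(np.flatnonzero(mat.ids == "kid")[0])
        assert mat.values[i, j] == 0.0

    @pytest.mark.parametrize(
        "pair, expected",
        [(("s1", "s2"), 0.25), (("c1", "c2"), 1.0 / 16.0)],
    )
    def test_matches_enumeration_oracle(
        self, full_sibs, double_first_cousins, pair, expected
    ):
        ped = full_sibs if pair == ("s1", "s2") else double_first_cousins
        mat = delta7_matrix(ped)
        i = int(np.flatnonzero(mat.ids == pair[0])[0])
        j = int(np.flatnonzero(mat.ids == pair[1])[0])
        oracle = enumerate_delta7(ped, *pair)
        assert oracle == pytest.approx(expected, abs=1e-12)
        assert mat.values[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_inbred_rejected(self, inbred_ped):
        with pytest.raises(PedigreeStructureError, match="inbred"):
            delta7_matrix(inbred_ped)

    def test_diagonal_one_and_range(self, small_study):
        ped, _, _ = small_study
        mat = delta7_matrix(ped)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert mat.values.min() >= 0.0 and mat.values.max() <= 1.0


class TestHousehold:
    def test_same_and_different_household(self):
        ped = ped_from(
            [
                ("a", None, None, "male", "h1"),
                ("b", None, None, "female", "h1"),
                ("c", None, None, "male", "h2"),
                ("d", None, None, "male", None),  # singleton
            ]
        )
        H = household_matrix(ped).values
        assert H[0, 1] == 1.0
        assert H[0, 2] == 0.0
        assert np.array_equal(H[3], [0, 0, 0, 1])
        assert np.allclose(np.diag(H), 1.0)


def _three_gen_pedigree():
    spec = SimSpec(
        n_pedigrees=2, founder_couples=1, generations=3, sibship_range=(3, 3), seed=11
    )
    return simulate_pedigree(spec, np.random.default_rng(11))


class TestEmpiricalKinship:
    def test_duplicate_rows_equal_diagonal(self):
        ped = ped_from(
            [("a", None, None, "male", None), ("b", None, None, "male", None),
             ("c", None, None, "male", None)]
        )
        geno = gene_drop(ped, np.full(40, 0.3), np.random.default_rng(5))
        geno.dosages[1] = geno.dosages[0]  # b duplicates a
        K = grm_kinship(geno).values
        assert K[0, 1] == pytest.approx(K[0, 0])
        M = mom_kinship(geno).values
        assert M[0, 1] == pytest.approx(M[0, 0])
        # identical fully-informative rows dominate any non-identical pair
        assert M[0, 1] >= M[0, 2]

    @pytest.mark.parametrize("estimator", [grm_kinship, mom_kinship])
    def test_unrelated_founders_mean_near_zero(self, estimator):
        # Sample allele frequencies make standardized dosages sum to ~0, so
        # the off-diagonal mean carries a known -mean(diag)/(n-1) term; after
        # removing it the residual should sit within 3 SEs of zero.
        n = 60
        spec = SimSpec(n_unrelated=n, seed=13)
        ped = simulate_pedigree(spec, np.random.default_rng(13))
        geno = gene_drop(ped, np.random.default_rng(14).uniform(0.1, 0.5, 10_000),
                         np.random.default_rng(15))
        K = estimator(geno).values
        off = K[np.triu_indices_from(K, k=1)]
        se_mean = off.std(ddof=1) / np.sqrt(len(off))
        bias = -np.diag(K).mean() / (n - 1)
        assert abs(off.mean() - bias) < 3 * se_mean + 1e-3
        assert abs(off.mean()) < 0.02

    @pytest.mark.parametrize(
        "estimator, tol", [(grm_kinship, 0.02), (mom_kinship, 0.03)]
    )
    def test_converges_to_theoretical(self, estimator, tol):
        # 20 gene-dropped 3-generation pedigrees: many founders keep the
        # sample allele frequencies close to the founder-population MAFs.
        spec = SimSpec(
            n_pedigrees=20, founder_couples=1, generations=3,
            sibship_range=(3, 3), seed=11,
        )
        ped = simulate_pedigree(spec, np.random.default_rng(11))
        theo = theoretical_kinship(ped).values
        rmses = []
        for S, seed in [(1000, 21), (10_000, 22)]:
            geno = gene_drop(
                ped, np.random.default_rng(seed).uniform(0.1, 0.5, S),
                np.random.default_rng(seed + 100),
            )
            K = estimator(geno).values
            rmses.append(np.sqrt(np.mean((K - theo) ** 2)))
        assert rmses[1] < rmses[0]
        assert rmses[1] < tol

    def test_within_pedigree_scope_zeroes_cross_entries(self):
        ped = _three_gen_pedigree()
        geno = gene_drop(ped, np.full(500, 0.3), np.random.default_rng(3))
        K = grm_kinship(geno, scope="within_pedigree", ped=ped).values
        labels = ped.pedigree_id
        cross = labels[:, None] != labels[None, :]
        assert np.all(K[cross] == 0.0)
        assert np.any(K[~cross] != 0.0)

    def test_symmetry(self):
        ped = _three_gen_pedigree()
        geno = gene_drop(ped, np.full(300, 0.25), np.random.default_rng(9))
        for est in (grm_kinship, mom_kinship):
            K = est(geno).values
            assert np.allclose(K, K.T)
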