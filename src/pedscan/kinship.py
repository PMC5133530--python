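"""Structure matrices for the variance-component model.

Four kinds of n x n matrices enter the trait covariance
``2*Sigma_a (x) Phi + Sigma_d (x) Delta7 + Sigma_h (x) H + Sigma_e (x) I``:

* ``Phi`` — kinship, either theoretical (recursion over the pedigree) or
  SNP-based (GRM or method of moments, globally or masked within pedigrees);
* ``Delta7`` — the condensed identity coefficient multiplying dominance
  variance between non-inbred relatives;
* ``H`` — the household indicator (1 for co-housed pairs, diagonal 1);
* the identity, supplied implicitly by the model fitter.

Founders are assumed non-inbred and mutually unrelated; the Delta7
computation additionally requires a non-inbred pedigree and checks for it
rather than assuming it (general Jacquard coefficients are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedio import Pedigree, GenotypeMatrix, PedigreeStructureError

__all__ = [
    "StructureMatrix",
    "theoretical_kinship",
    "delta7_matrix",
    "household_matrix",
    "grm_kinship",
    "mom_kinship",
    "write_structure_matrix",
]


class KinshipEstimationError(ValueError):
    """Raised when SNP-based kinship estimation is impossible."""


@dataclass(frozen=True)
class StructureMatrix:
    """A symmetric n x n relationship matrix tied to an individual ordering."""

    kind: str
    values: np.ndarray
    ids: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def block(self, idx: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(idx, idx)]


def theoretical_kinship(ped: Pedigree) -> StructureMatrix:
    """Kinship coefficients phi from the pedigree structure.

    Recursive computation in parents-before-children order: a founder has
    self-kinship 1/2 and kinship 0 with every earlier individual; a child k
    of parents (f, m) has ``phi_kk = (1 + phi_fm) / 2`` and
    ``phi_kj = (phi_fj + phi_mj) / 2`` for previously processed j.  Values
    are exact dyadic rationals up to floating representation.
    """
    n = ped.n
    phi = np.zeros((n, n))
    for k in range(n):
        f, m = ped.father[k], ped.mother[k]
        if f < 0:  # founder
            phi[k, k] = 0.5
            continue
        if f >= k or m >= k:
            raise PedigreeStructureError(
                f"pedigree not in parents-before-children order at "
                f"{ped.person_id[k]!r}"
            )
        phi[k, :k] = 0.5 * (phi[f, :k] + phi[m, :k])
        phi[:k, k] = phi[k, :k]
        phi[k, k] = 0.5 * (1.0 + phi[f, m])
    return StructureMatrix("theoretical_kinship", phi, ped.person_id.copy())


def delta7_matrix(ped: Pedigree) -> StructureMatrix:
    """Condensed identity coefficient Delta7 (dominance sharing).

    For non-inbred individuals i (parents a, b) and j (parents c, d),
    ``Delta7(i, j) = phi_ac * phi_bd + phi_ad * phi_bc``; the diagonal is 1
    and founder-anyone off-diagonal entries are 0.  Requires every
    individual to be non-inbred (each non-founder's parents have kinship 0);
    inbred pedigrees need the full Jacquard coefficients, which are not
    supported.
    """
    phi = theoretical_kinship(ped).values
    n = ped.n
    for k in range(n):
        f, m = ped.father[k], ped.mother[k]
        if f >= 0 and phi[f, m] != 0.0:
            raise PedigreeStructureError(
                f"individual {ped.person_id[k]!r} is inbred (parental kinship "
                f"{phi[f, m]:g}); Delta7 supports only non-inbred pedigrees"
            )
    d7 = np.eye(n)
    nonfounder = np.flatnonzero(ped.father >= 0)
    for ii, i in enumerate(nonfounder):
        a, b = ped.father[i], ped.mother[i]
        for j in nonfounder[:ii]:
            c, d = ped.father[j], ped.mother[j]
            val = phi[a, c] * phi[b, d] + phi[a, d] * phi[b, c]
            d7[i, j] = d7[j, i] = val
    return StructureMatrix("delta7", d7, ped.person_id.copy())


def household_matrix(ped: Pedigree) -> StructureMatrix:
    """Indicator matrix H with ``h_ij = 1`` for individuals sharing a
    household and 0 otherwise; diagonal 1.  Individuals without a household
    ID form singleton households."""
    n = ped.n
    H = np.eye(n)
    hid = ped.household_id
    for i in range(n):
        if hid[i] is None:
            continue
        for j in range(i):
            if hid[j] is not None and hid[j] == hid[i]:
                H[i, j] = H[j, i] = 1.0
    return StructureMatrix("household", H, ped.person_id.copy())


# ---------------------------------------------------------------------------
# SNP-based kinship
# ---------------------------------------------------------------------------


def _prepare_empirical(geno: GenotypeMatrix):
    """Shared setup: drop monomorphic SNPs, return dosages, missingness mask
    and sample allele frequencies."""
    X = geno.dosages
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise KinshipEstimationError("all SNPs are monomorphic or all-missing")
    X = X[:, poly]
    p = p[poly]
    miss = np.isnan(X)
    return X, miss, p


def _mask_scope(values: np.ndarray, scope: str, geno, ped: Pedigree) -> np.ndarray:
    if scope == "global":
        return values
    if scope != "within_pedigree":
        raise ValueError(f"unknown kinship scope {scope!r}")
    if ped is None:
        raise ValueError("within_pedigree scope requires a pedigree")
    ped_of = dict(zip(ped.person_id, ped.pedigree_id))
    labels = np.array([ped_of[i] for i in geno.ids], dtype=object)
    same = labels[:, None] == labels[None, :]
    return np.where(same, values, 0.0)


def grm_kinship(
    geno: GenotypeMatrix, scope: str = "global", ped: Pedigree | None = None
) -> StructureMatrix:
    """Genetic-relationship-matrix kinship estimate on the kinship scale.

    ``Phi_hat_ij = mean_s (x_is - 2p_s)(x_js - 2p_s) / (4 p_s (1 - p_s))``
    over the SNPs non-missing in both individuals (pairwise-complete), with
    per-SNP standardization and allele frequencies estimated from all
    individuals.  Monomorphic SNPs are skipped.  ``within_pedigree`` scope
    zeroes entries between different pedigrees.
    """
    X, miss, p = _prepare_empirical(geno)
    Z = (X - 2.0 * p) / np.sqrt(4.0 * p * (1.0 - p))
    Z[miss] = 0.0
    obs = (~miss).astype(float)
    pair_count = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (Z @ Z.T) / pair_count
    K[pair_count == 0] = 0.0
    K = _mask_scope(K, scope, geno, ped)
    return StructureMatrix("grm", K, geno.ids.copy())


def mom_kinship(
    geno: GenotypeMatrix, scope: str = "global", ped: Pedigree | None = None
) -> StructureMatrix:
    """Method-of-moments kinship from allele-matching proportions.

    With ``e_ij = (1/4) sum_s [x_is x_js + (2 - x_is)(2 - x_js)]`` over
    pairwise-complete SNPs and ``c_ij = sum_s (p_s^2 + q_s^2)`` over the same
    SNPs, ``phi_hat_ij = (e_ij - c_ij) / (S'_ij - c_ij)``.
    """
    X, miss, p = _prepare_empirical(geno)
    A = np.where(miss, 0.0, X)
    B = np.where(miss, 0.0, 2.0 - X)
    e = 0.25 * (A @ A.T + B @ B.T)
    obs = (~miss).astype(float)
    w = p**2 + (1.0 - p) ** 2
    c = (obs * w) @ obs.T
    s_pair = obs @ obs.T
    denom = s_pair - c
    if np.any(denom <= 0):
        raise KinshipEstimationError(
            "method-of-moments denominator non-positive for some pair "
            "(too few informative SNPs)"
        )
    K = (e - c) / denom
    K = _mask_scope(K, scope, geno, ped)
    return StructureMatrix("mom", K, geno.ids.copy())


def write_structure_matrix(mat: StructureMatrix, path) -> None:
    """Write the lower triangle as 3-column TSV (id_i, id_j, value)."""
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i in range(mat.n):
            for j in range(i + 1):
                fh.write(f"{mat.ids[i]}\t{mat.ids[j]}\t{mat.values[i, j]:.10g}\n")
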