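"""Multivariate variance-component trait model on pedigrees.

The trait matrix Y (n individuals x T traits) is modelled, per pedigree, as

    vec(Y) ~ N(A beta,  Sigma),
    Sigma = 2 Sigma_a (x) Phi + Sigma_d (x) Delta7 + Sigma_h (x) H
            + Sigma_e (x) I,

in trait-major vec ordering: entry ((t, i), (t', j)) of Sigma equals
``2 Sigma_a[t, t'] Phi[i, j]`` and so on.  The T x T component matrices
Sigma_a (additive polygenic), Sigma_d (dominance), Sigma_h (household) and
Sigma_e (environment/measurement error) are the parameters of interest;
fixed effects enter through the mean A beta, with optional equality
constraints tying one coefficient across several (covariate, trait) cells —
the standard way to share a covariate effect across longitudinal time
points.

Missing data are handled likelihood-exactly: missing trait entries delete
the corresponding rows/columns of vec(Y), A and Sigma (marginalization of
the multivariate normal); individuals missing any model covariate are
dropped from the analysis entirely and logged.

The loglikelihood of a pedigree includes the -(m/2) ln 2*pi normalizing
constant (m = observed trait entries), so values are directly comparable
with any generic multivariate-normal density; implementations that omit the
constant differ by exactly that known amount.

Maximum likelihood uses a quasi-Newton search over Cholesky-parametrized
component matrices (guaranteeing positive semidefiniteness) with the mean
coefficients profiled out by generalized least squares at every iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
import pandas as pd

from .pedio import Pedigree, TraitTable
from .kinship import StructureMatrix

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "ModelData",
    "NullFit",
    "FitError",
    "NonIdentifiableWarning",
    "build_design",
    "prepare_model_data",
    "loglikelihood",
    "fit_null",
    "pedigree_outlier_report",
]

COMPONENTS = ("additive", "dominance", "household", "environmental")

LOG2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    """Model fitting failed; carries the loglikelihood trace if available."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class NonIdentifiableWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Model specification and design
# ---------------------------------------------------------------------------


def _parse_term(term: str) -> tuple[str, ...]:
    term = term.strip()
    if term == "1":
        return ()
    return tuple(v.strip() for v in term.split("*"))


@dataclass(frozen=True)
class ModelSpec:
    """Mean and covariance structure of the null (no-SNP) model.

    ``terms`` are covariate names, ``"1"`` for the intercept, or ``"a*b"``
    for an elementwise interaction.  ``constraints`` lists groups of
    ``(term, trait)`` cells that share a single coefficient.  The
    environmental component is always active.
    """

    traits: tuple[str, ...]
    terms: tuple[str, ...] = ("1",)
    constraints: tuple[tuple[tuple[str, str], ...], ...] = ()
    components: tuple[str, ...] = ("additive", "environmental")
    kinship_source: str = "theoretical"

    def __post_init__(self):
        if "environmental" not in self.components:
            raise ValueError("the environmental component is always active")
        for comp in self.components:
            if comp not in COMPONENTS:
                raise ValueError(f"unknown variance component {comp!r}")
        seen = set()
        for group in self.constraints:
            for cell in group:
                if cell in seen:
                    raise ValueError(
                        f"constraint groups must partition cells; {cell} repeated"
                    )
                seen.add(cell)

    @property
    def T(self) -> int:
        return len(self.traits)

    @classmethod
    def longitudinal(
        cls,
        traits,
        terms=("1",),
        trait_groups: dict[str, list[str]] | None = None,
        **kwargs,
    ) -> "ModelSpec":
        """Spec with every term's effect constrained to be equal across the
        time points of each trait group (e.g. one sex effect shared by
        SBP_1..SBP_4 and another by DBP_1..DBP_4)."""
        traits = tuple(traits)
        if trait_groups is None:
            from .pedio import _infer_groups

            idx_groups = _infer_groups(list(traits))
            trait_groups = {
                g: [traits[j] for j in idx] for g, idx in idx_groups.items()
            }
        constraints = []
        for term in terms:
            for members in trait_groups.values():
                if len(members) > 1:
                    constraints.append(tuple((term, tr) for tr in members))
        return cls(
            traits=traits, terms=tuple(terms), constraints=tuple(constraints), **kwargs
        )

    # -- plain-text config ---------------------------------------------------

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        """Parse a flat ``key = value`` config; ``constraint`` may repeat,
        each listing ``term:trait`` cells separated by commas."""
        traits = terms = None
        components = ("additive", "environmental")
        kinship = "theoretical"
        constraints = []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if key == "traits":
                traits = tuple(v.strip() for v in val.split(","))
            elif key == "terms":
                terms = tuple(v.strip() for v in val.split(","))
            elif key == "components":
                components = tuple(v.strip() for v in val.split(","))
            elif key == "kinship":
                kinship = val
            elif key == "constraint":
                cells = []
                for cell in val.split(","):
                    term, _, trait = cell.strip().partition(":")
                    cells.append((term.strip(), trait.strip()))
                constraints.append(tuple(cells))
            else:
                raise ValueError(f"unknown model config key {key!r}")
        if traits is None:
            raise ValueError("model config must define 'traits'")
        return cls(
            traits=traits,
            terms=terms or ("1",),
            constraints=tuple(constraints),
            components=components,
            kinship_source=kinship,
        )

    def to_config(self) -> str:
        lines = [
            f"traits = {', '.join(self.traits)}",
            f"terms = {', '.join(self.terms)}",
            f"components = {', '.join(self.components)}",
            f"kinship = {self.kinship_source}",
        ]
        for group in self.constraints:
            lines.append(
                "constraint = " + ", ".join(f"{t}:{tr}" for t, tr in group)
            )
        return "\n".join(lines) + "\n"


@dataclass
class DesignInfo:
    """Mapping from (term, trait) cells to mean coefficients.

    ``cell_coef[k, t]`` is the coefficient index for term k on trait t;
    constrained cells share an index.  ``term_values`` holds the
    per-individual covariate columns (NaN where a covariate is missing).
    """

    coef_names: list[str]
    cell_coef: np.ndarray
    term_values: np.ndarray
    term_names: list[str]

    @property
    def n_coef(self) -> int:
        return len(self.coef_names)


def build_design(spec: ModelSpec, traits: TraitTable) -> DesignInfo:
    """Expand terms into per-individual covariate columns and resolve
    equality constraints into a coefficient index map.

    Each constraint group collapses its member (term, trait) cells into one
    coefficient whose design column is the sum of the member columns.
    """
    cov_idx = {name: j for j, name in enumerate(traits.covariate_names)}
    n = traits.n
    term_cols = np.empty((n, len(spec.terms)))
    for k, term in enumerate(spec.terms):
        variables = _parse_term(term)
        col = np.ones(n)
        for v in variables:
            if v not in cov_idx:
                raise ValueError(f"unknown covariate {v!r} in term {term!r}")
            col = col * traits.covariates[:, cov_idx[v]]
        term_cols[:, k] = col

    trait_idx = {tr: t for t, tr in enumerate(spec.traits)}
    term_pos = {term: k for k, term in enumerate(spec.terms)}
    cell_coef = np.full((len(spec.terms), spec.T), -1, dtype=int)
    coef_names: list[str] = []
    for group in spec.constraints:
        scales = set()
        for term, trait in group:
            if term not in term_pos:
                raise ValueError(f"constraint references unknown term {term!r}")
            if trait not in trait_idx:
                raise ValueError(f"constraint references unknown trait {trait!r}")
            scales.add(trait)
        idx = len(coef_names)
        term0, trait0 = group[0]
        coef_names.append(f"{term0}:{trait0.rstrip('0123456789').rstrip('_') or trait0}")
        for term, trait in group:
            cell_coef[term_pos[term], trait_idx[trait]] = idx
    for k, term in enumerate(spec.terms):
        for t, trait in enumerate(spec.traits):
            if cell_coef[k, t] < 0:
                cell_coef[k, t] = len(coef_names)
                coef_names.append(f"{term}:{trait}")
    return DesignInfo(
        coef_names=coef_names,
        cell_coef=cell_coef,
        term_values=term_cols,
        term_names=list(spec.terms),
    )


# ---------------------------------------------------------------------------
# Per-pedigree data blocks
# ---------------------------------------------------------------------------


@dataclass
class PedBlock:
    """All quantities the likelihood needs for one pedigree.

    ``ind_idx`` indexes the analysis-individual ordering; ``cell_ind`` and
    ``cell_trait`` give, for each observed vec(Y) cell (trait-major order),
    the local individual and trait index.  ``structs`` maps component name
    to the pedigree sub-block of its structure matrix (the additive block
    already includes the factor 2: it is 2*Phi).
    """

    pedigree_id: str
    ind_idx: np.ndarray
    cell_ind: np.ndarray
    cell_trait: np.ndarray
    y: np.ndarray
    A: np.ndarray
    structs: dict[str, np.ndarray]

    @property
    def m(self) -> int:
        return len(self.y)

    def assemble_sigma(self, components: dict[str, np.ndarray]) -> np.ndarray:
        ti, tj = np.meshgrid(self.cell_trait, self.cell_trait, indexing="ij")
        sigma = np.zeros((self.m, self.m))
        for name, M in self.structs.items():
            C = components[name]
            sigma += C[ti, tj] * M
        return sigma


@dataclass
class ModelData:
    """Analysis-ready data: aligned individuals split into pedigree blocks."""

    spec: ModelSpec
    design: DesignInfo
    ids: np.ndarray
    blocks: list[PedBlock]
    dropped: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return sum(b.m for b in self.blocks)

    def with_extra_columns(self, extra: np.ndarray, names: list[str]) -> "ModelData":
        """Append per-trait fixed-effect columns for a SNP dosage vector.

        ``extra`` is one value per analysis individual; each trait gets its
        own column (the T-column augmentation used for SNP testing).
        """
        T = self.spec.T
        new_blocks = []
        for b in self.blocks:
            g = extra[b.ind_idx]
            Xs = np.zeros((b.m, T))
            rows = np.arange(b.m)
            Xs[rows, b.cell_trait] = g[b.cell_ind]
            new_blocks.append(
                PedBlock(
                    pedigree_id=b.pedigree_id,
                    ind_idx=b.ind_idx,
                    cell_ind=b.cell_ind,
                    cell_trait=b.cell_trait,
                    y=b.y,
                    A=np.hstack([b.A, Xs]),
                    structs=b.structs,
                )
            )
        design = DesignInfo(
            coef_names=self.design.coef_names + list(names),
            cell_coef=self.design.cell_coef,
            term_values=self.design.term_values,
            term_names=self.design.term_names,
        )
        return ModelData(
            spec=self.spec,
            design=design,
            ids=self.ids,
            blocks=new_blocks,
            dropped=self.dropped,
        )


def _psd_project(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def prepare_model_data(
    spec: ModelSpec,
    ped: Pedigree,
    traits: TraitTable,
    structures: dict[str, StructureMatrix],
) -> ModelData:
    """Join pedigree, traits and structure matrices into per-pedigree blocks.

    Analysis individuals are those with at least one observed trait, no
    missing model covariate, and presence in every required structure
    matrix.  Empirical (GRM / method-of-moments) kinship matrices are
    projected onto the PSD cone before entering the covariance.  Dropped
    individuals are recorded with a reason.
    """
    design = build_design(spec, traits)
    needed = [c for c in spec.components if c != "environmental"]
    for comp in needed:
        if comp not in structures:
            raise ValueError(f"no structure matrix supplied for component {comp!r}")

    struct_pos: dict[str, dict] = {}
    struct_vals: dict[str, np.ndarray] = {}
    for comp in needed:
        mat = structures[comp]
        vals = mat.values
        if comp == "additive" and mat.kind in {"grm", "mom"}:
            vals = _psd_project(vals)
        struct_vals[comp] = vals
        struct_pos[comp] = {pid: i for i, pid in enumerate(mat.ids)}

    dropped: list[dict] = []
    keep = np.zeros(ped.n, dtype=bool)
    any_trait = np.isfinite(traits.traits).any(axis=1)
    cov_ok = np.isfinite(design.term_values).all(axis=1)
    for i in range(ped.n):
        pid = ped.person_id[i]
        if not any_trait[i]:
            dropped.append({"person_id": pid, "reason": "no_observed_traits"})
            continue
        if not cov_ok[i]:
            dropped.append({"person_id": pid, "reason": "missing_covariate"})
            continue
        if any(pid not in struct_pos[c] for c in needed):
            dropped.append({"person_id": pid, "reason": "missing_structure_row"})
            continue
        keep[i] = True

    ids = ped.person_id[keep]
    if len(ids) == 0:
        raise FitError("no analyzable individuals after missing-data handling")
    global_pos = {pid: g for g, pid in enumerate(ids)}

    T = spec.T
    blocks: list[PedBlock] = []
    for ped_id, members in ped.pedigree_blocks().items():
        members = members[keep[members]]
        if len(members) == 0:
            continue
        np_loc = len(members)
        member_ids = ped.person_id[members]
        Ymat = traits.traits[members][:, :T]
        obs = np.isfinite(Ymat)
        # trait-major cell order: trait index outer, individual inner
        cell_trait, cell_ind = np.nonzero(obs.T)
        y = Ymat[cell_ind, cell_trait]
        # design rows: term k contributes its value at the cell's coefficient
        m_obs = len(y)
        A = np.zeros((m_obs, design.n_coef))
        tv = design.term_values[members]
        rows = np.arange(m_obs)
        for k in range(len(design.term_names)):
            np.add.at(A, (rows, design.cell_coef[k, cell_trait]), tv[cell_ind, k])
        structs: dict[str, np.ndarray] = {}
        for comp in needed:
            pos = struct_pos[comp]
            sub = np.array([pos[pid] for pid in member_ids])
            M = struct_vals[comp][np.ix_(sub, sub)]
            if comp == "additive":
                M = 2.0 * M
            structs[comp] = M[np.ix_(cell_ind, cell_ind)]
        structs["environmental"] = np.eye(np_loc)[np.ix_(cell_ind, cell_ind)]
        blocks.append(
            PedBlock(
                pedigree_id=ped_id,
                ind_idx=np.array([global_pos[pid] for pid in member_ids]),
                cell_ind=cell_ind,
                cell_trait=cell_trait,
                y=y,
                A=A,
                structs=structs,
            )
        )
    return ModelData(
        spec=spec,
        design=design,
        ids=ids,
        blocks=blocks,
        dropped=pd.DataFrame(dropped, columns=["person_id", "reason"]),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _block_loglik(block: PedBlock, beta, components) -> float:
    sigma = block.assemble_sigma(components)
    r = block.y - block.A @ beta
    try:
        L = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        raise FitError(
            f"covariance not positive definite in pedigree {block.pedigree_id!r}"
        )
    z = linalg.solve_triangular(L, r, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (logdet + z @ z + block.m * LOG2PI)


def loglikelihood(
    beta: np.ndarray, components: dict[str, np.ndarray], data: ModelData
) -> float:
    """Multivariate-normal loglikelihood summed over pedigrees,
    including the ln 2*pi constant."""
    comp = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in components.items()}
    beta = np.asarray(beta, dtype=float)
    return float(sum(_block_loglik(b, beta, comp) for b in data.blocks))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _vech_indices(T: int):
    return np.tril_indices(T)


def _theta_to_components(theta, active, T) -> dict[str, np.ndarray]:
    rows, cols = _vech_indices(T)
    k = len(rows)
    comps = {}
    for j, name in enumerate(active):
        Lmat = np.zeros((T, T))
        Lmat[rows, cols] = theta[j * k : (j + 1) * k]
        comps[name] = Lmat @ Lmat.T
    return comps


def _components_to_theta(comps, active, T) -> np.ndarray:
    rows, cols = _vech_indices(T)
    parts = []
    for name in active:
        M = np.atleast_2d(comps[name])
        # modified Cholesky: eigenvalue-floor then factor, for PSD inits
        w, V = np.linalg.eigh((M + M.T) / 2.0)
        w = np.clip(w, 1e-10, None)
        Lmat = np.linalg.cholesky((V * w) @ V.T)
        parts.append(Lmat[rows, cols])
    return np.concatenate(parts)


@dataclass
class NullFit:
    """A fitted null (or SNP-augmented) model with cached per-pedigree
    factors for downstream score tests."""

    spec: ModelSpec
    data: ModelData
    beta: np.ndarray
    components: dict[str, np.ndarray]
    loglik: float
    loglik_by_pedigree: dict[str, float]
    trace: list[float]
    converged: bool
    boundary_flags: list[str]
    non_identifiable: list[str]
    # caches (aligned with data.blocks)
    chol: list[np.ndarray] = field(default_factory=list, repr=False)
    resid: list[np.ndarray] = field(default_factory=list, repr=False)
    siginv_r: list[np.ndarray] = field(default_factory=list, repr=False)
    siginv_A: list[np.ndarray] = field(default_factory=list, repr=False)
    AtWA_inv: np.ndarray | None = None

    @property
    def coef_names(self) -> list[str]:
        return self.data.design.coef_names

    @property
    def n_obs(self) -> int:
        return self.data.n_obs

    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.AtWA_inv))

    def parameter_table(self) -> pd.DataFrame:
        rows = [
            {"parameter": name, "estimate": est, "se": se}
            for name, est, se in zip(self.coef_names, self.beta, self.beta_se())
        ]
        rows_idx, cols_idx = _vech_indices(self.spec.T)
        for comp, M in self.components.items():
            for r, c in zip(rows_idx, cols_idx):
                rows.append(
                    {
                        "parameter": f"Sigma_{comp[0]}[{r},{c}]",
                        "estimate": M[r, c],
                        "se": np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def estimate_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Asymptotic covariance of (beta, vech of each active component)
        from the numerically differentiated observed information."""
        T = self.spec.T
        rows, cols = _vech_indices(T)
        active = list(self.components)
        names = list(self.coef_names)
        for comp in active:
            names += [f"Sigma_{comp[0]}[{r},{c}]" for r, c in zip(rows, cols)]

        beta0 = self.beta.copy()
        vech0 = np.concatenate(
            [self.components[c][rows, cols] for c in active]
        )
        x0 = np.concatenate([beta0, vech0])
        nb = len(beta0)
        k = len(rows)

        def unpack(x):
            beta = x[:nb]
            comps = {}
            for j, c in enumerate(active):
                M = np.zeros((T, T))
                v = x[nb + j * k : nb + (j + 1) * k]
                M[rows, cols] = v
                M[cols, rows] = v
                comps[c] = M
            return beta, comps

        def f(x):
            beta, comps = unpack(x)
            return loglikelihood(beta, comps, self.data)

        p = len(x0)
        h = 1e-4 * np.maximum(np.abs(x0), 1.0)
        H = np.zeros((p, p))
        f0 = f(x0)
        fp = np.zeros(p)
        fm = np.zeros(p)
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = h[i]
            fp[i] = f(x0 + ei)
            fm[i] = f(x0 - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(p):
            for j in range(i):
                ei = np.zeros(p)
                ej = np.zeros(p)
                ei[i] = h[i]
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j]
                    + f(x0 - ei - ej)
                ) / (2 * h[i] * h[j])
        cov = np.linalg.pinv(-H)
        return cov, names


def _profile_negloglik(theta, data: ModelData, active, T, cache=None):
    comps = _theta_to_components(theta, active, T)
    K = data.design.n_coef
    AtWA = np.zeros((K, K))
    AtWy = np.zeros(K)
    chols = []
    try:
        for b in data.blocks:
            sigma = b.assemble_sigma(comps)
            L = linalg.cholesky(sigma, lower=True)
            chols.append(L)
            WA = linalg.cho_solve((L, True), b.A)
            AtWA += b.A.T @ WA
            AtWy += WA.T @ b.y
    except linalg.LinAlgError:
        return np.inf, None
    try:
        beta = linalg.solve(AtWA, AtWy, assume_a="pos")
    except linalg.LinAlgError:
        beta = np.linalg.lstsq(AtWA, AtWy, rcond=None)[0]
    ll = 0.0
    for b, L in zip(data.blocks, chols):
        r = b.y - b.A @ beta
        z = linalg.solve_triangular(L, r, lower=True)
        ll += -0.5 * (2.0 * np.log(np.diag(L)).sum() + z @ z + b.m * LOG2PI)
    if cache is not None:
        cache["beta"] = beta
        cache["comps"] = comps
        cache["AtWA"] = AtWA
    return -ll, beta


def _profile_negloglik_and_grad(theta, data: ModelData, active, T):
    """Profiled negative loglikelihood and its analytic gradient.

    Beta is the GLS optimum at the current variance parameters, so by the
    envelope theorem the gradient only needs the partial derivative with
    beta held fixed:
    ``d(-L)/dSigma = (1/2)(Sigma^-1 - Sigma^-1 r r' Sigma^-1)`` contracted
    with each component's Kronecker pattern, then chained through the
    Cholesky parametrization C = L L'.
    """
    rows_i, cols_i = _vech_indices(T)
    k = len(rows_i)
    comps = _theta_to_components(theta, active, T)
    Lfacs = {}
    for j, name in enumerate(active):
        Lmat = np.zeros((T, T))
        Lmat[rows_i, cols_i] = theta[j * k : (j + 1) * k]
        Lfacs[name] = Lmat

    f, beta = _profile_negloglik(theta, data, active, T)
    if not np.isfinite(f):
        return f, np.zeros_like(theta)

    gC = {name: np.zeros((T, T)) for name in active}
    for b in data.blocks:
        sigma = b.assemble_sigma(comps)
        L = linalg.cholesky(sigma, lower=True)
        W = linalg.cho_solve((L, True), np.eye(b.m))
        u = linalg.cho_solve((L, True), b.y - b.A @ beta)
        sel = np.zeros((T, b.m))
        sel[b.cell_trait, np.arange(b.m)] = 1.0
        for name in active:
            M = b.structs[name]
            P = sel @ (W * M) @ sel.T
            su = sel * u
            R = su @ M @ su.T
            gC[name] += 0.5 * (P - R)
    grad = np.empty_like(theta)
    for j, name in enumerate(active):
        G = gC[name]
        dL = (G + G.T) @ Lfacs[name]
        grad[j * k : (j + 1) * k] = dL[rows_i, cols_i]
    return f, grad


def _initial_components(data: ModelData, active, T) -> dict[str, np.ndarray]:
    """Deterministic start: Sigma_e from OLS residual covariance, the
    additive component at half of it, other components a small multiple of
    its diagonal."""
    A_all = np.vstack([b.A for b in data.blocks])
    y_all = np.concatenate([b.y for b in data.blocks])
    beta0 = np.linalg.lstsq(A_all, y_all, rcond=None)[0]
    # per-trait residual covariance from pairwise-complete cells
    S = np.zeros((T, T))
    counts = np.zeros((T, T))
    for b in data.blocks:
        r = b.y - b.A @ beta0
        rmat = np.full((len(b.ind_idx), T), np.nan)
        rmat[b.cell_ind, b.cell_trait] = r
        obs = np.isfinite(rmat)
        rz = np.nan_to_num(rmat)
        S += rz.T @ rz
        counts += obs.astype(float).T @ obs.astype(float)
    counts = np.maximum(counts, 1.0)
    S = S / counts
    S = S + 1e-6 * np.mean(np.diag(S)) * np.eye(T)
    comps = {}
    for name in active:
        if name == "environmental":
            comps[name] = S if len(active) == 1 else S / 2.0
        elif name == "additive":
            comps[name] = S / 2.0
        else:
            comps[name] = 0.05 * np.diag(np.diag(S))
    return comps


def _check_identifiability(data: ModelData) -> list[str]:
    """With Phi = I/2 the additive kron block equals the environmental one
    and the two components are confounded."""
    flags = []
    if "additive" in data.spec.components:
        confounded = all(
            np.allclose(b.structs["additive"], b.structs["environmental"], atol=1e-10)
            for b in data.blocks
        )
        if confounded:
            flags.append("additive~environmental")
    return flags


def fit_null(
    spec_or_data,
    ped: Pedigree | None = None,
    traits: TraitTable | None = None,
    structures: dict[str, StructureMatrix] | None = None,
    init_components: dict[str, np.ndarray] | None = None,
    max_iter: int = 500,
) -> NullFit:
    """Maximize the loglikelihood over beta and the active variance
    components.

    Accepts either a prepared :class:`ModelData` or a
    (:class:`ModelSpec`, pedigree, traits, structures) quadruple.  Beta is
    profiled out by GLS at every variance iterate; components are
    parametrized through Cholesky factors so the search stays in the PSD
    cone.  Convergence requires a relative loglikelihood change below 1e-8
    and parameter change below 1e-6; the accepted-iterate loglikelihood
    trace is monotone non-decreasing.  Components estimated at the boundary
    (essentially zero) are flagged, not errors.
    """
    if isinstance(spec_or_data, ModelData):
        data = spec_or_data
    else:
        data = prepare_model_data(spec_or_data, ped, traits, structures)
    spec = data.spec
    T = spec.T
    active = list(spec.components)

    if data.design.n_coef:
        A_all = np.vstack([b.A for b in data.blocks])
        if np.linalg.matrix_rank(A_all) < data.design.n_coef:
            raise FitError("design matrix rank-deficient after constraint collapsing")

    non_ident = _check_identifiability(data)
    if non_ident:
        warnings.warn(
            "variance components confounded (kinship is I/2 — unrelated "
            f"individuals): {non_ident}",
            NonIdentifiableWarning,
        )

    comps0 = init_components or _initial_components(data, active, T)
    theta0 = _components_to_theta(comps0, active, T)

    trace: list[float] = []
    best = {"f": np.inf}

    def objective(theta):
        f, g = _profile_negloglik_and_grad(theta, data, active, T)
        if f < best["f"]:
            best["f"] = f
        return f, g

    def callback(theta):
        trace.append(-best["f"])

    f0, _ = _profile_negloglik(theta0, data, active, T)
    trace.append(-f0)
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9, "maxcor": 20},
    )
    if not res.success and res.status == 1:
        raise FitError(
            f"variance-component optimization did not converge in {max_iter} "
            "iterations",
            trace=trace,
        )

    cache: dict = {}
    f_final, _ = _profile_negloglik(res.x, data, active, T, cache=cache)
    beta = cache["beta"]
    comps = cache["comps"]
    trace.append(-f_final)

    # boundary detection: component contributes ~nothing relative to total
    scale = np.mean([np.trace(comps[c]) for c in active]) + 1e-300
    boundary = [c for c in active if np.trace(comps[c]) < 1e-6 * scale]

    # per-pedigree caches for score tests and outlier reports
    chols, resids, siginv_r, siginv_A = [], [], [], []
    ll_by_ped = {}
    for b in data.blocks:
        sigma = b.assemble_sigma(comps)
        L = linalg.cholesky(sigma, lower=True)
        r = b.y - b.A @ beta
        z = linalg.solve_triangular(L, r, lower=True)
        ll_by_ped[b.pedigree_id] = float(
            -0.5 * (2.0 * np.log(np.diag(L)).sum() + z @ z + b.m * LOG2PI)
        )
        chols.append(L)
        resids.append(r)
        siginv_r.append(linalg.cho_solve((L, True), r))
        siginv_A.append(linalg.cho_solve((L, True), b.A))
    AtWA = cache["AtWA"]
    AtWA_inv = np.linalg.pinv(AtWA)

    return NullFit(
        spec=spec,
        data=data,
        beta=beta,
        components=comps,
        loglik=float(-f_final),
        loglik_by_pedigree=ll_by_ped,
        trace=trace,
        converged=True,
        boundary_flags=boundary,
        non_identifiable=non_ident,
        chol=chols,
        resid=resids,
        siginv_r=siginv_r,
        siginv_A=siginv_A,
        AtWA_inv=AtWA_inv,
    )


# ---------------------------------------------------------------------------
# Outlier diagnostics
# ---------------------------------------------------------------------------


def pedigree_outlier_report(fit: NullFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank pedigrees and individuals by improbability under the fitted
    model.

    Pedigrees get the Mahalanobis statistic ``r' Sigma^-1 r`` with its
    observation count m and upper-tail chi-square probability.  Individuals
    get standardized conditional residuals (each observed trait entry given
    all other entries of its pedigree), aggregated as the largest absolute
    z-score.  Both tables are sorted most-outlying first.
    """
    ped_rows = []
    ind_rows = []
    for b, L, r, wr in zip(fit.data.blocks, fit.chol, fit.resid, fit.siginv_r):
        stat = float(r @ wr)
        ped_rows.append(
            {
                "pedigree_id": b.pedigree_id,
                "statistic": stat,
                "m": b.m,
                "p": float(stats.chi2.sf(stat, b.m)),
            }
        )
        siginv = linalg.cho_solve((L, True), np.eye(b.m))
        z = wr / np.sqrt(np.diag(siginv))
        for loc in range(b.m):
            ind_rows.append(
                {
                    "person_id": fit.data.ids[b.ind_idx[b.cell_ind[loc]]],
                    "trait": fit.spec.traits[b.cell_trait[loc]],
                    "z": float(z[loc]),
                }
            )
    ped_df = pd.DataFrame(ped_rows).sort_values("p", kind="stable").reset_index(
        drop=True
    )
    ind_df = pd.DataFrame(ind_rows)
    ind_df["abs_z"] = ind_df["z"].abs()
    ind_df = (
        ind_df.sort_values("abs_z", ascending=False, kind="stable")
        .drop(columns="abs_z")
        .reset_index(drop=True)
    )
    return ped_df, ind_df
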