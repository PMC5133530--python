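"""Synthetic pedigrees, gene-dropped genotypes, and model-faithful traits.

Every other module is testable without external data because this module
can generate (a) random non-inbred multi-generation pedigrees with
household structure, (b) genotypes dropped through the pedigree by random
Mendelian transmission from founder alleles, and (c) multivariate traits
drawn from exactly the variance-component covariance
``2 Sigma_a (x) Phi + Sigma_d (x) Delta7 + Sigma_h (x) H + Sigma_e (x) I``
with fixed effects and optional causal SNPs entering the mean.

A single seed fully determines all outputs; the random stream is consumed
in the fixed order pedigree -> genotypes -> traits, so regenerating a
prefix of the study reproduces it.

Default parameters mirror a blood-pressure family study: 20 extended
pedigrees, a bivariate (SBP, DBP)-like trait with additive and
environmental components ``Sigma_a = [[43.15, 17.03], [17.03, 12.07]]`` and
``Sigma_e = [[294.88, 113.90], [113.90, 102.61]]``, sex and age effects of
about (10.9, 4.6) and (0.43, -0.13), and SNP minor-allele frequencies
uniform on [0.05, 0.5].  Causal SNP effects enter the mean, matching how
SNPs are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pedio import Pedigree, GenotypeMatrix, TraitTable
from . import kinship as _kinship

__all__ = [
    "SimSpec",
    "simulate_pedigree",
    "gene_drop",
    "gene_drop_origins",
    "empirical_ibd_kinship",
    "simulate_traits",
    "simulate_study",
    "apply_missingness",
]

_DEFAULT_SIGMA_A = np.array([[43.15, 17.03], [17.03, 12.07]])
_DEFAULT_SIGMA_E = np.array([[294.88, 113.90], [113.90, 102.61]])


@dataclass
class SimSpec:
    """Parameters of a simulated study; the seed determines everything.

    ``n_unrelated > 0`` replaces the pedigree template with a cohort of
    singleton pedigrees.  ``beta`` maps a model term (``"1"``, a covariate
    name, or ``"a*b"``) to its per-trait effect vector; ``causal`` maps a
    SNP index to a per-trait mean shift per minor-allele copy.
    """

    n_pedigrees: int = 20
    founder_couples: int = 1
    generations: int = 3
    sibship_range: tuple[int, int] = (2, 4)
    n_unrelated: int = 0
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    traits: tuple[str, ...] = ("SBP", "DBP")
    beta: dict = field(
        default_factory=lambda: {
            "1": np.array([94.87, 78.46]),
            "sex": np.array([10.90, 4.62]),
            "age": np.array([0.43, -0.13]),
        }
    )
    components: dict = field(
        default_factory=lambda: {
            "additive": _DEFAULT_SIGMA_A.copy(),
            "environmental": _DEFAULT_SIGMA_E.copy(),
        }
    )
    causal: dict = field(default_factory=dict)
    trait_missing: float = 0.0
    covariate_missing: float = 0.0
    genotype_missing: float = 0.0
    seed: int = 0

    @property
    def T(self) -> int:
        return len(self.traits)

    def __post_init__(self):
        for name, M in self.components.items():
            w = np.linalg.eigvalsh(np.atleast_2d(np.asarray(M, dtype=float)))
            if w.min() < -1e-10:
                raise ValueError(f"component {name!r} is not PSD")


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


def simulate_pedigree(spec: SimSpec, rng: np.random.Generator) -> Pedigree:
    """Random non-inbred pedigrees with nuclear-family households.

    Each pedigree starts from founder couples; every child of a
    non-terminal generation marries an unrelated founder and reproduces,
    with sibship sizes uniform over ``sibship_range``.  Each individual's
    household is the nuclear family in which they are a parent, falling
    back to their family of origin.
    """
    records: list[dict] = []
    if spec.n_unrelated > 0:
        for i in range(spec.n_unrelated):
            records.append(
                {
                    "pedigree_id": f"U{i + 1}",
                    "person_id": f"U{i + 1}_1",
                    "father_id": None,
                    "mother_id": None,
                    "sex": "male" if rng.integers(2) else "female",
                    "household_id": f"U{i + 1}_h",
                }
            )
        return Pedigree.from_records(records)

    lo, hi = spec.sibship_range
    for p in range(spec.n_pedigrees):
        ped = f"P{p + 1}"
        counter = [0]
        house = [0]

        def new_id():
            counter[0] += 1
            return f"{ped}_{counter[0]}"

        def new_house():
            house[0] += 1
            return f"{ped}_h{house[0]}"

        couples = []
        for _ in range(spec.founder_couples):
            fa, mo = new_id(), new_id()
            hh = new_house()
            records.append(_rec(ped, fa, None, None, "male", hh))
            records.append(_rec(ped, mo, None, None, "female", hh))
            couples.append((fa, mo, hh))
        for gen in range(1, spec.generations):
            terminal = gen == spec.generations - 1
            next_couples = []
            for fa, mo, hh in couples:
                k = int(rng.integers(lo, hi + 1))
                for _ in range(k):
                    child = new_id()
                    sex = "male" if rng.integers(2) else "female"
                    if terminal:
                        records.append(_rec(ped, child, fa, mo, sex, hh))
                    else:
                        spouse = new_id()
                        chh = new_house()
                        records.append(_rec(ped, child, fa, mo, sex, chh))
                        records.append(
                            _rec(
                                ped,
                                spouse,
                                None,
                                None,
                                "female" if sex == "male" else "male",
                                chh,
                            )
                        )
                        if sex == "male":
                            next_couples.append((child, spouse, chh))
                        else:
                            next_couples.append((spouse, child, chh))
            couples = next_couples
    return Pedigree.from_records(records)


def _rec(ped, pid, fa, mo, sex, hh):
    return {
        "pedigree_id": ped,
        "person_id": pid,
        "father_id": fa,
        "mother_id": mo,
        "sex": sex,
        "household_id": hh,
    }


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def gene_drop_origins(
    ped: Pedigree, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    """Drop uniquely-labelled founder alleles; returns (n, 2, n_loci)
    integer labels.  Two entries are identical by descent iff their labels
    match."""
    n = ped.n
    origins = np.empty((n, 2, n_loci), dtype=np.int32)
    for i in range(n):
        f, m = ped.father[i], ped.mother[i]
        if f < 0:
            origins[i, 0] = 2 * i
            origins[i, 1] = 2 * i + 1
        else:
            pick_f = rng.integers(0, 2, size=n_loci)
            pick_m = rng.integers(0, 2, size=n_loci)
            origins[i, 0] = origins[f, pick_f, np.arange(n_loci)]
            origins[i, 1] = origins[m, pick_m, np.arange(n_loci)]
    return origins


def empirical_ibd_kinship(origins: np.ndarray) -> np.ndarray:
    """Monte Carlo kinship from labelled gene drops: the fraction of loci
    on which a randomly chosen allele from i is IBD to one from j,
    averaged over the four allele pairings."""
    n, _, S = origins.shape
    phi = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            match = 0.0
            for a in range(2):
                for b in range(2):
                    match += (origins[i, a] == origins[j, b]).mean()
            phi[i, j] = phi[j, i] = match / 4.0
    return phi


def gene_drop(
    ped: Pedigree,
    mafs: np.ndarray,
    rng: np.random.Generator,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Genotypes by random Mendelian transmission of founder alleles.

    Founder alleles are i.i.d. Bernoulli(maf) minor-allele indicators per
    locus; each child inherits one uniformly chosen allele from each
    parent, independently across loci.  Dosages are then oriented to the
    sample minor allele like any loaded genotype matrix.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("founder minor-allele frequencies must be in (0, 1/2]")
    n, S = ped.n, len(mafs)
    H = np.empty((n, 2, S), dtype=np.int8)
    for i in range(n):
        f, m = ped.father[i], ped.mother[i]
        if f < 0:
            H[i] = rng.random((2, S)) < mafs
        else:
            pick_f = rng.integers(0, 2, size=S)
            pick_m = rng.integers(0, 2, size=S)
            H[i, 0] = H[f, pick_f, np.arange(S)]
            H[i, 1] = H[m, pick_m, np.arange(S)]
    dosages = H.sum(axis=1).astype(float)
    p = dosages.mean(axis=0) / 2.0
    flip = p > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    minor = np.where(flip, "A", "B").astype(object)
    major = np.where(flip, "B", "A").astype(object)
    bp = np.arange(1, S + 1) * 1000
    return GenotypeMatrix(
        ids=ped.person_id.copy(),
        dosages=dosages,
        snp_ids=np.array([f"{chrom}-{b}" for b in bp], dtype=object),
        chrom=np.full(S, chrom, dtype=object),
        bp=bp,
        minor_allele=minor,
        major_allele=major,
        flipped=flip,
    )


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_traits(
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    spec: SimSpec,
    rng: np.random.Generator,
) -> TraitTable:
    """Traits drawn from the variance-component model.

    Covariates: ``sex`` (male = 1) from the pedigree and ``age`` ~
    N(45, 12^2).  The mean is ``A beta`` plus any causal-SNP contributions;
    the random part is multivariate normal per pedigree with the assembled
    component covariance in trait-major ordering.
    """
    n, T = ped.n, spec.T
    covs = {"sex": (ped.sex == "male").astype(float), "age": rng.normal(45.0, 12.0, n)}
    mean = np.zeros((n, T))
    for term, b in spec.beta.items():
        b = np.asarray(b, dtype=float)
        if term == "1":
            col = np.ones(n)
        else:
            col = np.ones(n)
            for v in term.split("*"):
                col = col * covs[v.strip()]
        mean += col[:, None] * b[None, :]
    if spec.causal:
        if geno is None:
            raise ValueError("causal SNP effects require a genotype matrix")
        pos = {pid: i for i, pid in enumerate(geno.ids)}
        rows = np.array([pos[pid] for pid in ped.person_id])
        for s, b in spec.causal.items():
            d = np.nan_to_num(geno.dosages[rows, s])
            mean += d[:, None] * np.asarray(b, dtype=float)[None, :]

    structures = {}
    if "additive" in spec.components:
        structures["additive"] = _kinship.theoretical_kinship(ped)
    if "dominance" in spec.components:
        structures["dominance"] = _kinship.delta7_matrix(ped)
    if "household" in spec.components:
        structures["household"] = _kinship.household_matrix(ped)

    Y = mean.copy()
    for members in ped.pedigree_blocks().values():
        m = len(members)
        sigma = np.zeros((T * m, T * m))
        for name, C in spec.components.items():
            C = np.atleast_2d(np.asarray(C, dtype=float))
            if name == "environmental":
                M = np.eye(m)
            else:
                M = structures[name].values[np.ix_(members, members)]
                if name == "additive":
                    M = 2.0 * M
            sigma += np.kron(C, M)  # trait-major: trait index outer
        w, V = np.linalg.eigh((sigma + sigma.T) / 2.0)
        root = V * np.sqrt(np.clip(w, 0.0, None))
        g = root @ rng.standard_normal(T * m)
        Y[members] += g.reshape(T, m).T

    traits = TraitTable(
        ids=ped.person_id.copy(),
        trait_names=list(spec.traits),
        traits=Y,
        covariate_names=["sex", "age"],
        covariates=np.column_stack([covs["sex"], covs["age"]]),
    )
    if spec.trait_missing > 0:
        mask = rng.random(traits.traits.shape) < spec.trait_missing
        traits.traits[mask] = np.nan
    if spec.covariate_missing > 0:
        mask = rng.random(traits.covariates.shape) < spec.covariate_missing
        traits.covariates[mask] = np.nan
    return traits


def apply_missingness(
    geno: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Return a copy with dosages set missing independently at ``rate``."""
    d = geno.dosages.copy()
    d[rng.random(d.shape) < rate] = np.nan
    return replace(geno, dosages=d)


def simulate_study(spec: SimSpec):
    """Generate (pedigree, genotypes, traits) from one seed, consuming the
    random stream in that order."""
    rng = np.random.default_rng(spec.seed)
    ped = simulate_pedigree(spec, rng)
    mafs = rng.uniform(*spec.maf_range, size=spec.n_snps)
    geno = gene_drop(ped, mafs, rng)
    if spec.genotype_missing > 0:
        geno = apply_missingness(geno, spec.genotype_missing, rng)
    traits = simulate_traits(ped, geno, spec, rng)
    return ped, geno, traits
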