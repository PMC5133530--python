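"""Per-SNP association against a fitted null model.

Each SNP enters the mean model as T extra fixed-effect columns (one per
trait, each holding the minor-allele dosage in that trait's slot) and the T
coefficients are tested jointly.  The workhorse is the score test: with the
variance parameters held at the null MLE it needs no iteration, so a
genome's worth of SNPs costs a few matrix products per pedigree.  The SNPs
with the smallest score p-values (top 10 by default) are re-tested by the
slower likelihood-ratio method, which re-maximizes everything including the
variance components and also yields per-trait SNP effect estimates.

Missing dosages are mean-imputed to 2*p_hat for testing only (never for
kinship estimation): it keeps each SNP's score evaluation a single vector
product, at a small, well-understood cost in power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pedio import GenotypeMatrix, SCAN_COLUMNS
from .vcmodel import NullFit, FitError, fit_null

__all__ = [
    "ScanResult",
    "ScanError",
    "score_test",
    "score_test_batch",
    "lrt",
    "gwas_scan",
    "genomic_inflation",
    "bonferroni_threshold",
    "bh_fdr_threshold",
]


class ScanError(RuntimeError):
    pass


@dataclass
class ScanResult:
    """Per-SNP scan table plus scan-level metadata.

    ``table`` has one row per input SNP in genome order with columns
    snp_id, chrom, bp, maf, hwe_p, score_stat, df, score_p, lrt_stat,
    lrt_p, filter_flag; ``metadata`` carries m_tested, the Bonferroni and
    FDR thresholds and the genomic inflation factor.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    snp_effects: dict = field(default_factory=dict)


def _impute_dosage(g: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean-impute missing dosages to 2*p_hat; returns (vector, maf)."""
    g = np.asarray(g, dtype=float)
    obs = np.isfinite(g)
    if not obs.any():
        return np.zeros_like(g), np.nan
    p = g[obs].mean() / 2.0
    out = g.copy()
    out[~obs] = 2.0 * p
    return out, float(min(p, 1.0 - p))


def score_test_batch(fit: NullFit, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score statistics for many SNPs at once.

    ``G`` is (n_analysis x S) with missing dosages already imputed.  Returns
    (statistics, p-values); SNPs whose information matrix is singular
    (dosage constant over the analyzed individuals) come back NaN.
    """
    T = fit.spec.T
    K = fit.data.design.n_coef
    S = G.shape[1]
    U = np.zeros((T, S))
    B1 = np.zeros((T, T, S))
    B2 = np.zeros((T, K, S))
    for b, L, wr, wA in zip(fit.data.blocks, fit.chol, fit.siginv_r, fit.siginv_A):
        gcell = G[b.ind_idx][b.cell_ind]  # m x S
        siginv = linalg.cho_solve((L, True), np.eye(b.m))
        idx = [np.flatnonzero(b.cell_trait == t) for t in range(T)]
        for t in range(T):
            if len(idx[t]) == 0:
                continue
            U[t] += wr[idx[t]] @ gcell[idx[t]]
            B2[t] += wA[idx[t]].T @ gcell[idx[t]]
            for u in range(t + 1):
                if len(idx[u]) == 0:
                    continue
                M = siginv[np.ix_(idx[t], idx[u])]
                vals = np.einsum("ms,ms->s", gcell[idx[t]], M @ gcell[idx[u]])
                B1[t, u] += vals
                if u != t:
                    B1[u, t] += vals
    stats_out = np.full(S, np.nan)
    pvals = np.full(S, np.nan)
    Ainv = fit.AtWA_inv
    spread = G.max(axis=0) - G.min(axis=0)
    constant = spread <= 1e-12 * np.maximum(1.0, np.abs(G).max(axis=0))
    for s in range(S):
        if constant[s]:
            continue
        V = B1[:, :, s] - B2[:, :, s] @ Ainv @ B2[:, :, s].T
        u = U[:, s]
        try:
            c = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError:
            continue
        if np.min(np.diag(c)) < 1e-10 * max(np.max(np.diag(c)), 1.0):
            continue
        z = linalg.solve_triangular(c, u, lower=True)
        stats_out[s] = z @ z
        pvals[s] = stats.chi2.sf(stats_out[s], T)
    return stats_out, pvals


def score_test(fit: NullFit, dosage: np.ndarray) -> tuple[float, int, float]:
    """T-df score test of one SNP against the null fit.

    ``dosage`` is aligned with the analysis individuals (``fit.data.ids``);
    missing values are mean-imputed.  Returns (statistic, df, p); a
    constant dosage yields (nan, T, nan).
    """
    g, _ = _impute_dosage(dosage)
    if len(g) != fit.data.n:
        raise ValueError(
            f"dosage length {len(g)} does not match the {fit.data.n} analyzed "
            "individuals"
        )
    s, p = score_test_batch(fit, g[:, None])
    return float(s[0]), fit.spec.T, float(p[0])


def lrt(
    fit: NullFit, dosage: np.ndarray, max_iter: int = 500
) -> tuple[float, int, float, np.ndarray, bool]:
    """Likelihood-ratio test of one SNP: the alternative model adds T SNP
    coefficients and re-maximizes everything, warm-started at the null
    variance components.

    Returns (Lambda, df, p, per-trait effect estimates, converged).  On
    alternative-fit non-convergence the statistic is NaN and the caller
    should fall back to the score test.
    """
    T = fit.spec.T
    g, _ = _impute_dosage(dosage)
    data_alt = fit.data.with_extra_columns(
        g, [f"snp:{tr}" for tr in fit.spec.traits]
    )
    try:
        alt = fit_null(data_alt, init_components=fit.components, max_iter=max_iter)
    except FitError:
        return np.nan, T, np.nan, np.full(T, np.nan), False
    lam = 2.0 * (alt.loglik - fit.loglik)
    if lam < -1e-6:
        raise AssertionError(
            f"LRT statistic {lam:.3g} < 0: alternative fit worse than null"
        )
    lam = max(lam, 0.0)
    effects = alt.beta[-T:]
    return float(lam), T, float(stats.chi2.sf(lam, T)), effects, True


def genomic_inflation(statistics, df: int) -> float:
    """lambda_GC = median observed statistic / median of the chi-square_df
    null distribution."""
    s = np.asarray(statistics, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(s) / stats.chi2.median(df))


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Family-wise threshold alpha/m and its -log10, the latter rounded to
    2 decimals for display."""
    if m < 1:
        raise ValueError("m must be >= 1")
    level = alpha / m
    return level, round(-np.log10(level), 2)


def bh_fdr_threshold(pvalues, q: float) -> float | None:
    """Benjamini-Hochberg step-up cutoff: the largest p_(i) with
    p_(i) <= (i/m) q, or None if nothing is discovered."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    m = len(p)
    if m == 0:
        return None
    ok = p <= (np.arange(1, m + 1) / m) * q
    if not ok.any():
        return None
    return float(p[np.flatnonzero(ok).max()])


def gwas_scan(
    fit: NullFit,
    geno: GenotypeMatrix,
    top_k: int = 10,
    maf_min: float = 0.0,
    maf_comparator: str = "lt",
    hwe_p: np.ndarray | None = None,
    filter_flags: np.ndarray | None = None,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> ScanResult:
    """Scan every SNP: score test for all testable SNPs, LRT refinement of
    the ``top_k`` smallest score p-values (ties broken by genome order),
    genomic inflation, Bonferroni and FDR thresholds.

    The MAF rule (threshold plus strict/inclusive comparator) and any
    upstream QC ``filter_flags`` exclude SNPs from testing but keep their
    rows in the output with the flag set and empty p fields.
    """
    ids_pos = {pid: i for i, pid in enumerate(geno.ids)}
    n = fit.data.n
    S = geno.n_snps
    # dosage rows aligned to analysis individuals; absent genotype -> missing
    G_raw = np.full((n, S), np.nan)
    have = np.array([pid in ids_pos for pid in fit.data.ids])
    src = np.array([ids_pos[pid] for pid in fit.data.ids[have]], dtype=int)
    G_raw[have] = geno.dosages[src]

    mafs = np.full(S, np.nan)
    G = np.empty_like(G_raw)
    for s in range(S):
        G[:, s], mafs[s] = _impute_dosage(G_raw[:, s])

    flags = np.array([""] * S, dtype=object)
    if filter_flags is not None:
        flags = np.array(
            [f if isinstance(f, str) else "" for f in filter_flags], dtype=object
        )
    if maf_comparator == "lt":
        low = mafs < maf_min
    elif maf_comparator == "le":
        low = mafs <= maf_min
    else:
        raise ValueError(f"unknown MAF comparator {maf_comparator!r}")
    low |= ~np.isfinite(mafs)
    flags = np.where((flags == "") & low, "low_maf", flags)

    testable = flags == ""
    if not testable.any():
        raise ScanError("no testable SNPs after the MAF rule")

    score_stat = np.full(S, np.nan)
    score_p = np.full(S, np.nan)
    stat_t, p_t = score_test_batch(fit, G[:, testable])
    score_stat[testable] = stat_t
    score_p[testable] = p_t
    undefined = testable & ~np.isfinite(score_stat)
    flags = np.where(undefined, "undefined_test", flags)

    tested = np.isfinite(score_p)
    m_tested = int(tested.sum())
    if m_tested == 0:
        raise ScanError("all testable SNPs had singular score information")

    # top-k refinement, ties by genome (input) order
    order = np.lexsort((np.arange(S), np.where(tested, score_p, np.inf)))
    refine = order[: min(top_k, m_tested)]
    lrt_stat = np.full(S, np.nan)
    lrt_p = np.full(S, np.nan)
    effects = {}
    for s in refine:
        lam, _, p, eff, ok = lrt(fit, G_raw[:, s])
        if ok:
            lrt_stat[s] = lam
            lrt_p[s] = p
            effects[geno.snp_ids[s]] = eff
        else:
            flags[s] = "lrt_nonconvergence"

    lam_gc = genomic_inflation(score_stat[tested], fit.spec.T)
    bonf_p, bonf_log = bonferroni_threshold(alpha, m_tested)
    fdr_cut = bh_fdr_threshold(score_p[tested], fdr_q)

    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.chrom,
            "bp": geno.bp,
            "maf": mafs,
            "hwe_p": hwe_p if hwe_p is not None else np.full(S, np.nan),
            "score_stat": score_stat,
            "df": np.where(tested, float(fit.spec.T), np.nan),
            "score_p": score_p,
            "lrt_stat": lrt_stat,
            "lrt_p": lrt_p,
            "filter_flag": flags,
        },
        columns=SCAN_COLUMNS,
    )
    metadata = {
        "m_tested": m_tested,
        "top_k": top_k,
        "df": fit.spec.T,
        "alpha": alpha,
        "bonferroni_p": bonf_p,
        "bonferroni_neglog10": bonf_log,
        "fdr_q": fdr_q,
        "fdr_cutoff": fdr_cut if fdr_cut is not None else "",
        "lambda_gc": lam_gc,
    }
    return ScanResult(table=table, metadata=metadata, snp_effects=effects)
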