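"""Quality control: call-rate filters, minor-allele frequencies, and the
Hardy-Weinberg exact test in founders.

The pipeline order is fixed and documented because survivor counts depend on
it: (1) SNPs failing the SNP call-rate threshold are dropped; (2) individual
call rates are computed on the surviving SNPs and failing individuals
dropped; (3) the MAF rule flags (default) or drops SNPs, with both the
threshold and its comparator configurable because different analyses use
strict ``< 0.03`` and inclusive ``<= 0.01`` rules; (4) founder-genotype HWE
p-values are computed for reporting.  HWE is report-only by default: a
grossly out-of-equilibrium SNP signals possible genotyping error and is
flagged, not silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedio import Pedigree, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "minor_allele_frequency",
    "hwe_exact_test",
    "run_qc",
]


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for :func:`run_qc`.

    Call-rate comparisons are strict ("below 98 %" excludes).  ``maf_min``
    with comparator ``"lt"`` excludes SNPs with MAF < maf_min; ``"le"``
    excludes MAF <= maf_min.  ``maf_action`` is ``"flag"`` (exclude from
    testing but keep the genotypes, the default) or ``"drop"``.
    ``hwe_min`` optionally hard-filters SNPs with founder HWE p below it.
    """

    ind_call_rate: float = 0.98
    snp_call_rate: float = 0.98
    maf_min: float = 0.03
    maf_comparator: str = "lt"
    maf_action: str = "flag"
    hwe_min: float | None = None


@dataclass
class QCReport:
    excluded_snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded_individuals: pd.DataFrame = field(default_factory=pd.DataFrame)
    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    individual_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def summary(self) -> str:
        lines = ["QC summary", "=========="]
        lines.append(f"thresholds: {self.thresholds}")
        if len(self.excluded_snps):
            counts = self.excluded_snps["reason"].value_counts()
            for reason, cnt in counts.items():
                lines.append(f"SNPs excluded ({reason}): {cnt}")
        else:
            lines.append("SNPs excluded: 0")
        if len(self.excluded_individuals):
            counts = self.excluded_individuals["reason"].value_counts()
            for reason, cnt in counts.items():
                lines.append(f"individuals excluded ({reason}): {cnt}")
        else:
            lines.append("individuals excluded: 0")
        lines.append(f"SNPs surviving: {len(self.snp_table)}")
        lines.append(f"individuals surviving: {len(self.individual_table)}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for line in self.summary().splitlines():
                fh.write(f"# {line}\n")
            self.snp_table.to_csv(fh, sep="\t", index=False)


def minor_allele_frequency(
    dosages: np.ndarray, subset: np.ndarray | None = None
) -> float:
    """MAF = min(p, 1-p) with p the sample frequency of the counted allele,
    optionally over a designated subset of individuals (e.g. founders)."""
    d = np.asarray(dosages, dtype=float)
    if subset is not None:
        d = d[subset]
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise QCError("MAF undefined: all dosages missing in the subset")
    p = d.sum() / (2.0 * d.size)
    return float(min(p, 1.0 - p))


def hwe_exact_pvalues(n_total: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact-test p-values for every heterozygote count compatible with the
    allele counts.

    Returns ``(hs, pvals)`` where ``hs`` runs over the support
    ``n_minor mod 2, ..., n_minor`` and ``pvals[k]`` is the two-sided exact
    p-value when ``hs[k]`` heterozygotes are observed: the total conditional
    probability of heterozygote counts no more probable than the observed
    one.  The distribution is evaluated in log space via the recurrence
    ``p(h+2)/p(h) = (m-h)(2n-m-h) / ((h+2)(h+1))``.
    """
    n, m = int(n_total), int(n_minor)
    if n < 1 or m < 0 or m > n:
        raise QCError("need total >= 1 and 0 <= n_minor <= total")
    if m == 0:
        return np.array([0]), np.array([1.0])
    hs = np.arange(m % 2, m + 1, 2)
    h = hs[:-1].astype(float)
    steps = np.log(m - h) + np.log(2 * n - m - h) - np.log(h + 2) - np.log(h + 1)
    logp = np.concatenate([[0.0], np.cumsum(steps)])
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    # p-value for each possible observation: cumulative sum in probability
    # order; a relative tolerance guards exact ties against rounding
    order = np.argsort(prob, kind="stable")
    csum = np.cumsum(prob[order])
    sorted_prob = prob[order]
    cutoffs = np.searchsorted(sorted_prob, prob * (1.0 + 1e-12), side="right")
    pvals = np.minimum(csum[np.maximum(cutoffs - 1, 0)], 1.0)
    out = np.empty_like(pvals)
    out[:] = pvals
    return hs, out


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact test of Hardy-Weinberg proportions from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one — the
    standard two-sided exact test.  Counts in the thousands are fine.
    Monomorphic samples give p = 1.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise QCError("genotype counts must be non-negative with total >= 1")
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    hs, pvals = hwe_exact_pvalues(n, n_minor)
    obs = np.searchsorted(hs, n_Aa)
    if obs >= len(hs) or hs[obs] != n_Aa:
        raise QCError(
            f"heterozygote count {n_Aa} incompatible with allele total {n_minor}"
        )
    return float(pvals[obs])


def run_qc(
    geno: GenotypeMatrix,
    ped: Pedigree,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, QCReport]:
    """Run the QC pipeline; returns (filtered genotypes, retained individual
    IDs, report).

    The returned :class:`GenotypeMatrix` keeps MAF-flagged SNPs unless
    ``maf_action="drop"``; the report's ``snp_table`` carries a
    ``filter_flag`` column ("" for testable SNPs, ``low_maf`` otherwise)
    which the scan honours.
    """
    thr = thresholds or QCThresholds()
    n0, s0 = geno.n, geno.n_snps
    if n0 == 0 or s0 == 0:
        raise QCError("empty genotype matrix")

    excluded_snps: list[dict] = []
    # (1) SNP call rate
    snp_cr = 1.0 - np.isnan(geno.dosages).mean(axis=0)
    bad_snp = snp_cr < thr.snp_call_rate
    for s in np.flatnonzero(bad_snp):
        excluded_snps.append(
            {
                "snp_id": geno.snp_ids[s],
                "reason": "snp_call_rate",
                "value": snp_cr[s],
            }
        )
    geno1 = geno.subset_snps(~bad_snp)
    if geno1.n_snps == 0:
        raise QCError("no SNPs survive the call-rate filter")

    # (2) individual call rate on surviving SNPs
    ind_cr = 1.0 - np.isnan(geno1.dosages).mean(axis=1)
    bad_ind = ind_cr < thr.ind_call_rate
    excluded_individuals = [
        {
            "person_id": geno1.ids[i],
            "reason": "individual_call_rate",
            "value": ind_cr[i],
        }
        for i in np.flatnonzero(bad_ind)
    ]
    geno2 = geno1.subset_individuals(~bad_ind)
    if geno2.n == 0:
        raise QCError("no individuals survive the call-rate filter")

    # (3) MAF over retained individuals
    mafs = np.array(
        [minor_allele_frequency(geno2.dosages[:, s]) for s in range(geno2.n_snps)]
    )
    if thr.maf_comparator == "lt":
        low = mafs < thr.maf_min
    elif thr.maf_comparator == "le":
        low = mafs <= thr.maf_min
    else:
        raise ValueError(f"unknown MAF comparator {thr.maf_comparator!r}")

    # (4) founder HWE (report-only unless hwe_min given)
    founder_ids = set(ped.person_id[ped.founder])
    is_founder = np.array([i in founder_ids for i in geno2.ids])
    hwe_p = np.empty(geno2.n_snps)
    for s in range(geno2.n_snps):
        d = geno2.dosages[is_founder, s]
        d = d[np.isfinite(d)]
        if d.size == 0:
            hwe_p[s] = np.nan
            continue
        hwe_p[s] = hwe_exact_test(
            int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())
        )

    flags = np.where(low, "low_maf", "")
    keep = np.ones(geno2.n_snps, dtype=bool)
    if thr.maf_action == "drop":
        keep &= ~low
        for s in np.flatnonzero(low):
            excluded_snps.append(
                {"snp_id": geno2.snp_ids[s], "reason": "low_maf", "value": mafs[s]}
            )
    if thr.hwe_min is not None:
        bad_hwe = np.nan_to_num(hwe_p, nan=1.0) < thr.hwe_min
        for s in np.flatnonzero(bad_hwe & keep):
            excluded_snps.append(
                {"snp_id": geno2.snp_ids[s], "reason": "hwe", "value": hwe_p[s]}
            )
        keep &= ~bad_hwe

    snp_table = pd.DataFrame(
        {
            "snp_id": geno2.snp_ids[keep],
            "chrom": geno2.chrom[keep],
            "bp": geno2.bp[keep],
            "call_rate": (1.0 - np.isnan(geno2.dosages).mean(axis=0))[keep],
            "maf": mafs[keep],
            "hwe_p": hwe_p[keep],
            "filter_flag": flags[keep],
        }
    )
    ind_table = pd.DataFrame(
        {
            "person_id": geno2.ids,
            "call_rate": 1.0 - np.isnan(geno2.dosages).mean(axis=1),
        }
    )
    geno_out = geno2.subset_snps(keep)
    if geno_out.n_snps == 0:
        raise QCError("no SNPs survive QC")
    report = QCReport(
        excluded_snps=pd.DataFrame(excluded_snps, columns=["snp_id", "reason", "value"]),
        excluded_individuals=pd.DataFrame(
            excluded_individuals, columns=["person_id", "reason", "value"]
        ),
        snp_table=snp_table,
        individual_table=ind_table,
        thresholds=thr,
    )
    return geno_out, geno_out.ids.copy(), report
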