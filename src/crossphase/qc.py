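"""Variant QC: MAF and Hardy-Weinberg equilibrium filters.

The defaults mirror common array-QC practice for phasing panels: keep
biallelic SNPs with minor allele frequency >= 5% whose genotype counts pass
a 1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions at
p > .0005.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .cohort import PhasedCohort, compute_allele_frequencies

log = logging.getLogger(__name__)


def hwe_chisq_pvalue(n_hom_ref: np.ndarray, n_het: np.ndarray, n_hom_alt: np.ndarray) -> np.ndarray:
    """1-df chi-square HWE goodness-of-fit p-values from genotype counts.

    Expected counts use the sample allele frequency
    ``p = (2*n_hom_alt + n_het) / 2N``; chi2 = sum((O-E)^2/E) over the three
    genotype classes, compared to a chi-square with one degree of freedom
    (three classes, one estimated parameter).  Monomorphic SNPs get p = 1.
    """
    n0 = np.asarray(n_hom_ref, dtype=float)
    n1 = np.asarray(n_het, dtype=float)
    n2 = np.asarray(n_hom_alt, dtype=float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        e0 = n * (1 - p) ** 2
        e1 = 2 * n * p * (1 - p)
        e2 = n * p**2
        chi2 = np.zeros_like(p)
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            chi2 = chi2 + term
    pval = stats.chi2.sf(chi2, df=1)
    return np.where((p == 0) | (p == 1), 1.0, pval)


def qc_filter(
    cohort: PhasedCohort,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.0005,
    include_ids: set[str] | None = None,
) -> PhasedCohort:
    """Return a cohort restricted to SNPs passing MAF and HWE filters.

    ``include_ids`` optionally restricts further to a user-supplied SNP
    id include-list (e.g. SNPs shared between genotyping arrays).  A
    chromosome losing all of its SNPs is a hard error.
    """
    compute_allele_frequencies(cohort)
    variants = {}
    haplotypes = {}
    for chrom in cohort.chromosomes:
        tab = cohort.variants[chrom]
        g = cohort.diploid(chrom)
        counts = np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)])
        pval = hwe_chisq_pvalue(counts[0], counts[1], counts[2])
        maf = tab["maf"].to_numpy(float)
        keep = (maf >= maf_min) & (maf > 0) & (pval > hwe_p_min)
        if not keep.any():
            raise ValueError(f"QC removed every SNP on {chrom}")
        n_removed = int((~keep).sum())
        if n_removed:
            log.info("%s: QC removed %d of %d SNPs", chrom, n_removed, len(tab))
        sub = tab.loc[keep].reset_index(drop=True)
        if include_ids is not None:
            mask = sub["id"].isin(include_ids).to_numpy()
            if not mask.any():
                raise ValueError(f"include-list removed every SNP on {chrom}")
            idx = np.flatnonzero(keep)[mask]
            sub = tab.loc[idx].reset_index(drop=True)
            keep = np.zeros(len(tab), dtype=bool)
            keep[idx] = True
        variants[chrom] = sub
        haplotypes[chrom] = cohort.haplotypes[chrom][:, :, keep].copy()
    out = PhasedCohort(list(cohort.sample_ids), variants, haplotypes)
    compute_allele_frequencies(out)
    return out
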