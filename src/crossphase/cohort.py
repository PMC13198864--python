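"""Phased-cohort data model.

A :class:`PhasedCohort` holds, per chromosome, a ``(2, n, m)`` array of
haplotype allele codes for ``n`` individuals at ``m`` SNPs, plus a variant
table.  Allele codes are 0/1 with 1 meaning the minor allele once
:func:`recode_minor` has been applied; the two haplotype slots (A = slot 0,
B = slot 1) are arbitrary per individual per chromosome and carry no
across-chromosome phase meaning until phasing assigns one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: columns every variant table carries
VARIANT_COLUMNS = ("pos", "id", "ref", "alt", "cM", "maf", "swapped")


def _normalise_variants(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True).copy()
    if "cM" not in df:
        df["cM"] = np.nan
    if "maf" not in df:
        df["maf"] = np.nan
    if "swapped" not in df:
        df["swapped"] = False
    if "id" not in df:
        df["id"] = [f"snp{i}" for i in range(len(df))]
    if "ref" not in df:
        df["ref"] = "A"
    if "alt" not in df:
        df["alt"] = "G"
    return df


@dataclass
class PhasedCohort:
    """Per-chromosome phased haplotypes for a cohort of individuals.

    Parameters
    ----------
    sample_ids : list of str
        Ordered cohort identifiers (length ``n``).
    variants : dict of str -> DataFrame
        Per chromosome, a table with at least a strictly increasing ``pos``
        column (1-based bp); ``cM``, ``maf``, ``id``, ``ref``, ``alt`` and
        ``swapped`` are filled with defaults when absent.
    haplotypes : dict of str -> ndarray
        Per chromosome, a ``(2, n, m)`` uint8 array of allele codes in {0, 1}.
    """

    sample_ids: list[str]
    variants: dict[str, pd.DataFrame]
    haplotypes: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.variants = {c: _normalise_variants(v) for c, v in self.variants.items()}
        n = len(self.sample_ids)
        for chrom, hap in self.haplotypes.items():
            hap = np.asarray(hap, dtype=np.uint8)
            m = len(self.variants[chrom])
            if hap.shape != (2, n, m):
                raise ValueError(
                    f"haplotype array for {chrom} has shape {hap.shape}, "
                    f"expected {(2, n, m)}"
                )
            if hap.max(initial=0) > 1:
                raise ValueError(f"allele codes on {chrom} must be 0 or 1")
            pos = self.variants[chrom]["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions on {chrom} are not strictly increasing")
            self.haplotypes[chrom] = hap

    # -- basic views ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.variants)

    @property
    def m(self) -> int:
        """Total SNP count across chromosomes."""
        return sum(len(v) for v in self.variants.values())

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def diploid(self, chrom: str) -> np.ndarray:
        """Diploid genotypes (``n x m`` array of 0/1/2) for one chromosome."""
        hap = self.haplotypes[chrom]
        return hap[0].astype(np.int16) + hap[1]

    def diploid_genome(self) -> np.ndarray:
        """Diploid genotypes concatenated over all chromosomes (``n x m_total``)."""
        return np.concatenate([self.diploid(c) for c in self.chromosomes], axis=1)

    def maf_genome(self) -> np.ndarray:
        return np.concatenate(
            [self.variants[c]["maf"].to_numpy(float) for c in self.chromosomes]
        )

    def copy(self) -> "PhasedCohort":
        return PhasedCohort(
            list(self.sample_ids),
            {c: v.copy() for c, v in self.variants.items()},
            {c: h.copy() for c, h in self.haplotypes.items()},
        )

    def subset_samples(self, sample_ids: list[str]) -> "PhasedCohort":
        idx = [self.sample_index(s) for s in sample_ids]
        return PhasedCohort(
            list(sample_ids),
            {c: v.copy() for c, v in self.variants.items()},
            {c: h[:, idx, :].copy() for c, h in self.haplotypes.items()},
        )


def compute_allele_frequencies(cohort: PhasedCohort) -> dict[str, np.ndarray]:
    """Compute per-SNP minor allele frequencies over all ``2n`` haplotypes.

    Stores ``maf = min(f1, 1 - f1)`` (``f1`` the frequency of allele code 1)
    into each chromosome's variant table and returns the per-chromosome maf
    arrays.  Monomorphic SNPs (maf exactly 0) are flagged in a boolean
    ``monomorphic`` column; they must be removed by QC before any similarity
    computation, which divides by ``p(1-p)``.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, hap in cohort.haplotypes.items():
        f1 = hap.mean(axis=(0, 1), dtype=float)
        maf = np.minimum(f1, 1.0 - f1)
        tab = cohort.variants[chrom]
        tab["maf"] = maf
        tab["monomorphic"] = maf == 0.0
        n_mono = int(tab["monomorphic"].sum())
        if n_mono:
            log.warning("%s: %d monomorphic SNP(s) flagged", chrom, n_mono)
        out[chrom] = maf
    return out


def recode_minor(cohort: PhasedCohort) -> dict[str, np.ndarray]:
    """Flip allele codes so code 1 is always the minor allele.

    SNPs whose code-1 frequency exceeds 0.5 have both haplotype slots
    complemented and their ``swapped`` flag toggled (so the original VCF
    REF/ALT orientation can be restored on write).  Frequencies are
    recomputed afterwards.  Returns the per-chromosome boolean flip masks.
    """
    flips: dict[str, np.ndarray] = {}
    for chrom, hap in cohort.haplotypes.items():
        f1 = hap.mean(axis=(0, 1), dtype=float)
        flip = f1 > 0.5
        if flip.any():
            hap[:, :, flip] = 1 - hap[:, :, flip]
            tab = cohort.variants[chrom]
            tab["swapped"] = tab["swapped"].to_numpy() ^ flip
        flips[chrom] = flip
    compute_allele_frequencies(cohort)
    return flips
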