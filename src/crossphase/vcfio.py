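"""Phased-VCF reading and writing.

Reading goes through cyvcf2; only biallelic SNP records with fully phased
``GT`` fields are accepted.  On load, allele codes are re-oriented so code 1
is always the minor allele (the similarity metrics weight matches by the
minor allele frequency); the original REF/ALT orientation is remembered and
restored on write.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import PhasedCohort, compute_allele_frequencies, recode_minor

log = logging.getLogger(__name__)


class UnphasedGenotypeError(ValueError):
    """A sample has an unphased or missing GT at a retained record."""


def read_phased_vcf(
    path,
    region: str | None = None,
    on_missing: str = "error",
) -> PhasedCohort:
    """Load a phased VCF into a :class:`PhasedCohort`.

    Parameters
    ----------
    path : str
        Path to a ``.vcf`` or ``.vcf.gz`` file with phased ``GT`` entries.
    region : str, optional
        Restrict to one chromosome label.
    on_missing : {"error", "drop"}
        Whether a missing call aborts the load or drops the whole record.

    Non-biallelic / non-SNP records are skipped with a logged count.  An
    unphased genotype is a hard error naming the record and sample.
    """
    from cyvcf2 import VCF

    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows: dict[str, list] = {}
    haps: dict[str, list] = {}
    n_skipped = 0
    n_dropped_missing = 0
    for var in vcf:
        chrom = str(var.CHROM)
        if region is not None and chrom != region:
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # per sample: [allele_a, allele_b, phased]
        codes = np.empty((2, len(samples)), dtype=np.int16)
        missing = False
        for j, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                if on_missing == "drop":
                    missing = True
                    break
                raise UnphasedGenotypeError(
                    f"missing genotype at {chrom}:{var.POS} for sample {samples[j]}"
                )
            if not phased:
                raise UnphasedGenotypeError(
                    f"unphased genotype at {chrom}:{var.POS} for sample {samples[j]}"
                )
            codes[0, j] = a
            codes[1, j] = b
        if missing:
            n_dropped_missing += 1
            continue
        rows.setdefault(chrom, []).append(
            (int(var.POS), var.ID or f"{chrom}:{var.POS}", var.REF, var.ALT[0])
        )
        haps.setdefault(chrom, []).append(codes)
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP record(s)", n_skipped)
    if n_dropped_missing:
        log.info("dropped %d record(s) with missing calls", n_dropped_missing)
    if not rows:
        raise ValueError(f"no usable phased biallelic SNP records in {path}")

    variants = {
        c: pd.DataFrame(r, columns=["pos", "id", "ref", "alt"]) for c, r in rows.items()
    }
    hap_arrays = {
        c: np.transpose(np.stack(h, axis=0), (1, 2, 0)).astype(np.uint8)
        for c, h in haps.items()  # (m, 2, n) -> (2, n, m)
    }
    cohort = PhasedCohort(samples, variants, hap_arrays)
    compute_allele_frequencies(cohort)
    recode_minor(cohort)
    return cohort


def write_phased_vcf(cohort: PhasedCohort, path, header_lines: list[str] | None = None) -> None:
    """Write a cohort back to a phased VCF (GT-only, uncompressed).

    The minor-allele recoding applied at load time is undone record by
    record via the ``swapped`` flag, so a read/write round trip preserves
    the original GT fields and sample order.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crossphase\n")
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        for chrom in cohort.chromosomes:
            last = int(cohort.variants[chrom]["pos"].iloc[-1])
            fh.write(f"##contig=<ID={chrom},length={last + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for chrom in cohort.chromosomes:
            tab = cohort.variants[chrom]
            hap = cohort.haplotypes[chrom]
            swapped = tab["swapped"].to_numpy()
            for k in range(len(tab)):
                a = hap[0, :, k]
                b = hap[1, :, k]
                if swapped[k]:
                    a = 1 - a
                    b = 1 - b
                gts = "\t".join(f"{x}|{y}" for x, y in zip(a, b))
                fh.write(
                    f"{chrom}\t{tab['pos'].iloc[k]}\t{tab['id'].iloc[k]}\t"
                    f"{tab['ref'].iloc[k]}\t{tab['alt'].iloc[k]}\t.\tPASS\t.\tGT\t{gts}\n"
                )
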