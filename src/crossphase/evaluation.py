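"""Trio-based ground truth and across-chromosome phasing accuracy (ACPA).

At SNPs where an offspring is heterozygous and at least one parent is
homozygous, the transmitting parent of each allele is determined by
Mendelian logic, giving a per-SNP parental-origin gold standard.  ACPA is
the percentage of those resolved sites at which the allele placed in
parental set 1 by across-chromosome phasing truly descends from one and
the same parent, under a single genome-wide mapping between the two
phased sets and the two (arbitrarily labelled) parents.  Perfect phasing
scores 100%; random assignment is expected to score 50%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PhasedCohort

log = logging.getLogger(__name__)

# origin codes per SNP (focal-heterozygous sites only carry calls)
NOT_SCORED = -1  # focal not heterozygous here
UNRESOLVED = 2  # all three trio members heterozygous
MENDELIAN_ERROR = 3
# codes 0/1 mean: parent 1 transmitted allele 0 (resp. 1)


@dataclass
class TrioTruth:
    """Per-SNP parental-origin calls for one focal individual.

    ``origin[chrom][k]`` is the allele transmitted by parent 1 at a
    resolved focal-heterozygous SNP, or one of the sentinel codes above.
    "Parent 1" / "parent 2" is an arbitrary labelling; nothing identifies
    which is maternal.
    """

    focal_id: str
    origin: dict[str, np.ndarray] = field(repr=False)

    def resolved_mask(self, chrom: str) -> np.ndarray:
        o = self.origin[chrom]
        return (o == 0) | (o == 1)

    @property
    def n_resolved(self) -> int:
        return int(sum(self.resolved_mask(c).sum() for c in self.origin))

    @property
    def n_mendelian_errors(self) -> int:
        return int(sum((self.origin[c] == MENDELIAN_ERROR).sum() for c in self.origin))


def trio_ground_truth(
    offspring_haplotypes: dict[str, np.ndarray],
    parent1_genotypes: dict[str, np.ndarray],
    parent2_genotypes: dict[str, np.ndarray],
    focal_id: str = "focal",
) -> TrioTruth:
    """Derive parental origin from parental diploid genotypes.

    ``offspring_haplotypes``: chrom -> (2, m) phased allele codes;
    parent genotypes: chrom -> (m,) diploid counts in {0, 1, 2}.  At each
    focal-heterozygous site, a homozygous parent forces the origin of the
    matching offspring allele (cross-checked against the other parent);
    triple-heterozygous sites are unresolved; impossible configurations
    are flagged as Mendelian errors.  A Mendelian-error rate above 1% of
    heterozygous sites triggers a hard warning (likely sample mismatch).
    """
    origin: dict[str, np.ndarray] = {}
    n_het = 0
    for chrom, haps in offspring_haplotypes.items():
        g_off = haps[0].astype(np.int16) + haps[1]
        g1 = np.asarray(parent1_genotypes[chrom])
        g2 = np.asarray(parent2_genotypes[chrom])
        o = np.full(g_off.shape, NOT_SCORED, dtype=np.int8)
        het = g_off == 1
        n_het += int(het.sum())

        p1_hom = (g1 == 0) | (g1 == 2)
        p2_hom = (g2 == 0) | (g2 == 2)
        a1 = (g1 // 2).astype(np.int8)  # allele a homozygous parent 1 must transmit
        a2 = (g2 // 2).astype(np.int8)

        # parent 1 homozygous: parent 1 transmits a1, parent 2 must supply 1-a1
        m = het & p1_hom
        o[m] = a1[m]
        bad = m & p2_hom & (a2 != 1 - a1)
        o[bad] = MENDELIAN_ERROR
        # parent 1 het, parent 2 homozygous: parent 2 transmits a2
        m = het & ~p1_hom & p2_hom
        o[m] = (1 - a2)[m]
        # all three heterozygous
        o[het & ~p1_hom & ~p2_hom] = UNRESOLVED
        origin[chrom] = o

    truth = TrioTruth(focal_id, origin)
    if n_het and truth.n_mendelian_errors / n_het > 0.01:
        warnings.warn(
            f"{focal_id}: Mendelian-error rate "
            f"{truth.n_mendelian_errors / n_het:.1%} exceeds 1% — possible sample mismatch",
            stacklevel=2,
        )
    return truth


@dataclass
class AcpaReport:
    """ACPA score for one focal individual.

    ``per_chromosome`` uses the same global set-1<->parent mapping as the
    genome-wide score and may therefore fall below 50% on individual
    chromosomes even when the genome-wide score cannot (``mapping="best"``).
    """

    focal_id: str
    acpa_percent: float
    per_chromosome: dict[str, float]
    n_scored_snps: int
    orientation_used: bool  # True when the globally better mapping was the flipped one
    mapping: str = "best"

    @property
    def perfect(self) -> bool:
        return self.acpa_percent == 100.0


def acpa(
    cohort: PhasedCohort,
    focal: str,
    truth: TrioTruth,
    mapping: str = "best",
) -> AcpaReport:
    """Score across-chromosome phasing of one focal individual against truth.

    For every resolved site, the allele in haplotype slot 0 either matches
    the allele parent 1 transmitted or it does not.  With
    ``mapping="best"`` the global set-1<->parent correspondence is chosen
    once, genome-wide, to maximize agreement (scores land in [50, 100]);
    with ``mapping="fixed"`` the arbitrary truth labelling is kept as is,
    which is the convention under which random assignment scores 50% in
    expectation.
    """
    if mapping not in ("best", "fixed"):
        raise ValueError("mapping must be 'best' or 'fixed'")
    f = cohort.sample_index(focal)
    agree: dict[str, np.ndarray] = {}
    for chrom in truth.origin:
        res = truth.resolved_mask(chrom)
        if not res.any():
            continue
        slot0 = cohort.haplotypes[chrom][0, f]
        agree[chrom] = slot0[res] == truth.origin[chrom][res]
    total = sum(a.size for a in agree.values())
    if total == 0:
        raise ValueError(f"no resolved site to score for {focal}")
    n_match = sum(int(a.sum()) for a in agree.values())
    prop = n_match / total
    flipped = mapping == "best" and prop < 0.5
    if flipped:
        prop = 1.0 - prop
    per_chrom = {
        c: 100.0 * float((~a if flipped else a).mean()) for c, a in agree.items()
    }
    return AcpaReport(
        focal_id=focal,
        acpa_percent=100.0 * prop,
        per_chromosome=per_chrom,
        n_scored_snps=total,
        orientation_used=flipped,
        mapping=mapping,
    )


def summarize_acpa(reports: list[AcpaReport]) -> dict[str, float]:
    """Cohort-level summary: mean, median and share of perfectly phased."""
    vals = np.array([r.acpa_percent for r in reports])
    return {
        "n": int(vals.size),
        "mean_acpa": float(vals.mean()),
        "median_acpa": float(np.median(vals)),
        "fraction_perfect": float(np.mean([r.perfect for r in reports])),
    }


def restrict_truth(truth: TrioTruth, full_cohort, sub_cohort) -> TrioTruth:
    """Project truth onto a cohort whose SNPs are a subset (e.g. after QC)."""
    origin = {}
    for chrom in sub_cohort.chromosomes:
        keep_pos = sub_cohort.variants[chrom]["pos"].to_numpy()
        full_pos = full_cohort.variants[chrom]["pos"].to_numpy()
        idx = np.searchsorted(full_pos, keep_pos)
        origin[chrom] = truth.origin[chrom][idx].copy()
    return TrioTruth(truth.focal_id, origin)


# canonical expected pihat by relatedness degree; bins cut at midpoints
_DEGREE_EDGES = (
    ("1st", 0.375),
    ("2nd", 0.1875),
    ("3rd", 0.09375),
    ("4th", 0.046875),
)


def relatedness_stratum(max_pihat: float) -> str:
    for name, lo in _DEGREE_EDGES:
        if max_pihat >= lo:
            return name
    return "unrelated"


def stratify_by_relatedness(
    reports: list[AcpaReport], cohort: PhasedCohort
) -> pd.DataFrame:
    """Group focal individuals by their closest relative's pihat degree.

    For each focal individual the maximum pihat to any non-focal cohort
    member decides the stratum (1st/2nd/3rd/4th degree or unrelated, cut
    at midpoints between the canonical expectations 0.5, 0.25, 0.125,
    0.0625); mean and median ACPA are reported per stratum.
    """
    from .similarity import pihat_to_all

    rows = []
    for rep in reports:
        ph = pihat_to_all(cohort, rep.focal_id)
        ph[cohort.sample_index(rep.focal_id)] = -np.inf
        rows.append(
            dict(
                focal=rep.focal_id,
                stratum=relatedness_stratum(float(ph.max())),
                acpa=rep.acpa_percent,
            )
        )
    tab = pd.DataFrame(rows, columns=["focal", "stratum", "acpa"])
    if tab.empty:
        return pd.DataFrame(columns=["stratum", "n", "mean_acpa", "median_acpa"])
    out = (
        tab.groupby("stratum")["acpa"]
        .agg(n="size", mean_acpa="mean", median_acpa="median")
        .reset_index()
    )
    return out
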