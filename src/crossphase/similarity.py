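"""SNP similarity metrics: diploid relatedness and windowed haploid similarity.

Three statistics drive the phasing method:

* ``pihat`` — the standard genome-wide diploid relatedness (the GRM
  off-diagonal): ``(1/m) * sum_k (x_kf - 2 p_k)(x_ki - 2 p_k) / (2 p_k (1 - p_k))``
  with ``p_k`` the minor allele frequency.  Expected ~0.5 for
  parent-offspring, ~0.25 for 2nd-degree pairs, ~0 for unrelateds.  It is
  used only to exclude close relatives (``pihat >= 0.33``) from the partner
  pool, so accuracy estimates reflect cohorts without first-degree kin.

* ``psi_window`` (psi-hat) — a haploid, window-restricted similarity between
  one focal haplotype and one partner haplotype.  Both haplotypes are
  restricted to sites where the focal individual is heterozygous (the only
  phase-informative sites); over the longest contiguous run of identical
  alleles among those sites, the per-site terms
  ``((x_k - p_k)^2 / (p_k (1 - p_k)))^(1/5)`` are summed.  Because the run
  contains only identical alleles and p_k <= 0.5, every term is
  non-negative.  The 1/5 exponent damps the otherwise outsized weight of
  rare-allele matches; summing (rather than averaging) lets long stretches
  of haplotypic identity — the fingerprint of IBD sharing — dominate.

* ``psi_star`` — per window and focal haplotype, the larger of the psi-hat
  values against the partner's two haplotypes, then raised to a power
  (default 2) to sharpen the contrast between background similarity and
  IBD-driven similarity.  Taking the max per window makes the statistic
  robust to switch errors in *partner* phasing: each window is free to
  match either partner haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import best_run_sums
from .cohort import PhasedCohort
from .windows import WindowSet

log = logging.getLogger(__name__)

DEFAULT_TERM_EXPONENT = 1.0 / 5.0
DEFAULT_STAR_POWER = 2.0
DEFAULT_PIHAT_MAX = 0.33


# ---------------------------------------------------------------------------
# diploid relatedness
# ---------------------------------------------------------------------------

def pihat(focal_diploid, other_diploid, maf) -> float:
    """Genome-wide diploid SNP relatedness between two individuals."""
    x_f = np.asarray(focal_diploid, dtype=float)
    x_i = np.asarray(other_diploid, dtype=float)
    p = np.asarray(maf, dtype=float)
    if x_f.shape != x_i.shape or x_f.shape != p.shape:
        raise ValueError("genotype and maf vectors must share one length")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("maf must lie strictly between 0 and 1 (run QC first)")
    m = x_f.size
    return float(((x_f - 2 * p) * (x_i - 2 * p) / (2 * p * (1 - p))).sum() / m)


def pihat_to_all(cohort: PhasedCohort, focal: str) -> np.ndarray:
    """pihat between the focal individual and every cohort member (self = diagonal).

    Accumulated chromosome by chromosome in single precision to keep the
    standardized-genotype working set small at biobank-like SNP counts.
    """
    f = cohort.sample_index(focal)
    total = np.zeros(cohort.n)
    m = 0
    for chrom in cohort.chromosomes:
        p = cohort.variants[chrom]["maf"].to_numpy(float)
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("cohort contains monomorphic SNPs; run QC first")
        g = cohort.diploid(chrom).astype(np.float32)
        z = (g - np.float32(2) * p.astype(np.float32)) / np.sqrt(
            2 * p * (1 - p)
        ).astype(np.float32)
        total += (z @ z[f]).astype(float)
        m += g.shape[1]
    return total / m


def exclude_close_relatives(
    cohort: PhasedCohort, focal: str, threshold: float = DEFAULT_PIHAT_MAX
) -> tuple[list[str], list[str]]:
    """Split non-focal individuals into (partners, excluded) by pihat.

    Partners are those with ``pihat(focal, i) < threshold``; the default
    0.33 removes parents, offspring and full siblings while retaining
    2nd-degree and more distant relatives, whose sharing is exactly the
    signal the phasing method exploits.
    """
    ph = pihat_to_all(cohort, focal)
    f = cohort.sample_index(focal)
    partners, excluded = [], []
    for i, s in enumerate(cohort.sample_ids):
        if i == f:
            continue
        (partners if ph[i] < threshold else excluded).append(s)
    if not partners:
        raise ValueError(f"no partners below pihat {threshold} for {focal}; phasing impossible")
    return partners, excluded


# ---------------------------------------------------------------------------
# windowed haploid similarity
# ---------------------------------------------------------------------------

def _match_terms(focal_hap: np.ndarray, p: np.ndarray, exponent: float) -> np.ndarray:
    """Per-site term value, valid wherever a partner allele equals the focal's."""
    t = (focal_hap.astype(float) - p) ** 2 / (p * (1 - p))
    if (t < 0).any():  # cannot happen for codes in {0,1} and p in (0,1)
        raise AssertionError("negative similarity term")
    return t**exponent


def psi_window(
    focal_hap,
    other_hap,
    het_mask,
    maf,
    exponent: float = DEFAULT_TERM_EXPONENT,
) -> float:
    """Haploid similarity of two haplotypes within one window.

    Reference (pure NumPy) implementation: restrict both haplotypes to the
    focal-heterozygous sites, locate the longest contiguous run of
    identical alleles (ties: larger term sum, then leftmost), and return
    the summed, 1/5-exponentiated per-site terms over that run.  Returns
    0.0 when no site matches or the window has no heterozygous site.
    """
    het = np.asarray(het_mask, dtype=bool)
    fh = np.asarray(focal_hap)[het]
    oh = np.asarray(other_hap)[het]
    p = np.asarray(maf, dtype=float)[het]
    if fh.size == 0:
        return 0.0
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("maf must lie strictly in (0, 1)")
    match = fh == oh
    if not match.any():
        return 0.0
    terms = np.where(match, _match_terms(fh, p, exponent), 0.0)
    # maximal runs of True
    edges = np.diff(np.concatenate(([0], match.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    best = 0.0
    best_len = 0
    for a, b in zip(starts, stops):
        length = b - a
        s = float(terms[a:b].sum())
        if length > best_len or (length == best_len and s > best):
            best_len = length
            best = s
    return best


def psi_star(
    focal_hap_slot: int,
    focal: str,
    partner: str,
    window,
    cohort: PhasedCohort,
    exponent: float = DEFAULT_TERM_EXPONENT,
    power: float = DEFAULT_STAR_POWER,
) -> float:
    """Max-over-partner-haplotypes windowed similarity, raised to ``power``."""
    chrom = window.chrom
    sl = slice(window.snp_start, window.snp_stop)
    f = cohort.sample_index(focal)
    i = cohort.sample_index(partner)
    hap = cohort.haplotypes[chrom]
    het = cohort.diploid(chrom)[f, sl] == 1
    maf = cohort.variants[chrom]["maf"].to_numpy(float)[sl]
    fh = hap[focal_hap_slot, f, sl]
    vals = [psi_window(fh, hap[s, i, sl], het, maf, exponent) for s in (0, 1)]
    return max(vals) ** power


@dataclass
class PsiStarTensor:
    """psi-star values for one focal individual.

    ``values[s, w, j]`` is psi-star between focal haplotype slot ``s``
    (A = 0, B = 1) in window ``w`` and partner ``partner_ids[j]``; the
    partner axis is identical for every (haplotype, window) pair.  Windows
    with no focal-heterozygous SNP carry all-zero vectors and are flagged
    unusable for the correlation stage.
    """

    focal_id: str
    partner_ids: list[str]
    excluded_ids: list[str]
    windows: WindowSet
    values: np.ndarray = field(repr=False)  # (2, W, P)
    usable: np.ndarray = field(repr=False)  # (W,)

    def vectors(self, w: int) -> tuple[np.ndarray, np.ndarray]:
        """The (A, B) partner-axis vectors of window ``w``."""
        return self.values[0, w], self.values[1, w]


def build_psi_star_tensor(
    cohort: PhasedCohort,
    focal: str,
    windows: WindowSet,
    partners: list[str] | None = None,
    pihat_max: float = DEFAULT_PIHAT_MAX,
    exponent: float = DEFAULT_TERM_EXPONENT,
    power: float = DEFAULT_STAR_POWER,
) -> PsiStarTensor:
    """Fill the full ``(2, W, partners)`` psi-star tensor for one focal.

    When ``partners`` is not given, the pool is every non-focal individual
    with ``pihat < pihat_max``.  Deterministic given its inputs.
    """
    if partners is None:
        partners, excluded = exclude_close_relatives(cohort, focal, pihat_max)
    else:
        excluded = []
    f = cohort.sample_index(focal)
    pidx = np.array([cohort.sample_index(s) for s in partners])
    W = len(windows)
    P = len(partners)
    values = np.zeros((2, W, P))
    usable = np.ones(W, dtype=bool)
    n_empty = 0
    for w in windows:
        chrom = w.chrom
        sl = slice(w.snp_start, w.snp_stop)
        hap = cohort.haplotypes[chrom]
        het = (hap[0, f, sl].astype(np.int16) + hap[1, f, sl]) == 1
        if not het.any():
            usable[w.index] = False
            n_empty += 1
            continue
        p = cohort.variants[chrom]["maf"].to_numpy(float)[sl][het]
        block = hap[:, pidx, sl][:, :, het]  # (2, P, L)
        flat = block.reshape(2 * P, -1)
        for s in (0, 1):
            fh = hap[s, f, sl][het]
            terms = _match_terms(fh, p, exponent)
            sums = best_run_sums(flat == fh, terms)
            psi = sums.reshape(2, P)
            values[s, w.index] = np.maximum(psi[0], psi[1]) ** power
    if n_empty:
        log.warning("%s: %d window(s) without focal-heterozygous SNPs", focal, n_empty)
    return PsiStarTensor(focal, list(partners), list(excluded), windows, values, usable)
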