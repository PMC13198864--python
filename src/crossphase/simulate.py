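"""Synthetic phased cohorts with known parental origin.

The generator emulates the ingredients the phasing method feeds on:

* founder haplotypes drawn site-independently at configurable minor
  allele frequencies (optionally from two diverged subpopulations, to
  emulate parental-generation stratification);
* Mendelian transmission with crossovers placed by genetic distance
  (Poisson count with mean = map length / 100 cM, no interference,
  uniform on the cM axis);
* configurable pedigrees: each focal individual is a trio offspring and
  may be given 2nd-, 3rd- or 4th-degree relatives built through a shared
  grandparental couple (uncle/aunt, first cousin, cousin once removed);
* injected within-chromosome switch errors: at each heterozygous site,
  with a configured probability, the two haplotypes swap from that site
  to the chromosome end — the standard switch-error model of phasing
  pipelines.

Because transmissions are simulated, the parental origin of every focal
allele is known exactly, giving gap-free ground truth for ACPA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import PhasedCohort, compute_allele_frequencies
from .evaluation import NOT_SCORED, TrioTruth
from .gmap import RecombinationMap

log = logging.getLogger(__name__)


@dataclass
class SubpopulationConfig:
    """Two founder populations with Balding-Nichols allele-frequency divergence.

    The two parents of every focal individual are drawn from different
    subpopulations; unrelated individuals split evenly between the two.
    """

    fst: float = 0.05


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``relative_degrees`` lists, per focal individual, the degrees of
    planted relatives (2 = uncle/aunt through a shared grandparental
    couple, 3 = first cousin, 4 = first cousin once removed); sides
    alternate, the first relative attaching to parent 1's lineage, the
    second to parent 2's, and so on.  ``n_focal_no_relatives`` adds focal
    trios without any planted relative, for stratified comparisons.
    """

    seed: int = 0
    n_unrelated: int = 1920
    n_focal: int = 24
    relative_degrees: tuple[int, ...] = (2, 3)
    n_focal_no_relatives: int = 8
    n_chromosomes: int = 6
    snps_per_chromosome: int = 7000
    chromosome_length_cM: float = 80.0
    chromosome_length_bp: int = 100_000_000
    map_anchors_per_chromosome: int = 51
    map_region_spacing_cM: float = 40.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    switch_error_rate: float = 0.0
    include_parents: bool = False
    subpopulations: SubpopulationConfig | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.switch_error_rate < 1:
            raise ValueError("switch_error_rate must lie in [0, 1)")
        if min(self.n_unrelated, self.n_focal, self.n_focal_no_relatives) < 0:
            raise ValueError("counts must be non-negative")
        if any(d not in (1, 2, 3, 4) for d in self.relative_degrees):
            raise ValueError("relative degrees must be in {1, 2, 3, 4}")


@dataclass
class SimulatedCohort:
    """A synthetic cohort plus everything needed to score phasing on it."""

    cohort: PhasedCohort
    gmap: RecombinationMap
    truth: dict[str, TrioTruth]
    parents: dict[str, tuple[str, str]]
    parent_genotypes: dict[str, dict[str, np.ndarray]] = field(repr=False)
    relatives: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    switch_positions: dict = field(default_factory=dict, repr=False)
    config: SimulationConfig | None = None

    @property
    def focal_ids(self) -> list[str]:
        return list(self.truth)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def simulate_genetic_map(
    rng: np.random.Generator,
    length_cM: float,
    length_bp: int,
    n_anchors: int = 51,
    region_spacing_cM: float = 40.0,
) -> pd.DataFrame:
    """Anchor table (bp, cM) with spatially clustered recombination heat.

    Pedigree-based human maps show their strongest cM/Mb intervals
    clustered in a handful of hot regions per chromosome (often near the
    telomeres), not scattered uniformly; published hotspot-bounded window
    sets average ~44 cM per window for that reason.  The generator draws
    one hot region per ``region_spacing_cM`` of map length, boosts the
    rate of nearby anchor intervals ~30-fold over a heavy-tailed cold
    background, and normalises increments to the requested genetic length.
    """
    bp = np.linspace(1, length_bp, n_anchors).astype(np.int64)
    n_int = n_anchors - 1
    rate = rng.gamma(1.0, 1.0, size=n_int) + 0.05
    n_regions = max(1, int(round(length_cM / region_spacing_cM)))
    centers = rng.uniform(0.05, 0.95, size=n_regions) * n_int
    width = max(1.5, n_int * 0.04)
    x = np.arange(n_int)
    for c in centers:
        rate = rate * (1.0 + 30.0 * np.exp(-0.5 * ((x - c) / width) ** 2))
    inc = rate / rate.sum() * length_cM
    cm = np.concatenate([[0.0], np.cumsum(inc)])
    return pd.DataFrame({"bp": bp, "cM": cm})


def simulate_founders(
    rng: np.random.Generator, freqs: np.ndarray, n: int
) -> np.ndarray:
    """``(2, n, m)`` founder haplotypes, alleles independent Bernoulli(freq)."""
    return (rng.random((2, n, freqs.size)) < freqs).astype(np.uint8)


def meiosis(
    parent_hapA: np.ndarray,
    parent_hapB: np.ndarray,
    positions_cM: np.ndarray,
    length_cM: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's haplotype pair.

    Crossover count ~ Poisson(length_cM / 100), positions uniform on the
    cM axis, no interference; the starting haplotype is a fair coin.
    Returns the gamete and the crossover positions (cM).
    """
    n_x = rng.poisson(length_cM / 100.0)
    xpos = np.sort(rng.uniform(0.0, length_cM, size=n_x))
    start = int(rng.integers(2))
    seg = (start + np.searchsorted(xpos, positions_cM, side="right")) % 2
    gamete = np.where(seg == 0, parent_hapA, parent_hapB).astype(np.uint8)
    return gamete, xpos


def _child(haps_a: dict, haps_b: dict, meta: dict, rng) -> dict:
    """Gametes per chromosome from two parents' haplotype dicts."""
    out = {}
    for chrom, (pos_cm, length) in meta.items():
        g_a, _ = meiosis(haps_a[chrom][0], haps_a[chrom][1], pos_cm, length, rng)
        g_b, _ = meiosis(haps_b[chrom][0], haps_b[chrom][1], pos_cm, length, rng)
        out[chrom] = np.stack([g_a, g_b])
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def build_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort per ``config``; deterministic under its seed.

    The analysis cohort holds focal individuals, their planted relatives
    and unrelated fill (plus the parents when ``include_parents`` is set —
    by default parents exist only as ground-truth genotypes, mirroring
    evaluation designs that drop first-degree relatives before phasing).
    Haplotype slot order is randomised per individual per chromosome, so
    slots carry no across-chromosome phase information by construction.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    anchors = {}
    variants = {}
    meta = {}
    freqs: dict[str, np.ndarray] = {}
    pop_freqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        anchors[chrom] = simulate_genetic_map(
            rng, config.chromosome_length_cM, config.chromosome_length_bp,
            config.map_anchors_per_chromosome, config.map_region_spacing_cM,
        )
        pos = np.unique(
            rng.integers(1, config.chromosome_length_bp, size=2 * config.snps_per_chromosome)
        )
        while pos.size < config.snps_per_chromosome:  # extremely unlikely top-up
            extra = rng.integers(1, config.chromosome_length_bp, size=config.snps_per_chromosome)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=config.snps_per_chromosome, replace=False))
        gmap_one = RecombinationMap({chrom: anchors[chrom]})
        pos_cm = gmap_one.interpolate(chrom, pos)
        variants[chrom] = pd.DataFrame(
            {"pos": pos, "id": [f"{chrom}:{p}" for p in pos], "cM": pos_cm}
        )
        meta[chrom] = (pos_cm, config.chromosome_length_cM)
        p = rng.uniform(*config.maf_range, size=config.snps_per_chromosome)
        freqs[chrom] = p
        if config.subpopulations is not None:
            f = config.subpopulations.fst
            a = p * (1 - f) / f
            b = (1 - p) * (1 - f) / f
            pop_freqs[chrom] = (
                np.clip(rng.beta(a, b), 0.01, 0.99),
                np.clip(rng.beta(a, b), 0.01, 0.99),
            )
    gmap = RecombinationMap(anchors)

    def draw_founder(pop: int | None) -> dict:
        out = {}
        for chrom in chroms:
            p = freqs[chrom] if pop is None else pop_freqs[chrom][pop]
            out[chrom] = (rng.random((2, p.size)) < p).astype(np.uint8)
        return out

    two_pops = config.subpopulations is not None
    samples: list[str] = []
    haps: list[dict] = []
    truth: dict[str, TrioTruth] = {}
    parents: dict[str, tuple[str, str]] = {}
    parent_genotypes: dict[str, dict[str, np.ndarray]] = {}
    relatives: dict[str, list[tuple[str, int]]] = {}

    def add(sample_id: str, h: dict) -> None:
        samples.append(sample_id)
        haps.append(h)

    n_focal_total = config.n_focal + config.n_focal_no_relatives
    for i in range(n_focal_total):
        with_rel = i < config.n_focal
        fid = f"focal{i:04d}"
        degrees = config.relative_degrees if with_rel else ()
        # one lineage per parental side; grandparents exist only when a
        # relative hangs off that side
        side_pop = (0, 1) if two_pops else (None, None)
        par_haps = []
        rel_list: list[tuple[str, int]] = []
        parent_in_cohort = [False, False]
        for side in (0, 1):
            side_degrees = [d for j, d in enumerate(degrees) if j % 2 == side]
            if any(d >= 2 for d in side_degrees):
                # relatives attach through this side's grandparental couple
                g1 = draw_founder(side_pop[side])
                g2 = draw_founder(side_pop[side])
                parent = _child(g1, g2, meta, rng)
                for j, d in enumerate(side_degrees):
                    if d < 2:
                        continue
                    anc = _child(g1, g2, meta, rng)  # uncle/aunt (2nd degree)
                    for _ in range(d - 2):  # extend: cousin, then once removed
                        anc = _child(anc, draw_founder(side_pop[side]), meta, rng)
                    rid = f"rel{i:04d}_s{side}_{j}_d{d}"
                    add(rid, anc)
                    rel_list.append((rid, d))
            else:
                parent = draw_founder(side_pop[side])
            if 1 in side_degrees:  # a degree-1 "relative" is the parent itself
                parent_in_cohort[side] = True
                rel_list.append((f"p{i:04d}_{side + 1}", 1))
            par_haps.append(parent)

        p1, p2 = par_haps
        # focal gametes: one from each parent
        focal_h = {}
        origin = {}
        for chrom in chroms:
            pos_cm, length = meta[chrom]
            g_1, _ = meiosis(p1[chrom][0], p1[chrom][1], pos_cm, length, rng)
            g_2, _ = meiosis(p2[chrom][0], p2[chrom][1], pos_cm, length, rng)
            focal_h[chrom] = np.stack([g_1, g_2])
            o = np.full(g_1.shape, NOT_SCORED, dtype=np.int8)
            het = g_1 != g_2
            o[het] = g_1[het]  # allele transmitted by parent 1
            origin[chrom] = o
        add(fid, focal_h)
        truth[fid] = TrioTruth(fid, origin)
        p1_id, p2_id = f"p{i:04d}_1", f"p{i:04d}_2"
        parents[fid] = (p1_id, p2_id)
        parent_genotypes[p1_id] = {
            c: (p1[c][0].astype(np.int16) + p1[c][1]) for c in chroms
        }
        parent_genotypes[p2_id] = {
            c: (p2[c][0].astype(np.int16) + p2[c][1]) for c in chroms
        }
        relatives[fid] = rel_list
        if config.include_parents or parent_in_cohort[0]:
            add(p1_id, p1)
        if config.include_parents or parent_in_cohort[1]:
            add(p2_id, p2)

    for u in range(config.n_unrelated):
        pop = (u % 2 if two_pops else None)
        add(f"unrel{u:05d}", draw_founder(pop))

    # randomise slot order per individual per chromosome: slots must carry
    # no phase meaning before across-chromosome phasing
    for h in haps:
        for chrom in chroms:
            if rng.integers(2):
                h[chrom] = h[chrom][::-1].copy()

    hap_arrays = {
        chrom: np.stack([h[chrom] for h in haps], axis=1) for chrom in chroms
    }
    cohort = PhasedCohort(samples, variants, hap_arrays)

    # orient allele codes to the realised minor allele; truth and parental
    # genotypes must flip with the codes
    compute_allele_frequencies(cohort)
    _recode_minor_with_truth(cohort, truth, parent_genotypes)

    sim = SimulatedCohort(
        cohort=cohort,
        gmap=gmap,
        truth=truth,
        parents=parents,
        parent_genotypes=parent_genotypes,
        relatives=relatives,
        config=config,
    )
    if config.switch_error_rate > 0:
        sub_seed = int(rng.integers(2**31 - 1))
        sim = inject_switch_errors(sim, config.switch_error_rate, sub_seed)
    return sim


def _recode_minor_with_truth(cohort, truth, parent_genotypes):
    from .cohort import recode_minor

    flips = recode_minor(cohort)
    for t in truth.values():
        for chrom, flip in flips.items():
            o = t.origin[chrom]
            m = flip & ((o == 0) | (o == 1))
            o[m] = 1 - o[m]
    for geno in parent_genotypes.values():
        for chrom, flip in flips.items():
            geno[chrom][flip] = 2 - geno[chrom][flip]
    return flips


# ---------------------------------------------------------------------------
# switch errors
# ---------------------------------------------------------------------------

def inject_switch_errors(
    sim_or_cohort, rate: float, seed: int
) -> "SimulatedCohort | PhasedCohort":
    """Inject within-chromosome switch errors into every individual.

    At each heterozygous site, with probability ``rate``, the two
    haplotype slots swap from that site to the chromosome end.  Accepts a
    :class:`SimulatedCohort` (truth passes through unchanged — it records
    transmitted alleles, which errors do not rewrite) or a bare
    :class:`PhasedCohort`.  Rate 0 returns an identical copy.  Switch
    positions are recorded per (sample, chromosome).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    sim = isinstance(sim_or_cohort, SimulatedCohort)
    cohort = (sim_or_cohort.cohort if sim else sim_or_cohort).copy()
    rng = np.random.default_rng(seed)
    positions: dict[tuple[str, str], np.ndarray] = {}
    for chrom in cohort.chromosomes:
        hap = cohort.haplotypes[chrom]
        het = hap[0] != hap[1]  # (n, m)
        if rate > 0:
            flips = (rng.random(het.shape) < rate) & het
            state = np.cumsum(flips, axis=1) % 2 == 1
            for i, s in enumerate(cohort.sample_ids):
                idx = np.flatnonzero(flips[i])
                if idx.size:
                    positions[(s, chrom)] = idx
            swap = state
            a = hap[0].copy()
            hap[0][swap] = hap[1][swap]
            hap[1][swap] = a[swap]
    if not sim:
        return cohort
    return replace(sim_or_cohort, cohort=cohort, switch_positions=positions)
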