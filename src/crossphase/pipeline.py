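"""End-to-end orchestration: QC -> windows -> psi-star -> greedy phasing -> ACPA.

Focal individuals are phased independently of one another, so per-focal
work may run concurrently; results are bit-identical regardless of thread
count because each focal's computation is a pure function of the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

from .cohort import PhasedCohort
from .gmap import RecombinationMap, annotate_cM
from .phasing import OrientationState, apply_orientation_inplace, greedy_phase
from .qc import qc_filter
from .similarity import PsiStarTensor, build_psi_star_tensor
from .windows import WindowSet, assign_snps, build_windows

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the phasing pipeline, at their standard defaults."""

    hotspots_per_chrom: int = 10
    min_span_cM: float = 25.0
    psi_term_exponent: float = 1.0 / 5.0
    psi_star_power: float = 2.0
    same_chrom_penalty: float = 0.75
    group_aggregate: str = "standardized"
    pihat_max: float = 0.33
    maf_min: float = 0.05
    hwe_p_min: float = 0.0005
    seed: int = 0
    threads: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))

    def header_lines(self) -> list[str]:
        """Effective-config echo for report headers."""
        return [f"# {k}={v}" for k, v in sorted(self.to_dict().items())]


def prepare(
    cohort: PhasedCohort, gmap: RecombinationMap, config: RunConfig | None = None
) -> tuple[PhasedCohort, WindowSet]:
    """QC-filter the cohort, annotate genetic positions and build windows."""
    config = config or RunConfig()
    cohort = qc_filter(cohort, maf_min=config.maf_min, hwe_p_min=config.hwe_p_min)
    annotate_cM(cohort, gmap)
    windows = build_windows(
        gmap,
        min_span_cM=config.min_span_cM,
        hotspots_per_chrom=config.hotspots_per_chrom,
        chromosomes=cohort.chromosomes,
    )
    windows = assign_snps(windows, cohort)
    return cohort, windows


def phase_focal(
    cohort: PhasedCohort,
    windows: WindowSet,
    focal: str,
    config: RunConfig | None = None,
    partners: list[str] | None = None,
) -> tuple[OrientationState, PsiStarTensor]:
    """Phase one focal individual; pure function of (cohort, windows, config).

    ``partners`` may supply a precomputed partner pool (e.g. when rescoring
    the same cohort under injected switch errors, which leave diploid
    genotypes — and hence pihat — unchanged).
    """
    config = config or RunConfig()
    tensor = build_psi_star_tensor(
        cohort,
        focal,
        windows,
        partners=partners,
        pihat_max=config.pihat_max,
        exponent=config.psi_term_exponent,
        power=config.psi_star_power,
    )
    state = greedy_phase(
        tensor, penalty=config.same_chrom_penalty, aggregate=config.group_aggregate
    )
    return state, tensor


def phase_cohort(
    cohort: PhasedCohort,
    windows: WindowSet,
    focal_ids: list[str],
    config: RunConfig | None = None,
) -> tuple[PhasedCohort, dict[str, OrientationState]]:
    """Phase every listed focal individual and apply the orientations.

    Returns a cohort copy in which each focal's slot 0 carries parental
    set 1 across all chromosomes, plus the per-focal orientation states.
    """
    config = config or RunConfig()

    def one(focal: str) -> tuple[str, OrientationState]:
        state, _ = phase_focal(cohort, windows, focal, config)
        return focal, state

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            states = dict(pool.map(one, focal_ids))
    else:
        states = dict(map(one, focal_ids))

    phased = cohort.copy()
    for focal in focal_ids:  # fixed order: output independent of thread timing
        apply_orientation_inplace(phased, focal, states[focal])
    return phased, states
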