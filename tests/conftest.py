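"""Shared fixtures: small seeded simulations and synthetic tensor builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import crossphase as cp
from crossphase.similarity import PsiStarTensor
from crossphase.windows import Window, WindowSet

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_sim() -> cp.SimulatedCohort:
    """Small cohort: 2 focal trios with an uncle and a cousin, 1 focal without."""
    cfg = cp.SimulationConfig(
        seed=11,
        n_unrelated=90,
        n_focal=2,
        n_focal_no_relatives=1,
        relative_degrees=(2, 3),
        n_chromosomes=3,
        snps_per_chromosome=500,
        chromosome_length_cM=80.0,
    )
    return cp.build_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_sim):
    cohort, windows = cp.prepare(tiny_sim.cohort, tiny_sim.gmap)
    return tiny_sim, cohort, windows


def make_window_set(chrom_counts: dict[str, int]) -> WindowSet:
    """Synthetic windows with dummy spans, for tensor-level tests."""
    ws = WindowSet()
    for chrom, k in chrom_counts.items():
        for j in range(k):
            ws.windows.append(
                Window(
                    chrom=chrom,
                    index=len(ws.windows),
                    start_bp=j * 1000,
                    end_bp=(j + 1) * 1000,
                    start_cM=j * 30.0,
                    end_cM=(j + 1) * 30.0,
                    snp_start=0,
                    snp_stop=0,
                )
            )
    return ws


def planted_tensor(
    rng: np.random.Generator,
    chrom_counts: dict[str, int] | None = None,
    n_partners: int = 150,
    noise: float = 0.25,
    signal: float = 1.0,
) -> tuple[PsiStarTensor, np.ndarray]:
    """Synthetic psi-star tensor with a planted parental-side structure.

    Each window's side-1 vector is a shared latent partner profile plus
    noise (likewise side 2); the window's A/B slots are assigned by a
    random planted orientation.  Returns (tensor, planted orientations).
    """
    if chrom_counts is None:
        chrom_counts = {"chr1": 2, "chr2": 2, "chr3": 2}
    windows = make_window_set(chrom_counts)
    W = len(windows)
    u1 = rng.normal(size=n_partners)
    u2 = rng.normal(size=n_partners)
    orient = rng.choice([-1, 1], size=W)
    values = np.empty((2, W, n_partners))
    for w in range(W):
        s1 = signal * u1 + noise * rng.normal(size=n_partners)
        s2 = signal * u2 + noise * rng.normal(size=n_partners)
        if orient[w] > 0:
            values[0, w], values[1, w] = s1, s2
        else:
            values[0, w], values[1, w] = s2, s1
    values = values - values.min() + 0.1  # psi-star values are non-negative
    tensor = PsiStarTensor(
        focal_id="focal",
        partner_ids=[f"p{i}" for i in range(n_partners)],
        excluded_ids=[],
        windows=windows,
        values=values,
        usable=np.ones(W, dtype=bool),
    )
    return tensor, orient


def fig1_case(seed: int = 0, sites_per_chrom: int = 100):
    """Four equal-size chromosomes with per-chromosome agreement 100/88/100/0%.

    Builds a single-sample phased cohort (heterozygous everywhere) and a
    fully resolved parental-origin truth engineered so that, under one
    global parental labelling, the per-chromosome proportions of
    correctly traced SNPs are 1.00, 0.88, 1.00 and 0.00.
    """
    rng = np.random.default_rng(seed)
    fractions = {"chr1": 1.00, "chr2": 0.88, "chr3": 1.00, "chr4": 0.00}
    origin = {}
    haps = {}
    variants = {}
    for chrom, frac in fractions.items():
        n = sites_per_chrom
        parent1_allele = rng.integers(0, 2, n).astype(np.int8)
        slot0 = parent1_allele.copy()
        n_wrong = n - int(round(frac * n))
        wrong = rng.choice(n, size=n_wrong, replace=False)
        slot0[wrong] = 1 - slot0[wrong]
        origin[chrom] = parent1_allele
        haps[chrom] = np.stack([slot0, 1 - slot0])[:, None, :]
        variants[chrom] = pd.DataFrame({"pos": np.arange(1, n + 1)})
    cohort = cp.PhasedCohort(["offspring"], variants, haps)
    truth = cp.TrioTruth("offspring", origin)
    return cohort, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
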