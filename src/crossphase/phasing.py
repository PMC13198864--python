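"""Across-chromosome phasing: window-pair lambda and greedy merging.

For two windows g and h, the four Pearson correlations between their
psi-star partner vectors form a 2x2 matrix; the signed combination

    lambda = r(A_g, A_h) - r(A_g, B_h) - r(B_g, A_h) + r(B_g, B_h)

lies in [-4, 4] and its sign predicts whether the A haplotypes of the two
windows descend from the same parent (positive) or from different parents
(negative).  Relabeling one window's A/B slots flips the sign exactly.

Phasing is a greedy agglomeration: seed with the window pair of maximal
|adjusted lambda|, then repeatedly fold in the window whose |adjusted
lambda| against the merged group's aggregated vectors is largest,
orienting it by the sign.  A negative lambda between windows on the same
chromosome is shrunk by a 0.75 factor before comparison, encoding the
prior that within-chromosome switch errors between two windows occur less
than half the time — an opposite-parent call within a chromosome needs
stronger evidence than one across chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PhasedCohort
from .similarity import PsiStarTensor
from .windows import WindowSet

log = logging.getLogger(__name__)

DEFAULT_SAME_CHROM_PENALTY = 0.75


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float((xc @ yc) / denom)


def lambda_pair(vecs_g: tuple, vecs_h: tuple) -> float:
    """Signed correlation combination between two windows' psi-star vectors.

    Returns NaN when any of the four vectors has zero variance (the pair
    is then skipped by the caller).
    """
    a_g, b_g = vecs_g
    a_h, b_h = vecs_h
    # grouped so that relabeling one window's A/B flips the sign exactly
    # (IEEE negation of the same two partial sums)
    same = _pearson(a_g, a_h) + _pearson(b_g, b_h)
    cross = _pearson(a_g, b_h) + _pearson(b_g, a_h)
    return same - cross


def adjusted_lambda(
    lam: float, same_chromosome: bool, penalty: float = DEFAULT_SAME_CHROM_PENALTY
) -> float:
    """Shrink negative same-chromosome lambda by ``penalty``; else pass through."""
    if same_chromosome and lam < 0:
        return penalty * lam
    return lam


@dataclass
class OrientationState:
    """Result of greedy window merging for one focal individual.

    ``orientation[w] = +1`` means window ``w``'s slot-A haplotype joins
    parental set 1 (slot B joins set 2); ``-1`` the reverse.  Orientations
    are assigned once and never revised (greedy, no backtracking).
    Windows with no usable signal are flagged ``uninformative`` and carry
    orientation +1 by convention.  ``merge_log`` records each decision:
    seed pair first, then one row per folded-in window (window_h = -1
    denotes the merged group).
    """

    windows: WindowSet
    orientation: np.ndarray  # (W,) int8 in {+1, -1}
    uninformative: np.ndarray  # (W,) bool
    merge_log: pd.DataFrame = field(repr=False)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _member_vectors(values: np.ndarray, w: int, orientation: np.ndarray, aggregate: str) -> tuple:
    """One member window's (side-1, side-2) contribution to the group vectors.

    ``aggregate="standardized"`` z-scores each member vector before summing,
    so every window contributes comparably to the merged representation;
    under a raw ``"sum"`` the member with the largest psi-star outlier
    dominates the group's correlation structure and weaker IBD signals
    carried by other members are diluted.
    """
    a, b = values[0, w], values[1, w]
    if aggregate == "standardized":
        a, b = _zscore(a), _zscore(b)
    return (a, b) if orientation[w] > 0 else (b, a)


def greedy_phase(
    tensor: PsiStarTensor,
    penalty: float = DEFAULT_SAME_CHROM_PENALTY,
    aggregate: str = "standardized",
) -> OrientationState:
    """Greedily merge all usable windows into two genome-wide parental sets.

    ``aggregate`` selects the merged-group representation used for
    window-vs-group lambda: ``"standardized"`` (default) sums z-scored
    member vectors, ``"sum"`` sums them raw.  Ties on |adjusted lambda|
    break toward the lowest window index (pair), making the merge log
    deterministic for a fixed tensor.
    """
    if aggregate not in ("standardized", "sum"):
        raise ValueError("aggregate must be 'standardized' or 'sum'")
    windows = tensor.windows
    W = len(windows)
    values = tensor.values
    chrom = [w.chrom for w in windows]
    # a window is informative only if both its vectors carry variance
    var_ok = (values.std(axis=2) > 0).all(axis=0)
    usable = tensor.usable & var_ok
    usable_idx = np.flatnonzero(usable)
    if len(usable_idx) < 2:
        raise ValueError("fewer than 2 usable windows; across-chromosome phasing impossible")

    # pairwise adjusted lambda among usable windows
    pair_adj: dict[tuple[int, int], tuple[float, float]] = {}
    for ai, g in enumerate(usable_idx):
        for h in usable_idx[ai + 1 :]:
            lam = lambda_pair(tensor.vectors(g), tensor.vectors(h))
            if np.isnan(lam):
                continue
            adj = adjusted_lambda(lam, chrom[g] == chrom[h], penalty)
            pair_adj[(g, h)] = (lam, adj)
    if not pair_adj:
        raise ValueError("all pairwise lambda undefined; cannot seed phasing")

    # seed: maximal |adjusted lambda|, ties to the lowest (g, h)
    seed = max(sorted(pair_adj), key=lambda k: abs(pair_adj[k][1]))
    best = abs(pair_adj[seed][1])
    for key in sorted(pair_adj):
        if abs(pair_adj[key][1]) == best:
            seed = key
            break
    g0, h0 = seed
    lam0, adj0 = pair_adj[seed]

    orientation = np.ones(W, dtype=np.int8)
    assigned = np.zeros(W, dtype=bool)
    orientation[g0] = 1
    orientation[h0] = 1 if lam0 > 0 else -1
    assigned[[g0, h0]] = True
    members = [g0, h0]
    group_chroms = {chrom[g0], chrom[h0]}
    records = [
        dict(step=0, window_g=g0, window_h=h0, lam=lam0, adjusted=adj0,
             sign=int(orientation[h0]))
    ]

    v1, v2 = _member_vectors(values, g0, orientation, aggregate)
    w1, w2 = _member_vectors(values, h0, orientation, aggregate)
    g1, g2 = v1 + w1, v2 + w2
    step = 1
    remaining = [w for w in usable_idx if not assigned[w]]
    while remaining:
        best_w = None
        best_abs = -np.inf
        best_lam = best_adj = np.nan
        for w in remaining:  # ascending index: ties keep the lowest window
            lam = lambda_pair(tensor.vectors(w), (g1, g2))
            if np.isnan(lam):
                continue
            adj = adjusted_lambda(lam, chrom[w] in group_chroms, penalty)
            if abs(adj) > best_abs:
                best_abs = abs(adj)
                best_w, best_lam, best_adj = w, lam, adj
        if best_w is None:
            log.warning(
                "%s: %d window(s) uncorrelatable with the merged group; flagged uninformative",
                tensor.focal_id, len(remaining),
            )
            for w in remaining:
                usable[w] = False
            break
        orientation[best_w] = 1 if best_lam > 0 else -1
        assigned[best_w] = True
        members.append(best_w)
        group_chroms.add(chrom[best_w])
        records.append(
            dict(step=step, window_g=int(best_w), window_h=-1, lam=best_lam,
                 adjusted=best_adj, sign=int(orientation[best_w]))
        )
        v1, v2 = _member_vectors(values, best_w, orientation, aggregate)
        g1 = g1 + v1
        g2 = g2 + v2
        remaining.remove(best_w)
        step += 1

    uninformative = ~usable
    return OrientationState(
        windows=windows,
        orientation=orientation,
        uninformative=uninformative,
        merge_log=pd.DataFrame.from_records(records),
    )


def apply_orientation(
    cohort: PhasedCohort, focal: str, state: OrientationState
) -> PhasedCohort:
    """Rewrite the focal individual's slots so slot 0 carries parental set 1.

    Windows with orientation -1 have their two haplotype slices swapped;
    within-window sequences are untouched.  Single-use transform: applying
    it twice with the same state re-swaps back.
    """
    out = cohort.copy()
    apply_orientation_inplace(out, focal, state)
    return out


def apply_orientation_inplace(cohort: PhasedCohort, focal: str, state: OrientationState) -> None:
    f = cohort.sample_index(focal)
    for w in state.windows:
        if state.orientation[w.index] < 0:
            hap = cohort.haplotypes[w.chrom]
            sl = slice(w.snp_start, w.snp_stop)
            a = hap[0, f, sl].copy()
            hap[0, f, sl] = hap[1, f, sl]
            hap[1, f, sl] = a
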