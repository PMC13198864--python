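"""Recombination-hotspot-delimited chromosome windows.

The across-chromosome phasing signal is a correlation of window-level
similarity statistics, so windows should be approximately independent:
their boundaries are placed at the strongest recombination hotspots —
the map intervals with the highest cM-per-Mb ratio — subject to a minimum
genetic span per window.  Window construction uses the map alone, so a
window set is reusable across cohorts sharing a map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import PhasedCohort
from .gmap import RecombinationMap

log = logging.getLogger(__name__)


@dataclass
class Window:
    """One half-open chromosome window ``[start_bp, end_bp)``.

    ``snp_start:snp_stop`` is the contiguous index range into the owning
    chromosome's variant table once :func:`assign_snps` has run; ``index``
    is the window's position in the genome-wide flat ordering.
    """

    chrom: str
    index: int
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    snp_start: int | None = None
    snp_stop: int | None = None

    @property
    def span_cM(self) -> float:
        return self.end_cM - self.start_cM

    @property
    def n_snps(self) -> int:
        if self.snp_start is None:
            return 0
        return self.snp_stop - self.snp_start


@dataclass
class WindowSet:
    windows: list[Window] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]

    def by_chromosome(self) -> dict[str, list[Window]]:
        out: dict[str, list[Window]] = {}
        for w in self.windows:
            out.setdefault(w.chrom, []).append(w)
        return out

    def mean_span_cM(self) -> float:
        return float(np.mean([w.span_cM for w in self.windows]))

    def reindex(self) -> None:
        for i, w in enumerate(self.windows):
            w.index = i


def hotspot_candidates(gmap: RecombinationMap, chrom: str, k: int = 10) -> list[int]:
    """Boundary candidates: midpoints of the ``k`` hottest map intervals.

    Heat is the ratio of genetic to physical distance (cM/Mb) over
    consecutive map-anchor intervals.  Ties are broken toward the smaller
    bp position; the returned midpoints are sorted by position.
    """
    tab = gmap.anchors[chrom]
    bp = tab["bp"].to_numpy(float)
    cm = tab["cM"].to_numpy(float)
    dbp = np.diff(bp)
    dcm = np.diff(cm)
    valid = dbp > 0
    ratio = np.where(valid, dcm / (dbp / 1e6), -np.inf)
    n_int = int(valid.sum())
    if n_int < k:
        log.warning("%s: only %d map intervals for %d requested hotspots", chrom, n_int, k)
        k = n_int
    # stable ordering: descending ratio, ascending bp on ties
    order = np.lexsort((bp[:-1], -ratio))
    chosen = sorted(order[:k])
    mids = ((bp[:-1] + bp[1:]) / 2).astype(np.int64)
    return [int(mids[i]) for i in chosen]


def build_windows(
    gmap: RecombinationMap,
    candidates: dict[str, list[int]] | None = None,
    min_span_cM: float = 25.0,
    hotspots_per_chrom: int = 10,
    chromosomes: list[str] | None = None,
) -> WindowSet:
    """Sweep hotspot candidates into windows of at least ``min_span_cM``.

    Candidates are scanned left to right; one becomes a boundary iff the
    window it closes spans at least ``min_span_cM``.  The final window runs
    to the chromosome end and is merged into its left neighbour when it
    falls short of the minimum, so only a chromosome-end window may be
    shorter than ``min_span_cM``.  A chromosome shorter than the minimum
    yields a single whole-chromosome window.
    """
    chroms = chromosomes if chromosomes is not None else gmap.chromosomes
    ws = WindowSet()
    for chrom in chroms:
        cand = (
            candidates.get(chrom, [])
            if candidates is not None
            else hotspot_candidates(gmap, chrom, hotspots_per_chrom)
        )
        bp0, bp1, cm0, cm1 = gmap.span(chrom)
        if cm1 - cm0 < min_span_cM:
            log.info("%s: span %.1f cM < %.1f, single window", chrom, cm1 - cm0, min_span_cM)
        bounds = [bp0]
        for c in sorted(cand):
            if c <= bounds[-1] or c >= bp1:
                continue
            c_cm = float(gmap.interpolate(chrom, [c])[0])
            if c_cm - float(gmap.interpolate(chrom, [bounds[-1]])[0]) >= min_span_cM:
                bounds.append(int(c))
        bounds.append(bp1 + 1)  # half-open end past the last anchored bp
        cms = [float(gmap.interpolate(chrom, [b])[0]) for b in bounds]
        # terminal window shorter than the minimum: merge into left neighbour
        if len(bounds) > 2 and cms[-1] - cms[-2] < min_span_cM:
            del bounds[-2]
            del cms[-2]
        for j in range(len(bounds) - 1):
            ws.windows.append(
                Window(
                    chrom=chrom,
                    index=len(ws.windows),
                    start_bp=bounds[j],
                    end_bp=bounds[j + 1],
                    start_cM=cms[j],
                    end_cM=cms[j + 1],
                )
            )
    return ws


def assign_snps(windows: WindowSet, cohort: PhasedCohort, drop_empty: bool = True) -> WindowSet:
    """Assign every SNP to exactly one window by bp against half-open spans.

    A SNP exactly on a boundary goes to the right window.  SNPs outside all
    spans fall into the nearest terminal window (logged).  Windows left
    empty are dropped with a warning and their span folded into a
    neighbour, so the surviving windows still partition the SNPs.
    """
    out = WindowSet()
    for chrom, ws in windows.by_chromosome().items():
        if chrom not in cohort.variants:
            log.warning("%s: windows defined but chromosome absent from cohort", chrom)
            continue
        pos = cohort.variants[chrom]["pos"].to_numpy()
        inner = np.array([w.start_bp for w in ws[1:]], dtype=np.int64)
        cuts = np.searchsorted(pos, inner, side="left")
        starts = np.concatenate([[0], cuts])
        stops = np.concatenate([cuts, [len(pos)]])
        n_outside = int((pos < ws[0].start_bp).sum() + (pos >= ws[-1].end_bp).sum())
        if n_outside:
            log.info("%s: %d SNP(s) outside window spans kept in terminal windows", chrom, n_outside)
        kept: list[Window] = []
        for w, a, b in zip(ws, starts, stops):
            if b <= a:
                log.warning("%s: window [%d,%d) empty after SNP assignment, dropped", chrom, w.start_bp, w.end_bp)
                if not drop_empty:
                    kept.append(Window(chrom, 0, w.start_bp, w.end_bp, w.start_cM, w.end_cM, int(a), int(b)))
                continue
            kept.append(Window(chrom, 0, w.start_bp, w.end_bp, w.start_cM, w.end_cM, int(a), int(b)))
        # re-span neighbours of dropped windows so bp spans stay contiguous
        # (the SNP index ranges are contiguous already: empty ranges vanish)
        for left, right in zip(kept, kept[1:]):
            if left.end_bp != right.start_bp:
                left.end_bp = right.start_bp
                left.end_cM = right.start_cM
        out.windows.extend(kept)
    out.reindex()
    return out
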