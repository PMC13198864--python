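"""Genetic (recombination) map handling.

Maps are tabular anchor points ``(chromosome, position_bp, position_cM)``
with one header line, as distributed with published pedigree-based maps
such as the deCODE sex-averaged map.  Genetic positions of SNPs are
obtained by linear interpolation in bp between anchors; positions outside
the anchored range take the boundary cM value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class RecombinationMap:
    """Per-chromosome anchor points ``(bp, cM)``, both sorted by bp."""

    anchors: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        cleaned = {}
        for chrom, tab in self.anchors.items():
            tab = tab.sort_values("bp").reset_index(drop=True)
            if len(tab) < 2:
                raise ValueError(f"map for {chrom} needs at least 2 anchors")
            if not (np.diff(tab["bp"].to_numpy()) > 0).all():
                raise ValueError(f"map for {chrom} has duplicate bp anchors")
            if (np.diff(tab["cM"].to_numpy()) < 0).any():
                raise ValueError(f"map for {chrom} has decreasing cM")
            cleaned[chrom] = tab[["bp", "cM"]]
        self.anchors = cleaned

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def interpolate(self, chrom: str, positions_bp) -> np.ndarray:
        """Linearly interpolated cM positions; clamped outside anchor range."""
        tab = self.anchors[chrom]
        return np.interp(
            np.asarray(positions_bp, dtype=float),
            tab["bp"].to_numpy(float),
            tab["cM"].to_numpy(float),
        )

    def span(self, chrom: str) -> tuple[int, int, float, float]:
        """``(start_bp, end_bp, start_cM, end_cM)`` of the anchored range."""
        tab = self.anchors[chrom]
        return (
            int(tab["bp"].iloc[0]),
            int(tab["bp"].iloc[-1]),
            float(tab["cM"].iloc[0]),
            float(tab["cM"].iloc[-1]),
        )

    def length_cM(self, chrom: str) -> float:
        _, _, c0, c1 = self.span(chrom)
        return c1 - c0


def read_genetic_map(path, header: bool = True) -> RecombinationMap:
    """Read a whitespace/tab-delimited ``(chrom, bp, cM)`` map file."""
    tab = pd.read_csv(
        path,
        sep=r"\s+",
        header=0 if header else None,
        names=["chrom", "bp", "cM"],
        dtype={"chrom": str},
    )
    anchors = {
        str(chrom): grp[["bp", "cM"]].reset_index(drop=True)
        for chrom, grp in tab.groupby("chrom", sort=False)
    }
    return RecombinationMap(anchors)


def write_genetic_map(gmap: RecombinationMap, path) -> None:
    rows = []
    for chrom, tab in gmap.anchors.items():
        rows.append(tab.assign(chrom=chrom)[["chrom", "bp", "cM"]])
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def annotate_cM(cohort, gmap: RecombinationMap) -> None:
    """Fill each variant table's ``cM`` column by interpolation in-place."""
    for chrom in cohort.chromosomes:
        pos = cohort.variants[chrom]["pos"].to_numpy()
        cohort.variants[chrom]["cM"] = gmap.interpolate(chrom, pos)
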