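"""Recombination-map rescaling and physical-to-genetic length conversion.

Population-specific maps assign each chromosome a different total genetic
length, which would confound cross-population fragment-length comparisons.
Maps are therefore rescaled per chromosome so every population matches the
genetic length of the population with the shortest map, after which a
fragment's mean rate r-bar (overlap-weighted over map blocks) converts its
physical length to centiMorgans: s(cM) = s(bp) * 1e-6 * r-bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rates (cM/Mb) per chromosome.

    ``segments[chrom]`` is an (n, 3) float array of (start, end, rate) with
    0-based half-open coordinates tiling the covered extent.
    """

    population: str
    segments: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in list(self.segments.items()):
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            if (arr[:, 2] < 0).any():
                raise ValueError(f"negative recombination rate on {chrom}")
            if arr.shape[0] > 1 and not np.allclose(arr[1:, 0], arr[:-1, 1]):
                raise ValueError(f"segments do not tile {chrom}")
            self.segments[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return sorted(self.segments)

    def extent(self, chrom: str) -> tuple[float, float]:
        arr = self.segments[chrom]
        return float(arr[0, 0]), float(arr[-1, 1])

    def genetic_length(self, chrom: str) -> float:
        """Total genetic length l_pc of a chromosome in cM."""
        arr = self.segments[chrom]
        return float(((arr[:, 1] - arr[:, 0]) * arr[:, 2]).sum() * 1e-6)

    def scaled(self, factors: Mapping[str, float], suffix: str = "") -> "RecombinationMap":
        segs = {}
        for chrom, arr in self.segments.items():
            arr = arr.copy()
            arr[:, 2] *= factors.get(chrom, 1.0)
            segs[chrom] = arr
        return RecombinationMap(self.population + suffix, segs)


def rescale_maps(
    maps: Mapping[str, RecombinationMap], mode: str = "equalize"
) -> dict[str, RecombinationMap]:
    """Rescale every population's rates so chromosome genetic lengths agree.

    ``mode="equalize"`` multiplies population p's rates on chromosome c by
    l_qc / l_pc, where q is the population with the shortest map, so that all
    populations end at the shortest length (idempotent).  ``mode="printed"``
    applies the reciprocal factor l_pc / l_qc instead, for exact-replication
    experiments with the alternative convention.
    """
    if mode not in ("equalize", "printed"):
        raise ValueError("mode must be 'equalize' or 'printed'")
    pops = sorted(maps)
    if not pops:
        raise ValueError("no maps given")
    chroms = maps[pops[0]].chroms
    for p in pops[1:]:
        if maps[p].chroms != chroms:
            raise ValueError("populations cover different chromosome sets")
        for c in chroms:
            if maps[p].extent(c) != maps[pops[0]].extent(c):
                raise ValueError(f"chromosome extents differ on {c}")
    shortest = {c: min(maps[p].genetic_length(c) for p in pops) for c in chroms}
    out = {}
    for p in pops:
        factors = {}
        for c in chroms:
            l_pc = maps[p].genetic_length(c)
            if l_pc == 0:
                factors[c] = 1.0
            else:
                ratio = shortest[c] / l_pc
                factors[c] = ratio if mode == "equalize" else 1.0 / ratio
        out[p] = maps[p].scaled(factors)
    return out


def fragment_mean_rate(fragment: GenomicInterval, rmap: RecombinationMap) -> float:
    """Overlap-weighted mean rate r-bar (cM/Mb) of a fragment.

    Each map block contributes its rate weighted by overlap_bp / fragment_bp;
    the weights sum to 1.  The fragment must lie inside the map's extent.
    """
    arr = rmap.segments.get(fragment.chrom)
    if arr is None:
        raise ValueError(f"no map for chromosome {fragment.chrom}")
    lo, hi = rmap.extent(fragment.chrom)
    if fragment.start < lo or fragment.end > hi:
        raise ValueError(
            f"fragment {fragment.chrom}:{fragment.start}-{fragment.end} "
            f"extends beyond map extent [{lo}, {hi})"
        )
    overlap = np.minimum(arr[:, 1], fragment.end) - np.maximum(arr[:, 0], fragment.start)
    overlap = np.clip(overlap, 0, None)
    return float((arr[:, 2] * overlap).sum() / fragment.length)


def bp_to_cM(length_bp: float, mean_rate: float) -> float:
    """Convert a physical length to genetic length: bp * 1e-6 * r-bar."""
    if length_bp < 0:
        raise ValueError("length must be non-negative")
    if mean_rate < 0:
        raise ValueError("rate must be non-negative")
    return length_bp * 1e-6 * mean_rate


def fragment_length_cM(fragment: GenomicInterval, rmap: RecombinationMap) -> float:
    return bp_to_cM(fragment.length, fragment_mean_rate(fragment, rmap))


# -- HapMap-style text I/O --------------------------------------------------


def read_hapmap(path, population: str = "") -> RecombinationMap:
    """Read a HapMap-style map: columns chrom, position (bp, 1-based), rate (cM/Mb).

    Each rate applies from its position to the next row's position on the
    same chromosome (the last row closes the extent; its rate is unused).
    A header line is tolerated.  Positions convert to 0-based half-open.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if not df.iloc[0, 1].replace(".", "", 1).isdigit():
        df = df.iloc[1:]
    chroms = df.iloc[:, 0].astype(str).to_numpy()
    pos = df.iloc[:, 1].astype(float).to_numpy()
    rate = df.iloc[:, 2].astype(float).to_numpy()
    segs: dict[str, np.ndarray] = {}
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        p, r = pos[m], rate[m]
        if p.shape[0] < 2:
            raise ValueError(f"map for {chrom} needs >= 2 positions")
        starts = p[:-1] - 1.0  # 1-based -> 0-based
        ends = p[1:] - 1.0
        segs[chrom] = np.column_stack([starts, ends, r[:-1]])
    return RecombinationMap(population or str(path), segs)


def write_hapmap(rmap: RecombinationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\trate_cM_Mb\n")
        for chrom in rmap.chroms:
            arr = rmap.segments[chrom]
            for start, _end, rate in arr:
                fh.write(f"{chrom}\t{int(start) + 1}\t{rate:.8g}\n")
            fh.write(f"{chrom}\t{int(arr[-1, 1]) + 1}\t0\n")
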