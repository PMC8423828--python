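"""Sex-specific mutation signatures.

Three statistics separate paternal from maternal generation-interval shifts:

* X-to-A ratio — per-base derived-allele accumulation on the X over that on
  the autosomes, (d_X/L_X)/(d_A/L_A).  The X spends 2/3 of its history in
  females vs 1/2 for autosomes, so a relative increase of paternal over
  maternal age raises the ratio.  Computed for females (hemizygous male X
  halves the density).
* C>G clustered-DNM ratio r — per 1 Mb window p = d_C>G / d_non-C>G; p-bar
  is averaged separately over windows annotated as clustered-de-novo-
  mutation (cDNM) regions and the rest, and r = p-bar_cDNM / p-bar_non.
  r > 1 means maternal-age-driven C>G enrichment in cDNM regions.
* Y yearly-rate sensitivity — the percent change of the paternal yearly
  mutation rate per +1 year of paternal age, |d/da (6.05/a + 1.51)| relative
  to the rate (about 0.4-0.5%/year at human ages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gentime import DEFAULT_PARAMS, PedigreeRegressionParams


@dataclass(frozen=True)
class XARatioInput:
    d_X: float
    d_A: float
    L_X: float
    L_A: float
    sex: str = "F"  # "F" or "M"


def x_to_a_ratio(inp: XARatioInput, require_female: bool = True) -> float:
    """(d_X / L_X) / (d_A / L_A)."""
    if inp.L_X <= 0 or inp.L_A <= 0:
        raise ValueError("callable lengths must be positive")
    if inp.d_X < 0 or inp.d_A < 0:
        raise ValueError("counts must be non-negative")
    if inp.d_A == 0:
        raise ValueError("zero autosomal count: ratio undefined")
    if require_female and inp.sex.upper() != "F":
        raise ValueError("X-to-A ratio is computed on females only")
    return (inp.d_X / inp.L_X) / (inp.d_A / inp.L_A)


@dataclass(frozen=True)
class CgCdnmResult:
    r: float
    p_bar_cdnm: float
    p_bar_non_cdnm: float
    n_cdnm: int
    n_non_cdnm: int
    n_skipped: int


def cg_cdnm_ratio(windows: pd.DataFrame, weighted: bool = False) -> CgCdnmResult:
    """C>G enrichment ratio r of cDNM over non-cDNM 1 Mb windows.

    ``windows`` needs columns ``d_cg``, ``d_noncg`` and boolean ``cdnm``.
    Windows with zero non-C>G count (p undefined) are skipped and reported.
    ``weighted=True`` weights the per-class mean of p by total window counts
    instead of the default unweighted mean.
    """
    need = {"d_cg", "d_noncg", "cdnm"}
    if not need.issubset(windows.columns):
        raise ValueError(f"windows table needs columns {sorted(need)}")
    usable = windows[windows["d_noncg"] > 0]
    n_skipped = len(windows) - len(usable)
    p = usable["d_cg"] / usable["d_noncg"]
    means = {}
    for flag in (True, False):
        cls = usable["cdnm"].astype(bool) == flag
        if not cls.any():
            raise ValueError(f"no usable {'cDNM' if flag else 'non-cDNM'} windows")
        if weighted:
            w = (usable.loc[cls, "d_cg"] + usable.loc[cls, "d_noncg"]).to_numpy(float)
            means[flag] = float(np.average(p[cls], weights=w))
        else:
            means[flag] = float(p[cls].mean())
    if means[False] == 0:
        raise ValueError("non-cDNM mean p is zero: r undefined")
    return CgCdnmResult(
        r=means[True] / means[False],
        p_bar_cdnm=means[True],
        p_bar_non_cdnm=means[False],
        n_cdnm=int((usable["cdnm"].astype(bool)).sum()),
        n_non_cdnm=int((~usable["cdnm"].astype(bool)).sum()),
        n_skipped=n_skipped,
    )


def y_rate_sensitivity(a: float, params: PedigreeRegressionParams = DEFAULT_PARAMS) -> float:
    """Percent decrease of the paternal yearly rate per +1 year of paternal age.

    The paternal yearly rate is mu_f,g(a)/a = intercept/a + slope; the
    sensitivity is (intercept/a^2) / (intercept/a + slope) * 100.
    """
    if a <= 0:
        raise ValueError("age must be positive")
    rate = params.paternal_intercept / a + params.paternal_slope
    return (params.paternal_intercept / a**2) / rate * 100.0
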