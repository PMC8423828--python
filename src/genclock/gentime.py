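"""Converting derived-allele accumulation differences into generation intervals.

Pedigree (trio) studies give the expected number of de novo mutations
transmitted per generation as linear functions of parental age:

    mu_f,g = 6.05 + 1.51 * a_f   (paternal)
    mu_m,g = 3.61 + 0.37 * a_m   (maternal)

so with equal parental ages a the per-generation rate is 9.66 + 1.88 a and
the yearly rate is (9.66 + 1.88 a) / a = 9.66/a + 1.88, a decreasing
function of a: populations with shorter generation intervals accumulate
derived alleles faster per year.  Comparing two populations that split T
years ago, the ratio of accumulated derived alleles equals the ratio of
their yearly rates, which can be inverted for the unknown mean parental age
a_x given the reference age a_z:

    a_x = 9.66 / ( (d_x/d_z) * (9.66/a_z + 1.88) - 1.88 )

An observed accumulation excess measured over the whole post-Out-of-Africa
period must first be scaled up by t_ooa / t_split, because the excess could
only accrue while the two populations were separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class PedigreeRegressionParams:
    """Trio-regression coefficients (mutations per generation vs parental age)."""

    paternal_intercept: float = 6.05
    paternal_slope: float = 1.51
    maternal_intercept: float = 3.61
    maternal_slope: float = 0.37

    def __post_init__(self) -> None:
        if min(self.paternal_intercept, self.paternal_slope,
               self.maternal_intercept, self.maternal_slope) <= 0:
            raise ValueError("intercepts and slopes must be positive")

    @property
    def intercept(self) -> float:
        """Combined intercept (9.66 with the default coefficients)."""
        return self.paternal_intercept + self.maternal_intercept

    @property
    def slope(self) -> float:
        """Combined slope (1.88 with the default coefficients)."""
        return self.paternal_slope + self.maternal_slope

    def paternal_per_generation(self, a_f: float) -> float:
        return self.paternal_intercept + self.paternal_slope * a_f

    def maternal_per_generation(self, a_m: float) -> float:
        return self.maternal_intercept + self.maternal_slope * a_m


DEFAULT_PARAMS = PedigreeRegressionParams()


@dataclass(frozen=True)
class GenerationEstimate:
    d_ratio: float
    a_z: float
    a_x: float

    @property
    def difference(self) -> float:
        """Implied generation-interval difference a_z - a_x in years."""
        return self.a_z - self.a_x


def mu_per_generation(
    a_f: float, a_m: float, params: PedigreeRegressionParams = DEFAULT_PARAMS
) -> float:
    """Total mutations per generation for parental ages (a_f, a_m) in years."""
    if a_f <= 0 or a_m <= 0:
        raise ValueError("parental ages must be positive")
    return params.paternal_per_generation(a_f) + params.maternal_per_generation(a_m)


def mu_per_year(a: float, params: PedigreeRegressionParams = DEFAULT_PARAMS) -> float:
    """Yearly mutation rate at equal parental ages a: intercept/a + slope."""
    if a <= 0:
        raise ValueError("age must be positive")
    return params.intercept / a + params.slope


def excess_scaling(excess_pct: float, t_ooa_years: float, t_split_years: float) -> float:
    """Scale a whole-period accumulation excess to the post-split period.

    excess_pct * t_ooa / t_split; e.g. a 1.09% excess over 60 kyr concentrated
    in a 40 kyr post-split window is a 1.64% (1.635) rate excess.
    """
    if not 0 < t_split_years <= t_ooa_years:
        raise ValueError("need 0 < t_split <= t_ooa")
    return excess_pct * t_ooa_years / t_split_years


def estimate_parental_age(
    d_ratio: float, a_z: float, params: PedigreeRegressionParams = DEFAULT_PARAMS
) -> GenerationEstimate:
    """Mean parental age a_x implied by an accumulation ratio d_x/d_z.

    Inverts the yearly-rate ratio; requires the implied yearly rate of x to
    exceed the asymptotic slope, otherwise no positive age reproduces the
    ratio.
    """
    if a_z <= 0:
        raise ValueError("reference age must be positive")
    if d_ratio <= 0:
        raise ValueError("accumulation ratio must be positive")
    denom = d_ratio * mu_per_year(a_z, params) - params.slope
    if denom <= 0:
        raise ValueError("ratio implies non-positive generation time")
    a_x = params.intercept / denom
    return GenerationEstimate(d_ratio=d_ratio, a_z=a_z, a_x=a_x)


def expected_accumulation_ratio(
    a_x: float,
    a_z: float,
    params: PedigreeRegressionParams = DEFAULT_PARAMS,
    epochs: Sequence[tuple[float, bool]] | None = None,
) -> float:
    """Expected d_x/d_z for mean parental ages a_x vs a_z.

    Without ``epochs``, the single-epoch yearly-rate ratio (the algebraic
    inverse of :func:`estimate_parental_age`).  With ``epochs`` — a sequence
    of (duration_years, is_shared) — shared epochs contribute identically to
    both lineages (ratio 1) and only private epochs separate the rates.
    """
    r_x, r_z = mu_per_year(a_x, params), mu_per_year(a_z, params)
    if not epochs:
        return r_x / r_z
    num = sum(t * (r_z if shared else r_x) for t, shared in epochs)
    den = sum(t * r_z for t, _ in epochs)
    if den == 0:
        raise ValueError("epochs have zero total duration")
    return num / den
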