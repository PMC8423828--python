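"""Per-mutation-type linear models and the cross-dataset slope comparison.

Two regressions are compared for each of the nine mutation types: the
fraction of derived alleles against mean archaic fragment length across
individuals (polymorphism data; fragment length proxies mean generation
time), and the fraction of de novo mutations against mean parental age
across trio probands (pedigree data; probands aggregated by equal mean
parental age, points from fewer than two probands discarded, weighted least
squares with the proband count as weight).  Regressing one slope set on the
other across the nine types quantifies whether both datasets respond to
parental age the same way (a 1-to-1 relationship).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .spectrum import BASE6_TYPES, CT_SUBTYPES, TYPES9

#: The eight mutually exclusive categories underlying the nine reported types.
DISJOINT8 = tuple(t for t in TYPES9 if t != "C>T")


@dataclass(frozen=True)
class LinearFit:
    label: str
    intercept: float
    slope: float
    se_slope: float
    p_slope: float
    n: int
    weighted: bool = False

    @property
    def significant(self) -> bool:
        return self.p_slope < 0.05


def _fit(x: np.ndarray, y: np.ndarray, label: str, weights: np.ndarray | None = None) -> LinearFit:
    if x.size < 3:
        raise ValueError(f"{label}: need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError(f"{label}: constant predictor")
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    return LinearFit(
        label=label, intercept=float(res.params[0]), slope=float(res.params[1]),
        se_slope=float(res.bse[1]), p_slope=float(res.pvalues[1]), n=int(x.size),
        weighted=weights is not None,
    )


def fit_type_vs_fraglen(individuals: pd.DataFrame) -> dict[str, LinearFit]:
    """OLS of each of the nine type fractions on mean fragment length.

    ``individuals`` needs a ``mean_fragment_length`` column plus one column
    per type in :data:`genclock.spectrum.TYPES9` holding fractions.
    """
    x = individuals["mean_fragment_length"].to_numpy(float)
    return {t: _fit(x, individuals[t].to_numpy(float), t) for t in TYPES9}


# -- trio de novo mutation (DNM) table --------------------------------------


def read_dnm_table(path) -> pd.DataFrame:
    """Read a trio DNM table: proband, father_age, mother_age, per-type counts.

    Count columns may be the eight disjoint categories (C>T given by its
    three subtypes) or include a redundant C>T column, which is checked.
    Rows flagged as indels (optional boolean ``indel`` column) are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_dnm_table(df)


def validate_dnm_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "indel" in df.columns:
        df = df[~df["indel"].astype(bool)].drop(columns="indel")
    missing = [c for c in ("father_age", "mother_age", *DISJOINT8) if c not in df.columns]
    if missing:
        raise ValueError(f"DNM table missing columns {missing}")
    if ((df["father_age"] <= 10) | (df["mother_age"] <= 10)).any():
        raise ValueError("parental ages must exceed 10 years")
    subs = df[list(CT_SUBTYPES)].sum(axis=1)
    if "C>T" in df.columns:
        if not (df["C>T"] == subs).all():
            raise ValueError("C>T column inconsistent with its subtypes")
    else:
        df["C>T"] = subs
    return df


def aggregate_dnm(table: pd.DataFrame, round_decimals: int = 1) -> pd.DataFrame:
    """Aggregate proband DNM counts by equal (rounded) mean parental age.

    Mean parental age per proband is (father + mother)/2, rounded to
    ``round_decimals`` to define the grouping key.  Counts are summed within
    a group and fractions computed from the sums (not averaged over
    probands); groups with fewer than 2 probands are discarded.
    """
    table = validate_dnm_table(table)
    age = ((table["father_age"] + table["mother_age"]) / 2).round(round_decimals)
    grouped = table[list(TYPES9)].groupby(age).sum()
    n_probands = age.value_counts()
    grouped["n_probands"] = n_probands
    grouped = grouped[grouped["n_probands"] >= 2]
    denom = grouped[list(BASE6_TYPES)].sum(axis=1)
    out = pd.DataFrame({"mean_parental_age": grouped.index.to_numpy(float),
                        "n_probands": grouped["n_probands"].to_numpy(int)})
    for t in TYPES9:
        out[t] = (grouped[t] / denom).to_numpy(float)
    return out.reset_index(drop=True)


def fit_type_vs_age(aggregated: pd.DataFrame) -> dict[str, LinearFit]:
    """WLS of each type fraction on mean parental age, weights = n_probands."""
    x = aggregated["mean_parental_age"].to_numpy(float)
    w = aggregated["n_probands"].to_numpy(float)
    return {t: _fit(x, aggregated[t].to_numpy(float), t, weights=w) for t in TYPES9}


def compare_slopes(
    fits_a: Mapping[str, LinearFit], fits_b: Mapping[str, LinearFit]
) -> LinearFit:
    """OLS of slope set a on slope set b across matched mutation types.

    A slope near 1 indicates the two datasets respond identically to the
    underlying parental-age axis (up to the x-scale of each regression).
    """
    if set(fits_a) != set(fits_b):
        raise ValueError("mismatched type labels between fit sets")
    labels = sorted(fits_a)
    ya = np.array([fits_a[t].slope for t in labels])
    yb = np.array([fits_b[t].slope for t in labels])
    return _fit(yb, ya, "slopes_a_on_b")


def fits_to_frame(fits: Mapping[str, LinearFit]) -> pd.DataFrame:
    rows = [(f.label, f.intercept, f.slope, f.se_slope, f.p_slope, f.n, f.weighted)
            for f in fits.values()]
    return pd.DataFrame(rows, columns=["type", "intercept", "slope", "se_slope",
                                       "p_slope", "n", "weighted"])
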