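"""Per-type linear fits, trio-table aggregation, slope-on-slope comparison."""

import numpy as np
import pandas as pd
import pytest

from genclock.regression import (
    DISJOINT8,
    aggregate_dnm,
    compare_slopes,
    fit_type_vs_age,
    fit_type_vs_fraglen,
    fits_to_frame,
    validate_dnm_table,
)
from genclock.simulate import CohortConfig, GroupSpec, simulate_dnm_table, spectrum_probs
from genclock.spectrum import TYPES9


def toy_dnm(rows):
    """rows: (father_age, mother_age, counts dict)"""
    data = []
    for fa, ma, counts in rows:
        data.append({"father_age": fa, "mother_age": ma,
                     **{t: counts.get(t, 0) for t in DISJOINT8}})
    return pd.DataFrame(data)


class TestAggregation:
    def test_same_age_key_groups_and_counts_probands(self):
        table = toy_dnm([(30, 28, {"C>A": 4}), (29, 29, {"C>A": 2, "T>C": 2}),
                         (40, 40, {"C>A": 1})])
        agg = aggregate_dnm(table)
        # the lone proband at age 40 is discarded; the two at 29 merge
        assert agg["mean_parental_age"].tolist() == [29.0]
        assert agg["n_probands"].tolist() == [2]

    def test_fraction_of_sums_not_mean_of_fractions(self):
        # proband A: 1 of 1 C>A; proband B: 1 of 10 C>A; proband C keeps key alive
        table = toy_dnm([
            (30, 30, {"C>A": 1}),
            (30, 30, {"C>A": 1, "T>C": 9}),
            (30, 30, {"T>C": 1}),
        ])
        agg = aggregate_dnm(table)
        # summed counts: C>A 2 of 12 total
        assert agg.loc[0, "C>A"] == pytest.approx(2 / 12)
        mean_of_fractions = np.mean([1.0, 0.1, 0.0])
        assert agg.loc[0, "C>A"] != pytest.approx(mean_of_fractions)

    def test_rounding_parameter(self):
        table = toy_dnm([(30.04, 30.0, {"C>A": 1}), (30.06, 30.0, {"C>A": 1})])
        assert len(aggregate_dnm(table, round_decimals=0)) == 1
        assert len(aggregate_dnm(table, round_decimals=2)) == 0  # two singletons dropped

    def test_indel_rows_dropped(self):
        table = toy_dnm([(30, 30, {"C>A": 1}), (30, 30, {"C>A": 1})])
        table["indel"] = [False, True]
        assert len(validate_dnm_table(table)) == 1

    def test_inconsistent_ct_column_rejected(self):
        table = toy_dnm([(30, 30, {"CpG>TpG": 1})])
        table["C>T"] = [5]
        with pytest.raises(ValueError, match="C>T"):
            validate_dnm_table(table)


class TestFits:
    @staticmethod
    def frame_from_law(x, slopes, noise=0.0, rng=None):
        rows = []
        for xi in x:
            row = {"mean_fragment_length": xi}
            for i, t in enumerate(TYPES9):
                val = 0.1 + slopes.get(t, 0.0) * xi
                if noise and rng is not None:
                    val += rng.normal(0, noise)
                row[t] = val
            rows.append(row)
        return pd.DataFrame(rows)

    def test_constant_fractions_give_zero_slope(self):
        df = self.frame_from_law([1.0, 2.0, 3.0, 4.0], {})
        fits = fit_type_vs_fraglen(df)
        for f in fits.values():
            assert f.slope == pytest.approx(0.0, abs=1e-12)

    def test_known_slopes_recovered(self, rng):
        slopes = {"TCC>TTC": -0.002, "T>C": 0.003}
        x = np.linspace(50, 90, 40)
        df = self.frame_from_law(x, slopes, noise=0.005, rng=rng)
        fits = fit_type_vs_fraglen(df)
        for t, beta in slopes.items():
            assert abs(fits[t].slope - beta) < 2 * fits[t].se_slope

    def test_permuted_labels_center_null_at_zero(self, rng):
        x = np.linspace(50, 90, 30)
        df = self.frame_from_law(x, {"T>C": 0.004})
        betas = []
        for _ in range(200):
            shuffled = df.copy()
            shuffled["T>C"] = rng.permutation(df["T>C"].to_numpy())
            betas.append(fit_type_vs_fraglen(shuffled)["T>C"].slope)
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas))

    def test_constant_x_errors(self):
        df = self.frame_from_law([2.0, 2.0, 2.0], {})
        with pytest.raises(ValueError, match="constant"):
            fit_type_vs_fraglen(df)

    def test_equal_weights_match_ols_and_weight_scaling(self):
        table = simulate_dnm_table(
            CohortConfig(groups=[GroupSpec("g", 2, 30, 28)], seed=4), n_probands=300)
        agg = aggregate_dnm(table)
        fits_w = fit_type_vs_age(agg)
        agg_scaled = agg.copy()
        agg_scaled["n_probands"] *= 2
        fits_2w = fit_type_vs_age(agg_scaled)
        for t in TYPES9:
            assert fits_w[t].slope == pytest.approx(fits_2w[t].slope, rel=1e-9)
        agg_eq = agg.copy()
        agg_eq["n_probands"] = 1
        fits_eq = fit_type_vs_age(agg_eq)
        x = agg["mean_parental_age"].to_numpy()
        y = agg["T>C"].to_numpy()
        beta_ols = np.polyfit(x, y, 1)[0]
        assert fits_eq["T>C"].slope == pytest.approx(beta_ols, rel=1e-6)


class TestCompareSlopes:
    def test_identity_and_doubling(self):
        table = simulate_dnm_table(
            CohortConfig(groups=[GroupSpec("g", 2, 30, 28)], seed=5), n_probands=300)
        fits = fit_type_vs_age(aggregate_dnm(table))
        comp = compare_slopes(fits, fits)
        assert comp.slope == pytest.approx(1.0, rel=1e-9)
        assert comp.intercept == pytest.approx(0.0, abs=1e-12)
        doubled = {t: f.__class__(**{**f.__dict__, "slope": 2 * f.slope})
                   for t, f in fits.items()}
        assert compare_slopes(doubled, fits).slope == pytest.approx(2.0, rel=1e-9)

    def test_mismatched_labels_error(self):
        table = simulate_dnm_table(
            CohortConfig(groups=[GroupSpec("g", 2, 30, 28)], seed=6), n_probands=200)
        fits = fit_type_vs_age(aggregate_dnm(table))
        partial = {t: f for t, f in fits.items() if t != "C>A"}
        with pytest.raises(ValueError, match="label"):
            compare_slopes(partial, fits)


def test_age_gap_restriction_robustness():
    """Refitting on probands with similar parental ages moves slopes < 2 SE."""
    cfg = CohortConfig(groups=[GroupSpec("g", 2, 31, 28)], seed=8)
    table = simulate_dnm_table(cfg, n_probands=2000)
    full = fit_type_vs_age(aggregate_dnm(table))
    gap = (table["father_age"] - table["mother_age"]).abs()
    restricted_table = table[gap <= 5]
    restricted = fit_type_vs_age(aggregate_dnm(restricted_table))
    for t in ("TCC>TTC", "T>C", "CpG>TpG"):
        se = max(full[t].se_slope, restricted[t].se_slope)
        assert abs(full[t].slope - restricted[t].slope) < 2 * se


def test_generator_slopes_flow_into_fits():
    """The trio generator's age-linear spectrum is recovered by the WLS fits."""
    cfg = CohortConfig(groups=[GroupSpec("g", 2, 31, 28)], seed=9)
    table = simulate_dnm_table(cfg, n_probands=4000)
    fits = fit_type_vs_age(aggregate_dnm(table))
    # configured direction: TCC>TTC decreases with parental age, T>C increases
    assert fits["TCC>TTC"].slope < 0
    assert fits["T>C"].slope > 0
    frame = fits_to_frame(fits)
    assert set(frame["type"]) == set(TYPES9)
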