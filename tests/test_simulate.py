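"""Synthetic-cohort generator: decay law, age-dependent counts, determinism."""

import numpy as np
import pytest

from genclock.fragstats import estimate_generations
from genclock.simulate import (
    ChromSpec,
    CohortConfig,
    Dilution,
    GroupSpec,
    SecondPulse,
    _markov_tracts,
    cdnm_windows,
    callable_mask,
    effective_mean_age,
    expected_mutation_count,
    generations_since,
    lineage_epochs,
    repeat_mask,
    simulate_cohort,
    simulate_fragment_decay,
    simulate_mutations,
    simulate_window_counts,
    spectrum_probs,
    substream,
)
from genclock.spectrum import count_spectrum


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="admixture_fraction"):
            CohortConfig(groups=[GroupSpec("g", 1, 28, 28)], admixture_fraction=1.5)
        with pytest.raises(ValueError, match="ages"):
            GroupSpec("g", 1, 9, 28)
        with pytest.raises(ValueError, match="sampling_time"):
            CohortConfig(groups=[GroupSpec("g", 1, 28, 28, sampling_time_years=60_000)])

    def test_yaml_roundtrip(self, tiny_config, tmp_path):
        tiny_config.second_pulse = SecondPulse("EAS", 30_000, 0.01)
        tiny_config.dilution = Dilution("WEU", 0.3)
        path = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(path)
        back = CohortConfig.from_yaml(path)
        assert back == tiny_config

    def test_lineage_epochs(self, tiny_config):
        epochs = lineage_epochs(tiny_config, "EAS", 60_000)
        # private epoch to the split at the group's ages, then shared ancestral
        assert epochs[0] == (40_000, 28.0, 28.0)
        assert epochs[1] == (20_000, 29.0, 29.0)
        g = generations_since(tiny_config, "EAS", 60_000)
        assert g == pytest.approx(40_000 / 28 + 20_000 / 29)

    def test_ancient_sample_skips_private_epoch(self, tiny_config):
        tiny_config.groups.append(GroupSpec("ancient", 1, 28, 28, sampling_time_years=45_000))
        epochs = lineage_epochs(tiny_config, "ancient", 55_000)
        assert epochs == [(10_000, 29.0, 29.0)]


class TestSubstreams:
    def test_named_streams_independent_of_order(self):
        a = substream(3, "tracts", "g", "i0", "chr1").random(3)
        b = substream(3, "tracts", "g", "i0", "chr1").random(3)
        c = substream(3, "tracts", "g", "i1", "chr1").random(3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestTractDecay:
    def test_no_recombination_limit(self):
        """g = 0: a carrier chromosome is one full-length archaic tract."""
        rng = np.random.default_rng(0)
        n_carrier = n_empty = 0
        for _ in range(2000):
            tracts = _markov_tracts(rng, 0.6, 0.0, 0.3)
            if tracts:
                assert tracts == [(0.0, 0.6)]
                n_carrier += 1
            else:
                n_empty += 1
        assert abs(n_carrier / 2000 - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 2000)

    def test_exponential_mean_and_proportion(self):
        rng = np.random.default_rng(1)
        g, alpha = 1500.0, 0.02
        lengths, covered, total = [], 0.0, 0.0
        while len(lengths) < 6000:
            tracts = _markov_tracts(rng, 0.6, g, alpha)
            lengths.extend(hi - lo for lo, hi in tracts)
            covered += sum(hi - lo for lo, hi in tracts)
            total += 0.6
        lengths = np.array(lengths)
        expected = 1 / (g * (1 - alpha))
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(lengths.mean() - expected) < 3 * se
        assert covered / total == pytest.approx(alpha, rel=0.15)

    def test_snapping_and_sorting(self, tiny_config):
        frags = simulate_fragment_decay(tiny_config, "EAS")
        for ivs in frags.values():
            assert ivs.is_merged()
            for iv in ivs:
                assert iv.start % 1000 == 0 and iv.end % 1000 == 0

    def test_dilution_thins_without_shortening(self):
        base = CohortConfig(
            groups=[GroupSpec("g", 40, 28, 28)],
            chromosomes=(ChromSpec("chr1", 30_000_000),), seed=21)
        diluted_cfg = CohortConfig(
            groups=[GroupSpec("g", 40, 28, 28)],
            chromosomes=(ChromSpec("chr1", 30_000_000),), seed=21,
            dilution=Dilution("g", 0.3))
        lens_base = np.concatenate(
            [s.lengths() for s in simulate_fragment_decay(base, "g").values()])
        lens_dil = np.concatenate(
            [s.lengths() for s in simulate_fragment_decay(diluted_cfg, "g").values()])
        # total sequence drops by ~30%
        assert lens_dil.sum() / lens_base.sum() == pytest.approx(0.7, abs=0.06)
        # mean length unchanged within 3 SE
        se = np.sqrt(lens_base.var(ddof=1) / lens_base.size + lens_dil.var(ddof=1) / lens_dil.size)
        assert abs(lens_base.mean() - lens_dil.mean()) < 3 * se

    def test_deterministic_given_seed(self, tiny_config):
        a = simulate_fragment_decay(tiny_config, "WEU")
        b = simulate_fragment_decay(tiny_config, "WEU")
        assert all(a[k] == b[k] for k in a)


class TestMutations:
    def test_symmetric_groups_equal_expectation(self):
        cfg = CohortConfig(
            groups=[GroupSpec("a", 1, 29, 29), GroupSpec("b", 1, 29, 29)], seed=0)
        chrom = cfg.chromosomes[0]
        ea = expected_mutation_count(cfg, "a", chrom, "F", 10_000_000)
        eb = expected_mutation_count(cfg, "b", chrom, "F", 10_000_000)
        assert ea == eb

    def test_age_ratio_matches_closed_form(self):
        """Autosomal expectations follow the per-year pedigree rates by epoch."""
        from genclock.gentime import mu_per_year

        cfg = CohortConfig(
            groups=[GroupSpec("young", 1, 28, 28), GroupSpec("old", 1, 32, 32)],
            split_time_years=40_000, ooa_time_years=60_000, ancestral_mean_age=29,
            seed=0)
        chrom = cfg.chromosomes[0]
        r = (expected_mutation_count(cfg, "young", chrom, "F", 10_000_000)
             / expected_mutation_count(cfg, "old", chrom, "F", 10_000_000))
        num = 40_000 * mu_per_year(28) + 20_000 * mu_per_year(29)
        den = 40_000 * mu_per_year(32) + 20_000 * mu_per_year(29)
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_simulated_ratio_within_3se(self):
        cfg = CohortConfig(
            groups=[GroupSpec("young", 12, 28, 28), GroupSpec("old", 12, 32, 32)],
            chromosomes=(ChromSpec("chr1", 30_000_000),),
            seed=2, count_scale=2.0)
        young = simulate_mutations(cfg, "young")
        old = simulate_mutations(cfg, "old")
        cy = np.array([sum(r.dosage for r in recs) for recs in young.values()])
        co = np.array([sum(r.dosage for r in recs) for recs in old.values()])
        chrom = cfg.chromosomes[0]
        arr = callable_mask(cfg).arrays("chr1")
        call_bp = int((arr[:, 1] - arr[:, 0]).sum())
        # dosage weighting cancels in the ratio of group means
        exp_ratio = (expected_mutation_count(cfg, "young", chrom, "F", call_bp)
                     / expected_mutation_count(cfg, "old", chrom, "F", call_bp))
        ratio = cy.mean() / co.mean()
        se = ratio * np.sqrt(cy.var(ddof=1) / cy.size / cy.mean() ** 2
                             + co.var(ddof=1) / co.size / co.mean() ** 2)
        assert abs(ratio - exp_ratio) < 3 * se

    def test_variants_lie_in_callable_mask(self, tiny_config):
        muts = simulate_mutations(tiny_config, "EAS")
        mask = callable_mask(tiny_config)
        for recs in muts.values():
            for r in recs[:200]:
                assert mask.contains_position(r.chrom, r.pos - 1)

    def test_y_only_in_males_x_scaled_by_sex(self, tiny_config):
        muts = simulate_mutations(tiny_config, "EAS")
        for ind, recs in muts.items():
            sex = tiny_config.individual_sex("EAS", ind)
            y_count = sum(1 for r in recs if r.chrom == "chrY")
            if sex == "F":
                assert y_count == 0
            else:
                assert y_count > 0

    def test_contexts_consistent_with_categories(self, tiny_config):
        muts = simulate_mutations(tiny_config, "WEU")
        recs = next(iter(muts.values()))
        counts = count_spectrum(recs)
        assert counts.n_skipped == 0
        counts.validate()

    def test_cdnm_null_inflation_identical_probs(self):
        cfg = CohortConfig(groups=[GroupSpec("g", 1, 28, 28)], seed=0,
                           cdnm_cg_inflation_slope=0.0)
        from genclock.simulate import _inflate_cg
        probs = spectrum_probs(cfg, 28.5)
        assert _inflate_cg(probs, 1.0) == pytest.approx(probs)

    def test_cdnm_inflation_enriches_cg(self):
        cfg = CohortConfig(
            groups=[GroupSpec("g", 6, 28, 34)],
            chromosomes=(ChromSpec("chr1", 30_000_000),),
            seed=6, count_scale=3.0, cdnm_fraction=0.3)
        muts = simulate_mutations(cfg, "g")
        flags = cdnm_windows(cfg)["chr1"]
        inside = outside = in_cg = out_cg = 0
        for recs in muts.values():
            for r in recs:
                is_cg = {r.ancestral, r.derived} == {"C", "G"}
                if flags[(r.pos - 1) // cfg.cdnm_window_bp]:
                    inside += 1
                    in_cg += is_cg
                else:
                    outside += 1
                    out_cg += is_cg
        assert in_cg / inside > out_cg / outside

    def test_spectrum_probs_sum_to_one(self, tiny_config):
        probs = spectrum_probs(tiny_config, 26.0)
        assert sum(probs.values()) == pytest.approx(1.0)
        # configured directions
        assert probs["TCC>TTC"] > spectrum_probs(tiny_config, 32.0)["TCC>TTC"]


class TestWindowCounts:
    def test_poisson_mean_inside_fragments(self):
        cfg = CohortConfig(
            groups=[GroupSpec("g", 10, 28, 28)],
            chromosomes=(ChromSpec("chr1", 30_000_000),), seed=31)
        frags = simulate_fragment_decay(cfg, "g")
        tracks = simulate_window_counts(frags, cfg)
        tot = n = expo = 0.0
        for ind, per_chrom in tracks.items():
            t = per_chrom["chr1"]
            arr = frags[ind].arrays("chr1")
            if arr.shape[0] == 0:
                continue
            mid = (t.starts + t.ends) // 2
            idx = np.searchsorted(arr[:, 0], mid, side="right") - 1
            inside = (idx >= 0) & (mid < arr[np.clip(idx, 0, None), 1])
            tot += t.counts[inside].sum()
            n += inside.sum()
            expo += t.exposure[inside].sum()
        expected = cfg.lambda_archaic * expo
        se = np.sqrt(expected)  # Poisson
        assert abs(tot - expected) < 3 * se
        assert n > 500

    def test_track_shape_and_determinism(self, tiny_config):
        frags = simulate_fragment_decay(tiny_config, "EAS")
        t1 = simulate_window_counts(frags, tiny_config)
        t2 = simulate_window_counts(frags, tiny_config)
        ind = next(iter(t1))
        a, b = t1[ind]["chr1"], t2[ind]["chr1"]
        assert np.array_equal(a.counts, b.counts)
        assert np.allclose(a.callability, b.callability)
        assert a.ends[-1] == 10_000_000


class TestCohortBundle:
    def test_dataset_written_and_deterministic(self, tiny_config, tmp_path):
        from genclock.simulate import write_dataset

        ds1 = simulate_cohort(tiny_config)
        ds2 = simulate_cohort(tiny_config)
        assert ds1.metadata.equals(ds2.metadata)
        ind = ds1.metadata["individual"].iloc[0]
        assert ds1.variants[ind] == ds2.variants[ind]
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_dataset(ds1, out1)
        write_dataset(ds2, out2)
        for f in sorted(out1.iterdir()):
            assert (out2 / f.name).read_bytes() == f.read_bytes()

    def test_masks_partition_genome(self, tiny_config):
        rep = repeat_mask(tiny_config)
        call = callable_mask(tiny_config)
        from genclock.intervals import intersect_total
        _, shared = intersect_total(rep, call)
        assert shared == 0
        genome = sum(c.length for c in tiny_config.chromosomes)
        assert rep.total_bp + call.total_bp == genome

    def test_effective_mean_age_time_weighted(self, tiny_config):
        af, am = effective_mean_age(tiny_config, "EAS")
        assert af == pytest.approx((40_000 * 28 + 20_000 * 29) / 60_000)
        assert am == af
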