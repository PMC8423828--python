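"""End-to-end orchestration: simulate -> call -> compare -> infer.

Stages hand off through flat files in the output directory (so each stage is
independently re-runnable from the CLI) and contribute to one JSON report.
Every stage entry records the seed and wall time; the run is idempotent for
a given (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import fragstats, gentime, recomb, regression, sexsig, spectrum
from .hmm import (
    decode_fragments,
    fit_hmm,
    fragments_to_intervalset,
    high_confidence_fragments,
    write_fragments_bed,
)
from .intervals import (
    IntervalSet,
    classify_individual_fragments,
    downsample_individuals,
    intersect_total,
    merge_intervals,
    window_frequency,
    write_bed,
    write_frequency_bed,
)
from .simulate import CohortConfig, SyntheticDataset, simulate_cohort, write_dataset

log = logging.getLogger("genclock")


@dataclass
class PipelineConfig:
    cohort: CohortConfig
    n_perm: int = 999
    n_boot: int = 2000
    posterior_threshold: float = 0.8
    hmm_max_iter: int = 200
    hmm_tol: float = 1e-4
    reference_group: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cohort = CohortConfig.from_dict(doc.pop("cohort"))
        return cls(cohort=cohort, **doc)


STAGE_ORDER = (
    "simulate", "call", "intervals", "stats", "convert",
    "spectrum", "gentime", "sex", "regress",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _group_mean_lengths(called: dict[str, dict[str, IntervalSet]]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for group, per_ind in called.items():
        out[group] = {
            ind: float(ivs.lengths().mean()) if len(ivs) else float("nan")
            for ind, ivs in per_ind.items()
        }
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Any]:
    """Run all stages on a synthetic cohort; returns (and writes) the report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.cohort.seed
    report: dict[str, Any] = {"seed": seed, "stages": {}}

    ds: SyntheticDataset | None = None
    called: dict[str, dict[str, IntervalSet]] = {}
    mean_len_bp: dict[str, dict[str, float]] = {}
    mean_len_cM: dict[str, dict[str, float]] = {}
    fractions: dict[str, dict[str, float]] = {}
    counts_by_ind: dict[str, spectrum.SpectrumCounts] = {}

    def stage(name):
        def deco(fn):
            if name not in config.stages:
                return None
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as err:  # surface stage context
                raise StageError(name, err) from err
            wall = time.perf_counter() - t0
            report["stages"][name] = {"seed": seed, "wall_s": round(wall, 3), **(result or {})}
            log.info("stage %s: done in %.2fs", name, wall)
            return result
        return deco

    @stage("simulate")
    def _simulate():
        nonlocal ds
        ds = simulate_cohort(config.cohort)
        write_dataset(ds, out / "dataset")
        props = {}
        genome_bp = sum(c.length for c in config.cohort.chromosomes if not c.is_y)
        for group, per_ind in ds.truth_fragments.items():
            props[group] = float(np.mean([s.total_bp / genome_bp for s in per_ind.values()]))
        return {"n_individuals": len(ds.metadata), "true_archaic_proportion": props}

    @stage("call")
    def _call():
        assert ds is not None
        all_tracks = [t for tracks in ds.window_tracks.values() for t in tracks.values()]
        fit = fit_hmm(all_tracks, max_iter=config.hmm_max_iter, tol=config.hmm_tol)
        stats = {"lambda_background": fit.params.lambda_background,
                 "lambda_archaic": fit.params.lambda_archaic,
                 "converged": fit.converged, "warning": fit.warning}
        meta = ds.metadata.set_index("individual")
        recall_num = recall_den = false_num = called_den = 0
        for ind, tracks in ds.window_tracks.items():
            frags = [f for t in tracks.values()
                     for f in decode_fragments(t, fit.params, config.posterior_threshold,
                                               individual=ind)]
            frags = high_confidence_fragments(frags, config.posterior_threshold)
            group = meta.loc[ind, "group"]
            called.setdefault(group, {})[ind] = fragments_to_intervalset(frags)
            write_fragments_bed(frags, out / f"called_{ind}.bed")
            truth = ds.truth_fragments[group][ind]
            _, shared = intersect_total(merge_intervals(called[group][ind]), truth)
            recall_num += shared
            recall_den += truth.total_bp
            false_num += called[group][ind].total_bp - shared
            called_den += called[group][ind].total_bp
        stats["truth_bp_recall"] = recall_num / recall_den if recall_den else float("nan")
        stats["false_bp_fraction"] = false_num / called_den if called_den else float("nan")
        return stats

    @stage("intervals")
    def _intervals():
        groups = sorted(called)
        res: dict[str, Any] = {"joined_total_bp": {}, "frequency_mean": {}}
        joined = {}
        n_common = min(len(called[g]) for g in groups)
        balanced = {g: downsample_individuals(called[g], n_common, seed) for g in groups}
        for g in groups:
            joined[g] = merge_intervals(*balanced[g].values())
            res["joined_total_bp"][g] = joined[g].total_bp
            write_bed(joined[g], out / f"joined_{g}.bed")
            freq = window_frequency(joined[g], list(balanced[g].values()),
                                    config.cohort.window_bp)
            write_frequency_bed(freq, out / f"frequency_{g}.bed")
            res["frequency_mean"][g] = float(freq["count"].mean()) if len(freq) else 0.0
        if len(groups) >= 2:
            a, b = groups[:2]
            shared_set, shared_bp = intersect_total(joined[a], joined[b])
            write_bed(shared_set, out / "shared_joined.bed")
            res["shared_bp"] = shared_bp
            res["private_bp"] = {a: joined[a].total_bp - shared_bp,
                                 b: joined[b].total_bp - shared_bp}
            n_shared = {g: 0 for g in (a, b)}
            for g, other in ((a, b), (b, a)):
                for ind, ivs in balanced[g].items():
                    sh, _pr = classify_individual_fragments(ivs, joined[other])
                    n_shared[g] += len(sh)
            res["n_shared_individual_fragments"] = n_shared
        return res

    @stage("stats")
    def _stats():
        nonlocal mean_len_bp
        mean_len_bp = _group_mean_lengths(called)
        res: dict[str, Any] = {"group_mean_length_bp": {}, "bootstrap_ci": {}}
        for group, per_ind in mean_len_bp.items():
            vals = [v for v in per_ind.values() if np.isfinite(v)]
            res["group_mean_length_bp"][group] = float(np.mean(vals))
            ci = fragstats.bootstrap_ci(vals, np.mean, n_boot=config.n_boot, seed=seed)
            res["bootstrap_ci"][group] = [ci.lo, ci.hi]
        groups = sorted(mean_len_bp)
        if len(groups) >= 2:
            a, b = groups[:2]
            test = fragstats.permutation_diff_means(
                list(mean_len_bp[a].values()), list(mean_len_bp[b].values()),
                n_perm=config.n_perm, seed=seed)
            res["perm_diff_means"] = {"observed": test.observed, "p": test.p,
                                      "floored": test.floored, "n_perm": test.n_perm}
        if len(groups) >= 3:
            ftest = fragstats.permutation_F(
                [list(mean_len_bp[g].values()) for g in groups],
                n_perm=config.n_perm, seed=seed)
            res["perm_F"] = {"observed": ftest.observed, "p": ftest.p}
        pd.DataFrame(
            [(g, i, v) for g, d in mean_len_bp.items() for i, v in d.items()],
            columns=["group", "individual", "mean_fragment_length_bp"],
        ).to_csv(out / "fragment_summary.tsv", sep="\t", index=False)
        return res

    @stage("convert")
    def _convert():
        assert ds is not None
        nonlocal mean_len_cM
        rescaled = recomb.rescale_maps(ds.recomb_maps)
        res: dict[str, Any] = {"group_mean_length_cM": {}, "estimated_generations": {}}
        for group, per_ind in called.items():
            rmap = rescaled[group]
            per = {}
            for ind, ivs in per_ind.items():
                if len(ivs) == 0:
                    continue
                per[ind] = float(np.mean([recomb.fragment_length_cM(iv, rmap) for iv in ivs]))
            mean_len_cM[group] = per
            gmean = float(np.mean(list(per.values())))
            res["group_mean_length_cM"][group] = gmean
            res["estimated_generations"][group] = fragstats.estimate_generations(
                gmean, config.cohort.admixture_fraction)
        return res

    @stage("spectrum")
    def _spectrum():
        assert ds is not None
        meta = ds.metadata.set_index("individual")
        autosomes = {c.name for c in config.cohort.chromosomes if not (c.is_x or c.is_y)}
        res: dict[str, Any] = {"group_fractions": {}, "group_mean_count": {}}
        per_group_counts: dict[str, list[float]] = {}
        for ind, recs in ds.variants.items():
            auto = [r for r in recs if r.chrom in autosomes]
            counts = spectrum.count_spectrum(auto, individual=ind)
            counts_by_ind[ind] = counts
            fractions[ind] = spectrum.spectrum_fractions(counts)
            per_group_counts.setdefault(meta.loc[ind, "group"], []).append(counts.denominator)
        frame = pd.DataFrame(fractions).T
        frame.index.name = "individual"
        frame.to_csv(out / "spectrum_fractions.tsv", sep="\t")
        for group in per_group_counts:
            inds = meta.index[meta["group"] == group]
            res["group_fractions"][group] = {
                t: float(np.mean([fractions[i][t] for i in inds])) for t in spectrum.TYPES9}
            res["group_mean_count"][group] = float(np.mean(per_group_counts[group]))
        return res

    @stage("gentime")
    def _gentime():
        groups = [g.name for g in config.cohort.groups]
        if len(groups) < 2:
            return {}
        meta = (ds.metadata.set_index("individual") if ds is not None else None)
        mean_counts = {}
        for g in groups:
            inds = meta.index[meta["group"] == g]
            mean_counts[g] = float(np.mean([counts_by_ind[i].denominator for i in inds]))
        b = config.reference_group or groups[-1]  # reference population
        a = next(g for g in groups if g != b)  # test population
        ratio = mean_counts[a] / mean_counts[b]
        excess_pct = (ratio - 1) * 100
        scaled = gentime.excess_scaling(
            excess_pct, config.cohort.ooa_time_years, config.cohort.split_time_years)
        ref_age = config.cohort.group(b).mean_age
        est = gentime.estimate_parental_age(1 + scaled / 100, ref_age,
                                            config.cohort.pedigree_params)
        return {
            "count_ratio": ratio, "excess_pct": excess_pct, "scaled_excess_pct": scaled,
            "reference_group": b, "reference_age": ref_age,
            "estimated_age": est.a_x, "implied_difference_years": est.difference,
        }

    @stage("sex")
    def _sex():
        assert ds is not None
        meta = ds.metadata.set_index("individual")
        autosomes = {c.name for c in config.cohort.chromosomes if not (c.is_x or c.is_y)}
        xchroms = {c.name for c in config.cohort.chromosomes if c.is_x}
        from .simulate import callable_mask
        callable_ = callable_mask(config.cohort)
        L_A = sum((callable_.arrays(c)[:, 1] - callable_.arrays(c)[:, 0]).sum()
                  for c in autosomes)
        L_X = sum((callable_.arrays(c)[:, 1] - callable_.arrays(c)[:, 0]).sum()
                  for c in xchroms)
        res: dict[str, Any] = {"x_to_a": {}, "cg_cdnm_r": {}}
        ratios: dict[str, list[float]] = {}
        rvals: dict[str, list[float]] = {}
        for ind, recs in ds.variants.items():
            group = meta.loc[ind, "group"]
            if meta.loc[ind, "sex"] == "F" and L_X > 0:
                d_X = sum(r.dosage for r in recs if r.chrom in xchroms)
                d_A = sum(r.dosage for r in recs if r.chrom in autosomes)
                if d_A:
                    ratios.setdefault(group, []).append(sexsig.x_to_a_ratio(
                        sexsig.XARatioInput(d_X, d_A, float(L_X), float(L_A))))
            win = {}
            for r in recs:
                if r.chrom not in autosomes:
                    continue
                key = (r.chrom, (r.pos - 1) // config.cohort.cdnm_window_bp)
                d_cg, d_non = win.get(key, (0, 0))
                is_cg = {r.ancestral, r.derived} == {"C", "G"}
                win[key] = (d_cg + r.dosage * is_cg, d_non + r.dosage * (not is_cg))
            rows = [(c, w, ds.cdnm_flags[c][w], cg, non) for (c, w), (cg, non) in win.items()]
            df = pd.DataFrame(rows, columns=["chrom", "window", "cdnm", "d_cg", "d_noncg"])
            try:
                rvals.setdefault(group, []).append(sexsig.cg_cdnm_ratio(df).r)
            except ValueError:
                pass
        for group in sorted(set(ratios) | set(rvals)):
            if group in ratios:
                res["x_to_a"][group] = float(np.mean(ratios[group]))
            if group in rvals:
                res["cg_cdnm_r"][group] = float(np.mean(rvals[group]))
        res["y_rate_sensitivity_pct"] = {
            g.name: sexsig.y_rate_sensitivity(g.a_f, config.cohort.pedigree_params)
            for g in config.cohort.groups}
        return res

    @stage("regress")
    def _regress():
        assert ds is not None
        meta = ds.metadata.set_index("individual")
        rows = []
        for ind, fr in fractions.items():
            group = meta.loc[ind, "group"]
            ml = mean_len_bp.get(group, {}).get(ind)
            if ml is None or not np.isfinite(ml):
                continue
            rows.append({"individual": ind, "mean_fragment_length": ml, **fr})
        cohort_fits = regression.fit_type_vs_fraglen(pd.DataFrame(rows))
        agg = regression.aggregate_dnm(ds.dnm_table)
        dnm_fits = regression.fit_type_vs_age(agg)
        comp = regression.compare_slopes(cohort_fits, dnm_fits)
        regression.fits_to_frame(cohort_fits).to_csv(out / "fits_cohort.tsv", sep="\t", index=False)
        regression.fits_to_frame(dnm_fits).to_csv(out / "fits_dnm.tsv", sep="\t", index=False)
        return {
            "cohort_slopes": {t: f.slope for t, f in cohort_fits.items()},
            "dnm_slopes": {t: f.slope for t, f in dnm_fits.items()},
            "slope_on_slope": comp.slope,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
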