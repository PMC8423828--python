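"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator produces, from one seed, everything the downstream stages
consume: true archaic tracts per individual (exponential length decay under
one-pulse, two-pulse or dilution demographies), per-window private-SNP
tracks with callability and local mutation-rate scale (the HMM caller's
input), derived-allele collections whose counts and 9-type spectrum depend
linearly on parental age (with X/Y sex-exposure scaling and C>G-enriched
clustered-DNM windows), per-group recombination maps, callable masks, and a
trio de novo mutation table.

Tract model.  Along a chromosome measured in Morgans, archaic ancestry g
generations after a pulse of fraction alpha is approximated as a two-state
Markov process: archaic segment lengths ~ Exp(mean 1/(g(1-alpha))), gaps
~ Exp(mean 1/(g*alpha)), stationary archaic fraction alpha.  g accrues
piecewise over the lineage's epochs (ancestral mean age before the split,
the group's own mean parental age after).  A second pulse layers an
independent, younger (hence longer-tract) process onto its target group;
dilution drops whole tracts with the stated probability, leaving the length
distribution untouched.  Boundaries snap to the 1 kb window grid.

Randomness.  All draws flow from the cohort seed through named substreams
(one per individual x chromosome x purpose), so adding individuals or
stages never perturbs existing output; same seed + config is byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gentime import DEFAULT_PARAMS, PedigreeRegressionParams
from .hmm import WindowTrack, write_window_tracks
from .intervals import IntervalSet, merge_intervals, write_bed
from .recomb import RecombinationMap, write_hapmap
from .spectrum import COMPLEMENT, VariantRecord, write_variants_tsv

BASES = np.array(list("ACGT"))

#: Default 9-type spectrum composition at a mean parental age of 29 years
#: (eight disjoint categories; roughly the human polymorphism spectrum).
DEFAULT_SPECTRUM_BASE = {
    "C>A": 0.095, "C>G": 0.085, "CpG>TpG": 0.170, "TCC>TTC": 0.030,
    "C>T'": 0.190, "T>A": 0.065, "T>C": 0.265, "T>G": 0.100,
}
#: Per-year slopes of the category fractions in mean parental age (sum 0).
#: TCC>TTC decreases with parental age; CpG>TpG is flat.
DEFAULT_SPECTRUM_SLOPES = {
    "C>A": 0.0002, "C>G": 0.0, "CpG>TpG": 0.0, "TCC>TTC": -0.0008,
    "C>T'": -0.0004, "T>A": 0.0, "T>C": 0.0008, "T>G": 0.0002,
}


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    is_x: bool = False
    is_y: bool = False


DEFAULT_CHROMOSOMES = (
    ChromSpec("chr1", 50_000_000),
    ChromSpec("chr2", 50_000_000),
    ChromSpec("chrX", 30_000_000, is_x=True),
    ChromSpec("chrY", 10_000_000, is_y=True),
)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_individuals: int
    a_f: float  # mean paternal age, years
    a_m: float  # mean maternal age, years
    sampling_time_years: float = 0.0
    sex_ratio: float = 0.5  # proportion female

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.a_f <= 10 or self.a_m <= 10:
            raise ValueError("parental ages must exceed 10 years")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")

    @property
    def mean_age(self) -> float:
        return (self.a_f + self.a_m) / 2


@dataclass(frozen=True)
class SecondPulse:
    target_group: str
    time_years: float
    fraction: float


@dataclass(frozen=True)
class Dilution:
    target_group: str
    proportion: float  # proportion of non-admixed ancestry mixed in


@dataclass
class CohortConfig:
    groups: list[GroupSpec]
    chromosomes: tuple[ChromSpec, ...] = DEFAULT_CHROMOSOMES
    admixture_time_years: float = 55_000.0
    admixture_fraction: float = 0.02
    split_time_years: float = 40_000.0
    ooa_time_years: float = 60_000.0
    ancestral_mean_age: float = 29.0
    second_pulse: SecondPulse | None = None
    dilution: Dilution | None = None
    seed: int = 0
    # recombination map
    recomb_rate_cM_Mb: float = 1.2
    recomb_blocks: int = 1
    recomb_rate_jitter: float = 0.0  # lognormal sigma on block rates
    # window tracks
    window_bp: int = 1000
    lambda_background: float = 0.02
    lambda_archaic: float = 0.4
    callability_beta: tuple[float, float] = (18.0, 2.0)
    low_callability_fraction: float = 0.02
    mutrate_scale_cv: float = 0.2
    # mutations
    genome_ref_bp: float = 2.9e9
    count_scale: float = 1.0
    het_fraction: float = 0.7
    spectrum_base: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM_BASE))
    spectrum_slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM_SLOPES))
    spectrum_ref_age: float = 29.0
    cdnm_window_bp: int = 1_000_000
    cdnm_fraction: float = 0.1
    cdnm_cg_inflation_slope: float = 0.05  # factor = 1 + slope * (a_m - 20)
    repeat_mask_fraction: float = 0.05
    pedigree_params: PedigreeRegressionParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        if not 0 < self.admixture_fraction < 1:
            raise ValueError("admixture_fraction must lie in (0, 1)")
        if not 0 <= self.split_time_years <= self.admixture_time_years:
            raise ValueError("need admixture_time >= split_time >= 0")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g in self.groups:
            if g.sampling_time_years >= self.admixture_time_years:
                raise ValueError(
                    f"group {g.name}: sampling_time must precede the admixture event"
                )
        if self.second_pulse and self.second_pulse.target_group not in names:
            raise ValueError("second_pulse target group not in config")
        if self.dilution and self.dilution.target_group not in names:
            raise ValueError("dilution target group not in config")

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no group named {name!r}")

    def individuals(self, group: str) -> list[str]:
        g = self.group(group)
        return [f"{g.name}_{i:03d}" for i in range(g.n_individuals)]

    def individual_sex(self, group: str, individual: str) -> str:
        """Deterministic sex assignment honouring the group's sex ratio."""
        g = self.group(group)
        idx = self.individuals(group).index(individual)
        n_female = round(g.n_individuals * g.sex_ratio)
        return "F" if idx < n_female else "M"

    # -- YAML round-trip -----------------------------------------------

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["chromosomes"] = [asdict(c) for c in self.chromosomes]
        doc["groups"] = [asdict(g) for g in self.groups]
        doc["pedigree_params"] = asdict(self.pedigree_params)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "CohortConfig":
        doc = dict(doc)
        doc["groups"] = [GroupSpec(**g) for g in doc["groups"]]
        if "chromosomes" in doc:
            doc["chromosomes"] = tuple(ChromSpec(**c) for c in doc["chromosomes"])
        if doc.get("second_pulse"):
            doc["second_pulse"] = SecondPulse(**doc["second_pulse"])
        if doc.get("dilution"):
            doc["dilution"] = Dilution(**doc["dilution"])
        if doc.get("pedigree_params"):
            doc["pedigree_params"] = PedigreeRegressionParams(**doc["pedigree_params"])
        if "callability_beta" in doc:
            doc["callability_beta"] = tuple(doc["callability_beta"])
        return cls(**doc)


def substream(seed: int, *names) -> np.random.Generator:
    """Named, order-independent RNG substream derived from the cohort seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


# -- demographic bookkeeping -------------------------------------------------


def lineage_epochs(
    config: CohortConfig, group: str, until_years: float
) -> list[tuple[float, float, float]]:
    """(duration, a_f, a_m) epochs along a group's lineage back to ``until_years``.

    From the sampling time back to the population split the lineage uses the
    group's own parental ages; beyond the split (and for samples older than
    the split) the shared ancestral mean age applies to both parents.
    """
    g = config.group(group)
    t0 = g.sampling_time_years
    if until_years <= t0:
        raise ValueError("epoch horizon precedes the sampling time")
    split = config.split_time_years
    anc = config.ancestral_mean_age
    epochs: list[tuple[float, float, float]] = []
    private_end = min(split, until_years)
    if private_end > t0:
        epochs.append((private_end - t0, g.a_f, g.a_m))
    shared_start = max(split, t0)
    if until_years > shared_start:
        epochs.append((until_years - shared_start, anc, anc))
    return epochs


def generations_since(config: CohortConfig, group: str, event_time_years: float) -> float:
    """Generations between a group's sampling time and a past event."""
    return sum(t / ((af + am) / 2) for t, af, am in lineage_epochs(config, group, event_time_years))


# -- recombination maps ------------------------------------------------------


def group_recomb_map(config: CohortConfig, group: str) -> RecombinationMap:
    """Per-group piecewise-constant map (jittered block rates if configured)."""
    segs: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        if chrom.is_y:
            continue
        rng = substream(config.seed, "map", group, chrom.name)
        n = max(1, config.recomb_blocks)
        edges = np.linspace(0, chrom.length, n + 1)
        rates = np.full(n, config.recomb_rate_cM_Mb)
        if config.recomb_rate_jitter > 0:
            rates = rates * rng.lognormal(
                -config.recomb_rate_jitter**2 / 2, config.recomb_rate_jitter, n
            )
        segs[chrom.name] = np.column_stack([edges[:-1], edges[1:], rates])
    return RecombinationMap(group, segs)


def _morgan_grid(segments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (bp edges, Morgan edges) for a piecewise-constant map."""
    bp = np.r_[segments[0, 0], segments[:, 1]]
    morgans = np.r_[0.0, np.cumsum((segments[:, 1] - segments[:, 0]) * segments[:, 2] * 1e-8)]
    return bp, morgans


def _morgan_to_bp(pos_m: np.ndarray, bp_edges: np.ndarray, m_edges: np.ndarray) -> np.ndarray:
    return np.interp(pos_m, m_edges, bp_edges)


# -- archaic tract simulation ------------------------------------------------


def _markov_tracts(
    rng: np.random.Generator, total_morgans: float, g: float, alpha: float
) -> list[tuple[float, float]]:
    """Alternating archaic/background exponential segments over [0, total] M."""
    if g <= 0:
        # no recombination since admixture: carrier chromosome is one tract
        return [(0.0, total_morgans)] if rng.random() < alpha else []
    mean_arch = 1.0 / (g * (1 - alpha))
    mean_back = 1.0 / (g * alpha)
    pos = 0.0
    archaic = rng.random() < alpha
    tracts = []
    while pos < total_morgans:
        seg = rng.exponential(mean_arch if archaic else mean_back)
        end = min(pos + seg, total_morgans)
        if archaic:
            tracts.append((pos, end))
        pos = end
        archaic = not archaic
    return tracts


def _snap(value: float, grid: int) -> int:
    return int(round(value / grid)) * grid


def simulate_fragment_decay(
    config: CohortConfig, group: str, rmap: RecombinationMap | None = None
) -> dict[str, IntervalSet]:
    """True archaic tracts per individual of a group.

    Tract lengths follow the exponential decay law for the group's
    generations-since-admixture (piecewise over shared and private epochs);
    a configured second pulse adds an independent younger layer private to
    its target group; dilution thins tracts without changing their lengths.
    Boundaries snap to the 1 kb grid.
    """
    gspec = config.group(group)
    if gspec.sampling_time_years >= config.admixture_time_years:
        raise ValueError("sampling_time must precede the admixture event")
    rmap = rmap or group_recomb_map(config, group)
    layers: list[tuple[str, float, float]] = [
        ("pulse1", generations_since(config, group, config.admixture_time_years),
         config.admixture_fraction)
    ]
    sp = config.second_pulse
    if sp is not None and sp.target_group == group:
        if not gspec.sampling_time_years < sp.time_years <= config.admixture_time_years:
            raise ValueError("second pulse time outside (sampling, admixture]")
        layers.append(("pulse2", generations_since(config, group, sp.time_years), sp.fraction))
    out: dict[str, IntervalSet] = {}
    for ind in config.individuals(group):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom in config.chromosomes:
            if chrom.is_y:
                continue
            segs = rmap.segments[chrom.name]
            bp_edges, m_edges = _morgan_grid(segs)
            total_m = float(m_edges[-1])
            snapped: list[tuple[int, int]] = []
            for layer_name, g, alpha in layers:
                rng = substream(config.seed, "tracts", layer_name, group, ind, chrom.name)
                for lo_m, hi_m in _markov_tracts(rng, total_m, g, alpha):
                    lo, hi = _morgan_to_bp(np.array([lo_m, hi_m]), bp_edges, m_edges)
                    start = _snap(lo, config.window_bp)
                    end = _snap(hi, config.window_bp)
                    if end > start:
                        snapped.append((start, min(end, chrom.length)))
            if snapped:
                per_chrom[chrom.name] = snapped
        tracts = merge_intervals(
            IntervalSet.from_tuples((c, s, e) for c, ivs in per_chrom.items() for s, e in ivs)
        )
        dil = config.dilution
        if dil is not None and dil.target_group == group:
            rng = substream(config.seed, "dilution", group, ind)
            keep = IntervalSet.from_tuples(
                iv for iv in tracts if rng.random() >= dil.proportion
            )
            tracts = keep
        out[ind] = tracts
    return out


# -- masks and cDNM annotation ----------------------------------------------


def repeat_mask(config: CohortConfig) -> IntervalSet:
    """Cohort-wide repeat mask: random 10 kb blocks covering the configured fraction."""
    block = 10_000
    ivs = []
    for chrom in config.chromosomes:
        rng = substream(config.seed, "mask", chrom.name)
        n_blocks = int(config.repeat_mask_fraction * chrom.length / block)
        if n_blocks == 0:
            continue
        starts = rng.choice(chrom.length // block, size=n_blocks, replace=False) * block
        ivs.extend((chrom.name, int(s), int(s) + block) for s in starts)
    return merge_intervals(IntervalSet.from_tuples(ivs)) if ivs else IntervalSet()


def callable_mask(config: CohortConfig) -> IntervalSet:
    """Complement of the repeat mask over the configured chromosomes."""
    repeats = repeat_mask(config)
    ivs = []
    for chrom in config.chromosomes:
        pos = 0
        for _, s, e in (iv for iv in repeats if iv.chrom == chrom.name):
            if s > pos:
                ivs.append((chrom.name, pos, s))
            pos = max(pos, e)
        if pos < chrom.length:
            ivs.append((chrom.name, pos, chrom.length))
    return IntervalSet.from_tuples(ivs)


def cdnm_windows(config: CohortConfig) -> dict[str, np.ndarray]:
    """Cohort-wide cDNM flags per 1 Mb window (autosomes), seeded from config."""
    flags: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        if chrom.is_x or chrom.is_y:
            continue
        n = -(-chrom.length // config.cdnm_window_bp)
        rng = substream(config.seed, "cdnm", chrom.name)
        flags[chrom.name] = rng.random(n) < config.cdnm_fraction
    return flags


# -- mutation simulation -----------------------------------------------------

_EXPOSURE = {"A": (0.5, 0.5), "X": (1 / 3, 2 / 3), "Y": (1.0, 0.0)}  # (paternal, maternal)


def _chrom_class(chrom: ChromSpec) -> str:
    return "X" if chrom.is_x else "Y" if chrom.is_y else "A"


def _copies(chrom: ChromSpec, sex: str) -> int:
    if chrom.is_y:
        return 0 if sex == "F" else 1
    if chrom.is_x:
        return 2 if sex == "F" else 1
    return 2


def expected_mutation_count(
    config: CohortConfig, group: str, chrom: ChromSpec, sex: str, callable_bp: int
) -> float:
    """Expected derived-allele count on one chromosome since the Out-of-Africa.

    Per epoch, each parental lineage contributes its per-generation pedigree
    rate converted to a yearly rate by its own mean age, weighted by the
    chromosome's sex exposure (autosomes 1/2:1/2, X 1/3 paternal : 2/3
    maternal, Y paternal only):

        rate/year = 2 (w_f mu_f,g(a_f)/a_f + w_m mu_m,g(a_m)/a_m)

    scaled by chromosome copies/2 and callable_bp / genome_ref_bp.  With
    a_f = a_m = a-bar this reduces to (1/a-bar) * mu_g on the autosomes, the
    yearly-rate form the generation-time equations invert.
    """
    w_f, w_m = _EXPOSURE[_chrom_class(chrom)]
    params = config.pedigree_params
    rate_years = 0.0
    for t, af, am in lineage_epochs(config, group, config.ooa_time_years):
        per_year = 2 * (w_f * params.paternal_per_generation(af) / af
                        + w_m * params.maternal_per_generation(am) / am)
        rate_years += t * per_year
    copies = _copies(chrom, sex)
    return (copies / 2) * rate_years * callable_bp / config.genome_ref_bp * config.count_scale


def effective_mean_age(config: CohortConfig, group: str) -> tuple[float, float]:
    """Time-weighted (a_f, a_m) over the lineage back to the Out-of-Africa."""
    epochs = lineage_epochs(config, group, config.ooa_time_years)
    total = sum(t for t, _, _ in epochs)
    af = sum(t * af for t, af, _ in epochs) / total
    am = sum(t * am for t, _, am in epochs) / total
    return af, am


def spectrum_probs(config: CohortConfig, mean_age: float) -> dict[str, float]:
    """Eight-category type probabilities, linear in mean parental age."""
    probs = {
        t: max(config.spectrum_base[t]
               + config.spectrum_slopes.get(t, 0.0) * (mean_age - config.spectrum_ref_age), 0.0)
        for t in config.spectrum_base
    }
    total = sum(probs.values())
    return {t: p / total for t, p in probs.items()}


def _inflate_cg(probs: dict[str, float], factor: float) -> dict[str, float]:
    out = dict(probs)
    out["C>G"] = probs["C>G"] * factor
    total = sum(out.values())
    return {t: p / total for t, p in out.items()}


def _allowed_contexts(category: str) -> tuple[str, str, list[tuple[str, str]]]:
    """Pyrimidine-strand (anc, der, allowed (ctx5, ctx3) pairs) per category."""
    all_pairs = [(a, b) for a in "ACGT" for b in "ACGT"]
    if category == "CpG>TpG":
        return "C", "T", [(a, "G") for a in "ACGT"]
    if category == "TCC>TTC":
        return "C", "T", [("T", "C")]
    if category == "C>T'":
        return "C", "T", [p for p in all_pairs if p[1] != "G" and p != ("T", "C")]
    anc, der = category.split(">")
    return anc, der, all_pairs


_CONTEXT_TABLE = {
    c: _allowed_contexts(c)
    for c in ("C>A", "C>G", "CpG>TpG", "TCC>TTC", "C>T'", "T>A", "T>C", "T>G")
}


def _realize_contexts(
    categories: np.ndarray, cats: list[str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (anc, der, ctx5, ctx3) draws; half recorded on the purine strand."""
    n = categories.shape[0]
    anc = np.empty(n, dtype="U1")
    der = np.empty(n, dtype="U1")
    c5 = np.empty(n, dtype="U1")
    c3 = np.empty(n, dtype="U1")
    for ci, cat in enumerate(cats):
        sel = categories == ci
        k = int(sel.sum())
        if k == 0:
            continue
        a, d, pairs = _CONTEXT_TABLE[cat]
        pick = rng.integers(0, len(pairs), size=k)
        anc[sel] = a
        der[sel] = d
        c5[sel] = np.array([p[0] for p in pairs], dtype="U1")[pick]
        c3[sel] = np.array([p[1] for p in pairs], dtype="U1")[pick]
    flip = rng.random(n) < 0.5
    comp = np.vectorize(COMPLEMENT.get)
    if flip.any():
        anc[flip], der[flip] = comp(anc[flip]), comp(der[flip])
        c5[flip], c3[flip] = comp(c3[flip]), comp(c5[flip])
    return anc, der, c5, c3


def simulate_mutations(config: CohortConfig, group: str) -> dict[str, list[VariantRecord]]:
    """Derived-allele records per individual (autosomes, X, Y).

    Counts are Poisson with the epoch-summed, age-dependent means of
    :func:`expected_mutation_count`; categories follow the age-linear
    spectrum, with the C>G fraction inflated inside cohort-wide cDNM windows
    by 1 + slope * (a_m - 20); positions are uniform over the callable mask.
    """
    gspec = config.group(group)
    callable_ = callable_mask(config)
    cdnm = cdnm_windows(config)
    af_eff, am_eff = effective_mean_age(config, group)
    base_probs = spectrum_probs(config, (af_eff + am_eff) / 2)
    inflation = max(1.0 + config.cdnm_cg_inflation_slope * (gspec.a_m - 20.0), 0.0)
    cdnm_probs = _inflate_cg(base_probs, inflation)
    cats = sorted(base_probs)
    p_base = np.array([base_probs[c] for c in cats])
    p_cdnm = np.array([cdnm_probs[c] for c in cats])
    out: dict[str, list[VariantRecord]] = {}
    for ind in config.individuals(group):
        sex = config.individual_sex(group, ind)
        records: list[VariantRecord] = []
        for chrom in config.chromosomes:
            arr = callable_.arrays(chrom.name)
            if arr.shape[0] == 0:
                continue
            lens = arr[:, 1] - arr[:, 0]
            call_bp = int(lens.sum())
            mean = expected_mutation_count(config, group, chrom, sex, call_bp)
            if mean <= 0:
                continue
            rng = substream(config.seed, "mutations", group, ind, chrom.name)
            n = rng.poisson(mean)
            if n == 0:
                continue
            offsets = np.sort(rng.integers(0, call_bp, size=n))
            cum = np.r_[0, np.cumsum(lens)]
            block = np.searchsorted(cum, offsets, side="right") - 1
            pos0 = arr[block, 0] + (offsets - cum[block])
            flags = cdnm.get(chrom.name)
            if flags is not None:
                in_cdnm = flags[pos0 // config.cdnm_window_bp]
            else:
                in_cdnm = np.zeros(n, dtype=bool)
            cat_idx = np.empty(n, dtype=np.int64)
            if (~in_cdnm).any():
                cat_idx[~in_cdnm] = rng.choice(len(cats), size=int((~in_cdnm).sum()), p=p_base)
            if in_cdnm.any():
                cat_idx[in_cdnm] = rng.choice(len(cats), size=int(in_cdnm.sum()), p=p_cdnm)
            anc, der, c5, c3 = _realize_contexts(cat_idx, cats, rng)
            dosage = np.where(rng.random(n) < config.het_fraction, 1, 2)
            for i in range(n):
                records.append(VariantRecord(
                    chrom=chrom.name, pos=int(pos0[i]) + 1, ancestral=str(anc[i]),
                    derived=str(der[i]), ctx5=str(c5[i]), ctx3=str(c3[i]),
                    dosage=int(dosage[i]), individual=ind,
                ))
        out[ind] = records
    return out


# -- window tracks -----------------------------------------------------------


def simulate_window_counts(
    truth_fragments: Mapping[str, IntervalSet], config: CohortConfig
) -> dict[str, dict[str, WindowTrack]]:
    """Per-individual 1 kb window tracks with Poisson private-SNP counts.

    Window state (archaic/background) follows the truth fragments (snapped to
    the window grid); counts ~ Poisson(lambda_state * callability *
    mutrate_scale); a small fraction of windows get near-zero callability to
    emulate coverage dips.
    """
    out: dict[str, dict[str, WindowTrack]] = {}
    for ind, fragments in truth_fragments.items():
        tracks: dict[str, WindowTrack] = {}
        for chrom in config.chromosomes:
            if chrom.is_y:
                continue
            rng = substream(config.seed, "windows", ind, chrom.name)
            starts = np.arange(0, chrom.length, config.window_bp, dtype=np.int64)
            ends = np.minimum(starts + config.window_bp, chrom.length)
            a, b = config.callability_beta
            call = rng.beta(a, b, size=starts.shape[0])
            dips = rng.random(starts.shape[0]) < config.low_callability_fraction
            call[dips] = rng.uniform(0, 0.04, size=int(dips.sum()))
            cv = config.mutrate_scale_cv
            if cv > 0:
                shape = 1.0 / cv**2
                scale = rng.gamma(shape, 1.0 / shape, size=starts.shape[0])
            else:
                scale = np.ones(starts.shape[0])
            mid = (starts + ends) // 2
            frag_arr = fragments.arrays(chrom.name)
            state = np.zeros(starts.shape[0], dtype=bool)
            if frag_arr.shape[0]:
                idx = np.searchsorted(frag_arr[:, 0], mid, side="right") - 1
                ok = idx >= 0
                state[ok] = mid[ok] < frag_arr[idx[ok], 1]
            lam = np.where(state, config.lambda_archaic, config.lambda_background)
            counts = rng.poisson(lam * call * scale)
            tracks[chrom.name] = WindowTrack(chrom.name, starts, ends, counts, call, scale)
        out[ind] = tracks
    return out


# -- trio DNM table ----------------------------------------------------------


def simulate_dnm_table(
    config: CohortConfig,
    n_probands: int = 500,
    mean_father_age: float = 31.0,
    mean_mother_age: float = 28.0,
    age_sd: float = 4.5,
) -> pd.DataFrame:
    """Synthetic trio table: parental ages and per-type de novo counts.

    Total DNM per proband ~ Poisson(pedigree per-generation rate at the
    proband's parental ages); the split over the eight categories follows
    the age-linear spectrum at the proband's mean parental age.
    """
    rng = substream(config.seed, "dnm")
    params = config.pedigree_params
    fa = np.clip(rng.normal(mean_father_age, age_sd, n_probands), 16, 60)
    ma = np.clip(rng.normal(mean_mother_age, age_sd, n_probands), 16, 60)
    cats = sorted(config.spectrum_base)
    rows = []
    for i in range(n_probands):
        total = rng.poisson(params.paternal_per_generation(fa[i])
                            + params.maternal_per_generation(ma[i]))
        probs = spectrum_probs(config, (fa[i] + ma[i]) / 2)
        counts = rng.multinomial(total, [probs[c] for c in cats])
        rows.append((f"proband_{i:04d}", round(fa[i], 1), round(ma[i], 1), *counts))
    return pd.DataFrame(rows, columns=["proband", "father_age", "mother_age", *cats])


# -- cohort bundle -----------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: CohortConfig
    truth_fragments: dict[str, dict[str, IntervalSet]]  # group -> individual -> set
    window_tracks: dict[str, dict[str, WindowTrack]]  # individual -> chrom -> track
    variants: dict[str, list[VariantRecord]]  # individual -> records
    recomb_maps: dict[str, RecombinationMap]  # group -> map
    cdnm_flags: dict[str, np.ndarray]
    masks: IntervalSet  # repeat mask (non-callable)
    metadata: pd.DataFrame  # individual, group, sex, sampling_time
    dnm_table: pd.DataFrame


def simulate_cohort(config: CohortConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset for every group in the config."""
    truth: dict[str, dict[str, IntervalSet]] = {}
    variants: dict[str, list[VariantRecord]] = {}
    maps: dict[str, RecombinationMap] = {}
    meta_rows = []
    all_tracks: dict[str, dict[str, WindowTrack]] = {}
    for g in config.groups:
        maps[g.name] = group_recomb_map(config, g.name)
        truth[g.name] = simulate_fragment_decay(config, g.name, maps[g.name])
        variants.update(simulate_mutations(config, g.name))
        all_tracks.update(simulate_window_counts(truth[g.name], config))
        for ind in config.individuals(g.name):
            meta_rows.append((ind, g.name, config.individual_sex(g.name, ind),
                              g.sampling_time_years))
    return SyntheticDataset(
        config=config,
        truth_fragments=truth,
        window_tracks=all_tracks,
        variants=variants,
        recomb_maps=maps,
        cdnm_flags=cdnm_windows(config),
        masks=repeat_mask(config),
        metadata=pd.DataFrame(meta_rows, columns=["individual", "group", "sex", "sampling_time"]),
        dnm_table=simulate_dnm_table(config),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Flat-file export: BED truth, TSV variants/tracks/metadata, HapMap maps, YAML config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.config.to_yaml(out / "config.yaml")
    ds.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    ds.dnm_table.to_csv(out / "dnm_table.tsv", sep="\t", index=False)
    write_bed(ds.masks, out / "repeat_mask.bed")
    cdnm_rows = []
    for chrom, flags in sorted(ds.cdnm_flags.items()):
        for i, flag in enumerate(flags):
            cdnm_rows.append((chrom, i * ds.config.cdnm_window_bp,
                              (i + 1) * ds.config.cdnm_window_bp, int(flag)))
    pd.DataFrame(cdnm_rows, columns=["chrom", "start", "end", "cdnm"]).to_csv(
        out / "cdnm_windows.tsv", sep="\t", index=False)
    for group, per_ind in ds.truth_fragments.items():
        write_hapmap(ds.recomb_maps[group], out / f"recomb_{group}.map")
        for ind, ivs in per_ind.items():
            write_bed(ivs, out / f"truth_{ind}.bed")
    for ind, tracks in ds.window_tracks.items():
        write_window_tracks(list(tracks.values()), out / f"windows_{ind}.tsv")
    for ind, recs in ds.variants.items():
        write_variants_tsv(recs, out / f"variants_{ind}.tsv")
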