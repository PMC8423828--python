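"""Fragment-length summaries and resampling inference.

The study's inference is exclusively resampling-based: means carry normal-
approximation bootstrap confidence intervals (mean +/- z * sd of the
bootstrap distribution), two-group comparisons use a difference-of-means
permutation test with the one-tailed fraction doubled, and multi-group
comparisons permute the one-way F statistic.  When no permuted statistic is
as extreme as the observed one, the p-value is reported as a floored bound
(fraction < 1/n_perm) rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class FragmentSummary:
    n: int
    mean: float
    median: float
    sd: float
    se: float


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lo: float
    hi: float
    n_boot: int
    level: float


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p: float
    n_perm: int
    tails: int
    floored: bool

    def __str__(self) -> str:
        rel = "<" if self.floored else "="
        return f"stat={self.observed:.6g}, P {rel} {self.p:.3g} ({self.n_perm} permutations)"


def summarize_fragments(lengths: Sequence[float]) -> FragmentSummary:
    """Sample mean / median / unbiased sd / se of fragment lengths (bp).

    A single observation yields sd = se = 0 by convention.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise ValueError("no fragment lengths given")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return FragmentSummary(
        n=int(x.size),
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=sd,
        se=sd / math.sqrt(x.size),
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[..., float] = np.mean,
    n_boot: int = 100_000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "normal",
) -> BootstrapCI:
    """Bootstrap confidence interval for ``statistic`` of ``values``.

    ``method="normal"`` (default) follows the study's construction: the CI is
    the bootstrap-distribution mean +/- z_{(1+level)/2} times its standard
    deviation.  ``method="percentile"`` returns empirical quantiles instead.
    Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    if method not in ("normal", "percentile"):
        raise ValueError("method must be 'normal' or 'percentile'")
    rng = np.random.default_rng(seed)
    point = float(statistic(x))
    boots = np.empty(n_boot, dtype=float)
    # Vectorized fast path for statistics that accept an axis argument.
    chunk = max(1, min(n_boot, int(4e7) // max(x.size, 1)))
    try:
        done = 0
        while done < n_boot:
            k = min(chunk, n_boot - done)
            idx = rng.integers(0, x.size, size=(k, x.size))
            boots[done : done + k] = statistic(x[idx], axis=1)
            done += k
    except TypeError:  # statistic without axis support
        for i in range(n_boot):
            boots[i] = statistic(x[rng.integers(0, x.size, size=x.size)])
    if method == "normal":
        z = sps.norm.ppf((1 + level) / 2)
        center, sd = float(boots.mean()), float(boots.std(ddof=1))
        lo, hi = center - z * sd, center + z * sd
    else:
        lo, hi = np.quantile(boots, [(1 - level) / 2, (1 + level) / 2])
    return BootstrapCI(point=point, lo=float(lo), hi=float(hi), n_boot=n_boot, level=level)


def _permuted_group_means(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of the first group under ``n_perm`` random label permutations."""
    out = np.empty(n_perm, dtype=float)
    chunk = max(1, min(n_perm, int(2e7) // max(pooled.size, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        keys = rng.random((k, pooled.size))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        out[done : done + k] = pooled[idx].mean(axis=1)
        done += k
    return out


def permutation_diff_means(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 100_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-tailed permutation test on mean(a) - mean(b).

    The one-tailed fraction of permuted statistics as-or-more extreme in the
    observed direction (ties count as extreme) is doubled; if no permutation
    qualifies, the fraction is floored at 1/n_perm and the result flagged as
    a "<" bound.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    total = pooled.sum()
    mean_a = _permuted_group_means(pooled, a.size, n_perm, rng)
    mean_b = (total - mean_a * a.size) / b.size
    perm = mean_a - mean_b
    if observed >= 0:
        count = int((perm >= observed).sum())
    else:
        count = int((perm <= observed).sum())
    floored = count == 0
    frac = max(count, 1) / n_perm
    return PermutationResult(
        observed=observed, p=min(1.0, 2 * frac), n_perm=n_perm, tails=2, floored=floored
    )


def _f_statistic(pooled: np.ndarray, sizes: np.ndarray, group_sums: np.ndarray) -> np.ndarray:
    """One-way F from group sums over a fixed pooled sample.

    ``group_sums`` may be 2-D (n_perm, n_groups) for vectorized permutations.
    All-identical data yields F = 0 by convention.
    """
    n, k = pooled.size, sizes.size
    grand_mean = pooled.mean()
    ss_total = ((pooled - grand_mean) ** 2).sum()
    means = group_sums / sizes
    ss_between = (sizes * (means - grand_mean) ** 2).sum(axis=-1)
    ss_within = ss_total - ss_between
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return np.where(ss_between <= 0, 0.0, np.where(ss_within <= 0, np.inf, f))


def permutation_F(
    groups: Sequence[Sequence[float]],
    n_perm: int = 100_000,
    seed: int | None = None,
) -> PermutationResult:
    """One-tailed permutation test on the one-way F statistic (large F extreme)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(gs)
    sizes = np.array([g.size for g in gs])
    bounds = np.cumsum(sizes)[:-1]
    observed_sums = np.array([g.sum() for g in gs])
    observed = float(_f_statistic(pooled, sizes, observed_sums))
    if not np.all(pooled == pooled[0]):
        perm_f = np.empty(n_perm, dtype=float)
        chunk = max(1, min(n_perm, int(2e7) // max(pooled.size, 1)))
        done = 0
        while done < n_perm:
            kk = min(chunk, n_perm - done)
            keys = rng.random((kk, pooled.size))
            idx = np.argsort(keys, axis=1)
            shuffled = pooled[idx]
            sums = np.add.reduceat(shuffled, np.r_[0, bounds], axis=1)
            perm_f[done : done + kk] = _f_statistic(pooled, sizes, sums)
            done += kk
        count = int((perm_f >= observed).sum())
    else:
        count = n_perm  # every permutation ties at F = 0
    floored = count == 0
    frac = max(count, 1) / n_perm
    return PermutationResult(
        observed=observed, p=min(1.0, frac), n_perm=n_perm, tails=1, floored=floored
    )


def estimate_generations(mean_length_cM: float, admix_fraction: float = 0.0) -> float:
    """Generations since admixture implied by a mean tract length in cM.

    Inverts the exponential tract-length law (mean 1/(g(1-alpha)) Morgans):
    g-hat = 100 / (mean_cM * (1 - alpha)).
    """
    if mean_length_cM <= 0:
        raise ValueError("mean length must be positive")
    if not 0 <= admix_fraction < 1:
        raise ValueError("admixture fraction must be in [0, 1)")
    return 100.0 / (mean_length_cM * (1.0 - admix_fraction))
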