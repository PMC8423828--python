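"""Two-state window HMM calling archaic ancestry from private-SNP density.

Non-overlapping windows (default 1 kb) carry a private-SNP count, a
callability fraction and a local mutation-rate scale.  Counts are modelled
as Poisson with mean lambda_state * callability * mutrate_scale; the hidden
state alternates between a low-density background and a high-density
archaic state with sticky transitions.  Parameters are fitted by
Baum-Welch EM (monotone in log-likelihood), states decoded by
forward-backward posteriors, and maximal runs of windows with archaic
posterior > 0.5 become called fragments annotated with their mean
posterior.  Windows with callability below a floor are treated as missing:
they contribute no emission term but transitions still apply, so fragments
do not break at coverage dips.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .intervals import IntervalSet

MISSING_CALLABILITY = 0.05


@dataclass
class WindowTrack:
    """Fixed-width windows tiling one chromosome (last may be shorter)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    callability: np.ndarray
    mutrate_scale: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.callability = np.asarray(self.callability, dtype=float)
        self.mutrate_scale = np.asarray(self.mutrate_scale, dtype=float)
        n = self.starts.shape[0]
        if not all(a.shape[0] == n for a in (self.ends, self.counts, self.callability, self.mutrate_scale)):
            raise ValueError("window arrays must have equal length")
        if n > 1 and not np.array_equal(self.starts[1:], self.ends[:-1]):
            raise ValueError("windows must tile the chromosome without gaps or overlaps")
        if (self.counts < 0).any() or (self.callability < 0).any() or (self.callability > 1).any():
            raise ValueError("counts must be >= 0 and callability in [0, 1]")
        if (self.mutrate_scale <= 0).any():
            raise ValueError("mutrate_scale must be positive")

    def __len__(self) -> int:
        return int(self.starts.shape[0])

    @property
    def exposure(self) -> np.ndarray:
        return self.callability * self.mutrate_scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.starts, "end": self.ends,
            "count": self.counts, "callability": self.callability,
            "mutrate_scale": self.mutrate_scale,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindowTrack":
        (chrom,) = df["chrom"].astype(str).unique()
        return cls(chrom, df["start"].to_numpy(), df["end"].to_numpy(),
                   df["count"].to_numpy(), df["callability"].to_numpy(),
                   df["mutrate_scale"].to_numpy())


def read_window_tracks(path) -> dict[str, WindowTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {c: WindowTrack.from_frame(g) for c, g in df.groupby("chrom", sort=True)}


def write_window_tracks(tracks: Sequence[WindowTrack], path) -> None:
    pd.concat([t.to_frame() for t in tracks]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class HMMParams:
    p_stay_background: float = 0.999
    p_stay_archaic: float = 0.98
    lambda_background: float = 0.02
    lambda_archaic: float = 0.4
    pi_archaic: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.p_stay_background, self.p_stay_archaic, self.pi_archaic):
            if not 0 < p < 1:
                raise ValueError("probabilities must lie in (0, 1)")
        if self.lambda_background < 0 or self.lambda_archaic < 0:
            raise ValueError("emission rates must be non-negative")


@dataclass
class FitResult:
    params: HMMParams
    log_likelihood: float
    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    warning: str | None = None


@dataclass(frozen=True)
class ArchaicFragment:
    """A called (or simulated) introgressed tract, 0-based half-open."""

    chrom: str
    start: int
    end: int
    mean_posterior: float
    individual: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


# State order in kernels: 0 = background, 1 = archaic.


@njit(cache=True)
def _emission_logprobs(counts, exposure, missing, lam0, lam1):
    n = counts.shape[0]
    logb = np.zeros((n, 2))
    lams = (lam0, lam1)
    for t in range(n):
        if missing[t]:
            continue
        c = counts[t]
        lg = math.lgamma(c + 1.0)
        for s in range(2):
            mu = lams[s] * exposure[t]
            if mu <= 0.0:
                logb[t, s] = 0.0 if c == 0 else -745.0
            else:
                logb[t, s] = c * math.log(mu) - mu - lg
    return logb


@njit(cache=True)
def _forward_backward(logb, a00, a11, pi1):
    """Scaled forward-backward; returns (loglik, gamma, xi_sum)."""
    n = logb.shape[0]
    A = np.array([[a00, 1.0 - a00], [1.0 - a11, a11]])
    pi = np.array([1.0 - pi1, pi1])
    b = np.empty((n, 2))
    for t in range(n):
        m = max(logb[t, 0], logb[t, 1])
        b[t, 0] = math.exp(logb[t, 0] - m)
        b[t, 1] = math.exp(logb[t, 1] - m)
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    alpha[0, 0] = pi[0] * b[0, 0]
    alpha[0, 1] = pi[1] * b[0, 1]
    scale[0] = alpha[0, 0] + alpha[0, 1]
    alpha[0] /= scale[0]
    for t in range(1, n):
        for j in range(2):
            alpha[t, j] = (alpha[t - 1, 0] * A[0, j] + alpha[t - 1, 1] * A[1, j]) * b[t, j]
        scale[t] = alpha[t, 0] + alpha[t, 1]
        alpha[t] /= scale[t]
    beta = np.empty((n, 2))
    beta[n - 1, 0] = 1.0
    beta[n - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(n - 2, -1, -1):
        bb0 = b[t + 1, 0] * beta[t + 1, 0]
        bb1 = b[t + 1, 1] * beta[t + 1, 1]
        for i in range(2):
            beta[t, i] = (A[i, 0] * bb0 + A[i, 1] * bb1) / scale[t + 1]
        denom = 0.0
        for i in range(2):
            for j in range(2):
                denom += alpha[t, i] * A[i, j] * (b[t + 1, j] * beta[t + 1, j])
        if denom > 0:
            for i in range(2):
                xi[i, 0] += alpha[t, i] * A[i, 0] * bb0 / denom
                xi[i, 1] += alpha[t, i] * A[i, 1] * bb1 / denom
    gamma = alpha * beta
    for t in range(n):
        tot = gamma[t, 0] + gamma[t, 1]
        if tot > 0:
            gamma[t] /= tot
    # log-likelihood: sum log scale, restoring the per-window max shift
    ll = 0.0
    for t in range(n):
        m = max(logb[t, 0], logb[t, 1])
        ll += math.log(scale[t]) + m
    return ll, gamma, xi


def _as_track_list(tracks) -> list[WindowTrack]:
    return [tracks] if isinstance(tracks, WindowTrack) else list(tracks)


def _missing_mask(track: WindowTrack, min_callability: float) -> np.ndarray:
    return track.callability < min_callability


def _initial_params(tracks: list[WindowTrack], min_callability: float) -> HMMParams:
    """Moment-style init: lambdas from the 50th / 99th density percentiles."""
    dens = []
    for t in tracks:
        ok = ~_missing_mask(t, min_callability)
        dens.append(t.counts[ok] / t.exposure[ok])
    d = np.concatenate(dens) if dens else np.array([0.0])
    lam0 = max(float(np.percentile(d, 50)), 1e-3)
    lam1 = max(float(np.percentile(d, 99)), lam0 * 2, 1e-2)
    return HMMParams(lambda_background=lam0, lambda_archaic=lam1)


def fit_hmm(
    tracks: WindowTrack | Sequence[WindowTrack],
    init: HMMParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_callability: float = MISSING_CALLABILITY,
) -> FitResult:
    """Baum-Welch fit of the two-state Poisson-emission HMM.

    Multiple tracks (chromosomes/individuals) are treated as independent
    chains sharing one parameter set.  The log-likelihood is non-decreasing
    across iterations; iteration stops when the improvement falls below
    ``tol`` or after ``max_iter`` rounds.  An all-zero-count input drives
    lambda-hat to 0 and is flagged in ``FitResult.warning``.
    """
    track_list = _as_track_list(tracks)
    n_windows = sum(len(t) for t in track_list)
    if n_windows < 100:
        raise ValueError("need at least 100 windows to fit")
    params = init or _initial_params(track_list, min_callability)
    missing = [_missing_mask(t, min_callability) for t in track_list]
    lls: list[float] = []
    converged = False
    for it in range(max_iter):
        ll_total = 0.0
        num = np.zeros(2)      # sum gamma * count
        den = np.zeros(2)      # sum gamma * exposure
        occ = np.zeros(2)      # sum gamma (all windows)
        xi_total = np.zeros((2, 2))
        pi_acc = np.zeros(2)
        for t, miss in zip(track_list, missing):
            logb = _emission_logprobs(t.counts, t.exposure, miss,
                                      params.lambda_background, params.lambda_archaic)
            ll, gamma, xi = _forward_backward(
                logb, params.p_stay_background, params.p_stay_archaic, params.pi_archaic
            )
            ll_total += ll
            ok = ~miss
            num += gamma[ok].T @ t.counts[ok]
            den += gamma[ok].T @ t.exposure[ok]
            occ += gamma.sum(axis=0)
            xi_total += xi
            pi_acc += gamma[0]
        lls.append(ll_total)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(den > 0, num / den, 0.0)
        stay = np.clip(np.diag(xi_total) / np.clip(xi_total.sum(axis=1), 1e-300, None),
                       1e-6, 1 - 1e-6)
        pi1 = float(np.clip(pi_acc[1] / pi_acc.sum(), 1e-6, 1 - 1e-6))
        # keep state identity: archaic is the denser state
        if lam[1] < lam[0]:
            lam = lam[::-1]
            stay = stay[::-1]
            pi1 = 1 - pi1
        params = HMMParams(
            p_stay_background=float(stay[0]), p_stay_archaic=float(stay[1]),
            lambda_background=float(lam[0]), lambda_archaic=float(lam[1]),
            pi_archaic=pi1,
        )
    warning = None
    if params.lambda_archaic <= 1e-9:
        warning = "degenerate fit: archaic emission rate collapsed to 0"
        warnings.warn(warning, stacklevel=2)
    elif params.lambda_archaic <= params.lambda_background * 1.01:
        warning = "emission rates nearly equal: states unidentifiable"
    return FitResult(params=params, log_likelihood=lls[-1], log_likelihoods=lls,
                     n_iter=len(lls), converged=converged, warning=warning)


def posterior_archaic(
    track: WindowTrack, params: HMMParams, min_callability: float = MISSING_CALLABILITY
) -> np.ndarray:
    """Per-window posterior probability of the archaic state."""
    miss = _missing_mask(track, min_callability)
    logb = _emission_logprobs(track.counts, track.exposure, miss,
                              params.lambda_background, params.lambda_archaic)
    _, gamma, _ = _forward_backward(
        logb, params.p_stay_background, params.p_stay_archaic, params.pi_archaic
    )
    return gamma[:, 1]


def decode_fragments(
    track: WindowTrack,
    params: HMMParams,
    posterior_threshold: float = 0.8,
    individual: str = "",
    min_callability: float = MISSING_CALLABILITY,
) -> list[ArchaicFragment]:
    """Call fragments as maximal runs of windows with archaic posterior > 0.5.

    Each fragment carries the mean posterior over its windows; the
    high-confidence subset is obtained with :func:`high_confidence_fragments`
    at ``posterior_threshold`` (validated here, in (0.5, 1]).
    """
    if not 0.5 < posterior_threshold <= 1.0:
        raise ValueError("posterior_threshold must lie in (0.5, 1]")
    post = posterior_archaic(track, params, min_callability)
    hot = post > 0.5
    frags: list[ArchaicFragment] = []
    edges = np.flatnonzero(np.diff(np.r_[0, hot.view(np.int8), 0]))
    for lo, hi in zip(edges[::2], edges[1::2]):
        frags.append(ArchaicFragment(
            chrom=track.chrom, start=int(track.starts[lo]), end=int(track.ends[hi - 1]),
            mean_posterior=float(post[lo:hi].mean()), individual=individual,
        ))
    return frags


def high_confidence_fragments(
    fragments: Sequence[ArchaicFragment], posterior_threshold: float = 0.8
) -> list[ArchaicFragment]:
    if not 0.5 < posterior_threshold <= 1.0:
        raise ValueError("posterior_threshold must lie in (0.5, 1]")
    return [f for f in fragments if f.mean_posterior >= posterior_threshold]


def fragments_to_intervalset(fragments: Sequence[ArchaicFragment]) -> IntervalSet:
    return IntervalSet.from_tuples((f.chrom, f.start, f.end) for f in fragments)


def write_fragments_bed(fragments: Sequence[ArchaicFragment], path) -> None:
    """BED with two extra columns: mean posterior and length (bp)."""
    with open(path, "w") as fh:
        for f in sorted(fragments, key=lambda f: (f.chrom, f.start)):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.mean_posterior:.6f}\t{f.length}\n")
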