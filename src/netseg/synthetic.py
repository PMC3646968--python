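"""Synthetic multivariate time-series benchmark with planted breakpoints.

Emulates the standard benchmark for network-based segmentation: a fixed
number of variables observed over T time points, partitioned into regimes
by planted breakpoints. Each regime owns a small pool of characteristic
profiles simulated from a zero-mean stationary ARMA process; every
variable copies one uniformly sampled pool profile per regime, receives
additive i.i.d. Gaussian noise, and the regime boundaries are smoothed
with a 3-tap discrete filter approximating a Gaussian kernel so adjacent
segments remain temporally dependent.

Defaults: 70 variables, 36 time points, breakpoints after time points
7, 12 and 21, profile pools of sizes 2, 6, 3 and 7, ARMA(1,1) with
AR 0.6 / MA 0.3 rescaled to unit process variance, noise sd 0.1, kernel
(0.25, 0.5, 0.25). The noise level is calibrated so the pair-distance
range of the default instance reproduces the published tuning-parameter
bounds of the relative-density benchmark (about 0.05 to 6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.arima_process import ArmaProcess

from netseg.data_io import ExpressionMatrix, segments_from_breakpoints


@dataclass
class BenchmarkConfig:
    n_vars: int = 70
    T: int = 36
    breakpoints: tuple[int, ...] = (7, 12, 21)
    profiles_per_segment: tuple[int, ...] = (2, 6, 3, 7)
    ar: tuple[float, ...] = (0.6,)
    ma: tuple[float, ...] = (0.3,)
    noise_sd: float = 0.1
    kernel: tuple[float, float, float] = (0.25, 0.5, 0.25)
    seed: int | None = None

    def __post_init__(self) -> None:
        bps = tuple(self.breakpoints)
        if list(bps) != sorted(set(bps)) or (bps and (bps[0] < 2 or bps[-1] >= self.T)):
            raise ValueError(
                "breakpoints must be strictly increasing within (1, T)"
            )
        if len(self.profiles_per_segment) != len(bps) + 1:
            raise ValueError(
                "profiles_per_segment must have one entry per segment"
            )
        if any(p < 1 for p in self.profiles_per_segment):
            raise ValueError("each segment needs at least one profile")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or len(k) != 3 or np.any(k < 0) or not np.isclose(k.sum(), 1.0) or k[0] != k[2]:
            raise ValueError(
                "kernel must be 3 symmetric non-negative weights summing to 1"
            )

    @property
    def segment_bounds(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each planted segment."""
        return segments_from_breakpoints(self.breakpoints, self.T)

    @property
    def n_segments(self) -> int:
        return len(self.profiles_per_segment)


@dataclass
class Benchmark:
    """A generated instance: the matrix, its truth and the profile choices."""

    matrix: ExpressionMatrix
    breakpoints: tuple[int, ...]
    assignments: np.ndarray = field(repr=False)  # (n_vars, n_segments) profile index
    config: BenchmarkConfig = field(repr=False, default=None)


def _arma_process(config: BenchmarkConfig) -> tuple[ArmaProcess, float]:
    proc = ArmaProcess(
        np.r_[1.0, -np.asarray(config.ar, dtype=float)],
        np.r_[1.0, np.asarray(config.ma, dtype=float)],
    )
    if not proc.isstationary:
        raise ValueError("AR coefficients define a non-stationary process")
    if not proc.isinvertible:
        raise ValueError("MA coefficients define a non-invertible process")
    # innovation scale that gives the process unit variance
    sd = float(np.sqrt(proc.acovf(1)[0]))
    return proc, 1.0 / sd


def simulate_segment_profiles(
    config: BenchmarkConfig,
    segment_index: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Characteristic profiles for one segment: zero-mean unit-variance ARMA draws.

    Returns an array of shape (profiles_per_segment[segment_index],
    segment_length).
    """
    proc, scale = _arma_process(config)
    start, end = config.segment_bounds[segment_index]
    length = end - start + 1
    n_profiles = config.profiles_per_segment[segment_index]
    out = np.empty((n_profiles, length))
    for j in range(n_profiles):
        out[j] = scale * proc.generate_sample(
            nsample=length, burnin=200, distrvs=rng.standard_normal
        )
    return out


def smooth_boundaries(
    values: np.ndarray,
    breakpoints: tuple[int, ...] | list[int],
    kernel: tuple[float, float, float] = (0.25, 0.5, 0.25),
) -> np.ndarray:
    """Smooth each segment's left boundary with a 3-tap kernel.

    For each row and each left boundary time b (1-based, b > 1) the value
    at b is replaced by ``k0*x[b-1] + k1*x[b] + k2*x[b+1]``; all other
    entries are untouched. A normalized symmetric kernel leaves constant
    and affine-in-time rows unchanged.
    """
    values = np.asarray(values, dtype=float)
    T = values.shape[1]
    k0, k1, k2 = kernel
    out = values.copy()
    for bp in breakpoints:
        b = bp + 1  # left boundary of the following segment, 1-based
        if b <= 1 or b >= T:
            raise ValueError(
                f"boundary at time {b} has no neighbour on both sides"
            )
        j = b - 1  # 0-based column
        out[:, j] = k0 * values[:, j - 1] + k1 * values[:, j] + k2 * values[:, j + 1]
    return out


def assemble_benchmark(config: BenchmarkConfig | None = None) -> Benchmark:
    """Generate a full benchmark instance from a configuration.

    Per segment, each variable copies one uniformly sampled characteristic
    profile and receives i.i.d. Gaussian noise; boundaries are then
    smoothed. The same seed reproduces the instance bit-identically.
    """
    if config is None:
        config = BenchmarkConfig()
    rng = np.random.default_rng(config.seed)
    values = np.empty((config.n_vars, config.T))
    assignments = np.empty((config.n_vars, config.n_segments), dtype=int)
    for s, (start, end) in enumerate(config.segment_bounds):
        profiles = simulate_segment_profiles(config, s, rng)
        choice = rng.integers(0, profiles.shape[0], size=config.n_vars)
        assignments[:, s] = choice
        values[:, start - 1 : end] = profiles[choice]
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    values = smooth_boundaries(values, config.breakpoints, config.kernel)
    matrix = ExpressionMatrix(
        entity_ids=[f"V{j + 1}" for j in range(config.n_vars)],
        time_labels=[f"t{j + 1}" for j in range(config.T)],
        values=values,
    )
    return Benchmark(
        matrix=matrix,
        breakpoints=tuple(config.breakpoints),
        assignments=assignments,
        config=config,
    )
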