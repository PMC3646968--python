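"""Canned benchmark experiment: segment the synthetic benchmark end to end.

Reproduces the reference study on the generator's default instance:
relative-density network distance, per-length rotation-null thresholds,
count-criterion penalized DP, 20-point tuning sweep with modal consensus,
replicated over independent seeds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from netseg.multseg import (
    PenaltyConfig,
    SegmentationResult,
    build_dag,
    lambda_bounds,
    pair_weight_table,
    sweep,
)
from netseg.netrecon import build_threshold_table
from netseg.synthetic import BenchmarkConfig, assemble_benchmark


@dataclass
class BenchmarkRun:
    seed: int
    result: SegmentationResult
    lambda_low: float
    lambda_high: float
    true_breakpoints: tuple[int, ...]

    def recovered_within(self, tol: int = 1) -> bool:
        """Whether every planted cut has a consensus cut within ``tol``."""
        return all(
            any(abs(b - t) <= tol for b in self.result.breakpoints)
            for t in self.true_breakpoints
        )


def run_benchmark_replicate(
    seed: int,
    config: BenchmarkConfig | None = None,
    L_min: int = 4,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_grid: int = 20,
    criterion: str = "count",
) -> BenchmarkRun:
    """Generate one benchmark instance and segment it with the full pipeline."""
    if config is None:
        config = BenchmarkConfig(seed=seed)
    bench = assemble_benchmark(config)
    thresholds = build_threshold_table(
        bench.matrix,
        min_length=L_min,
        max_length=config.T - L_min,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )
    table = pair_weight_table(
        bench.matrix,
        L_min=L_min,
        property="relative_density",
        distance="global",
        thresholds=thresholds,
    )
    dag = build_dag(table)
    low, high = lambda_bounds(table, dag)
    result = sweep(dag, PenaltyConfig(criterion=criterion), (low, high), n_grid)
    return BenchmarkRun(
        seed=seed,
        result=result,
        lambda_low=low,
        lambda_high=high,
        true_breakpoints=bench.breakpoints,
    )


def replicate_seeds(base_seed: int, n_replicates: int = 20) -> list[int]:
    """Derive independent replicate seeds (< 2^31) from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n_replicates)
    return [int(s % (2**31)) for s in state]


def benchmark_study(
    base_seed: int, n_replicates: int = 20, **kwargs
) -> list[BenchmarkRun]:
    """Run the benchmark experiment over independent replicate seeds."""
    return [
        run_benchmark_replicate(seed, **kwargs)
        for seed in replicate_seeds(base_seed, n_replicates)
    ]


def consensus_segment_count(runs: list[BenchmarkRun]) -> int:
    """Majority (modal) consensus segment count across replicates."""
    counts = Counter(run.result.n_segments for run in runs)
    # ties toward fewer segments, for determinism
    return min(counts, key=lambda k: (-counts[k], k))


def recovery_fraction(runs: list[BenchmarkRun], tol: int = 1) -> float:
    """Fraction of replicates recovering all planted cuts within ``tol``."""
    return sum(run.recovered_within(tol) for run in runs) / len(runs)
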