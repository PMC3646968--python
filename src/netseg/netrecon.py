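"""Per-segment correlation networks with permutation-derived thresholds.

A candidate segment of the time axis defines a column window of the
expression matrix; Pearson correlation between every pair of profiles in
that window yields a similarity matrix, which is thresholded into an
undirected graph on the fixed entity node set. The threshold is the
(1 - alpha) quantile of a null distribution of absolute correlations
obtained by a dependence-preserving randomization: each profile is
independently circularly rotated, which keeps the autocorrelation of
adjacent time points intact. On autocorrelated data this null has a
heavier upper tail than a full shuffle, hence a higher (more
conservative) threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from netseg.data_io import ExpressionMatrix


@dataclass(frozen=True, order=True)
class Segment:
    """A contiguous time window, 1-based inclusive on both ends."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment [{self.start}..{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def columns(self) -> slice:
        """0-based column slice into the values array."""
        return slice(self.start - 1, self.end)


def _pearson_matrix(window: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of rows; NaN where a row has zero variance."""
    centered = window - window.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    defined = norms > 0
    safe = np.where(defined, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    undef = ~defined
    corr[undef, :] = np.nan
    corr[:, undef] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def similarity_matrix(
    matrix: ExpressionMatrix, segment: Segment, measure: str = "pearson"
) -> np.ndarray:
    """Similarity between all profile pairs restricted to ``segment``.

    Returns a symmetric n x n array with unit diagonal; entries involving a
    zero-variance profile are NaN (undefined) rather than raising.
    """
    if measure != "pearson":
        raise ValueError(f"unsupported similarity measure {measure!r}")
    if segment.end > matrix.n_timepoints:
        raise ValueError(
            f"segment [{segment.start}..{segment.end}] exceeds "
            f"T={matrix.n_timepoints}"
        )
    if segment.length < 2:
        raise ValueError("Pearson correlation needs a segment of length >= 2")
    return _pearson_matrix(matrix.values[:, segment.columns()])


def _pooled_null_quantile(null: np.ndarray, alpha: float) -> float:
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValueError("empty null distribution (all similarities undefined)")
    return float(np.quantile(null, 1.0 - alpha, method="higher"))


def _offdiag(corr: np.ndarray, absolute: bool = True) -> np.ndarray:
    iu = np.triu_indices(corr.shape[-1], k=1)
    vals = corr[..., iu[0], iu[1]]
    return np.abs(vals) if absolute else vals


def permutation_threshold(
    matrix: ExpressionMatrix,
    length: int,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    strategy: str = "rotation",
    exhaustive: bool = False,
    absolute: bool = True,
) -> float:
    """Significance threshold for the correlation at a given segment length.

    Builds a null distribution of Pearson correlations between
    independently randomized profiles, windowed to ``length`` time points,
    pooled over all entity pairs, and returns its (1 - alpha) quantile.

    Parameters
    ----------
    strategy : {"rotation", "shuffle"}
        "rotation" circularly rotates each full profile by an independent
        offset (dependence-preserving); "shuffle" fully permutes each
        profile (destroys autocorrelation; for comparison only).
    exhaustive : bool
        Enumerate all T x T rotation-offset combinations for every entity
        pair instead of sampling (rotation strategy only; small inputs).
    absolute : bool
        Pool |r| (matching an edge rule on |r|); with False, pool signed r
        (matching the edge rule r >= tau).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if length < 2:
        raise ValueError("length must be >= 2")
    T = matrix.n_timepoints
    if length > T:
        raise ValueError(f"length {length} exceeds T={T}")
    X = matrix.values
    n = X.shape[0]
    if exhaustive:
        if strategy != "rotation":
            raise ValueError("exhaustive enumeration applies to rotation only")
        pooled = []
        rotations = np.stack([np.roll(X, -off, axis=1) for off in range(T)])
        for u, v in itertools.combinations(range(n), 2):
            for ou, ov in itertools.product(range(T), range(T)):
                a = rotations[ou, u, :length]
                b = rotations[ov, v, :length]
                pooled.append(_pair_corr(a, b, absolute))
        return _pooled_null_quantile(np.array(pooled), alpha)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cols = np.arange(T)
    samples = []
    batch = 256
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        if strategy == "rotation":
            offsets = rng.integers(0, T, size=(b, n))
            idx = (cols[None, None, :] + offsets[:, :, None]) % T
            permuted = X[np.arange(n)[None, :, None], idx]
        elif strategy == "shuffle":
            idx = np.argsort(rng.random((b, n, T)), axis=2)
            permuted = X[np.arange(n)[None, :, None], idx]
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        window = permuted[:, :, :length]
        centered = window - window.mean(axis=2, keepdims=True)
        norms = np.linalg.norm(centered, axis=2)
        defined = norms > 0
        unit = centered / np.where(defined, norms, 1.0)[:, :, None]
        corr = unit @ unit.transpose(0, 2, 1)
        np.clip(corr, -1.0, 1.0, out=corr)
        undef = ~defined
        corr[undef[:, :, None] | undef[:, None, :]] = np.nan
        samples.append(_offdiag(corr, absolute).ravel())
        done += b
    return _pooled_null_quantile(np.concatenate(samples), alpha)


def _pair_corr(a: np.ndarray, b: np.ndarray, absolute: bool = True) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    r = max(-1.0, min(float(a @ b) / (na * nb), 1.0))
    return abs(r) if absolute else r


@dataclass
class ThresholdTable:
    """Cached per-segment-length thresholds tau(l)."""

    taus: dict[int, float]
    alpha: float
    n_perm: int
    seed: int | None = None
    strategy: str = "rotation"

    def __getitem__(self, length: int) -> float:
        try:
            return self.taus[length]
        except KeyError:
            raise KeyError(f"no threshold cached for segment length {length}") from None

    def lengths(self) -> list[int]:
        return sorted(self.taus)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("length\ttau\n")
            for length in self.lengths():
                fh.write(f"{length}\t{self.taus[length]!r}\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, alpha: float = float("nan"), n_perm: int = 0
    ) -> "ThresholdTable":
        taus: dict[int, float] = {}
        with Path(path).open() as fh:
            next(fh)
            for line in fh:
                length, tau = line.split("\t")
                taus[int(length)] = float(tau)
        return cls(taus, alpha=alpha, n_perm=n_perm)


def build_threshold_table(
    matrix: ExpressionMatrix,
    min_length: int,
    max_length: int | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    strategy: str = "rotation",
    absolute: bool = True,
) -> ThresholdTable:
    """Compute tau(l) once for every admissible segment length.

    Each length draws its permutations from an independent child stream of
    ``seed``, so the table is reproducible as a whole.
    """
    if max_length is None:
        max_length = matrix.n_timepoints
    lengths = range(max(2, min_length), max_length + 1)
    children = np.random.SeedSequence(seed).spawn(len(lengths))
    taus = {
        length: permutation_threshold(
            matrix,
            length,
            alpha=alpha,
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            strategy=strategy,
            absolute=absolute,
        )
        for length, child in zip(lengths, children)
    }
    return ThresholdTable(taus, alpha=alpha, n_perm=n_perm, seed=seed, strategy=strategy)


def build_segment_network(
    matrix: ExpressionMatrix,
    segment: Segment,
    tau: float,
    measure: str = "pearson",
    absolute: bool = True,
) -> nx.Graph:
    """Threshold the segment's similarity matrix into an undirected graph.

    The node set is always the full entity list (required for comparing
    graphs from different segments). An edge (u, v) is present iff the
    similarity is defined and ``|r| >= tau`` (or ``r >= tau`` with
    ``absolute=False``). Zero-variance profiles have all similarities
    undefined and therefore no incident edges.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    sim = similarity_matrix(matrix, segment, measure=measure)
    vals = np.abs(sim) if absolute else sim
    np.fill_diagonal(vals, -np.inf)
    with np.errstate(invalid="ignore"):
        adj = vals >= tau
    adj &= ~np.isnan(sim)
    G = nx.Graph(segment=segment, tau=tau)
    G.add_nodes_from(matrix.entity_ids)
    rows, cols = np.nonzero(np.triu(adj, k=1))
    G.add_edges_from(
        (matrix.entity_ids[u], matrix.entity_ids[v]) for u, v in zip(rows, cols)
    )
    return G
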