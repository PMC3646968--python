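"""The MULTSEG core: pair enumeration, DAG construction and the DP solvers.

Given an entities-by-time matrix, every admissible pair of consecutive
segments ([a..i], [i+1..b]) receives a weight d(a, i, b): the distance
between the networks reconstructed from the two segments. The weighted
triples become the nodes of a directed acyclic graph (plus a source s and
target t) whose s-t paths are exactly the segmentations of [1..T] into
k >= 2 segments of length >= L_min, with path weight equal to the summed
distance over consecutive segment pairs. The segmentation problem is then
a maximum-weight path problem, solved by one pass in topological order;
a breakpoint penalty (growing with segment count, or shrinking with
segment length, scaled by a tuning parameter lambda) turns it into a
model-selection problem swept over a lambda grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from netseg.data_io import ExpressionMatrix, segments_from_breakpoints
from netseg.graph_metrics import PROPERTY_VECTORS, lp_property_distance
from netseg.netrecon import Segment, ThresholdTable, _pearson_matrix

Triple = tuple[int, int, int]


def enumerate_pairs(T: int, L_min: int = 1) -> list[Triple]:
    """All admissible triples (a, i, b): left [a..i], right [i+1..b].

    Both segment lengths must be >= ``L_min``; triples are returned sorted
    lexicographically. With ``L_min = 1`` the count has the closed form
    T(T^2 - 1)/6.
    """
    if L_min < 1:
        raise ValueError("L_min must be >= 1")
    if T < 2 * L_min:
        raise ValueError(
            f"T={T} admits no segment pair with minimum length {L_min}"
        )
    out: list[Triple] = []
    for a in range(1, T - 2 * L_min + 2):
        for i in range(a + L_min - 1, T - L_min + 1):
            out.extend((a, i, b) for b in range(i + L_min, T + 1))
    return out


@dataclass
class PairTable:
    """Weights d(a, i, b) >= 0 for every admissible consecutive segment pair."""

    T: int
    L_min: int
    weights: dict[Triple, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = enumerate_pairs(self.T, self.L_min)
        missing = [t for t in expected if t not in self.weights]
        if missing:
            raise ValueError(
                f"pair table is missing {len(missing)} admissible triples "
                f"(first: {missing[0]})"
            )
        for triple, d in self.weights.items():
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"invalid weight {d!r} for triple {triple}")

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, triple: Triple) -> float:
        return self.weights[triple]

    def path_objective(self, breakpoints: Sequence[int]) -> float:
        """Sum of d over consecutive segment pairs of a segmentation."""
        segs = segments_from_breakpoints(breakpoints, self.T)
        return sum(
            self.weights[(segs[j][0], segs[j][1], segs[j + 1][1])]
            for j in range(len(segs) - 1)
        )

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("a\ti\tb\td\n")
            for (a, i, b) in sorted(self.weights):
                fh.write(f"{a}\t{i}\t{b}\t{self.weights[(a, i, b)]!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, T: int, L_min: int) -> "PairTable":
        weights: dict[Triple, float] = {}
        with Path(path).open() as fh:
            next(fh)
            for line in fh:
                a, i, b, d = line.split("\t")
                weights[(int(a), int(i), int(b))] = float(d)
        return cls(T=T, L_min=L_min, weights=weights)


def _segment_edge_arrays(
    matrix: ExpressionMatrix,
    segments: Sequence[Segment],
    thresholds: "ThresholdTable | float",
    absolute: bool = True,
) -> dict[Segment, np.ndarray]:
    """Boolean upper-triangle edge indicators for each segment's network."""
    n = matrix.n_entities
    iu = np.triu_indices(n, k=1)
    out: dict[Segment, np.ndarray] = {}
    for seg in segments:
        tau = thresholds if isinstance(thresholds, (int, float)) else thresholds[seg.length]
        sim = _pearson_matrix(matrix.values[:, seg.columns()])
        vals = np.abs(sim) if absolute else sim
        with np.errstate(invalid="ignore"):
            adj = vals[iu] >= tau
        adj &= ~np.isnan(sim[iu])
        out[seg] = adj
    return out


def _edge_array_to_graph(matrix: ExpressionMatrix, edges: np.ndarray):
    import networkx as nx

    n = matrix.n_entities
    iu = np.triu_indices(n, k=1)
    G = nx.Graph()
    G.add_nodes_from(matrix.entity_ids)
    for u, v in zip(iu[0][edges], iu[1][edges]):
        G.add_edge(matrix.entity_ids[u], matrix.entity_ids[v])
    return G


def pair_weight_table(
    matrix: ExpressionMatrix,
    L_min: int = 4,
    property: str = "relative_density",
    distance: str = "global",
    p: float = 2,
    thresholds: "ThresholdTable | float" = 0.0,
    absolute: bool = True,
) -> PairTable:
    """Distance between the networks of every admissible segment pair.

    Each distinct segment's network is reconstructed once and cached. With
    ``distance="global"`` and relative density the weight is the ratio of
    symmetric-difference to union edges; with ``distance="lp"`` it is the
    lp-norm distance of the per-node property vectors (degree, betweenness
    or closeness).
    """
    if property in ("density",):
        property = "relative_density"
    triples = enumerate_pairs(matrix.n_timepoints, L_min)
    segments = sorted(
        {Segment(a, i) for a, i, _ in triples}
        | {Segment(i + 1, b) for _, i, b in triples}
    )
    edge_arrays = _segment_edge_arrays(matrix, segments, thresholds, absolute)
    weights: dict[Triple, float] = {}
    if distance == "global":
        if property != "relative_density":
            raise ValueError(
                f"global distance supports relative_density, not {property!r}"
            )
        for a, i, b in triples:
            e1 = edge_arrays[Segment(a, i)]
            e2 = edge_arrays[Segment(i + 1, b)]
            union = int(np.sum(e1 | e2))
            weights[(a, i, b)] = (
                0.0 if union == 0 else int(np.sum(e1 ^ e2)) / union
            )
    elif distance == "lp":
        try:
            prop_fn = PROPERTY_VECTORS[property]
        except KeyError:
            raise ValueError(
                f"lp distance supports {sorted(PROPERTY_VECTORS)}, "
                f"not {property!r}"
            ) from None
        vectors = {
            seg: prop_fn(_edge_array_to_graph(matrix, edges))
            for seg, edges in edge_arrays.items()
        }
        for a, i, b in triples:
            weights[(a, i, b)] = lp_property_distance(
                vectors[Segment(a, i)], vectors[Segment(i + 1, b)], p=p
            )
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return PairTable(
        T=matrix.n_timepoints,
        L_min=L_min,
        weights=weights,
        meta={"property": property, "distance": distance, "p": p,
              "absolute": absolute},
    )


@dataclass
class SegDAG:
    """Edge-weighted DAG whose s-t paths are the multi-segment segmentations.

    One node per pair-table triple plus a source ``s`` and target ``t``.
    ``s`` points (zero weight) to every node whose left segment starts at
    time 1; node u points to node v iff v's left segment equals u's right
    segment (carrying d(u)); nodes whose right segment ends at T point to
    ``t`` (carrying their own d). Every s-t path's weight therefore equals
    the sum of d over its pair nodes.
    """

    T: int
    L_min: int
    nodes: list[Triple]
    d: np.ndarray
    firsts: list[int]
    terminal: np.ndarray
    succs: list[list[int]]

    @property
    def node_count(self) -> int:
        """Pair nodes plus the two special nodes s and t."""
        return len(self.nodes) + 2

    def edge_list(self) -> Iterator[tuple[object, object, float]]:
        """All directed edges (u, v, weight); s and t as string sentinels."""
        for j in self.firsts:
            yield ("s", self.nodes[j], 0.0)
        for u, vs in enumerate(self.succs):
            for v in vs:
                yield (self.nodes[u], self.nodes[v], float(self.d[u]))
        for u in np.nonzero(self.terminal)[0]:
            yield (self.nodes[int(u)], "t", float(self.d[int(u)]))

    def max_breakpoints(self) -> int:
        """Maximum possible number of breakpoints for a series of T points."""
        return self.T - 1


def build_dag(pair_table: PairTable) -> SegDAG:
    """Construct the segmentation DAG from a pair-weight table."""
    if len(pair_table) == 0:
        raise ValueError("empty pair table")
    nodes = sorted(pair_table.weights)
    index = {t: j for j, t in enumerate(nodes)}
    d = np.array([pair_table.weights[t] for t in nodes], dtype=float)
    by_left: dict[tuple[int, int], list[int]] = {}
    for j, (a, i, _b) in enumerate(nodes):
        by_left.setdefault((a, i), []).append(j)
    succs = [by_left.get((i + 1, b), []) for (_a, i, b) in nodes]
    firsts = [j for j, (a, _i, _b) in enumerate(nodes) if a == 1]
    terminal = np.array([b == pair_table.T for (_a, _i, b) in nodes])
    return SegDAG(
        T=pair_table.T,
        L_min=pair_table.L_min,
        nodes=nodes,
        d=d,
        firsts=firsts,
        terminal=terminal,
        succs=succs,
    )


def bp_penalty_count(depth: int, K_max: int, lam: float) -> float:
    """Breakpoint penalty under the segment-count criterion.

    ``lam * depth / K_max`` with ``depth`` the number of segments of the
    path prefix and ``K_max`` the maximum possible number of breakpoints:
    zero at lam = 0 and strictly increasing in depth for lam > 0, so the
    accumulated path penalty is convex in the segment count.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if not 1 <= depth <= K_max + 1:
        raise ValueError(f"depth {depth} outside [1, K_max + 1 = {K_max + 1}]")
    return lam * depth / K_max


def bp_penalty_length(seg_len: int, lam: float) -> float:
    """Breakpoint penalty under the segment-length criterion.

    ``lam / seg_len``: zero at lam = 0 and strictly decreasing in the
    length of the newly added segment (reciprocal relationship), so short
    segments are discouraged.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if seg_len < 1:
        raise ValueError("segment length must be >= 1")
    return lam / seg_len


@dataclass
class PenaltyConfig:
    """Breakpoint-penalty settings for the penalized DP."""

    criterion: str = "count"  # "count" | "length" | "none"
    lam: float = 0.0
    K_max: int | None = None
    L_min: int | None = None

    def __post_init__(self) -> None:
        if self.criterion not in ("count", "length", "none"):
            raise ValueError(f"unknown penalty criterion {self.criterion!r}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class LambdaSolution:
    """One solution of the penalized DP at a fixed tuning value."""

    lam: float
    breakpoints: tuple[int, ...]
    n_segments: int
    objective: float
    penalty_total: float
    score: float

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "breakpoints": list(self.breakpoints),
            "n_segments": self.n_segments,
            "objective": self.objective,
            "penalty_total": self.penalty_total,
            "score": self.score,
        }


@dataclass
class SegmentationResult:
    """Optimal segmentation: breakpoints are segment-final time points."""

    breakpoints: tuple[int, ...]
    T: int
    objective: float
    penalty_total: float = 0.0
    lam: float | None = None
    criterion: str | None = None
    meta: dict = field(default_factory=dict)
    per_lambda: list[LambdaSolution] | None = None

    def __post_init__(self) -> None:
        self.breakpoints = tuple(self.breakpoints)
        if len(self.breakpoints) < 1:
            raise ValueError("a result must have k >= 2 segments")

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1

    @property
    def score(self) -> float:
        return self.objective - self.penalty_total

    def segments(self) -> list[tuple[int, int]]:
        return segments_from_breakpoints(self.breakpoints, self.T)

    def to_dict(self) -> dict:
        out = {
            "breakpoints": list(self.breakpoints),
            "T": self.T,
            "n_segments": self.n_segments,
            "objective": self.objective,
            "penalty_total": self.penalty_total,
            "score": self.score,
            "lambda": self.lam,
            "criterion": self.criterion,
            "meta": self.meta,
        }
        if self.per_lambda is not None:
            out["per_lambda"] = [sol.to_dict() for sol in self.per_lambda]
        return out


def _right_length(node: Triple) -> int:
    return node[2] - node[1]


def _dp(
    dag: SegDAG,
    lam: float = 0.0,
    criterion: str = "none",
    K_max: int | None = None,
) -> tuple[float, float, tuple[int, ...]]:
    """Layered maximum-score pass over the DAG in topological order.

    Layer l holds the best path prefix with l segments ending at each node;
    this makes the depth-dependent count penalty exact. Charging happens on
    every hop except the first (s to its first node necessarily opens two
    segments at once and is exempt). Returns (score, objective, breakpoints)
    of the best complete path: maximum score, then fewest segments, then
    lexicographically smallest breakpoint sequence.
    """
    if K_max is None:
        K_max = dag.max_breakpoints()
    max_depth = K_max + 1
    d = dag.d
    # state: node index -> (score, objective, breakpoints so far)
    layer: dict[int, tuple[float, float, tuple[int, ...]]] = {
        j: (float(d[j]), float(d[j]), (dag.nodes[j][1],)) for j in dag.firsts
    }
    best: tuple[float, int, tuple[int, ...], float] | None = None  # score, k, bps, F
    depth = 2
    while layer and depth <= max_depth:
        for j, (score, obj, bps) in layer.items():
            if dag.terminal[j]:
                cand = (score, depth, bps, obj)
                if (
                    best is None
                    or cand[0] > best[0]
                    or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
                ):
                    best = cand
        nxt: dict[int, tuple[float, float, tuple[int, ...]]] = {}
        if depth < max_depth:
            for j, (score, obj, bps) in layer.items():
                for v in dag.succs[j]:
                    if criterion == "count":
                        pen = bp_penalty_count(depth + 1, K_max, lam)
                    elif criterion == "length":
                        pen = bp_penalty_length(_right_length(dag.nodes[v]), lam)
                    else:
                        pen = 0.0
                    cand = (
                        score + float(d[v]) - pen,
                        obj + float(d[v]),
                        bps + (dag.nodes[v][1],),
                    )
                    cur = nxt.get(v)
                    if (
                        cur is None
                        or cand[0] > cur[0]
                        or (cand[0] == cur[0] and cand[2] < cur[2])
                    ):
                        nxt[v] = cand
        layer = nxt
        depth += 1
    if best is None:
        raise ValueError(
            "the DAG admits no source-target path (L_min too large?)"
        )
    score, _k, bps, obj = best
    return score, obj, bps


def max_weight_min_length_path(dag: SegDAG) -> SegmentationResult:
    """Unpenalized optimum: maximum weight, tie-broken by fewest segments.

    Remaining ties go to the lexicographically smallest breakpoint
    sequence, making the result deterministic.
    """
    score, obj, bps = _dp(dag)
    return SegmentationResult(
        breakpoints=bps, T=dag.T, objective=obj, penalty_total=0.0,
        criterion="none",
    )


def penalized_path(dag: SegDAG, config: PenaltyConfig) -> SegmentationResult:
    """Penalized optimum: maximize path weight minus accumulated BP-penalty.

    No penalty is charged on the hop out of the source, where two new
    breakpoints are necessarily added; every later hop is charged per the
    configured criterion. With lam = 0 this reduces to
    :func:`max_weight_min_length_path`.
    """
    K_max = config.K_max if config.K_max is not None else dag.max_breakpoints()
    score, obj, bps = _dp(dag, lam=config.lam, criterion=config.criterion, K_max=K_max)
    return SegmentationResult(
        breakpoints=bps,
        T=dag.T,
        objective=obj,
        penalty_total=obj - score,
        lam=config.lam,
        criterion=config.criterion,
    )


def lambda_bounds(
    pair_table: PairTable, dag: SegDAG | None = None
) -> tuple[float, float]:
    """Data-derived tuning range: (min positive d, unpenalized path weight).

    The lower bound is the smallest positive pair distance; the upper bound
    is the weight of the unpenalized optimal path, i.e. the largest
    attainable objective, so the grid spans penalties from negligible to
    path-dominating. Degenerate all-zero tables raise.
    """
    positive = [v for v in pair_table.weights.values() if v > 0]
    if not positive:
        raise ValueError("all pair distances are zero; no tuning range exists")
    low = min(positive)
    if dag is None:
        dag = build_dag(pair_table)
    high = max_weight_min_length_path(dag).objective
    return low, max(high, low)


def sweep(
    dag: SegDAG,
    config: PenaltyConfig,
    bounds: tuple[float, float],
    n_grid: int = 20,
) -> SegmentationResult:
    """Penalized DP over an equidistant lambda grid with modal consensus.

    Runs the penalized DP at ``n_grid`` equidistant lambda values spanning
    ``bounds`` inclusive (a single-point grid uses the lower bound); the
    consensus is the modal breakpoint set across the grid, ties broken
    toward fewer segments and then lexicographically.
    """
    low, high = bounds
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    if low > high:
        raise ValueError("lambda bounds must satisfy low <= high")
    lams = [low] if n_grid == 1 else list(np.linspace(low, high, n_grid))
    solutions: list[LambdaSolution] = []
    for lam in lams:
        pc = PenaltyConfig(criterion=config.criterion, lam=float(lam), K_max=config.K_max)
        res = penalized_path(dag, pc)
        solutions.append(
            LambdaSolution(
                lam=float(lam),
                breakpoints=res.breakpoints,
                n_segments=res.n_segments,
                objective=res.objective,
                penalty_total=res.penalty_total,
                score=res.score,
            )
        )
    counts: dict[tuple[int, ...], int] = {}
    for sol in solutions:
        counts[sol.breakpoints] = counts.get(sol.breakpoints, 0) + 1
    consensus = min(counts, key=lambda bps: (-counts[bps], len(bps), bps))
    rep = next(s for s in solutions if s.breakpoints == consensus)
    return SegmentationResult(
        breakpoints=consensus,
        T=dag.T,
        objective=rep.objective,
        penalty_total=rep.penalty_total,
        lam=rep.lam,
        criterion=config.criterion,
        meta={"lambda_low": low, "lambda_high": high, "n_grid": n_grid,
              "consensus_support": counts[consensus]},
        per_lambda=solutions,
    )
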