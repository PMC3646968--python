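"""sklearn-style estimator wrapping the full segmentation pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from netseg.data_io import ExpressionMatrix
from netseg.multseg import (
    PairTable,
    PenaltyConfig,
    SegmentationResult,
    build_dag,
    lambda_bounds,
    max_weight_min_length_path,
    pair_weight_table,
    penalized_path,
    sweep,
)
from netseg.netrecon import build_threshold_table


class NetworkSegmenter(BaseEstimator):
    """Network-based change-point detector for multivariate time series.

    ``fit`` takes an entities-by-time matrix (rows are variables, columns
    are ordered time points), reconstructs a correlation network on every
    candidate segment at a permutation-derived significance threshold,
    weighs every admissible pair of consecutive segments by a network
    distance, and finds the optimal segmentation with a (penalized)
    maximum-weight path dynamic program, swept over a tuning-parameter
    grid unless a fixed ``lam`` is given.

    Parameters
    ----------
    property : {"relative_density", "degree", "betweenness", "closeness"}
        Network property the distance operates on.
    distance : {"global", "lp"}
        "global" compares a global property of the symmetric-difference
        and union graphs (relative density only); "lp" compares per-node
        property vectors with an lp-norm.
    p : float
        Norm order for the "lp" distance (2 = Euclidean).
    min_segment_length : int
        Shortest admissible segment (>= 4 recommended so segment-level
        correlations are statistically meaningful).
    alpha : float
        Significance level of the permutation threshold.
    n_permutations : int
        Permutation rounds per segment length.
    penalty : {"count", "length", "none"}
        Breakpoint-penalty criterion; "none" runs the unpenalized DP.
    lam : float or None
        Fixed tuning value; None sweeps ``n_lambdas`` equidistant values
        between the data-derived bounds and reports the modal consensus.
    n_lambdas : int
        Grid size of the sweep.
    absolute : bool
        Threshold |r| (anti-correlation also couples entities) rather
        than signed r.
    random_state : int or None
        Seed for the permutation null; fixed seeds reproduce results
        bit-identically.

    Attributes
    ----------
    breakpoints_ : tuple of int
        Segment-final time points (1-based) of the chosen segmentation.
    n_segments_ : int
    labels_ : ndarray of shape (T,)
        Segment index (0-based) of every time point.
    result_ : SegmentationResult
        Full result including per-lambda solutions when swept.
    lambda_bounds_ : tuple of float
    thresholds_ : ThresholdTable
    pair_table_ : PairTable
    """

    def __init__(
        self,
        property: str = "relative_density",
        distance: str = "global",
        p: float = 2,
        min_segment_length: int = 4,
        alpha: float = 0.05,
        n_permutations: int = 1000,
        penalty: str = "count",
        lam: float | None = None,
        n_lambdas: int = 20,
        absolute: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.property = property
        self.distance = distance
        self.p = p
        self.min_segment_length = min_segment_length
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.penalty = penalty
        self.lam = lam
        self.n_lambdas = n_lambdas
        self.absolute = absolute
        self.random_state = random_state

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix.from_frame(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D entities-by-time matrix")
        return ExpressionMatrix(
            [f"V{j + 1}" for j in range(X.shape[0])],
            [f"t{j + 1}" for j in range(X.shape[1])],
            X,
        )

    def fit(self, X, y=None) -> "NetworkSegmenter":
        """Segment the time axis of ``X`` (entities x time points)."""
        matrix = self._as_matrix(X)
        if matrix.has_missing():
            raise ValueError(
                "X contains missing values; filter profiles first"
            )
        T = matrix.n_timepoints
        L = self.min_segment_length
        if T < 2 * L:
            raise ValueError(
                f"T={T} admits no pair of segments of length >= {L}"
            )
        self.thresholds_ = build_threshold_table(
            matrix,
            min_length=L,
            max_length=T - L,
            alpha=self.alpha,
            n_perm=self.n_permutations,
            seed=self.random_state,
            absolute=self.absolute,
        )
        self.pair_table_ = pair_weight_table(
            matrix,
            L_min=L,
            property=self.property,
            distance=self.distance,
            p=self.p,
            thresholds=self.thresholds_,
            absolute=self.absolute,
        )
        dag = build_dag(self.pair_table_)
        if self.penalty == "none":
            self.lambda_bounds_ = None
            result = max_weight_min_length_path(dag)
        elif self.lam is not None:
            self.lambda_bounds_ = None
            result = penalized_path(
                dag, PenaltyConfig(criterion=self.penalty, lam=self.lam)
            )
        else:
            self.lambda_bounds_ = lambda_bounds(self.pair_table_, dag)
            result = sweep(
                dag,
                PenaltyConfig(criterion=self.penalty),
                self.lambda_bounds_,
                n_grid=self.n_lambdas,
            )
        result.meta.update(
            property=self.property,
            distance=self.distance,
            p=self.p,
            min_segment_length=L,
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            penalty=self.penalty,
            random_state=self.random_state,
        )
        self.result_ = result
        self.breakpoints_ = result.breakpoints
        self.n_segments_ = result.n_segments
        labels = np.zeros(T, dtype=int)
        for j, (start, end) in enumerate(result.segments()):
            labels[start - 1 : end] = j
        self.labels_ = labels
        return self

    def predict(self, X=None) -> np.ndarray:
        """Segment label (0-based) of every time point of the fitted axis."""
        self._check_fitted()
        if X is not None:
            matrix = self._as_matrix(X)
            if matrix.n_timepoints != len(self.labels_):
                raise ValueError(
                    "X has a different number of time points than the "
                    "fitted matrix"
                )
        return self.labels_.copy()

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict()

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise AttributeError(
                "this NetworkSegmenter instance is not fitted yet"
            )


def segment_time_series(X, **params) -> SegmentationResult:
    """Functional one-call interface over :class:`NetworkSegmenter`."""
    return NetworkSegmenter(**params).fit(X).result_
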