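"""The max-snippet detector: scoring, likelihood, and maximum-likelihood fitting.

Model
-----
Every snippet feature vector ``f`` is scored by a logistic detector

    logit = b0 + W . f        score = sigmoid(logit)

with a single shared ``(b0, W)``.  A patient's diagnosis probability is the
*maximum* snippet score over their repertoire (multiple-instance max
pooling): one high-scoring receptor suffices for a positive call.  Parameters
are fit by minimizing the negative log-likelihood of the patient labels
under this max-pooled probability, using full-batch Adam from many random
restarts; the restart with the lowest final (unpenalized) training NLL wins.

Numerics
--------
``log p`` and ``log(1 - p)`` are always computed from the max *logit* via the
stable softplus, never from a clipped probability.  The gradient of the max
is the subgradient through the argmax snippet (first index on ties).  Public
reference functions (:func:`negative_log_likelihood`, :func:`nll_gradient`,
:func:`adam_step`) are float64; the restart-vectorized training engine runs
in float32 with a single BLAS matmul per iteration and is cross-checked
against the reference path in the test suite.

Reproducibility
---------------
All randomness derives from ``(config.seed, key, restart_index)`` through
``numpy`` seed sequences, so results are independent of execution order or
degree of parallelism.  Patients are canonically ordered by ``patient_id``
inside :func:`fit`, making the result invariant to input order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atchley import atchley_checksum
from .featurization import FeatureEncoding, FeatureMatrix, Snippet

__all__ = [
    "DetectorParams",
    "EarlyStoppingConfig",
    "FitConfig",
    "FitResult",
    "RepertoirePrediction",
    "FittingError",
    "ChecksumError",
    "snippet_logit",
    "snippet_score",
    "repertoire_probability",
    "negative_log_likelihood",
    "nll_gradient",
    "AdamState",
    "adam_step",
    "fit",
    "predict",
    "bagged_fit",
    "bagged_predict",
    "save_model",
    "load_model",
    "restart_log_frame",
]


class FittingError(RuntimeError):
    """All restarts diverged or the fit inputs are unusable."""


class ChecksumError(ValueError):
    """Serialized model was built against a different Atchley table."""


@dataclass
class DetectorParams:
    """Bias and weight vector of the logistic detector."""

    b0: float
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 1:
            raise ValueError("W must be a 1-d vector")
        if not (np.isfinite(self.b0) and np.all(np.isfinite(self.W))):
            raise ValueError("detector parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


@dataclass
class EarlyStoppingConfig:
    """Hold out a fraction of training patients and stop on plateau."""

    holdout_fraction: float = 0.2
    patience: int = 5
    check_every: int = 25


@dataclass
class FitConfig:
    """Optimizer settings.

    Defaults reproduce the published fitting recipe (2500 Adam iterations,
    step size 0.01, beta1 0.9, beta2 0.999, epsilon 1e-8, bias initialized
    to 0 and weights drawn from N(0, 1/n_features)), except that the restart
    count defaults to a desk-scale 1000 rather than 10^5; per-restart
    randomness depends only on (seed, key, restart index), so raising the
    count extends rather than reshuffles the search.

    ``init_reading`` selects how N(0, n_features^-1) is read: ``"variance"``
    (the conventional reading, default) or ``"sd"``.
    """

    n_restarts: int = 1000
    n_iterations: int = 2500
    step_size: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0
    l1: float = 0.0
    l2: float = 0.0
    engine: str = "auto"
    init_reading: str = "variance"
    early_stopping: EarlyStoppingConfig | None = None
    bagging: int | None = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.n_iterations < 1:
            raise ValueError("n_restarts and n_iterations must be positive")
        if self.step_size <= 0 or self.epsilon <= 0:
            raise ValueError("step_size and epsilon must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1/beta2 must lie in [0, 1)")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("l1/l2 must be nonnegative")
        if self.init_reading not in ("variance", "sd"):
            raise ValueError("init_reading must be 'variance' or 'sd'")

    def init_sd(self, n_features: int) -> float:
        if self.init_reading == "variance":
            return 1.0 / math.sqrt(n_features)
        return 1.0 / n_features

    @classmethod
    def from_file(cls, path: str | Path) -> "FitConfig":
        """Load a config from YAML or JSON (YAML being a superset of JSON)."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        es = data.pop("early_stopping", None)
        if es is not None:
            data["early_stopping"] = EarlyStoppingConfig(**es)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class RestartRecord:
    restart: int
    seed_key: tuple
    final_nll: float


@dataclass
class FitResult:
    """Best-of-restarts parameters plus per-restart diagnostics."""

    params: DetectorParams
    train_nll: float
    per_restart: list[RestartRecord]
    converged_flags: list[bool]
    best_restart: int
    n_features: int
    config: FitConfig


@dataclass
class RepertoirePrediction:
    patient_id: str
    probability: float
    diagnosis: str
    argmax_snippet: Snippet | None
    argmax_score: float
    boundary_flag: bool = False


# ---------------------------------------------------------------------------
# reference (float64) operations
# ---------------------------------------------------------------------------


def snippet_logit(features: np.ndarray, params: DetectorParams) -> float:
    """``b0 + W . f`` for one snippet."""
    features = np.asarray(features, dtype=np.float64)
    if features.shape != params.W.shape:
        raise ValueError(
            f"feature length {features.shape} != weight length {params.W.shape}"
        )
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite snippet features")
    return float(params.b0 + features @ params.W)


def snippet_score(logit: float) -> float:
    """Overflow-safe sigmoid, strictly increasing, range (0, 1)."""
    if logit >= 0:
        return 1.0 / (1.0 + math.exp(-logit))
    z = math.exp(logit)
    return z / (1.0 + z)


def repertoire_probability(scores: Sequence[float]) -> tuple[float, int]:
    """Max-pooled diagnosis probability and the first argmax index."""
    scores = list(scores)
    if not scores:
        raise ValueError("patient has no snippets; diagnosis undefined")
    idx = int(np.argmax(scores))
    return float(scores[idx]), idx


def _softplus(x: float) -> float:
    # log(1 + e^x), stable for large |x|
    if x > 0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


def _as_matrix(fm) -> np.ndarray:
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("each patient needs a nonempty 2-d feature matrix")
    return X


def negative_log_likelihood(
    params: DetectorParams,
    feature_matrices: Sequence,
    labels: Sequence[int],
    l1: float = 0.0,
    l2: float = 0.0,
) -> float:
    """Summed NLL of the max-pooled diagnosis probabilities.

    ``-sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`` with
    ``p_i = sigmoid(max logit)``, evaluated via softplus of the max logit so
    saturated probabilities never produce -inf; plus ``l1 |W|_1 + l2 |W|_2^2``
    when regularization is enabled.
    """
    if len(feature_matrices) != len(labels):
        raise ValueError("one feature matrix per label required")
    nll = 0.0
    for fm, y in zip(feature_matrices, labels):
        X = _as_matrix(fm)
        z = float(np.max(X @ params.W + params.b0))
        # y=1: -log p = softplus(-z); y=0: -log(1-p) = softplus(z)
        nll += _softplus(-z) if y == 1 else _softplus(z)
    if l1:
        nll += l1 * float(np.sum(np.abs(params.W)))
    if l2:
        nll += l2 * float(params.W @ params.W)
    return nll


def nll_gradient(
    params: DetectorParams,
    feature_matrices: Sequence,
    labels: Sequence[int],
    l1: float = 0.0,
    l2: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Analytic subgradient of :func:`negative_log_likelihood`.

    The max is piecewise-differentiable: per patient the gradient flows only
    through the argmax snippet (first index on exact ties) and equals
    ``(p - y)`` times that snippet's features (1 for the bias).  The L1
    subgradient at exactly 0 is taken as 0.
    """
    if len(feature_matrices) != len(labels):
        raise ValueError("one feature matrix per label required")
    d_b0 = 0.0
    d_W = np.zeros_like(params.W)
    for fm, y in zip(feature_matrices, labels):
        X = _as_matrix(fm)
        logits = X @ params.W + params.b0
        j = int(np.argmax(logits))
        p = snippet_score(float(logits[j]))
        c = p - float(y)
        d_b0 += c
        d_W += c * X[j]
    if l1:
        d_W += l1 * np.sign(params.W)
    if l2:
        d_W += 2.0 * l2 * params.W
    return d_b0, d_W


@dataclass
class AdamState:
    """Flat parameter vector (bias first) plus Adam moment estimates."""

    theta: np.ndarray
    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def initialize(cls, theta: np.ndarray) -> "AdamState":
        theta = np.asarray(theta, dtype=np.float64)
        return cls(theta.copy(), np.zeros_like(theta), np.zeros_like(theta), 0)


def adam_step(state: AdamState, gradient: np.ndarray, config: FitConfig) -> AdamState:
    """One standard Adam update with bias-corrected moments."""
    g = np.asarray(gradient, dtype=np.float64)
    t = state.t + 1
    m = config.beta1 * state.m + (1 - config.beta1) * g
    v = config.beta2 * state.v + (1 - config.beta2) * g * g
    m_hat = m / (1 - config.beta1**t)
    v_hat = v / (1 - config.beta2**t)
    theta = state.theta - config.step_size * m_hat / (np.sqrt(v_hat) + config.epsilon)
    return AdamState(theta, m, v, t)


# ---------------------------------------------------------------------------
# restart-vectorized engine (float32)
# ---------------------------------------------------------------------------


def _restart_seed_key(config: FitConfig, key: tuple, r: int) -> tuple:
    return (int(config.seed),) + tuple(int(x) for x in key) + (int(r),)


def _init_weights(config: FitConfig, key: tuple, n_features: int) -> np.ndarray:
    """Per-restart initial parameters: bias 0, weights N(0, init_sd^2)."""
    R = config.n_restarts
    W = np.empty((R, n_features + 1), dtype=np.float32)
    W[:, 0] = 0.0
    sd = config.init_sd(n_features)
    for r in range(R):
        ss = np.random.SeedSequence(_restart_seed_key(config, key, r))
        rng = np.random.Generator(np.random.PCG64(ss))
        W[r, 1:] = rng.normal(0.0, sd, n_features)
    return W


def _sigmoid32(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class _DenseOps:
    """Forward/gradient on an explicit float32 design matrix (BLAS gemm).

    ``X`` is (N, n_features + 1) with a leading ones column standing in for
    the bias, so the bias follows the same Adam update as the weights.
    """

    def __init__(self, X: np.ndarray, slices, n_restarts: int):
        self.X = X
        self.XT = np.ascontiguousarray(X.T)
        self.slices = slices
        self.L = np.empty((n_restarts, X.shape[0]), dtype=np.float32)
        self._rows = np.arange(n_restarts)

    def forward(self, W: np.ndarray, patients):
        """Per-patient max logit and (first) argmax snippet row under W."""
        np.dot(W, self.XT, out=self.L)
        mx = np.empty((len(patients), W.shape[0]), dtype=np.float32)
        amax = np.empty((len(patients), W.shape[0]), dtype=np.int64)
        for i, p in enumerate(patients):
            s, e = self.slices[p]
            blk = self.L[:, s:e]
            a = np.argmax(blk, axis=1)
            amax[i] = s + a
            mx[i] = blk[self._rows, a]
        return mx, amax

    def grad(self, W: np.ndarray, C: np.ndarray, amax: np.ndarray) -> np.ndarray:
        g = np.zeros_like(W)
        for i in range(C.shape[0]):
            g += C[i][:, None] * self.X[amax[i]]
        return g


class _CategoricalOps:
    """Forward/gradient exploiting the positional-categorical factorization.

    Builds the (k, S, R) per-position symbol score tables from W each
    iteration and fuses the gather-sum/max in a compiled kernel; the weight
    gradient is recovered from per-symbol gradient mass via k tiny matmuls.
    Numerically equivalent to :class:`_DenseOps` up to float32 summation
    order (cross-checked in the test suite).
    """

    def __init__(self, codes: np.ndarray, basis: np.ndarray, slices, n_restarts: int):
        from ._categorical import _forward_max, _grad_scatter

        self._forward_max = _forward_max
        self._grad_scatter = _grad_scatter
        self.codes = codes
        self.B = np.ascontiguousarray(basis.astype(np.float32))
        self.S, self.Fs = self.B.shape
        self.k = codes.shape[1]
        self.starts = np.array([s for s, _ in slices], dtype=np.int64)
        self.ends = np.array([e for _, e in slices], dtype=np.int64)
        self.T = np.empty((self.k, self.S, n_restarts), dtype=np.float32)

    def _tables(self, W: np.ndarray) -> None:
        for p in range(self.k):
            block = W[:, 1 + p * self.Fs : 1 + (p + 1) * self.Fs]
            np.dot(self.B, np.ascontiguousarray(block.T), out=self.T[p])

    def forward(self, W: np.ndarray, patients):
        self._tables(W)
        R = W.shape[0]
        mx = np.empty((len(patients), R), dtype=np.float32)
        amax = np.empty((len(patients), R), dtype=np.int64)
        self._forward_max(
            self.codes, self.T, self.starts[patients], self.ends[patients], mx, amax
        )
        mx += W[:, 0][None, :]  # shared bias shifts every logit equally
        return mx, amax

    def grad(self, W: np.ndarray, C: np.ndarray, amax: np.ndarray) -> np.ndarray:
        G = np.zeros((self.k, self.S, W.shape[0]), dtype=np.float32)
        self._grad_scatter(self.codes, amax, C, G)
        g = np.empty_like(W)
        g[:, 0] = C.sum(axis=0)
        for p in range(self.k):
            g[:, 1 + p * self.Fs : 1 + (p + 1) * self.Fs] = (self.B.T @ G[p]).T
        return g


def _nll_per_restart(mx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unpenalized NLL per restart from per-patient max logits (float64)."""
    z = mx.astype(np.float64)
    signed = np.where(y[:, None] == 1, -z, z)
    return np.logaddexp(0.0, signed).sum(axis=0)


def _fit_engine(ops, n_patients: int, y: np.ndarray, config: FitConfig, key: tuple,
                n_features: int):
    """Run all restarts in lockstep through an ops backend.

    Returns (W, final_nll, initial_nll) with W of shape
    (n_restarts, n_features + 1), bias in column 0.
    """
    R = config.n_restarts
    W = _init_weights(config, key, n_features)
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    y32 = y.astype(np.float32)
    all_patients = list(range(n_patients))

    es = config.early_stopping
    if es is not None:
        n_val = max(1, int(round(es.holdout_fraction * n_patients)))
        if n_patients - n_val < 2:
            raise FittingError("early stopping holdout leaves too few training patients")
        ss = np.random.SeedSequence(
            (int(config.seed),) + tuple(int(x) for x in key) + (2**20,)
        )
        rng = np.random.Generator(np.random.PCG64(ss))
        order = rng.permutation(n_patients)
        val_patients = sorted(order[:n_val].tolist())
        train_patients = sorted(order[n_val:].tolist())
        if len({int(y[p]) for p in train_patients}) < 2:
            raise FittingError("early stopping holdout removed one label entirely")
        best_W = W.copy()
        best_val = np.full(R, np.inf)
        strikes = np.zeros(R, dtype=np.int64)
        active = np.ones(R, dtype=bool)
    else:
        train_patients = all_patients
        val_patients = []

    y_train = y32[train_patients]

    mx0, _ = ops.forward(W, all_patients)
    initial_nll = _nll_per_restart(mx0, y)

    l1 = np.float32(config.l1)
    l2 = np.float32(config.l2)
    for t in range(1, config.n_iterations + 1):
        mx, amax = ops.forward(W, train_patients)
        C = _sigmoid32(mx) - y_train[:, None]
        g = ops.grad(W, C, amax)
        if l2:
            g[:, 1:] += (2.0 * l2) * W[:, 1:]
        if l1:
            g[:, 1:] += l1 * np.sign(W[:, 1:])
        m *= config.beta1
        m += (1 - config.beta1) * g
        v *= config.beta2
        v += (1 - config.beta2) * g * g
        m_hat = m / np.float32(1 - config.beta1**t)
        v_hat = v / np.float32(1 - config.beta2**t)
        upd = np.float32(config.step_size) * m_hat / (np.sqrt(v_hat) + np.float32(config.epsilon))
        if es is not None:
            upd[~active] = 0.0
        W -= upd

        if es is not None and t % es.check_every == 0:
            mx_v, _ = ops.forward(W, val_patients)
            val_nll = _nll_per_restart(mx_v, y[val_patients])
            improved = val_nll < best_val - 1e-9
            best_W[improved & active] = W[improved & active]
            best_val = np.where(improved, val_nll, best_val)
            strikes = np.where(improved, 0, strikes + 1)
            active &= strikes < es.patience
            if not active.any():
                break

    if es is not None:
        W = best_W
    mx_f, _ = ops.forward(W, all_patients)
    final_nll = _nll_per_restart(mx_f, y)
    return W, final_nll, initial_nll


def _assemble(feature_matrices: Sequence[FeatureMatrix], labels: Sequence[int]):
    """Canonically order patients by id and stack their features (float32)."""
    if len(feature_matrices) != len(labels):
        raise ValueError("one feature matrix per label required")
    order = sorted(
        range(len(feature_matrices)),
        key=lambda i: (feature_matrices[i].patient_id, i),
    )
    fms = [feature_matrices[i] for i in order]
    y = np.asarray([labels[i] for i in order], dtype=np.int64)
    if set(y.tolist()) != {0, 1}:
        raise FittingError("fitting requires patients of both labels")
    n_feat = fms[0].X.shape[1]
    blocks, slices, start = [], [], 0
    for fm in fms:
        X = _as_matrix(fm)
        if X.shape[1] != n_feat:
            raise ValueError("inconsistent feature dimension across patients")
        block = np.empty((X.shape[0], n_feat + 1), dtype=np.float32)
        block[:, 0] = 1.0
        block[:, 1:] = X
        blocks.append(block)
        slices.append((start, start + X.shape[0]))
        start += X.shape[0]
    return np.concatenate(blocks, axis=0), slices, y, fms


def _categorical_parts(fms: Sequence[FeatureMatrix]):
    """Stacked symbol codes and the shared basis, or None if inapplicable."""
    basis = None
    for fm in fms:
        if fm.codes is None or fm.basis is None:
            return None
        if basis is None:
            basis = fm.basis
        elif fm.basis.shape != basis.shape or not np.array_equal(fm.basis, basis):
            return None
    return np.concatenate([fm.codes for fm in fms], axis=0), basis


def _make_ops(X, slices, fms, config: FitConfig):
    if config.engine not in ("auto", "dense", "categorical"):
        raise ValueError(f"unknown engine {config.engine!r}")
    if config.engine != "dense":
        from ._categorical import HAVE_NUMBA

        parts = _categorical_parts(fms)
        if parts is not None and HAVE_NUMBA:
            return _CategoricalOps(parts[0], parts[1], slices, config.n_restarts)
        if config.engine == "categorical":
            raise ValueError(
                "categorical engine requires numba and positional-categorical features"
            )
    return _DenseOps(X, slices, config.n_restarts)


def fit(
    feature_matrices: Sequence[FeatureMatrix],
    labels: Sequence[int],
    config: FitConfig,
    key: tuple = (),
) -> FitResult:
    """Maximum-likelihood fit with random restarts.

    ``key`` namespaces the restart seeds (cross-validation folds and ensemble
    members pass distinct keys); restart ``r`` always draws its initial
    weights from ``SeedSequence((seed, *key, r))``.
    """
    X, slices, y, fms = _assemble(feature_matrices, labels)
    ops = _make_ops(X, slices, fms, config)
    W, final_nll, initial_nll = _fit_engine(
        ops, len(slices), y, config, key, X.shape[1] - 1
    )
    finite = np.isfinite(final_nll)
    if not finite.any():
        raise FittingError(
            f"all {config.n_restarts} restarts produced non-finite NLL; "
            f"initial NLLs ranged {np.nanmin(initial_nll):.3g}.."
            f"{np.nanmax(initial_nll):.3g}"
        )
    nll_for_choice = np.where(finite, final_nll, np.inf)
    best = int(np.argmin(nll_for_choice))
    params = DetectorParams(b0=float(W[best, 0]), W=W[best, 1:].astype(np.float64))
    per_restart = [
        RestartRecord(r, _restart_seed_key(config, key, r), float(final_nll[r]))
        for r in range(config.n_restarts)
    ]
    converged = (finite & (final_nll <= initial_nll + 1e-3)).tolist()
    return FitResult(
        params=params,
        train_nll=float(final_nll[best]),
        per_restart=per_restart,
        converged_flags=converged,
        best_restart=best,
        n_features=X.shape[1] - 1,
        config=config,
    )


def predict(params: DetectorParams, fm: FeatureMatrix) -> RepertoirePrediction:
    """Score one patient: max snippet score; positive iff probability > 0.5.

    A probability of exactly 0.5 maps to a negative diagnosis and raises the
    boundary flag.
    """
    X = _as_matrix(fm)
    logits = X @ params.W + params.b0
    j = int(np.argmax(logits))
    prob = snippet_score(float(logits[j]))
    boundary = prob == 0.5
    snippet = fm.snippets[j] if isinstance(fm, FeatureMatrix) and fm.snippets else None
    return RepertoirePrediction(
        patient_id=fm.patient_id if isinstance(fm, FeatureMatrix) else "",
        probability=prob,
        diagnosis="positive" if prob > 0.5 else "negative",
        argmax_snippet=snippet,
        argmax_score=prob,
        boundary_flag=boundary,
    )


def bagged_fit(
    feature_matrices: Sequence[FeatureMatrix],
    labels: Sequence[int],
    config: FitConfig,
    key: tuple = (),
    max_resample_retries: int = 100,
) -> list[FitResult]:
    """Fit an ensemble on bootstrap resamples of patients (with replacement)."""
    n_bags = config.bagging or 1
    if n_bags == 1:
        return [fit(feature_matrices, labels, config, key)]
    n = len(feature_matrices)
    members = []
    for b in range(n_bags):
        ss = np.random.SeedSequence(
            (int(config.seed),) + tuple(int(x) for x in key) + (2, b, 2**16)
        )
        rng = np.random.Generator(np.random.PCG64(ss))
        for attempt in range(max_resample_retries):
            idx = rng.integers(0, n, size=n)
            if len({labels[i] for i in idx}) == 2:
                break
        else:
            raise FittingError(f"bag {b}: could not draw a two-label bootstrap sample")
        members.append(
            fit([feature_matrices[i] for i in idx], [labels[i] for i in idx],
                config, key + (2, b))
        )
    return members


def bagged_predict(members: Sequence[FitResult], fm: FeatureMatrix) -> RepertoirePrediction:
    """Ensemble probability = mean of member max-pooled probabilities."""
    if not members:
        raise ValueError("empty ensemble")
    probs = [predict(m.params, fm).probability for m in members]
    prob = float(np.mean(probs))
    return RepertoirePrediction(
        patient_id=fm.patient_id,
        probability=prob,
        diagnosis="positive" if prob > 0.5 else "negative",
        argmax_snippet=None,
        argmax_score=prob,
        boundary_flag=prob == 0.5,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(
    path: str | Path,
    params: DetectorParams,
    encoding: FeatureEncoding,
    config: FitConfig | None = None,
    train_nll: float | None = None,
) -> None:
    """Write the fitted detector as JSON, fingerprinting the Atchley table."""
    payload = {
        "scheme": encoding.scheme,
        "k": encoding.k,
        "unit": encoding.unit,
        "b0": params.b0,
        "W": params.W.tolist(),
        "atchley_table_checksum": atchley_checksum(),
        "fit_config": _config_dict(config) if config is not None else None,
        "train_nll": train_nll,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _config_dict(config: FitConfig) -> dict:
    d = asdict(config)
    return d


def load_model(path: str | Path) -> tuple[DetectorParams, FeatureEncoding, dict]:
    """Load a serialized detector; refuse an Atchley checksum mismatch."""
    payload = json.loads(Path(path).read_text())
    if payload["atchley_table_checksum"] != atchley_checksum():
        raise ChecksumError(
            "model was fit against a different Atchley table "
            f"({payload['atchley_table_checksum'][:12]}...)"
        )
    params = DetectorParams(b0=float(payload["b0"]), W=np.asarray(payload["W"]))
    encoding = FeatureEncoding(scheme=payload["scheme"], k=int(payload["k"]))
    meta = {k: payload.get(k) for k in ("fit_config", "train_nll", "unit")}
    return params, encoding, meta


def restart_log_frame(result: FitResult) -> pd.DataFrame:
    """Per-restart seed keys and final NLLs, for the run log."""
    return pd.DataFrame(
        {
            "restart": [r.restart for r in result.per_restart],
            "seed_key": [",".join(map(str, r.seed_key)) for r in result.per_restart],
            "final_nll": [r.final_nll for r in result.per_restart],
            "converged": result.converged_flags,
        }
    )
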