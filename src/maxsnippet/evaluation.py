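"""Model assessment: exhaustive LOOCV, model selection, permutation null, ROC.

Leave-one-out cross-validation holds each patient out once, refits the
detector on the remainder with fresh restarts (fold-specific seed keys
derived from ``(config.seed, fold index, restart index)``), and scores the
held-out patient.  Model selection runs LOOCV for each candidate
representation (snippet length x encoding scheme) and declares the winner by
cross-validated accuracy, ties broken toward fewer features.  The
permutation test shuffles patient labels (label counts preserved) and reruns
the *entire* LOOCV procedure per permutation; its p-value uses the add-one
estimator ``(1 + #{perm >= observed}) / (1 + n_permutations)``, which gives
p = 1/21 < 0.05 when the observed accuracy beats all of 20 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .featurization import SCHEMES, FeatureEncoding, FeatureMatrix, encode_cohort
from .model import FitConfig, FitResult, fit, predict
from .preprocessing import Cohort

__all__ = [
    "FoldRecord",
    "CVResult",
    "CandidateRow",
    "ModelSelectionTable",
    "PermutationResult",
    "ROCResult",
    "loocv",
    "select_model",
    "refit_full",
    "permutation_test",
    "permutation_pvalue",
    "roc",
    "cv_frame",
    "selection_frame",
    "permutation_frame",
    "roc_frame",
]


@dataclass
class FoldRecord:
    held_out_patient_id: str
    probability: float
    predicted: int
    true: int


@dataclass
class CVResult:
    per_fold: list[FoldRecord]
    n_correct: int
    accuracy: float

    @property
    def n_total(self) -> int:
        return len(self.per_fold)


@dataclass
class CandidateRow:
    encoding: FeatureEncoding
    feasible: bool
    cv: CVResult | None = None
    reason: str = ""

    @property
    def accuracy(self) -> float:
        return self.cv.accuracy if self.cv is not None else float("nan")


@dataclass
class ModelSelectionTable:
    rows: list[CandidateRow]
    winner: FeatureEncoding
    tie_log: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    observed_n_correct: int
    permuted_n_correct: list[int]
    p_value: float
    mean_permuted_accuracy: float
    n_total: int
    observed_cv: CVResult | None = None


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


#: The default model-selection grid: snippet lengths 4-7 in the biochemical
#: representation, two codon-snippet lengths one-hot in nucleotides, and a
#: 6-mer amino-acid one-hot control.
DEFAULT_GRID: tuple[tuple[int, str], ...] = (
    (4, "atchley"),
    (5, "atchley"),
    (6, "atchley"),
    (7, "atchley"),
    (6, "nt_onehot"),
    (18, "nt_onehot"),
    (6, "aa_onehot"),
)


def loocv(
    feature_matrices: Sequence[FeatureMatrix],
    labels: Sequence[int],
    config: FitConfig,
    key: tuple = (),
) -> CVResult:
    """Exhaustive leave-one-out cross-validation.

    Folds are enumerated in sorted patient-id order so the result is
    invariant to input ordering; fold ``i`` derives its restart seeds from
    ``key + (1, i)``.
    """
    n = len(feature_matrices)
    if n != len(labels):
        raise ValueError("one feature matrix per label required")
    counts = {0: 0, 1: 0}
    for y in labels:
        counts[int(y)] += 1
    order = sorted(range(n), key=lambda i: (feature_matrices[i].patient_id, i))
    per_fold = []
    for fold, i in enumerate(order):
        held = feature_matrices[i]
        if counts[int(labels[i])] < 2:
            raise ValueError(
                f"fold {fold} (hold out {held.patient_id}): training fold "
                f"would lose label {labels[i]} entirely"
            )
        train_fms = [feature_matrices[j] for j in order if j != i]
        train_y = [labels[j] for j in order if j != i]
        result = fit(train_fms, train_y, config, key=key + (1, fold))
        pred = predict(result.params, held)
        per_fold.append(
            FoldRecord(
                held_out_patient_id=held.patient_id,
                probability=pred.probability,
                predicted=1 if pred.diagnosis == "positive" else 0,
                true=int(labels[i]),
            )
        )
    n_correct = sum(f.predicted == f.true for f in per_fold)
    return CVResult(per_fold, n_correct, n_correct / n)


def _as_encoding(candidate) -> FeatureEncoding:
    if isinstance(candidate, FeatureEncoding):
        return candidate
    k, scheme = candidate
    return FeatureEncoding(scheme=scheme, k=int(k))


def select_model(
    cohort: Cohort,
    grid: Sequence = DEFAULT_GRID,
    config: FitConfig | None = None,
    key: tuple = (),
) -> ModelSelectionTable:
    """LOOCV over a grid of candidate representations; declare a winner.

    A candidate that cannot encode the data (e.g. every CDR3 of some patient
    shorter than ``k``, or nucleotide sequences absent) is kept in the table
    marked infeasible.  The winner is the feasible row with highest accuracy;
    exact ties break toward smaller ``n_features`` (logged), then toward
    smaller ``(k, scheme)`` for full determinism.  Each candidate's fold
    seeds derive from the candidate itself, never from its grid position, so
    the winner is invariant to row order.
    """
    if not grid:
        raise ValueError("candidate grid must be nonempty")
    config = config or FitConfig()
    rows = []
    for cand in grid:
        enc = _as_encoding(cand)
        try:
            fms = encode_cohort(cohort, enc)
        except ValueError as exc:
            rows.append(CandidateRow(enc, feasible=False, reason=str(exc)))
            continue
        cand_key = key + (4, enc.k, SCHEMES.index(enc.scheme))
        cv = loocv(fms, cohort.labels, config, key=cand_key)
        rows.append(CandidateRow(enc, feasible=True, cv=cv))

    winner, tie_log = declare_winner(rows)
    rows.sort(key=lambda r: (-(r.accuracy if r.feasible else -1), r.encoding.n_features))
    return ModelSelectionTable(rows, winner, tie_log)


def declare_winner(rows: Sequence[CandidateRow]) -> tuple[FeatureEncoding, list[str]]:
    """Best feasible candidate by accuracy; exact ties break toward fewer
    features (logged), then toward smaller (k, scheme) for determinism."""
    feasible = [r for r in rows if r.feasible]
    if not feasible:
        raise ValueError("no feasible candidate in the grid")
    best_acc = max(r.accuracy for r in feasible)
    tied = [r for r in feasible if r.accuracy == best_acc]
    tie_log = []
    if len(tied) > 1:
        tie_log.append(
            "accuracy tie at {:.4f} between {}; broken toward fewer features".format(
                best_acc, ", ".join(r.encoding.describe() for r in tied)
            )
        )
    winner = min(
        tied, key=lambda r: (r.encoding.n_features, r.encoding.k, r.encoding.scheme)
    ).encoding
    return winner, tie_log


def refit_full(
    cohort: Cohort,
    candidate,
    config: FitConfig,
    key: tuple = (),
) -> tuple[FitResult, FeatureEncoding, list[FeatureMatrix]]:
    """Refit the winning representation on the full cohort (the deployable model)."""
    enc = _as_encoding(candidate)
    fms = encode_cohort(cohort, enc)
    return fit(fms, cohort.labels, config, key=key), enc, fms


def permutation_pvalue(observed_n_correct: int, permuted_n_correct: Sequence[int]) -> float:
    """Add-one permutation p-value: ``(1 + #{perm >= obs}) / (1 + n_perm)``."""
    n = len(permuted_n_correct)
    if n < 1:
        raise ValueError("need at least one permutation")
    ge = sum(1 for c in permuted_n_correct if c >= observed_n_correct)
    return (1 + ge) / (1 + n)


def permutation_test(
    feature_matrices: Sequence[FeatureMatrix],
    labels: Sequence[int],
    config: FitConfig,
    n_permutations: int = 20,
    perm_seed: int | None = None,
    key: tuple = (),
    observed_cv: CVResult | None = None,
) -> PermutationResult:
    """Label-permutation null for the LOOCV accuracy.

    Each permutation uniformly shuffles the label vector over patients
    (label counts preserved) and reruns the full LOOCV procedure.  Pass
    ``observed_cv`` to reuse an already-computed observed run.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if perm_seed is None:
        perm_seed = config.seed
    if observed_cv is None:
        observed_cv = loocv(feature_matrices, labels, config, key=key)
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(perm_seed), 3)))
    )
    labels_arr = np.asarray(labels, dtype=np.int64)
    permuted_counts = []
    for p in range(n_permutations):
        perm_labels = rng.permutation(labels_arr)
        cv = loocv(feature_matrices, perm_labels.tolist(), config, key=key + (3, p))
        permuted_counts.append(cv.n_correct)
    n_total = len(feature_matrices)
    return PermutationResult(
        observed_n_correct=observed_cv.n_correct,
        permuted_n_correct=permuted_counts,
        p_value=permutation_pvalue(observed_cv.n_correct, permuted_counts),
        mean_permuted_accuracy=float(np.mean(permuted_counts)) / n_total,
        n_total=n_total,
        observed_cv=observed_cv,
    )


def roc(probabilities: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve over a threshold sweep of the diagnosis probabilities.

    AUC is the trapezoid-rule area under the (FPR, TPR) staircase; tied
    probabilities step simultaneously.
    """
    labels_arr = np.asarray(labels, dtype=np.int64)
    if len(set(labels_arr.tolist())) < 2:
        raise ValueError("ROC requires both labels present")
    fpr, tpr, thresholds = _sk_roc_curve(labels_arr, probabilities, drop_intermediate=False)
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------


def cv_frame(cv: CVResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [f.held_out_patient_id for f in cv.per_fold],
            "probability": [f.probability for f in cv.per_fold],
            "predicted": [f.predicted for f in cv.per_fold],
            "true": [f.true for f in cv.per_fold],
        }
    )


def selection_frame(table: ModelSelectionTable) -> pd.DataFrame:
    rows = []
    for r in table.rows:
        rows.append(
            {
                "k": r.encoding.k,
                "unit": r.encoding.unit,
                "scheme": r.encoding.scheme,
                "n_features": r.encoding.n_features,
                "feasible": r.feasible,
                "n_correct": r.cv.n_correct if r.cv else None,
                "n_total": r.cv.n_total if r.cv else None,
                "cv_accuracy": r.accuracy,
                "winner": r.encoding == table.winner,
                "note": r.reason,
            }
        )
    return pd.DataFrame(rows)


def permutation_frame(result: PermutationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "permutation": list(range(1, len(result.permuted_n_correct) + 1)),
            "n_correct": result.permuted_n_correct,
            "accuracy": [c / result.n_total for c in result.permuted_n_correct],
        }
    )


def roc_frame(result: ROCResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": result.thresholds, "fpr": result.fpr, "tpr": result.tpr}
    )
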