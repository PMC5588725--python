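"""Post-fit analyses of a fitted detector.

Covers the interpretive read-outs that accompany the classifier: the weight
grid over (snippet position, Atchley factor), the top-scoring snippet per
patient located within its source CDR3, score histograms by diagnosis group,
and the codon encoding-degeneracy comparison between diagnostic
(score > 0.5) and non-diagnostic snippets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atchley import ATCHLEY_TABLE, N_FACTORS
from .featurization import FeatureEncoding, FeatureMatrix
from .genetic_code import CODON_COUNTS
from .model import DetectorParams, predict, snippet_score
from .preprocessing import Cohort

__all__ = [
    "WeightMap",
    "TopSnippetRow",
    "ScoreHistogram",
    "DegeneracySummary",
    "weight_map",
    "flatten_weight_map",
    "top_snippets",
    "score_histogram",
    "encoding_count",
    "degeneracy_comparison",
    "degeneracy_analysis",
]

FACTOR_NAMES = ("I", "II", "III", "IV", "V")


@dataclass
class WeightMap:
    """Detector weights re-indexed as (position 1..k, factor I..V) plus bias."""

    grid: np.ndarray  # (k, 5)
    b0: float

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.grid,
            index=[f"pos{i + 1}" for i in range(self.grid.shape[0])],
            columns=[f"factor_{f}" for f in FACTOR_NAMES],
        )
        return df


@dataclass
class TopSnippetRow:
    patient_id: str
    label: int | None
    cdr3: str | None
    snippet: str
    offset: int
    score: float
    atchley: np.ndarray | None  # (k, 5) factor values of the snippet


@dataclass
class ScoreHistogram:
    bin_edges: np.ndarray
    counts_by_group: dict[int, np.ndarray]
    above_threshold_per_patient: dict[str, int]
    threshold: float


@dataclass
class DegeneracySummary:
    per_snippet: pd.DataFrame  # snippet, count, group
    statistic: float
    p_value: float
    test: str
    direction: str
    medians: dict[str, float] = field(default_factory=dict)


def weight_map(params: DetectorParams, encoding: FeatureEncoding) -> WeightMap:
    """Re-index the flat weight vector into the (position, factor) grid.

    Only defined for the Atchley scheme, whose features are laid out
    position-major (residue 1's five factors first).
    """
    if encoding.scheme != "atchley":
        raise ValueError(f"weight map requires the atchley scheme, got {encoding.scheme}")
    if params.n_features != encoding.n_features:
        raise ValueError("weight length does not match encoding")
    return WeightMap(grid=params.W.reshape(encoding.k, N_FACTORS).copy(), b0=params.b0)


def flatten_weight_map(wm: WeightMap) -> DetectorParams:
    """Inverse of :func:`weight_map` (the re-indexing is a bijection)."""
    return DetectorParams(b0=wm.b0, W=wm.grid.reshape(-1).copy())


def top_snippets(
    params: DetectorParams,
    feature_matrices: Sequence[FeatureMatrix],
    cohort: Cohort | None = None,
) -> list[TopSnippetRow]:
    """The argmax snippet of each patient (first index on ties).

    When the cohort is supplied, the snippet is located within its source
    CDR3 string and its per-residue Atchley factor values are attached.
    """
    reps = {r.patient_id: r for r in cohort.repertoires} if cohort is not None else {}
    rows = []
    for fm in feature_matrices:
        pred = predict(params, fm)
        sn = pred.argmax_snippet
        rep = reps.get(fm.patient_id)
        cdr3 = None
        if rep is not None and sn is not None:
            sources = rep.cdr3_nt if set(sn.text) <= set("ACGT") and rep.cdr3_nt else rep.cdr3_aa
            cdr3 = sources[sn.source_cdr3_index]
        atchley = None
        if sn is not None and all(aa in ATCHLEY_TABLE for aa in sn.text):
            atchley = np.array([ATCHLEY_TABLE[aa] for aa in sn.text])
        rows.append(
            TopSnippetRow(
                patient_id=fm.patient_id,
                label=rep.label if rep is not None else None,
                cdr3=cdr3,
                snippet=sn.text if sn is not None else "",
                offset=sn.offset if sn is not None else -1,
                score=pred.probability,
                atchley=atchley,
            )
        )
    return rows


def score_histogram(
    params: DetectorParams,
    feature_matrices: Sequence[FeatureMatrix],
    labels: Sequence[int],
    threshold: float = 0.5,
    n_bins: int = 20,
) -> ScoreHistogram:
    """Bin all snippet scores by diagnosis group; count above-threshold snippets.

    Bin totals conserve snippet totals exactly (scores of 1.0 fall in the
    last bin).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = {0: np.zeros(n_bins, dtype=np.int64), 1: np.zeros(n_bins, dtype=np.int64)}
    above = {}
    for fm, y in zip(feature_matrices, labels):
        logits = fm.X @ params.W + params.b0
        scores = np.array([snippet_score(float(z)) for z in logits])
        hist, _ = np.histogram(scores, bins=edges)
        counts[int(y)] += hist
        above[fm.patient_id] = int(np.sum(scores > threshold))
    return ScoreHistogram(edges, counts, above, threshold)


def encoding_count(snippet_aa: str) -> int:
    """Number of distinct DNA spellings of an amino-acid string.

    Product over residues of the standard-genetic-code codon multiplicity;
    e.g. one for all-Met, 6^k for all-Leu.
    """
    if not snippet_aa:
        raise ValueError("empty snippet")
    total = 1
    for aa in snippet_aa:
        try:
            total *= CODON_COUNTS[aa]
        except KeyError:
            raise ValueError(f"nonstandard residue {aa!r} in snippet {snippet_aa!r}") from None
    return total


def degeneracy_comparison(
    diagnostic_counts: Sequence[int],
    non_diagnostic_counts: Sequence[int],
    test: str = "mannwhitney",
) -> DegeneracySummary:
    """Two-sided comparison of encoding counts between snippet groups.

    Default is the Mann-Whitney U rank test (normal approximation with tie
    correction), appropriate for the discrete, heavily skewed counts; a
    Welch t-test is available behind the flag.
    """
    diag = np.asarray(diagnostic_counts, dtype=np.float64)
    non = np.asarray(non_diagnostic_counts, dtype=np.float64)
    if diag.size == 0 or non_diagnostic_counts is None or non.size == 0:
        raise ValueError("both snippet groups must be nonempty")
    if test == "mannwhitney":
        res = stats.mannwhitneyu(diag, non, alternative="two-sided", method="asymptotic")
    elif test == "welch":
        res = stats.ttest_ind(diag, non, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    med_d, med_n = float(np.median(diag)), float(np.median(non))
    if med_d < med_n:
        direction = "diagnostic snippets have fewer encodings"
    elif med_d > med_n:
        direction = "diagnostic snippets have more encodings"
    else:
        direction = "no median shift"
    per_snippet = pd.DataFrame(
        {
            "count": np.concatenate([diag, non]),
            "group": ["diagnostic"] * diag.size + ["non_diagnostic"] * non.size,
        }
    )
    return DegeneracySummary(
        per_snippet=per_snippet,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test=test,
        direction=direction,
        medians={"diagnostic": med_d, "non_diagnostic": med_n},
    )


def degeneracy_analysis(
    params: DetectorParams,
    feature_matrices: Sequence[FeatureMatrix],
    threshold: float = 0.5,
    unique: bool = True,
    test: str = "mannwhitney",
) -> DegeneracySummary:
    """Group snippets by whether they score above the diagnostic threshold
    and compare their codon encoding degeneracies.

    ``unique=True`` (default) analyses distinct snippet strings; set it
    False for an occurrence-weighted analysis.  Snippets must be amino-acid
    strings (Atchley or amino-acid one-hot encodings).
    """
    scored: dict[str, float] = {}
    occurrences: list[tuple[str, float]] = []
    for fm in feature_matrices:
        logits = fm.X @ params.W + params.b0
        for sn, z in zip(fm.snippets, logits):
            s = snippet_score(float(z))
            scored[sn.text] = s
            occurrences.append((sn.text, s))
    items = scored.items() if unique else occurrences
    diag, non = [], []
    for text, s in items:
        (diag if s > threshold else non).append(encoding_count(text))
    if not diag or not non:
        raise ValueError(
            "one snippet group is empty at threshold "
            f"{threshold} (diagnostic={len(diag)}, non_diagnostic={len(non)})"
        )
    summary = degeneracy_comparison(diag, non, test=test)
    summary.per_snippet["unique_snippets"] = unique
    return summary
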