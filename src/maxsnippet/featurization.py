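"""Snippet extraction and numeric encoding of CDR3 sequences.

Each CDR3 of length ``L`` is cut into all ``L - k + 1`` overlapping k-mers
("snippets", step 1); CDR3s shorter than ``k`` contribute none and are
counted in a skip log.  A snippet is then mapped to a fixed-length feature
vector under one of three schemes:

``atchley``
    Each residue contributes its five Atchley factor values; the feature
    vector is the position-major concatenation (residue 1's five factors,
    then residue 2's, ...), length ``5 k``.  For ``k = 6`` this gives the
    30-dimensional biochemical representation the classifier is built on.
``aa_onehot``
    ``k`` blocks of 20 indicator entries, alphabet ``ACDEFGHIKLMNPQRSTVWY``.
``nt_onehot``
    ``k`` blocks of 4 indicator entries, alphabet ``ACGT`` (nucleotide
    snippets; ``k`` counted in nucleotides and required to be a multiple of
    3 so snippets cover whole codons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atchley import AMINO_ACIDS, ATCHLEY_TABLE, N_FACTORS
from .preprocessing import Cohort, Repertoire

__all__ = [
    "Snippet",
    "SnippetSet",
    "FeatureEncoding",
    "FeatureMatrix",
    "EncodingError",
    "extract_snippets",
    "encode_snippet",
    "encode_repertoire",
    "encode_cohort",
    "feature_matrix_frame",
]

NT_ALPHABET = "ACGT"
SCHEMES = ("atchley", "aa_onehot", "nt_onehot")
UNITS = ("amino_acid", "nucleotide")


class EncodingError(ValueError):
    """A snippet contains a symbol outside the scheme's alphabet."""


@dataclass(frozen=True)
class Snippet:
    """A k-mer with a back-reference to its source CDR3 and offset."""

    text: str
    source_cdr3_index: int
    offset: int
    patient_id: str


@dataclass
class SnippetSet:
    """All overlapping k-mers of one repertoire."""

    k: int
    unit: str
    snippets: list[Snippet]
    patient_id: str
    n_skipped_cdr3s: int = 0

    def __len__(self) -> int:
        return len(self.snippets)


@dataclass(frozen=True)
class FeatureEncoding:
    """A representation scheme together with the snippet length it encodes."""

    scheme: str
    k: int

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not isinstance(self.k, int) or self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k!r}")
        if self.scheme == "nt_onehot" and self.k % 3 != 0:
            raise ValueError("nucleotide snippet length must be a multiple of 3")

    @property
    def unit(self) -> str:
        return "nucleotide" if self.scheme == "nt_onehot" else "amino_acid"

    @property
    def n_features(self) -> int:
        per_symbol = {"atchley": N_FACTORS, "aa_onehot": 20, "nt_onehot": 4}[self.scheme]
        return self.k * per_symbol

    def describe(self) -> str:
        if self.scheme == "nt_onehot":
            return f"{self.k // 3} DNA triplets, nucleotide one-hot"
        name = "Atchley factors" if self.scheme == "atchley" else "amino-acid one-hot"
        return f"{self.k} amino acids, {name}"


@dataclass
class FeatureMatrix:
    """Encoded snippets of one patient: one row per snippet.

    ``snippets`` is parallel to the rows of ``X`` so any row can be mapped
    back to (source CDR3, offset).  For the built-in (positional-
    categorical) schemes, ``codes`` holds the (n_snippets, k) symbol indices
    and ``basis`` the per-symbol feature rows with ``X == basis[codes]``
    flattened position-major; the trainer exploits this factorization.
    """

    patient_id: str
    X: np.ndarray
    snippets: list[Snippet] = field(repr=False)
    codes: np.ndarray | None = field(default=None, repr=False)
    basis: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.X.shape[0]


def extract_snippets(repertoire: Repertoire, k: int, unit: str = "amino_acid") -> SnippetSet:
    """Cut every CDR3 of a repertoire into its overlapping k-mers.

    A CDR3 of length ``L >= k`` yields snippets at offsets ``0 .. L - k``;
    shorter CDR3s yield none and increment the skip counter.
    """
    if not isinstance(k, int) or isinstance(k, bool) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if unit not in UNITS:
        raise ValueError(f"unknown unit {unit!r}")
    if unit == "nucleotide":
        if repertoire.cdr3_nt is None:
            raise ValueError(
                f"patient {repertoire.patient_id}: nucleotide snippets need cdr3_nt"
            )
        if k % 3 != 0:
            raise ValueError("nucleotide snippet length must be a multiple of 3")
        sources = repertoire.cdr3_nt
    else:
        sources = repertoire.cdr3_aa

    snippets = []
    skipped = 0
    for idx, seq in enumerate(sources):
        if len(seq) < k:
            skipped += 1
            continue
        for off in range(len(seq) - k + 1):
            snippets.append(Snippet(seq[off : off + k], idx, off, repertoire.patient_id))
    return SnippetSet(k, unit, snippets, repertoire.patient_id, skipped)


def _encode_onehot(text: str, alphabet: str, snippet: Snippet) -> np.ndarray:
    n = len(alphabet)
    vec = np.zeros(len(text) * n, dtype=np.float64)
    for pos, sym in enumerate(text):
        j = alphabet.find(sym)
        if j < 0:
            raise EncodingError(
                f"snippet {snippet.text!r} (patient {snippet.patient_id}, "
                f"cdr3 {snippet.source_cdr3_index}, position {pos}): "
                f"symbol {sym!r} not in alphabet"
            )
        vec[pos * n + j] = 1.0
    return vec


def encode_snippet(
    snippet: Snippet,
    encoding: FeatureEncoding,
    table: dict[str, tuple[float, ...]] = ATCHLEY_TABLE,
) -> np.ndarray:
    """Encode one snippet as a length-``n_features`` vector (position-major)."""
    if len(snippet.text) != encoding.k:
        raise EncodingError(
            f"snippet length {len(snippet.text)} != encoding k {encoding.k}"
        )
    if encoding.scheme == "aa_onehot":
        return _encode_onehot(snippet.text, AMINO_ACIDS, snippet)
    if encoding.scheme == "nt_onehot":
        return _encode_onehot(snippet.text, NT_ALPHABET, snippet)
    vec = np.empty(encoding.n_features, dtype=np.float64)
    for pos, aa in enumerate(snippet.text):
        try:
            vec[pos * N_FACTORS : (pos + 1) * N_FACTORS] = table[aa]
        except KeyError:
            raise EncodingError(
                f"snippet {snippet.text!r} (patient {snippet.patient_id}, "
                f"cdr3 {snippet.source_cdr3_index}, position {pos}): "
                f"residue {aa!r} not in Atchley table"
            ) from None
    return vec


def encode_repertoire(
    repertoire: Repertoire,
    encoding: FeatureEncoding,
    table: dict[str, tuple[float, ...]] = ATCHLEY_TABLE,
) -> FeatureMatrix:
    """Extract and encode all snippets of one patient.

    Raises if the patient yields zero snippets: a diagnosis cannot be
    computed for an empty snippet set.
    """
    sset = extract_snippets(repertoire, encoding.k, encoding.unit)
    if not sset.snippets:
        raise ValueError(
            f"patient {repertoire.patient_id}: no snippets at k={encoding.k} "
            f"({encoding.unit}); cannot compute a diagnosis"
        )
    if table is not ATCHLEY_TABLE and encoding.scheme == "atchley":
        # custom table: generic per-snippet path, no categorical factorization
        X = np.empty((len(sset), encoding.n_features), dtype=np.float64)
        for i, sn in enumerate(sset.snippets):
            X[i] = encode_snippet(sn, encoding, table)
        return FeatureMatrix(repertoire.patient_id, X, sset.snippets)

    alphabet = {
        "atchley": AMINO_ACIDS,
        "aa_onehot": AMINO_ACIDS,
        "nt_onehot": NT_ALPHABET,
    }[encoding.scheme]
    if encoding.scheme == "atchley":
        basis = np.array([ATCHLEY_TABLE[aa] for aa in AMINO_ACIDS], dtype=np.float64)
    else:
        basis = np.eye(len(alphabet), dtype=np.float64)
    index = {sym: i for i, sym in enumerate(alphabet)}
    codes = np.empty((len(sset), encoding.k), dtype=np.uint8)
    for i, sn in enumerate(sset.snippets):
        for pos, sym in enumerate(sn.text):
            j = index.get(sym, -1)
            if j < 0:
                raise EncodingError(
                    f"snippet {sn.text!r} (patient {sn.patient_id}, "
                    f"cdr3 {sn.source_cdr3_index}, position {pos}): "
                    f"symbol {sym!r} not in alphabet"
                )
            codes[i, pos] = j
    X = basis[codes].reshape(len(sset), encoding.n_features)
    return FeatureMatrix(repertoire.patient_id, X, sset.snippets, codes, basis)


def encode_cohort(
    cohort: Cohort,
    encoding: FeatureEncoding,
    table: dict[str, tuple[float, ...]] = ATCHLEY_TABLE,
) -> list[FeatureMatrix]:
    """Encode every repertoire of a cohort; one FeatureMatrix per patient."""
    return [encode_repertoire(rep, encoding, table) for rep in cohort.repertoires]


def feature_matrix_frame(fm: FeatureMatrix) -> pd.DataFrame:
    """Audit export: snippet provenance plus feature columns ``f1..fN``."""
    meta = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in fm.snippets],
            "cdr3_index": [s.source_cdr3_index for s in fm.snippets],
            "offset": [s.offset for s in fm.snippets],
            "snippet": [s.text for s in fm.snippets],
        }
    )
    feats = pd.DataFrame(fm.X, columns=[f"f{i + 1}" for i in range(fm.X.shape[1])])
    return pd.concat([meta, feats], axis=1)
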