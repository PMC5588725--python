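"""Synonymous-codon bookkeeping under the standard genetic code.

Built from Biopython's standard DNA codon table (61 sense codons, no stop
codons, no selenocysteine or alternative codes — human BCR loci).
"""

from __future__ import annotations

from Bio.Data import CodonTable

_FORWARD = CodonTable.standard_dna_table.forward_table

#: amino acid -> sorted list of its codons (e.g. M -> ["ATG"]).
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _FORWARD.items():
    SYNONYMOUS_CODONS.setdefault(_aa, []).append(_codon)
for _aa in SYNONYMOUS_CODONS:
    SYNONYMOUS_CODONS[_aa].sort()

#: amino acid -> codon multiplicity (Met/Trp 1 ... Leu/Ser/Arg 6).
CODON_COUNTS: dict[str, int] = {aa: len(c) for aa, c in SYNONYMOUS_CODONS.items()}

#: codon -> amino acid, for round-trip translation checks.
CODON_TO_AA: dict[str, str] = dict(_FORWARD)
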