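"""Standard genetic-code lookups used by the substitution machinery.

Built once from Biopython's table 1 (the standard code); stop codons are
represented by ``*``.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

CODONS = tuple(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES)

STOP_CODONS = frozenset(_TABLE.stop_codons)

AA_OF = {c: _TABLE.forward_table.get(c, "*") for c in CODONS}

SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for stops."""
    return AA_OF[codon]
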