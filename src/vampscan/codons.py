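"""Codon-level helpers: reverse translation and codon substitution.

Translation itself is delegated to Biopython's standard table.  Reverse
translation uses a fixed single-codon-per-residue table (the most common
human codon for each amino acid); the choice is configurable wherever a
coding sequence is built.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .variants import STOP, DesignError

# Most frequent human codon per amino acid (plus a stop codon).
PREFERRED_CODONS: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    STOP: "TGA",
}

# All codons per residue, from the standard table (stops added by hand).
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(aa, []).append(codon)
CODONS_BY_AA[STOP] = sorted(standard_dna_table.stop_codons)


def translate(cds: str) -> str:
    """Translate a coding sequence; stops render as '*'."""
    if len(cds) % 3 != 0:
        raise DesignError("coding sequence length must be divisible by 3")
    return str(Seq(cds).translate())


def reverse_translate(peptide: str, codon_table: dict[str, str] | None = None) -> str:
    """Build a coding sequence for a peptide, one fixed codon per residue."""
    table = codon_table or PREFERRED_CODONS
    try:
        return "".join(table[aa] for aa in peptide)
    except KeyError as exc:
        raise DesignError(f"no codon for residue {exc.args[0]!r}") from exc


def substitute_codon(cds: str, position: int, alt_aa: str) -> str:
    """Replace the codon at a 1-based residue position so it encodes ``alt_aa``.

    The preferred codon for ``alt_aa`` is used; if that codon equals the
    reference codon (a requested synonymous change) an alternative codon
    for the same residue is chosen instead.
    """
    if len(cds) % 3 != 0:
        raise DesignError("coding sequence length must be divisible by 3")
    n_codons = len(cds) // 3
    if not 1 <= position <= n_codons:
        raise DesignError(f"codon position {position} outside 1..{n_codons}")
    start = (position - 1) * 3
    ref_codon = cds[start : start + 3]
    new_codon = PREFERRED_CODONS[alt_aa]
    if new_codon == ref_codon:
        alternatives = [c for c in CODONS_BY_AA[alt_aa] if c != ref_codon]
        if not alternatives:
            raise DesignError(f"residue {alt_aa} has a single codon; no synonymous change")
        new_codon = alternatives[0]
    return cds[:start] + new_codon + cds[start + 3 :]
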