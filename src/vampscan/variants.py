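"""Core identifiers for protein sequences and single amino-acid variants.

A variant is written in the field's one-letter convention: ``R42P`` for a
missense change, ``Q34*`` for a nonsense (premature stop) change.  Two
special, position-free identifiers exist: ``WT`` for barcodes whose DNA
exactly matches the reference, and ``synWT`` for synonymous wild-type
(DNA differs, protein identical).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

MISSENSE = "missense"
NONSENSE = "nonsense"
WILD_TYPE = "wild-type"
SYNONYMOUS = "synonymous-wild-type"

_VARIANT_RE = re.compile(r"^([A-Y])(\d+)([A-Y*])$")


class DesignError(ValueError):
    """Raised for invalid sequences, variants, or design parameters."""


@dataclass(frozen=True, order=True)
class VariantId:
    """A single amino-acid change, or a wild-type / synonymous marker.

    ``position`` is a 1-based residue index; it is ``None`` for the
    position-free wild-type and synonymous categories.
    """

    position: int | None
    wt_aa: str | None
    alt_aa: str | None
    category: str = field(default=MISSENSE)

    def __post_init__(self) -> None:
        if self.category in (WILD_TYPE, SYNONYMOUS):
            if self.position is not None or self.alt_aa is not None:
                raise DesignError(f"{self.category} variant carries no position")
            return
        if self.position is None or self.position < 1:
            raise DesignError("variant position must be a 1-based index")
        if self.wt_aa not in AA_ALPHABET:
            raise DesignError(f"invalid wild-type residue {self.wt_aa!r}")
        if self.category == MISSENSE:
            if self.alt_aa not in AA_ALPHABET or self.alt_aa == self.wt_aa:
                raise DesignError(
                    f"missense substitution must change the residue: "
                    f"{self.wt_aa}{self.position}{self.alt_aa}"
                )
        elif self.category == NONSENSE:
            if self.alt_aa != STOP:
                raise DesignError("nonsense variant must substitute a stop")
        else:
            raise DesignError(f"unknown category {self.category!r}")

    def __str__(self) -> str:
        if self.category == WILD_TYPE:
            return "WT"
        if self.category == SYNONYMOUS:
            return "synWT"
        return f"{self.wt_aa}{self.position}{self.alt_aa}"

    @classmethod
    def wild_type(cls) -> "VariantId":
        return cls(None, None, None, WILD_TYPE)

    @classmethod
    def synonymous(cls) -> "VariantId":
        return cls(None, None, None, SYNONYMOUS)

    @classmethod
    def from_string(cls, text: str) -> "VariantId":
        """Parse ``R42P`` / ``Q34*`` / ``WT`` / ``synWT``."""
        text = text.strip()
        if text in ("WT", "wt", "wild-type"):
            return cls.wild_type()
        if text in ("synWT", "sWT", "synonymous"):
            return cls.synonymous()
        m = _VARIANT_RE.match(text)
        if not m:
            raise DesignError(f"cannot parse variant identifier {text!r}")
        wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        category = NONSENSE if alt == STOP else MISSENSE
        return cls(pos, wt, alt, category)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein in 1-letter code with 1-based residue numbering."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise DesignError("protein sequence must contain at least one residue")
        bad = set(self.residues) - set(AA_ALPHABET)
        if bad:
            raise DesignError(f"non-standard residues in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise DesignError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]
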