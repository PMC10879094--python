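"""Mutational design space, peptide tiling, and tile-oligo design.

The design space of a site-saturation scan is every single amino-acid
substitution (19 per position), optionally the nonsense variant at each
position, and a wild-type entry.  For degron mapping the protein is cut
into fixed-length peptide tiles on a half-length step; tiles are split
into Odds / Evens / CT sub-libraries so overlapping oligos never share a
pool, with shared control peptides spiked into every sub-library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .codons import reverse_translate
from .variants import (
    AA_ALPHABET,
    MISSENSE,
    NONSENSE,
    STOP,
    SYNONYMOUS,
    WILD_TYPE,
    DesignError,
    ProteinSequence,
    VariantId,
)

ODDS = "Odds"
EVENS = "Evens"
CT = "CT"
CONTROL = "control"

#: Synthetic stand-ins for the three APPY-derived control peptides: a
#: 22-residue hydrophobic degron ending in -RLLL, plus the strongly
#: (-DAAA) and mildly (-RAAA) stabilized variants of the same peptide.
#: These are constructed sequences for simulation and fitting, not the
#: published control peptides.
CONTROL_PEPTIDES: dict[str, str] = {
    "RLLL": "SWLKVVNSLFFIVPIILARLLL",
    "RAAA": "SWLKVVNSLFFIVPIILARAAA",
    "DAAA": "SWLKVVNSLFFIVPIILADAAA",
}


@dataclass(frozen=True)
class Tile:
    """A peptide tile with 1-based inclusive residue coordinates."""

    index: int
    start: int
    end: int
    peptide: str
    library: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise DesignError(
                f"tile {self.index}: span {self.start}-{self.end} does not "
                f"match peptide length {len(self.peptide)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def central_position(self) -> int:
        """Central residue; for even tile lengths, the lower-middle residue
        (residue 12 of a 24-mer starting at 1)."""
        return self.start + (self.length - 1) // 2


@dataclass(frozen=True)
class OligoDesign:
    """An ordered oligo: tile core plus two cloning adaptors."""

    tile_index: int
    name: str
    library: str
    core_nt: str
    adaptor_5: str
    adaptor_3: str

    @property
    def sequence(self) -> str:
        return self.adaptor_5 + self.core_nt + self.adaptor_3

    @property
    def core_nt_length(self) -> int:
        return len(self.core_nt)

    @property
    def adaptored_nt_length(self) -> int:
        return len(self.sequence)


@dataclass
class DesignSpace:
    """The enumerated variant collection of a site-saturation library."""

    variants: list[VariantId] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def counts_by_category(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.variants:
            counts[v.category] = counts.get(v.category, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": [str(v) for v in self.variants],
                "position": [v.position for v in self.variants],
                "wt_aa": [v.wt_aa for v in self.variants],
                "alt_aa": [v.alt_aa for v in self.variants],
                "category": [v.category for v in self.variants],
            }
        )


def enumerate_design_space(
    seq: ProteinSequence,
    include_nonsense: bool = True,
    nonsense_excluded_positions: Iterable[int] = (1,),
    include_wild_type: bool = True,
    include_synonymous: bool = False,
) -> DesignSpace:
    """Enumerate every single amino-acid variant of ``seq``.

    Missense: 19 substitutions at each of the L positions.  Nonsense: a
    stop at every position except ``nonsense_excluded_positions``
    (default: position 1, since a stop at the initiator codon yields no
    protein).  ``include_wild_type`` adds the single WT entry;
    ``include_synonymous`` adds the position-free synonymous-WT marker
    used by scoring.
    """
    length = len(seq)
    excluded = set(nonsense_excluded_positions) if include_nonsense else set()
    if not excluded <= set(range(1, length + 1)) and include_nonsense:
        raise DesignError("nonsense exclusion positions outside the sequence")

    variants: list[VariantId] = []
    for pos in range(1, length + 1):
        wt = seq.residue(pos)
        for alt in AA_ALPHABET:
            if alt != wt:
                variants.append(VariantId(pos, wt, alt, MISSENSE))
        if include_nonsense and pos not in excluded:
            variants.append(VariantId(pos, wt, STOP, NONSENSE))
    if include_wild_type:
        variants.append(VariantId.wild_type())
    if include_synonymous:
        variants.append(VariantId.synonymous())
    return DesignSpace(variants)


def tile_protein(
    seq: ProteinSequence, tile_len: int = 24, step: int = 12
) -> list[Tile]:
    """Cut ``seq`` into overlapping fixed-length tiles.

    Tiles start at 1, 1+step, 1+2*step, ...; if the regular grid does not
    end exactly at the C-terminus, one final tile is anchored to end at
    the last residue, giving it a longer overlap with its predecessor.
    Every tile has exactly ``tile_len`` residues and every residue is
    covered.
    """
    length = len(seq)
    if tile_len > length:
        raise DesignError(f"tile length {tile_len} exceeds protein length {length}")
    if not 1 <= step <= tile_len:
        raise DesignError("step must be between 1 and the tile length")

    starts = list(range(1, length - tile_len + 2, step))
    if starts[-1] + tile_len - 1 < length:
        starts.append(length - tile_len + 1)

    tiles = []
    for i, start in enumerate(starts, start=1):
        end = start + tile_len - 1
        tiles.append(Tile(i, start, end, seq.residues[start - 1 : end]))
    return tiles


def partition_tiles(tiles: Sequence[Tile]) -> list[Tile]:
    """Assign tiles to the Odds / Evens / CT sub-libraries.

    Odd tile indices go to Odds, even indices to Evens, and the final
    (C-terminal) tile to CT regardless of parity, so no sub-library
    contains two tiles that overlap each other.
    """
    if [t.index for t in tiles] != list(range(1, len(tiles) + 1)):
        raise DesignError("tiles must be indexed consecutively from 1")
    out = []
    for t in tiles:
        if t.index == len(tiles):
            lib = CT
        elif t.index % 2 == 1:
            lib = ODDS
        else:
            lib = EVENS
        out.append(Tile(t.index, t.start, t.end, t.peptide, lib))
    return out


def control_tiles(peptides: dict[str, str] | None = None) -> list[Tile]:
    """Control peptides as library='control' tiles (no protein coordinates:
    start/end span 1..len so coordinate invariants hold trivially)."""
    peptides = peptides if peptides is not None else CONTROL_PEPTIDES
    return [
        Tile(0, 1, len(pep), pep, CONTROL)
        for name, pep in peptides.items()
    ]


DEFAULT_ADAPTOR_5 = "CAGCCTCTGGGTCCAAGGGTAGCGGCAGCG"  # 30 nt
DEFAULT_ADAPTOR_3 = "TGAGGCGCGCCACTTCTAAATAAGCGAATT"  # 30 nt


def build_tile_oligos(
    tiles: Sequence[Tile],
    adaptor_5: str = DEFAULT_ADAPTOR_5,
    adaptor_3: str = DEFAULT_ADAPTOR_3,
    control_peptides: dict[str, str] | None = None,
    codon_table: dict[str, str] | None = None,
) -> list[OligoDesign]:
    """Reverse-translate tiles and controls into adaptored oligos.

    A 24-residue tile yields a 72-nt core; with two 30-nt adaptors the
    ordered oligo is 132 nt.  The 22-residue control peptides yield
    66-nt cores and 126-nt oligos.  Controls are added to every
    sub-library present among ``tiles``.
    """
    libraries = sorted({t.library for t in tiles if t.library and t.library != CONTROL})
    oligos: list[OligoDesign] = []
    for t in tiles:
        core = reverse_translate(t.peptide, codon_table)
        oligos.append(
            OligoDesign(t.index, f"tile{t.index:03d}", t.library or "", core,
                        adaptor_5, adaptor_3)
        )
    controls = control_peptides if control_peptides is not None else CONTROL_PEPTIDES
    for lib in libraries or [""]:
        for name, pep in controls.items():
            core = reverse_translate(pep, codon_table)
            oligos.append(OligoDesign(0, f"ctrl-{name}", lib, core, adaptor_5, adaptor_3))
    return oligos


def tiles_to_frame(tiles: Sequence[Tile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tile": [f"tile{t.index:03d}" for t in tiles],
            "index": [t.index for t in tiles],
            "start": [t.start for t in tiles],
            "end": [t.end for t in tiles],
            "central_position": [t.central_position for t in tiles],
            "peptide": [t.peptide for t in tiles],
            "library": [t.library for t in tiles],
        }
    )
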