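"""Barcode-variant map subassembly from long reads.

Each long read covers the whole barcode+CDS construct.  The barcode and
the coding sequence are located by exact matching of the fixed flank
sequences; reads whose CDS length differs from the reference (an indel)
or that carry ten or more nucleotide substitutions are rejected, as are
reads encoding more than one substituted residue.  Barcodes observed
with several variants are resolved by majority read support; exact ties
are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .codons import translate
from .synthetic_data import ConstructLayout
from .variants import (
    MISSENSE,
    NONSENSE,
    STOP,
    SYNONYMOUS,
    WILD_TYPE,
    VariantId,
)

REJECT_MISSING_FLANK = "missing-flank"
REJECT_AMBIGUOUS = "ambiguous-flank"
REJECT_BARCODE_LENGTH = "barcode-length"
REJECT_INDEL = "indel"
REJECT_TOO_MANY_SUBS = "too-many-substitutions"
REJECT_MULTI_RESIDUE = "multi-residue-variant"
REJECT_BAD_CHARACTER = "non-acgt"
REJECT_TIE = "conflict-tie"


@dataclass
class SubassemblyStats:
    """Bookkeeping of read and barcode fates during map construction."""

    reads_total: int = 0
    reads_mapped: int = 0
    rejections: Counter = field(default_factory=Counter)
    barcodes_unique: int = 0
    barcodes_dropped_tie: int = 0
    barcodes_conflict_resolved: int = 0

    def as_dict(self) -> dict:
        return {
            "reads_total": self.reads_total,
            "reads_mapped": self.reads_mapped,
            "rejections": dict(self.rejections),
            "barcodes_unique": self.barcodes_unique,
            "barcodes_dropped_tie": self.barcodes_dropped_tie,
            "barcodes_conflict_resolved": self.barcodes_conflict_resolved,
        }


def _find_unique(haystack: str, needle: str) -> int | None | str:
    """Offset of a unique exact occurrence; None if absent, 'ambiguous' if >1."""
    first = haystack.find(needle)
    if first < 0:
        return None
    if haystack.find(needle, first + 1) >= 0:
        return "ambiguous"
    return first


def extract_barcode_and_cds(
    sequence: str,
    layout: ConstructLayout,
    barcode_len_tolerance: int = 2,
) -> tuple[str, str] | tuple[None, str]:
    """Locate the barcode and CDS between the construct flanks.

    Returns ``(barcode, cds)`` on success, or ``(None, reason)`` when
    the read is rejected: a flank is missing or occurs more than once,
    or the barcode segment deviates from the expected length by more
    than ``barcode_len_tolerance`` (an indel in the barcode).
    """
    positions = {}
    for name, flank in (
        ("flank_5", layout.flank_5),
        ("flank_mid", layout.flank_mid),
        ("flank_3", layout.flank_3),
    ):
        hit = _find_unique(sequence, flank)
        if hit is None:
            return None, REJECT_MISSING_FLANK
        if hit == "ambiguous":
            return None, REJECT_AMBIGUOUS
        positions[name] = hit

    bc_start = positions["flank_5"] + len(layout.flank_5)
    bc_end = positions["flank_mid"]
    cds_start = positions["flank_mid"] + len(layout.flank_mid)
    cds_end = positions["flank_3"]
    if not bc_start <= bc_end or not cds_start <= cds_end:
        return None, REJECT_MISSING_FLANK
    barcode = sequence[bc_start:bc_end]
    if abs(len(barcode) - layout.barcode_len) > barcode_len_tolerance:
        return None, REJECT_BARCODE_LENGTH
    return barcode, sequence[cds_start:cds_end]


def call_variant(
    cds: str, reference_cds: str, max_subs: int = 10
) -> VariantId | str:
    """Classify an extracted CDS against the reference.

    Rejection rules: any length difference (indel), ``max_subs`` or more
    nucleotide substitutions (default: ten or more), non-ACGT
    characters, or more than one substituted residue after translation.
    Otherwise the call is wild-type (identical DNA), synonymous
    wild-type (DNA differs, protein identical), or the single
    amino-acid variant.  Returns a :class:`VariantId` or a rejection
    reason string.
    """
    if len(reference_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if set(cds) - set("ACGT"):
        return REJECT_BAD_CHARACTER
    if len(cds) != len(reference_cds):
        return REJECT_INDEL
    n_subs = sum(a != b for a, b in zip(cds, reference_cds))
    if n_subs >= max_subs:
        return REJECT_TOO_MANY_SUBS
    if n_subs == 0:
        return VariantId.wild_type()
    protein = translate(cds)
    ref_protein = translate(reference_cds)
    diffs = [
        (i + 1, w, a)
        for i, (w, a) in enumerate(zip(ref_protein, protein))
        if w != a
    ]
    if not diffs:
        return VariantId.synonymous()
    if len(diffs) > 1:
        return REJECT_MULTI_RESIDUE
    pos, wt, alt = diffs[0]
    category = NONSENSE if alt == STOP else MISSENSE
    return VariantId(pos, wt, alt, category)


def build_barcode_map(
    reads: pd.DataFrame,
    layout: ConstructLayout,
    reference_cds: str,
    max_subs: int = 10,
) -> tuple[pd.DataFrame, SubassemblyStats]:
    """Assemble the barcode→variant map from long reads.

    Per barcode, the variant with the most supporting reads wins;
    barcodes whose top variants tie are dropped.  Returns the map frame
    (``barcode, variant, position, wt_aa, alt_aa, category,
    supporting_reads``) and the rejection statistics.
    """
    stats = SubassemblyStats(reads_total=len(reads))
    support: dict[str, Counter] = {}
    variant_obj: dict[str, VariantId] = {}
    for seq in reads["sequence"]:
        barcode, payload = extract_barcode_and_cds(seq, layout)
        if barcode is None:
            stats.rejections[payload] += 1
            continue
        call = call_variant(payload, reference_cds, max_subs=max_subs)
        if isinstance(call, str):
            stats.rejections[call] += 1
            continue
        key = str(call)
        variant_obj.setdefault(key, call)
        support.setdefault(barcode, Counter())[key] += 1
        stats.reads_mapped += 1

    rows = []
    for barcode in sorted(support):
        counts = support[barcode]
        ranked = counts.most_common()
        if len(ranked) > 1:
            if ranked[0][1] == ranked[1][1]:
                stats.barcodes_dropped_tie += 1
                continue
            stats.barcodes_conflict_resolved += 1
        name, n = ranked[0]
        v = variant_obj[name]
        rows.append(
            (barcode, name, v.position, v.wt_aa, v.alt_aa, v.category, n)
        )
    barcode_map = pd.DataFrame(
        rows,
        columns=[
            "barcode",
            "variant",
            "position",
            "wt_aa",
            "alt_aa",
            "category",
            "supporting_reads",
        ],
    )
    stats.barcodes_unique = len(barcode_map)
    return barcode_map, stats
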