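"""Tile stability indices and cross-library renormalization.

Each 24-residue peptide tile fused to GFP receives a tile stability
index (TSI) — the frequency-weighted mean FACS-gate index, exactly the
barcode PSI computation with tiles in place of barcodes.  Because the
Odds / Evens / CT sub-libraries are sorted in separate runs, their TSI
scales drift by a roughly affine amount; shared control peptides
present in every pool anchor an affine rescaling of each library onto
the reference (Odds) scale.  With exactly two controls the rescaling is
the exact interpolant through the two anchor points; with more it is
the least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance_scoring import ScoringError, _gate_mean, normalize_frequencies
from .library_design import CONTROL, Tile


@dataclass(frozen=True)
class ControlAnchorFit:
    """Affine map from one library's TSI scale onto the reference scale."""

    library: str
    slope: float
    intercept: float
    control_ids: tuple[str, ...]

    def __call__(self, tsi):
        return self.intercept + self.slope * tsi


def remove_contaminants(
    counts: pd.DataFrame, tile_library: pd.Series | dict
) -> pd.DataFrame:
    """Drop reads of tiles that do not belong to the sorted library.

    Tiles observed in the pool of a different sub-library are unsorted
    carry-over and are discarded; control tiles are legitimate members
    of every pool and are always retained.  ``tile_library`` maps tile
    id to its designed library (controls map to ``'control'``).
    """
    lib_of = pd.Series(tile_library)
    if not set(counts["tile"]) <= set(lib_of.index):
        missing = sorted(set(counts["tile"]) - set(lib_of.index))
        raise ScoringError(f"tiles without a library assignment: {missing[:5]}")
    member = counts["tile"].map(lib_of)
    keep = (member == counts["run_library"]) | (member == CONTROL)
    return counts[keep].reset_index(drop=True)


def tsi_per_tile(counts: pd.DataFrame) -> pd.DataFrame:
    """TSI per tile per replicate from a (tile, gate, replicate, count) table.

    Contract identical to the barcode PSI: per-gate frequency
    normalization without pseudocounts, then the frequency-weighted
    gate mean; tiles absent from all gates are absent from the output.
    Output: ``tile, replicate, tsi``.
    """
    freqs = normalize_frequencies(counts, id_col="tile")
    return _gate_mean(freqs, "tile", "tsi")


def average_tsi(tsi: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged TSI with the SD over replicates as the error."""
    grouped = tsi.groupby("tile", as_index=False)
    return grouped.agg(tsi=("tsi", "mean"), sd=("tsi", "std"), n_replicates=("tsi", "size"))


def fit_control_renormalization(
    lib_tsi: pd.DataFrame,
    ref_tsi: pd.DataFrame,
    control_ids: Sequence[str],
    library: str = "",
) -> ControlAnchorFit:
    """Fit the affine map sending a library's control TSIs onto the reference's.

    ``lib_tsi``/``ref_tsi`` are tables with columns ``tile, tsi``
    (replicate-averaged).  Exactly two controls give the exact two-point
    interpolant; more give the least-squares line.  The fit must be
    orientation-preserving (positive slope).
    """
    lib = lib_tsi.set_index("tile")["tsi"]
    ref = ref_tsi.set_index("tile")["tsi"]
    shared = [c for c in control_ids if c in lib.index and c in ref.index]
    if len(shared) < 2:
        raise ScoringError(
            f"need at least two shared controls with defined TSI, got {shared}"
        )
    x = lib.loc[shared].to_numpy(dtype=float)
    y = ref.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ScoringError("controls have identical TSI in the library; singular fit")
    if len(shared) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
    else:
        slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ScoringError("renormalization reversed the scale (slope <= 0)")
    return ControlAnchorFit(library, float(slope), float(intercept), tuple(shared))


def apply_renormalization(tsi: pd.DataFrame, fit: ControlAnchorFit) -> pd.DataFrame:
    """Apply an affine control-anchor fit to a TSI table."""
    out = tsi.copy()
    out["tsi"] = fit(out["tsi"])
    if "sd" in out.columns:
        out["sd"] = out["sd"] * fit.slope
    return out


def renormalize_libraries(
    tsi_by_library: dict[str, pd.DataFrame],
    control_ids: Sequence[str],
    reference: str = "Odds",
) -> tuple[pd.DataFrame, dict[str, ControlAnchorFit]]:
    """Renormalize every library onto the reference library's scale.

    The reference library gets the identity fit.  Returns the combined
    renormalized table (with a ``library`` column) and the per-library
    fits.
    """
    if reference not in tsi_by_library:
        raise ScoringError(f"reference library {reference!r} missing")
    ref = tsi_by_library[reference]
    fits: dict[str, ControlAnchorFit] = {}
    frames = []
    for lib, table in tsi_by_library.items():
        if lib == reference:
            fit = ControlAnchorFit(lib, 1.0, 0.0, tuple(control_ids))
        else:
            fit = fit_control_renormalization(table, ref, control_ids, library=lib)
        fits[lib] = fit
        frames.append(apply_renormalization(table, fit).assign(library=lib))
    return pd.concat(frames, ignore_index=True), fits


def assign_tsi_to_positions(
    tsi: pd.DataFrame, tiles: Sequence[Tile]
) -> pd.DataFrame:
    """Place each tile's averaged TSI at its central residue.

    For even tile lengths the center is the lower-middle residue
    (residue 12 of a 24-mer starting at residue 1).  Control tiles have
    no protein coordinates and are skipped.  Output: ``position, tile,
    tsi`` sorted by position; positions covered by no tile center are
    simply absent.
    """
    centers = {
        f"tile{t.index:03d}": t.central_position
        for t in tiles
        if t.library != CONTROL
    }
    df = tsi[tsi["tile"].isin(centers)].copy()
    df["position"] = df["tile"].map(centers)
    return (
        df[["position", "tile", "tsi"]]
        .sort_values("position")
        .reset_index(drop=True)
    )
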