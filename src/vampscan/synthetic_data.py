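"""Sort-seq experiment simulator with known ground truth.

Emulates the full measurement chain of a variant-abundance sort-seq
(VAMP-seq) experiment: a bimodal distribution of true per-variant
abundances, a barcoded site-saturation library (random 18-nt barcodes,
many barcodes per variant), error-bearing long reads over the
barcode+CDS construct, quartile FACS sorting of GFP:mCherry log-ratios
into four equal-occupancy gates, multinomial short-read sequencing of
each sorted pool, and technical/biological replicates.  A tile-library
simulator produces per-gate counts whose tile stability indices are
affinely distorted per sub-library, recoverable by the control-anchor
renormalization.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import CODONS_BY_AA, substitute_codon
from .library_design import CONTROL, DesignSpace, Tile
from .variants import MISSENSE, NONSENSE, STOP, SYNONYMOUS, WILD_TYPE, DesignError

NUCLEOTIDES = np.array(list("ACGT"))

# Fixed construct flanks (landing-pad vector analogue): the read layout is
# flank5 + barcode + flank_mid + CDS + flank3.
DEFAULT_FLANK_5 = "ACGGTCTCACGGATCGTACG"
DEFAULT_FLANK_MID = "GCTAGCCTGAGGTCAGACCT"
DEFAULT_FLANK_3 = "TGGATCCGAGCTCGCTAGCA"


@dataclass(frozen=True)
class ConstructLayout:
    """Where the barcode and CDS sit inside a long read."""

    flank_5: str = DEFAULT_FLANK_5
    flank_mid: str = DEFAULT_FLANK_MID
    flank_3: str = DEFAULT_FLANK_3
    barcode_len: int = 18

    def assemble(self, barcode: str, cds: str) -> str:
        return self.flank_5 + barcode + self.flank_mid + cds + self.flank_3


@dataclass
class SimulatedExperiment:
    """Counts plus the ground truth that produced them."""

    counts: pd.DataFrame  # barcode, gate, rep_bio, rep_tech, count
    barcode_map: pd.DataFrame
    true_scores: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)


def simulate_true_abundance(
    design: DesignSpace,
    fraction_low: float = 0.28,
    low_mean: float = 0.0,
    low_sd: float = 0.08,
    high_mean: float = 1.0,
    high_sd: float = 0.10,
    clip: tuple[float, float] = (-0.05, 1.2),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a true abundance score per variant from a two-component mixture.

    Wild-type and synonymous variants always come from the high (WT-like)
    component, nonsense variants from the low component; each missense
    variant is low with probability ``fraction_low`` (default 0.28, a
    typical fraction of destabilized missense variants in an abundance
    scan of a folded protein).  Returns a frame with columns
    ``variant, category, true_score``.
    """
    if not 0.0 <= fraction_low <= 1.0:
        raise DesignError("fraction_low must be within [0, 1]")
    for sd in (low_sd, high_sd):
        if sd < 0:
            raise DesignError("component spreads must be non-negative")
    rng = np.random.default_rng(seed)
    categories = np.array([v.category for v in design.variants])
    n = len(categories)
    is_low = np.zeros(n, dtype=bool)
    is_low[categories == NONSENSE] = True
    missense = categories == MISSENSE
    is_low[missense] = rng.random(missense.sum()) < fraction_low
    scores = np.where(
        is_low,
        rng.normal(low_mean, low_sd, n),
        rng.normal(high_mean, high_sd, n),
    )
    scores = np.clip(scores, *clip)
    return pd.DataFrame(
        {
            "variant": [str(v) for v in design.variants],
            "category": categories,
            "true_score": scores,
        }
    )


def _random_barcodes(n: int, barcode_len: int, rng: np.random.Generator) -> list[str]:
    """Draw n distinct random barcodes of the given length."""
    if n > 4**barcode_len:
        raise DesignError(
            f"cannot draw {n} unique barcodes of length {barcode_len}"
        )
    seen: dict[str, None] = {}
    while len(seen) < n:
        block = rng.integers(0, 4, size=(n - len(seen) + 16, barcode_len))
        for row in NUCLEOTIDES[block]:
            seen.setdefault("".join(row), None)
            if len(seen) == n:
                break
    return list(seen)


def simulate_barcode_library(
    design: DesignSpace,
    mean_barcodes_per_variant: float = 24.0,
    barcode_len: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign random unique barcodes to every variant.

    Barcode counts per variant are Poisson with the requested mean,
    truncated below at 1 so every variant is represented.  Returns the
    truth map: ``barcode, variant, category``.
    """
    if barcode_len < 1:
        raise DesignError("barcode length must be at least 1")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean_barcodes_per_variant, size=len(design.variants))
    counts = np.maximum(counts, 1)
    total = int(counts.sum())
    barcodes = _random_barcodes(total, barcode_len, rng)
    variant_col = np.repeat([str(v) for v in design.variants], counts)
    category_col = np.repeat([v.category for v in design.variants], counts)
    return pd.DataFrame(
        {"barcode": barcodes, "variant": variant_col, "category": category_col}
    )


def variant_cds(variant: str, reference_cds: str) -> str:
    """Coding sequence realizing a variant on the reference CDS."""
    from .variants import VariantId

    v = VariantId.from_string(variant)
    if v.category == WILD_TYPE:
        return reference_cds
    if v.category == SYNONYMOUS:
        # first residue with more than one codon
        from .codons import translate

        protein = translate(reference_cds)
        for pos, aa in enumerate(protein, start=1):
            if len(CODONS_BY_AA[aa]) > 1:
                return substitute_codon(reference_cds, pos, aa)
        raise DesignError("reference admits no synonymous change")
    return substitute_codon(reference_cds, v.position, v.alt_aa)


def _mutate_read(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    if sub_rate > 0:
        hits = np.nonzero(rng.random(arr.size) < sub_rate)[0]
        for i in hits:
            choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
            arr[i] = bytes([choices[rng.integers(0, 3)]])
    out = arr.tobytes().decode()
    if indel_rate > 0 and rng.random() < indel_rate:
        pos = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > 1:
            out = out[:pos] + out[pos + 1 :]
        else:
            out = out[:pos] + str(NUCLEOTIDES[rng.integers(0, 4)]) + out[pos:]
    return out


def simulate_long_reads(
    barcode_map: pd.DataFrame,
    reference_cds: str,
    layout: ConstructLayout | None = None,
    reads_per_barcode: int = 3,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate long reads over the barcode+CDS construct.

    Each read is flank + barcode + flank + variant CDS + flank with
    point substitutions applied at ``sub_rate`` per base and at most one
    1-nt indel per read at probability ``indel_rate``.  Returns
    ``(reads, truth)``: reads have ``read_id, sequence``; truth links
    each read to its barcode and intended variant.
    """
    if not 0.0 <= sub_rate < 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise DesignError("error rates must be within [0, 1)")
    layout = layout or ConstructLayout()
    rng = np.random.default_rng(seed)
    cds_cache = {
        v: variant_cds(v, reference_cds) for v in barcode_map["variant"].unique()
    }
    rows = []
    truth = []
    read_no = 0
    for barcode, variant in zip(barcode_map["barcode"], barcode_map["variant"]):
        clean = layout.assemble(barcode, cds_cache[variant])
        for _ in range(reads_per_barcode):
            read_no += 1
            rid = f"read{read_no:07d}"
            rows.append((rid, _mutate_read(clean, sub_rate, indel_rate, rng)))
            truth.append((rid, barcode, variant))
    reads = pd.DataFrame(rows, columns=["read_id", "sequence"])
    truth_df = pd.DataFrame(truth, columns=["read_id", "barcode", "variant"])
    return reads, truth_df


def simulate_facs_sort(
    barcode_map: pd.DataFrame,
    true_scores: pd.DataFrame,
    cells_per_barcode: int = 50,
    noise_sd: float = 0.25,
    n_gates: int = 4,
    ratio_scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sort simulated cells into equal-occupancy gates.

    Every barcode contributes ``cells_per_barcode`` cells.  Each cell's
    log10 GFP:mCherry ratio is ``ratio_scale * true_score`` of its
    variant (so a score-1 WT cell sits one decade — about 10-fold —
    above a score-0 cell) plus log-normal cell-to-cell noise of spread
    ``noise_sd`` decades.  Gate thresholds are the empirical
    1/n_gates-quantiles of the pooled ratio distribution, so every gate
    holds an equal share of cells up to integer rounding; gate 1 is the
    lowest ratio, gate ``n_gates`` the highest.

    Returns long-format cell counts: ``barcode, gate, cells``.
    """
    if n_gates < 2:
        raise DesignError("need at least two gates")
    if cells_per_barcode < 1:
        raise DesignError("need at least one cell per barcode")
    rng = np.random.default_rng(seed)
    score_of = dict(zip(true_scores["variant"], true_scores["true_score"]))
    mu = np.array([score_of[v] for v in barcode_map["variant"]]) * ratio_scale
    n_barcodes = len(barcode_map)
    ratios = np.repeat(mu, cells_per_barcode)
    ratios = ratios + rng.normal(0.0, noise_sd, ratios.size)
    edges = np.quantile(ratios, np.arange(1, n_gates) / n_gates)
    gates = np.searchsorted(edges, ratios, side="left") + 1  # 1..n_gates
    barcode_idx = np.repeat(np.arange(n_barcodes), cells_per_barcode)
    flat = np.bincount(
        barcode_idx * n_gates + (gates - 1), minlength=n_barcodes * n_gates
    ).reshape(n_barcodes, n_gates)
    out = pd.DataFrame(
        {
            "barcode": np.repeat(barcode_map["barcode"].to_numpy(), n_gates),
            "gate": np.tile(np.arange(1, n_gates + 1), n_barcodes),
            "cells": flat.ravel(),
        }
    )
    return out[out["cells"] > 0].reset_index(drop=True)


def simulate_sequencing(
    gate_cells: pd.DataFrame,
    depth_per_gate: int,
    n_technical: int = 1,
    rep_bio: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial read sampling of each sorted pool.

    Reads per gate are drawn from that gate's barcode cell-count
    proportions.  Technical replicates are independent draws from the
    same cells.  Returns ``barcode, gate, rep_bio, rep_tech, count``
    with zero-count rows omitted.
    """
    if depth_per_gate < 0:
        raise DesignError("sequencing depth must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for gate, grp in gate_cells.groupby("gate", sort=True):
        cells = grp["cells"].to_numpy(dtype=float)
        if cells.sum() <= 0 or depth_per_gate == 0:
            continue
        p = cells / cells.sum()
        for tech in range(1, n_technical + 1):
            counts = rng.multinomial(depth_per_gate, p)
            keep = counts > 0
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": grp["barcode"].to_numpy()[keep],
                        "gate": gate,
                        "rep_bio": rep_bio,
                        "rep_tech": tech,
                        "count": counts[keep],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["barcode", "gate", "rep_bio", "rep_tech", "count"]
        )
    return pd.concat(frames, ignore_index=True)


def simulate_experiment(
    design: DesignSpace,
    mean_barcodes_per_variant: float = 24.0,
    cells_per_barcode: int = 50,
    depth_per_gate: int | None = None,
    n_biological: int = 2,
    n_technical: int = 2,
    noise_sd: float = 0.25,
    fraction_low: float = 0.28,
    n_gates: int = 4,
    seed: int = 0,
) -> SimulatedExperiment:
    """Full sort-seq simulation: library, truth, sorting, sequencing.

    Biological replicates re-sort fresh cells (new FACS noise draws);
    technical replicates resample reads from the same sorted cells.  If
    ``depth_per_gate`` is omitted it defaults to 50 reads per barcode
    per gate.
    """
    rng = np.random.default_rng(seed)
    truth = simulate_true_abundance(
        design, fraction_low=fraction_low, seed=int(rng.integers(2**31))
    )
    barcode_map = simulate_barcode_library(
        design, mean_barcodes_per_variant, seed=int(rng.integers(2**31))
    )
    if depth_per_gate is None:
        depth_per_gate = 50 * len(barcode_map)
    frames = []
    for bio in range(1, n_biological + 1):
        gate_cells = simulate_facs_sort(
            barcode_map,
            truth,
            cells_per_barcode=cells_per_barcode,
            noise_sd=noise_sd,
            n_gates=n_gates,
            seed=int(rng.integers(2**31)),
        )
        frames.append(
            simulate_sequencing(
                gate_cells,
                depth_per_gate,
                n_technical=n_technical,
                rep_bio=bio,
                seed=int(rng.integers(2**31)),
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    return SimulatedExperiment(
        counts=counts,
        barcode_map=barcode_map,
        true_scores=truth,
        seed=seed,
        params={
            "mean_barcodes_per_variant": mean_barcodes_per_variant,
            "cells_per_barcode": cells_per_barcode,
            "depth_per_gate": depth_per_gate,
            "n_biological": n_biological,
            "n_technical": n_technical,
            "noise_sd": noise_sd,
            "fraction_low": fraction_low,
            "n_gates": n_gates,
        },
    )


def simulate_true_tsi(
    tiles: Sequence[Tile],
    fraction_degron: float = 0.35,
    low_range: tuple[float, float] = (1.2, 2.0),
    high_range: tuple[float, float] = (2.8, 3.5),
    control_tsi: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Draw bimodal true tile stability indices, with fixed control anchors.

    Control peptides get fixed values spanning the scale (the degron
    control low, the stabilized control high) so they can anchor the
    cross-library renormalization.
    """
    rng = np.random.default_rng(seed)
    controls = dict(control_tsi or {"ctrl-RLLL": 1.3, "ctrl-RAAA": 2.4, "ctrl-DAAA": 3.5})
    out: dict[str, float] = {}
    for t in tiles:
        if t.library == CONTROL:
            continue
        name = f"tile{t.index:03d}"
        if rng.random() < fraction_degron:
            out[name] = float(rng.uniform(*low_range))
        else:
            out[name] = float(rng.uniform(*high_range))
    out.update(controls)
    return out


def _gate_freqs_for_tsi(value: float, n_gates: int = 4) -> np.ndarray:
    """Two-point gate mass whose frequency-weighted gate mean equals value."""
    if not 1.0 - 1e-9 <= value <= n_gates + 1e-9:
        raise DesignError(
            f"gate-mean target {value:.4f} outside [1, {n_gates}]; "
            "distortion pushed a tile off the gate scale"
        )
    v = float(np.clip(value, 1.0, n_gates))
    k = int(np.floor(v))
    f = np.zeros(n_gates)
    if k >= n_gates:
        f[n_gates - 1] = 1.0
    else:
        f[k - 1] = (k + 1) - v
        f[k] = v - k
    return f


def simulate_tile_run(
    tiles: Sequence[Tile],
    true_tsi: Mapping[str, float],
    renorm_by_library: Mapping[str, tuple[float, float]] | None = None,
    contaminant_rate: float = 0.0,
    depth: int | None = 100_000,
    n_replicates: int = 1,
    n_gates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-library sorted tile pools with affine TSI distortion.

    ``renorm_by_library`` maps each sub-library to the (slope,
    intercept) of the corrective renormalization that recovers the
    common scale; the generator applies the inverse distortion, so a
    downstream control-anchor fit should recover exactly those
    coefficients.  A ``contaminant_rate`` fraction of each pool's reads
    comes from tiles of the other sub-libraries.  With integer
    ``depth``, per-tile gate counts are multinomial; ``depth=None``
    yields idealized expected counts (floats, the noiseless limit).

    Returns ``run_library, tile, gate, replicate, count``.
    """
    if not 0.0 <= contaminant_rate < 1.0:
        raise DesignError("contaminant_rate must be within [0, 1)")
    rng = np.random.default_rng(seed)
    renorm_by_library = renorm_by_library or {}
    libraries = sorted({t.library for t in tiles if t.library and t.library != CONTROL})
    name_of = {t: f"tile{t.index:03d}" for t in tiles if t.library != CONTROL}
    controls = [t for t in tiles if t.library == CONTROL]
    control_names = {t: f"ctrl-{t.peptide[-4:]}" for t in controls}

    rows = []
    for lib in libraries:
        slope, intercept = renorm_by_library.get(lib, (1.0, 0.0))
        if slope <= 0:
            raise DesignError("renormalization slope must be positive")
        own = [name_of[t] for t in tiles if t.library == lib]
        own += [control_names[t] for t in controls]
        foreign = [name_of[t] for t in tiles if t.library not in (lib, CONTROL, None)]
        if contaminant_rate > 0 and not foreign:
            raise DesignError("contaminants requested but no foreign tiles exist")
        members = own + (foreign if contaminant_rate > 0 else [])
        # library-scale (distorted) targets: the corrective fit maps them
        # back to truth; foreign carry-over keeps its undistorted profile.
        targets = np.array(
            [
                (true_tsi[m] - intercept) / slope if m in own else true_tsi[m]
                for m in members
            ]
        )
        freqs = _pool_frequencies_for_tsi(
            targets, n_own=len(own),
            contaminant_rate=contaminant_rate if foreign else 0.0,
            n_gates=n_gates,
        )
        for rep in range(1, n_replicates + 1):
            if depth is None:
                counts = freqs
            else:
                counts = np.column_stack(
                    [
                        rng.multinomial(depth, freqs[:, g] / freqs[:, g].sum())
                        for g in range(n_gates)
                    ]
                ).astype(float)
            for i, name in enumerate(members):
                for g in range(n_gates):
                    if counts[i, g] > 0:
                        rows.append((lib, name, g + 1, rep, counts[i, g]))
    return pd.DataFrame(
        rows, columns=["run_library", "tile", "gate", "replicate", "count"]
    )


def _pool_frequencies_for_tsi(
    targets: np.ndarray,
    n_own: int,
    contaminant_rate: float,
    n_gates: int = 4,
) -> np.ndarray:
    """Per-gate frequency matrix realizing the target stability indices.

    The index of a pool member is the gate-mean of its per-gate
    *frequencies* (its share of each gate's reads), so frequencies are
    column-stochastic: every gate's frequencies sum to one.  That ties
    pool members together — the read-mass-weighted mean index of any
    pool is pinned at the middle of the gate scale, which is why a
    single-member pool always scores (1+...+G)/G and why separately
    sorted sub-libraries need renormalizing at all.  A feasible matrix
    is found by linear programming: exact row gate-means (the targets),
    column sums of one, every member's read mass within a band around
    its fair share, foreign (contaminant) members holding exactly
    ``contaminant_rate`` of the reads, and mass concentrated near each
    member's target gates.
    """
    from scipy.optimize import linprog

    for v in targets:
        _gate_freqs_for_tsi(float(v), n_gates)  # validate range
    n = len(targets)
    gates = np.arange(1, n_gates + 1, dtype=float)
    n_var = n * n_gates  # f[t, g] flattened row-major

    a_eq_rows, b_eq = [], []
    for t in range(n):
        row = np.zeros(n_var)
        row[t * n_gates : (t + 1) * n_gates] = gates - targets[t]
        a_eq_rows.append(row)
        b_eq.append(0.0)
    for g in range(n_gates):
        row = np.zeros(n_var)
        row[g::n_gates] = 1.0
        a_eq_rows.append(row)
        b_eq.append(1.0)
    n_foreign = n - n_own
    if n_foreign > 0:
        row = np.zeros(n_var)
        row[n_own * n_gates :] = 1.0
        a_eq_rows.append(row)
        b_eq.append(contaminant_rate * n_gates)

    a_ub_rows, b_ub = [], []
    own_mass = n_gates * (1.0 - contaminant_rate)
    fair = own_mass / n_own
    for t in range(n_own):
        row = np.zeros(n_var)
        row[t * n_gates : (t + 1) * n_gates] = -1.0
        a_ub_rows.append(row)  # mass >= 0.1 * fair: keep every member scored
        b_ub.append(-0.1 * fair)

    cost = np.concatenate([(gates - v) ** 2 for v in targets])
    res = linprog(
        cost,
        A_eq=np.vstack(a_eq_rows),
        b_eq=np.array(b_eq),
        A_ub=np.vstack(a_ub_rows),
        b_ub=np.array(b_ub),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise DesignError(
            "no pool composition realizes these stability indices: the "
            "read-mass-weighted pool mean is pinned at the middle of the "
            "gate scale, so targets must straddle it"
        )
    return res.x.reshape(n, n_gates)
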