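"""Per-gate counts to normalized abundance scores.

The protein stability index (PSI) of a barcode is the frequency-weighted
mean of the FACS gate indices it was sequenced in,

    PSI_b = sum_g g * f_{b,g} / sum_g f_{b,g},

where f_{b,g} is the barcode's read frequency in gate g (per-gate
normalization, no pseudocounts).  Barcode PSIs are averaged per variant
and per replicate, replicate PSIs are averaged, and the result is
rescaled so the wild type scores 1 and the median nonsense variant
scores 0:

    abundance = (PSI_i - PSI_stop) / (PSI_WT - PSI_stop).

With four quartile gates, PSI runs from 1 (all reads in the lowest
gate) to 4 (all in the highest), and a variant spread evenly across the
gates sits at 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import NONSENSE, SYNONYMOUS, WILD_TYPE


class ScoringError(ValueError):
    """Raised for structurally invalid count tables or degenerate anchors."""


def merge_technical_replicates(
    counts: pd.DataFrame, id_col: str = "barcode"
) -> pd.DataFrame:
    """Sum technical-replicate counts per (element, gate, biological rep).

    Merging happens on raw counts, before frequency normalization.  The
    result uses a single ``replicate`` column (the biological
    replicate).  All technical replicates must cover the same gate set.
    """
    required = {id_col, "gate", "count"}
    if not required <= set(counts.columns):
        raise ScoringError(f"count table must have columns {sorted(required)}")
    df = counts.copy()
    if "rep_bio" not in df.columns:
        df["rep_bio"] = 1
    if "rep_tech" in df.columns:
        gate_sets = df.groupby(["rep_bio", "rep_tech"])["gate"].agg(frozenset)
        if gate_sets.groupby("rep_bio").nunique().gt(1).any():
            raise ScoringError("technical replicates cover different gate sets")
    merged = (
        df.groupby([id_col, "gate", "rep_bio"], as_index=False)["count"]
        .sum()
        .rename(columns={"rep_bio": "replicate"})
    )
    return merged


def normalize_frequencies(
    counts: pd.DataFrame, id_col: str = "barcode"
) -> pd.DataFrame:
    """Turn per-gate counts into per-gate frequencies, no pseudocounts.

    Within every (replicate, gate) the counts are divided by the gate
    total, so each gate's frequencies sum to one; zero counts stay
    exactly zero.  Gates with a zero total are dropped (they carry no
    information for the gate-mean).
    """
    df = counts.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if (df["count"] < 0).any():
        raise ScoringError("counts must be non-negative")
    totals = df.groupby(["replicate", "gate"])["count"].transform("sum")
    df = df[totals > 0].copy()
    totals = totals[totals > 0]
    df["freq"] = df["count"] / totals
    return df


def _gate_mean(freqs: pd.DataFrame, id_col: str, value_col: str) -> pd.DataFrame:
    """Frequency-weighted mean gate index per (element, replicate)."""
    df = freqs[freqs["freq"] > 0]
    weighted = df["freq"] * df["gate"]
    grouped = df.assign(_w=weighted).groupby([id_col, "replicate"])
    psi = grouped["_w"].sum() / grouped["freq"].sum()
    return psi.rename(value_col).reset_index()


def psi_per_barcode(freqs: pd.DataFrame) -> pd.DataFrame:
    """PSI per barcode per replicate.

    Barcodes absent from every gate of a replicate are simply absent
    from the output (never zero-filled).  PSI is bounded by the lowest
    and highest gate index.
    """
    return _gate_mean(freqs, "barcode", "psi")


def psi_per_variant(
    psi: pd.DataFrame, barcode_map: pd.DataFrame
) -> pd.DataFrame:
    """Unweighted mean of barcode PSIs per variant per replicate.

    Barcodes missing from the map are dropped.  Output columns:
    ``variant, category, replicate, psi, n_barcodes``.
    """
    mapping = barcode_map[["barcode", "variant", "category"]]
    joined = psi.merge(mapping, on="barcode", how="inner")
    grouped = joined.groupby(["variant", "category", "replicate"], as_index=False)
    out = grouped.agg(psi=("psi", "mean"), n_barcodes=("psi", "size"))
    return out


@dataclass
class AbundanceScores:
    """Per-variant abundance scores with replicate detail and anchors."""

    scores: pd.DataFrame  # variant, category, score, sd, n_barcodes, n_replicates
    per_replicate: pd.DataFrame  # variant, replicate, psi, score
    psi_wt: float
    psi_stop: float


def _anchors(
    variant_psi: pd.DataFrame,
    pool_synonymous_wt: bool,
    stop_median_per_position: bool,
    position_of: pd.Series | None = None,
) -> tuple[float, float]:
    wt_cats = [WILD_TYPE] + ([SYNONYMOUS] if pool_synonymous_wt else [])
    wt = variant_psi.loc[variant_psi["category"].isin(wt_cats), "psi"]
    if wt.empty:
        raise ScoringError("no wild-type barcodes scored; cannot anchor")
    stops = variant_psi[variant_psi["category"] == NONSENSE]
    if stops.empty:
        raise ScoringError("no nonsense variants scored; cannot anchor")
    if stop_median_per_position and position_of is not None:
        per_pos = stops.assign(position=stops["variant"].map(position_of))
        psi_stop = float(per_pos.groupby("position")["psi"].median().median())
    else:
        psi_stop = float(stops["psi"].median())
    return float(wt.mean()), psi_stop


def abundance_scores(
    variant_psi: pd.DataFrame,
    pool_synonymous_wt: bool = False,
    stop_median_per_position: bool = False,
) -> AbundanceScores:
    """Average replicate PSIs and normalize to the WT/stop anchors.

    The headline score is computed from replicate-averaged PSIs with
    anchors from the same averaged table, so the wild type scores
    exactly 1 and the median nonsense variant exactly 0.  Per-replicate
    scores (anchored within each replicate) are emitted for QC, and the
    reported standard deviation is taken over those per-replicate
    scores.
    """
    pos_of = None
    if stop_median_per_position:
        pos_of = (
            variant_psi.assign(
                position=variant_psi["variant"].str.extract(r"(\d+)")[0].astype(float)
            )
            .drop_duplicates("variant")
            .set_index("variant")["position"]
        )

    averaged = variant_psi.groupby(["variant", "category"], as_index=False).agg(
        psi=("psi", "mean"),
        n_barcodes=("n_barcodes", "max"),
        n_replicates=("replicate", "nunique"),
    )
    psi_wt, psi_stop = _anchors(
        averaged, pool_synonymous_wt, stop_median_per_position, pos_of
    )
    if psi_wt == psi_stop:
        raise ScoringError("degenerate normalization: PSI_WT equals PSI_stop")
    averaged["score"] = (averaged["psi"] - psi_stop) / (psi_wt - psi_stop)

    rep_frames = []
    for rep, grp in variant_psi.groupby("replicate"):
        try:
            w, s = _anchors(grp, pool_synonymous_wt, stop_median_per_position, pos_of)
        except ScoringError:
            continue
        if w == s:
            continue
        g = grp.copy()
        g["score"] = (g["psi"] - s) / (w - s)
        rep_frames.append(g)
    per_replicate = (
        pd.concat(rep_frames, ignore_index=True)
        if rep_frames
        else variant_psi.iloc[0:0].assign(score=np.nan)
    )
    sd = (
        per_replicate.groupby("variant")["score"]
        .std(ddof=1)
        .rename("sd")
        .reset_index()
    )
    scores = averaged.merge(sd, on="variant", how="left")
    scores = scores[
        ["variant", "category", "psi", "score", "sd", "n_barcodes", "n_replicates"]
    ]
    return AbundanceScores(
        scores=scores, per_replicate=per_replicate, psi_wt=psi_wt, psi_stop=psi_stop
    )


def replicate_qc(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-replicate scores.

    Correlations run over the variants scored in both replicates of a
    pair; pairs sharing fewer than two variants are reported with a NaN
    correlation.  Output: ``rep_a, rep_b, pearson_r, n_shared``.
    """
    wide = per_replicate.pivot_table(
        index="variant", columns="replicate", values="score"
    )
    reps = list(wide.columns)
    if len(reps) < 2:
        raise ScoringError("replicate QC needs at least two replicates")
    rows = []
    for i, a in enumerate(reps):
        for b in reps[i + 1 :]:
            pair = wide[[a, b]].dropna()
            r = (
                float(np.corrcoef(pair[a], pair[b])[0, 1])
                if len(pair) >= 2
                else float("nan")
            )
            rows.append((a, b, r, len(pair)))
    return pd.DataFrame(rows, columns=["rep_a", "rep_b", "pearson_r", "n_shared"])


def flatten_replicates(counts: pd.DataFrame, id_col: str = "barcode") -> pd.DataFrame:
    """Keep technical replicates separate, as ``bio.tech`` replicate labels.

    Used for QC of raw technical reproducibility; the standard scoring
    path merges technical replicates instead.
    """
    df = counts.copy()
    if "rep_bio" not in df.columns:
        df["rep_bio"] = 1
    if "rep_tech" not in df.columns:
        df["rep_tech"] = 1
    df["replicate"] = (
        df["rep_bio"].astype(str) + "." + df["rep_tech"].astype(str)
    )
    return df[[id_col, "gate", "replicate", "count"]]


def score_counts(
    counts: pd.DataFrame,
    barcode_map: pd.DataFrame,
    pool_synonymous_wt: bool = False,
    min_reads_per_barcode: int = 0,
    merge_technical: bool = True,
) -> AbundanceScores:
    """Convenience pipeline: raw counts + barcode map → abundance scores."""
    if merge_technical:
        merged = merge_technical_replicates(counts)
    else:
        merged = flatten_replicates(counts)
    if min_reads_per_barcode > 0:
        totals = merged.groupby(["barcode", "replicate"])["count"].transform("sum")
        merged = merged[totals >= min_reads_per_barcode]
    freqs = normalize_frequencies(merged)
    psi_b = psi_per_barcode(freqs)
    psi_v = psi_per_variant(psi_b, barcode_map)
    return abundance_scores(psi_v, pool_synonymous_wt=pool_synonymous_wt)
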