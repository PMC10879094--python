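"""Variant-effect-map assembly and downstream analyses.

Builds the positions × substitutions abundance matrix, summarizes
positions by their median missense score, flags low-abundance variants,
evaluates how well low abundance predicts clinical pathogenicity
(ROC/AUC), correlates abundance with external per-variant scores
(ΔΔG, conservation), and assigns coarse per-position classes from
configurable stability/conservation thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .variants import AA_ALPHABET, MISSENSE, STOP, DesignError, ProteinSequence

SUBSTITUTIONS = list(AA_ALPHABET) + [STOP]


@dataclass
class VariantEffectMap:
    """Positions × substitutions score matrix.

    ``scores`` has substitutions (20 residues + stop) as rows and
    1-based positions as columns; the wild-type cell of each position
    is masked (NaN in ``scores``, True in ``wt_mask``) and never
    scored.  ``coverage`` is the scored fraction of non-WT cells.
    """

    scores: pd.DataFrame
    wt_mask: pd.DataFrame
    sequence: ProteinSequence
    n_scored: int = 0
    n_possible: int = 0

    @property
    def coverage(self) -> float:
        return self.n_scored / self.n_possible if self.n_possible else 0.0


def build_effect_map(
    scores: pd.DataFrame,
    seq: ProteinSequence,
    n_possible: int | None = None,
) -> VariantEffectMap:
    """Arrange per-variant scores into the effect-map matrix.

    ``scores`` needs ``variant`` (one-letter form, e.g. R42P or Q34*)
    and ``score`` columns; the position-free WT/synonymous entries are
    ignored here.  A variant whose stated wild-type residue disagrees
    with the sequence, or a duplicated cell, is an error.  By default
    ``n_possible`` counts 19 missense + 1 stop per position.
    """
    length = len(seq)
    mat = pd.DataFrame(
        np.nan, index=SUBSTITUTIONS, columns=range(1, length + 1)
    )
    wt_mask = pd.DataFrame(False, index=SUBSTITUTIONS, columns=mat.columns)
    for pos in range(1, length + 1):
        wt_mask.loc[seq.residue(pos), pos] = True

    n_scored = 0
    from .variants import VariantId

    for name, value in zip(scores["variant"], scores["score"]):
        v = VariantId.from_string(str(name))
        if v.position is None:
            continue
        if v.position > length:
            raise DesignError(f"variant {name} beyond sequence length {length}")
        if v.wt_aa != seq.residue(v.position):
            raise DesignError(
                f"variant {name}: wild-type residue disagrees with sequence "
                f"({seq.residue(v.position)} at position {v.position})"
            )
        if not np.isnan(mat.loc[v.alt_aa, v.position]):
            raise DesignError(f"duplicate score for cell {name}")
        mat.loc[v.alt_aa, v.position] = value
        n_scored += 1
    if n_possible is None:
        n_possible = length * 20
    return VariantEffectMap(mat, wt_mask, seq, n_scored, n_possible)


def effect_map_to_scores(emap: VariantEffectMap) -> pd.DataFrame:
    """Flatten the effect map back to a per-variant score table."""
    rows = []
    for pos in emap.scores.columns:
        wt = emap.sequence.residue(pos)
        for alt in SUBSTITUTIONS:
            value = emap.scores.loc[alt, pos]
            if not np.isnan(value):
                rows.append((f"{wt}{pos}{alt}", value))
    return pd.DataFrame(rows, columns=["variant", "score"])


def position_medians(emap: VariantEffectMap, min_n: int = 17) -> pd.DataFrame:
    """Median missense score per position, gated on measurement depth.

    Stop substitutions are excluded from the median.  Positions with
    fewer than ``min_n`` scored missense variants (default 17) get an
    undefined (NaN) median; the count is always reported.  Output:
    ``position, median_score, n_scored``.
    """
    missense = emap.scores.loc[list(AA_ALPHABET)]
    n = missense.notna().sum(axis=0)
    med = missense.median(axis=0, skipna=True)
    med[n < min_n] = np.nan
    return pd.DataFrame(
        {"position": missense.columns, "median_score": med.to_numpy(),
         "n_scored": n.to_numpy()}
    )


def classify_low_abundance(
    scores: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Flag variants whose abundance score falls below the threshold.

    Returns the input with a boolean ``low_abundance`` column plus
    summary attributes ``n_low`` / ``fraction_low`` in ``attrs``.
    """
    out = scores.copy()
    out["low_abundance"] = out["score"] < threshold
    out.attrs["n_low"] = int(out["low_abundance"].sum())
    out.attrs["n_total"] = int(len(out))
    out.attrs["fraction_low"] = (
        out.attrs["n_low"] / out.attrs["n_total"] if len(out) else float("nan")
    )
    return out


@dataclass
class RocResult:
    """ROC curve points and area under the curve."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    low_score_is_positive: bool = True,
) -> RocResult:
    """ROC of the abundance score as a pathogenicity classifier.

    ``labels`` carries ``variant`` and ``label`` (``pathogenic`` /
    ``benign``).  By default a *low* abundance score predicts the
    pathogenic class (destabilized variants are lost to degradation),
    so the decision score is the negated abundance.  AUC is the
    trapezoid area, equivalent to the Mann–Whitney rank statistic with
    half-credit for ties.
    """
    merged = labels.merge(scores[["variant", "score"]], on="variant", how="inner")
    if merged.empty:
        raise DesignError("no labelled variants present in the score table")
    y = (merged["label"].str.lower() == "pathogenic").to_numpy()
    if y.all() or not y.any():
        raise DesignError("ROC needs both pathogenic and benign labels")
    decision = -merged["score"].to_numpy() if low_score_is_positive else merged[
        "score"
    ].to_numpy()
    fpr, tpr, thresholds = roc_curve(y, decision)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds, fpr, tpr, auc, int(y.sum()), int((~y).sum()))


def correlate_external(
    scores: pd.DataFrame,
    external: pd.DataFrame,
    value_col: str,
    method: str = "spearman",
    key: str = "variant",
) -> tuple[float, int]:
    """Correlate abundance scores with an external per-variant table.

    ``external`` is keyed by ``variant`` (or ``position`` for
    position-level tables such as residue medians).  The sign is never
    flipped: destabilizing predictors (positive ΔΔG) correlate
    negatively with abundance.  Returns ``(correlation, n_shared)``;
    fewer than three shared entries gives NaN.
    """
    if method not in ("pearson", "spearman"):
        raise DesignError(f"unknown correlation method {method!r}")
    score_col = "median_score" if key == "position" else "score"
    merged = scores[[key, score_col]].merge(
        external[[key, value_col]], on=key, how="inner"
    ).dropna()
    n = len(merged)
    if n < 3:
        return float("nan"), n
    if method == "pearson":
        r = sps.pearsonr(merged[score_col], merged[value_col]).statistic
    else:
        r = sps.spearmanr(merged[score_col], merged[value_col]).statistic
    return float(r), n


@dataclass
class PositionClassThresholds:
    """Cutoffs for the coarse per-position classification.

    These are configurable working defaults, not canonical values: a
    variant is called unstable when its abundance score drops below
    ``abundance_low`` or its predicted ΔΔG exceeds ``ddg_destabilizing``
    (kcal/mol), and functionally constrained when it is stable yet
    evolutionarily conserved (conservation score below
    ``conservation_cut``, the GEMME convention where more negative
    means less tolerated).
    """

    abundance_low: float = 0.5
    ddg_destabilizing: float = 2.0
    conservation_cut: float = -2.0


def classify_positions(
    scores: pd.DataFrame,
    stability: pd.DataFrame,
    conservation: pd.DataFrame,
    thresholds: PositionClassThresholds | None = None,
) -> pd.DataFrame:
    """Per-position class from the most common per-variant verdict.

    Variant verdicts: ``total-loss`` (unstable), ``functional`` (stable
    but conserved, i.e. likely loss of activity when substituted) or
    ``WT-like`` (stable and tolerant).  A position takes the strictly
    most common verdict among its variants; positions with no strict
    winner or with missing inputs are ``unassigned``.  Inputs are
    per-variant tables: ``scores`` (variant, score), ``stability``
    (variant, ddg), ``conservation`` (variant, conservation).
    """
    th = thresholds or PositionClassThresholds()
    merged = (
        scores[["variant", "score"]]
        .merge(stability[["variant", "ddg"]], on="variant", how="inner")
        .merge(conservation[["variant", "conservation"]], on="variant", how="inner")
        .dropna()
    )
    from .variants import VariantId

    merged["position"] = [
        VariantId.from_string(v).position for v in merged["variant"]
    ]
    merged = merged[merged["position"].notna()]
    unstable = (merged["score"] < th.abundance_low) | (
        merged["ddg"] > th.ddg_destabilizing
    )
    conserved = merged["conservation"] < th.conservation_cut
    verdict = np.where(
        unstable, "total-loss", np.where(conserved, "functional", "WT-like")
    )
    merged["verdict"] = verdict

    rows = []
    for pos, grp in merged.groupby("position"):
        counts = grp["verdict"].value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            cls, reason = "unassigned", "tied-verdicts"
        else:
            cls, reason = counts.index[0], ""
        rows.append((int(pos), cls, int(len(grp)), reason))
    return pd.DataFrame(rows, columns=["position", "class", "n_variants", "reason"])
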