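"""Effect-map assembly, position medians, ROC/AUC, external correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vampscan as vs
from vampscan.atlas_analysis import (
    PositionClassThresholds,
    build_effect_map,
    classify_low_abundance,
    classify_positions,
    correlate_external,
    effect_map_to_scores,
    position_medians,
    roc_auc,
)
from vampscan.variants import AA_ALPHABET, DesignError


def score_table(rows):
    return pd.DataFrame(rows, columns=["variant", "score"])


@pytest.fixture(scope="module")
def full_map(protein10):
    """Complete design on a 10-residue protein, deterministic scores."""
    design = vs.enumerate_design_space(
        protein10, nonsense_excluded_positions=(), include_wild_type=False
    )
    rng = np.random.default_rng(70)
    frame = pd.DataFrame(
        {
            "variant": [str(v) for v in design.variants],
            "score": rng.uniform(-0.1, 1.2, len(design.variants)),
        }
    )
    return build_effect_map(frame, protein10), frame


class TestBuildEffectMap:
    def test_complete_design_covers_everything(self, full_map, protein10):
        emap, frame = full_map
        assert emap.n_scored == len(frame) == 10 * 20
        assert emap.coverage == pytest.approx(1.0)
        # wild-type cells masked, never scored
        assert emap.wt_mask.to_numpy().sum() == 10
        assert emap.scores.to_numpy()[emap.wt_mask.to_numpy()].size == 10

    def test_empty_scores_all_missing(self, protein10):
        emap = build_effect_map(score_table([]), protein10)
        assert emap.coverage == 0.0
        assert np.isnan(emap.scores.to_numpy()).all()

    def test_wrong_wild_type_residue_rejected(self, protein10):
        # position 1 is M, claiming A there is inconsistent
        with pytest.raises(DesignError):
            build_effect_map(score_table([("A1V", 0.5)]), protein10)

    def test_duplicate_cell_rejected(self, protein10):
        with pytest.raises(DesignError):
            build_effect_map(
                score_table([("M1V", 0.5), ("M1V", 0.6)]), protein10
            )

    def test_round_trip_identity(self, full_map, protein10):
        emap, frame = full_map
        back = effect_map_to_scores(emap)
        merged = frame.merge(back, on="variant", suffixes=("_in", "_out"))
        assert len(merged) == len(frame)
        assert np.allclose(merged.score_in, merged.score_out)


class TestPositionMedians:
    def test_min_n_gate_at_boundary(self, protein10):
        """16 missense scores leave the median undefined; 17 define it."""
        wt1, wt2 = protein10.residue(1), protein10.residue(2)
        alts1 = [a for a in AA_ALPHABET if a != wt1][:16]
        alts2 = [a for a in AA_ALPHABET if a != wt2][:17]
        rows = [(f"{wt1}1{a}", 0.4) for a in alts1]
        rows += [(f"{wt2}2{a}", 0.8) for a in alts2]
        emap = build_effect_map(score_table(rows), protein10)
        med = position_medians(emap, min_n=17).set_index("position")
        assert np.isnan(med.loc[1, "median_score"])
        assert med.loc[1, "n_scored"] == 16
        assert med.loc[2, "median_score"] == pytest.approx(0.8)

    def test_stops_excluded_from_median(self, protein10):
        wt = protein10.residue(3)
        rows = [(f"{wt}3{a}", 1.0) for a in AA_ALPHABET if a != wt]
        rows.append((f"{wt}3*", 0.0))
        emap = build_effect_map(score_table(rows), protein10)
        med = position_medians(emap, min_n=1).set_index("position")
        assert med.loc[3, "median_score"] == pytest.approx(1.0)
        assert med.loc[3, "n_scored"] == 19

    def test_matches_sort_and_middle_oracle(self, full_map):
        emap, frame = full_map
        med = position_medians(emap, min_n=1).set_index("position")
        from vampscan.variants import VariantId

        by_pos = {}
        for _, row in frame.iterrows():
            v = VariantId.from_string(row.variant)
            if v.alt_aa != "*":
                by_pos.setdefault(v.position, []).append(row.score)
        for pos, values in by_pos.items():
            ordered = sorted(values)
            n = len(ordered)
            middle = (
                ordered[n // 2]
                if n % 2
                else (ordered[n // 2 - 1] + ordered[n // 2]) / 2
            )
            assert med.loc[pos, "median_score"] == pytest.approx(middle)


class TestClassifyLowAbundance:
    def test_threshold_partition(self):
        out = classify_low_abundance(score_table([("M1V", 0.2), ("M1C", 0.7)]))
        assert out.low_abundance.tolist() == [True, False]
        assert out.attrs["n_low"] == 1

    def test_zero_threshold_boundary(self):
        out = classify_low_abundance(
            score_table([("M1V", 0.0), ("M1C", 0.4)]), threshold=0.0
        )
        assert out.attrs["n_low"] == 0

    def test_recovers_generator_mixture_fraction(self, default_experiment):
        exp = default_experiment
        result = vs.score_counts(exp.counts, exp.barcode_map)
        missense = result.scores[result.scores.category == "missense"]
        out = classify_low_abundance(missense)
        truth = exp.true_scores
        true_frac = (
            truth[truth.category == "missense"].true_score < 0.5
        ).mean()
        n = len(missense)
        tolerance = 3 * np.sqrt(true_frac * (1 - true_frac) / n) + 2 / n
        assert abs(out.attrs["fraction_low"] - true_frac) < tolerance


def auc_concordance_oracle(scores, labels):
    """Brute-force pair concordance (half credit for ties)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def label_frame(self, scores, labels):
        return (
            pd.DataFrame(
                {
                    "variant": [f"M1{a}" for a in "ACDEFGHIKLNPQRSTVWY"[: len(scores)]],
                    "score": scores,
                }
            ),
            pd.DataFrame(
                {
                    "variant": [f"M1{a}" for a in "ACDEFGHIKLNPQRSTVWY"[: len(scores)]],
                    "label": ["pathogenic" if l else "benign" for l in labels],
                }
            ),
        )

    def test_perfect_separation(self):
        scores, labels = self.label_frame([0.1, 0.2, 0.9, 1.0], [1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        scores, labels = self.label_frame([0.1, 0.2], [1, 1])
        with pytest.raises(DesignError):
            roc_auc(scores, labels)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(71)
        n = 2000
        variants = [f"v{i}" for i in range(n)]
        scores = pd.DataFrame({"variant": variants, "score": rng.uniform(0, 1, n)})
        labels = pd.DataFrame(
            {
                "variant": variants,
                "label": rng.choice(["pathogenic", "benign"], n),
            }
        )
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    @given(
        n=st.integers(4, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_trapezoid_auc_equals_pair_concordance(self, n, seed):
        """The trapezoid ROC area equals the normalized Mann-Whitney pair
        count on every random instance (ties included)."""
        rng = np.random.default_rng(seed)
        values = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            return
        variants = [f"v{i}" for i in range(n)]
        scores = pd.DataFrame({"variant": variants, "score": values})
        label_frame = pd.DataFrame(
            {
                "variant": variants,
                "label": np.where(labels, "pathogenic", "benign"),
            }
        )
        result = roc_auc(scores, label_frame)
        # low scores predict the positive class, so concordance on -score
        oracle = auc_concordance_oracle(-values, labels)
        assert result.auc == pytest.approx(oracle, abs=1e-12)
        assert (np.diff(result.fpr) >= 0).all()
        assert (np.diff(result.tpr) >= 0).all()


class TestCorrelateExternal:
    def test_self_correlation_is_one(self):
        frame = score_table([("M1V", 0.1), ("M1C", 0.6), ("M1D", 0.9)])
        external = frame.rename(columns={"score": "ddg"})
        r, n = correlate_external(frame, external, "ddg", method="pearson")
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_spearman_invariant_under_monotone_transform(self):
        frame = score_table([("M1V", 0.1), ("M1C", 0.6), ("M1D", 0.9), ("M1E", 0.3)])
        external = frame.assign(gemme=np.exp(frame.score * 3)).drop(columns="score")
        r, _ = correlate_external(frame, external, "gemme", method="spearman")
        assert r == pytest.approx(1.0)

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(72)
        n = 40
        variants = [f"v{i}" for i in range(n)]
        a, b = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        frame = pd.DataFrame({"variant": variants, "score": a})
        external = pd.DataFrame({"variant": variants, "ddg": b})
        r, _ = correlate_external(frame, external, "ddg", method="spearman")
        ra = pd.Series(a).rank()
        rb = pd.Series(b).rank()
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_too_few_shared_flagged(self):
        frame = score_table([("M1V", 0.1)])
        external = pd.DataFrame({"variant": ["M1V"], "ddg": [1.0]})
        r, n = correlate_external(frame, external, "ddg")
        assert np.isnan(r)
        assert n == 1


class TestClassifyPositions:
    def build_inputs(self, verdict_counts: dict[str, int], position=1):
        """Construct variant tables realizing given per-variant verdicts."""
        rows = []
        presets = {
            "WT-like": (0.9, 0.5, 0.0),      # stable, tolerant
            "total-loss": (0.1, 4.0, -3.0),  # unstable
            "functional": (0.9, 0.5, -3.0),  # stable but conserved
        }
        alts = [a for a in AA_ALPHABET if a != "M"]
        i = 0
        for verdict, count in verdict_counts.items():
            for _ in range(count):
                score, ddg, cons = presets[verdict]
                rows.append((f"M{position}{alts[i]}", score, ddg, cons))
                i += 1
        frame = pd.DataFrame(rows, columns=["variant", "score", "ddg", "conservation"])
        return (
            frame[["variant", "score"]],
            frame[["variant", "ddg"]],
            frame[["variant", "conservation"]],
        )

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"WT-like": 5}, "WT-like"),
            ({"total-loss": 5}, "total-loss"),
            ({"functional": 6, "WT-like": 2, "total-loss": 2}, "functional"),
            ({"WT-like": 3, "total-loss": 3}, "unassigned"),
        ],
    )
    def test_majority_rule(self, counts, expected):
        scores, ddg, cons = self.build_inputs(counts)
        out = classify_positions(scores, ddg, cons)
        assert out["class"].iloc[0] == expected

    def test_thresholds_configurable(self):
        scores, ddg, cons = self.build_inputs({"WT-like": 4})
        strict = classify_positions(
            scores, ddg, cons,
            PositionClassThresholds(abundance_low=0.95),
        )
        assert strict["class"].iloc[0] == "total-loss"
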