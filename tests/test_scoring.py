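import numpy as np
import pandas as pd
import pytest

from clasp import fixtures as fx
from clasp.scoring import (
    ConfusionCounts,
    NoMatchError,
    Thresholds,
    Weights,
    best_match,
    clasp_score,
    distance_term,
    metrics,
    pd_term,
    rank_library,
    roc_auc,
    roc_sweep,
    sensitivity_at_fpr,
)

from tests.conftest import minimal_structure


class TestDistanceTerm:
    def test_zero_deviation_zero_term(self):
        assert distance_term([0, 0, 0], [4, 6, 8]) == 0.0

    def test_reference_normalization(self):
        # same 1 Å deviation weighs more at 4 Å than at 8 Å reference
        assert distance_term([1.0], [4.0]) == pytest.approx(0.25)
        assert distance_term([1.0], [8.0]) == pytest.approx(0.125)

    def test_additive_over_pairs(self):
        a = distance_term([1.0], [4.0])
        b = distance_term([0.5], [5.0])
        assert distance_term([1.0, 0.5], [4.0, 5.0]) == pytest.approx(a + b)

    def test_zero_reference_distance_errors(self):
        with pytest.raises(ValueError):
            distance_term([0.1], [0.0])

    def test_scale_invariance(self):
        d_ref = np.array([3.3, 7.8, 5.5])
        dev = np.array([0.2, 0.4, 0.1])
        assert distance_term(3 * dev, 3 * d_ref) == \
            pytest.approx(distance_term(dev, d_ref))


class TestPdTerm:
    def test_equal_pds_zero(self):
        assert pd_term([-201.7, 22.3], [-201.7, 22.3]) == 0.0

    def test_both_near_zero_ignored(self):
        assert pd_term([3.0], [2.0], Thresholds(eps_zero=25.0)) == 0.0

    def test_only_one_near_zero_not_ignored(self):
        assert pd_term([3.0], [200.0]) > 0.0

    def test_looser_constraint_at_large_reference_pd(self):
        hi = pd_term([250.0], [200.0])   # |dev| 50 at |ref| 200
        lo = pd_term([100.0], [50.0])    # |dev| 50 at |ref| 50
        assert hi < lo

    def test_denominator_floor_applies_below_floor(self):
        # |ref| 30 is floored to 50
        assert pd_term([70.0], [30.0], Thresholds(eps_zero=25.0, p_floor=50.0)) \
            == pytest.approx(40.0 / 50.0)


class TestClaspScore:
    def test_self_score_exactly_zero(self, triad_structure, triad_motif,
                                     triad_grid):
        top, _ = best_match(triad_structure, triad_motif, triad_grid)
        assert top.score == 0.0
        assert top.distance_term == 0.0 and top.pd_term == 0.0

    def test_wp_zero_reduces_to_spatial(self, triad_motif):
        match = _perturbed_match(triad_motif)
        spatial = clasp_score(match, triad_motif, p_q=[0.0, 0.0, 0.0],
                              weights=Weights(1.0, 0.0))
        assert spatial.score == pytest.approx(spatial.distance_term)

    def test_monotone_in_each_distance_deviation(self, triad_motif):
        base = _perturbed_match(triad_motif)
        s0 = clasp_score(base, triad_motif).score
        for k in range(3):
            worse = _perturbed_match(triad_motif)
            worse.delta_d = base.delta_d.copy()
            worse.delta_d[k] += 0.3
            worse.d_q = triad_motif.d_ref + worse.delta_d
            assert clasp_score(worse, triad_motif).score > s0


def _perturbed_match(motif):
    from clasp.congruence import MatchGeometry
    delta = np.full(motif.d_ref.shape, 0.2)
    return MatchGeometry(
        residue_ids=tuple(("A", i + 1, "") for i in range(motif.n)),
        residue_types=tuple(s[0][:3].upper() for s in motif.sites),
        atoms=(), d_q=motif.d_ref + delta, delta_d=delta)


class TestBestMatch:
    def test_single_match_returned(self, triad_structure, triad_motif):
        top, alts = best_match(triad_structure, triad_motif)
        assert top.geometry.residue_types[0] == "SER"

    def test_planted_copy_beats_decoy(self, triad_motif):
        coords = fx.embed_distances(triad_motif.d_ref, 3)
        entries = [("SER", "OG", coords[0]), ("HIS", "NE2", coords[1]),
                   ("ASP", "OD1", coords[2]),
                   ("SER", "OG", coords[0] + (0.9, 0, 0)),
                   ]
        s = minimal_structure(entries)
        top, _ = best_match(s, triad_motif)
        assert top.geometry.residue_ids[0] == ("A", 1, "")
        assert top.score == pytest.approx(0.0, abs=1e-9)

    def test_no_match_is_an_error_not_zero(self, triad_motif):
        s = minimal_structure([("ALA", "CB", (0, 0, 0))])
        with pytest.raises(NoMatchError):
            best_match(s, triad_motif)

    def test_group_relaxation_admits_tyr_nucleophile(self, triad_motif):
        # a Tyr can fill the Ser-like site, mirroring the class C
        # beta-lactamase Tyr substitution
        coords = fx.embed_distances(triad_motif.d_ref, 3)
        s = minimal_structure([("TYR", "OH", coords[0]),
                               ("HIS", "NE2", coords[1]),
                               ("ASP", "OD1", coords[2])])
        top, _ = best_match(s, triad_motif)
        assert top.geometry.residue_types[0] == "TYR"


class TestRankLibrary:
    def test_empty_library_empty_table(self, triad_structure):
        result = rank_library(triad_structure, [])
        assert len(result.table) == 0

    def test_sorted_ascending(self, triad_structure, triad_motif,
                              lactamase_motif, triad_grid):
        result = rank_library(triad_structure, [lactamase_motif, triad_motif],
                              triad_grid)
        scores = result.table["score"].to_numpy()
        assert np.all(np.diff(scores) >= 0)

    def test_own_motif_ranks_first_with_zero(self, triad_structure,
                                             triad_motif, lactamase_motif,
                                             triad_grid):
        result = rank_library(triad_structure, [lactamase_motif, triad_motif],
                              triad_grid)
        assert result.table.iloc[0]["motif"] == triad_motif.source_id
        assert result.table.iloc[0]["score"] == 0.0
        assert lactamase_motif.source_id in result.no_match


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, tn=90, fp=0, fn=0))
        assert m["sensitivity"] == 1.0 and m["fpr"] == 0.0

    def test_printed_formulas(self):
        m = metrics(ConfusionCounts(tp=9, tn=90, fp=10, fn=1))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["fpr"] == pytest.approx(0.1)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["recall"] == m["sensitivity"]

    def test_zero_denominator_flagged_nan(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m["sensitivity"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestRocSweep:
    def test_perfect_separation_hits_corner(self):
        curve = roc_sweep([0.1, 0.2, 5.0, 6.0], [True, True, False, False])
        at_corner = curve[(curve["fpr"] == 0.0) & (curve["sensitivity"] == 1.0)]
        assert len(at_corner) >= 1
        assert sensitivity_at_fpr(curve, 0.0) == 1.0

    def test_identical_scores_single_point(self):
        curve = roc_sweep([1.0, 1.0, 1.0], [True, False, True])
        assert list(curve[["sensitivity", "fpr"]].iloc[-1]) == [1.0, 1.0]
        assert len(curve) == 2  # origin anchor + the single step

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_sweep([1.0, 2.0], [True, True])

    def test_stepwise_monotone(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 40)
        labels = rng.uniform(0, 1, 40) < 0.4
        curve = roc_sweep(scores, labels)
        assert np.all(np.diff(curve["sensitivity"]) >= 0)
        assert np.all(np.diff(curve["fpr"]) >= 0)

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        labels = rng.uniform(0, 1, 200) < 0.3
        scores = np.where(labels, rng.normal(0.5, 1.0, 200),
                          rng.normal(2.0, 1.0, 200))
        ours = roc_auc(roc_sweep(scores, labels))
        # sklearn ranks high score = positive, ours low score = positive
        theirs = roc_auc_score(labels, -scores)
        assert ours == pytest.approx(theirs, abs=1e-9)
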