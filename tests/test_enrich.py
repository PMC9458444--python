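"""Ranking, weighted-KS enrichment, background z-scores, ORA, candidate calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ribohet as rh
from ribohet.contacts import ContactSetCollection
from ribohet.enrich import _es_from_hit_ranks

from conftest import make_reference


def _dt(scores, padj=None, log2fc=None):
    n = len(scores)
    return pd.DataFrame(
        {
            "log2FC": log2fc if log2fc is not None else np.ones(n),
            "padj": padj if padj is not None else np.full(n, 0.5),
            "rank_score": scores,
        },
        index=pd.Index(np.arange(n), name="concat_index"),
    )


def walk_extrema(scores_ranked, member_ranks):
    """Independent step-by-step running-sum oracle: (max, min) of the walk."""
    member_ranks = set(member_ranks)
    nr = sum(abs(scores_ranked[r]) for r in member_ranks)
    n, k = len(scores_ranked), len(member_ranks)
    running, hi, lo = 0.0, 0.0, 0.0
    for r in range(n):
        if r in member_ranks:
            running += abs(scores_ranked[r]) / nr if nr > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi, lo


def walk_es(scores_ranked, member_ranks):
    """Signed extremum of the walk; positive side wins an exact tie."""
    hi, lo = walk_extrema(scores_ranked, member_ranks)
    return hi if hi >= -lo else lo


class TestRankPositions:
    def test_descending_by_score(self):
        dt = _dt([3.0, 1.0, 2.0])
        pos, scores = rh.rank_positions(dt)
        assert pos.tolist() == [0, 2, 1]
        assert scores.tolist() == [3.0, 2.0, 1.0]

    def test_ties_break_by_ascending_position(self):
        dt = _dt([1.0, 1.0, 1.0, 1.0])
        pos, _ = rh.rank_positions(dt)
        assert pos.tolist() == [0, 1, 2, 3]

    def test_matches_stable_sort_oracle(self):
        rng = np.random.default_rng(8)
        scores = rng.choice([0.5, 1.0, 2.0, 3.0], size=50)
        dt = _dt(scores)
        pos, _ = rh.rank_positions(dt)
        oracle = [p for p, _ in sorted(enumerate(scores), key=lambda t: (-t[1], t[0]))]
        assert pos.tolist() == oracle


class TestEnrichmentScore:
    def test_hand_computed_ten_element_walk(self):
        scores = np.arange(10, 0, -1, dtype=float)
        es = rh.enrichment_score(scores, np.array([0, 3, 7]))
        # walk: +10/20, -1/7 x2, +7/20, -1/7 x3, +3/20, -1/7 x2 -> max 79/140
        assert es == pytest.approx(79 / 140)
        assert es == pytest.approx(walk_es(scores, [0, 3, 7]))

    def test_matches_walk_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.exponential(2.0, size=40))[::-1].copy()
        for _ in range(25):
            k = int(rng.integers(2, 12))
            hits = np.sort(rng.choice(40, size=k, replace=False))
            es = rh.enrichment_score(scores, hits)
            hi, lo = walk_extrema(scores, hits)
            if abs(hi + lo) > 1e-9:  # clear winner: exact signed match
                assert es == pytest.approx(hi if hi > -lo else lo)
            else:  # exact magnitude tie: either sign is a valid extremum
                assert abs(es) == pytest.approx(hi)

    def test_top_concentrated_set_scores_near_one(self):
        scores = np.concatenate([np.full(5, 10.0), np.full(95, 0.01)])
        es = rh.enrichment_score(scores, np.arange(5))
        assert es > 0.9

    def test_uniform_spread_in_constant_ranking_scores_low(self):
        scores = np.ones(100)
        es = rh.enrichment_score(scores, np.arange(0, 100, 10))
        assert abs(es) < 0.15

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.exponential(1.0, size=60))[::-1].copy()
        hits = np.array([2, 17, 40, 55])
        a = rh.enrichment_score(scores, hits)
        b = rh.enrichment_score(scores * 7.3, hits)
        assert a == pytest.approx(b)

    def test_bottom_concentrated_set_scores_negative(self):
        scores = np.concatenate([np.full(90, 5.0), np.full(10, 0.001)])
        es = rh.enrichment_score(scores, np.arange(90, 100))
        assert es < -0.5


class TestNormalizedES:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        scores = np.sort(rng.exponential(1.0, size=200))[::-1].copy()
        hits = np.arange(0, 30)
        a = rh.normalized_es(scores, hits, n_perm=200, seed=9)
        b = rh.normalized_es(scores, hits, n_perm=200, seed=9)
        assert a == b
        c = rh.normalized_es(scores, hits, n_perm=200, seed=10)
        assert a != c  # permutation noise moves with the seed

    def test_nes_is_es_over_same_sign_null_mean(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.exponential(1.0, size=150))[::-1].copy()
        hits = np.arange(10, 22)
        es = rh.enrichment_score(scores, hits)
        nes, p = rh.normalized_es(scores, hits, n_perm=500, seed=3)
        assert np.sign(nes) == np.sign(es)
        assert 0 < p <= 1

    def test_requires_minimum_permutations(self):
        with pytest.raises(ValueError, match="n_perm"):
            rh.normalized_es(np.ones(10), np.array([0]), n_perm=10)


class TestES2:
    def test_centering_gives_zero(self):
        assert rh.es2_zscore(1.3, np.array([1.3, 1.3 - 0.4, 1.3 + 0.4])) == 0.0

    def test_plain_arithmetic(self):
        bg = np.array([0.5, 1.0, 1.5])  # mean 1.0, sd 0.5
        assert rh.es2_zscore(2.0, bg) == pytest.approx(2.0)

    def test_matches_brute_force_mean_sd(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(1.0, 0.3, size=100)
        val = 1.7
        brute = (val - bg.mean()) / bg.std(ddof=1)
        assert rh.es2_zscore(val, bg) == pytest.approx(brute)

    def test_missing_backgrounds_dropped(self):
        bg = np.array([1.0, np.nan, 2.0, 3.0])
        brute = (2.5 - 2.0) / np.std([1.0, 2.0, 3.0], ddof=1)
        assert rh.es2_zscore(2.5, bg) == pytest.approx(brute)

    def test_constant_backgrounds_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(rh.es2_zscore(1.0, np.array([2.0, 2.0, 2.0])))


class TestORA:
    def test_closed_form_hypergeometric_example(self):
        # universe 100, significant 10, set 20, overlap 5
        padj = np.full(100, 0.5)
        lfc = np.ones(100)
        padj[:5] = 0.001  # the 5 overlapping significant positions
        padj[20:25] = 0.001  # 5 significant positions outside the set
        dt = _dt(np.ones(100), padj=padj, log2fc=lfc)
        set_pos = np.arange(20)
        p, k, n_set, m_uni, n_sig = rh.ora_test(dt, set_pos)
        assert (k, n_set, m_uni, n_sig) == (5, 20, 100, 10)
        expected = sum(
            math.comb(10, x) * math.comb(90, 20 - x) for x in range(5, 11)
        ) / math.comb(100, 20)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        padj = np.full(50, 0.5)
        padj[40:] = 0.001
        dt = _dt(np.ones(50), padj=padj)
        p, k, *_ = rh.ora_test(dt, np.arange(10))
        assert k == 0 and p == 1.0

    def test_fully_significant_set_attains_minimum_tail(self):
        padj = np.full(30, 0.5)
        padj[:6] = 1e-4
        dt = _dt(np.ones(30), padj=padj)
        p, k, n_set, m_uni, n_sig = rh.ora_test(dt, np.arange(6))
        assert k == n_set == n_sig == 6
        assert p == pytest.approx(1 / math.comb(30, 6), rel=1e-9)

    def test_sig_rule_needs_both_padj_and_lfc(self):
        padj = np.array([0.001, 0.001, 0.5])
        lfc = np.array([2.0, 0.1, 2.0])  # only position 0 passes both
        dt = _dt(np.ones(3), padj=padj, log2fc=lfc)
        _, _, _, _, n_sig = rh.ora_test(dt, np.array([0]))
        assert n_sig == 1

    def test_equals_exhaustive_enumeration_on_small_universes(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            m_uni = int(rng.integers(5, 21))
            padj = np.where(rng.random(m_uni) < 0.3, 0.001, 0.9)
            dt = _dt(np.ones(m_uni), padj=padj)
            n_set = int(rng.integers(1, m_uni + 1))
            set_pos = rng.choice(m_uni, size=n_set, replace=False)
            p, k, n_set_out, _, n_sig = rh.ora_test(dt, set_pos)
            sig = set(np.flatnonzero(padj < 0.05).tolist())
            # exhaustive: over all same-size draws, mass with >= k successes
            hits = 0
            total = 0
            for combo in itertools.combinations(range(m_uni), n_set_out):
                total += 1
                if len(sig.intersection(combo)) >= k:
                    hits += 1
            assert p == pytest.approx(hits / total, rel=1e-9)


class TestPredictRPs:
    def test_recovers_injected_rp_first_and_reports_all(self, toy_bundle):
        coll = toy_bundle["collection"]
        spec = rh.SimulationSpec(target_rp="P3", seed=101)
        m, truth = rh.simulate_counts(toy_bundle["ref"], coll, spec)
        m = rh.filter_low_counts(m)
        res = rh.run_differential(m)
        report = rh.predict_rps(res.table, coll, n_perm=500, seed=5)
        t = report.table
        assert t.shape[0] == len(coll.rp_ids)
        assert t.iloc[0]["rp_id"] == "P3"
        assert t.iloc[0]["candidate"]
        assert set(truth["concat_index"]).issubset(set(coll.sets["P3"].tolist()))

    def test_candidate_threshold_is_inclusive(self, toy_bundle):
        coll = toy_bundle["collection"]
        m, _ = rh.simulate_counts(
            toy_bundle["ref"], coll, rh.SimulationSpec(target_rp="P2", seed=33)
        )
        res = rh.run_differential(rh.filter_low_counts(m))
        base = rh.predict_rps(res.table, coll, n_perm=300, seed=1)
        top_es2 = float(base.table["es2"].iloc[0])
        at = rh.predict_rps(res.table, coll, n_perm=300, seed=1, es2_threshold=top_es2)
        above = rh.predict_rps(
            res.table, coll, n_perm=300, seed=1, es2_threshold=top_es2 + 1e-9
        )
        assert bool(at.table.iloc[0]["candidate"])
        assert not bool(above.table.iloc[0]["candidate"])

    def test_report_sorted_by_es2_and_bh_over_rps_only(self, toy_bundle):
        coll = toy_bundle["collection"]
        m, _ = rh.simulate_counts(
            toy_bundle["ref"], coll, rh.SimulationSpec(target_rp=None, seed=55)
        )
        res = rh.run_differential(rh.filter_low_counts(m))
        report = rh.predict_rps(res.table, coll, n_perm=300, seed=2)
        es2 = report.table["es2"].dropna().to_numpy()
        assert np.all(np.diff(es2) <= 1e-12)
        # BH across the RP sets only: adjusted never below raw, <= n_rp * raw
        t = report.table.dropna(subset=["gsea_p"])
        assert np.all(t["gsea_padj"] >= t["gsea_p"] - 1e-12)
        assert np.all(t["gsea_padj"] <= np.minimum(1, len(t) * t["gsea_p"]) + 1e-12)

    def test_empty_candidate_report_still_emitted(self, toy_bundle):
        coll = toy_bundle["collection"]
        m, _ = rh.simulate_counts(
            toy_bundle["ref"], coll, rh.SimulationSpec(target_rp=None, seed=77)
        )
        res = rh.run_differential(rh.filter_low_counts(m))
        report = rh.predict_rps(res.table, coll, n_perm=300, seed=3, es2_threshold=50.0)
        assert report.table.shape[0] == len(coll.rp_ids)
        assert report.candidates() == []

    def test_contact_positions_outside_universe_are_dropped(self):
        ref = make_reference("A" * 40)
        scores = np.linspace(5, 0.1, 30)
        dt = _dt(scores)  # universe = positions 0..29; 30..39 not retained
        sets = {"rp": np.array([0, 1, 2, 35, 38])}
        coll = ContactSetCollection(
            reference=ref, threshold_tau=10.0, max_set_size=360, shift_s=4,
            n_backgrounds=5, sets=sets,
            backgrounds={"rp": rh.build_background_sets(sets["rp"], 40, 4, 5)},
        )
        report = rh.predict_rps(dt, coll, n_perm=100, seed=0)
        assert int(report.table.iloc[0]["set_size"]) == 3
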