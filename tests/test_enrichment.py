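"""Labeling, enrichment factor, BEDROC, and the binder-subsampling protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctmd.enrichment import (
    BINDER,
    EXCLUDED,
    NONBINDER,
    ScreenTable,
    bedroc,
    classify_by_pki,
    ef_at,
    hit_rate,
    subsample_enrichment,
)


def make_table(n_binders, n_nonbinders, rng=None, perfect=False):
    """Screen with random scores, or binders strictly above non-binders."""
    rows = []
    for i in range(n_binders):
        rows.append((f"B{i:03d}", 0.0, BINDER))
    for i in range(n_nonbinders):
        rows.append((f"N{i:03d}", 0.0, NONBINDER))
    df = ScreenTable(rows)
    if perfect:
        df["score"] = [1000.0 + i for i in range(n_binders)] + [float(i) for i in range(n_nonbinders)]
    else:
        df["score"] = (rng if rng is not None else np.random.default_rng(0)).uniform(size=len(df))
    return df


def bedroc_oracle(ranks, n_total, alpha):
    """Independent direct-formula BEDROC (Truchon & Bailly), plain loops."""
    n = len(ranks)
    s = 0.0
    for r in ranks:
        s += math.exp(-alpha * r / n_total)
    rie = s / n / ((1.0 / n_total) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1.0))
    ra = n / n_total
    top = ra * math.sinh(alpha / 2.0)
    bot = math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    return rie * top / bot + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))


class TestClassifyByPki:
    @pytest.mark.parametrize(
        "pki, expected",
        [(4.2, NONBINDER), (6.5, BINDER), (5.5, EXCLUDED), (5.0, EXCLUDED), (6.0, EXCLUDED)],
    )
    def test_threshold_rule(self, pki, expected):
        assert classify_by_pki(pki) == expected

    def test_custom_band(self):
        assert classify_by_pki(5.5, lower=5.4, upper=5.45) == BINDER

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_by_pki(float("nan"))


class TestHitRate:
    def test_14_of_41(self):
        assert hit_rate(make_table(14, 27)) == pytest.approx(14 / 41)
        assert round(100 * hit_rate(make_table(14, 27))) == 34

    def test_5_of_32(self):
        assert hit_rate(make_table(5, 27)) == pytest.approx(0.15625)

    def test_all_binders(self):
        assert hit_rate(make_table(3, 0)) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hit_rate(ScreenTable([]))


class TestEfAt:
    def test_ef100_is_one_on_random_tables(self, rng):
        for _ in range(20):
            t = make_table(int(rng.integers(1, 10)), int(rng.integers(1, 30)), rng)
            assert ef_at(t, 100.0).ef == pytest.approx(1.0, abs=1e-12)

    def test_perfect_ranking_5_of_32_at_30(self):
        """ceil(0.3*32)=10 selected, all 5 binders inside: EF = (5/9.6)/(5/32)."""
        res = ef_at(make_table(5, 27, perfect=True), 30.0)
        assert res.n_selected == 10
        assert res.hits_in_selection == 5
        assert res.ef == pytest.approx(10.0 / 3.0)

    def test_pure_tie_permutation_expectation(self):
        """All-equal scores: averaging the deterministic tie order over random
        id relabelings recovers EF ~ 1 (permutation expectation oracle)."""
        rng = np.random.default_rng(99)
        base = make_table(5, 27)
        base["score"] = 1.0
        ids = list(base["ligand_id"])
        efs = []
        for _ in range(1000):
            shuffled = base.copy()
            shuffled["ligand_id"] = rng.permutation(ids)
            efs.append(ef_at(shuffled, 30.0).ef)
        assert np.mean(efs) == pytest.approx(1.0, abs=0.1)

    def test_invariant_to_monotone_score_transform(self, rng):
        t = make_table(6, 20, rng)
        a = ef_at(t, 25.0).ef
        t2 = t.copy()
        t2["score"] = np.exp(3.0 * t2["score"]) + 7.0
        assert ef_at(t2, 25.0).ef == a

    def test_no_binders_rejected(self):
        with pytest.raises(ValueError, match="no binders"):
            ef_at(make_table(0, 5), 30.0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ef_at(make_table(2, 2), 0.0)


class TestBedroc:
    def test_perfect_ranking_matches_oracle(self):
        t = make_table(5, 27, perfect=True)
        want = bedroc_oracle(list(range(1, 6)), 32, 20.0)
        assert bedroc(t, 20.0) == pytest.approx(want, abs=1e-10)
        assert want > 0.9

    def test_worst_ranking_matches_oracle_and_is_tiny(self):
        t = make_table(5, 27, perfect=True)
        t["score"] = -t["score"]  # actives now ranked last
        want = bedroc_oracle(list(range(28, 33)), 32, 20.0)
        assert bedroc(t, 20.0) == pytest.approx(want, abs=1e-10)
        assert bedroc(t, 20.0) < 0.01

    def test_single_active_on_top_of_two(self):
        t = ScreenTable([("A", 2.0, BINDER), ("B", 1.0, NONBINDER)])
        assert bedroc(t, 20.0) == pytest.approx(1.0, abs=1e-3)

    def test_value_in_unit_interval(self, rng):
        for _ in range(20):
            t = make_table(int(rng.integers(1, 8)), int(rng.integers(2, 30)), rng)
            assert -1e-6 <= bedroc(t, 20.0) <= 1.0 + 1e-6

    @given(st.integers(0, 10_000))
    def test_monotone_under_pairwise_rank_swap(self, seed):
        """Swapping an active downward past an inactive never raises BEDROC."""
        rng = np.random.default_rng(seed)
        t = make_table(4, 20, rng)
        ranked = t.sort_values(["score", "ligand_id"], ascending=[False, True]).reset_index(drop=True)
        act = np.flatnonzero((ranked["label"] == BINDER).to_numpy())
        i = int(rng.choice(act))
        lower_inact = np.flatnonzero((ranked["label"] == NONBINDER).to_numpy()[i:]) + i
        if lower_inact.size == 0:
            return
        j = int(rng.choice(lower_inact))
        before = bedroc(ranked, 20.0)
        swapped = ranked.copy()
        lab = swapped["label"].to_numpy().copy()
        lab[i], lab[j] = lab[j], lab[i]
        swapped["label"] = lab
        assert bedroc(swapped, 20.0) <= before + 1e-12

    def test_no_actives_rejected(self):
        with pytest.raises(ValueError):
            bedroc(make_table(0, 5), 20.0)


class TestRandomRankingCalibration:
    def test_mean_ef30_and_bedroc_under_random_scores(self):
        """i.i.d. uniform scores: EF30 averages 1 and BEDROC matches its
        analytic uniform expectation (2000 repeats)."""
        rng = np.random.default_rng(7)
        efs, beds = [], []
        for _ in range(2000):
            t = make_table(5, 27, rng)
            efs.append(ef_at(t, 30.0).ef)
            beds.append(bedroc(t, 20.0))
        assert np.mean(efs) == pytest.approx(1.0417, abs=0.1)  # E[hits]=10*5/32 over 9.6
        alpha, ra = 20.0, 5 / 32
        uniform_bedroc = ra * math.sinh(alpha / 2) / (
            math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
        ) + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
        assert np.mean(beds) == pytest.approx(uniform_bedroc, abs=0.02)


class TestSubsampleEnrichment:
    def test_subsample_row_counts_and_base_rate(self):
        t = make_table(14, 27)
        out = subsample_enrichment(t, k=5, n_repeats=10, xx_list=(30.0,), alpha_list=(20.0,), seed=1)
        assert set(out["metric"]) == {"EF", "BEDROC"}
        # base rate of each subsample is 5/32; verify via the perfect-ranking EF
        assert 5 / 32 == pytest.approx(0.15625)

    def test_seed_determinism(self):
        t = make_table(14, 27, rng=np.random.default_rng(3))
        a = subsample_enrichment(t, k=5, n_repeats=20, seed=11)
        b = subsample_enrichment(t, k=5, n_repeats=20, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_separation_gives_exact_ef30_every_repeat(self):
        """All binders above all non-binders: every 5-binder subsample ranks
        them on top, so EF30 = 10/3 with zero spread."""
        t = make_table(14, 27, perfect=True)
        out = subsample_enrichment(t, k=5, n_repeats=50, xx_list=(30.0,), alpha_list=(20.0,), seed=5)
        row = out[(out["metric"] == "EF") & (out["param"] == 30.0)].iloc[0]
        assert row["mean"] == pytest.approx(10.0 / 3.0)
        assert row["ci_lo"] == pytest.approx(10.0 / 3.0)
        assert row["ci_hi"] == pytest.approx(10.0 / 3.0)

    def test_k_larger_than_binder_pool_is_allowed(self):
        t = make_table(3, 10)
        out = subsample_enrichment(t, k=5, n_repeats=5, seed=0)
        assert len(out) > 0

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            subsample_enrichment(make_table(3, 10), k=0)

    def test_no_binders_rejected(self):
        with pytest.raises(ValueError):
            subsample_enrichment(make_table(0, 10), k=5)
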