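"""Lagged association rate estimation, null rate, model family and jackknife."""

import numpy as np
import pandas as pd
import pytest

from podsoc.sightings import GroupByIndividual, build_gbi, daily_dedup
from podsoc.synthetic import generate_society, simulate_sightings
from podsoc.temporal import (
    LaggedAssociationModel,
    _pair_period_counts,
    jackknife_errors,
    lagged_association_rate,
    null_association_rate,
)

from conftest import lar_recovery_config, make_table, uniform_probs


def gbi_from_memberships(day_groups):
    """Build a GBI from {day_offset: [group member lists]}."""
    rows = []
    for day, groups in sorted(day_groups.items()):
        date = str((pd.Timestamp("2020-06-01") + pd.Timedelta(days=day)).date())
        for g, members in enumerate(groups):
            rows.extend(
                (date, f"g{g}", m, "UN", "A", len(members), len(members), False)
                for m in members
            )
    return build_gbi(make_table(rows))


def brute_force_lar(gbi):
    """Exhaustive enumeration over period pairs and ordered individual pairs."""
    uniq = np.unique(gbi.periods)
    n = gbi.n_individuals
    assoc = {}
    seen = {}
    for p in uniq:
        rows = gbi.matrix[gbi.periods == p]
        a = np.zeros((n, n), dtype=bool)
        for r in rows:
            members = np.flatnonzero(r)
            for i in members:
                for j in members:
                    if i != j:
                        a[i, j] = True
        assoc[p] = a
        seen[p] = rows.any(axis=0)
    num, den, lag = [], [], []
    for t in uniq:
        for t2 in uniq:
            tau = (t2 - t).astype("timedelta64[D]").astype(int)
            if tau <= 0:
                continue
            nn = dd = 0
            for i in range(n):
                for j in range(n):
                    if i == j or not assoc[t][i, j]:
                        continue
                    if seen[t2][i]:
                        dd += 1
                        if assoc[t2][i, j]:
                            nn += 1
            num.append(nn)
            den.append(dd)
            lag.append(tau)
    return np.array(num), np.array(den), np.array(lag)


class TestLarEstimator:
    def test_permanent_pairs_give_unity(self):
        groups = {d: [["A", "B"], ["C", "D"]] for d in range(6)}
        curve = lagged_association_rate(gbi_from_memberships(groups))
        np.testing.assert_allclose(curve.g, 1.0)

    def test_hand_enumerated_three_periods(self):
        # day0: {A,B},{C};  day1: {A,B,C};  day2: {A,C},{B}
        groups = {0: [["A", "B"], ["C"]],
                  1: [["A", "B", "C"]],
                  2: [["A", "C"], ["B"]]}
        gbi = gbi_from_memberships(groups)
        num, den, lag, _ = _pair_period_counts(gbi)
        # lag 1: (day0 -> day1): A-B assoc at both: num 2 (ordered), den 2
        #        (day1 -> day2): of 6 ordered pairs at day1, only A-C persists
        sel = lag == 1
        assert num[sel].sum() == 2 + 2
        assert den[sel].sum() == 2 + 6
        # lag 2: day0 -> day2: A-B at day0, not at day2; both seen
        sel = lag == 2
        assert num[sel].sum() == 0
        assert den[sel].sum() == 2

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            n_days = int(rng.integers(2, 6))
            day_groups = {}
            for d in range(n_days):
                pool = rng.choice(8, size=int(rng.integers(3, 9)), replace=False)
                pool = np.array([f"I{k}" for k in pool])
                splits = sorted(rng.choice(range(1, len(pool)), size=2,
                                           replace=False)) if len(pool) > 2 else []
                day_groups[d] = [list(g) for g in np.split(pool, splits) if len(g)]
            gbi = gbi_from_memberships(day_groups)
            num, den, lag = _pair_period_counts(gbi)[:3]
            bnum, bden, blag = brute_force_lar(gbi)
            order = np.lexsort((num, lag))
            border = np.lexsort((bnum, blag))
            np.testing.assert_array_equal(lag[order], blag[border])
            np.testing.assert_array_equal(num[order], bnum[border])
            np.testing.assert_array_equal(den[order], bden[border])

    def test_preference_free_days_sit_near_null(self):
        rng = np.random.default_rng(1)
        n, k = 12, 3                      # groups of 3+3+3+3 each day
        day_groups = {}
        for d in range(40):
            perm = rng.permutation(n)
            day_groups[d] = [
                [f"I{j}" for j in perm[i:i + k]] for i in range(0, n, k)
            ]
        gbi = gbi_from_memberships(day_groups)
        curve = lagged_association_rate(gbi)
        null = null_association_rate(gbi)
        assert null == pytest.approx((k - 1) / (n - 1))
        np.testing.assert_allclose(curve.g, null, atol=0.04)


class TestNullRate:
    def test_closed_form_for_constant_group_size(self):
        groups = {d: [["A", "B"], ["C", "D", "E"]] for d in range(3)}
        gbi = gbi_from_memberships(groups)
        k_mean = 2.5
        assert null_association_rate(gbi) == pytest.approx((k_mean - 1) / 4)

    def test_pair_society_enumeration(self):
        # N=10 in pairs: random repartner each day -> null 1/9
        rng = np.random.default_rng(2)
        day_groups = {}
        for d in range(60):
            perm = rng.permutation(10)
            day_groups[d] = [[f"I{perm[i]}", f"I{perm[i + 1]}"]
                             for i in range(0, 10, 2)]
        gbi = gbi_from_memberships(day_groups)
        assert null_association_rate(gbi) == pytest.approx(1 / 9)
        curve = lagged_association_rate(gbi)
        np.testing.assert_allclose(curve.g, 1 / 9, atol=0.05)

    def test_planted_society_sits_above_null(self):
        cfg = lar_recovery_config(5, n_days=100)
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        curve = lagged_association_rate(gbi)
        assert (curve.g > curve.null_rate).all()


class TestModelFamily:
    def test_pure_cc_selects_constant_at_one(self):
        cfg = lar_recovery_config(0, n_individuals=12, n_days=40,
                                  cc_fraction=1.0, ca_fraction=0.0,
                                  groups_observed_per_day=None,
                                  age_counts={"A": 12},
                                  sex_counts={"F": 6, "M": 6})
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        res = LaggedAssociationModel(gbi, min_per_bin=5).fit(seed=0, jackknife=False)
        assert res.best.effective_components(40) == frozenset({"CC"})
        np.testing.assert_allclose(res.best.predict([1, 10, 30]), 1.0, atol=0.02)

    def test_planted_mixture_recovers_decay_rate(self):
        cfg = lar_recovery_config(4)
        society = generate_society(cfg)
        truth = society.true_lar_params()
        gbi = build_gbi(daily_dedup(simulate_sightings(society)))
        res = LaggedAssociationModel(gbi).fit(seed=4, jackknife=True)
        fit = next(m for m in res.models if m.name == "RD+CC+CA")
        assert fit.param_dict["a1"] == pytest.approx(truth["a1"], abs=0.1)
        assert fit.param_dict["a2"] == pytest.approx(truth["a2"], abs=0.05)
        assert fit.param_dict["a3"] == pytest.approx(truth["a3"], abs=0.08)
        # acquaintance duration heuristic: reciprocal decay, in days
        assert fit.ca_duration_days()["a1"] == pytest.approx(
            1 / fit.param_dict["a1"]
        )

    def test_qaic_ranking_invariant_to_time_rescaling(self):
        cfg = lar_recovery_config(6, n_days=60)
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        model = LaggedAssociationModel(gbi)
        res = model.fit(seed=1, jackknife=False)
        # stretch the calendar 3x: same counts land in 3x-wider bins
        base = gbi.periods.min()
        periods3 = base + 3 * (gbi.periods - base)
        gbi3 = GroupByIndividual(gbi.matrix, gbi.individuals, periods3,
                                 gbi.row_covariates, gbi.column_attributes)
        model3 = LaggedAssociationModel(gbi3, lag_bins=model.bin_edges * 3)
        res3 = model3.fit(seed=1, jackknife=False)
        assert [m.name for m in res.models] == [m.name for m in res3.models]
        a1, a1_3 = (next(m for m in r.models if m.name == "RD+CC+CA").param_dict["a1"]
                    for r in (res, res3))
        assert a1_3 == pytest.approx(a1 / 3, rel=0.05)

    def test_degenerate_saturated_data_still_ranks_all_models(self):
        groups = {d: [["A", "B"], ["C", "D"]] for d in range(4)}
        gbi = gbi_from_memberships(groups)
        res = LaggedAssociationModel(gbi, min_per_bin=1).fit(seed=0, jackknife=False)
        assert len(res.models) == 8
        assert np.isfinite([m.qaic for m in res.models]).all()

    def test_summary_mentions_support_convention(self):
        cfg = lar_recovery_config(7, n_days=60)
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        res = LaggedAssociationModel(gbi).fit(seed=0, jackknife=False)
        text = res.summary()
        assert "QAIC" in text and "dQAIC > 2" in text


class TestJackknife:
    def test_constant_estimator_zero_se(self):
        cfg = lar_recovery_config(8, n_days=120)
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        se, _ = jackknife_errors(gbi, lambda g: 1.0, block_days=30)
        assert se == pytest.approx(0.0)

    def test_textbook_formula_by_hand(self):
        cfg = lar_recovery_config(9, n_days=90)
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        est = lambda g: float(g.matrix.sum(axis=1).mean())
        se, reps = jackknife_errors(gbi, est, block_days=30)
        b = len(reps)
        expected = np.sqrt((b - 1) / b * ((reps - reps.mean()) ** 2).sum())
        assert se == pytest.approx(expected)
        assert b == 3

    def test_single_block_raises(self):
        cfg = lar_recovery_config(10, n_days=20)
        gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
        with pytest.raises(ValueError, match="blocks"):
            jackknife_errors(gbi, lambda g: 1.0, block_days=400)


def test_best_model_asymptotes_within_unit_interval():
    cfg = lar_recovery_config(11, n_days=120)
    gbi = build_gbi(daily_dedup(simulate_sightings(generate_society(cfg))))
    res = LaggedAssociationModel(gbi).fit(seed=2, jackknife=False)
    best = res.best
    tau = np.linspace(0.01, 5000, 200)
    g = best.predict(tau)
    assert (g >= 0).all() and (g <= 1).all()
    assert (np.diff(g) <= 1e-12).all()          # decay models never increase
    const, _ = best._structure()
    # all decay rates are bounded away from 0, so g(inf) is the constant level
    assert best.predict([1e8])[0] == pytest.approx(const, abs=1e-6)
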