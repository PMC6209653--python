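import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genemeta.genetic_models import ContingencyTable
from genemeta.meta_engine import (
    FIXED_MH,
    RANDOM_DL,
    EffectEstimate,
    PooledResult,
    PoolingError,
    effects_from_tables,
    heterogeneity,
    is_informative,
    pool,
    pool_fixed_mh,
    pool_random_dl,
    select_method,
    study_effect,
    wald_p,
)

from ._oracles import oracle_dl, oracle_iv_fixed, oracle_mh

T = ContingencyTable

cell_strategy = st.integers(1, 200)
table_strategy = st.tuples(cell_strategy, cell_strategy, cell_strategy, cell_strategy).map(
    lambda t: T(*t)
)


class TestStudyEffect:
    def test_null_symmetric_table(self):
        e = study_effect(T(10, 10, 10, 10))
        assert e.or_value == pytest.approx(1.0)
        assert e.log_or == 0.0
        assert e.se == pytest.approx(0.6324555320336759)

    def test_worked_example(self):
        e = study_effect(T(20, 10, 10, 20))
        assert e.or_value == pytest.approx(4.0)
        assert e.log_or == pytest.approx(math.log(4.0))
        assert e.se == pytest.approx(math.sqrt(0.3))

    def test_zero_cell_correction(self):
        e = study_effect(T(0, 10, 10, 10))
        assert e.corrected
        assert e.or_value == pytest.approx(0.5 * 10.5 / (10.5 * 10.5))

    def test_non_informative_returns_sentinel(self):
        assert study_effect(T(0, 10, 0, 10)) is None
        assert study_effect(T(10, 0, 10, 0)) is None
        assert not is_informative(T(0, 10, 0, 10))

    def test_weight_is_inverse_variance(self):
        e = study_effect(T(20, 10, 10, 20))
        assert e.weight == pytest.approx(1.0 / e.se**2)


class TestMantelHaenszel:
    def test_single_study_equals_crude(self):
        r = pool_fixed_mh([T(20, 10, 10, 20)])
        assert r.pooled_or == pytest.approx(4.0)
        assert r.method == FIXED_MH
        assert r.tau_squared == 0.0

    def test_duplicated_table(self):
        r = pool_fixed_mh([T(20, 10, 10, 20), T(20, 10, 10, 20)])
        assert r.pooled_or == pytest.approx(4.0)

    def test_hand_computed_sums(self):
        r = pool_fixed_mh([T(10, 10, 5, 15), T(8, 12, 4, 16)])
        assert r.pooled_or == pytest.approx((3.75 + 3.2) / (1.25 + 1.2))

    def test_empty_input_raises(self):
        with pytest.raises(PoolingError):
            pool_fixed_mh([])

    def test_all_non_informative_raises(self):
        with pytest.raises(PoolingError):
            pool_fixed_mh([T(0, 10, 0, 10)])

    @settings(max_examples=50)
    @given(st.lists(table_strategy, min_size=1, max_size=3))
    def test_matches_oracle(self, tables):
        r = pool_fixed_mh(tables)
        log_or, se = oracle_mh([(t.a, t.b, t.c, t.d) for t in tables])
        assert math.log(r.pooled_or) == pytest.approx(log_or, rel=1e-10)
        assert r.ci_low == pytest.approx(math.exp(log_or - 1.959963984540054 * se), rel=1e-10)

    @settings(max_examples=50)
    @given(st.lists(table_strategy, min_size=1, max_size=5))
    def test_case_control_swap_inverts_or(self, tables):
        r = pool_fixed_mh(tables)
        s = pool_fixed_mh([t.swapped_rows() for t in tables])
        assert s.pooled_or == pytest.approx(1.0 / r.pooled_or, rel=1e-10)
        assert s.z == pytest.approx(-r.z, abs=1e-10)


class TestDerSimonianLaird:
    def test_worked_example(self):
        effects = [EffectEstimate("a", 0.2, 0.1), EffectEstimate("b", 0.6, 0.1)]
        r = pool_random_dl(effects)
        assert r.q == pytest.approx(8.0)
        assert r.tau_squared == pytest.approx(0.07)
        assert math.log(r.pooled_or) == pytest.approx(0.4)
        se = (math.log(r.ci_high) - math.log(r.pooled_or)) / 1.959963984540054
        assert se == pytest.approx(0.2)

    def test_identical_effects_reduce_to_fixed_iv(self):
        effects = [EffectEstimate(str(i), 0.3, 0.15) for i in range(4)]
        r = pool_random_dl(effects)
        assert r.tau_squared == 0.0
        pooled, se = oracle_iv_fixed([0.3] * 4, [0.15] * 4)
        assert math.log(r.pooled_or) == pytest.approx(pooled)

    def test_single_effect_pools_to_itself(self):
        r = pool_random_dl([EffectEstimate("a", 0.5, 0.2)])
        assert math.log(r.pooled_or) == pytest.approx(0.5)
        assert r.tau_squared == 0.0
        assert r.k == 1

    @settings(max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(-1.5, 1.5), st.floats(0.05, 1.0)),
            min_size=2,
            max_size=6,
        )
    )
    def test_ci_never_narrower_than_fixed_iv(self, params):
        effects = [EffectEstimate(str(i), y, se) for i, (y, se) in enumerate(params)]
        r = pool_random_dl(effects)
        _, se_fixed = oracle_iv_fixed([e.log_or for e in effects], [e.se for e in effects])
        width = math.log(r.ci_high) - math.log(r.ci_low)
        assert width >= 2 * 1.959963984540054 * se_fixed - 1e-12

    @settings(max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(-1.5, 1.5), st.floats(0.05, 1.0)),
            min_size=1,
            max_size=3,
        )
    )
    def test_matches_oracle(self, params):
        effects = [EffectEstimate(str(i), y, se) for i, (y, se) in enumerate(params)]
        r = pool_random_dl(effects)
        pooled, se, tau2 = oracle_dl([e.log_or for e in effects], [e.se for e in effects])
        assert math.log(r.pooled_or) == pytest.approx(pooled, rel=1e-10, abs=1e-12)
        assert r.tau_squared == pytest.approx(tau2, rel=1e-10, abs=1e-12)

    def test_removing_zero_weight_effect_is_neutral(self):
        # a study whose weight vanishes must not move the pooled OR
        # (tau2 stays 0 here, so the df shift it causes is inert)
        effects = [EffectEstimate("a", 0.3, 0.1), EffectEstimate("b", 0.3, 0.12)]
        ghost = EffectEstimate("ghost", 3.0, 1e9)
        with_ghost = pool_random_dl(effects + [ghost])
        without = pool_random_dl(effects)
        assert with_ghost.pooled_or == pytest.approx(without.pooled_or, abs=1e-12)


class TestHeterogeneity:
    def test_identical_effects(self):
        h = heterogeneity([EffectEstimate(str(i), 0.4, 0.1) for i in range(3)])
        assert h.q == pytest.approx(0.0, abs=1e-12)
        assert h.i_squared == 0.0

    def test_worked_example(self):
        h = heterogeneity([EffectEstimate("a", 0.2, 0.1), EffectEstimate("b", 0.6, 0.1)])
        assert h.q == pytest.approx(8.0)
        assert h.df == 1
        assert h.i_squared == pytest.approx(87.5)

    def test_i2_floored_when_q_below_df(self):
        h = heterogeneity([EffectEstimate("a", 0.30, 0.5), EffectEstimate("b", 0.31, 0.5)])
        assert h.q < h.df
        assert h.i_squared == 0.0
        assert h.tau_squared == 0.0

    def test_single_study(self):
        h = heterogeneity([EffectEstimate("a", 0.4, 0.1)])
        assert h.df == 0 and h.i_squared == 0.0 and h.p_q == 1.0


class TestSelectMethod:
    @pytest.mark.parametrize(
        "p_q,i2,expected",
        [
            (0.5, 0.0, FIXED_MH),
            (0.05, 40.0, FIXED_MH),  # second disjunct
            (0.5, 60.0, FIXED_MH),  # first disjunct
            (0.05, 60.0, RANDOM_DL),
            (0.1, 50.0, FIXED_MH),  # boundary: I2 <= 50 is fixed
            (0.11, 99.0, FIXED_MH),  # boundary: p_Q > 0.1 is fixed
        ],
    )
    def test_rule(self, p_q, i2, expected):
        assert select_method(p_q, i2) == expected


class TestWald:
    def test_null(self):
        z, p = wald_p(0.0, 0.5)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        z, p = wald_p(1.3863, 0.5477)
        assert z == pytest.approx(2.531, abs=1e-3)
        assert p == pytest.approx(0.0114, abs=1e-4)

    @given(st.floats(0.01, 5), st.floats(0.01, 5))
    def test_monotone_in_abs_z(self, a, b):
        lo, hi = sorted([a, b])
        _, p_lo = wald_p(lo, 1.0)
        _, p_hi = wald_p(hi, 1.0)
        assert p_hi <= p_lo


class TestPoolDispatch:
    def test_auto_selects_fixed_for_homogeneous(self):
        r = pool([T(20, 10, 10, 20)] * 3)
        assert r.method == FIXED_MH

    def test_auto_selects_random_for_heterogeneous(self):
        tables = [T(400, 100, 100, 400), T(100, 400, 400, 100), T(300, 80, 90, 310)]
        effects = effects_from_tables(tables)
        h = heterogeneity(effects)
        assert select_method(h.p_q, h.i_squared) == RANDOM_DL
        r = pool(tables)
        assert r.method == RANDOM_DL
        assert r.tau_squared > 0

    def test_forced_method(self):
        tables = [T(20, 10, 10, 20), T(15, 12, 11, 18)]
        assert pool(tables, method=FIXED_MH).method == FIXED_MH
        assert pool(tables, method=RANDOM_DL).method == RANDOM_DL

    def test_non_informative_tables_dropped(self):
        r = pool([T(20, 10, 10, 20), T(0, 10, 0, 10)])
        assert r.k == 1


class TestPooledResultInvariants:
    def test_fixed_requires_zero_tau(self):
        with pytest.raises(ValueError):
            PooledResult(
                variant_id="rs1", group="overall", genetic_model="allele",
                method=FIXED_MH, k=2, pooled_or=1.2, ci_low=1.0, ci_high=1.4,
                z=2.0, p=0.04, q=1.0, df=1, p_q=0.3, i_squared=0.0,
                tau_squared=0.1,
            )

    def test_ci_must_bracket_or(self):
        with pytest.raises(ValueError):
            PooledResult(
                variant_id="rs1", group="overall", genetic_model="allele",
                method=FIXED_MH, k=2, pooled_or=2.0, ci_low=1.0, ci_high=1.4,
                z=2.0, p=0.04, q=1.0, df=1, p_q=0.3, i_squared=0.0,
                tau_squared=0.0,
            )
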