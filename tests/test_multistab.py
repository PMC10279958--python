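"""Multistability census against analytic toy oracles and its invariants."""

import numpy as np
import pytest

from spnsim.fixtures import make_fixtures
from spnsim.multistab import (
    compare_parameter_distributions,
    dedup_states,
    records_frame,
    run_multistab_census,
)
from spnsim.params import default_table


class ToyCensusModel:
    """Wraps the 1-D bistable toy as a degenerate 'model' for the census."""

    def __init__(self):
        self._toy, self.expect = make_fixtures("toy_bistable")
        self.n_species = 1
        self.params = default_table()
        self.species_names = self._toy.species_names

    def rhs(self, t, y):
        return self._toy.rhs(t, y)

    def rhs_for(self, pvec):
        return self.rhs


class TestDedup:
    def test_order_independent(self, rng):
        states = [rng.uniform(0, 1, 8) for _ in range(6)]
        states += [s + rng.uniform(-1e-4, 1e-4, 8) for s in states[:3]]
        base = dedup_states(states)
        for _ in range(5):
            perm = [states[i] for i in rng.permutation(len(states))]
            other = dedup_states(perm)
            assert len(other) == len(base)
            a = sorted(map(tuple, np.round(base, 9)))
            b = sorted(map(tuple, np.round(other, 9)))
            assert a == b

    def test_jitter_merges_distinct_states_survive(self):
        a, b = np.zeros(3), np.ones(3)
        near_a = a + 5e-5
        assert len(dedup_states([a, b, near_a])) == 2
        assert len(dedup_states([a, near_a])) == 1

    def test_single_ic_yields_at_most_one_state(self):
        model = ToyCensusModel()
        records, _ = run_multistab_census(model, n_params=3, n_ic=1, seed=0)
        assert all(r.n_distinct <= 1 for r in records)


class TestCensusOracle:
    def test_bistable_toy_reports_exactly_two_attractors(self):
        # ICs uniform on [0,1] with separatrix at 0.3: 15 draws essentially
        # always cover both basins
        model = ToyCensusModel()
        records, summary = run_multistab_census(model, n_params=2, n_ic=15, seed=4)
        for rec in records:
            assert rec.n_converged == 15
            assert rec.n_distinct == 2
            values = sorted(s[0] for s in rec.distinct_states)
            assert values[0] == pytest.approx(0.0, abs=1e-3)
            assert values[1] == pytest.approx(1.0, abs=1e-3)
        assert summary["multistable"] == 2

    def test_record_invariants_on_spn_model(self, model_1x4):
        records, summary = run_multistab_census(
            model_1x4, n_params=2, n_ic=3, seed=9, t_max=2e5
        )
        for rec in records:
            assert rec.n_distinct <= rec.n_converged <= rec.n_ic
            for state in rec.distinct_states:
                # independent residual check of every reported steady state
                resid = float(np.max(np.abs(model_1x4.rhs_for(
                    model_1x4.params.vector_from_sampled(rec.sampled_params)
                )(0.0, state))))
                assert resid < 1e-4
        assert 0 <= summary["multistable"] <= summary["with_steady_state"]


class TestCompare:
    def _records(self, mono_value, multi_value, n=6):
        model = ToyCensusModel()
        table = model.params
        recs, _ = run_multistab_census(model, n_params=n, n_ic=4, seed=1)
        for k, rec in enumerate(recs):
            if k < n // 2:
                rec.distinct_states = rec.distinct_states[:1]
                rec.sampled_params = np.full(table.n_sampled, mono_value)
            else:
                rec.sampled_params = np.full(table.n_sampled, multi_value)
        return recs, table

    def test_fabricated_medians_give_expected_fold_change(self):
        recs, table = self._records(2.0, 10.0)
        out = compare_parameter_distributions(recs, table)
        assert np.allclose(out["fold_change"], 5.0)

    def test_identical_groups_give_fold_one(self):
        recs, table = self._records(3.0, 3.0)
        out = compare_parameter_distributions(recs, table)
        assert np.allclose(out["fold_change"], 1.0)

    def test_empty_group_signalled(self):
        recs, table = self._records(1.0, 1.0)
        for rec in recs:
            rec.distinct_states = rec.distinct_states[:1]
        with pytest.raises(ValueError):
            compare_parameter_distributions(recs, table)

    def test_records_frame_shape(self):
        recs, table = self._records(1.0, 2.0)
        frame = records_frame(recs, table)
        assert len(frame) == len(recs)
        assert "n_distinct" in frame.columns
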