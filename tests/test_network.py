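"""Model assembly: species/parameter counts, wiring symmetry, conservation."""

import numpy as np
import pytest

from spnsim import _kernel as K
from spnsim.kinetics import GuardConfig
from spnsim.network import (
    BOUNDARY_KEYS,
    SPECIES_PER_CELL,
    build_model,
    build_single_cell,
    compile_rhs,
)
from spnsim.params import ParameterTable, default_table


class TestStructure:
    def test_1x4_has_132_dynamic_species(self, model_1x4):
        assert model_1x4.n_species == 132
        assert len(model_1x4.species_names) == 132
        assert len(set(model_1x4.species_names)) == 132

    def test_parameter_registry_counts(self, model_1x4):
        assert len(model_1x4.params) == 53
        assert model_1x4.params.n_sampled == 48

    def test_single_cell_has_33_species(self):
        model = build_single_cell(boundary_values={k: 0.0 for k in BOUNDARY_KEYS})
        assert model.n_species == 33

    def test_per_cell_species_inventory(self, model_1x4):
        cell0 = model_1x4.species_names[:SPECIES_PER_CELL]
        mrnas = [s for s in cell0 if s.split("_")[0] in ("en", "wg", "ptc", "ci", "hh")]
        membrane = [s for s in cell0 if s[:3] in ("EWG", "PTC", "PH1", "PH2", "PH3",
                                                  "PH4", "PH5", "PH6") or s[:2] == "HH"]
        assert len(mrnas) == 5
        assert len(membrane) == 24

    def test_scale_ranges_for_concentration_scale_factors(self):
        table = default_table()
        for name in ("PTC_0", "HH_0"):
            assert (table[name].range_lo, table[name].range_hi) == (1, 1000)

    def test_missing_parameter_is_a_named_error(self):
        table = default_table()
        rows = [r for r in table.rows if r.name != "kappa_CNptc"]
        with pytest.raises(ValueError, match="kappa_CNptc"):
            build_model(1, 4, ParameterTable(rows))

    def test_totals_are_derived_not_dynamic(self, model_1x4):
        y = np.random.default_rng(0).uniform(0, 1, 132)
        totals = model_1x4.eval_totals(y)
        assert len(totals) == 12  # EWG_T, PTC_T, PH_T per cell
        ptc = sum(y[model_1x4.species_index(f"PTC{j}_0_1")] for j in range(1, 7))
        assert totals["PTC_T_0_1"] == pytest.approx(ptc)
        # EWG_T sums the six apposed neighbour pools (left sides 4-6, right 1-3)
        ewg = sum(y[model_1x4.species_index(f"EWG{j}_0_0")] for j in (4, 5, 6)) + sum(
            y[model_1x4.species_index(f"EWG{j}_0_2")] for j in (1, 2, 3)
        )
        assert totals["EWG_T_0_1"] == pytest.approx(ewg)


class TestCompiledRhs:
    def test_kernel_matches_reaction_registry(self, model_1x4, rng):
        f = compile_rhs(model_1x4)
        for _ in range(5):
            y = rng.uniform(0, 1, model_1x4.n_species)
            fast = f(0.0, y)
            slow = model_1x4.rhs_from_reactions(y)
            np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)

    def test_finite_on_overshoot_box_with_guards(self, model_1x4, rng):
        f = compile_rhs(model_1x4)
        for _ in range(50):
            y = rng.uniform(-1e-6, 2.0, model_1x4.n_species)
            assert np.all(np.isfinite(f(0.0, y)))

    def test_all_zero_state_gives_finite_derivatives(self, model_1x4):
        dy = compile_rhs(model_1x4)(0.0, np.zeros(132))
        assert np.all(np.isfinite(dy))

    def test_homogeneous_state_gives_identical_cell_blocks(self, model_1x4, rng):
        block = rng.uniform(0, 1, SPECIES_PER_CELL)
        y = np.tile(block, 4)
        dy = compile_rhs(model_1x4)(0.0, y).reshape(4, SPECIES_PER_CELL)
        for c in range(1, 4):
            np.testing.assert_allclose(dy[c], dy[0], rtol=1e-12)

    def test_translation_symmetry_of_rhs(self, model_1x4, rng):
        # shifting all cell blocks by one column commutes with the RHS
        y = rng.uniform(0, 1, 132).reshape(4, SPECIES_PER_CELL)
        f = compile_rhs(model_1x4)
        dy = f(0.0, y.ravel()).reshape(4, SPECIES_PER_CELL)
        y_shift = np.roll(y, 1, axis=0)
        dy_shift = f(0.0, y_shift.ravel()).reshape(4, SPECIES_PER_CELL)
        np.testing.assert_allclose(dy_shift, np.roll(dy, 1, axis=0), rtol=1e-12)

    def test_lateral_diffusion_conserves_membrane_totals(self, rng):
        # with everything but lateral diffusion switched off, each protein's
        # within-cell pool sum is exactly conserved
        table = default_table()
        for row in table.rows:
            if row.category == "half_life":
                row.value = float("inf")  # no decay
            elif row.name.startswith("r_LMxfer"):
                row.value = 3.0
            elif row.category == "rate" and row.name != "B_ci":
                row.value = row.range_lo if row.sampled else 0.0
        for row in table.rows:
            if row.name in ("alpha_CIwg", "alpha_WGwg", "C_CI", "k_PTCHH",
                            "r_ExoWG", "r_EndoWG", "r_MxferWG", "V_max", "P_trans"):
                row.value = 0.0
        model = build_model(1, 4, table)
        y = rng.uniform(0, 1, 132)
        dy = model.rhs(0.0, y)
        for c in range(4):
            b = c * SPECIES_PER_CELL
            for off in (K.S_EWG, K.S_PTC, K.S_HH, K.S_PH):
                assert abs(dy[b + off : b + off + 6].sum()) < 1e-12

    def test_state_length_mismatch_raises(self, model_1x4):
        with pytest.raises(ValueError):
            compile_rhs(model_1x4)(0.0, np.zeros(7))


class TestSingleCell:
    def test_missing_boundary_species_raises(self):
        incomplete = {k: 0.0 for k in BOUNDARY_KEYS[:-1]}
        with pytest.raises(ValueError, match="HH6"):
            build_single_cell(boundary_values=incomplete)

    def test_matches_embedded_cell_of_1x4_model(self, model_1x4, rng):
        # boundary set to the instantaneous neighbour values of cell (0,1)
        y = rng.uniform(0, 1, 132)
        boundary = {}
        for j0 in range(6):
            nb = int(model_1x4.neighbor[1, j0])
            js = (j0 + 3) % 6
            lab = f"0_{nb}"
            for prot in ("EWG", "PTC", "HH"):
                boundary[f"{prot}{j0 + 1}"] = y[
                    model_1x4.species_index(f"{prot}{js + 1}_{lab}")
                ]
        single = build_single_cell(boundary_values=boundary)
        b = SPECIES_PER_CELL
        dy_single = single.rhs(0.0, y[b : 2 * b])
        dy_full = model_1x4.rhs(0.0, y)[b : 2 * b]
        np.testing.assert_allclose(dy_single, dy_full, rtol=1e-12, atol=1e-15)

    def test_zero_boundary_en_decays_from_any_start(self):
        from spnsim.dynamics import run_timecourse

        single = build_single_cell(boundary_values={k: 0.0 for k in BOUNDARY_KEYS})
        x0 = np.full(33, 0.5)
        traj = run_timecourse(single, x0, t_end=600.0, dt_out=5.0)
        assert traj.status == "ok"
        en_final = traj.final[0]
        assert en_final < 1e-3  # no Wingless input, engrailed shuts off


class TestGuardOff:
    def test_unguarded_rhs_can_produce_nan(self, rng):
        model = build_model(1, 4, guard=GuardConfig(enabled=False))
        f = compile_rhs(model)
        y = rng.uniform(0, 1, 132)
        y[model.species_index("CN_0_0")] = -1e-12  # overshoot below zero
        dy = f(0.0, y)
        assert not np.all(np.isfinite(dy))
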