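"""The free-energy-based set size estimator: branches, limits, monotonicity."""

import math

import numpy as np
import pytest

from rnaneutralset.energies import load_params, loop_free_energy
from rnaneutralset.enumeration import StructureConstraints, sample_structures
from rnaneutralset.estimator import (
    Branch,
    CutoffPolicy,
    constrained_sequence_count,
    estimate_batch,
    estimate_low_energy_set_size,
    estimate_mfe_set_size,
    heuristic_cutoff,
    mfe_offset,
)
from rnaneutralset.structures import (
    StructuralFeatures,
    compute_features,
    parse_structure,
)


class TestHeuristicCutoff:
    @pytest.mark.parametrize("n_bp, x", [(9, -7.5), (2, -0.5), (1, 0.5)])
    def test_values(self, n_bp, x):
        assert heuristic_cutoff(n_bp) == pytest.approx(x)

    def test_rejects_open_structure(self):
        with pytest.raises(ValueError):
            heuristic_cutoff(0)


def test_per_site_constraint_product():
    """One fixed site, one two-letter site, one free site of an L=3 RNA: 8 seqs."""
    assert constrained_sequence_count([1, 2, 4]) == 8


def _x_for_g_stacking(db, target, params):
    """Cut-off that makes G_stacking land exactly on `target` for structure db."""
    f = compute_features(parse_structure(db))
    g_loop = loop_free_energy(f.loop_inventory, params)
    return target * f.n_stack + g_loop - params.a_eos * f.n_eos


class TestBranches:
    DB = "((...........))"

    def test_unconstrained_returns_nc_exactly(self, params):
        est = estimate_low_energy_set_size(self.DB, x=100.0, params=params)
        assert est.branch is Branch.UNCONSTRAINED
        assert est.log10_size == pytest.approx(math.log10(est.n_c))
        assert est.v_bp == est.v_eos == 1.0

    def test_gc_endpoint(self, params):
        x = _x_for_g_stacking(self.DB, -3.0, params)
        est = estimate_low_energy_set_size(self.DB, x=x, params=params)
        assert est.v_bp == pytest.approx(2 / 6)
        assert est.v_eos == 1.0
        assert est.log10_size == pytest.approx(
            math.log10(est.n_c) + est.n_bp * math.log10(1 / 3)
        )

    def test_interpolation_midpoint(self, params):
        x = _x_for_g_stacking(self.DB, -1.75, params)
        est = estimate_low_energy_set_size(self.DB, x=x, params=params)
        assert est.branch is Branch.INTERPOLATED
        assert est.v_bp == pytest.approx(2 / 3)

    def test_infeasible_fallback(self, params):
        est = estimate_low_energy_set_size(self.DB, x=-50.0, params=params)
        assert est.branch is Branch.INFEASIBLE_FALLBACK
        assert not est.feasible
        expected = (
            math.log10(est.n_c)
            + 2 * math.log10(1 / 3)
            + 2 * math.log10(1 / 4)
            + math.log10(0.1)
        )
        assert est.log10_size == pytest.approx(expected)

    def test_versatilities_within_bounds_and_decreasing(self, params):
        xs = np.linspace(-40, 20, 121)
        prev_v = None
        for x in xs:
            est = estimate_low_energy_set_size(self.DB, x=float(x), params=params)
            assert 2 / 6 - 1e-12 <= est.v_bp <= 1.0
            assert 0.25 - 1e-12 <= est.v_eos <= 1.0
            if est.branch is Branch.INTERPOLATED and prev_v is not None:
                assert est.v_bp >= prev_v - 1e-12  # increasing with x
            prev_v = est.v_bp if est.branch is Branch.INTERPOLATED else None

    def test_rejects_structures_without_stacks(self, params):
        with pytest.raises(ValueError):
            estimate_low_energy_set_size(parse_structure("......"), x=0.0)
        with pytest.raises(ValueError):
            # single lonely pair: no stacking term
            estimate_low_energy_set_size(parse_structure("(...)"), x=0.0)

    def test_no_eos_shortcut_to_fallback(self, params):
        """With no end-of-stack terms left to constrain, infeasibility is direct."""
        f = compute_features(parse_structure("((...))"))
        starved = StructuralFeatures(
            n_bp=f.n_bp, n_stack_regions=f.n_stack_regions, n_stack=f.n_stack,
            n_eos=0, loop_inventory=f.loop_inventory, length=f.length,
        )
        est = estimate_low_energy_set_size(
            parse_structure("((...))"), x=-50.0, params=params, features=starved
        )
        assert est.branch is Branch.INFEASIBLE_FALLBACK


class TestMonotonicityProperty:
    def test_size_non_decreasing_in_x(self, params):
        """Size grows with x; the only drop is the 0.1 factor entering fallback."""
        structures = sample_structures(StructureConstraints(L=30), 25, seed=202)
        xs = np.arange(-45.0, 15.0, 0.25)
        for s in structures:
            prev = None
            prev_branch = None
            for x in xs:
                est = estimate_low_energy_set_size(s, float(x), params=params)
                assert est.log10_size <= math.log10(est.n_c) + 1e-9
                if prev is not None:
                    leaving_fallback = (
                        prev_branch is Branch.INFEASIBLE_FALLBACK
                        and est.branch is not Branch.INFEASIBLE_FALLBACK
                    )
                    if not leaving_fallback:
                        assert est.log10_size >= prev - 1e-9, (
                            s.dotbracket, x, est.branch, prev_branch
                        )
                prev, prev_branch = est.log10_size, est.branch

    def test_fallback_drop_is_exactly_factor_ten(self, params):
        """At the infeasibility boundary the estimate drops by exactly 10x."""
        db = "((...........))"
        f = compute_features(parse_structure(db))
        g_loop = loop_free_energy(f.loop_inventory, params)
        # boundary where the eos-constrained band is exhausted
        x_edge = (
            params.G_stack_min * f.n_stack
            - (params.eos_gc_bonus + params.eos_max_extra) * f.n_eos
            + g_loop - params.a_eos * f.n_eos
        )
        inside = estimate_low_energy_set_size(db, x_edge + 1e-6, params=params)
        outside = estimate_low_energy_set_size(db, x_edge - 1e-6, params=params)
        assert inside.branch is Branch.EOS_CONSTRAINED
        assert outside.branch is Branch.INFEASIBLE_FALLBACK
        assert inside.log10_size - outside.log10_size == pytest.approx(1.0, abs=1e-3)


class TestMfeEstimate:
    def test_equals_low_energy_at_heuristic_cutoff(self, params):
        db = "((..((...))..))" + "." * 20
        f = compute_features(parse_structure(db))
        a = estimate_mfe_set_size(db, params=params)
        b = estimate_low_energy_set_size(
            db, heuristic_cutoff(f.n_bp), params=params
        )
        assert a.log10_size == b.log10_size

    @pytest.mark.parametrize("L, b", [(35, 1.15), (50, 1.9)])
    def test_offset(self, L, b):
        assert mfe_offset(L) == pytest.approx(b)
        db = "((...........))" + "." * (L - 15)
        with_off = estimate_mfe_set_size(db, apply_offset=True)
        without = estimate_mfe_set_size(db)
        assert with_off.log10_size - without.log10_size == pytest.approx(b)


class TestBatch:
    def test_columns_and_policy(self, params):
        dbs = ["((...))..", "((.((...))))", "........."[:9]]
        table = estimate_batch(dbs[:2], CutoffPolicy(mode="fixed_x", x=0.0))
        assert list(table.columns) == [
            "structure", "L", "n_bp", "n_stack", "n_eos", "G_loop", "x",
            "branch", "v_bp", "v_eos", "log10_size",
        ]
        assert (table["x"] == 0.0).all()
        heur = estimate_batch(dbs[:2], CutoffPolicy(mode="heuristic"))
        assert heur["x"].tolist() == [
            heuristic_cutoff(2), heuristic_cutoff(4)
        ]

    def test_bad_policy(self):
        with pytest.raises(ValueError):
            CutoffPolicy(mode="fixed_x")
        with pytest.raises(ValueError):
            CutoffPolicy(mode="nonsense")
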