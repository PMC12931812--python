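import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damagepde.model_core import DediffRule, EffectiveRates, PartitionFractions, make_grid
from damagepde.remap_partition import dedifferentiation_sources, division_sources, remap_density


def point_mass(grid, x, mass=1.0):
    u = np.zeros(grid.size)
    i = int(round(x / grid.dx))
    u[i] = mass / grid.dx
    return u


class TestRemapDensity:
    def test_identity_at_unit_fraction(self, grid, random_density):
        out = remap_density(random_density, 1.0, grid)
        assert np.array_equal(out, random_density)

    def test_node_aligned_point_mass(self, grid):
        u = point_mass(grid, 0.4)
        out = remap_density(u, 0.5, grid)
        assert grid.mass(out) == pytest.approx(1.0, abs=1e-14)
        assert out[int(round(0.2 / grid.dx))] == pytest.approx(1.0 / grid.dx)
        assert np.count_nonzero(out) == 1

    def test_gaussian_matches_analytic_rescaling(self):
        # oracle: (1/a) u(x/a) for a Gaussian is the Gaussian with center and
        # width scaled by a and amplitude scaled by 1/a, evaluated exactly
        a = 1.0 / 3.0
        g = make_grid(2.0, 400)
        u = g.gaussian(1.0, 0.9, 0.1)
        out = remap_density(u, a, g)
        exact = g.gaussian(1.0 / a, a * 0.9, a * 0.1)
        # deposition is first-order pointwise; compare in L1 at O(dx)
        err = g.dx * np.abs(out - exact).sum()
        assert err < 5 * g.dx
        fine = make_grid(2.0, 4000)
        err_fine = fine.dx * np.abs(remap_density(fine.gaussian(1.0, 0.9, 0.1), a, fine) - fine.gaussian(1.0 / a, a * 0.9, a * 0.1)).sum()
        assert err_fine < err / 5  # refining the grid 10x shrinks the error

    @given(a=st.floats(0.05, 1.0), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_mass_conserved_and_moment_scaled_exactly(self, a, seed):
        g = make_grid(2.0, 200)
        u = np.random.default_rng(seed).random(g.size)
        out = remap_density(u, a, g)
        assert g.mass(out) == pytest.approx(g.mass(u), rel=1e-12)
        assert g.first_moment(out) == pytest.approx(a * g.first_moment(u), rel=1e-12, abs=1e-13)
        assert np.all(out >= 0)

    def test_linear_in_density(self, grid, rng):
        u = rng.random(grid.size)
        v = rng.random(grid.size)
        lhs = remap_density(2.0 * u + 3.0 * v, 0.37, grid)
        rhs = 2.0 * remap_density(u, 0.37, grid) + 3.0 * remap_density(v, 0.37, grid)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_composition_scales_moment_multiplicatively(self, grid, random_density):
        out = remap_density(remap_density(random_density, 0.6, grid), 0.5, grid)
        assert grid.first_moment(out) == pytest.approx(0.3 * grid.first_moment(random_density), rel=1e-12)

    @pytest.mark.parametrize("a", [0.0, -0.5, 1.2])
    def test_invalid_fraction_rejected(self, grid, random_density, a):
        with pytest.raises(ValueError):
            remap_density(random_density, a, grid)

    def test_gather_variant_is_consistent_but_not_conservative(self, grid):
        u = grid.gaussian(1.0, 0.8, 0.1)
        out = remap_density(u, 0.5, grid, method="gather")
        exact = grid.gaussian(2.0, 0.4, 0.05)
        assert grid.dx * np.abs(out - exact).sum() < 1e-3


class TestDivisionSources:
    def test_pure_self_renewal_point_mass(self, grid):
        P = point_mass(grid, 0.4)
        rates = EffectiveRates(p1=1.0, p2=0.0, p3=0.0, lam_P=1.0, lam_R=0.0)
        src = division_sources(P, rates, PartitionFractions(), grid)
        assert np.allclose(src.source_W, 0.0)
        # two daughters appear at x = 0.2, the mother leaves at x = 0.4
        assert src.source_P[int(round(0.2 / grid.dx))] == pytest.approx(2.0 / grid.dx)
        assert src.source_P[int(round(0.4 / grid.dx))] == pytest.approx(-1.0 / grid.dx)

    def test_symmetric_division_bookkeeping(self, grid, random_density):
        rates = EffectiveRates(p1=0.5, p2=0.5, p3=0.0, lam_P=1.0, lam_R=0.0)
        src = division_sources(random_density, rates, PartitionFractions(), grid)
        P_bar = grid.mass(random_density)
        assert src.number_change_P == pytest.approx(0.0, abs=1e-12 * P_bar)
        assert src.number_change_W == pytest.approx(P_bar, rel=1e-12)

    @given(
        p1=st.floats(0.0, 1.0),
        w2=st.floats(0.0, 1.0),
        w3=st.floats(0.0, 1.0),
        lam_P=st.floats(0.1, 2.0),
        a1=st.floats(0.05, 0.95),
        b1=st.floats(0.05, 0.95),
        g1=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_division_conserves_total_damage(self, p1, w2, w3, lam_P, a1, b1, g1, seed):
        # random simplex point (p1, p2, p3) and random fraction pairs
        total = p1 + w2 + w3
        if total == 0:
            p1, p2, p3 = 1.0, 0.0, 0.0
        else:
            p1, p2, p3 = p1 / total, w2 / total, w3 / total
        g = make_grid(2.0, 150)
        P = np.random.default_rng(seed).random(g.size)
        rates = EffectiveRates(p1=p1, p2=p2, p3=p3, lam_P=lam_P, lam_R=0.0)
        fr = PartitionFractions.from_first(a1, b1, g1)
        src = division_sources(P, rates, fr, g)
        combined = src.moment_change_P + src.moment_change_W
        assert combined == pytest.approx(0.0, abs=1e-12 * lam_P * g.first_moment(P))
        # cell-number bookkeeping of the two compartments
        P_bar = g.mass(P)
        assert src.number_change_P == pytest.approx((2 * p1 + p3 - 1) * lam_P * P_bar, rel=1e-10, abs=1e-12)
        assert src.number_change_W == pytest.approx((2 * p2 + p3) * lam_P * P_bar, rel=1e-10, abs=1e-12)

    def test_shape_mismatch_rejected(self, grid):
        rates = EffectiveRates(0.5, 0.5, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            division_sources(np.zeros(7), rates, PartitionFractions(), grid)


class TestDedifferentiationSources:
    def test_constant_rule_is_local_identity(self, grid, random_density):
        src = dedifferentiation_sources(random_density, 0.05, DediffRule("constant"), grid)
        assert np.allclose(src.source_P, 0.05 * random_density)
        assert np.allclose(src.source_W, -0.05 * random_density)

    def test_threshold_below_support_gives_zero(self, grid):
        W = grid.indicator(0.1, 0.5, 2.0)
        src = dedifferentiation_sources(W, 0.05, DediffRule("threshold", x_c=0.6), grid)
        assert np.allclose(src.source_P, 0.0)
        assert np.allclose(src.source_W, 0.0)

    def test_threshold_boundary_node_included(self, grid):
        W = np.zeros(grid.size)
        i = int(round(0.6 / grid.dx))
        W[i] = 1.0
        src = dedifferentiation_sources(W, 1.0, DediffRule("threshold", x_c=0.6), grid)
        assert src.source_P[i] == pytest.approx(1.0)

    def test_partial_repair_moves_point_mass(self, grid):
        W = point_mass(grid, 0.8)
        src = dedifferentiation_sources(W, 1.0, DediffRule("partial_repair", rho=0.5), grid)
        assert src.source_P[int(round(0.4 / grid.dx))] == pytest.approx(1.0 / grid.dx)
        assert grid.mass(src.source_P) == pytest.approx(-grid.mass(src.source_W), rel=1e-12)

    def test_state_dependent_conserves_cell_number(self, grid, random_density):
        rule = DediffRule(
            "state_dependent",
            rho_min=0.5,
            rho_max=0.9,
            shape=lambda x: 1.0 - x / 2.0,
        )
        src = dedifferentiation_sources(random_density, 0.7, rule, grid)
        assert grid.mass(src.source_P) == pytest.approx(-grid.mass(src.source_W), rel=1e-12)
        # gain moment is the retention-weighted loss moment
        x = grid.nodes
        loss = 0.7 * random_density
        expected_moment = grid.dx * (rule.retention(x) * x * loss).sum()
        assert grid.first_moment(src.source_P) == pytest.approx(expected_moment, rel=1e-12)

    def test_variant_equivalence_at_full_retention(self, grid, random_density):
        variants = [
            DediffRule("constant"),
            DediffRule("threshold", x_c=0.0),
            DediffRule("partial_repair", rho=1.0),
        ]
        outs = [dedifferentiation_sources(random_density, 0.03, v, grid) for v in variants]
        for other in outs[1:]:
            assert np.allclose(outs[0].source_P, other.source_P)
            assert np.allclose(outs[0].source_W, other.source_W)

    def test_kernel_loss_form_sheds_post_repair_profile(self, grid, random_density):
        local = dedifferentiation_sources(random_density, 0.1, DediffRule("partial_repair", rho=0.5), grid)
        kernel = dedifferentiation_sources(
            random_density, 0.1, DediffRule("partial_repair", rho=0.5, loss_form="kernel"), grid
        )
        assert np.allclose(kernel.source_W, -kernel.source_P)
        assert np.allclose(kernel.source_P, local.source_P)
        assert grid.mass(kernel.source_W) == pytest.approx(grid.mass(local.source_W), rel=1e-12)

    def test_complete_repair_deposits_at_zero_damage(self, grid, random_density):
        src = dedifferentiation_sources(random_density, 1.0, DediffRule("partial_repair", rho=0.0), grid)
        assert np.count_nonzero(src.source_P) == 1
        assert src.source_P[0] * grid.dx == pytest.approx(-grid.mass(src.source_W), rel=1e-12)
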