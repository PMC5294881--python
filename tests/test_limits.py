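import numpy as np
import pytest
from scipy.stats import binom

from adaptci import (
    cp_binomial_lower,
    cp_binomial_two_sided,
    enumerate_space,
    limit_table,
    lower_limit,
    omega_probability,
    omega_rr,
    tail_set,
)
from adaptci.limits import ORDERING_NAMES
from conftest import point


# --- independent oracles -----------------------------------------------------

def _cp_lower_oracle(x, n, alpha, tol=1e-10):
    """Bisection on the exact binomial tail P(X >= x | n, pi) = alpha."""
    if x == 0:
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if binom.sf(x - 1, n, mid) < alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _omega_prob_oracle(space, omega, pi):
    """Direct product-of-binomials sum, independent of the package vectors."""
    design = space.design
    total = 0.0
    for p in omega:
        if p.x2 is None:
            total += binom.pmf(p.x1, design.n1, pi)
        else:
            total += binom.pmf(p.x1, design.n1, pi) * binom.pmf(
                p.x2, design.n2[p.x1], pi
            )
    return total


def _grid_prob_oracle(space, omega, grid):
    design = space.design
    total = np.zeros_like(grid)
    for p in omega:
        if p.x2 is None:
            total += binom.pmf(p.x1, design.n1, grid)
        else:
            total += binom.pmf(p.x1, design.n1, grid) * binom.pmf(
                p.x2, design.n2[p.x1], grid
            )
    return total


def _lower_limit_oracle(space, omega, alpha, step=1e-5):
    """Dense-grid scan for the first pi with P(omega|pi) > alpha, refined by
    predicate bisection within the bracketing grid cell."""
    grid = np.arange(0.0, 1.0 + step, step)
    vals = _grid_prob_oracle(space, omega, grid)
    above = np.nonzero(vals > alpha)[0]
    if above.size == 0 or above[0] == 0:
        return 0.0 if above.size else 1.0
    lo, hi = grid[above[0] - 1], grid[above[0]]
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _omega_prob_oracle(space, omega, mid) > alpha:
            hi = mid
        else:
            lo = mid
    return hi


# --- Clopper-Pearson ---------------------------------------------------------

class TestCPBinomial:
    def test_zero_successes_give_zero_lower_limit(self):
        for n in (1, 5, 22):
            assert cp_binomial_lower(0, n, 0.05) == 0.0

    def test_all_successes_closed_form(self):
        # P(X = n | n, L) = L**n = alpha
        assert cp_binomial_lower(2, 2, 0.05) == pytest.approx(np.sqrt(0.05), abs=1e-12)
        assert cp_binomial_lower(7, 7, 0.05) == pytest.approx(0.05 ** (1 / 7), abs=1e-12)

    @pytest.mark.parametrize("x, n", [(11, 22), (1, 10), (6, 9)])
    def test_lower_matches_tail_bisection_oracle(self, x, n):
        assert cp_binomial_lower(x, n, 0.05) == pytest.approx(
            _cp_lower_oracle(x, n, 0.05), abs=1e-8
        )

    def test_two_sided_endpoints(self):
        lo, hi = cp_binomial_two_sided(0, 10, 0.95)
        assert lo == 0.0
        lo, hi = cp_binomial_two_sided(10, 10, 0.95)
        assert hi == 1.0

    def test_two_sided_matches_oracle_both_sides(self):
        lo, hi = cp_binomial_two_sided(11, 22, 0.95)
        assert lo == pytest.approx(_cp_lower_oracle(11, 22, 0.025), abs=1e-8)
        # upper limit mirrors: P(X <= x | n, U) = tail
        from scipy.stats import beta

        assert hi == pytest.approx(beta.ppf(0.975, 12, 11), abs=1e-12)
        assert lo < 11 / 22 < hi

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cp_binomial_lower(5, 3, 0.05)
        with pytest.raises(ValueError):
            cp_binomial_lower(1, 3, 1.5)


# --- confidence-set probability and inversion --------------------------------

class TestOmegaProbability:
    def test_whole_space_is_one(self, toy_space):
        for pi in (0.1, 0.5, 0.9):
            assert omega_probability(toy_space, toy_space.points, pi) == pytest.approx(1.0)

    def test_toy_g3_is_pi_squared(self, toy_space):
        for pi in (0.2, 0.7):
            assert omega_probability(toy_space, toy_space.g3, pi) == pytest.approx(pi**2)

    def test_tail_probability_equals_p_value_at_pi0(self, toy_space):
        theta = tail_set(toy_space, point(toy_space, 1, 1))
        assert omega_probability(toy_space, theta, 0.5) == pytest.approx(0.625)


class TestLowerLimit:
    def test_entire_space_gives_zero(self, toy_space):
        assert lower_limit(toy_space, toy_space.points, 0.05) == 0.0

    def test_toy_g3_closed_form(self, toy_space):
        got = lower_limit(toy_space, toy_space.g3, 0.05)
        assert got == pytest.approx(np.sqrt(0.05), abs=1e-8)

    def test_toy_tail_matches_oracle(self, toy_space):
        theta = tail_set(toy_space, point(toy_space, 1, 1))
        got = lower_limit(toy_space, theta, 0.05)
        assert got == pytest.approx(_lower_limit_oracle(toy_space, theta, 0.05), abs=1e-6)

    def test_root_verification(self, generated_designs):
        # |P(omega | L) - alpha| small whenever 0 < L < 1
        for design in generated_designs[:6]:
            space = enumerate_space(design)
            for p in space.g2:
                omega = omega_rr(space, p)
                lim = lower_limit(space, omega, 0.05)
                if 0.0 < lim < 1.0:
                    assert omega_probability(space, omega, lim) == pytest.approx(
                        0.05, abs=1e-6
                    )

    def test_oracle_equivalence_on_tiny_designs(self, tiny_designs):
        for design in tiny_designs[:6]:
            space = enumerate_space(design)
            for name in ("RR", "PV", "RR-B"):
                table = limit_table(space, name, 0.05)
                from adaptci import ordered_space

                ordered = ordered_space(space, name, alpha=0.05)
                for p in space.points:
                    expected = _lower_limit_oracle(space, ordered.omega(p), 0.05)
                    assert table[p] == pytest.approx(expected, abs=1e-6), (design, p)

    def test_empty_omega_rejected(self, toy_space):
        with pytest.raises(ValueError):
            lower_limit(toy_space, [], 0.05)


class TestLimitTable:
    def test_stage1_limits_equal_cp_binomial(self, generated_designs):
        for design in generated_designs[:8]:
            space = enumerate_space(design)
            for name in ORDERING_NAMES:
                table = limit_table(space, name, 0.05)
                for p in list(space.g1) + list(space.g3):
                    assert table[p] == pytest.approx(
                        cp_binomial_lower(p.x1, design.n1, 0.05), abs=1e-8
                    )

    def test_full_response_limit_closed_form(self, generated_designs):
        for design in generated_designs[:10]:
            if not design.has_efficacy_stop:
                continue
            space = enumerate_space(design)
            table = limit_table(space, "PV", 0.05)
            top = [p for p in space.g3 if p.x1 == design.n1][0]
            assert table[top] == pytest.approx(0.05 ** (1 / design.n1), abs=1e-8)

    def test_limits_monotone_in_ordering(self, generated_designs):
        # Omega(p) subset of Omega(q) implies L(p) >= L(q)
        for design in generated_designs[:6]:
            space = enumerate_space(design)
            for name in ("PV", "RR-B"):
                from adaptci import ordered_space

                ordered = ordered_space(space, name, alpha=0.05)
                table = limit_table(space, name, 0.05)
                pts = sorted(space.points, key=lambda p: len(ordered.omega(p)))
                lims = [table[p] for p in pts]
                assert np.all(np.diff(lims) <= 1e-10)

    def test_rr_limits_dominate_pv_limits(self, generated_designs):
        # pointwise consequence of the tail-area containment
        for design in generated_designs[:10]:
            space = enumerate_space(design)
            t_rr = limit_table(space, "RR", 0.05)
            t_pv = limit_table(space, "PV", 0.05)
            for p in space.points:
                assert t_rr[p] >= t_pv[p] - 1e-9

    def test_exact_flag(self, toy_space):
        assert limit_table(toy_space, "RR", 0.05).exact is False
        assert limit_table(toy_space, "PV", 0.05).exact is True

    def test_csv_dump_columns(self, toy_space, tmp_path):
        import pandas as pd

        path = tmp_path / "limits.csv"
        limit_table(toy_space, "RR-B", 0.05).to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "x1", "x2", "group", "ordering", "lower_limit", "exact_flag"
        ]
        assert len(frame) == len(toy_space)
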