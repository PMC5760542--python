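"""Bifurcation toolkit: multi-start oracle, stability, continuation and
fold detection, validated on systems with closed-form answers."""

import numpy as np
import pytest

from meioswitch.bifurcation import (continue_branch, find_steady_states,
                                    jacobian_stability, subsystem_branch)

# cubic normal form dx/dt = p + x - x^3: folds at p = -/+ 2/(3 sqrt 3),
# x = +/- 1/sqrt(3) (where both f and f_x vanish)
FOLD_P = 2.0 / (3.0 * np.sqrt(3.0))


def cubic(y, p):
    return np.array([p + y[0] - y[0] ** 3])


class TestOracle:
    def test_known_roots_of_logistic(self):
        eqs = find_steady_states(lambda y: np.array([y[0] * (1 - y[0])]),
                                 [(-0.3, 1.3)], n_starts=20, seed=0)
        assert [round(float(e[0]), 9) for e in eqs] == [0.0, 1.0]

    def test_deterministic_given_seed(self):
        f = lambda y: cubic(y, 0.1)
        a = find_steady_states(f, [(-2, 2)], n_starts=15, seed=7)
        b = find_steady_states(f, [(-2, 2)], n_starts=15, seed=7)
        assert len(a) == len(b) == 3
        assert all(np.allclose(x, y) for x, y in zip(a, b))

    def test_no_equilibrium_returns_empty(self):
        eqs = find_steady_states(lambda y: np.array([1.0 + 0 * y[0]]),
                                 [(-1, 1)], n_starts=5, seed=0)
        assert eqs == []

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            find_steady_states(lambda y: y, [(-1, np.inf)])
        with pytest.raises(ValueError):
            find_steady_states(lambda y: y, [(-1, 1)], n_starts=0)


class TestStability:
    def test_linear_decay_is_stable(self):
        stable, eig = jacobian_stability(lambda y: -y, np.zeros(1))
        assert stable and eig[0].real == pytest.approx(-1.0)

    def test_logistic_origin_is_unstable(self):
        stable, eig = jacobian_stability(
            lambda y: np.array([y[0] * (1 - y[0])]), np.zeros(1))
        assert not stable and eig[0].real == pytest.approx(1.0, rel=1e-4)

    def test_non_equilibrium_rejected(self):
        with pytest.raises(ValueError, match="equilibrium"):
            jacobian_stability(lambda y: -y + 1.0, np.zeros(1))


@pytest.fixture(scope="module")
def cubic_branch():
    # start on the lower stable branch at p = -1
    x0 = min(r.real for r in np.roots([-1.0, 0.0, 1.0, -1.0])
             if abs(r.imag) < 1e-12)
    return continue_branch(cubic, "p", (-1.0, 1.0),
                           np.array([x0]), initial_step=2e-3,
                           max_step=0.02)


class TestContinuation:

    def test_folds_match_closed_form(self, cubic_branch):
        folds = sorted(bp.param for bp in cubic_branch.folds())
        assert len(folds) == 2
        assert folds[0] == pytest.approx(-FOLD_P, abs=2e-4)
        assert folds[1] == pytest.approx(FOLD_P, abs=2e-4)

    def test_stability_flips_only_at_folds(self, cubic_branch):
        br = cubic_branch
        flips = np.flatnonzero(br.stable[:-1] != br.stable[1:])
        assert len(flips) == 2
        fold_params = sorted(bp.param for bp in br.folds())
        flip_params = sorted(br.params[i] for i in flips)
        for fp, bp in zip(flip_params, fold_params):
            assert abs(fp - bp) < 0.02

    def test_middle_branch_is_unstable(self, cubic_branch):
        br = cubic_branch
        mid = (np.abs(br.states[:, 0]) < 0.5) & \
            (np.abs(br.params) < 0.3)
        assert mid.any()
        assert not br.stable[mid].any()

    def test_oracle_continuation_agreement(self, cubic_branch):
        """At 20 evenly spaced parameter values the multi-start oracle and
        the (Newton-refined) branch intersections coincide to 1e-5."""
        from scipy import optimize
        br = cubic_branch
        for p in np.linspace(-0.9, 0.9, 20):
            oracle = find_steady_states(lambda y: cubic(y, p),
                                        [(-2.0, 2.0)], n_starts=12, seed=1)
            xs = br.states_at(p)
            refined = sorted(
                float(optimize.root(lambda y: cubic(y, p), x).x[0])
                for x in xs)
            expect = sorted(float(e[0]) for e in oracle)
            assert len(refined) == len(expect)
            assert max(abs(a - b) for a, b in zip(refined, expect)) < 1e-5

    def test_bad_start_state_rejected(self):
        with pytest.raises(ValueError, match="equilibrium"):
            continue_branch(cubic, "p", (-1.0, 1.0), np.array([0.3]))


@pytest.mark.parametrize("direction", ["given"])
def test_subsystem_resting_branch_reaches_its_fold(meiosis_params,
                                                   direction):
    """The resting branch of the meiotic subsystem, continued in the
    Ste11 import rate under rich inputs, ends in a saddle-node (the
    ignition fold) and the branch carries an unstable (saddle) segment
    with a positive leading eigenvalue beyond it."""
    br = subsystem_branch(meiosis_params, "k_imste11", (0.1, 3.0),
                          initial_step=5e-3, max_step=0.05, max_points=250)
    folds = [bp.param for bp in br.folds()]
    assert folds, "no fold found on the resting branch"
    assert 0.5 < folds[0] < 1.5
    # beyond the fold the branch is a saddle: unstable points present
    assert (~br.stable).any()
    assert br.leading_real[~br.stable].max() > 0
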