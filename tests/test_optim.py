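"""Proximal operators against brute-force oracles; ADAM semantics; paths."""

import numpy as np
import pytest

from motifnet import autodiff as ad
from motifnet.optim import PathResult, ProxAdam, prox_l1, prox_mcp

_GOLD = np.longdouble(2) / (np.longdouble(1) + np.sqrt(np.longdouble(5)))


def numeric_prox(theta_hat, weight, lam, penalty, b=3.0):
    """Brute-force minimizer of weight/2 * (t - theta_hat)^2 + pen(t).

    ``weight`` plays the role of (sqrt(C) + delta) / lr, making the
    effective threshold lam / weight; grid scan plus golden-section polish
    in extended precision (a double-precision objective cannot localize a
    flat minimum better than ~sqrt(eps)), sharing no code with the closed
    forms under test.
    """
    theta_hat = np.longdouble(theta_hat)
    weight = np.longdouble(weight)
    lam = np.longdouble(lam)
    b = np.longdouble(b)

    def pen(t):
        a = abs(t)
        if penalty == "l1":
            return lam * a
        # MCP value: quadratic spline flattening out at b * lam
        if a <= b * lam:
            return lam * a - t * t / (2 * b)
        return b * lam * lam / 2

    def obj(t):
        return weight / 2 * (t - theta_hat) ** 2 + pen(t)

    lo, hi = -abs(theta_hat) - 1, abs(theta_hat) + 1
    grid = np.linspace(lo, hi, 20001, dtype=np.longdouble)
    t0 = grid[np.argmin([obj(t) for t in grid])]
    span = (hi - lo) / 20000
    a, d = t0 - 2 * span, t0 + 2 * span
    bb, cc = d - _GOLD * (d - a), a + _GOLD * (d - a)
    fb, fc = obj(bb), obj(cc)
    for _ in range(120):  # interval shrinks by 0.618 per step
        if fb < fc:
            d, cc, fc = cc, bb, fb
            bb = d - _GOLD * (d - a)
            fb = obj(bb)
        else:
            a, bb, fb = bb, cc, fc
            cc = a + _GOLD * (d - a)
            fc = obj(cc)
    best = bb if fb < fc else cc
    if obj(np.longdouble(0)) < obj(best):
        best = np.longdouble(0)
    return float(best)


class TestProxOperators:
    def test_l1_zero_penalty_is_identity(self, rng):
        theta = rng.normal(size=20)
        assert np.array_equal(prox_l1(theta, 0.0), theta)

    def test_l1_dead_zone_gives_exact_zero(self):
        assert prox_l1(np.array([0.3]), 0.5)[0] == 0.0

    def test_l1_shifts_by_threshold(self):
        assert prox_l1(np.array([-1.0]), 0.25)[0] == pytest.approx(-0.75)

    def test_mcp_identity_zone(self):
        # |theta| >= b * tau: unshrunk
        assert prox_mcp(np.array([0.7]), 0.2, b=3.0)[0] == pytest.approx(0.7)

    def test_mcp_dead_zone(self):
        assert prox_mcp(np.array([0.1]), 0.2, b=3.0)[0] == 0.0

    def test_mcp_middle_zone_hand_value(self):
        # b=3, tau=0.2, theta=0.4 -> min(3*0.2/2, 0.4) = 0.3
        assert prox_mcp(np.array([0.4]), 0.2, b=3.0)[0] == pytest.approx(0.3)

    def test_mcp_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            prox_mcp(np.array([1.0]), 0.1, b=1.0)

    @pytest.mark.parametrize("penalty", ["l1", "mcp"])
    def test_matches_numeric_minimizer(self, penalty, rng):
        """1000 random draws: the closed form solves the preconditioned
        penalized quadratic to 1e-8.

        Draws whose input sits within 1e-6 of a thresholding boundary are
        skipped: there the two minimizer branches are equal to float
        precision and either side is a correct answer.
        """
        draws = 1000
        theta_hat = rng.normal(scale=2.0, size=draws)
        weight = rng.uniform(0.2, 5.0, size=draws)  # (sqrt(C)+delta)/lr
        lam = rng.uniform(0.0, 1.5, size=draws)
        b = 3.0
        checked = 0
        for i in range(draws):
            tau = lam[i] / weight[i]
            if penalty == "mcp":
                # the scaled problem's concavity parameter is b * weight;
                # skip draws where it degenerates (operator requires > 1)
                b_eff = b * weight[i]
                if b_eff <= 1.0 + 1e-6:
                    continue
                boundaries = (tau, b_eff * tau)
                if any(abs(abs(theta_hat[i]) - x) < 1e-6 for x in boundaries):
                    continue
                want = numeric_prox(theta_hat[i], weight[i], lam[i], "mcp", b=b)
                got_i = prox_mcp(np.array([theta_hat[i]]), tau, b_eff)[0]
            else:
                if abs(abs(theta_hat[i]) - tau) < 1e-6:
                    continue
                want = numeric_prox(theta_hat[i], weight[i], lam[i], "l1")
                got_i = prox_l1(np.array([theta_hat[i]]), tau)[0]
            checked += 1
            assert got_i == pytest.approx(want, abs=1e-8)
        assert checked > 900  # boundary skips are rare

    def test_mcp_converges_to_l1_as_b_grows(self, rng):
        theta = rng.normal(scale=2.0, size=500)
        tau = rng.uniform(0.0, 1.0, size=500)
        assert np.allclose(
            prox_mcp(theta, tau, b=1e6), prox_l1(theta, tau), atol=1e-6
        )

    @pytest.mark.parametrize("penalty", ["l1", "mcp"])
    def test_monotone_and_nonexpansive(self, penalty, rng):
        xs = np.sort(rng.normal(scale=3.0, size=400))
        tau = 0.37
        out = prox_l1(xs, tau) if penalty == "l1" else prox_mcp(xs, tau, 3.0)
        diffs = np.diff(out)
        steps = np.diff(xs)
        assert np.all(diffs >= -1e-12)  # monotone
        # MCP is 1-Lipschitz outside the middle zone and b/(b-1)-Lipschitz
        # inside it; L1 is globally 1-Lipschitz
        lip = 1.0 if penalty == "l1" else 3.0 / 2.0
        assert np.all(diffs <= lip * steps + 1e-12)


class TestProxAdam:
    def test_zero_gradient_is_fixed_point(self):
        theta = ad.parameter(np.array([1.0, -2.0]))
        opt = ProxAdam({"w": theta}, lr=0.1)
        theta.grad = np.zeros(2)
        opt.step()
        assert np.array_equal(theta.data, [1.0, -2.0])

    def test_first_step_matches_hand_computation(self):
        theta = ad.parameter(np.array([0.5]))
        opt = ProxAdam({"w": theta}, lr=0.01)
        g = 0.3
        theta.grad = np.array([g])
        opt.step()
        mhat = g  # bias correction cancels on step 1
        vhat = g * g
        expected = 0.5 - 0.01 * mhat / (np.sqrt(vhat) + 1e-8)
        assert theta.data[0] == pytest.approx(expected, rel=1e-12)

    def test_identical_coordinates_update_identically(self):
        theta = ad.parameter(np.array([0.7, 0.7]))
        opt = ProxAdam({"w": theta}, lr=0.05)
        theta.grad = np.array([0.2, 0.2])
        opt.step()
        assert theta.data[0] == theta.data[1]

    def test_non_finite_gradient_names_parameter(self):
        theta = ad.parameter(np.array([1.0]))
        opt = ProxAdam({"bad": theta})
        theta.grad = np.array([np.nan])
        with pytest.raises(FloatingPointError, match="bad"):
            opt.step()

    def test_penalty_applies_only_to_designated_tensor(self):
        coef = ad.parameter(np.array([1e-4]))
        other = ad.parameter(np.array([1e-4]))
        opt = ProxAdam({"coef": coef, "other": other}, lr=0.01,
                       penalty="l1", lam=10.0)
        coef.grad = np.array([1e-5])
        other.grad = np.array([1e-5])
        opt.step()
        assert coef.data[0] == 0.0  # thresholded to exact zero
        assert other.data[0] != 0.0

    def test_invalid_settings_rejected(self):
        theta = ad.parameter(np.zeros(1))
        with pytest.raises(ValueError):
            ProxAdam({"w": theta}, penalty="ridge")
        with pytest.raises(ValueError):
            ProxAdam({"w": theta}, penalty="mcp", b_mcp=0.5)
        with pytest.raises(ValueError):
            ProxAdam({"w": theta}, lam=-1.0)


class TestPathResult:
    def _result(self, vals, supports):
        k = len(vals)
        return PathResult(
            lambdas=np.logspace(-3, 0, k),
            coefs=[np.ones((1, s)) if s else np.zeros((1, 1)) for s in supports],
            val_loss=np.asarray(vals, float),
            support_size=np.asarray(supports),
        )

    def test_best_index_strict_minimum(self):
        res = self._result([0.5, 0.4, 0.45], [3, 2, 1])
        assert res.best_index() == 1

    def test_best_index_parsimony_prefers_sparser(self):
        res = self._result([0.400, 0.401, 0.402, 0.9], [5, 4, 2, 0])
        assert res.best_index(tol=0.02) == 2

    def test_descending_grid_rejected(self):
        from motifnet.optim import run_path

        with pytest.raises(ValueError):
            run_path(None, None, None, np.array([1.0, 0.5]))
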