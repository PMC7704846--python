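"""Single-decision mathematics of the dynamic prospect-theory bidder.

At every clock step the agent chooses between bidding now (a riskless
prospect: gain the item's perceived value, lose the current price) and
waiting one step (the same prospect at the next, lower price, discounted by
the probability that a competitor bids first).  Utilities follow the
standard two-branch power form with loss aversion; the risk of waiting is
filtered through an inverse-S probability weighting function; the two
weighted utilities are converted to a bid probability by a softmax rule.

Two documented corrections to the source equations are applied by default
and are switchable for audit:

* the probability weighting function uses the canonical two-parameter form
  ``p^e / (p^e + (1-p)^e)^(1/e)`` (the printed denominator is degenerate);
* the softmax exponent is positive, so higher weighted utility means higher
  choice probability (``softmax_sign="corrected"``; ``"as_printed"`` keeps
  the sign-flipped variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "ProspectParams",
    "OpponentBelief",
    "utility",
    "weight",
    "competitor_hazard",
    "net_utility_now",
    "net_utility_wait",
    "bid_probability",
]


@dataclass(frozen=True)
class ProspectParams:
    """Decision parameters of one bidder.

    ``alpha``/``beta`` are the gain/loss utility exponents, ``lam`` the
    loss-aversion coefficient, ``gamma``/``delta`` the weighting exponents
    for gain-framed and loss-framed prospects, ``c`` the softmax
    sensitivity and ``V`` the perceived-value multiplier that maps the
    anchor price to the item's subjective dollar value.

    ``value_anchor`` selects the dollar anchor for perceived value:
    ``"start_price"`` (item worth ``V * C(0)``, the default — the only
    anchor that reproduces the published simulation behaviour) or
    ``"current_price"`` (worth ``V * C(t)``).
    """

    alpha: float = 0.88
    beta: float = 0.88
    lam: float = 2.25
    gamma: float = 0.61
    delta: float = 0.69
    c: float = 1.0
    V: float = 1.0
    softmax_sign: str = "corrected"
    value_anchor: str = "start_price"
    wait_cost_time: str = "next"

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1 and 0 < self.beta <= 1):
            raise ValueError("alpha and beta must lie in (0, 1]")
        if self.lam < 1:
            raise ValueError("loss-aversion coefficient lam must be >= 1")
        # below ~0.28 the one-parameter weighting form loses monotonicity
        if not (0.28 < self.gamma <= 1 and 0.28 < self.delta <= 1):
            raise ValueError("gamma and delta must lie in (0.28, 1]")
        if self.c < 0:
            raise ValueError("softmax sensitivity c must be >= 0")
        if self.V <= 0:
            raise ValueError("perceived-value multiplier V must be positive")
        if self.softmax_sign not in ("corrected", "as_printed"):
            raise ValueError(f"unknown softmax_sign {self.softmax_sign!r}")
        if self.value_anchor not in ("start_price", "current_price"):
            raise ValueError(f"unknown value_anchor {self.value_anchor!r}")
        # "next" prices the wait prospect at C(t+dt) (the stated rationale:
        # waiting is better because the price will have dropped); "current"
        # keeps C(t) as displayed in the original expression.
        if self.wait_cost_time not in ("next", "current"):
            raise ValueError(f"unknown wait_cost_time {self.wait_cost_time!r}")


@dataclass(frozen=True)
class OpponentBelief:
    """Believed bid-time distribution of each competitor: N(mu, sigma)
    truncated to the auction window [0, duration] and renormalised."""

    mu: float = 2.01
    sigma: float = 0.97
    n_opponents: int = 2
    duration: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_opponents < 1:
            raise ValueError("n_opponents must be >= 1")

    def cdf(self, t) -> np.ndarray:
        """Truncated-normal CDF of one competitor's bid time."""
        lo = stats.norm.cdf(0.0, self.mu, self.sigma)
        hi = stats.norm.cdf(self.duration, self.mu, self.sigma)
        tt = np.clip(np.asarray(t, dtype=float), 0.0, self.duration)
        return (stats.norm.cdf(tt, self.mu, self.sigma) - lo) / (hi - lo)


def utility(x, params: ProspectParams) -> np.ndarray | float:
    """Two-branch power utility: gains ``x^alpha``, losses ``-lam*(-x)^beta``."""
    xa = np.asarray(x, dtype=float)
    out = np.where(
        xa > 0,
        np.abs(xa) ** params.alpha,
        np.where(xa < 0, -params.lam * np.abs(xa) ** params.beta, 0.0),
    )
    return out if xa.ndim else float(out)


def weight(p, exponent) -> np.ndarray | float:
    """Inverse-S probability weighting ``p^e / (p^e + (1-p)^e)^(1/e)``.

    Identity at ``e = 1``; for ``e < 1`` overweights small and underweights
    large probabilities.  ``p`` must lie in [0, 1].
    """
    pa = np.asarray(p, dtype=float)
    if np.any((pa < 0) | (pa > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    e = np.asarray(exponent, dtype=float)
    num = pa**e
    out = num / (num + (1.0 - pa) ** e) ** (1.0 / e)
    return out if (pa.ndim or e.ndim) else float(out)


def competitor_hazard(
    F: Callable[[float], float] | np.ndarray,
    t,
    dt: float,
    n_opponents: int = 2,
) -> np.ndarray | float:
    """Probability that at least one of ``n_opponents`` bids in (t, t+dt].

    With window mass ``q = F(t+dt) - F(t)`` this is ``1 - (1-q)^n``.
    ``F`` may be a callable CDF or a pre-evaluated pair is not accepted;
    pass :meth:`OpponentBelief.cdf` or any non-decreasing CDF.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = np.asarray(F(np.asarray(t) + dt)) - np.asarray(F(t))
    if np.any(q < -1e-12):
        raise ValueError("opponent CDF decreases over the window")
    q = np.clip(q, 0.0, 1.0)
    out = 1.0 - (1.0 - q) ** n_opponents
    return out if out.ndim else float(out)


def net_utility_now(P, cost, params: ProspectParams) -> np.ndarray | float:
    """Riskless utility of bidding at the current price: U(P) + U(-cost)."""
    return utility(P, params) + utility(-np.asarray(cost, dtype=float), params)


def net_utility_wait(P, cost_next, r, params: ProspectParams) -> np.ndarray | float:
    """Weighted utility of waiting one step.

    The wait prospect succeeds with probability ``1 - r`` and then yields
    ``U(P) + U(-C(t+dt))`` (the price after the next decrement); being
    beaten yields zero.  The weighting exponent follows the frame of the
    bracketed net utility: ``gamma`` when it is a net gain, ``delta`` when
    a net loss.
    """
    ra = np.asarray(r, dtype=float)
    if np.any((ra < 0) | (ra > 1)):
        raise ValueError("competitor hazard r must lie in [0, 1]")
    bracket = np.asarray(net_utility_now(P, cost_next, params))
    e = np.where(bracket >= 0, params.gamma, params.delta)
    out = weight(1.0 - ra, e) * bracket
    return out if out.ndim else float(out)


def bid_probability(u_now, u_wait, c: float, sign: str = "corrected"):
    """Softmax choice rule: Pr(bid now) from the two weighted utilities.

    ``corrected`` uses a positive exponent (probability increases with an
    option's utility); ``as_printed`` retains the sign-flipped original.
    Computed via the logistic function, so it is stable for large ``|c*u|``
    and satisfies Pr(now) + Pr(wait) = 1 exactly.
    """
    if c < 0:
        raise ValueError("softmax sensitivity c must be >= 0")
    diff = c * (np.asarray(u_now, dtype=float) - np.asarray(u_wait, dtype=float))
    if sign == "as_printed":
        diff = -diff
    elif sign != "corrected":
        raise ValueError(f"unknown softmax sign convention {sign!r}")
    # canonical symmetric evaluation so Pr(now) + Pr(wait) = 1 *exactly*
    # under argument swap, not just to rounding error
    diff = np.asarray(diff, dtype=float)
    out = np.where(diff >= 0, expit(diff), 1.0 - expit(-diff))
    return out if out.ndim else float(out)
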