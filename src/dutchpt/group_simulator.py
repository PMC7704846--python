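"""Bid-time distributions and Monte-Carlo simulation of three-bidder auctions.

The per-step softmax bid probabilities of :mod:`dutchpt.prospect_agent` form
a discrete-time hazard sequence.  This module converts that hazard into a
density/CDF over bid steps, composes independent bidders through the
minimum-order-statistic CDF ``1 - (1 - G)^n``, and simulates auctions where
the earliest bidder wins at the current clock price.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .auction_env import PriceClock, sample_start_price
from .prospect_agent import (
    OpponentBelief,
    ProspectParams,
    bid_probability,
    competitor_hazard,
    net_utility_now,
    net_utility_wait,
)

__all__ = [
    "BidDistribution",
    "AuctionOutcome",
    "step_hazards",
    "bid_time_distribution",
    "winning_time_cdf",
    "simulate_auctions",
    "summarize_simulation",
    "outcomes_to_frame",
]


@dataclass(frozen=True)
class BidDistribution:
    """Discrete bid-time distribution of a single bidder.

    ``hazards[k]`` is the probability of bidding at step k+1 given no bid
    yet; ``density`` and ``cdf`` follow by the product-form transformation
    ``g_k = h_k * prod_{j<k}(1 - h_j)``; ``survival_final`` is the
    probability of never bidding before the clock reaches $0.
    """

    hazards: np.ndarray
    density: np.ndarray
    cdf: np.ndarray
    survival_final: float

    def __post_init__(self) -> None:
        total = self.density.sum() + self.survival_final
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"density + survival must total 1, got {total}")


@dataclass(frozen=True)
class AuctionOutcome:
    """Result of one simulated auction; ``winner`` is None when censored."""

    auction_id: int
    condition: str
    start_price: float
    unit_quantity: int
    winning_step: int | None
    winning_price: float | None
    winner: int | None
    n_tied: int = 0


def step_hazards(
    params: ProspectParams,
    belief: OpponentBelief,
    clock_dt: float,
    start_prices,
    duration: float = 5.0,
) -> np.ndarray:
    """Per-step bid probabilities for one bidder.

    Vectorised over auctions: ``start_prices`` may be a scalar (returns a
    1-D array over steps) or shape ``(m,)`` (returns ``(m, n_steps)``).

    At the final step the clock price is $0 and the wait prospect keeps the
    zero cost, so the only deterrent to bidding is the residual competitor
    risk weighting.
    """
    s = np.atleast_1d(np.asarray(start_prices, dtype=float))
    n = round(duration / clock_dt)
    k = np.arange(1, n + 1)
    t = k * clock_dt
    price_now = s[:, None] * (1.0 - k / n)
    price_next = np.maximum(s[:, None] * (1.0 - (k + 1) / n), 0.0)

    r = competitor_hazard(belief.cdf, t, clock_dt, belief.n_opponents)

    if params.value_anchor == "start_price":
        perceived = params.V * s[:, None] * np.ones_like(price_now)
    else:
        perceived = params.V * price_now

    wait_cost = price_next if params.wait_cost_time == "next" else price_now
    u_now = net_utility_now(perceived, price_now, params)
    u_wait = net_utility_wait(perceived, wait_cost, r[None, :], params)
    if not (np.all(np.isfinite(u_now)) and np.all(np.isfinite(u_wait))):
        bad = int(np.argwhere(~(np.isfinite(u_now) & np.isfinite(u_wait)))[0][1]) + 1
        raise FloatingPointError(f"non-finite utility at step {bad}")
    h = bid_probability(u_now, u_wait, params.c, params.softmax_sign)
    return h if np.ndim(start_prices) else h[0]


def bid_time_distribution(
    params: ProspectParams,
    belief: OpponentBelief,
    clock: PriceClock,
) -> BidDistribution:
    """Hazard, density, CDF and final survival of one bidder's bid time."""
    h = step_hazards(params, belief, clock.dt, clock.start_price, clock.duration)
    no_bid_before = np.concatenate([[1.0], np.cumprod(1.0 - h)])
    g = h * no_bid_before[:-1]
    G = np.cumsum(g)
    return BidDistribution(
        hazards=h, density=g, cdf=G, survival_final=float(no_bid_before[-1])
    )


def winning_time_cdf(G, n_players: int = 3) -> np.ndarray:
    """CDF of the earliest bid among ``n_players`` i.i.d. bidders."""
    return 1.0 - (1.0 - np.asarray(G, dtype=float)) ** n_players


def _resolve_params(
    params_by_player, n_players: int
) -> list[ProspectParams]:
    if isinstance(params_by_player, ProspectParams):
        return [params_by_player] * n_players
    params = list(params_by_player)
    if len(params) != n_players:
        raise ValueError(f"expected {n_players} parameter sets, got {len(params)}")
    return params


def simulate_auctions(
    params_by_player: ProspectParams | Sequence[ProspectParams],
    belief: OpponentBelief,
    n_auctions: int,
    seed: int | np.random.Generator,
    dt: float = 0.5,
    duration: float = 5.0,
    start_price_range: tuple[float, float] = (80.0, 120.0),
    start_price: float | None = None,
    unit_quantity: int = 100,
    condition: str | None = None,
    n_players: int = 3,
    chunk_size: int = 20_000,
) -> list[AuctionOutcome]:
    """Monte-Carlo simulate ``n_auctions`` independent group auctions.

    Each active player bids at step k with their hazard probability; the
    earliest bidder wins at the post-decrement clock price, with
    simultaneous bids broken uniformly at random (``n_tied`` records how
    many bid at the winning step).  Auctions where nobody bids are kept as
    censored records with ``winner=None``.

    ``start_price`` fixes the clock start; otherwise each auction draws
    uniformly from ``start_price_range``.
    """
    if n_auctions < 1:
        raise ValueError("n_auctions must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    params = _resolve_params(params_by_player, n_players)
    homogeneous = all(p is params[0] for p in params)
    label = condition or ("discrete" if dt >= 0.5 else "continuous")
    n_steps = round(duration / dt)

    outcomes: list[AuctionOutcome] = []
    for lo in range(0, n_auctions, chunk_size):
        m = min(chunk_size, n_auctions - lo)
        if start_price is None:
            starts = sample_start_price(start_price_range, rng, size=m)
        else:
            starts = np.full(m, float(start_price))

        if homogeneous:
            h = step_hazards(params[0], belief, dt, starts, duration)
            haz = np.broadcast_to(h[:, None, :], (m, n_players, n_steps))
        else:
            haz = np.stack(
                [step_hazards(p, belief, dt, starts, duration) for p in params],
                axis=1,
            )

        bids = rng.random((m, n_players, n_steps)) < haz
        any_bid = bids.any(axis=2)
        first = np.where(any_bid, bids.argmax(axis=2), n_steps)  # 0-based step
        win_step = first.min(axis=1)
        decided = win_step < n_steps
        tied = first == win_step[:, None]
        n_tied = tied.sum(axis=1)
        # uniform tie-break: highest random key among tied players
        keys = np.where(tied, rng.random((m, n_players)), -1.0)
        winner = keys.argmax(axis=1)

        prices = starts * (1.0 - (win_step + 1) / n_steps)
        for i in range(m):
            if decided[i]:
                outcomes.append(
                    AuctionOutcome(
                        auction_id=lo + i,
                        condition=label,
                        start_price=float(starts[i]),
                        unit_quantity=unit_quantity,
                        winning_step=int(win_step[i]) + 1,
                        winning_price=float(prices[i]),
                        winner=int(winner[i]) + 1,
                        n_tied=int(n_tied[i]),
                    )
                )
            else:
                outcomes.append(
                    AuctionOutcome(
                        auction_id=lo + i,
                        condition=label,
                        start_price=float(starts[i]),
                        unit_quantity=unit_quantity,
                        winning_step=None,
                        winning_price=None,
                        winner=None,
                        n_tied=0,
                    )
                )
    return outcomes


def outcomes_to_frame(outcomes: Sequence[AuctionOutcome]) -> pd.DataFrame:
    """Tabulate outcomes; censored auctions keep NaN step/price/winner."""
    return pd.DataFrame(
        {
            "auction_id": [o.auction_id for o in outcomes],
            "condition": [o.condition for o in outcomes],
            "start_price": [o.start_price for o in outcomes],
            "unit_quantity": [o.unit_quantity for o in outcomes],
            "winning_step": [o.winning_step for o in outcomes],
            "winning_price": [o.winning_price for o in outcomes],
            "winner": [o.winner for o in outcomes],
            "n_tied": [o.n_tied for o in outcomes],
        }
    )


def summarize_simulation(outcomes: Sequence[AuctionOutcome]) -> pd.DataFrame:
    """Per-condition mean/SD of winning price and step over decided auctions.

    Censored (no-bid) auctions are excluded from the moments and counted in
    ``n_censored``.  Raises ``ValueError`` when every auction is censored.
    """
    df = outcomes_to_frame(outcomes)
    decided = df[df["winner"].notna()]
    if decided.empty:
        raise ValueError("no decided auctions to summarise (all censored)")
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        dec = grp[grp["winner"].notna()]
        rows.append(
            {
                "condition": cond,
                "n_auctions": len(grp),
                "n_decided": len(dec),
                "n_censored": len(grp) - len(dec),
                "mean_price": dec["winning_price"].mean(),
                "sd_price": dec["winning_price"].std(ddof=1),
                "mean_step": dec["winning_step"].mean(),
                "sd_step": dec["winning_step"].std(ddof=1),
                "tie_rate": (dec["n_tied"] > 1).mean(),
            }
        )
    return pd.DataFrame(rows)
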