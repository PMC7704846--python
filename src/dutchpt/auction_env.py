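"""Dutch-auction environment: price clock, stimulus sampling, experiment design.

The auction clock starts at a sampled dollar price and falls linearly to $0
over a fixed duration.  Two step-rate conditions are supported: a coarse
clock (dt = 0.5 s, 10 decrements) and a fine clock (dt = 0.05 s, 100
decrements).  Step indexing is 1-based and the price is evaluated *after*
the step's decrement, so the first biddable price is ``start * (1 - 1/n)``
and the final step's price is exactly $0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriceClock",
    "ExperimentDesign",
    "price_at",
    "sample_start_price",
    "sample_unit_quantity",
    "normalize_discrete_step",
    "STEP_NORMALISATION_FACTOR",
]

#: Multiplier applied to coarse-clock winning steps (1..10) so they can be
#: plotted against fine-clock steps (1..100).  An I/O-level convention only;
#: never used inside the decision model.
STEP_NORMALISATION_FACTOR = 11


@dataclass(frozen=True)
class PriceClock:
    """Linear descending price schedule C(t).

    Parameters
    ----------
    start_price
        Dollar price at t = 0.  Must be positive.
    duration
        Auction length in seconds.
    dt
        Seconds between price decrements; ``n_steps = round(duration / dt)``.
    """

    start_price: float
    duration: float = 5.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if self.start_price <= 0:
            raise ValueError(f"start_price must be positive, got {self.start_price}")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration/dt = {n} is not an integer step count")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def step_drop(self) -> float:
        """Constant dollar decrement per step."""
        return self.start_price / self.n_steps

    def times(self) -> np.ndarray:
        """Decision times t_k = k*dt for k = 1..n_steps."""
        return self.dt * np.arange(1, self.n_steps + 1)

    def prices(self) -> np.ndarray:
        """Post-decrement prices at every step, ending at exactly 0."""
        k = np.arange(1, self.n_steps + 1)
        return self.start_price * (1.0 - k / self.n_steps)

    def price_at(self, step_index: int) -> float:
        return price_at(self, step_index)


def price_at(clock: PriceClock, step_index: int) -> float:
    """Price after the ``step_index``-th decrement (1-based).

    Raises
    ------
    IndexError
        If ``step_index`` is outside ``1..n_steps``.
    """
    n = clock.n_steps
    if not 1 <= step_index <= n:
        raise IndexError(f"step_index {step_index} out of range 1..{n}")
    return clock.start_price * (1.0 - step_index / n)


@dataclass(frozen=True)
class ExperimentDesign:
    """Block/trial structure and stimulus ranges of one experiment.

    Defaults mirror the in-lab sessions: 11 three-person groups, 5 scored
    blocks (plus one practice block) of 12 trials, start prices uniform on
    [$50, $150], a $250 budget and a 500-unit warehouse per block.
    """

    n_groups: int = 11
    players_per_group: int = 3
    n_blocks: int = 5
    trials_per_block: int = 12
    start_price_range: tuple[float, float] = (50.0, 150.0)
    unit_mode: str = "fixed"  # "fixed" -> 100 units; "uniform" -> [unit_low, unit_high]
    unit_range: tuple[int, int] = (50, 150)
    budget: float = 250.0
    warehouse_capacity: int = 500
    include_practice: bool = True

    def __post_init__(self) -> None:
        for name in ("n_groups", "players_per_group", "n_blocks", "trials_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.start_price_range
        if not lo < hi:
            raise ValueError(f"start_price_range low must be < high, got {lo}, {hi}")
        if self.unit_mode not in ("fixed", "uniform"):
            raise ValueError(f"unknown unit_mode {self.unit_mode!r}")


def sample_start_price(
    price_range: tuple[float, float], rng: np.random.Generator, size: int | None = None
):
    """Uniform start-price draw(s) on ``[low, high]`` (real-valued dollars)."""
    lo, hi = price_range
    if not lo < hi:
        raise ValueError(f"price range low must be < high, got {lo}, {hi}")
    return rng.uniform(lo, hi, size=size)


def sample_unit_quantity(
    mode: str,
    rng: np.random.Generator,
    unit_range: tuple[int, int] = (50, 150),
    size: int | None = None,
):
    """Units offered on one trial: the constant 100 or a uniform integer draw."""
    if mode == "fixed":
        return 100 if size is None else np.full(size, 100, dtype=int)
    if mode == "uniform":
        lo, hi = unit_range
        return (
            int(rng.integers(lo, hi + 1))
            if size is None
            else rng.integers(lo, hi + 1, size=size)
        )
    raise ValueError(f"unknown unit mode {mode!r}")


def normalize_discrete_step(step: int) -> int:
    """Map a coarse-clock step 1..10 to the comparison scale (×11 -> 11..110)."""
    if not 1 <= step <= 10:
        raise ValueError(f"discrete step must be in 1..10, got {step}")
    return step * STEP_NORMALISATION_FACTOR
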