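"""Experiment-shaped synthetic trial logs.

Wraps the group simulator in the in-lab session structure (groups x
step-rate conditions x blocks x trials) and writes/reads the platform's
CSV dialect, so the whole analysis pipeline can run without any download.
Budget and warehouse numbers are post-hoc bookkeeping — the model agents
ignore them — unless ``enforce_capacity`` is set, in which case a player
whose warehouse is full sits out the remaining auctions of the block.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .auction_env import (
    ExperimentDesign,
    PriceClock,
    normalize_discrete_step,
    sample_unit_quantity,
)
from .group_simulator import simulate_auctions
from .prospect_agent import OpponentBelief, ProspectParams

__all__ = [
    "TrialRecord",
    "generate_experiment",
    "write_trials",
    "read_trials",
    "records_to_frame",
    "write_manifest",
]

CSV_COLUMNS = [
    "group_id",
    "block",
    "trial",
    "condition",
    "start_price",
    "unit_quantity",
    "winning_step",
    "winning_step_norm",
    "winning_price",
    "winner_id",
    "remaining_funds",
    "warehouse_fill",
]

_PSEUDONYM_POOL = [
    "Falcon", "Heron", "Lynx", "Otter", "Raven", "Swift", "Badger", "Crane",
    "Dingo", "Egret", "Gecko", "Ibis", "Jackal", "Kestrel", "Marten", "Numbat",
    "Osprey", "Pika", "Quokka", "Rosella", "Skink", "Tern", "Urchin", "Vole",
    "Wombat", "Yabby", "Zebra", "Bilby", "Corella", "Dunnart",
]


@dataclass(frozen=True)
class TrialRecord:
    """One auction's outcome row in the platform CSV dialect.

    Censored trials (price reached $0 with no bid) carry ``None`` in the
    winning fields.  ``winning_step_norm`` applies the x11 comparison rule
    for the discrete condition and is the raw step otherwise.
    """

    group_id: int
    block: int
    trial: int
    condition: str
    start_price: float
    unit_quantity: int
    winning_step: int | None
    winning_step_norm: int | None
    winning_price: float | None
    winner_id: str | None
    remaining_funds: float | None
    warehouse_fill: int | None


def _pseudonyms(group_id: int, seed: int, n: int = 3) -> list[str]:
    """Deterministic distinct pseudonyms for one group's seats."""
    rng = np.random.default_rng([seed, group_id, 0xFACE])
    picks = rng.choice(len(_PSEUDONYM_POOL), size=n, replace=False)
    return [f"{_PSEUDONYM_POOL[i]}{group_id:02d}" for i in picks]


def generate_experiment(
    design: ExperimentDesign,
    params_by_condition: dict[str, ProspectParams],
    belief: OpponentBelief,
    seed: int,
    dt_by_condition: dict[str, float] | None = None,
    duration: float = 5.0,
    enforce_capacity: bool = False,
) -> list[TrialRecord]:
    """Generate one experiment's full trial log.

    Produces ``n_groups x len(conditions) x n_blocks x trials_per_block``
    scored records plus one practice block (block 0) per group/condition
    when the design includes it.  Funds and warehouse fill refresh at each
    block boundary and are tracked per player; the row records the
    winner's totals after the purchase.
    """
    dt_by_condition = dt_by_condition or {"continuous": 0.05, "discrete": 0.5}
    unknown = set(params_by_condition) - set(dt_by_condition)
    if unknown:
        raise ValueError(f"no dt configured for condition(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    blocks = ([0] if design.include_practice else []) + list(
        range(1, design.n_blocks + 1)
    )
    n_players = design.players_per_group

    for group_id in range(1, design.n_groups + 1):
        names = _pseudonyms(group_id, seed, n_players)
        for condition, params in params_by_condition.items():
            dt = dt_by_condition[condition]
            n_steps = round(duration / dt)
            for block in blocks:
                funds = np.full(n_players, design.budget)
                fill = np.zeros(n_players, dtype=int)
                for trial in range(1, design.trials_per_block + 1):
                    units = sample_unit_quantity(
                        design.unit_mode, rng, design.unit_range
                    )
                    eligible = (
                        np.flatnonzero(fill < design.warehouse_capacity)
                        if enforce_capacity
                        else np.arange(n_players)
                    )
                    if len(eligible) == 0:
                        # whole group at capacity: auction runs out unbid
                        eligible = np.array([], dtype=int)
                    if len(eligible) > 0:
                        (outcome,) = simulate_auctions(
                            params,
                            belief,
                            n_auctions=1,
                            seed=rng,
                            dt=dt,
                            duration=duration,
                            start_price_range=design.start_price_range,
                            unit_quantity=int(units),
                            condition=condition,
                            n_players=len(eligible),
                        )
                    else:
                        outcome = None
                    if outcome is not None and outcome.winner is not None:
                        seat = int(eligible[outcome.winner - 1])
                        price = round(outcome.winning_price, 2)
                        funds[seat] -= price
                        fill[seat] += int(units)
                        step = outcome.winning_step
                        norm = (
                            normalize_discrete_step(step)
                            if condition == "discrete"
                            else step
                        )
                        records.append(
                            TrialRecord(
                                group_id=group_id,
                                block=block,
                                trial=trial,
                                condition=condition,
                                start_price=round(outcome.start_price, 2),
                                unit_quantity=int(units),
                                winning_step=step,
                                winning_step_norm=norm,
                                winning_price=price,
                                winner_id=names[seat],
                                remaining_funds=round(float(funds[seat]), 2),
                                warehouse_fill=int(fill[seat]),
                            )
                        )
                    else:
                        start = (
                            outcome.start_price
                            if outcome is not None
                            else float(
                                rng.uniform(*design.start_price_range)
                            )
                        )
                        records.append(
                            TrialRecord(
                                group_id=group_id,
                                block=block,
                                trial=trial,
                                condition=condition,
                                start_price=round(start, 2),
                                unit_quantity=int(units),
                                winning_step=None,
                                winning_step_norm=None,
                                winning_price=None,
                                winner_id=None,
                                remaining_funds=None,
                                warehouse_fill=None,
                            )
                        )
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)
    return df


def write_trials(path, records: Sequence[TrialRecord]) -> None:
    """Write records as UTF-8 CSV with header row and '.' decimals."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def _coerce(row_idx: int, col: str, value, caster):
    if pd.isna(value) or value == "":
        return None
    try:
        return caster(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"malformed value {value!r} in column {col!r}, data row {row_idx + 1}"
        ) from exc


def read_trials(
    path,
    drop_practice: bool = False,
    validate: bool = True,
    column_map: dict[str, str] | None = None,
    duration: float = 5.0,
) -> list[TrialRecord]:
    """Read a trial-log CSV back into records.

    ``column_map`` adapts foreign layouts: maps canonical names to the
    file's column names.  With ``validate=True``, rows whose winning price
    disagrees with the clock (recomputed from start price and step) raise
    a warning naming the row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = TrialRecord(
            group_id=_coerce(i, "group_id", row.group_id, int),
            block=_coerce(i, "block", row.block, int),
            trial=_coerce(i, "trial", row.trial, int),
            condition=str(row.condition),
            start_price=_coerce(i, "start_price", row.start_price, float),
            unit_quantity=_coerce(i, "unit_quantity", row.unit_quantity, int),
            winning_step=_coerce(i, "winning_step", row.winning_step, lambda v: int(float(v))),
            winning_step_norm=_coerce(i, "winning_step_norm", row.winning_step_norm, lambda v: int(float(v))),
            winning_price=_coerce(i, "winning_price", row.winning_price, float),
            winner_id=(str(row.winner_id) if row.winner_id != "" else None),
            remaining_funds=_coerce(i, "remaining_funds", row.remaining_funds, float),
            warehouse_fill=_coerce(i, "warehouse_fill", row.warehouse_fill, lambda v: int(float(v))),
        )
        if rec.start_price is None or rec.start_price <= 0:
            raise ValueError(f"non-positive start_price in data row {i + 1}")
        if validate and rec.winning_step is not None and rec.winning_price is not None:
            dt = 0.5 if rec.condition == "discrete" else 0.05
            clock = PriceClock(rec.start_price, duration=duration, dt=dt)
            expected = clock.price_at(rec.winning_step)
            # 2-decimal I/O rounding of start and price leaves <= ~1.5 cents
            if abs(expected - rec.winning_price) > 0.02:
                warnings.warn(
                    f"row {i + 1}: winning_price {rec.winning_price} != "
                    f"clock price {expected:.4f}",
                    stacklevel=2,
                )
        if drop_practice and rec.block == 0:
            continue
        records.append(rec)
    return records


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(csv_path, seed: int, config: dict, command: str = "") -> Path:
    """Sidecar JSON manifest (seed, config hash, timestamp) next to a CSV."""
    import datetime

    from . import __version__

    path = Path(str(csv_path) + ".manifest.json")
    payload = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "package_version": __version__,
        "written_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "output": str(csv_path),
    }
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
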