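"""Campaign persistence in the canonical table schema, plus the bundled
75-experiment validation campaign.

A campaign CSV has one row per experiment with the ten condition columns
(``Conf, LiSalt, LiSaltEq, Acid, AcceptorEq, ConcM, PartEt2O, PartMeCN,
MS, TempC``) followed by the measured outcomes (``YieldPct, BetaPct``).
Optional bookkeeping columns — experiment number, batch index, proposal
mode, objective provenance — round-trip unchanged, as do any unknown
columns. Hypervolume columns are never read back as inputs; analytics
always recompute them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .space import Conditions

__all__ = [
    "ExperimentResult",
    "read_campaign",
    "write_campaign",
    "load_fixture_campaign",
    "CONDITION_COLUMNS",
]

CONDITION_COLUMNS = (
    "Conf", "LiSalt", "LiSaltEq", "Acid", "AcceptorEq",
    "ConcM", "PartEt2O", "PartMeCN", "MS", "TempC",
)
OUTCOME_COLUMNS = ("YieldPct", "BetaPct")
_NUMERIC = {"LiSaltEq", "AcceptorEq", "ConcM", "PartEt2O", "PartMeCN",
            "TempC", "YieldPct", "BetaPct"}


@dataclass
class ExperimentResult:
    """One executed (or pending) experiment of a campaign."""

    conditions: Conditions
    yield_pct: float | None = None
    beta_pct: float | None = None
    exp_no: int | None = None
    batch: int | None = None
    mode: str | None = None       # random | pareto_exploit | steinerberger_explore
    objective: str | None = None  # which optimizer proposed it (beta | alpha)
    extras: dict = field(default_factory=dict)

    @property
    def pending(self) -> bool:
        return self.yield_pct is None or self.beta_pct is None

    def __post_init__(self):
        if self.beta_pct is not None and not 0 <= self.beta_pct <= 100:
            raise ValueError(f"beta_pct must be in [0, 100], got {self.beta_pct}")
        if self.yield_pct is not None and self.yield_pct < 0:
            raise ValueError(f"yield_pct must be >= 0, got {self.yield_pct}")


def _row_to_conditions(row: pd.Series, rownum: int) -> Conditions:
    def num(col):
        v = row[col]
        try:
            return float(v)
        except (TypeError, ValueError):
            raise ValueError(f"row {rownum}: unparsable numeric in column {col}: {v!r}")

    return Conditions(
        donor_config=str(row["Conf"]),
        li_salt=str(row["LiSalt"]),
        li_salt_eq=num("LiSaltEq"),
        acid=str(row["Acid"]),
        acceptor_eq=num("AcceptorEq"),
        conc=num("ConcM"),
        part_et2o=num("PartEt2O"),
        part_mecn=num("PartMeCN"),
        sieves=str(row["MS"]),
        temp=int(num("TempC")),
    )


def _opt_num(row, col, rownum, as_int=False):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
        return None
    try:
        return int(float(v)) if as_int else float(v)
    except (TypeError, ValueError):
        raise ValueError(f"row {rownum}: unparsable numeric in column {col}: {v!r}")


def read_campaign(path_or_buf) -> list[ExperimentResult]:
    """Read a campaign CSV into experiment records.

    Missing required columns raise with the column named; unparsable
    numerics raise with the row number. Pending rows (empty outcome
    cells) are allowed.
    """
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    for col in CONDITION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    known = set(CONDITION_COLUMNS) | set(OUTCOME_COLUMNS) | {
        "Exp", "Batch", "Mode", "Objective"
    }
    results = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        extras = {c: row[c] for c in df.columns if c not in known}
        results.append(ExperimentResult(
            conditions=_row_to_conditions(row, i),
            yield_pct=_opt_num(row, "YieldPct", i),
            beta_pct=_opt_num(row, "BetaPct", i),
            exp_no=_opt_num(row, "Exp", i, as_int=True),
            batch=_opt_num(row, "Batch", i, as_int=True),
            mode=row["Mode"] if "Mode" in df.columns else None,
            objective=row["Objective"] if "Objective" in df.columns else None,
            extras=extras,
        ))
    return results


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def write_campaign(results: Sequence[ExperimentResult], path) -> None:
    """Write records in the canonical schema (dot decimals, UTF-8, comma)."""
    rows = []
    for r in results:
        c = r.conditions
        row = {
            "Exp": _fmt(r.exp_no),
            "Conf": c.donor_config, "LiSalt": c.li_salt,
            "LiSaltEq": _fmt(c.li_salt_eq), "Acid": c.acid,
            "AcceptorEq": _fmt(c.acceptor_eq), "ConcM": _fmt(c.conc),
            "PartEt2O": _fmt(c.part_et2o), "PartMeCN": _fmt(c.part_mecn),
            "MS": c.sieves, "TempC": _fmt(c.temp),
            "YieldPct": _fmt(r.yield_pct), "BetaPct": _fmt(r.beta_pct),
            "Batch": _fmt(r.batch), "Objective": r.objective or "",
            "Mode": r.mode or "",
        }
        row.update({k: _fmt(v) for k, v in r.extras.items()})
        rows.append(row)
    header = ["Exp", *CONDITION_COLUMNS, *OUTCOME_COLUMNS,
              "Batch", "Objective", "Mode"]
    df = pd.DataFrame(rows, columns=None if rows else header)
    df.to_csv(path, index=False, encoding="utf-8")


def load_fixture_campaign(which: int) -> list[ExperimentResult]:
    """The bundled validation campaigns.

    ``which=1``: the 55 experiments of the yield / β-selectivity campaign
    (10 random + 9 batches of 5). ``which=2``: the 20 experiments of the
    dual campaign (4 batches of 5; per batch, 2 proposed by the
    β-optimizer and 3 by the α-optimizer). ``which=0``: both, concatenated.
    """
    if which == 0:
        return load_fixture_campaign(1) + load_fixture_campaign(2)
    if which not in (1, 2):
        raise ValueError("which must be 0, 1 or 2")
    with resources.files("glycobo.data").joinpath(f"campaign{which}.csv").open() as fh:
        return read_campaign(fh)
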