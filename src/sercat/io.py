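"""File formats: item-parameter CSV, response matrices, trace JSONL, manifests.

Conventions shared by every format:

* categories are written 1-based on disk (the "1..5" convention of portal
  extracts) and converted to the package's 0-based convention on read;
* item-parameter CSVs have columns ``item_id, alpha, beta_1 .. beta_k`` with
  empty cells padding ragged banks;
* traces are JSON-lines, one respondent per line, with full-precision floats
  so round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .engine import CatStep, CatTrace, StoppingRules
from .grm import ItemBank, ItemParameters

__all__ = [
    "read_item_bank",
    "write_item_bank",
    "read_traces_jsonl",
    "write_traces_jsonl",
    "read_responses_wide",
    "write_responses_wide",
    "read_responses_long",
    "write_responses_long",
    "write_manifest",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# item-parameter CSV

def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank as ``item_id, alpha, beta_1..beta_k`` CSV (ragged-padded)."""
    max_k = max(len(it.betas) for it in bank)
    rows = []
    for it in bank:
        row: Dict[str, object] = {"item_id": it.item_id, "alpha": repr(it.alpha)}
        for k in range(max_k):
            row[f"beta_{k + 1}"] = repr(it.betas[k]) if k < len(it.betas) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_item_bank(path: str | Path) -> ItemBank:
    """Parse an item-parameter CSV, validating every item; errors name the row."""
    df = pd.read_csv(path, dtype={"item_id": str}, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no items")
    required = {"item_id", "alpha"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)} plus beta_1..beta_k")
    beta_cols = sorted(
        (c for c in df.columns if c.startswith("beta_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    if not beta_cols:
        raise ValueError(f"{path}: no beta_k columns found")
    items: List[ItemParameters] = []
    for idx, row in df.iterrows():
        row_no = int(idx) + 2  # header is line 1
        betas = [float(row[c]) for c in beta_cols if pd.notna(row[c]) and row[c] != ""]
        try:
            items.append(ItemParameters(item_id=str(row["item_id"]),
                                        alpha=float(row["alpha"]), betas=tuple(betas)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from None
    try:
        return ItemBank(items=tuple(items))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# trace JSONL

def write_traces_jsonl(traces: Sequence[CatTrace], path: str | Path) -> None:
    """One trace per line; categories 1-based on disk; floats at full precision."""
    with open(path, "w") as fh:
        for trace in traces:
            obj = {
                "respondent_id": trace.respondent_id,
                "stop_reason": trace.stop_reason,
                "steps": [
                    {
                        "step": s.step,
                        "item_id": s.item_id,
                        "category": s.category + 1,
                        "theta": s.theta,
                        "se": s.se,
                        "ser": s.ser,
                    }
                    for s in trace.steps
                ],
            }
            fh.write(json.dumps(obj) + "\n")


def read_traces_jsonl(path: str | Path, bank: Optional[ItemBank] = None) -> Tuple[CatTrace, ...]:
    """Read traces written by :func:`write_traces_jsonl`; validates against ``bank`` if given."""
    traces: List[CatTrace] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                steps = tuple(
                    CatStep(
                        step=int(s["step"]),
                        item_id=str(s["item_id"]),
                        category=int(s["category"]) - 1,
                        theta=float(s["theta"]),
                        se=float(s["se"]),
                        ser=None if s.get("ser") is None else float(s["ser"]),
                    )
                    for s in obj["steps"]
                )
                trace = CatTrace(
                    respondent_id=str(obj["respondent_id"]),
                    steps=steps,
                    stop_reason=str(obj["stop_reason"]),
                )
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}, line {line_no}: {exc}") from None
            if bank is not None:
                _validate_steps_against_bank(trace, bank, f"{path}, line {line_no}")
            traces.append(trace)
    return tuple(traces)


def _validate_steps_against_bank(trace: CatTrace, bank: ItemBank, where: str) -> None:
    for s in trace.steps:
        if s.item_id not in bank:
            raise ValueError(f"{where}: unknown item {s.item_id!r}")
        n_cat = bank[s.item_id].n_categories
        if not 0 <= s.category < n_cat:
            raise ValueError(
                f"{where}: category {s.category + 1} outside 1..{n_cat} for item {s.item_id!r}"
            )


# ---------------------------------------------------------------------------
# response matrices

def write_responses_wide(
    matrix: np.ndarray,
    respondent_ids: Sequence[str],
    item_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Full response matrix as wide CSV (one column per item, 1-based categories)."""
    df = pd.DataFrame(np.asarray(matrix) + 1, columns=list(item_ids))
    df.insert(0, "respondent_id", list(respondent_ids))
    df.to_csv(path, index=False)


def read_responses_wide(
    path: str | Path, bank: Optional[ItemBank] = None
) -> Tuple[np.ndarray, Tuple[str, ...], Tuple[str, ...]]:
    """Read a wide response CSV -> (0-based matrix, respondent ids, item ids)."""
    df = pd.read_csv(path, dtype={"respondent_id": str})
    if "respondent_id" not in df.columns:
        raise ValueError(f"{path}: missing respondent_id column")
    item_ids = tuple(c for c in df.columns if c != "respondent_id")
    if not item_ids:
        raise ValueError(f"{path}: no item columns")
    respondent_ids = tuple(df["respondent_id"])
    if len(set(respondent_ids)) != len(respondent_ids):
        raise ValueError(f"{path}: duplicate respondent ids")
    values = df[list(item_ids)].to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(~np.isfinite(values.astype(float))):
        raise ValueError(f"{path}: non-numeric or missing response cells")
    matrix = values.astype(np.int64) - 1
    if np.any(matrix < 0):
        bad = np.argwhere(matrix < 0)[0]
        raise ValueError(
            f"{path}: category {matrix[bad[0], bad[1]] + 1} below 1 "
            f"(respondent {respondent_ids[bad[0]]!r}, item {item_ids[bad[1]]!r})"
        )
    if bank is not None:
        for j, item_id in enumerate(item_ids):
            if item_id not in bank:
                raise ValueError(f"{path}: unknown item {item_id!r}")
            n_cat = bank[item_id].n_categories
            over = np.argwhere(matrix[:, j] >= n_cat)
            if over.size:
                i = int(over[0, 0])
                raise ValueError(
                    f"{path}: category {matrix[i, j] + 1} outside 1..{n_cat} "
                    f"(respondent {respondent_ids[i]!r}, item {item_id!r})"
                )
    return matrix, respondent_ids, item_ids


def write_responses_long(
    sequences: Sequence[Tuple[str, Sequence[Tuple[str, int]]]], path: str | Path
) -> None:
    """Ordered (respondent, step, item, category) rows, 1-based categories."""
    rows = [
        {"respondent_id": rid, "step": t + 1, "item_id": item_id, "category": cat + 1}
        for rid, pairs in sequences
        for t, (item_id, cat) in enumerate(pairs)
    ]
    pd.DataFrame(rows, columns=["respondent_id", "step", "item_id", "category"]).to_csv(
        path, index=False
    )


def read_responses_long(
    path: str | Path, bank: Optional[ItemBank] = None
) -> Tuple[Tuple[str, Tuple[Tuple[str, int], ...]], ...]:
    """Read long-format recordings -> ordered (respondent_id, ((item_id, cat0), ...)).

    Rows out of step order are accepted, sorted, and logged as a warning.
    Duplicate (respondent, item) pairs are an error.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str, "item_id": str})
    required = {"respondent_id", "step", "item_id", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    out: List[Tuple[str, Tuple[Tuple[str, int], ...]]] = []
    for rid, group in df.groupby("respondent_id", sort=False):
        if not group["step"].is_monotonic_increasing:
            logger.warning("%s: respondent %r rows out of step order; sorted", path, rid)
            group = group.sort_values("step", kind="stable")
        if group["item_id"].duplicated().any():
            dup = group.loc[group["item_id"].duplicated(), "item_id"].iloc[0]
            raise ValueError(f"{path}: duplicate (respondent {rid!r}, item {dup!r})")
        pairs = []
        for _, row in group.iterrows():
            cat = int(row["category"]) - 1
            if cat < 0:
                raise ValueError(
                    f"{path}: category {cat + 1} below 1 (respondent {rid!r}, "
                    f"item {row['item_id']!r})"
                )
            if bank is not None:
                item_id = str(row["item_id"])
                if item_id not in bank:
                    raise ValueError(f"{path}: unknown item {item_id!r} (respondent {rid!r})")
                n_cat = bank[item_id].n_categories
                if cat >= n_cat:
                    raise ValueError(
                        f"{path}: category {cat + 1} outside 1..{n_cat} "
                        f"(respondent {rid!r}, item {item_id!r})"
                    )
            pairs.append((str(row["item_id"]), cat))
        out.append((str(rid), tuple(pairs)))
    return tuple(out)


# ---------------------------------------------------------------------------
# manifests

def write_manifest(path: str | Path, config: Dict[str, object]) -> None:
    """Record everything needed to reproduce a run beside its outputs."""
    manifest = {
        "sercat_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": _jsonable(config),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def stopping_rules_from_dict(d: Dict[str, object]) -> StoppingRules:
    """Build :class:`StoppingRules` from a config mapping (unknown keys rejected)."""
    allowed = {"min_items", "max_items", "se_threshold", "ser_threshold"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown stopping-rule keys: {sorted(unknown)}")
    return StoppingRules(**d)  # type: ignore[arg-type]
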