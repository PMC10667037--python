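"""Reading and writing graphs and result records.

Migration matrices travel as headerless CSV (D rows x D columns, full
float precision so round-trips are bitwise) or as JSON
``{"D": ..., "convention": ..., "m": [[...]]}``.  Result records are
self-describing dictionaries: they echo every parameter needed to re-run
the point, the method used, the RNG seed and the package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import MigrationGraph

__all__ = ["load_graph", "save_graph", "result_record", "write_records"]


def load_graph(path: str | Path) -> MigrationGraph:
    """Load a migration graph from ``.csv`` or ``.json`` (by extension)."""
    path = Path(path)
    if path.suffix == ".json":
        return MigrationGraph.from_json(path)
    return MigrationGraph.from_csv(path)


def save_graph(g: MigrationGraph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        g.to_json(path)
    else:
        g.to_csv(path)


def _plain(value):
    if is_dataclass(value) and not isinstance(value, type):
        return {k: _plain(v) for k, v in asdict(value).items()}
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def result_record(method: str, params: dict, estimates: dict,
                  warnings: list[str] | None = None, seed: int | None = None) -> dict:
    """A self-describing record for one computed point."""
    from . import __version__

    return _plain(
        {
            "method": method,
            "params": params,
            "estimates": estimates,
            "warnings": warnings or [],
            "seed": seed,
            "version": __version__,
        }
    )


def write_records(records: list[dict], path: str | Path) -> None:
    """Write records as JSON (``.json``) or a flat CSV table (anything else)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1))
        return
    rows = []
    for rec in records:
        row = {"method": rec["method"], "seed": rec.get("seed")}
        row.update({f"param_{k}": v for k, v in rec["params"].items()
                    if not isinstance(v, (list, dict))})
        row.update({k: v for k, v in rec["estimates"].items()
                    if not isinstance(v, (list, dict))})
        row["warnings"] = "; ".join(rec.get("warnings", []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
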