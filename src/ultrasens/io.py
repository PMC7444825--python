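"""Table and parameter-set serialization.

CSV tables use a fixed column order, '.' decimal separator and empty fields
for undefined values, and round-trip through :func:`read_table`.  Every
artifact written through this module gets a JSON sidecar
(``<path>.meta.json``) embedding the full configuration and seed that
produced it, so results stay reproducible from the artifact alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .independent import IndependentParameters
from .mwc import MWCParameters

__all__ = [
    "serialize_table",
    "read_table",
    "write_json",
    "params_from_dict",
    "load_params",
]


class SchemaError(ValueError):
    """A table does not conform to the expected column schema."""


def serialize_table(rows: pd.DataFrame, schema: Sequence[str],
                    path: Union[str, Path],
                    meta: Optional[dict] = None) -> Path:
    """Write a DataFrame as CSV with a fixed column order.

    ``schema`` names the expected columns; a mismatch raises
    :class:`SchemaError` naming the offending column.  ``None``/NaN cells are
    written as empty fields.  An empty frame yields a header-only file.
    """
    path = Path(path)
    for col in schema:
        if col not in rows.columns:
            raise SchemaError(f"missing column {col!r}")
    extra = [c for c in rows.columns if c not in schema]
    if extra:
        raise SchemaError(f"unexpected column {extra[0]!r}")
    rows[list(schema)].to_csv(path, index=False, na_rep="")
    if meta is not None:
        write_sidecar(path, meta)
    return path


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV written by :func:`serialize_table` (empty fields -> NaN)."""
    return pd.read_csv(path)


def write_sidecar(path: Path, meta: dict) -> Path:
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return sidecar


def write_json(obj: dict, path: Union[str, Path],
               meta: Optional[dict] = None) -> Path:
    """Write a result object as JSON (None for undefined values)."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
    if meta is not None:
        write_sidecar(path, meta)
    return path


def params_from_dict(d: dict):
    """Build a parameter set from its flat JSON object representation.

    Dispatches on the ``"model"`` key: ``"mwc"`` or ``"independent"``.
    """
    model = d.get("model")
    if model == "mwc":
        return MWCParameters.from_dict(d)
    if model == "independent":
        return IndependentParameters.from_dict(d)
    raise ValueError(f"unknown or missing model tag {model!r}")


def load_params(path: Union[str, Path]):
    """Load a parameter set from a JSON file."""
    return params_from_dict(json.loads(Path(path).read_text()))
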