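"""CSV schemas, provenance headers, and the deposited-dataset adapter."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = [
    "write_csv",
    "read_csv",
    "config_hash",
    "load_deposited_tracts",
    "DEPOSITED_COLUMN_MAP",
]


def config_hash(obj) -> str:
    """Short stable hash of a config mapping, for provenance headers."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a CSV with a ``#``-prefixed provenance header.

    The header records the package version plus any supplied key/value pairs
    (seed, config hash, stage).  :func:`read_csv` skips it transparently.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# rxaccess {__version__}"]
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (or any plain CSV)."""
    return pd.read_csv(path, comment="#", **kwargs)


#: Default mapping from the deposited tract-level dataset's columns to the
#: tract-records schema.  Adjust via the ``column_map`` argument if the
#: source file uses different headers.
DEPOSITED_COLUMN_MAP = {
    "tract_id": "GEOID",
    "pwmsd_km": "pwmsd_km",
    "population": "population",
    "pct_poverty": "pct_poverty",
    "pct_higher_ed": "pct_higher_ed",
    "pct_black_aa": "pct_black_aa",
    "pct_hispanic": "pct_hispanic",
    "median_income": "median_income",
    "pct_white": "pct_white",
    "pop_density": "pop_density",
}


def load_deposited_tracts(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Adapter for an externally produced tract-level dataset.

    Reads a CSV of tracts that already carry a computed PWMSD (for example a
    published state-wide dataset) and renames columns into the tract-records
    schema consumed by :class:`rxaccess.disparity.QuartileDisparityModel`.
    Required target columns: ``tract_id, pwmsd_km, population`` and the four
    analysis covariates; optional ones are mapped when present.
    """
    cmap = dict(DEPOSITED_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, comment="#")
    out = pd.DataFrame()
    required = (
        "tract_id", "pwmsd_km", "population",
        "pct_poverty", "pct_higher_ed", "pct_black_aa", "pct_hispanic",
    )
    for target, source in cmap.items():
        if source in raw.columns:
            out[target] = raw[source]
        elif target in required:
            raise ValueError(
                f"deposited dataset lacks column {source!r} (mapped to {target!r}); "
                "supply a column_map matching the file's headers"
            )
    out["tract_id"] = out["tract_id"].astype(str)
    return out
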