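"""Readers, writers and run configuration for reproducible analyses.

All tables are comma-separated UTF-8 text with a header row.  Spectra files
carry columns ``sample_id, replicate, m360, m361, m362`` (glucose) or
``sample_id, replicate, m57, m58, m59`` (acetone); standard-curve files carry
``p_known, m1_fraction``.  Result files embed the resolved configuration as
``# key: value`` comment lines so every output is self-describing.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .isotopes import IsotopeTable
from .pathway_analysis import MeasuredSpectrum

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_spectra",
    "read_standard_curve",
    "write_table",
    "write_results",
    "load_isotope_table",
    "save_isotope_table",
]

GLUCOSE_COLUMNS = ("m360", "m361", "m362")
ACETONE_COLUMNS = ("m57", "m58", "m59")


class SchemaError(ValueError):
    """An input file does not have the expected columns."""


@dataclass
class RunConfig:
    """Resolved configuration of one command-line run."""

    command: str = ""
    fragment_formula: str = "C15H22N1O9"
    window: str = "three-ion"
    n_gng: int = 6
    n_ggl: int = 1
    p: float | None = None
    p_source: str = "fixed"
    baseline_mode: str = "theoretical"
    calibrated_c13: float | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_metadata(self) -> dict:
        d = asdict(self)
        d["software"] = f"gngmida {__version__}"
        return d


def read_spectra(path: str | Path, analyte: str = "glucose") -> list[MeasuredSpectrum]:
    """Read a spectra CSV into measured-spectrum records."""
    cols = GLUCOSE_COLUMNS if analyte == "glucose" else ACETONE_COLUMNS
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("sample_id", *cols) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for i, row in df.iterrows():
        rep = int(row["replicate"]) if "replicate" in df.columns and pd.notna(row.get("replicate")) else None
        out.append(
            MeasuredSpectrum(
                sample_id=str(row["sample_id"]),
                m0=float(row[cols[0]]), m1=float(row[cols[1]]), m2=float(row[cols[2]]),
                replicate=rep,
            )
        )
    if not out:
        raise SchemaError(f"{path}: no data rows")
    return out


def read_standard_curve(path: str | Path) -> list[tuple[float, float]]:
    """Read an acetone standard curve (known p vs fractional M+1 response)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("p_known", "m1_fraction") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return [(float(r.p_known), float(r.m1_fraction)) for r in df.itertuples()]


def _metadata_header(config: RunConfig | None) -> str:
    if config is None:
        return ""
    buf = _io.StringIO()
    for k, v in config.to_metadata().items():
        if v in (None, "", {}):
            continue
        buf.write(f"# {k}: {json.dumps(v) if isinstance(v, dict) else v}\n")
    return buf.getvalue()


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
                index: bool = True) -> None:
    """Write a results table as CSV with an embedded config header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(config))
        df.to_csv(fh, index=index, float_format="%.6f", lineterminator="\n")


def write_results(records: list[dict], path: str | Path, config: RunConfig | None = None) -> None:
    write_table(pd.DataFrame(records), path, config, index=False)


def load_isotope_table(path: str | Path) -> IsotopeTable:
    """Load a versioned isotope-abundance config (YAML element -> [[shift, abundance]])."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return IsotopeTable.from_dict(data["abundances"] if "abundances" in data else data)


def save_isotope_table(table: IsotopeTable, path: str | Path, version: str = "1") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"version": version, "abundances": table.to_dict()}, fh, sort_keys=True)
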