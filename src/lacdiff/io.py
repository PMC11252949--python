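"""Delimited-table IO and pipeline configuration.

Canonical interchange schema for attenuation curves — delimited text (CSV,
or TSV by extension) with header columns::

    subject_id, group, metabolite, b, signal[, sd]

b in ms/µm², signal dimensionless.  A permissive ``column_map`` lets
differently-labelled deposits be read without editing the file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .curves import AttenuationCurve
from .exceptions import TableFormatError
from .scheme import DEFAULT_B_GRID, DEFAULT_DIFFUSION_TIME

REQUIRED_COLUMNS = ("subject_id", "group", "metabolite", "b", "signal")


def _delimiter_for(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_attenuation_table(
    path,
    dialect: str | None = None,
    normalize: bool = True,
    column_map: dict[str, str] | None = None,
) -> list[AttenuationCurve]:
    """Read attenuation curves from a delimited text table.

    Parameters
    ----------
    path
        CSV/TSV file (delimiter auto-detected by extension, or forced with
        ``dialect``).
    normalize
        Divide each curve by its signal at the lowest b on load.
    column_map
        Mapping from the file's column names to the canonical ones, e.g.
        ``{"animal": "subject_id"}``.

    Raises
    ------
    TableFormatError
        Missing columns, non-numeric cells, or duplicate
        (subject, metabolite, b) rows — the offending row is named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, dialect),
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path.name}: missing required columns {missing}")

    for col in ("b", "signal") + (("sd",) if "sd" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise TableFormatError(
                f"{path.name}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column {col!r} at row {bad[0] + 2}"  # +2: header + 1-based
            )
        df[col] = coerced
    if df[["b", "signal"]].isna().any().any():
        row = int(df.index[df[["b", "signal"]].isna().any(axis=1)][0])
        raise TableFormatError(f"{path.name}: empty b/signal cell at row {row + 2}")

    dup = df.duplicated(subset=["subject_id", "metabolite", "b"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise TableFormatError(
            f"{path.name}: duplicate (subject, metabolite, b) = "
            f"({r['subject_id']}, {r['metabolite']}, {r['b']})"
        )

    curves = []
    for (subject, group, metabolite), sub in df.groupby(
            ["subject_id", "group", "metabolite"], sort=True):
        sub = sub.sort_values("b")
        sd = sub["sd"].to_numpy() if "sd" in sub.columns and sub["sd"].notna().all() else None
        curve = AttenuationCurve(
            metabolite=str(metabolite), subject_id=str(subject), group=str(group),
            b=sub["b"].to_numpy(), S=sub["signal"].to_numpy(), sd=sd,
        )
        curves.append(curve.normalized() if normalize else curve)
    return curves


def write_attenuation_table(curves: list[AttenuationCurve], path, dialect: str | None = None) -> None:
    """Write curves in the canonical schema (CSV/TSV by extension)."""
    path = Path(path)
    rows = []
    has_sd = any(c.sd is not None for c in curves)
    for c in curves:
        for j in range(c.n_points):
            row = {
                "subject_id": c.subject_id, "group": c.group,
                "metabolite": c.metabolite, "b": c.b[j], "signal": c.S[j],
            }
            if has_sd:
                row["sd"] = c.sd[j] if c.sd is not None else np.nan
            rows.append(row)
    # shortest round-trip float representation so read-back is bit-exact
    pd.DataFrame(rows).to_csv(path, sep=_delimiter_for(path, dialect),
                              index=False, float_format=lambda v: repr(float(v)))


class FitSettings(BaseModel):
    """Serializable subset of :class:`~lacdiff.fitting.FitOptions`."""

    n_starts: int = 3
    weighted: bool = True
    fix_f_sphere: float | None = None
    bootstrap_draws: int = 0
    seed: int = 0


class PipelineConfig(BaseModel):
    """Full pipeline configuration; round-trips through JSON."""

    b_values: list[float] = Field(default_factory=lambda: list(DEFAULT_B_GRID))
    t_d: float = DEFAULT_DIFFUSION_TIME
    pulse_model: str = "narrow_pulse"
    delta: float | None = None
    Delta: float | None = None
    lactate_lambda: float = 1.3
    intracellular_model: str = "sticks_spheres"  # or "cylinders"
    fit: FitSettings = Field(default_factory=FitSettings)
    equal_var_ttest: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())
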