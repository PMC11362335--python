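"""Event-file and configuration readers/writers.

All interchange is comma-separated UTF-8 text.  An event file carries a
mandatory ``# key: value`` header (schema version, medium, duration, duty
cycle, sample identity) followed by one row per detection::

    # caspm-events: v1
    # medium: seawater
    # duration_s: 120.0
    # duty_cycle: 1.0
    channel,time_s,re_s_um,im_s_um
    s,0.1351,0.4521,0.0614

Malformed rows are rejected individually and reported with their line
numbers; a missing header is a format error.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["EventFile", "FormatError", "read_events", "write_events", "load_config"]

SCHEMA_VERSION = "v1"
_COLUMNS = ["channel", "time_s", "re_s_um", "im_s_um"]


class FormatError(ValueError):
    """Structurally invalid event file or configuration."""


@dataclass
class EventFile:
    """Parsed event file: header metadata, event table, rejected rows."""

    header: dict
    events: pd.DataFrame
    rejected: list = field(default_factory=list)  # (line_number, reason)

    @property
    def medium(self) -> str:
        return self.header.get("medium", "seawater")

    @property
    def duration_s(self) -> float:
        return float(self.header.get("duration_s", 0.0))

    @property
    def duty_cycle(self) -> float:
        return float(self.header.get("duty_cycle", 1.0))


def write_events(path, events: pd.DataFrame, header: dict) -> None:
    """Write an event table with its metadata header."""
    hdr = {"caspm-events": SCHEMA_VERSION, **header}
    with open(path, "w", encoding="utf-8") as f:
        for k, v in hdr.items():
            f.write(f"# {k}: {v}\n")
        f.write(",".join(_COLUMNS) + "\n")
        for row in events[_COLUMNS].itertuples(index=False):
            f.write(
                f"{row.channel},{float(row.time_s)!r},"
                f"{float(row.re_s_um)!r},{float(row.im_s_um)!r}\n"
            )


def read_events(path, strict: bool = False) -> EventFile:
    """Parse an event file; malformed rows are rejected with line numbers.

    With ``strict=True`` any rejected row raises instead.
    """
    header: dict = {}
    rejected: list = []
    rows = []
    with open(path, encoding="utf-8") as f:
        lines = f.readlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition(":")
        header[key.strip()] = value.strip()
    else:
        i = len(lines)
    if header.get("caspm-events") != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: missing or unrecognized event-file header "
            f"(expected '# caspm-events: {SCHEMA_VERSION}')"
        )
    if i >= len(lines) or lines[i].strip() != ",".join(_COLUMNS):
        raise FormatError(f"{path}: missing column header line {_COLUMNS}")
    for ln in range(i + 1, len(lines)):
        raw = lines[ln].strip()
        if not raw:
            continue
        parts = raw.split(",")
        if len(parts) != 4:
            rejected.append((ln + 1, f"expected 4 fields, got {len(parts)}"))
            continue
        ch, t, re_s, im_s = parts
        if ch not in ("s", "l"):
            rejected.append((ln + 1, f"unknown channel {ch!r}"))
            continue
        try:
            t_f, re_f, im_f = float(t), float(re_s), float(im_s)
        except ValueError as e:
            rejected.append((ln + 1, f"non-numeric field: {e}"))
            continue
        if not (math.isfinite(t_f) and math.isfinite(re_f) and math.isfinite(im_f)):
            rejected.append((ln + 1, "non-finite amplitude or time"))
            continue
        rows.append((ch, t_f, re_f, im_f))
    if strict and rejected:
        raise FormatError(f"{path}: rejected rows {rejected}")
    events = pd.DataFrame(rows, columns=_COLUMNS)
    return EventFile(header=header, events=events, rejected=rejected)


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_SCHEMA = {
    "seed": int,
    "medium": str,
    "output_dir": str,
    "events": list,
    "metadata": str,
    "simulate": {
        "stations": int,
        "depths_m": list,
        "duration_s": (int, float),
        "noise_sigma_um": (int, float),
        "chl_coupling": (int, float),
        "flow_velocity_m_s": (int, float),
    },
    "optics": {"wavelength_um": (int, float)},
    "calibration": {
        "flow_velocity_m_s": (int, float),
        "duty_cycle": (int, float),
        "effective_area_s_m2": (int, float),
        "effective_area_l_m2": (int, float),
    },
    "boundaries": {
        "curve_m": list,
        "line_a": list,
        "line_b": list,
        "ellipse": list,
    },
    "lookup": {
        "m_min": (int, float),
        "m_max": (int, float),
        "m_step": (int, float),
        "d_min": (int, float),
        "d_max": (int, float),
        "n_diameters": int,
    },
    "grid": {
        "d_min": (int, float),
        "d_max": (int, float),
        "bins_per_decade": int,
    },
    "bc_calibration": str,
    "log_level": str,
}


def _check_keys(section: dict, schema: dict, prefix: str = "") -> None:
    for key, value in section.items():
        if key not in schema:
            raise FormatError(f"unknown config key {prefix}{key!r}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(value, dict):
                raise FormatError(f"config key {prefix}{key!r} must be a mapping")
            _check_keys(value, expect, prefix=f"{prefix}{key}.")


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path, encoding="utf-8") as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    _check_keys(cfg, _CONFIG_SCHEMA)
    for key in ("events",):
        for p in cfg.get(key) or []:
            if not Path(p).exists():
                raise FormatError(f"referenced event file does not exist: {p}")
    if "metadata" in cfg and not Path(cfg["metadata"]).exists():
        raise FormatError(f"referenced metadata file does not exist: {cfg['metadata']}")
    bc = cfg.get("bc_calibration")
    if bc and bc != "synthetic" and not Path(bc).exists():
        raise FormatError(f"referenced BC calibration does not exist: {bc}")
    return cfg
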