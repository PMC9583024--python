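"""CSV/JSON/YAML file formats.

Time-series CSV: columns ``time_s, component, value`` with ``# key=value``
header lines carrying metadata (load case, plateau strain, units).

Element-field CSV: columns ``element_id, volume_nm3, time_s, component,
stress_Pa, strain`` (strain blank where only stress was recorded), with the
RVE volume in the header.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import ElementField
from .viscoelastic import TimeSeries

__all__ = [
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_element_field_csv",
    "read_element_field_csv",
    "load_yaml_config",
]


def _write_with_header(path, df: pd.DataFrame, meta: dict) -> None:
    buf = _io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}={v}\n")
    # repr() emits the shortest digit string that parses back bit-exactly
    df.to_csv(buf, index=False, lineterminator="\n",
              float_format=lambda v: repr(float(v)))
    Path(path).write_text(buf.getvalue())


def _read_with_header(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    text = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    # round_trip parsing: the default fast parser can be off by one ulp
    df = pd.read_csv(_io.StringIO("\n".join(text[body_start:])),
                     float_precision="round_trip")
    return df, meta


def write_timeseries_csv(path, series: list[TimeSeries], meta: dict | None = None
                         ) -> None:
    frames = [
        pd.DataFrame({"time_s": ts.times, "component": ts.component,
                      "value": ts.values, "kind": ts.kind})
        for ts in series
    ]
    _write_with_header(path, pd.concat(frames, ignore_index=True), meta or {})


def read_timeseries_csv(path) -> tuple[list[TimeSeries], dict]:
    """Read time series; unsorted rows are sorted with a warning."""
    df, meta = _read_with_header(path)
    required = {"time_s", "component", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: time-series CSV needs columns {sorted(required)}")
    bad = df[df[["time_s", "component", "value"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"{path}: malformed rows at lines "
            f"{[int(i) + 2 + len(meta) for i in bad.index[:5]]}"
        )
    out = []
    kind_col = df["kind"] if "kind" in df else pd.Series("stress", index=df.index)
    for (comp, kind), grp in df.assign(kind=kind_col).groupby(
            ["component", "kind"], sort=True):
        if not grp["time_s"].is_monotonic_increasing:
            warnings.warn(f"{path}: unsorted times for component {comp}; sorting")
            grp = grp.sort_values("time_s")
        out.append(TimeSeries(grp["time_s"].to_numpy(), grp["value"].to_numpy(),
                              component=int(comp), kind=str(kind)))
    return out, meta


def write_element_field_csv(path, field: ElementField, meta: dict | None = None
                            ) -> None:
    rows = []
    for e in range(field.n_elements):
        for comp in sorted(set(field.stress) | set(field.strain)):
            stress = field.stress.get(comp)
            strain = field.strain.get(comp)
            rows.append(pd.DataFrame({
                "element_id": e,
                "volume_nm3": field.volumes[e],
                "time_s": field.times,
                "component": comp,
                "stress_Pa": stress[e] if stress is not None else np.nan,
                "strain": strain[e] if strain is not None else np.nan,
            }))
    meta = dict(meta or {})
    meta["V_RVE_nm3"] = repr(field.V_RVE)
    _write_with_header(path, pd.concat(rows, ignore_index=True), meta)


def read_element_field_csv(path) -> tuple[ElementField, dict]:
    df, meta = _read_with_header(path)
    required = {"element_id", "volume_nm3", "time_s", "component", "stress_Pa",
                "strain"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: element CSV needs columns {sorted(required)}")
    times = np.unique(df["time_s"].to_numpy())
    elements = np.unique(df["element_id"].to_numpy())
    volumes = (
        df.drop_duplicates("element_id").set_index("element_id")["volume_nm3"]
        .loc[elements].to_numpy()
    )
    stress: dict[int, np.ndarray] = {}
    strain: dict[int, np.ndarray] = {}
    for comp, grp in df.groupby("component"):
        pivot = grp.pivot_table(index="element_id", columns="time_s")
        for name, table in (("stress_Pa", stress), ("strain", strain)):
            if name in pivot.columns.get_level_values(0):
                block = pivot[name].loc[elements, times].to_numpy()
                if not np.all(np.isnan(block)):
                    table[int(comp)] = block
    v_rve = float(meta.get("V_RVE_nm3", volumes.sum()))
    field = ElementField(times=times, volumes=volumes, stress=stress,
                         strain=strain, V_RVE=v_rve)
    return field, meta


def load_yaml_config(path, allowed_keys: set[str]) -> dict:
    """Load a YAML mapping, rejecting unknown top-level keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - allowed_keys
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
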