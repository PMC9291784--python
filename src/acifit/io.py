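"""Readers, writers, unit conversion and configuration.

Gas-exchange tables arrive as CSV/TSV with one row per measurement. Two
column dialects ship by default: ``canonical`` (this package's own headers,
CO2 in Pa) and ``licor6800`` (LI-6800-style headers with CO2 as a mole
fraction in umol mol-1 and pressure column ``Pa`` in kPa). Mole-fraction CO2
converts to partial pressure via

    Ci[Pa] = Ci[umol mol-1] * Patm[kPa] * 1e-3

(e.g. 400 umol mol-1 at 101.3 kPa -> 40.52 Pa). Internal canonical units are
fixed: CO2 in Pa, O2 in kPa, temperature in degC, rates in umol m-2 s-1;
conversion happens only at this boundary.

Curves are re-sorted ascending in Ci on read — the model is order-free and
split-order measurement protocols inject noise — with the original row order
retained in curve metadata.

Configuration is a flat ``key = value`` text file (kinetic constants at
25 degC, activation energies, fluorescence factors), diffable and
language-neutral.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import ACiCurve, FitComparison, FitResult, GasExchangePoint

__all__ = [
    "ColumnDialect",
    "DIALECTS",
    "read_gas_exchange",
    "write_curve_csv",
    "write_fit_report",
    "read_fit_report",
    "read_config",
    "write_config",
]

logger = logging.getLogger(__name__)

_CANONICAL_FIELDS = ("A", "Ci", "Tleaf", "Qin", "PhiPS2", "O2", "Patm")


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from canonical field names to source column headers, plus the
    unit each CO2/O2 column is expressed in."""

    columns: Mapping[str, str]
    ci_unit: str = "Pa"       # "Pa" or "umol_mol"
    o2_unit: str = "kPa"      # "kPa" or "percent"

    def __post_init__(self) -> None:
        for mandatory in ("A", "Ci"):
            if mandatory not in self.columns:
                raise ValueError(f"dialect must map the mandatory column {mandatory!r}")
        if self.ci_unit not in ("Pa", "umol_mol"):
            raise ValueError(f"unsupported ci_unit {self.ci_unit!r}")
        if self.o2_unit not in ("kPa", "percent"):
            raise ValueError(f"unsupported o2_unit {self.o2_unit!r}")


DIALECTS: dict[str, ColumnDialect] = {
    "canonical": ColumnDialect(
        columns={f: f for f in _CANONICAL_FIELDS}, ci_unit="Pa", o2_unit="kPa"),
    "licor6800": ColumnDialect(
        columns={"A": "A", "Ci": "Ci", "Tleaf": "Tleaf", "Qin": "Qin",
                 "PhiPS2": "PhiPS2", "Patm": "Pa"},
        ci_unit="umol_mol", o2_unit="kPa"),
}

_DEFAULTS = {"Tleaf": 25.0, "Qin": 1500.0, "O2": 21.0, "Patm": 101.325}


def read_gas_exchange(path: str | Path,
                      dialect: str | ColumnDialect = "canonical",
                      curve_id: str | None = None) -> ACiCurve:
    """Read one A/Ci curve from a CSV/TSV file.

    Rows failing validation (non-finite A, Ci <= 0) are dropped with a
    logged count; remaining points are sorted ascending by Ci with the
    original row order kept in ``curve.metadata["source_order"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; available: "
                             f"{', '.join(sorted(DIALECTS))}") from None

    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    for canon in ("A", "Ci"):
        col = dialect.columns[canon]
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} (canonical {canon!r}) in {path}")

    def series(canon: str) -> pd.Series:
        col = dialect.columns.get(canon)
        if col is not None and col in df.columns:
            return pd.to_numeric(df[col], errors="coerce")
        return pd.Series(_DEFAULTS[canon], index=df.index, dtype=float)

    a = pd.to_numeric(df[dialect.columns["A"]], errors="coerce")
    ci = pd.to_numeric(df[dialect.columns["Ci"]], errors="coerce")
    tleaf, qin = series("Tleaf"), series("Qin")
    o2, patm = series("O2"), series("Patm")
    phi_col = dialect.columns.get("PhiPS2")
    phi = (pd.to_numeric(df[phi_col], errors="coerce")
           if phi_col is not None and phi_col in df.columns
           else pd.Series(np.nan, index=df.index))

    tleaf, qin, o2, patm = (s.fillna(_DEFAULTS[n]) for s, n in
                            zip((tleaf, qin, o2, patm), ("Tleaf", "Qin", "O2", "Patm")))
    if dialect.ci_unit == "umol_mol":
        ci = ci * patm * 1e-3
    if dialect.o2_unit == "percent":
        o2 = o2 / 100.0 * patm

    valid = a.notna() & ci.notna() & (ci > 0) & (patm > 0)
    bad_phi = phi.notna() & ~phi.between(0.0, 1.0)
    phi = phi.mask(bad_phi)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)

    rows = df.index[valid]
    if len(rows) == 0:
        raise ValueError(f"{path}: no valid rows")
    pts = [GasExchangePoint(
        a_obs=float(a[i]), ci=float(ci[i]), tleaf=float(tleaf[i]),
        qin=float(qin[i]),
        phi_ps2=None if pd.isna(phi[i]) else float(phi[i]),
        o2=float(o2[i]), patm=float(patm[i])) for i in rows]

    order = sorted(range(len(pts)), key=lambda i: pts[i].ci)
    curve = ACiCurve(
        points=[pts[i] for i in order],
        id=curve_id or path.stem,
        metadata={"path": str(path), "n_dropped": n_dropped,
                  "source_order": [int(rows[i]) for i in order]},
    )
    return curve


def write_curve_csv(curve: ACiCurve, path: str | Path) -> None:
    """Write a curve in the canonical dialect (round-trips through the reader)."""
    rows = [{"A": pt.a_obs, "Ci": pt.ci, "Tleaf": pt.tleaf, "Qin": pt.qin,
             "PhiPS2": "" if pt.phi_ps2 is None else repr(pt.phi_ps2),
             "O2": pt.o2, "Patm": pt.patm} for pt in curve.points]
    df = pd.DataFrame(rows, columns=list(_CANONICAL_FIELDS))
    for col in ("A", "Ci", "Tleaf", "Qin", "O2", "Patm"):
        df[col] = df[col].map(repr)  # full float precision
    df.to_csv(path, index=False)


_PARAM_ROWS = ("Vcmax", "J", "TPU", "gm", "RL", "alphaG", "alphaS", "SSR")
_ROW_GETTERS = {
    "Vcmax": lambda r: r.params.vcmax,
    "J": lambda r: r.params.j,
    "TPU": lambda r: r.params.tpu,
    "gm": lambda r: r.params.gm,
    "RL": lambda r: r.params.rl,
    "alphaG": lambda r: r.params.alpha_g if r.params.tpu is not None else None,
    "alphaS": lambda r: r.params.alpha_s if r.params.tpu is not None else None,
    "SSR": lambda r: r.ssr,
}


def write_fit_report(result: FitResult, path_prefix: str | Path,
                     comparison: FitComparison | None = None,
                     diagnostics: dict | None = None,
                     result_without: FitResult | None = None,
                     curve: ACiCurve | None = None) -> dict[str, Path]:
    """Write a fit report as three files.

    ``<prefix>.json`` — full results (reloadable via :func:`read_fit_report`);
    ``<prefix>_params.csv`` — one row per parameter, one column per fit
    variant, absent TPU-branch entries rendered as "-";
    ``<prefix>_points.csv`` — per-point Ci, A_obs, A_fit, limitation state,
    residual and (when supplied in ``diagnostics``) the PhiII trend.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload: dict = {"fit": result.to_dict()}
    if result_without is not None:
        payload["fit_without_tpu"] = result_without.to_dict()
    if comparison is not None:
        payload["comparison"] = dataclasses.asdict(comparison)
    if diagnostics is not None:
        payload["diagnostics"] = diagnostics
    jpath = prefix.with_suffix(".json")
    jpath.write_text(_json_dumps(payload))
    written["json"] = jpath

    variants = {}
    if result_without is not None:
        variants["without TPU"] = result_without
    variants["with TPU" if result.params.tpu is not None else "fit"] = result
    table = {name: [_fmt(_ROW_GETTERS[row](res)) for row in _PARAM_ROWS]
             for name, res in variants.items()}
    pdf = pd.DataFrame(table, index=list(_PARAM_ROWS))
    pdf.index.name = "parameter"
    ppath = prefix.parent / (prefix.name + "_params.csv")
    pdf.to_csv(ppath)
    written["params_csv"] = ppath

    rows = []
    trend = (diagnostics or {}).get("per_point_trend")
    idx_map = {}
    if trend is not None:
        idx_map = dict(zip((diagnostics or {}).get("point_indices", range(len(trend))), trend))
    for i in range(result.n_points):
        row = {"Ci": curve.points[i].ci if curve else None,
               "A_obs": curve.points[i].a_obs if curve else None,
               "A_fit": (curve.points[i].a_obs - float(result.residuals[i])) if curve else None,
               "state": result.states[i].value,
               "residual": float(result.residuals[i]),
               "phi_trend": idx_map.get(i, "")}
        rows.append(row)
    tpath = prefix.parent / (prefix.name + "_points.csv")
    pd.DataFrame(rows).to_csv(tpath, index=False)
    written["points_csv"] = tpath
    return written


def read_fit_report(json_path: str | Path) -> dict:
    """Reload a JSON fit report; ``"fit"`` (and ``"fit_without_tpu"`` when
    present) come back as :class:`FitResult` objects."""
    payload = json.loads(Path(json_path).read_text())
    out = dict(payload)
    out["fit"] = FitResult.from_dict(payload["fit"])
    if "fit_without_tpu" in payload:
        out["fit_without_tpu"] = FitResult.from_dict(payload["fit_without_tpu"])
    return out


def _fmt(v) -> str:
    if v is None:
        return "-"
    if isinstance(v, float) and math.isinf(v):
        return "inf"
    return f"{v:.6g}"


def _json_dumps(obj) -> str:
    def default(o):
        if isinstance(o, float) and math.isinf(o):  # pragma: no cover
            return "inf"
        raise TypeError(o)
    return json.dumps(_sanitize(obj), indent=2, sort_keys=True, default=default)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


# --- flat key = value configuration ---------------------------------------

CONFIG_KEYS = ("gamma_star_25", "kc_25", "ko_25", "o2",
               "ha_gamma_star", "ha_kc", "ha_ko",
               "absorptance", "beta_psii")


def read_config(path: str | Path) -> dict[str, float]:
    """Parse a flat ``key = value`` config; unknown keys raise."""
    cfg: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if key not in CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}; "
                             f"known: {', '.join(CONFIG_KEYS)}")
        cfg[key] = float(val)
    return cfg


def write_config(cfg: Mapping[str, float], path: str | Path) -> None:
    lines = [f"{k} = {cfg[k]!r}" for k in CONFIG_KEYS if k in cfg]
    Path(path).write_text("\n".join(lines) + "\n")
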