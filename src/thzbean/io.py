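"""File formats and run configuration: the pipeline's operational shell.

The ``thz-tsv`` dialect is a plain-text, self-describing container for
traces and transfer functions:

* header lines start with ``#``; the first must be ``# thz-tsv 1`` (format
  version); subsequent lines carry ``key=value`` metadata (kind, geometry,
  seed, the full JSON-encoded simulation config, a config hash);
* a ``# columns=...`` line names the tab-separated data columns — traces
  use ``t_ps, field``; spectra/transfer functions use
  ``f_THz, re, im, intensity, mask``;
* numeric payloads are written with 17 significant digits, so a
  write/read round trip reproduces every float bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .containers import FieldTrace, ThzTsvError, TransferFunction
from .fitting import FitConfig
from .phantom import CALIBRATION_VERSION, AcquisitionConfig

__all__ = ["write_trace", "read_trace", "write_transfer", "read_transfer",
           "RunConfig", "load_config", "config_hash"]

FORMAT_LINE = "# thz-tsv 1"
TRACE_COLUMNS = ("t_ps", "field")
TRANSFER_COLUMNS = ("f_THz", "re", "im", "intensity", "mask")

_JSON_META_KEYS = ("config", "vapor_lines", "orientation_factors",
                   "composite_weights")


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _encode_meta_value(key: str, value) -> str:
    if isinstance(value, (dict, list, tuple)) or key in _JSON_META_KEYS:
        return json.dumps(value, sort_keys=True, separators=(",", ":"))
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return _fmt(value)
    return str(value)


def _decode_meta_value(value: str):
    if value and value[0] in "[{":
        return json.loads(value)
    if value in ("true", "false"):
        return value == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def _write_header(fh, meta: dict, columns: tuple) -> None:
    fh.write(FORMAT_LINE + "\n")
    for key in sorted(meta):
        val = _encode_meta_value(key, meta[key])
        if "\n" in val or "\t" in val:
            raise ThzTsvError(f"metadata value for {key!r} contains "
                              "tabs/newlines")
        fh.write(f"# {key}={val}\n")
    fh.write("# columns=" + "\t".join(columns) + "\n")


def _read_header(lines) -> tuple[dict, tuple, int]:
    if not lines or lines[0].rstrip("\n") != FORMAT_LINE:
        raise ThzTsvError("line 1: missing or wrong format version header "
                          f"(expected {FORMAT_LINE!r})")
    meta: dict = {}
    columns: tuple | None = None
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if "=" not in body:
            raise ThzTsvError(f"line {i + 1}: malformed header line")
        key, _, value = body.partition("=")
        key = key.strip()
        if key == "columns":
            columns = tuple(value.split("\t"))
        else:
            meta[key] = _decode_meta_value(value)
        i += 1
    if columns is None:
        raise ThzTsvError("header ended without a columns line")
    return meta, columns, i


def _parse_rows(lines, start: int, ncol: int) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ThzTsvError(f"line {lineno}: expected {ncol} columns, "
                              f"got {len(parts)}")
        try:
            row = [float(p) for p in parts]
        except ValueError:
            raise ThzTsvError(f"line {lineno}: non-numeric value") from None
        if not all(np.isfinite(row)):
            raise ThzTsvError(f"line {lineno}: non-finite value")
        rows.append(row)
    if not rows:
        raise ThzTsvError("file contains no data rows")
    return np.asarray(rows, dtype=float)


def write_trace(trace: FieldTrace, path) -> None:
    """Write a field trace in the thz-tsv dialect."""
    meta = dict(trace.meta)
    meta["kind"] = trace.kind
    meta.setdefault("units", "t_ps:ps,field:arb")
    meta.setdefault("format", "thz-tsv")
    with open(path, "w") as fh:
        _write_header(fh, meta, TRACE_COLUMNS)
        for t, e in zip(trace.time, trace.field):
            fh.write(f"{_fmt(t)}\t{_fmt(e)}\n")


def read_trace(path) -> FieldTrace:
    """Read a thz-tsv trace; malformed files raise line-numbered errors."""
    with open(path) as fh:
        lines = fh.readlines()
    meta, columns, start = _read_header(lines)
    if columns != TRACE_COLUMNS:
        raise ThzTsvError(f"expected columns {TRACE_COLUMNS}, got {columns}")
    if "units" not in meta:
        raise ThzTsvError("header missing the units declaration")
    data = _parse_rows(lines, start, 2)
    time, field_vals = data[:, 0], data[:, 1]
    steps = np.diff(time)
    if time.size >= 2:
        bad = np.flatnonzero(np.abs(steps - steps[0]) > 1e-9)
        if steps[0] <= 0 or bad.size:
            row = (bad[0] + 2) if bad.size else 2
            raise ThzTsvError(
                f"line {start + row}: non-uniform time step"
            )
    kind = meta.pop("kind", "sample")
    return FieldTrace(time, field_vals, kind=kind, meta=meta)


def write_transfer(tf: TransferFunction, path) -> None:
    """Write a transfer function (or spectrum) in the thz-tsv dialect."""
    meta = dict(tf.meta)
    meta["geometry"] = tf.geometry
    meta.setdefault("units", "f_THz:THz,re:1,im:1,intensity:1,mask:bool")
    with open(path, "w") as fh:
        _write_header(fh, meta, TRANSFER_COLUMNS)
        intensity = tf.intensity
        for i in range(tf.frequency.size):
            fh.write(
                f"{_fmt(tf.frequency[i])}\t{_fmt(tf.values[i].real)}\t"
                f"{_fmt(tf.values[i].imag)}\t{_fmt(intensity[i])}\t"
                f"{int(tf.mask[i])}\n"
            )


def read_transfer(path) -> TransferFunction:
    """Read a thz-tsv transfer function."""
    with open(path) as fh:
        lines = fh.readlines()
    meta, columns, start = _read_header(lines)
    if columns != TRANSFER_COLUMNS:
        raise ThzTsvError(f"expected columns {TRANSFER_COLUMNS}, got {columns}")
    if "units" not in meta:
        raise ThzTsvError("header missing the units declaration")
    data = _parse_rows(lines, start, 5)
    geometry = meta.pop("geometry", "transmission")
    return TransferFunction(
        data[:, 0],
        data[:, 1] + 1j * data[:, 2],
        geometry=geometry,
        mask=data[:, 4] > 0.5,
        meta=meta,
    )


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

_DEFAULT_BINS = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Bundles the acquisition settings, the fit settings, the imaging bin
    edges and the reflectivity integration band; unknown keys in a config
    file are rejected rather than ignored.
    """

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    bins: tuple = _DEFAULT_BINS
    reflect_band: tuple = (0.2, 0.8)
    calibration_version: int = CALIBRATION_VERSION

    def to_dict(self) -> dict:
        return {
            "acquisition": self.acquisition.as_dict(),
            "fit": {k: getattr(self.fit, k)
                    for k in self.fit.__dataclass_fields__},
            "bins": list(self.bins),
            "reflect_band": list(self.reflect_band),
            "calibration_version": self.calibration_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"acquisition", "fit", "bins", "reflect_band",
                 "calibration_version"}
        unknown = set(d) - known
        if unknown:
            raise ThzTsvError(f"unknown config keys: {sorted(unknown)}")
        acq_d = dict(d.get("acquisition", {}))
        acq_known = set(AcquisitionConfig.__dataclass_fields__)
        bad = set(acq_d) - acq_known
        if bad:
            raise ThzTsvError(f"unknown acquisition keys: {sorted(bad)}")
        if "vapor_lines" in acq_d:
            acq_d["vapor_lines"] = tuple(tuple(x) for x in acq_d["vapor_lines"])
        fit_d = dict(d.get("fit", {}))
        fit_known = set(FitConfig.__dataclass_fields__)
        bad = set(fit_d) - fit_known
        if bad:
            raise ThzTsvError(f"unknown fit keys: {sorted(bad)}")
        for key in ("oscillator_centers", "weights", "band"):
            if key in fit_d:
                fit_d[key] = tuple(fit_d[key])
        return cls(
            acquisition=AcquisitionConfig(**acq_d),
            fit=FitConfig(**fit_d),
            bins=tuple(d.get("bins", _DEFAULT_BINS)),
            reflect_band=tuple(d.get("reflect_band", (0.2, 0.8))),
            calibration_version=d.get("calibration_version",
                                      CALIBRATION_VERSION),
        )


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True,
                         separators=(",", ":")).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a JSON run configuration, rejecting unknown keys."""
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))
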