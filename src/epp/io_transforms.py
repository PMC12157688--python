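"""Event-table input, logicle display transforms and out-of-range censoring.

Cytometry events arrive either as FCS 3.0/3.1 binary files or as plain
CSV/TSV tables (rows = events, columns = markers).  Raw intensities are
mapped onto the unit interval by the logicle biexponential transform
(linear around data zero, logarithmic at high signal) and any event with a
phenotyping-dimension value outside the closed interval [0, 1] is removed
before analysis, so the density grids can assume in-range data.
"""

from __future__ import annotations

import json
import logging
import math
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import EPPIOError, ValidationError

log = logging.getLogger("epp")

__all__ = [
    "EventMatrix",
    "TransformSpec",
    "Logicle",
    "read_events",
    "write_events_csv",
    "write_fcs",
    "load_transform_config",
    "transform_events",
    "censor",
]


@dataclass
class EventMatrix:
    """N x D event-by-marker matrix with bookkeeping that survives censoring.

    ``values`` holds unitless intensities; after ``transform_events`` every
    retained value of a phenotyping dimension lies in [0, 1].
    ``source_ids`` are the original row indices, stable through censoring.
    """

    values: np.ndarray
    marker_names: list[str]
    phenotyping_mask: np.ndarray
    source_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("event values must be a 2-D matrix")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValidationError("duplicate channel names: %r" % (self.marker_names,))
        if self.values.shape[1] != len(self.marker_names):
            raise ValidationError("marker_names length does not match columns")
        self.phenotyping_mask = np.asarray(self.phenotyping_mask, dtype=bool)
        self.source_ids = np.asarray(self.source_ids, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def phenotyping_dims(self) -> np.ndarray:
        return np.flatnonzero(self.phenotyping_mask)

    def take(self, row_mask: np.ndarray) -> "EventMatrix":
        return EventMatrix(
            self.values[row_mask],
            list(self.marker_names),
            self.phenotyping_mask.copy(),
            self.source_ids[row_mask],
        )


@dataclass(frozen=True)
class TransformSpec:
    """Logicle parameters for one dimension.

    T: top-of-scale raw value; M: total display decades; W: linearization
    width in decades (W = 0 degenerates to a rescaled arcsinh, as used for
    mass cytometry); A: additional negative display decades.
    """

    T: float
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.M > 0 and self.W >= 0):
            raise ValidationError(f"invalid logicle parameters {self}")
        if self.A < -self.W:
            raise ValidationError("negative decades A must be >= -W")


class Logicle:
    """Parks-Moore logicle function mapping raw scale values onto [0, 1].

    The biexponential inverse S(x) = a e^{bx} - c e^{-dx} - f is analytic;
    the forward transform solves S(x) = s by vectorized bisection (S is
    strictly increasing).  S(1) = T by construction.
    """

    def __init__(self, spec: TransformSpec) -> None:
        self.spec = spec
        T, M, W, A = spec.T, spec.M, spec.W, spec.A
        b = (M + A) * math.log(10.0)
        w = W / (M + A)
        x2 = A / (M + A)
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        if w == 0.0:
            d = b
        else:
            d = brentq(lambda u: 2.0 * (math.log(u) - math.log(b)) + w * (b + u),
                       1e-300, b, xtol=1e-15, rtol=1e-15)
        c_a = math.exp(x0 * (b + d))
        mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
        a = T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
        self._a, self._b, self._c, self._d, self._f = a, b, c_a * a, d, -mf_a * a
        self.x1 = x1  # display position of data zero

    def inverse(self, x):
        """Raw scale value at display position x (the biexponential)."""
        x = np.asarray(x, dtype=np.float64)
        return self._a * np.exp(self._b * x) - self._c * np.exp(-self._d * x) + self._f

    def transform(self, s):
        """Display position of raw value s, by bisection on the inverse."""
        s = np.asarray(s, dtype=np.float64)
        out = np.full(s.shape, np.nan)
        ok = np.isfinite(s)
        sv = s[ok]
        if sv.size:
            lo_val, hi_val = -2.0, 3.0
            while self.inverse(lo_val) > sv.min():
                lo_val -= 1.0
            while self.inverse(hi_val) < sv.max():
                hi_val += 1.0
            lo = np.full(sv.shape, lo_val)
            hi = np.full(sv.shape, hi_val)
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                below = self.inverse(mid) < sv
                lo = np.where(below, mid, lo)
                hi = np.where(below, hi, mid)
            out[ok] = 0.5 * (lo + hi)
        return out if out.ndim else float(out)


def read_events(path, format: str | None = None) -> EventMatrix:
    """Read an FCS 3.0/3.1 file or a delimited event table.

    Returns raw, untransformed intensities.  ``format`` is ``"fcs"`` or
    ``"csv"``; when omitted it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "fcs":
        values, names = _read_fcs(path)
    elif format == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        try:
            with open(path, encoding="utf-8") as fh:
                header = fh.readline().rstrip("\r\n")
            names = [c.strip() for c in header.split(sep)] if header else []
            df = pd.read_csv(path, sep=sep)
        except OSError as exc:
            raise EPPIOError(f"cannot parse event table {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64) if len(df) else np.empty((0, len(names)))
    else:
        raise ValidationError(f"unknown format {format!r}")
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate channel names in {path}: {names}")
    n = values.shape[0]
    return EventMatrix(values, names, np.ones(len(names), dtype=bool), np.arange(n))


def write_events_csv(events: EventMatrix, path) -> None:
    """Write the event values as a plain comma-separated table with header."""
    df = pd.DataFrame(events.values, columns=events.marker_names)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# minimal FCS 3.0/3.1 support

def _read_fcs(path: Path) -> tuple[np.ndarray, list[str]]:
    raw = path.read_bytes()
    if len(raw) < 58:
        raise EPPIOError(f"{path}: FCS HEADER segment truncated ({len(raw)} bytes)")
    version = raw[0:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise EPPIOError(f"{path}: HEADER does not start with FCS magic ({version!r})")

    def _offset(a: int, b: int, what: str) -> int:
        txt = raw[a:b].decode("ascii", "replace").strip()
        try:
            return int(txt) if txt else 0
        except ValueError:
            raise EPPIOError(f"{path}: garbled HEADER offset for {what}: {txt!r}")

    tb = _offset(10, 18, "TEXT begin")
    te = _offset(18, 26, "TEXT end")
    db = _offset(26, 34, "DATA begin")
    de = _offset(34, 42, "DATA end")
    if not (0 < tb < te < len(raw)):
        raise EPPIOError(f"{path}: TEXT segment offsets out of range ({tb}, {te})")
    text = raw[tb:te + 1]
    delim = text[0:1]
    if not delim:
        raise EPPIOError(f"{path}: empty TEXT segment")
    parts = text[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise EPPIOError(f"{path}: TEXT segment has an odd number of tokens")
    kw = {parts[i].decode("ascii", "replace").strip().upper():
          parts[i + 1].decode("ascii", "replace").strip()
          for i in range(0, len(parts), 2)}

    def _req(key: str) -> str:
        if key not in kw:
            raise EPPIOError(f"{path}: TEXT segment missing required keyword {key}")
        return kw[key]

    par = int(_req("$PAR"))
    tot = int(_req("$TOT"))
    dtype_code = _req("$DATATYPE").upper()
    byteord = _req("$BYTEORD")
    if db == 0 or de == 0:
        db = int(_req("$BEGINDATA"))
        de = int(_req("$ENDDATA"))
    endian = "<" if byteord.startswith("1") else ">"
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, par + 1)]
    if len(set(bits)) != 1:
        raise EPPIOError(f"{path}: mixed $PnB widths {sorted(set(bits))} unsupported")
    nbytes = bits[0] // 8
    if dtype_code == "F":
        np_dtype = np.dtype(endian + "f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(endian + "f8")
    elif dtype_code == "I":
        np_dtype = np.dtype(endian + {1: "u1", 2: "u2", 4: "u4"}.get(nbytes, "u4"))
    else:
        raise EPPIOError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    need = tot * par * np_dtype.itemsize
    data = raw[db:de + 1]
    if len(data) < need:
        raise EPPIOError(f"{path}: DATA segment holds {len(data)} bytes, "
                         f"need {need} for $TOT={tot} $PAR={par}")
    values = np.frombuffer(data[:need], dtype=np_dtype).reshape(tot, par)
    names = []
    for i in range(1, par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        names.append(name)
    return values.astype(np.float64), names


def write_fcs(path, values: np.ndarray, names: list[str]) -> None:
    """Write a minimal single-dataset FCS 3.1 file (float32, little endian)."""
    values = np.asarray(values, dtype="<f4")
    tot, par = values.shape
    data = values.tobytes()
    delim = "/"
    kv = {"$DATATYPE": "F", "$BYTEORD": "1,2,3,4", "$MODE": "L",
          "$PAR": str(par), "$TOT": str(tot), "$NEXTDATA": "0"}
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    # iterate: data offsets depend on the TEXT length
    begin_data = 256
    for _ in range(4):
        kv["$BEGINDATA"] = str(begin_data)
        kv["$ENDDATA"] = str(begin_data + len(data) - 1)
        kv["$BEGINANALYSIS"] = "0"
        kv["$ENDANALYSIS"] = "0"
        kv["$BEGINSTEXT"] = "0"
        kv["$ENDSTEXT"] = "0"
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
        text_end = 58 + len(text) - 1
        new_begin = text_end + 1
        if new_begin == begin_data:
            break
        begin_data = new_begin
    header = (f"FCS3.1    {58:8d}{text_end:8d}"
              f"{begin_data:8d}{begin_data + len(data) - 1:8d}{0:8d}{0:8d}")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(text.encode("ascii"))
        fh.write(data)


# ---------------------------------------------------------------------------
# transform configuration

def load_transform_config(path) -> dict:
    """Parse the transform/phenotyping config JSON.

    Schema: {"dimensions": [{"name", "T", "M", "W", "A", "phenotyping"}...],
    plus optional top-level algorithm keys passed through to EPPConfig.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    if "dimensions" not in cfg:
        raise ValidationError(f"{path}: transform config lacks 'dimensions'")
    return cfg


def transform_events(events: EventMatrix, config: dict) -> EventMatrix:
    """Apply per-dimension logicle transforms and set the phenotyping mask.

    Dimensions not named in the config are carried through untouched and
    marked non-phenotyping.
    """
    by_name = {d["name"]: d for d in config["dimensions"]}
    values = events.values.copy()
    mask = np.zeros(events.d, dtype=bool)
    for j, name in enumerate(events.marker_names):
        dim = by_name.get(name)
        if dim is None:
            continue
        spec = TransformSpec(T=float(dim["T"]), M=float(dim.get("M", 4.5)),
                             W=float(dim.get("W", 0.5)), A=float(dim.get("A", 0.0)))
        values[:, j] = Logicle(spec).transform(values[:, j])
        mask[j] = bool(dim.get("phenotyping", True))
    unknown = set(by_name) - set(events.marker_names)
    if unknown:
        raise ValidationError(f"config names unknown dimensions: {sorted(unknown)}")
    return EventMatrix(values, list(events.marker_names), mask, events.source_ids.copy())


def censor(events: EventMatrix) -> EventMatrix:
    """Drop every event with any phenotyping value outside the closed [0, 1].

    Non-finite values (NaN from non-finite raw input) are likewise censored.
    Idempotent; survivors keep their source ids and ordering.
    """
    dims = events.phenotyping_dims
    if dims.size == 0:
        return events.take(np.ones(events.n, dtype=bool))
    sub = events.values[:, dims]
    keep = np.all((sub >= 0.0) & (sub <= 1.0), axis=1)  # NaN compares False
    removed = int(events.n - keep.sum())
    if removed:
        log.info("censored %d of %d events outside [0, 1]", removed, events.n)
    return events.take(keep)
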