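"""FCS event-file I/O and the in-memory event container.

The toolkit stores and processes intensities on the LINEAR scale; display
transforms are never applied to stored data.  Files are written as FCS 3.1,
list mode, ``$DATATYPE F`` (one 32-bit float per value), and read back for
both FCS 3.0 and 3.1 with F/D/I data types.  Voltage metadata travels in the
standard ``$PnV`` keyword; scalar acquisition metadata (sample label,
dilution, voltage step) travels in ``CYTOTUNE_*`` custom keywords.  Per-event
ground-truth vectors produced by the simulator live only in memory / sidecar
CSVs, never inside the FCS payload.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .exceptions import (
    ConfigError,
    FcsParseError,
    IncompatibleChannelsError,
    InvalidTableError,
    UnsupportedFcsVersionError,
)

__all__ = ["ChannelDef", "EventTable", "read_fcs", "write_fcs", "concatenate"]

_DELIM = "/"
_META_PREFIX = "CYTOTUNE_"


@dataclass(frozen=True)
class ChannelDef:
    """One detector channel: name, assigned dye, PMT voltage, full scale."""

    detector: str
    fluorochrome: str | None = None
    pmt_voltage: float | None = None
    adc_max: float = defaults.ADC_MAX

    def __post_init__(self):
        if not self.detector:
            raise ConfigError("detector name must be non-empty")
        if self.adc_max <= 0:
            raise ConfigError("adc_max must be positive")
        if self.pmt_voltage is not None and not 0 <= self.pmt_voltage <= 1000:
            raise ConfigError(
                f"pmt_voltage {self.pmt_voltage} outside [0, 1000] V"
            )


@dataclass
class EventTable:
    """Events x channels intensity matrix with channel and run metadata.

    ``data`` is a float array with one row per event and one column per
    channel, on the linear scale.  ``meta`` may hold scalars (sample label,
    voltage, dilution) and per-event numpy arrays (simulation truth labels);
    array values must match the event count.
    """

    data: np.ndarray
    channels: list[ChannelDef]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidTableError("event data must be a 2-D matrix")
        if not self.channels:
            raise InvalidTableError("a table needs at least one channel")
        if self.data.shape[1] != len(self.channels):
            raise InvalidTableError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel definitions"
            )
        names = [c.detector for c in self.channels]
        if len(set(names)) != len(names):
            raise InvalidTableError("detector names must be unique")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise InvalidTableError("event intensities must be finite")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def detector_names(self) -> list[str]:
        return [c.detector for c in self.channels]

    def channel_index(self, detector: str) -> int:
        try:
            return self.detector_names.index(detector)
        except ValueError:
            raise KeyError(f"no channel named {detector!r}") from None

    def column(self, detector: str) -> np.ndarray:
        return self.data[:, self.channel_index(detector)]

    def channel(self, detector: str) -> ChannelDef:
        return self.channels[self.channel_index(detector)]

    def with_data(self, data: np.ndarray, **meta_updates) -> "EventTable":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EventTable(data=data, channels=list(self.channels), meta=meta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.detector_names)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def _format_number(x) -> str:
    f = float(x)
    return str(int(f)) if f == int(f) else repr(f)


def write_fcs(table: EventTable, path) -> None:
    """Write an EventTable as a single-dataset FCS 3.1 file.

    Values are stored as little-endian 32-bit floats; ``$PnV`` is emitted for
    channels with a known PMT voltage and scalar metadata is embedded as
    custom keywords so a write/read roundtrip preserves it.
    """
    if not table.channels:
        raise InvalidTableError("cannot write a table with no channels")
    n, p = table.data.shape

    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(p)),
        ("$TOT", str(n)),
    ]
    for i, ch in enumerate(table.channels, start=1):
        kw.append((f"$P{i}N", ch.detector))
        if ch.fluorochrome:
            kw.append((f"$P{i}S", ch.fluorochrome))
        kw.append((f"$P{i}B", "32"))
        kw.append((f"$P{i}E", "0,0"))
        kw.append((f"$P{i}R", _format_number(ch.adc_max)))
        if ch.pmt_voltage is not None:
            kw.append((f"$P{i}V", _format_number(ch.pmt_voltage)))
    for key, value in table.meta.items():
        if isinstance(value, (str, int, float, np.integer, np.floating)):
            kw.append((_META_PREFIX + str(key), str(value)))

    # $BEGINDATA/$ENDDATA are fixed-width so the TEXT length is known before
    # the offsets are.
    data_bytes = np.ascontiguousarray(table.data, dtype="<f4").tobytes()
    placeholder = "%010d"
    kw.insert(0, ("$ENDDATA", placeholder))
    kw.insert(0, ("$BEGINDATA", placeholder))

    def render(begin: int, end: int) -> bytes:
        parts = [_DELIM]
        for key, value in kw:
            if value == placeholder:
                value = "%010d" % (begin if key == "$BEGINDATA" else end)
            parts.append(f"{_escape(key)}{_DELIM}{_escape(value)}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text = render(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1 if data_bytes else 0
    text = render(data_begin, data_end)

    def off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:  # too large for the header; TEXT keywords authoritative
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + off(text_begin) + off(text_end)
    header += off(data_begin if data_end <= 99_999_999 else 0)
    header += off(data_end if data_end <= 99_999_999 else 0)
    header += off(0) + off(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    try:
        text = raw.decode("utf-8", errors="strict")
    except UnicodeDecodeError as exc:
        raise FcsParseError(f"TEXT segment is not valid text: {exc}") from None
    if not text:
        raise FcsParseError("empty TEXT segment")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters are escapes
    tokens: list[str] = []
    cur: list[str] = []
    i = 0
    while i < len(body):
        c = body[i]
        if c == delim:
            if i + 1 < len(body) and body[i + 1] == delim:
                cur.append(delim)
                i += 2
                continue
            tokens.append("".join(cur))
            cur = []
            i += 1
        else:
            cur.append(c)
            i += 1
    tokens.append("".join(cur))
    if len(tokens) % 2 != 0:
        raise FcsParseError("TEXT segment has an odd number of tokens")
    return {
        tokens[j].strip().upper() if tokens[j].startswith("$") else tokens[j].strip():
            tokens[j + 1]
        for j in range(0, len(tokens), 2)
    }


def _require(kw: dict[str, str], key: str) -> str:
    if key not in kw:
        raise FcsParseError(f"required keyword {key} missing from TEXT segment")
    return kw[key]


def _coerce_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def read_fcs(path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Channel names come from ``$PnN`` (display name ``$PnS`` becomes the
    fluorochrome), voltages from ``$PnV`` when present and the full scale
    from ``$PnR``.  Intensities are returned on the linear scale stored in
    the file.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58 or not blob.startswith(b"FCS"):
        raise FcsParseError(f"{path} is not an FCS file (bad magic)")
    version = blob[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFcsVersionError(
            f"unsupported FCS version {version!r}; only 3.0/3.1 are accepted"
        )

    def header_off(i: int) -> int:
        fielddata = blob[10 + 8 * i: 18 + 8 * i].decode("ascii", errors="replace").strip()
        try:
            return int(fielddata) if fielddata else 0
        except ValueError:
            raise FcsParseError(
                f"malformed header offset field {i}: {fielddata!r}"
            ) from None

    text_begin, text_end = header_off(0), header_off(1)
    if text_begin <= 0 or text_end < text_begin or text_end >= len(blob):
        raise FcsParseError("invalid TEXT segment offsets in header")
    kw = _parse_text_segment(blob[text_begin:text_end + 1])

    n_par = int(_require(kw, "$PAR"))
    n_tot = int(_require(kw, "$TOT"))
    datatype = _require(kw, "$DATATYPE").strip().upper()
    byteord = _require(kw, "$BYTEORD").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsParseError(f"unsupported $BYTEORD {byteord!r}")

    data_begin = header_off(2) or int(kw.get("$BEGINDATA", "0"))
    data_end = header_off(3) or int(kw.get("$ENDDATA", "0"))

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
        if any(b != 32 for b in bits):
            raise FcsParseError("$DATATYPE F requires $PnB 32 for all channels")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        widths = set(bits)
        if len(widths) != 1 or widths.pop() not in (16, 32):
            raise FcsParseError(
                "$DATATYPE I supported only with uniform $PnB of 16 or 32"
            )
        dtype = np.dtype(endian + ("u2" if bits[0] == 16 else "u4"))
    else:
        raise FcsParseError(f"unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    expected = n_values * dtype.itemsize
    if n_values == 0:
        data = np.empty((0, n_par), dtype=float)
    else:
        if data_begin <= 0 or data_end - data_begin + 1 < expected:
            raise FcsParseError(
                "$BEGINDATA/$ENDDATA do not span the expected "
                f"{expected} data bytes"
            )
        raw = blob[data_begin:data_begin + expected]
        data = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)

    channels = []
    for i in range(1, n_par + 1):
        name = _require(kw, f"$P{i}N")
        volt = kw.get(f"$P{i}V")
        channels.append(ChannelDef(
            detector=name,
            fluorochrome=kw.get(f"$P{i}S"),
            pmt_voltage=float(volt) if volt is not None else None,
            adc_max=float(kw.get(f"$P{i}R", defaults.ADC_MAX)),
        ))

    meta = {
        key[len(_META_PREFIX):]: _coerce_scalar(value)
        for key, value in kw.items()
        if key.startswith(_META_PREFIX)
    }
    meta["fcs_keywords"] = kw
    return EventTable(data=data, channels=channels, meta=meta)


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def concatenate(tables: list[EventTable], label_key: str) -> EventTable:
    """Row-wise concatenation of tables sharing identical channel layouts.

    Each input must carry a scalar ``meta[label_key]`` (e.g. its dilution or
    voltage); the output carries a per-event vector under the same key
    recording every event's source value.  Per-event metadata arrays present
    in all inputs are concatenated as well.
    """
    if not tables:
        raise ConfigError("concatenate requires at least one table")
    ref = tables[0].detector_names
    for t in tables[1:]:
        if t.detector_names != ref:
            diff = sorted(set(ref).symmetric_difference(t.detector_names)) or ref
            raise IncompatibleChannelsError(
                "tables have incompatible channel layouts; differing "
                f"detectors/order: {diff}"
            )
    labels = []
    for t in tables:
        if label_key not in t.meta:
            raise ConfigError(
                f"table missing meta[{label_key!r}] needed for concatenation"
            )
        value = t.meta[label_key]
        if isinstance(value, np.ndarray):
            raise ConfigError(f"meta[{label_key!r}] must be a scalar per table")
        labels.append(np.repeat(value, t.n_events))

    data = np.vstack([t.data for t in tables])
    meta: dict = {label_key: np.concatenate(labels) if labels else np.array([])}
    # carry per-event arrays shared by all tables (e.g. simulation truth)
    array_keys = set.intersection(*[
        {k for k, v in t.meta.items()
         if isinstance(v, np.ndarray) and v.shape[:1] == (t.n_events,)}
        for t in tables
    ]) if tables else set()
    for key in sorted(array_keys - {label_key}):
        meta[key] = np.concatenate([t.meta[key] for t in tables])
    # keep scalar meta that is constant across all inputs
    scalar_keys = set.intersection(*[
        {k for k, v in t.meta.items()
         if isinstance(v, (str, int, float, np.integer, np.floating))}
        for t in tables
    ]) if tables else set()
    for key in sorted(scalar_keys - {label_key}):
        values = {t.meta[key] for t in tables}
        if len(values) == 1:
            meta[key] = values.pop()
    return EventTable(data=data, channels=list(tables[0].channels), meta=meta)
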