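"""Text-format I/O for multichannel physiological recordings and angiographic annotations.

A recording file is UTF-8 CSV.  ``#``-prefixed header lines carry the sampling
rate (``fs_hz``), per-channel units, the protocol condition and the animal id;
the first non-comment row holds the channel labels and every following row one
sample per channel.  Time is implicit (sample index / fs) — the format carries
a single sampling rate for all channels.

An angiographic annotation file is CSV with header ``vessel,first_fill_frame``
plus a ``# frame_rate=<f>`` comment line.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "Recording",
    "AngioAnnotation",
    "WaveformFormatError",
    "CONDITIONS",
    "read_recording",
    "write_recording",
    "read_angio_annotation",
    "write_angio_annotation",
]

#: Protocol states: pump off / maximal pump flow, plus the pre/post dissection
#: assessment phases.
CONDITIONS = ("P0", "P8", "baseline", "post_dissection")


class WaveformFormatError(ValueError):
    """Raised when a waveform or annotation file violates the dialect."""


@dataclass
class Trace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : array-like of float
        Sample values; at least two, all finite.
    fs : float
        Sampling rate in Hz, > 0.
    unit : str
        Physical unit of the samples (e.g. ``mmHg``, ``cm/s``, ``ml``).
    label : str
        Channel name.
    """

    samples: np.ndarray
    fs: float
    unit: str = "a.u."
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError(
                f"trace {self.label!r}: need a 1-D signal of >=2 samples, "
                f"got shape {self.samples.shape}"
            )
        if not (self.fs > 0):
            raise ValueError(f"trace {self.label!r}: fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(
                f"trace {self.label!r}: non-finite sample at index {bad}"
            )

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def copy_with(self, samples=None, fs=None, unit=None, label=None) -> "Trace":
        return Trace(
            samples=self.samples.copy() if samples is None else samples,
            fs=self.fs if fs is None else fs,
            unit=self.unit if unit is None else unit,
            label=self.label if label is None else label,
        )


@dataclass
class Recording:
    """A named set of equally sampled channels plus condition metadata."""

    channels: dict[str, Trace]
    animal_id: str = ""
    condition: str = "baseline"
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording has no channels")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )
        fss = {t.fs for t in self.channels.values()}
        if len(fss) != 1:
            raise ValueError(f"channels carry mixed sampling rates: {sorted(fss)}")
        lens = {t.n for t in self.channels.values()}
        if len(lens) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lens)}")
        for label, tr in self.channels.items():
            if tr.label != label:
                tr.label = label

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n(self) -> int:
        return next(iter(self.channels.values())).n

    def __getitem__(self, label: str) -> Trace:
        return self.channels[label]


@dataclass
class AngioAnnotation:
    """First-fill frame indices per vessel at a known angiographic frame rate."""

    frame_rate: float
    fills: dict[str, int]

    def __post_init__(self) -> None:
        if not (self.frame_rate > 0):
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        norm: dict[str, int] = {}
        for vessel, frame in self.fills.items():
            v = vessel.strip().upper()
            f = int(frame)
            if f != frame or f < 0:
                raise ValueError(
                    f"vessel {v}: first-fill frame must be a non-negative "
                    f"integer, got {frame!r}"
                )
            if v in norm:
                raise ValueError(f"duplicate vessel {v!r}")
            norm[v] = f
        self.fills = norm


def _parse_header_lines(lines: list[tuple[int, str]]) -> dict:
    """Parse ``# key=value`` comment lines; returns dict with units sub-dict."""
    out: dict = {"units": {}, "meta": {}}
    for lineno, raw in lines:
        body = raw.lstrip("#").strip()
        if not body:
            continue
        if "=" not in body:
            raise WaveformFormatError(
                f"line {lineno}: malformed header comment {raw!r} (expected key=value)"
            )
        key, _, value = body.partition("=")
        key = key.strip()
        value = value.strip()
        if key.startswith("unit:"):
            out["units"][key[len("unit:"):]] = value
        elif key.startswith("meta:"):
            out["meta"][key[len("meta:"):]] = value
        else:
            out[key] = value
    return out


def read_recording(path: str | os.PathLike) -> Recording:
    """Read a waveform CSV file into a :class:`Recording`.

    Raises
    ------
    WaveformFormatError
        On a missing/garbled header, unequal column lengths, or any
        non-finite sample (the offending line/row is named; nothing is
        imputed or dropped silently).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.readlines()

    comments: list[tuple[int, str]] = []
    data_start = None
    for i, line in enumerate(raw_lines):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            comments.append((i + 1, s))
        else:
            data_start = i
            break
    if data_start is None:
        raise WaveformFormatError(f"{path}: no data rows found")

    header = _parse_header_lines(comments)
    if "fs_hz" not in header:
        raise WaveformFormatError(f"{path}: header is missing an fs_hz line")
    try:
        fs = float(header["fs_hz"])
    except ValueError as exc:
        raise WaveformFormatError(
            f"{path}: unparsable fs_hz value {header['fs_hz']!r}"
        ) from exc

    body = io.StringIO("".join(raw_lines[data_start:]))
    try:
        df = pd.read_csv(body, comment="#")
    except Exception as exc:
        raise WaveformFormatError(f"{path}: unreadable data table: {exc}") from exc
    if df.shape[0] < 2:
        raise WaveformFormatError(f"{path}: fewer than 2 sample rows")

    labels = [str(c) for c in df.columns]
    if len(set(labels)) != len(labels):
        raise WaveformFormatError(f"{path}: duplicate channel labels {labels}")

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # find the first non-numeric cell for the error message
        for j, lab in enumerate(labels):
            col = pd.to_numeric(df[lab], errors="coerce")
            bad = col.index[col.isna() & df[lab].notna()]
            if len(bad):
                raise WaveformFormatError(
                    f"{path}: non-numeric value in channel {lab!r} at data row "
                    f"{int(bad[0]) + 1}"
                )
        raise WaveformFormatError(f"{path}: non-numeric data")
    if not np.all(np.isfinite(values)):
        row = int(np.flatnonzero(~np.isfinite(values).all(axis=1))[0])
        raise WaveformFormatError(
            f"{path}: non-finite sample at data row {row + 1}"
        )

    units = header.get("units", {})
    channels = {
        lab: Trace(values[:, j], fs=fs, unit=units.get(lab, "a.u."), label=lab)
        for j, lab in enumerate(labels)
    }
    return Recording(
        channels=channels,
        animal_id=header.get("animal_id", ""),
        condition=header.get("condition", "baseline"),
        meta=header.get("meta", {}),
    )


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a :class:`Recording` in the dialect read by :func:`read_recording`.

    Floats are written with 17 significant digits so a write/read round trip
    reproduces samples to better than 1e-9 relative.
    """
    labels = list(rec.channels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={rec.fs:.10g}\n")
        fh.write(f"# animal_id={rec.animal_id}\n")
        fh.write(f"# condition={rec.condition}\n")
        for lab in labels:
            fh.write(f"# unit:{lab}={rec.channels[lab].unit}\n")
        for k in sorted(rec.meta):
            fh.write(f"# meta:{k}={rec.meta[k]}\n")
        fh.write(",".join(labels) + "\n")
        mat = np.column_stack([rec.channels[lab].samples for lab in labels])
        np.savetxt(fh, mat, delimiter=",", fmt="%.17g")


def read_angio_annotation(path: str | os.PathLike) -> AngioAnnotation:
    """Read a ``vessel,first_fill_frame`` CSV with a ``# frame_rate=`` comment."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()

    frame_rate = None
    rows: list[tuple[int, str, str]] = []
    saw_header = False
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if body.startswith("frame_rate"):
                _, _, val = body.partition("=")
                try:
                    frame_rate = float(val)
                except ValueError as exc:
                    raise WaveformFormatError(
                        f"{path}: line {i + 1}: bad frame_rate {val!r}"
                    ) from exc
            continue
        if not saw_header:
            cols = [c.strip().lower() for c in s.split(",")]
            if cols != ["vessel", "first_fill_frame"]:
                raise WaveformFormatError(
                    f"{path}: line {i + 1}: expected header "
                    f"'vessel,first_fill_frame', got {s!r}"
                )
            saw_header = True
            continue
        parts = s.split(",")
        if len(parts) != 2:
            raise WaveformFormatError(f"{path}: line {i + 1}: malformed row {s!r}")
        rows.append((i + 1, parts[0].strip(), parts[1].strip()))

    if frame_rate is None:
        raise WaveformFormatError(f"{path}: missing '# frame_rate=' header line")
    if not rows:
        raise WaveformFormatError(f"{path}: no vessel rows")

    fills: dict[str, int] = {}
    for lineno, vessel, frame in rows:
        v = vessel.upper()
        try:
            fval = float(frame)
        except ValueError as exc:
            raise WaveformFormatError(
                f"{path}: line {lineno}: non-numeric frame {frame!r}"
            ) from exc
        if not fval.is_integer():
            raise WaveformFormatError(
                f"{path}: line {lineno}: frame index {frame!r} is not an integer"
            )
        if fval < 0:
            raise WaveformFormatError(
                f"{path}: line {lineno}: negative frame index {frame!r}"
            )
        if v in fills:
            raise WaveformFormatError(
                f"{path}: line {lineno}: duplicate vessel {v!r}"
            )
        fills[v] = int(fval)
    return AngioAnnotation(frame_rate=frame_rate, fills=fills)


def write_angio_annotation(ann: AngioAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# frame_rate={ann.frame_rate:.10g}\n")
        fh.write("vessel,first_fill_frame\n")
        for vessel in ann.fills:
            fh.write(f"{vessel},{ann.fills[vessel]}\n")


def _isclose_rel(a: np.ndarray, b: np.ndarray, rtol: float = 1e-9) -> bool:
    return bool(np.allclose(a, b, rtol=rtol, atol=1e-12))


def recordings_equal(a: Recording, b: Recording, rtol: float = 1e-9) -> bool:
    """Structural + numerical equality used by round-trip checks."""
    if set(a.channels) != set(b.channels):
        return False
    if (a.animal_id, a.condition) != (b.animal_id, b.condition):
        return False
    if not math.isclose(a.fs, b.fs, rel_tol=1e-12):
        return False
    for lab in a.channels:
        ta, tb = a.channels[lab], b.channels[lab]
        if ta.unit != tb.unit or ta.n != tb.n:
            return False
        if not _isclose_rel(ta.samples, tb.samples, rtol):
            return False
    return True
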