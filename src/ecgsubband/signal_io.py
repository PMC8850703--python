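"""ECG signal containers, readers/writers, resampling, segmentation, normalization.

The package works on short single-lead ECG segments (a few QRS cycles at
250 Hz). Amplitude normalization is the two-step form used throughout
feature extraction: remove the segment mean, then divide by the maximum
absolute deviation, so every normalized segment lies in [-1, +1] and the
amplitude range of different recordings is eliminated while morphology is
preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .errors import (
    DegenerateSignalError,
    EmptySignalError,
    MissingFileError,
    ParseError,
    SignalTooShortError,
    WFDBFormatError,
)

logger = logging.getLogger("ecgsubband")

CLASS_LABELS = ("AF", "CHF", "NSR")


@dataclass
class ECGSignal:
    """One fixed-rate ECG segment.

    Parameters
    ----------
    samples : ndarray
        Real amplitudes in arbitrary units (file order).
    fs : float
        Sampling rate in Hz (default 250).
    label : str or None
        Optional rhythm class, one of ``AF``, ``CHF``, ``NSR``.
    record_id : str or None
        Opaque identifier for provenance tracking.
    """

    samples: np.ndarray
    fs: float = 250.0
    label: str | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise EmptySignalError(f"record {self.record_id!r} has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id!r} contains NaN/Inf samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass
class NormalizedSignal:
    """Amplitude-normalized segment: zero mean, max absolute value exactly 1."""

    samples: np.ndarray
    fs: float
    provenance: str | None = None
    label: str | None = None

    def __len__(self) -> int:
        return int(self.samples.size)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path,
    format: str = "csv",
    fs: float = 250.0,
    label: str | None = None,
    record_id: str | None = None,
    channel: int = 0,
    has_header: bool = False,
) -> ECGSignal:
    """Read one ECG record from disk.

    ``csv`` accepts either one sample per row or a single comma-separated
    row, plain decimal; ``wfdb`` reads a PhysioNet ``.hea``/``.dat`` pair
    (formats 16 and 212) taking ``channel`` (default 0).
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise MissingFileError(f"no such file: {path}")
        samples = _parse_csv(path, has_header=has_header)
        return ECGSignal(samples, fs=fs, label=label, record_id=record_id or path.stem)
    if format == "wfdb":
        sig, wfdb_fs = _read_wfdb(path, channel=channel)
        return ECGSignal(sig, fs=wfdb_fs, label=label, record_id=record_id or path.stem)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def _parse_csv(path: Path, has_header: bool) -> np.ndarray:
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if has_header and lineno == 1:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for token in line.split(","):
                token = token.strip()
                if not token:
                    continue
                try:
                    values.append(float(token))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric token {token!r} on line {lineno}"
                    ) from None
    if not values:
        raise EmptySignalError(f"{path}: no samples found")
    return np.asarray(values, dtype=float)


def write_csv(signal: ECGSignal | NormalizedSignal, path: str | Path) -> None:
    """Write one sample per row with full double precision (lossless round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Minimal WFDB reader (.hea + .dat, formats 16 and 212)
# ---------------------------------------------------------------------------

def _read_wfdb(path: Path, channel: int = 0) -> tuple[np.ndarray, float]:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise MissingFileError(f"no such header: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    try:
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise WFDBFormatError(f"{hea}: malformed record line") from exc
    if not 0 <= channel < n_sig:
        raise WFDBFormatError(f"channel {channel} out of range (record has {n_sig})")
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain = 200.0
        baseline = 0
        if len(parts) > 2:
            gfield = parts[2]
            if "(" in gfield:
                gain_s, base_s = gfield.split("(")
                gain = float(gain_s) if gain_s else 200.0
                baseline = int(base_s.rstrip(")"))
            else:
                gain = float(gfield.split("/")[0]) or 200.0
        specs.append((fname, int(fmt), gain, baseline))
    fname, fmt, gain, baseline = specs[channel]
    if any(s[0] != specs[0][0] for s in specs):
        raise WFDBFormatError("multi-file WFDB records are not supported")
    dat = hea.parent / fname
    if not dat.exists():
        raise MissingFileError(f"no such signal file: {dat}")
    raw = dat.read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        frames = flat[: (flat.size // n_sig) * n_sig].reshape(-1, n_sig)
        adc = frames[:, channel]
    elif fmt == 212:
        adc = _decode_212(raw, n_sig, channel)
    else:
        raise WFDBFormatError(f"unsupported WFDB format {fmt} (supported: 16, 212)")
    if n_samp:
        adc = adc[:n_samp]
    if adc.size == 0:
        raise EmptySignalError(f"{dat}: empty signal")
    return (adc - baseline) / gain, fs


def _decode_212(raw: bytes, n_sig: int, channel: int) -> np.ndarray:
    """Unpack pairs of 12-bit two's-complement samples from 3-byte groups."""
    usable = (len(raw) // 3) * 3
    b = np.frombuffer(raw[:usable], dtype=np.uint8).reshape(-1, 3).astype(np.int64)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(2 * len(b), dtype=np.int64)
    flat[0::2], flat[1::2] = s0, s1
    frames = flat[: (flat.size // n_sig) * n_sig].reshape(-1, n_sig)
    return frames[:, channel]


# ---------------------------------------------------------------------------
# Resampling / segmentation / normalization
# ---------------------------------------------------------------------------

def resample(x: ECGSignal, target_fs: float) -> ECGSignal:
    """Rational (polyphase) resampling with anti-aliasing low-pass.

    Output length is ``round(len(x) * target_fs / x.fs)``; identity when the
    rates already match.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == x.fs:
        return ECGSignal(x.samples.copy(), fs=x.fs, label=x.label, record_id=x.record_id)
    frac = Fraction(target_fs / x.fs).limit_denominator(1000)
    y = resample_poly(x.samples, frac.numerator, frac.denominator)
    n_out = round(len(x) * target_fs / x.fs)
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return ECGSignal(y, fs=target_fs, label=x.label, record_id=x.record_id)


def segment(x: ECGSignal, window_s: float = 2.0, hop_s: float | None = None) -> list[ECGSignal]:
    """Cut fixed-length windows; trailing partial windows are dropped.

    Default is non-overlapping 2 s windows (hop = window), matching a few
    QRS cycles at typical heart rates. Segments inherit the record's label.
    """
    if hop_s is None:
        hop_s = window_s
    n_win = round(window_s * x.fs)
    n_hop = round(hop_s * x.fs)
    if n_win < 2:
        raise SignalTooShortError(f"window of {n_win} samples is below the 2-sample minimum")
    if n_hop <= 0:
        raise ValueError("hop must be positive")
    if len(x) < n_win:
        logger.warning(
            "record %s: %d samples shorter than %d-sample window; no segments",
            x.record_id, len(x), n_win,
        )
        return []
    out = []
    for i, start in enumerate(range(0, len(x) - n_win + 1, n_hop)):
        out.append(
            ECGSignal(
                x.samples[start : start + n_win].copy(),
                fs=x.fs,
                label=x.label,
                record_id=f"{x.record_id}_seg{i}" if x.record_id else None,
            )
        )
    return out


def normalize(x: ECGSignal | np.ndarray) -> NormalizedSignal:
    """Two-step amplitude normalization.

    y(n) = x(n) - mean(x);  z(n) = y(n) / max|y(n)|

    The population mean is taken over the full segment; the result has zero
    mean and max absolute amplitude exactly 1. Constant input is rejected
    (the division is undefined, and mapping to zeros would later poison
    mobility with 0/0).
    """
    if isinstance(x, ECGSignal):
        samples, fs, rid, label = x.samples, x.fs, x.record_id, x.label
    else:
        samples = np.asarray(x, dtype=float)
        fs, rid, label = 250.0, None, None
    if samples.size < 2:
        raise SignalTooShortError("normalization needs at least 2 samples")
    if np.ptp(samples) == 0:
        raise DegenerateSignalError(
            f"record {rid!r} is constant; amplitude normalization undefined"
        )
    y = samples - samples.mean()
    z = y / np.max(np.abs(y))
    return NormalizedSignal(z, fs=fs, provenance=rid, label=label)
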