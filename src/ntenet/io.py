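"""Reading and writing recordings: CSV (+ JSON sidecar) and EDF+.

CSV dialect: comma-separated, one row per sample, header row with the 14
channel labels plus a final ``state`` column (empty string where no state
is annotated). The sampling rate travels in a JSON sidecar (or is passed
explicitly). CSV round-trips recordings bit-exactly and is the primary
on-disk format.

EDF+ files are written by a small built-in writer (16-bit, 1-second data
records, states encoded as EDF+ annotations) and read through MNE. EDF is
an integer format: amplitudes are quantized to the 16-bit grid and the
last record is zero-padded to a whole second, so EDF round-trips are
close-but-not-bit-exact; use CSV where exactness matters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, N_CHANNELS
from .datasets import CouplingSpec, SubjectProfile
from .recording import Annotation, MultichannelRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# CSV


def write_csv(rec: MultichannelRecording, path) -> None:
    """Write a recording as CSV with a per-sample state column."""
    state = np.full(rec.n_samples, "", dtype=object)
    for ann in rec.annotations:
        state[ann.start:ann.stop] = ann.state
    df = pd.DataFrame(rec.samples.T, columns=list(CHANNELS))
    df["state"] = state
    # %.17g keeps every float64 bit so the CSV round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g")


def _annotations_from_states(states: np.ndarray) -> list[Annotation]:
    """Contiguous runs of a non-empty state label become annotations."""
    out: list[Annotation] = []
    start = None
    current = ""
    for i, s in enumerate(list(states) + [""]):
        if s != current:
            if current:
                out.append(Annotation(current, start, i))
            start, current = i, s
    return out


def read_csv(path, fs: float | None = None) -> MultichannelRecording:
    """Read a CSV recording; ``fs`` comes from a sidecar or the caller."""
    df = pd.read_csv(path, dtype={"state": str}, keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(
            f"CSV {path} is missing required channel(s): {', '.join(missing)}"
        )
    if fs is None:
        sidecar = Path(path).with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"no sampling rate: pass fs or provide sidecar {sidecar}"
            )
        fs = float(json.loads(sidecar.read_text())["fs"])
    samples = df[list(CHANNELS)].to_numpy(dtype=float).T
    states = df["state"].to_numpy() if "state" in df.columns else \
        np.full(samples.shape[1], "")
    return MultichannelRecording(samples, fs, _annotations_from_states(states))


def write_sidecar(
    path, fs: float, profile: SubjectProfile | None = None,
    coupling: CouplingSpec | None = None,
) -> None:
    """JSON sidecar with sampling rate and, for synthetic data, the
    generating profile and ground-truth coupling."""
    payload: dict = {"fs": fs}
    if profile is not None:
        payload["profile"] = dataclasses.asdict(profile)
    if coupling is not None:
        payload["coupling"] = coupling.matrix.tolist()
    Path(path).with_suffix(".json").write_text(json.dumps(payload, indent=1))


def read_sidecar(path) -> dict:
    data = json.loads(Path(path).with_suffix(".json").read_text())
    if "coupling" in data:
        data["coupling"] = CouplingSpec(np.asarray(data["coupling"]))
    if "profile" in data:
        data["profile"] = SubjectProfile(**data["profile"])
    return data


# ---------------------------------------------------------------------------
# EDF+


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: MultichannelRecording, path) -> None:
    """Write an EDF+C file: 14 int16 signals plus a TAL annotation channel.

    One-second data records; the final record is zero-padded. State spans
    are stored as EDF+ annotations in the first record's TAL stream.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((N_CHANNELS, n_records * spr))
    padded[:, :rec.n_samples] = rec.samples

    # Physical range per file (shared across channels keeps scaling simple).
    lo = float(np.floor(padded.min())) - 1.0
    hi = float(np.ceil(padded.max())) + 1.0
    gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
    digital = np.round((padded - lo) * gain + _DIG_MIN).astype("<i2")

    # TAL streams: record-start timestamp in every record, state
    # annotations appended to record 0.
    tals = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00"
        if r == 0:
            for ann in rec.annotations:
                onset = ann.start / fs
                dur = ann.n_samples / fs
                tal += f"+{onset:.4f}\x15{dur:.4f}\x14{ann.state}\x14\x00"
        tals.append(tal.encode("ascii"))
    tal_bytes = max(max(len(t) for t in tals), 2)
    tal_bytes += tal_bytes % 2  # even so it maps to int16 "samples"
    ann_spr = tal_bytes // 2

    ns = N_CHANNELS + 1
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 02-JAN-2000 X X X", 80),
        _pad("02.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    labels = [f"EEG {c}" for c in CHANNELS] + ["EDF Annotations"]
    fields = [
        (labels, 16),
        ([""] * ns, 80),                                     # transducer
        (["uV"] * N_CHANNELS + [""], 8),                     # phys dim
        ([f"{lo:.6g}"] * N_CHANNELS + ["-1"], 8),            # phys min
        ([f"{hi:.6g}"] * N_CHANNELS + ["1"], 8),             # phys max
        ([str(_DIG_MIN)] * ns, 8),
        ([str(_DIG_MAX)] * ns, 8),
        ([""] * ns, 80),                                     # prefiltering
        ([str(spr)] * N_CHANNELS + [str(ann_spr)], 8),
        ([""] * ns, 32),
    ]
    for values, width in fields:
        header += b"".join(_pad(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
            fh.write(tals[r].ljust(tal_bytes, b"\x00"))


def read_edf(path) -> MultichannelRecording:
    """Read an EDF/EDF+ file via MNE, reordering channels canonically."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = {}
    for idx, name in enumerate(raw.ch_names):
        stripped = name.removeprefix("EEG ").strip()
        names[stripped.upper()] = idx
    missing = [c for c in CHANNELS if c.upper() not in names]
    if missing:
        raise ValueError(
            f"EDF {path} is missing required channel(s): {', '.join(missing)}"
        )
    fs = float(raw.info["sfreq"])
    data = raw.get_data(units="uV")
    order = [names[c.upper()] for c in CHANNELS]
    samples = data[order]
    annotations = []
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration,
        raw.annotations.description,
    ):
        start = int(round(onset * fs))
        stop = start + int(round(dur * fs))
        annotations.append(Annotation(str(desc), start,
                                      min(stop, samples.shape[1])))
    return MultichannelRecording(samples, fs, annotations)


def read_recording(path, format: str | None = None,
                   fs: float | None = None) -> MultichannelRecording:
    """Read a recording, dispatching on ``format`` or the file suffix."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_csv(path, fs=fs)
    if fmt == "edf":
        return read_edf(path)
    raise ValueError(f"unknown recording format {fmt!r} (expected csv or edf)")
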