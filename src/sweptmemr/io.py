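"""File formats: WAV sessions with JSON sidecars, CSV matrices and tables.

Waveforms are stored as float PCM WAV (bit-exact round trip) next to a
JSON sidecar that carries the schedule, sample rate and — for synthetic
sessions — the simulator parameters and seed.  Binned matrices, LGFs and
feature tables travel as CSV with complex values split into re_/im_
columns, so every artifact is diff-able plain text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .curves import TotalChangeLGF
from .preprocess import BinnedResponseMatrix
from .schedule import DiscreteScheduleSpec, SweptScheduleSpec

__all__ = [
    "FORMAT_VERSION",
    "SessionRecording",
    "SessionSidecar",
    "write_session",
    "read_session",
    "matrix_to_frame",
    "frame_to_matrix",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_lgf_csv",
    "features_to_frame",
    "load_config",
]

FORMAT_VERSION = "1"


@dataclass
class SessionRecording:
    """Single-channel probe-microphone waveform at a fixed sample rate."""

    samples: np.ndarray
    fs: float = 96_000.0


@dataclass
class SessionSidecar:
    """Metadata stored beside a session WAV."""

    schedule: object  # SweptScheduleSpec | DiscreteScheduleSpec
    fs: float = 96_000.0
    channel_map: dict = field(default_factory=lambda: {"probe_mic": 0})
    simulation: dict | None = None
    version: str = FORMAT_VERSION

    def to_dict(self) -> dict:
        paradigm = "swept" if isinstance(self.schedule, SweptScheduleSpec) else "discrete"
        return {
            "version": self.version,
            "fs": self.fs,
            "paradigm": paradigm,
            "schedule": dataclasses.asdict(self.schedule),
            "channel_map": self.channel_map,
            "simulation": self.simulation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSidecar":
        version = str(d.get("version"))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported sidecar format version {version!r} "
                f"(this reader supports {FORMAT_VERSION!r})"
            )
        sched_cls = SweptScheduleSpec if d["paradigm"] == "swept" else DiscreteScheduleSpec
        sched_kwargs = dict(d["schedule"])
        for key in ("ascending_levels", "descending_levels"):
            if key in sched_kwargs:
                sched_kwargs[key] = tuple(sched_kwargs[key])
        return cls(
            schedule=sched_cls(**sched_kwargs),
            fs=float(d["fs"]),
            channel_map=d.get("channel_map", {"probe_mic": 0}),
            simulation=d.get("simulation"),
            version=version,
        )


def _sidecar_path(wav_path: Path) -> Path:
    return wav_path.with_suffix(".json")


def write_session(path, recording: SessionRecording, sidecar: SessionSidecar) -> Path:
    """Write WAV (float32 PCM) + JSON sidecar; returns the WAV path."""
    wav_path = Path(path).with_suffix(".wav")
    if recording.fs != sidecar.fs:
        raise ValueError("recording and sidecar sample rates disagree")
    wavfile.write(wav_path, int(recording.fs), recording.samples.astype(np.float32))
    _sidecar_path(wav_path).write_text(json.dumps(sidecar.to_dict(), indent=1))
    return wav_path


def read_session(path) -> tuple[SessionRecording, SessionSidecar]:
    """Read a WAV + sidecar pair, checking version and sample rate."""
    wav_path = Path(path).with_suffix(".wav")
    sc_path = _sidecar_path(wav_path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar {sc_path}")
    sidecar = SessionSidecar.from_dict(json.loads(sc_path.read_text()))
    fs, samples = wavfile.read(wav_path)
    if float(fs) != float(sidecar.fs):
        raise ValueError(
            f"WAV sample rate {fs} Hz disagrees with sidecar {sidecar.fs} Hz"
        )
    return SessionRecording(samples=samples, fs=float(fs)), sidecar


def matrix_to_frame(matrix: BinnedResponseMatrix) -> pd.DataFrame:
    """Flatten a binned matrix to the CSV schema (re_/im_ per bin)."""
    n_g, n_c, _ = matrix.values.shape
    g_idx, c_idx = np.meshgrid(np.arange(n_g), np.arange(n_c), indexing="ij")
    data = {
        "sweep": g_idx.ravel(),
        "click": c_idx.ravel(),
        "time_s": matrix.time_s.ravel(),
        "elicitor_db_fpl": matrix.levels_db.ravel(),
        "flag": matrix.flags.ravel().astype(int),
    }
    for b, fc in enumerate(matrix.bin_centers):
        data[f"re_{int(round(fc))}"] = matrix.values[:, :, b].real.ravel()
        data[f"im_{int(round(fc))}"] = matrix.values[:, :, b].imag.ravel()
    return pd.DataFrame(data)


def frame_to_matrix(frame: pd.DataFrame, paradigm: str = "swept") -> BinnedResponseMatrix:
    """Rebuild a binned matrix from its CSV schema."""
    bins = sorted(
        int(col[3:]) for col in frame.columns if col.startswith("re_")
    )
    n_g = int(frame["sweep"].max()) + 1
    n_c = int(frame["click"].max()) + 1
    shape = (n_g, n_c)
    values = np.zeros((*shape, len(bins)), dtype=complex)
    frame = frame.sort_values(["sweep", "click"])
    for b, fc in enumerate(bins):
        values[:, :, b] = (
            frame[f"re_{fc}"].to_numpy() + 1j * frame[f"im_{fc}"].to_numpy()
        ).reshape(shape)
    return BinnedResponseMatrix(
        values=values,
        bin_centers=np.asarray(bins, dtype=float),
        time_s=frame["time_s"].to_numpy().reshape(shape),
        levels_db=frame["elicitor_db_fpl"].to_numpy().reshape(shape),
        paradigm=paradigm,
        flags=frame["flag"].to_numpy().astype(bool).reshape(shape),
    )


def write_matrix_csv(path, matrix: BinnedResponseMatrix) -> None:
    matrix_to_frame(matrix).to_csv(path, index=False)


def read_matrix_csv(path, paradigm: str = "swept") -> BinnedResponseMatrix:
    return frame_to_matrix(pd.read_csv(path), paradigm=paradigm)


def write_lgf_csv(path, lgf: TotalChangeLGF, per_bin: bool = False) -> None:
    data = {
        "time_s": lgf.time_s,
        "elicitor_db_fpl": lgf.levels_db,
        "tc_linear": lgf.tc,
        "tc_db": lgf.tc_db,
    }
    if per_bin and lgf.per_bin_tc is not None:
        for b, fc in enumerate(lgf.bin_centers):
            data[f"tc_{int(round(fc))}"] = lgf.per_bin_tc[b]
    pd.DataFrame(data).to_csv(path, index=False)


def features_to_frame(features_list, subjects=None, repeats=None) -> pd.DataFrame:
    """Features table: one row per test (subject, repeat, five measures, flags)."""
    rows = []
    for i, feat in enumerate(features_list):
        row = {"subject": 0 if subjects is None else subjects[i],
               "repeat": i if repeats is None else repeats[i]}
        row.update(feat.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg
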