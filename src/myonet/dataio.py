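"""Reading and writing recordings, trained models, and metric reports.

Signals travel as delimited text (the layout of public lower-limb sEMG
exports: four electrode columns plus one goniometer column), model weights
as a NumPy ``.npz`` container with named blocks, and metric reports as JSON.
Angles are degrees throughout; sample indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .movements import MovementClass

COHORTS = ("healthy", "knee_pathology", "synthetic")


@dataclasses.dataclass
class Recording:
    """One subject/movement trial.

    Attributes
    ----------
    emg : ndarray of shape (n_samples, n_channels)
        Raw multichannel sEMG, arbitrary amplitude units.
    angle : ndarray of shape (n_samples,)
        Knee joint angle in degrees, aligned sample-for-sample with ``emg``.
    fs : float
        Sampling frequency in Hz.
    cls : MovementClass
        Movement label for the whole trial (no transition phases).
    subject_id : str
        Identifier of the subject/trial the data came from.
    cohort : str
        One of ``healthy``, ``knee_pathology``, ``synthetic``.
    """

    emg: np.ndarray
    angle: np.ndarray
    fs: float
    cls: MovementClass
    subject_id: str
    cohort: str = "synthetic"

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.emg.ndim != 2:
            raise ValueError("emg must be 2-D [n_samples, n_channels]")
        if self.angle.ndim != 1:
            raise ValueError("angle must be 1-D")
        if self.emg.shape[0] != self.angle.shape[0]:
            raise ValueError(
                f"emg has {self.emg.shape[0]} samples but angle has "
                f"{self.angle.shape[0]}"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}")
        self.cls = MovementClass.from_any(self.cls)
        if np.isnan(self.emg).any() or np.isnan(self.angle).any():
            raise ValueError("recording contains missing values")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]


@dataclasses.dataclass
class ColumnMap:
    """Where each signal lives in a delimited-text file.

    The public dataset's export dialect is not standardized, so the reader
    is fully configurable: delimiter, header rows to skip, and the 0-based
    column index of each sEMG channel and of the goniometer angle.
    """

    channel_columns: Sequence[int] = (0, 1, 2, 3)
    angle_column: int = 4
    delimiter: str = "\t"
    skip_rows: int = 1
    fs: float = 1000.0

    def __post_init__(self):
        cols = list(self.channel_columns) + [self.angle_column]
        if len(set(cols)) != len(cols):
            raise ValueError("mapped column indices must be distinct")
        if any(c < 0 for c in cols):
            raise ValueError("column indices must be non-negative")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


def read_recording(
    path,
    colmap: ColumnMap | None = None,
    cls: MovementClass | int | str = MovementClass.WALKING,
    subject_id: str = "unknown",
    cohort: str = "healthy",
) -> Recording:
    """Read a delimited-text trial into a :class:`Recording`.

    Rows are kept in file order.  Any non-numeric or missing cell in a
    mapped column raises with the offending (0-based, post-header) row.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=colmap.delimiter,
        skiprows=colmap.skip_rows,
        header=None,
        dtype=str,
        engine="python",
    )
    needed = list(colmap.channel_columns) + [colmap.angle_column]
    width = df.shape[1]
    bad = [c for c in needed if c >= width]
    if bad:
        raise ValueError(
            f"{path}: file has {width} columns but the column map requests "
            f"column(s) {bad}"
        )
    numeric = df[needed].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric or missing value at data row {row}")
    emg = numeric[list(colmap.channel_columns)].to_numpy(dtype=float)
    angle = numeric[colmap.angle_column].to_numpy(dtype=float)
    return Recording(
        emg=emg, angle=angle, fs=colmap.fs, cls=cls,
        subject_id=subject_id, cohort=cohort,
    )


def write_recording(rec: Recording, path, delimiter: str = "\t",
                    fmt: str = "%.6f") -> None:
    """Write a recording in the layout :func:`read_recording` consumes.

    Columns ``ch1..chN`` then ``angle``, one header row, tab-separated by
    default.  Round-trip error is bounded by the ``fmt`` precision.
    """
    path = Path(path)
    header = delimiter.join(
        [f"ch{i + 1}" for i in range(rec.n_channels)] + ["angle"]
    )
    data = np.column_stack([rec.emg, rec.angle])
    np.savetxt(path, data, fmt=fmt, delimiter=delimiter, header=header,
               comments="")


_MODEL_FORMAT_VERSION = 1


def save_model(model, path) -> None:
    """Serialize a trained network to an ``.npz`` container.

    Weights are stored under ``<block>/<param>`` keys so the three named
    blocks (``feature_extractor``, ``angle_head``, ``classification_head``)
    survive the round trip by name; config and training stage travel in a
    JSON sidecar key.
    """
    arrays = {}
    for block_name, params in model.named_blocks().items():
        for pname, arr in params.items():
            arrays[f"{block_name}/{pname}"] = arr
    meta = {
        "format_version": _MODEL_FORMAT_VERSION,
        "training_stage": model.training_stage,
        "config": model.config_dict(),
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path):
    """Load a network saved by :func:`save_model`.

    Raises ``ValueError`` on a missing/corrupted header or a format-version
    mismatch; shape mismatches surface when weights are assigned.
    """
    from .lrcn import LrcnConfig, LrcnNetwork

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with np.load(path) as npz:
            if "__meta__" not in npz:
                raise ValueError(f"{path}: not a myonet model file (no header)")
            meta = json.loads(bytes(npz["__meta__"].tobytes()).decode("utf-8"))
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path}: corrupted model container: {exc}") from exc
    if meta.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version "
            f"{meta.get('format_version')!r}"
        )
    cfg_dict = dict(meta["config"])
    y_center = cfg_dict.pop("_y_center", 0.0)
    y_scale = cfg_dict.pop("_y_scale", 1.0)
    cfg = LrcnConfig(**cfg_dict)
    net = LrcnNetwork(cfg)
    net.training_stage = meta["training_stage"]
    net.y_center = y_center
    net.y_scale = y_scale
    blocks: dict[str, dict[str, np.ndarray]] = {}
    for key, arr in arrays.items():
        block, pname = key.split("/", 1)
        blocks.setdefault(block, {})[pname] = arr
    net.set_block_weights(blocks)
    return net


def write_metrics_report(report, path) -> None:
    """Write a :class:`~myonet.evaluate.MetricsReport` as JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def read_metrics_report(path):
    """Read a JSON metrics report back into a MetricsReport."""
    from .evaluate import MetricsReport

    with open(path) as fh:
        return MetricsReport.from_dict(json.load(fh))
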