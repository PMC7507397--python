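"""File I/O: recordings as SNIRF (HDF5) or a plain TSV dialect, event
tables as BIDS-style events.tsv, and result tables.

The TSV recording dialect is a wide table with a ``time`` column followed
by one column per (participant, channel, component), named
``p{P}_ch{CC}_{label}``, where the component label is ``wl<nm>`` for
intensity/optical-density stages and ``hbo``/``hbr`` for the hemoglobin
stage.  Metadata travel in ``#``-prefixed header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import constants
from .errors import ValidationError
from .signal_synthesis import HyperscanRecording

__all__ = [
    "write_recording_tsv",
    "read_recording_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "write_snirf",
    "read_snirf",
    "write_table",
]

_FLOAT_FMT = "%.9g"


def _component_labels(rec: HyperscanRecording) -> list[str]:
    if rec.stage == "hb":
        return ["hbo", "hbr"]
    return [f"wl{int(round(w))}" for w in rec.wavelengths]


def write_events_tsv(timeline: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    timeline.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"events table missing columns: {sorted(missing)}")
    segs = df[df["trial_type"].isin(constants.SEGMENT_LABELS)].sort_values("onset")
    ends = (segs["onset"] + segs["duration"]).to_numpy()
    if np.any(segs["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
        raise ValidationError("overlapping segments in events table")
    return df.sort_values("onset", ignore_index=True, kind="stable")


def write_recording_tsv(rec: HyperscanRecording, path: str | Path) -> Path:
    path = Path(path)
    labels = _component_labels(rec)
    header = {
        "dyad_id": rec.dyad_id,
        "stage": rec.stage,
        "fs": rec.fs,
        "wavelengths": list(rec.wavelengths),
        "source_detector_distance": rec.source_detector_distance,
        "strategy": rec.strategy,
        "bad_channels": [
            [int(c) + 1 for c in np.nonzero(rec.bad_channels[p])[0]] for p in range(2)
        ],
    }
    cols = {"time": np.arange(rec.n_times) / rec.fs}
    for p in range(2):
        for c in range(rec.n_channels):
            for k, lab in enumerate(labels):
                cols[f"p{p + 1}_ch{c + 1:02d}_{lab}"] = rec.data[p, c, k]
    frame = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# dyadsync-recording {json.dumps(header)}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_recording_tsv(path: str | Path, timeline: pd.DataFrame | None = None) -> HyperscanRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# dyadsync-recording "):
            raise ValidationError(f"{path}: missing recording header line")
        try:
            header = json.loads(first[len("# dyadsync-recording ") :])
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: malformed header: {exc}") from exc
        df = pd.read_csv(fh, sep="\t")
    if "time" not in df.columns:
        raise ValidationError(f"{path}: missing 'time' column")
    stage = header["stage"]
    labels = (
        ["hbo", "hbr"]
        if stage == "hb"
        else [f"wl{int(round(w))}" for w in header["wavelengths"]]
    )
    chan_cols = [c for c in df.columns if c.startswith("p1_ch")]
    n_ch = len({c.split("_")[1] for c in chan_cols})
    n_t = len(df)
    data = np.empty((2, n_ch, 2, n_t))
    for p in range(2):
        for c in range(n_ch):
            for k, lab in enumerate(labels):
                col = f"p{p + 1}_ch{c + 1:02d}_{lab}"
                if col not in df.columns:
                    raise ValidationError(f"{path}: missing channel column {col!r}")
                data[p, c, k] = df[col].to_numpy()
    bad = np.zeros((2, n_ch), dtype=bool)
    for p, chans in enumerate(header.get("bad_channels", [[], []])):
        for ch in chans:
            bad[p, ch - 1] = True
    if timeline is None:
        timeline = pd.DataFrame(
            {
                "onset": np.cumsum([0.0] + list(constants.SEGMENT_DURATIONS_S[:-1])),
                "duration": constants.SEGMENT_DURATIONS_S,
                "trial_type": constants.SEGMENT_LABELS,
            }
        )
    return HyperscanRecording(
        dyad_id=header["dyad_id"],
        stage=stage,
        data=data,
        fs=float(header["fs"]),
        timeline=timeline,
        wavelengths=tuple(header["wavelengths"]),
        source_detector_distance=float(header.get("source_detector_distance", 3.0)),
        strategy=header.get("strategy"),
        bad_channels=bad,
    )


def write_snirf(rec: HyperscanRecording, directory: str | Path) -> tuple[Path, Path]:
    """Write one SNIRF file per participant (shared timeline as stim
    groups).  Returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = _component_labels(rec)
    paths = []
    for p in range(2):
        path = directory / f"{rec.dyad_id}_p{p + 1}.snirf"
        with h5py.File(path, "w") as f:
            f.create_dataset("formatVersion", data="1.0")
            nirs = f.create_group("nirs")
            meta = nirs.create_group("metaDataTags")
            meta.create_dataset("SubjectID", data=f"{rec.dyad_id}_p{p + 1}")
            meta.create_dataset("MeasurementDate", data="unknown")
            meta.create_dataset("MeasurementTime", data="unknown")
            meta.create_dataset("LengthUnit", data="cm")
            meta.create_dataset("TimeUnit", data="s")
            meta.create_dataset("FrequencyUnit", data="Hz")
            meta.create_dataset("dyadsyncStage", data=rec.stage)
            meta.create_dataset("dyadsyncStrategy", data=rec.strategy or "")
            data = nirs.create_group("data1")
            series = rec.data[p].reshape(rec.n_channels * 2, rec.n_times).T
            data.create_dataset("dataTimeSeries", data=series)
            data.create_dataset("time", data=np.arange(rec.n_times) / rec.fs)
            i = 1
            for c in range(rec.n_channels):
                for k, lab in enumerate(labels):
                    ml = data.create_group(f"measurementList{i}")
                    ml.create_dataset("sourceIndex", data=c + 1)
                    ml.create_dataset("detectorIndex", data=c + 1)
                    ml.create_dataset("wavelengthIndex", data=k + 1)
                    if rec.stage == "hb":
                        ml.create_dataset("dataType", data=99999)
                        ml.create_dataset("dataTypeLabel", data="HbO" if lab == "hbo" else "HbR")
                    else:
                        ml.create_dataset("dataType", data=1)
                    ml.create_dataset("dataTypeIndex", data=1)
                    i += 1
            probe = nirs.create_group("probe")
            probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))
            pos = np.zeros((rec.n_channels, 3))
            pos[:, 0] = np.arange(rec.n_channels)
            probe.create_dataset("sourcePos3D", data=pos)
            probe.create_dataset("detectorPos3D", data=pos)
            for j, (_, row) in enumerate(
                rec.timeline[rec.timeline["trial_type"].isin(constants.SEGMENT_LABELS)].iterrows(),
                start=1,
            ):
                stim = nirs.create_group(f"stim{j}")
                stim.create_dataset("name", data=row["trial_type"])
                stim.create_dataset(
                    "data", data=np.array([[row["onset"], row["duration"], 1.0]])
                )
        paths.append(path)
    return paths[0], paths[1]


def read_snirf(path_p1: str | Path, path_p2: str | Path) -> HyperscanRecording:
    """Read a dyad's pair of SNIRF files written by :func:`write_snirf`."""
    datas, metas, stims = [], [], []
    for path in (path_p1, path_p2):
        with h5py.File(path, "r") as f:
            if "nirs" not in f:
                raise ValidationError(f"{path}: not a SNIRF file (missing /nirs)")
            nirs = f["nirs"]
            series = np.asarray(nirs["data1/dataTimeSeries"])
            time = np.asarray(nirs["data1/time"])
            meta = {
                "stage": nirs["metaDataTags/dyadsyncStage"][()].decode()
                if "dyadsyncStage" in nirs["metaDataTags"]
                else "intensity",
                "strategy": nirs["metaDataTags/dyadsyncStrategy"][()].decode() or None
                if "dyadsyncStrategy" in nirs["metaDataTags"]
                else None,
                "wavelengths": tuple(np.asarray(nirs["probe/wavelengths"])),
                "fs": 1.0 / float(np.median(np.diff(time))),
                "subject": nirs["metaDataTags/SubjectID"][()].decode(),
            }
            rows = []
            j = 1
            while f"stim{j}" in nirs:
                name = nirs[f"stim{j}/name"][()].decode()
                for onset, duration, _ in np.atleast_2d(np.asarray(nirs[f"stim{j}/data"])):
                    rows.append({"onset": onset, "duration": duration, "trial_type": name})
                j += 1
            datas.append(series)
            metas.append(meta)
            stims.append(pd.DataFrame(rows).sort_values("onset", ignore_index=True))
    if datas[0].shape != datas[1].shape:
        raise ValidationError("participant files have mismatched shapes")
    n_t, n_cols = datas[0].shape
    n_ch = n_cols // 2
    data = np.stack(
        [d.T.reshape(n_ch, 2, n_t) for d in datas], axis=0
    )
    dyad_id = metas[0]["subject"].rsplit("_p", 1)[0]
    return HyperscanRecording(
        dyad_id=dyad_id,
        stage=metas[0]["stage"],
        data=data,
        fs=metas[0]["fs"],
        timeline=stims[0],
        wavelengths=metas[0]["wavelengths"],
        strategy=metas[0]["strategy"],
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with pinned float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path
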