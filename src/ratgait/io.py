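"""Readers and writers for the delimited on-disk formats.

Everything is plain tab-separated text (plus small JSON sidecars and
portable-graymap frames) so that datasets diff cleanly and reruns with the
same seeds are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

#: canonical column order for footfall-event tables
FOOTFALL_COLUMNS = ["trial_id", "limb", "event", "time_s", "x_cm", "y_cm"]
#: canonical column order for force recordings
GRF_COLUMNS = ["time_s", "fx_N", "fy_N", "fz_N"]

LIMBS = ("LH", "RH")
EVENTS = ("strike", "off")

#: fixed float formatting so that identical data always serializes identically
FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy table as TSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing input table: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # malformed delimiter/quoting/dtype soup
        raise FormatError(f"could not parse {path}: {exc}") from exc


def write_footfalls(events: pd.DataFrame, path: str | Path) -> None:
    write_table(events[FOOTFALL_COLUMNS], path)


def read_footfalls(path: str | Path) -> pd.DataFrame:
    """Read and validate a footfall-event table."""
    df = read_table(path)
    missing = [c for c in FOOTFALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing footfall columns {missing}")
    bad_limb = set(df["limb"].unique()) - set(LIMBS)
    if bad_limb:
        raise FormatError(f"{path}: unknown limb labels {sorted(bad_limb)}")
    bad_event = set(df["event"].unique()) - set(EVENTS)
    if bad_event:
        raise FormatError(f"{path}: unknown event kinds {sorted(bad_event)}")
    if not np.isfinite(df["time_s"]).all():
        raise FormatError(f"{path}: non-finite event times")
    return df[FOOTFALL_COLUMNS]


def write_grf(data: pd.DataFrame, meta: dict, path: str | Path) -> None:
    """Write a force recording as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    write_table(data[GRF_COLUMNS], path)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")


def read_grf(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    data = read_table(path)
    missing = [c for c in GRF_COLUMNS if c not in data.columns]
    if missing:
        raise FormatError(f"{path}: missing force columns {missing}")
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("body_weight_N", "sample_rate_hz"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing metadata key {key!r}")
    return data[GRF_COLUMNS], meta


def write_frames(frames: np.ndarray, background: np.ndarray, meta: dict,
                 directory: str | Path) -> None:
    """Write a grayscale frame stack as numbered PGM images + JSON metadata."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:05d}.pgm", _to_uint8(frame))
    iio.imwrite(directory / "background.pgm", _to_uint8(background))
    (directory / "stack.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n")


def read_frames(directory: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.pgm"))
    if not paths:
        raise FormatError(f"no frame_*.pgm files in {directory}")
    bg_path = directory / "background.pgm"
    if not bg_path.exists():
        raise FormatError(f"missing background frame in {directory}")
    meta_path = directory / "stack.json"
    if not meta_path.exists():
        raise FormatError(f"missing stack.json in {directory}")
    frames = np.stack([iio.imread(p).astype(float) for p in paths])
    background = iio.imread(bg_path).astype(float)
    meta = json.loads(meta_path.read_text())
    return frames, background, meta


def _to_uint8(frame: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)
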