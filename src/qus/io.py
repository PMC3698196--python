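"""File formats: the HDF5 RF container, PNG histology fields, cohort manifest.

RF container layout (one file per frame): dataset ``lines`` (int16,
n_lines x n_samples) with root attributes ``sampling_rate_mhz``,
``line_pitch_mm``, ``sound_speed_mm_us`` and ``kind`` ('tissue' or
'reference').
"""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .histology import HistologyField
from .synthetic_rf import RFFrame

__all__ = [
    "save_rf_frame",
    "load_rf_frame",
    "save_field_png",
    "load_field_png",
    "save_manifest",
    "load_manifest",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "rf_path",
    "ref_path",
    "histology_paths",
    "length_cm",
    "width_cm",
    "depth_cm",
]


def save_rf_frame(path, frame: RFFrame) -> None:
    with h5py.File(path, "w") as handle:
        handle.create_dataset("lines", data=np.asarray(frame.lines, dtype=np.int16))
        handle.attrs["sampling_rate_mhz"] = frame.sampling_rate
        handle.attrs["line_pitch_mm"] = frame.line_pitch
        handle.attrs["sound_speed_mm_us"] = frame.sound_speed
        handle.attrs["kind"] = frame.kind


def load_rf_frame(path) -> RFFrame:
    with h5py.File(path, "r") as handle:
        return RFFrame(
            lines=handle["lines"][...],
            sampling_rate=float(handle.attrs["sampling_rate_mhz"]),
            line_pitch=float(handle.attrs["line_pitch_mm"]),
            sound_speed=float(handle.attrs["sound_speed_mm_us"]),
            kind=str(handle.attrs["kind"]),
        )


def save_field_png(path, field: HistologyField) -> None:
    iio.imwrite(Path(path), field.pixels, extension=".png")


def load_field_png(path, pixel_size: float | None = None) -> HistologyField:
    return HistologyField(pixels=iio.imread(Path(path)), pixel_size=pixel_size)


def save_manifest(path, rows: list[dict]) -> None:
    """Write the cohort manifest CSV; histology_paths are ';'-separated."""
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    frame.to_csv(path, index=False)


def load_manifest(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return frame
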