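"""Plain-text serialisation of datasets, feature tables and models.

Layout of a dataset directory::

    manifest.json                 list of measurement ids + campaign info
    <mid>.json                    per-measurement sidecar (fs, wavelengths,
                                  glucose/SBP/DBP, times, channel files)
    <mid>_ch<k>.txt               one sample per line, one file per channel

Feature tables are CSV with the canonical feature names as header plus
``glucose_ref``/``sbp``/``dbp``/``subject_id``/``measurement_id`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureVector, feature_names
from .synth import Measurement, PPGRecord

__all__ = [
    "write_dataset",
    "read_dataset",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
]


def _write_channel(path: Path, rec: PPGRecord) -> None:
    np.savetxt(path, rec.samples, fmt="%.9g")


def write_dataset(dataset: dict, out_dir) -> Path:
    """Write a {subject_id: [Measurement, ...]} dataset as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": {}, "measurements": []}
    for sid, measurements in dataset.items():
        manifest["subjects"][sid] = [m.measurement_id for m in measurements]
        for m in measurements:
            sidecar = {
                "measurement_id": m.measurement_id,
                "subject_id": m.subject_id,
                "glucose_ref": m.glucose_ref,
                "sbp": m.sbp,
                "dbp": m.dbp,
                "acq_time": m.acq_time,
                "meal_times": list(m.meal_times),
                "channels": [],
            }
            for k, rec in enumerate(m.channels):
                fname = f"{m.measurement_id}_ch{k}.txt"
                _write_channel(out / fname, rec)
                sidecar["channels"].append(
                    {
                        "file": fname,
                        "fs": rec.fs,
                        "wavelength_nm": rec.wavelength_nm,
                        "channel_id": rec.channel_id,
                    }
                )
            (out / f"{m.measurement_id}.json").write_text(json.dumps(sidecar, indent=1))
            manifest["measurements"].append(m.measurement_id)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(in_dir) -> dict:
    """Read back a dataset directory written by :func:`write_dataset`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    dataset: dict[str, list[Measurement]] = {}
    for sid, mids in manifest["subjects"].items():
        measurements = []
        for mid in mids:
            sc = json.loads((root / f"{mid}.json").read_text())
            records = []
            for ch in sc["channels"]:
                samples = np.loadtxt(root / ch["file"])
                rec = PPGRecord(
                    samples=samples,
                    fs=ch["fs"],
                    wavelength_nm=ch["wavelength_nm"],
                    channel_id=ch["channel_id"],
                    subject_id=sc["subject_id"],
                    measurement_id=mid,
                )
                records.append(rec)
            measurements.append(
                Measurement(
                    ppg_880=[r for r in records if r.wavelength_nm == 880],
                    ppg_absorb=[r for r in records if r.wavelength_nm != 880],
                    glucose_ref=sc["glucose_ref"],
                    sbp=sc["sbp"],
                    dbp=sc["dbp"],
                    acq_time=sc["acq_time"],
                    meal_times=tuple(sc["meal_times"]),
                    subject_id=sc["subject_id"],
                    measurement_id=mid,
                )
            )
        dataset[sid] = measurements
    return dataset


def features_to_frame(vectors: list[FeatureVector], measurements: list[Measurement]) -> pd.DataFrame:
    """One row per measurement: 103 features plus companion columns."""
    rows = []
    for fv, m in zip(vectors, measurements):
        row = fv.as_dict()
        row.update(
            glucose_ref=m.glucose_ref,
            sbp=m.sbp,
            dbp=m.dbp,
            subject_id=m.subject_id,
            measurement_id=m.measurement_id,
        )
        rows.append(row)
    cols = list(feature_names()) + ["glucose_ref", "sbp", "dbp", "subject_id", "measurement_id"]
    return pd.DataFrame(rows, columns=cols)


def write_features_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
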