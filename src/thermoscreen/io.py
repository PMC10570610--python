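"""On-disk formats: TIFF scan stacks, cohort CSVs, curve CSVs, model JSON.

Scans are multi-frame 16-bit TIFF stacks with temperatures offset-encoded as
``value = (T - offset) / 0.01 K`` and a JSON sidecar carrying the encoding,
protocol and camera metadata.  Cohort tables are plain CSV with ROI columns
serialised as ``"cx,cy,r"``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .scan import (
    SITE_HEALTHY,
    SITE_MASS,
    CameraModel,
    ROI,
    ScanProtocol,
    TemperatureCurve,
    ThermalScan,
)
from .simulate import CohortDataset, LesionRecord

SCALE_K = 0.01  # kelvin per count in the 16-bit encoding

COHORT_COLUMNS = [
    "lesion_id",
    "dog_id",
    "tumor_type",
    "cytology_label",
    "histopath_label",
    "scan_path",
    "mass_roi",
    "healthy_roi",
]


def latest_scan_per_lesion(records: pd.DataFrame, time_col: str = "scan_time") -> pd.DataFrame:
    """Data-ingest rule for re-scans: keep only the latest scan per lesion.

    When a lesion was scanned more than once (movement, technical problem),
    only the most recent scan counts.  Rows must carry ``lesion_id`` and a
    sortable ``time_col``.
    """
    if time_col not in records.columns:
        raise ConfigurationError(f"records lack a {time_col!r} column")
    order = records.sort_values(time_col, kind="stable")
    return order.groupby("lesion_id", sort=False).tail(1)


def write_scan(scan: ThermalScan, path: str | Path) -> None:
    """Write a scan as a 16-bit TIFF stack plus a JSON metadata sidecar."""
    path = Path(path)
    offset = float(np.floor(scan.frames.min()) - 1.0)
    counts = np.round((scan.frames - offset) / SCALE_K)
    if counts.max() >= 2**16:
        raise ConfigurationError("temperature range exceeds 16-bit encoding")
    tifffile.imwrite(path, counts.astype(np.uint16))
    meta = {
        "scale_k": SCALE_K,
        "offset_c": offset,
        "timestamps": scan.timestamps.tolist(),
        "protocol": scan.protocol.to_dict(),
        "camera": scan.camera.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_scan(path: str | Path) -> ThermalScan:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    counts = tifffile.imread(path).astype(float)
    frames = counts * meta["scale_k"] + meta["offset_c"]
    return ThermalScan(
        frames=frames,
        timestamps=np.asarray(meta["timestamps"], dtype=float),
        protocol=ScanProtocol.from_dict(meta["protocol"]),
        camera=CameraModel(**meta["camera"]),
    )


def cohort_records_frame(cohort: CohortDataset) -> pd.DataFrame:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "dog_id": r.dog_id,
            "tumor_type": r.tumor_type,
            "cytology_label": r.cytology_label,
            "histopath_label": r.histopath_label,
            "scan_path": r.scan_path,
            "mass_roi": r.mass_roi.to_string(),
            "healthy_roi": r.healthy_roi.to_string(),
        }
        for r in cohort.records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: CohortDataset, out_dir: str | Path, scans: bool = False) -> Path:
    """Write cohort table + curves (and optionally TIFF scans) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = cohort_records_frame(cohort)
    if scans and cohort.scans:
        scan_dir = out_dir / "scans"
        scan_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(cohort.records):
            p = scan_dir / f"{rec.lesion_id}.tiff"
            write_scan(cohort.scans[rec.lesion_id], p)
            records.loc[i, "scan_path"] = str(p.relative_to(out_dir))
    records.to_csv(out_dir / "cohort.csv", index=False)
    curves_long = []
    for rec in cohort.records:
        mc, hc = cohort.curves[rec.lesion_id]
        for curve in (mc, hc):
            curves_long.append(
                pd.DataFrame(
                    {
                        "lesion_id": rec.lesion_id,
                        "site": curve.site,
                        "time_s": curve.timestamps,
                        "temp_c": curve.values,
                        "phase": curve.phase,
                    }
                )
            )
    pd.concat(curves_long, ignore_index=True).to_csv(out_dir / "curves.csv", index=False)
    return out_dir / "cohort.csv"


def read_cohort(out_dir: str | Path) -> CohortDataset:
    """Load a cohort written by :func:`write_cohort` (curves + records)."""
    out_dir = Path(out_dir)
    records_df = pd.read_csv(out_dir / "cohort.csv", keep_default_na=False)
    curves_df = pd.read_csv(out_dir / "curves.csv")
    records = []
    curves: Dict[str, Tuple[TemperatureCurve, TemperatureCurve]] = {}
    for _, r in records_df.iterrows():
        records.append(
            LesionRecord(
                lesion_id=r["lesion_id"],
                dog_id=r["dog_id"],
                tumor_type=r["tumor_type"],
                cytology_label=r["cytology_label"],
                histopath_label=r["histopath_label"],
                mass_roi=ROI.from_string(r["mass_roi"], site=SITE_MASS),
                healthy_roi=ROI.from_string(r["healthy_roi"], site=SITE_HEALTHY),
                scan_path=r["scan_path"],
            )
        )
    for lesion_id, grp in curves_df.groupby("lesion_id", sort=False):
        pair = {}
        for site, sub in grp.groupby("site"):
            pair[site] = TemperatureCurve(
                values=sub["temp_c"].to_numpy(),
                timestamps=sub["time_s"].to_numpy(),
                phase=sub["phase"].to_numpy(dtype=object),
                site=site,
            )
        curves[lesion_id] = (pair[SITE_MASS], pair[SITE_HEALTHY])
    return CohortDataset(records=records, curves=curves)
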