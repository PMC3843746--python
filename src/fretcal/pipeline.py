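"""End-to-end orchestration: quantify stacks, estimate coefficients, calibrate.

These functions glue the photometry, spectral-correction and calibration
stages together over tabular inputs, for both the command-line interface
and closure tests on synthetic datasets.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import io as _io
from .spectral import (
    CalibrationResult,
    ProximityCalibration,
    SpectralCoefficients,
    compute_proximity_ratio,
    efficiency_from_donor_quenching,
    estimate_spectral_coefficients,
)
from .synth import SyntheticDataset
from .types import ClusterMeasurement, InvalidInputError, RoiSpec

__all__ = [
    "quantify_dataset",
    "measurements_from_table",
    "calibrate_tables",
    "run_calibration_pipeline",
]

MEASUREMENT_COLUMNS = [
    "cell_id", "strain", "phase", "cluster", "focus_z",
    "I_donor", "I_acceptor", "I_fret", "roi_method", "roi_params",
]


def quantify_dataset(
    ds: SyntheticDataset,
    search_radius_px: int = 2,
    reference_channel: str = "donor",
    **kwargs,
) -> pd.DataFrame:
    """Run cluster photometry over every rendered cell of a synthetic dataset.

    The generator's true cluster positions play the role of the user's
    clicks; the search radius is kept below half the cluster separation so
    the focus search cannot lock onto the neighbouring cluster.
    """
    rows = []
    for cell in ds.cells:
        if cell.stacks is None:
            raise InvalidInputError("dataset was generated without rendered stacks")
        strain = ds.table.loc[ds.table.cell_id == cell.truth.cell_id, "strain"].iloc[0]
        # single-label controls carry signal only in their own channel
        ref = "acceptor" if not cell.truth.has_donor else reference_channel
        for idx, pos in enumerate(cell.positions):
            seed_yx = (int(round(pos[1])), int(round(pos[2])))
            m = _cluster.quantify_cell(
                cell.stacks,
                seed_yx,
                cell.truth.phase,
                cell_id=f"{cell.truth.cell_id}:{idx}",
                reference_channel=ref,
                search_radius_px=search_radius_px,
                **kwargs,
            )
            rows.append(
                {
                    "cell_id": cell.truth.cell_id,
                    "strain": strain,
                    "phase": cell.truth.phase,
                    "cluster": idx,
                    "focus_z": m.roi.focus_z,
                    "I_donor": m["donor"],
                    "I_acceptor": m["acceptor"],
                    "I_fret": m["fret"],
                    "roi_method": m.roi.method,
                    "roi_params": json.dumps(
                        {
                            "peak_yx": list(m.roi.peak_yx),
                            "box_origin": list(m.roi.box_origin) if m.roi.box_origin else None,
                            "gaussian_params": m.roi.gaussian_params,
                            "mask_sigma": m.roi.mask_sigma,
                            "mask_pixel_count": m.roi.mask_pixel_count,
                        }
                    ),
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measurements_from_table(df: pd.DataFrame) -> list[ClusterMeasurement]:
    """Rehydrate lightweight ClusterMeasurements from a measurement table."""
    out = []
    for _, row in df.iterrows():
        roi = RoiSpec(
            method=row.get("roi_method", "metaphase_box"),
            focus_z=int(row.get("focus_z", 0)),
            peak_yx=(0, 0),
            box_origin=(1, 1),
            mask_pixel_count=36,
        )
        out.append(
            ClusterMeasurement(
                cell_id=str(row["cell_id"]) + f":{row.get('cluster', 0)}",
                phase=row.get("phase", "metaphase"),
                intensities={
                    "donor": float(row["I_donor"]),
                    "acceptor": float(row["I_acceptor"]),
                    "fret": float(row["I_fret"]),
                },
                roi=roi,
            )
        )
    return out


def calibrate_tables(
    measurements: pd.DataFrame,
    donor_controls: pd.DataFrame,
    acceptor_controls: pd.DataFrame,
    coefficients: SpectralCoefficients | None = None,
) -> dict:
    """Full spectral + efficiency calibration from measurement tables.

    Steps: (1) alpha/beta from the single-label control tables;
    (2) per-(strain, phase) mean proximity ratio and donor-quenching
    efficiency, the latter against the donor-only controls of the same
    phase; (3) OLS line of efficiency on proximity ratio.

    ``coefficients`` overrides step (1) with externally estimated values —
    preferable when the controls come from well-separated (anaphase-like)
    clusters, where the ROI background is free of neighbour-cluster
    contamination.

    Returns a dict with ``coefficients`` (:class:`SpectralCoefficients`),
    ``strain_table`` (one row per strain/phase) and ``calibration``
    (:class:`CalibrationResult`).
    """
    coeffs = coefficients or estimate_spectral_coefficients(
        measurements_from_table(donor_controls),
        measurements_from_table(acceptor_controls),
    )
    strain_rows = []
    prs, effs = [], []
    for (strain, phase), group in measurements.groupby(["strain", "phase"]):
        ms = measurements_from_table(group)
        pr_values = [compute_proximity_ratio(m, coeffs).proximity_ratio for m in ms]
        donor_ref = donor_controls[donor_controls.phase == phase]
        if donor_ref.empty:
            donor_ref = donor_controls
        est = efficiency_from_donor_quenching(
            group["I_donor"].to_numpy(), donor_ref["I_donor"].to_numpy(), phase=phase
        )
        pr_mean = float(np.mean(pr_values))
        strain_rows.append(
            {
                "strain": strain,
                "phase": phase,
                "n_clusters": len(pr_values),
                "proximity_ratio_mean": pr_mean,
                "proximity_ratio_sd": float(np.std(pr_values, ddof=1)),
                "efficiency": est.efficiency,
                "efficiency_sd": est.sd,
            }
        )
        prs.append(pr_mean)
        effs.append(est)
    calibration = ProximityCalibration(prs, effs).fit()
    return {
        "coefficients": coeffs,
        "strain_table": pd.DataFrame(strain_rows),
        "calibration": calibration,
    }


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_calibration_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    phase: str = "metaphase",
    search_radius_px: int = 2,
    log_name: str = "pipeline_log.jsonl",
) -> dict:
    """Quantify -> calibrate -> write model.json over a directory of cells.

    Expects ``<input_dir>`` to contain per-cell TIFFs with sidecars and a
    ``clicks.csv`` table (columns: path, cell_id, strain, phase, y, x).
    Every stage appends a JSON-lines log record with its parameters and
    input hashes; on error, partial outputs keep a ``.partial`` suffix.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / log_name

    def log(stage: str, **payload) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **payload}) + "\n")

    clicks_path = input_dir / "clicks.csv"
    if not clicks_path.exists():
        raise InvalidInputError(f"no cells found: {clicks_path} is missing")
    clicks = _io.read_table(clicks_path)
    if clicks.empty:
        raise InvalidInputError("no cells found: clicks.csv is empty")
    log("quantify", n_cells=int(clicks.shape[0]), phase=phase,
        search_radius_px=search_radius_px, clicks_hash=_file_hash(clicks_path))

    rows = []
    for _, row in clicks.iterrows():
        stacks = _io.read_stacks(input_dir / row["path"])
        strain = str(row.get("strain", "unknown"))
        ref = "acceptor" if strain == "acceptor_only" else "donor"
        m = _cluster.quantify_cell(
            stacks, (int(row["y"]), int(row["x"])), str(row.get("phase", phase)),
            cell_id=str(row["cell_id"]), search_radius_px=search_radius_px,
            reference_channel=ref,
        )
        rows.append(
            {
                "cell_id": row["cell_id"],
                "strain": row.get("strain", "unknown"),
                "phase": str(row.get("phase", phase)),
                "cluster": int(row.get("cluster", 0)),
                "focus_z": m.roi.focus_z,
                "I_donor": m["donor"],
                "I_acceptor": m["acceptor"],
                "I_fret": m["fret"],
                "roi_method": m.roi.method,
                "roi_params": "{}",
            }
        )
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    meas_path = out_dir / "measurements.csv"
    try:
        _io.write_table(table, meas_path)
        donor_df = table[table.strain == "donor_only"]
        acceptor_df = table[table.strain == "acceptor_only"]
        fret_df = table[~table.strain.isin(["donor_only", "acceptor_only"])]
        result = calibrate_tables(fret_df, donor_df, acceptor_df)
        _io.save_json(result["coefficients"], out_dir / "coefficients.json")
        _io.save_json(result["calibration"], out_dir / "model.json")
        _io.write_table(result["strain_table"], out_dir / "strains.csv")
    except Exception:
        if meas_path.exists():
            meas_path.rename(meas_path.with_suffix(".csv.partial"))
        log("error", stage_failed="calibrate")
        raise
    log("calibrate", slope=result["calibration"].slope,
        intercept=result["calibration"].intercept,
        alpha=result["coefficients"].alpha, beta=result["coefficients"].beta)
    return result
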