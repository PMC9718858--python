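"""Reading and writing cohort directories (CSV tables + JSON metadata).

Layout of a cohort directory::

    manifest.json                   cohort-level metadata and FOV index
    traces/<fov_id>.csv             frame, roi_id, soma_f, neuropil_f
    rois.csv                        fov_id, roi_id, x_um, y_um
    plaques.csv                     fov_id, x_um, y_um  (plaque-bearing FOVs)
    ground_truth.json               optional; synthetic cohorts only
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .simulate import Cohort, FovRecording, RoiTrace, SyntheticGroundTruth

__all__ = ["write_cohort", "read_cohort", "read_ground_truth"]


def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    truth: SyntheticGroundTruth | None = None,
) -> Path:
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    fov_index = []
    roi_rows = []
    plaque_rows = []
    for fov in cohort.fovs:
        fov_index.append(
            {
                "fov_id": fov.fov_id,
                "animal_id": fov.animal_id,
                "genotype": fov.genotype,
                "cell_type": fov.cell_type,
                "fov_size_um": list(fov.fov_size_um),
                "frame_rate_hz": fov.frame_rate_hz,
            }
        )
        frames = []
        for roi in fov.rois:
            n = roi.soma_f.size
            frames.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(n),
                        "roi_id": roi.roi_id,
                        "soma_f": roi.soma_f,
                        "neuropil_f": roi.neuropil_f,
                    }
                )
            )
            roi_rows.append(
                {
                    "fov_id": fov.fov_id,
                    "roi_id": roi.roi_id,
                    "x_um": roi.centroid_xy[0],
                    "y_um": roi.centroid_xy[1],
                }
            )
        pd.concat(frames).to_csv(out / "traces" / f"{fov.fov_id}.csv", index=False)
        if fov.plaque_xy is not None:
            plaque_rows.append(
                {
                    "fov_id": fov.fov_id,
                    "x_um": fov.plaque_xy[0],
                    "y_um": fov.plaque_xy[1],
                }
            )
    pd.DataFrame(roi_rows).to_csv(out / "rois.csv", index=False)
    pd.DataFrame(plaque_rows, columns=["fov_id", "x_um", "y_um"]).to_csv(
        out / "plaques.csv", index=False
    )
    manifest = {"frame_rate_hz": cohort.frame_rate_hz, "fovs": fov_index}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if truth is not None:
        gt = {
            "seed": truth.seed,
            "modulation_amplitude": truth.modulation_amplitude,
            "modulation_length_um": truth.modulation_length_um,
            "neurons": truth.neurons.to_dict(orient="records"),
            "spikes": {
                f"{fov_id}/{roi_id}": frames.tolist()
                for (fov_id, roi_id), frames in truth.spikes.items()
            },
            "coactivation": {
                f"{fov_id}/{i}/{j}": n
                for (fov_id, i, j), n in truth.coactivation.items()
            },
        }
        (out / "ground_truth.json").write_text(json.dumps(gt))
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise InvalidInputError(f"no manifest.json under {src}")
    manifest = json.loads(manifest_path.read_text())
    rois = pd.read_csv(src / "rois.csv")
    plaques = (
        pd.read_csv(src / "plaques.csv")
        if (src / "plaques.csv").exists()
        else pd.DataFrame(columns=["fov_id", "x_um", "y_um"])
    )
    fovs = []
    for meta in manifest["fovs"]:
        fov_id = meta["fov_id"]
        trace_path = src / "traces" / f"{fov_id}.csv"
        if not trace_path.exists():
            raise InvalidInputError(f"missing trace table for FOV {fov_id}")
        table = pd.read_csv(trace_path)
        for col in ("frame", "roi_id", "soma_f", "neuropil_f"):
            if col not in table.columns:
                raise InvalidInputError(f"{trace_path}: missing column {col!r}")
        fov_rois = []
        roi_meta = rois[rois["fov_id"] == fov_id].set_index("roi_id")
        for roi_id, grp in table.groupby("roi_id", sort=True):
            grp = grp.sort_values("frame")
            if roi_id not in roi_meta.index:
                raise InvalidInputError(f"ROI {roi_id} in {fov_id} has no centroid")
            fov_rois.append(
                RoiTrace(
                    roi_id=str(roi_id),
                    soma_f=grp["soma_f"].to_numpy(dtype=float),
                    neuropil_f=grp["neuropil_f"].to_numpy(dtype=float),
                    centroid_xy=(
                        float(roi_meta.loc[roi_id, "x_um"]),
                        float(roi_meta.loc[roi_id, "y_um"]),
                    ),
                    fov_id=fov_id,
                    frame_rate_hz=float(meta["frame_rate_hz"]),
                )
            )
        pl = plaques[plaques["fov_id"] == fov_id]
        fovs.append(
            FovRecording(
                fov_id=fov_id,
                animal_id=meta["animal_id"],
                genotype=meta["genotype"],
                cell_type=meta["cell_type"],
                rois=fov_rois,
                plaque_xy=(
                    (float(pl.iloc[0]["x_um"]), float(pl.iloc[0]["y_um"]))
                    if len(pl)
                    else None
                ),
                fov_size_um=tuple(meta["fov_size_um"]),
                frame_rate_hz=float(meta["frame_rate_hz"]),
            )
        )
    return Cohort(fovs=fovs, frame_rate_hz=float(manifest["frame_rate_hz"]))


def read_ground_truth(in_dir: str | Path) -> SyntheticGroundTruth:
    gt = json.loads((Path(in_dir) / "ground_truth.json").read_text())
    spikes = {}
    for key, frames in gt["spikes"].items():
        fov_id, roi_id = key.rsplit("/", 1)
        spikes[(fov_id, roi_id)] = np.asarray(frames, dtype=np.int64)
    coact = {}
    for key, n in gt["coactivation"].items():
        fov_id, i, j = key.rsplit("/", 2)
        coact[(fov_id, i, j)] = int(n)
    return SyntheticGroundTruth(
        neurons=pd.DataFrame(gt["neurons"]),
        spikes=spikes,
        coactivation=coact,
        modulation_amplitude=gt["modulation_amplitude"],
        modulation_length_um=gt["modulation_length_um"],
        seed=gt["seed"],
    )
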