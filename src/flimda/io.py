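"""File formats: decay stacks as multi-page TIFF + JSON sidecar, models as
JSON, feature/EVI tables as CSV.

Conventions (also written into every sidecar): one TIFF page per time bin,
32-bit unsigned counts, row-major pixel order with the origin at top-left.
Vendor FLIM formats (.sdt, .fbd) are proprietary; ``read_decay_stack`` is
the shim point where a vendor importer would plug in.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .distance import FEATURE_NAMES, DAModel, EVIResult, WEIGHTED_INDICES
from .errors import FormatError
from .instrument import InstrumentConfig
from .phasor import CalibrationTransform, DecayImage
from .synthetic import EmbryoPhantom

_SIDECAR_REQUIRED = ("rep_rate_hz", "n_bins", "harmonic")


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_decay_stack(img: DecayImage, path: str | Path) -> Path:
    """Write a decay image as a multi-page TIFF (one page per time bin,
    uint32) with a JSON sidecar describing the instrument."""
    path = Path(path)
    pages = np.moveaxis(img.counts, 2, 0)  # (n_bins, h, w)
    tifffile.imwrite(path, np.round(pages).astype(np.uint32))
    sidecar = {
        **img.cfg.to_dict(),
        "pixel_order": "row-major",
        "origin": "top-left",
        "page_axis": "time_bin",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_decay_stack(path: str | Path) -> DecayImage:
    """Read a decay stack written by :func:`write_decay_stack`.

    Raises :class:`FormatError` naming the offending field when the sidecar
    is missing/incomplete or the page count disagrees with ``n_bins``.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar JSON: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise FormatError(f"sidecar {sidecar_path} missing field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_bins = int(sidecar["n_bins"])
    if pages.shape[0] != n_bins:
        raise FormatError(
            f"page count mismatch in {path}: sidecar n_bins={n_bins}, "
            f"found {pages.shape[0]} pages"
        )
    h, w = pages.shape[1:]
    cfg = InstrumentConfig(
        rep_rate_hz=float(sidecar["rep_rate_hz"]),
        n_bins=n_bins,
        width_px=int(sidecar.get("width_px", w)),
        height_px=int(sidecar.get("height_px", h)),
        harmonic=int(sidecar["harmonic"]),
    )
    counts = np.moveaxis(pages, 0, 2).astype(np.float64)
    return DecayImage(counts=counts, cfg=cfg)


def write_cohort(
    records: list[tuple[EmbryoPhantom, DecayImage]], out_dir: str | Path
) -> Path:
    """Write one TIFF+sidecar per embryo plus a ``truth.json`` with labels,
    stages and file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = []
    for phantom, img in records:
        fname = f"{phantom.embryo_id}.tif"
        write_decay_stack(img, out_dir / fname)
        truth.append(
            {
                "embryo_id": phantom.embryo_id,
                "stage": phantom.stage,
                "label": phantom.label,
                "file": fname,
            }
        )
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return out_dir


def read_cohort_index(cohort_dir: str | Path) -> list[dict]:
    cohort_dir = Path(cohort_dir)
    truth_path = cohort_dir / "truth.json"
    if not truth_path.exists():
        raise FormatError(f"missing cohort index: {truth_path}")
    return json.loads(truth_path.read_text())


def write_model(model: DAModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "feature_names": list(FEATURE_NAMES),
        "weighted_indices": list(WEIGHTED_INDICES),
        "mu_H": model.mu_H.tolist(),
        "var_H": model.var_H.tolist(),
        "mu_UH": model.mu_UH.tolist(),
        "var_UH": model.var_UH.tolist(),
        "weights": model.weights.tolist(),
        "evi_scale": model.evi_scale,
        "training_meta": model.training_meta,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_model(path: str | Path) -> DAModel:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing model file: {path}")
    d = json.loads(path.read_text())
    try:
        return DAModel(
            mu_H=np.array(d["mu_H"]),
            var_H=np.array(d["var_H"]),
            mu_UH=np.array(d["mu_UH"]),
            var_UH=np.array(d["var_UH"]),
            weights=np.array(d["weights"]),
            evi_scale=float(d["evi_scale"]),
            training_meta=d.get("training_meta", {}),
        )
    except KeyError as e:
        raise FormatError(f"model file {path} missing field {e.args[0]!r}")


def write_calibration(tr: CalibrationTransform, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(tr), indent=2))
    return path


def read_calibration(path: str | Path) -> CalibrationTransform:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing calibration file: {path}")
    d = json.loads(path.read_text())
    try:
        return CalibrationTransform(**d)
    except TypeError as e:
        raise FormatError(f"calibration file {path} malformed: {e}")


def features_to_frame(
    rows: list[tuple[str, str, str, np.ndarray]]
) -> pd.DataFrame:
    """(embryo_id, stage, label, feature_vector) rows -> tidy DataFrame."""
    return pd.DataFrame(
        [
            {"embryo_id": eid, "stage": stage, "label": label,
             **dict(zip(FEATURE_NAMES, vec))}
            for eid, stage, label, vec in rows
        ]
    )


def frame_to_features(df: pd.DataFrame) -> list[tuple[str, str, str, np.ndarray]]:
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing[:3]}...")
    return [
        (row["embryo_id"], row.get("stage", ""), row.get("label", "unknown"),
         np.array([row[c] for c in FEATURE_NAMES], dtype=float))
        for _, row in df.iterrows()
    ]


def evi_results_to_frame(
    results: list[EVIResult], true_labels: dict[str, str] | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"embryo_id": r.embryo_id, "raw_score": r.raw_score,
             "evi": r.evi, "predicted": r.predicted}
            for r in results
        ]
    )
    if true_labels:
        df["label"] = df["embryo_id"].map(true_labels)
    return df
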