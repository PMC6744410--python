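"""Stage-to-stage glue: decay stack -> phasor -> features -> EVI.

Thin convenience layer shared by the command-line interface, the tests and
reproduction scripts; all science lives in the stage modules.
"""

from __future__ import annotations

import numpy as np

from .distance import (
    DAModel,
    EVIResult,
    evi_score,
    features_from_phasor,
    optimize_weights,
)
from .phasor import (
    CalibrationTransform,
    DecayImage,
    PhasorImage,
    median_filter_phasor,
    phasor_transform,
)
from .synthetic import EmbryoPhantom


def phasor_of_image(
    img: DecayImage,
    min_photons: int = 20,
    calibration: CalibrationTransform | None = None,
    filter_window: int = 1,
) -> PhasorImage:
    """Transform, optionally calibrate, optionally median-filter."""
    ph = phasor_transform(img, min_photons=min_photons)
    if calibration is not None:
        g, s = calibration.apply(ph.g, ph.s)
        ph.g, ph.s = g, s
        ph.calibrated = True
    if filter_window > 1:
        ph = median_filter_phasor(ph, filter_window)
    return ph


def features_of_image(
    img: DecayImage,
    min_photons: int = 20,
    calibration: CalibrationTransform | None = None,
    filter_window: int = 1,
    **histogram_kwargs,
) -> np.ndarray:
    ph = phasor_of_image(img, min_photons, calibration, filter_window)
    return features_from_phasor(ph, **histogram_kwargs)


def cohort_feature_rows(
    records: list[tuple[EmbryoPhantom, DecayImage]],
    **kwargs,
) -> list[tuple[str, str, str, np.ndarray]]:
    """(embryo_id, stage, label, feature_vector) for every cohort member."""
    return [
        (ph.embryo_id, ph.stage, ph.label, features_of_image(img, **kwargs))
        for ph, img in records
    ]


def train_model(
    rows: list[tuple[str, str, str, np.ndarray]],
    budget: int = 100,
) -> DAModel:
    training = [(vec, label) for _, _, label, vec in rows
                if label in ("H", "UH")]
    return optimize_weights(training, budget=budget)


def score_rows(
    rows: list[tuple[str, str, str, np.ndarray]],
    model: DAModel,
    healthy_negative: bool = True,
) -> list[EVIResult]:
    return [
        evi_score(vec, model, embryo_id=eid, healthy_negative=healthy_negative)
        for eid, _, _, vec in rows
    ]
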