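"""Two-stage serial prediction system.

Stage 1 predicts the surgery-duration class; that class index replaces the
A24 input slot of the stage-2 emergence predictor, passing through the
SAME normalization affine map stage 2 was fitted with, so predicted and
true classes occupy identical input geometry. Stage 2 is trained on true
surgery classes; feeding it predicted ones at evaluation time quantifies
the cascade cost relative to the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from periopredict.datagen import ATTRIBUTE_COLUMNS
from periopredict.network import MLPModel, predict_classes
from periopredict.preprocess import (
    EMERGENCE_SCHEME,
    SURGERY_SCHEME,
    BinningScheme,
    NormalizationParams,
    apply_normalization,
    bin_duration,
)


@dataclass
class SerialSystem:
    """Trained stage-1 (surgery) and stage-2 (emergence) models with the
    normalization params and binning schemes that wire them together."""

    surgery_model: MLPModel
    emergence_model: MLPModel
    surgery_norm: NormalizationParams
    emergence_norm: NormalizationParams
    surgery_scheme: BinningScheme = SURGERY_SCHEME
    emergence_scheme: BinningScheme = EMERGENCE_SCHEME


@dataclass(frozen=True)
class SerialResult:
    """Three-way accuracy comparison of the combined system."""

    emergence_oracle_accuracy: float  # stage 2 fed the TRUE surgery class
    surgery_accuracy: float
    combined_accuracy: float  # stage 2 fed the PREDICTED surgery class

    @property
    def gap(self) -> float:
        return self.emergence_oracle_accuracy - self.combined_accuracy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "system": [
                    "emergence (true surgery class)",
                    "surgery",
                    "combined (predicted surgery class)",
                    "gap (oracle - combined)",
                ],
                "accuracy": [
                    self.emergence_oracle_accuracy,
                    self.surgery_accuracy,
                    self.combined_accuracy,
                    self.gap,
                ],
            }
        )


SURGERY_SUFFIX = "_s1"
EMERGENCE_SUFFIX = "_s2"


def intersect_cohorts(
    surgery_samples: pd.DataFrame,
    emergence_samples: pd.DataFrame,
    on: str = "case_id",
) -> pd.DataFrame:
    """Inner join of the two systems' attribute views on the case identifier.

    Each joined record carries both views (suffixes ``_s1``/``_s2``) and
    both true duration outcomes. Duplicate identifiers are a join error.
    """
    for name, df in (("surgery", surgery_samples), ("emergence", emergence_samples)):
        if on not in df.columns:
            raise KeyError(f"{name} cohort lacks identifier column {on!r}")
        dupes = df[on][df[on].duplicated()]
        if len(dupes):
            raise ValueError(
                f"duplicate case identifiers in {name} cohort: {sorted(set(dupes))[:5]}"
            )
    return surgery_samples.merge(
        emergence_samples, on=on, suffixes=(SURGERY_SUFFIX, EMERGENCE_SUFFIX)
    )


def _view(joined: pd.DataFrame, suffix: str) -> pd.DataFrame:
    out = {}
    for col in (*ATTRIBUTE_COLUMNS, "duration_minutes"):
        out[col] = joined[col + suffix] if col + suffix in joined.columns else joined[col]
    return pd.DataFrame(out, index=joined.index)


def _stage2_classes(
    system: SerialSystem, joined: pd.DataFrame, a24: np.ndarray
) -> np.ndarray:
    view = _view(joined, EMERGENCE_SUFFIX)
    view = view.assign(A24=a24)
    X = apply_normalization(view, system.emergence_norm)
    return predict_classes(system.emergence_model, X)


def predict_surgery_classes(system: SerialSystem, joined: pd.DataFrame) -> np.ndarray:
    view = _view(joined, SURGERY_SUFFIX)
    X = apply_normalization(view, system.surgery_norm)
    return predict_classes(system.surgery_model, X)


def serial_predict(system: SerialSystem, joined: pd.DataFrame) -> np.ndarray:
    """Stage-1 surgery class prediction routed into the A24 slot of stage 2;
    returns the predicted emergence classes."""
    predicted_surgery = predict_surgery_classes(system, joined)
    return _stage2_classes(system, joined, predicted_surgery)


def evaluate_serial(system: SerialSystem, joined: pd.DataFrame) -> SerialResult:
    """Compute the three-way accuracy comparison on joined samples carrying
    both true outcomes."""
    if len(joined) == 0:
        raise ValueError("cannot evaluate on an empty join")
    true_surgery = bin_duration(
        joined["duration_minutes" + SURGERY_SUFFIX].to_numpy(dtype=float),
        system.surgery_scheme,
    )
    true_emergence = bin_duration(
        joined["duration_minutes" + EMERGENCE_SUFFIX].to_numpy(dtype=float),
        system.emergence_scheme,
    )
    predicted_surgery = predict_surgery_classes(system, joined)
    oracle_pred = _stage2_classes(system, joined, true_surgery)
    combined_pred = _stage2_classes(system, joined, predicted_surgery)
    return SerialResult(
        emergence_oracle_accuracy=float((oracle_pred == true_emergence).mean()),
        surgery_accuracy=float((predicted_surgery == true_surgery).mean()),
        combined_accuracy=float((combined_pred == true_emergence).mean()),
    )
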