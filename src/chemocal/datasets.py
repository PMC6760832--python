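"""Published reference results for the six-model pyridostigmine bromide study.

The original comparison quantified pyridostigmine bromide (PR) in synthetic
mixtures with its impurities A and B by six multivariate calibration variants
— PLSR, DPLSR (first-derivative PLSR), OPLS-PLSR, linear SVR, DSVR and
OPLS-SVR — reporting, per sample, the taken and found concentrations
(μg mL⁻¹) and the percent recovery, for both the 16-mixture calibration set
(autoprediction) and the 9-mixture independent test set.

The raw instrument spectra were never deposited, but these per-sample result
columns were published in full (rounded to 2 decimals) and are reproduced
here verbatim.  They serve two purposes: recomputing the summary statistics
(mean/SD of recovery, RMSEC, RMSEP) from first principles, and providing
realistic fixtures for the evaluation machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODELS = ("PLSR", "DPLSR", "OPLS-PLSR", "SVR", "DSVR", "OPLS-SVR")

CALIBRATION_TAKEN = (20, 20, 30, 30, 60, 30, 20, 50, 50, 30, 50, 20, 60, 60, 50, 60)
TEST_TAKEN = (20, 50, 50, 20, 30, 45, 25, 30, 25)

# fmt: off
_CAL_FOUND = {
    "PLSR":      (19.45, 19.90, 30.09, 30.53, 59.60, 30.08, 19.83, 50.23, 49.94, 30.57, 49.44, 19.92, 59.87, 59.84, 50.33, 60.37),
    "DPLSR":     (19.06, 20.08, 30.56, 29.96, 59.38, 29.99, 20.08, 50.63, 50.46, 30.25, 50.10, 19.97, 60.01, 60.01, 50.03, 59.43),
    "OPLS-PLSR": (19.63, 20.02, 30.20, 30.26, 59.89, 30.11, 19.97, 50.18, 50.04, 30.40, 49.56, 19.83, 60.01, 59.94, 49.56, 60.38),
    "SVR":       (19.85, 20.15, 30.29, 30.15, 59.88, 30.15, 19.85, 50.07, 50.07, 30.15, 49.62, 19.85, 60.09, 60.00, 50.08, 60.15),
    "DSVR":      (19.34, 20.36, 30.64, 30.25, 59.29, 30.17, 19.64, 50.54, 50.36, 30.36, 50.01, 20.12, 59.67, 59.64, 49.64, 59.36),
    "OPLS-SVR":  (19.77, 20.13, 30.21, 30.21, 59.79, 30.15, 19.83, 50.04, 49.95, 30.21, 49.51, 19.79, 59.86, 59.79, 50.11, 60.21),
}

_CAL_RECOVERY = {
    "PLSR":      (97.25, 99.52, 100.31, 101.75, 99.33, 100.27, 99.15, 100.45, 99.89, 101.90, 98.88, 99.61, 99.79, 99.73, 100.66, 100.62),
    "DPLSR":     (95.28, 100.39, 101.88, 99.87, 98.96, 99.97, 100.41, 101.27, 100.92, 100.84, 100.21, 99.84, 100.02, 100.01, 100.06, 99.05),
    "OPLS-PLSR": (98.15, 100.10, 100.67, 100.87, 99.82, 100.37, 99.85, 100.36, 100.08, 101.33, 99.12, 99.15, 100.02, 99.90, 99.12, 100.63),
    "SVR":       (99.25, 100.75, 100.98, 100.50, 99.81, 100.49, 99.25, 100.14, 100.14, 100.50, 99.25, 99.25, 100.16, 100.00, 100.17, 100.25),
    "DSVR":      (96.70, 101.80, 102.14, 100.82, 98.82, 100.57, 98.20, 101.09, 100.72, 101.20, 100.01, 100.61, 99.44, 99.40, 99.28, 98.93),
    "OPLS-SVR":  (98.87, 100.63, 100.70, 100.70, 99.65, 100.51, 99.17, 100.09, 99.89, 100.70, 99.019, 98.97, 99.76, 99.65, 100.23, 100.35),
}

_TEST_FOUND = {
    "PLSR":      (19.72, 49.96, 49.19, 19.60, 30.63, 44.29, 24.53, 29.31, 24.97),
    "DPLSR":     (19.39, 50.58, 50.24, 19.06, 30.48, 45.18, 27.47, 32.09, 25.23),
    "OPLS-PLSR": (19.74, 50.58, 49.78, 19.59, 30.31, 44.95, 24.93, 29.92, 24.83),
    "SVR":       (20.12, 50.24, 49.61, 19.82, 30.10, 45.09, 24.89, 29.92, 24.64),
    "DSVR":      (20.28, 50.36, 49.64, 20.36, 29.64, 44.64, 25.36, 30.36, 25.36),
    "OPLS-SVR":  (20.05, 50.21, 49.79, 19.79, 30.21, 44.79, 24.87, 29.89, 24.79),
}

_TEST_RECOVERY = {
    "PLSR":      (98.59, 99.93, 98.37, 97.98, 102.10, 98.42, 98.11, 97.70, 99.89),
    "DPLSR":     (96.96, 101.15, 100.49, 95.28, 101.61, 100.41, 109.88, 106.95, 100.94),
    "OPLS-PLSR": (98.71, 101.16, 99.57, 97.96, 101.05, 99.89, 99.74, 99.74, 99.34),
    "SVR":       (100.58, 100.48, 99.22, 99.10, 100.34, 100.21, 99.58, 99.73, 98.54),
    "DSVR":      (101.38, 100.72, 99.28, 101.80, 98.80, 99.20, 101.44, 101.20, 101.44),
    "OPLS-SVR":  (100.27, 100.42, 99.58, 98.95, 100.70, 99.53, 99.48, 99.62, 99.16),
}
# fmt: on

_SPLITS = {
    "calibration": (CALIBRATION_TAKEN, _CAL_FOUND, _CAL_RECOVERY),
    "test": (TEST_TAKEN, _TEST_FOUND, _TEST_RECOVERY),
}


def _check_split(split: str):
    if split not in _SPLITS:
        raise ValueError(f"split must be one of {tuple(_SPLITS)}, got {split!r}")
    return _SPLITS[split]


def reference_taken(split: str = "test") -> np.ndarray:
    """Taken PR concentrations (μg mL⁻¹) for one split."""
    taken, _, _ = _check_split(split)
    return np.asarray(taken, dtype=float)


def reference_found(split: str, model: str) -> np.ndarray:
    """Found PR concentrations (μg mL⁻¹) for one model on one split."""
    _, found, _ = _check_split(split)
    if model not in found:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return np.asarray(found[model], dtype=float)


def reference_recovery(split: str, model: str) -> np.ndarray:
    """Published percent recoveries for one model on one split."""
    _, _, rec = _check_split(split)
    if model not in rec:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return np.asarray(rec[model], dtype=float)


def reference_results(split: str = "test") -> pd.DataFrame:
    """Long-format table: sample, model, taken, found, recovery_percent."""
    taken, found, rec = _check_split(split)
    rows = []
    for model in MODELS:
        for i, t in enumerate(taken):
            rows.append(
                (i + 1, model, float(t), float(found[model][i]), float(rec[model][i]))
            )
    return pd.DataFrame(
        rows, columns=["sample", "model", "taken", "found", "recovery_percent"]
    )
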