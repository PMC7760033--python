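"""End-to-end convenience layer tying processing, models and labels together."""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .processing import (BIN_WIDTH, FINGERPRINT_REGION, WATER_REGION, BinnedMatrix,
                         CalibrationError, Spectrum, bin_spectra, calibrate,
                         normalize_matrix)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

log = logging.getLogger("nmrfinger")

__all__ = ["FingerprintResult", "fingerprint_spectra", "simulate_fingerprint"]


@dataclass
class FingerprintResult:
    matrix: BinnedMatrix                 # normalized, water-excluded
    calibration_shifts: dict[str, float]  # ppm shift applied per subject
    excluded: dict[str, str]             # subject -> reason


def fingerprint_spectra(spectra: list[Spectrum],
                        region: tuple[float, float] = FINGERPRINT_REGION,
                        width: float = BIN_WIDTH,
                        water_region: tuple[float, float] = WATER_REGION,
                        reference_ppm: float = 5.24,
                        calibrate_spectra: bool = True) -> FingerprintResult:
    """Calibrate, bin and normalize one spectrum per subject.

    Subjects failing chemical-shift calibration are dropped with a logged
    warning and reported in ``excluded``; the run continues.
    """
    shifts: dict[str, float] = {}
    excluded: dict[str, str] = {}
    kept: list[Spectrum] = []
    for sp in spectra:
        if calibrate_spectra:
            try:
                sp, shift = calibrate(sp, reference_ppm=reference_ppm)
            except CalibrationError as err:
                log.warning("subject %s excluded: %s", sp.subject_id, err)
                excluded[sp.subject_id] = str(err)
                continue
            shifts[sp.subject_id] = shift
        else:
            shifts[sp.subject_id] = 0.0
        kept.append(sp)
    if not kept:
        raise ValueError("no spectrum survived calibration")
    matrix = normalize_matrix(bin_spectra(kept, region, width), water_region)
    return FingerprintResult(matrix, shifts, excluded)


def simulate_fingerprint(config: CohortConfig) -> tuple[BinnedMatrix, np.ndarray, SyntheticCohort]:
    """Generate a synthetic cohort and run it through the fingerprint pipeline.

    Returns the normalized matrix, the +/-1 class vector aligned to its rows,
    and the cohort itself (clinical records and ground truth included).
    """
    cohort = generate_cohort(config)
    fp = fingerprint_spectra(cohort.spectra)
    order = {sid: i for i, sid in enumerate(cohort.subject_ids)}
    y = cohort.y()[[order[sid] for sid in fp.matrix.subject_ids]]
    return fp.matrix, y, cohort


def align_matrix_labels(matrix: BinnedMatrix, labels: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Join fingerprint rows with a labels frame (index subject_id, column y).

    Raises when either side has subjects the other lacks, listing orphans.
    """
    mat_ids = set(matrix.subject_ids)
    lab_ids = set(labels.index)
    only_m = sorted(mat_ids - lab_ids)
    only_l = sorted(lab_ids - mat_ids)
    if only_m or only_l:
        raise ValueError(
            f"subject mismatch; only in matrix: {only_m[:5]}, only in labels: {only_l[:5]}")
    y = labels.loc[matrix.subject_ids, "y"].to_numpy(float)
    return matrix.values, y
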