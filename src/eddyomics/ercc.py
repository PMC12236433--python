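"""Spike-in calibration and absolute (per-ml) transcript normalization.

Known quantities of synthetic RNA standards spiked into every sample before
library preparation let raw transcript counts be converted to absolute
molecule numbers.  Per sample, the correction factor ``f`` is the slope of
the least-squares line of observed spike counts on spiked molecules forced
through the origin — the sample's capture efficiency in counts per
molecule — and the detection limit ``L`` is the smallest spiked molar
amount actually observed.  A transcript's absolute abundance is then
``count / f / volume_ml`` (molecules per ml); entries whose back-estimated
molecule number falls below ``L`` are flagged below-detection (retained,
never zeroed — downstream stages decide whether to exclude them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbsoluteAbundanceTable, AbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "SpikeInCalibration",
    "fit_correction_factor",
    "detection_limit",
    "normalize_to_per_ml",
    "ErccCalibrationModel",
    "ErccCalibrationResults",
]


@dataclass(frozen=True)
class SpikeInCalibration:
    """Per-sample spike-in calibration: slope, detection limit, spike tally."""

    sample_id: str
    correction_factor: float  # counts per molecule, > 0
    detection_limit: float    # molecules; a molar amount present in the reference
    n_spikes_detected: int

    def __post_init__(self) -> None:
        if self.correction_factor <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: correction factor must be > 0"
            )


def fit_correction_factor(
    molecules: np.ndarray, counts: np.ndarray, detected_only: bool = False
) -> float:
    """Forced-origin least-squares slope of counts on molecules.

    ``f = sum(molecules * counts) / sum(molecules^2)``.  By default every
    reference standard enters the fit, undetected (zero-count) ones
    included — a zero observation is informative in a through-origin fit;
    ``detected_only`` restricts to standards with counts > 0.
    """
    m = np.asarray(molecules, dtype=float)
    c = np.asarray(counts, dtype=float)
    if m.ndim != 1 or m.shape != c.shape or m.size < 2:
        raise ValueError("molecules and counts must be equal-length vectors (n >= 2)")
    if np.any(m <= 0):
        raise ValueError("molecule amounts must be > 0")
    if not np.any(c > 0):
        raise ValidationError("no spike-ins detected: all counts zero")
    if detected_only:
        keep = c > 0
        m, c = m[keep], c[keep]
    return float(np.sum(m * c) / np.sum(m * m))


def detection_limit(molecules: np.ndarray, counts: np.ndarray) -> float:
    """Smallest spiked molar amount whose standard was observed (count > 0)."""
    m = np.asarray(molecules, dtype=float)
    c = np.asarray(counts, dtype=float)
    if m.shape != c.shape:
        raise ValueError("molecules and counts must align")
    detected = m[c > 0]
    if detected.size == 0:
        raise ValidationError("no spike-ins detected: all counts zero")
    return float(detected.min())


def normalize_to_per_ml(
    counts: AbundanceTable,
    calibrations: dict[str, SpikeInCalibration],
    meta: SampleMetadata,
) -> AbsoluteAbundanceTable:
    """Convert raw transcript counts to molecules per ml of filtered water.

    value(t, s) = count(t, s) / f_s / volume_ml_s.  Entries whose molecule
    estimate ``count / f_s`` is below the sample's detection limit are
    flagged below-detection; the value is kept.
    """
    values = counts.values.astype(float).copy()
    flags = pd.DataFrame(False, index=values.index, columns=values.columns)
    for s in counts.samples:
        if s not in calibrations:
            raise ValidationError(f"sample {s!r} has no spike-in calibration")
        cal = calibrations[s]
        volume = meta.volume_ml(s) if s in meta.sample_ids else None
        if volume is None:
            raise ValidationError(f"sample {s!r} missing from metadata; volume unknown")
        molecule_est = values[s] / cal.correction_factor
        flags[s] = molecule_est < cal.detection_limit
        values[s] = molecule_est / volume
    return AbsoluteAbundanceTable(
        values, "transcript_per_ml", counts.annotations, below_detection=flags
    )


class ErccCalibrationModel:
    """Spike-in calibration model over a cohort of samples.

    Parameters
    ----------
    spike_counts
        Standards x samples table of observed spike-in read counts.
    reference
        Series mapping standard id -> molecules spiked per sample.
    detected_only
        Restrict each sample's slope fit to detected standards.
    """

    def __init__(
        self,
        spike_counts: AbundanceTable,
        reference: pd.Series,
        detected_only: bool = False,
    ) -> None:
        missing = [i for i in spike_counts.features if i not in reference.index]
        if missing:
            raise ValidationError(f"spike-in ids missing from reference: {missing[:5]}")
        self.spike_counts = spike_counts
        self.reference = reference.astype(float)
        self.detected_only = detected_only

    def fit(self) -> "ErccCalibrationResults":
        mols = self.reference.loc[self.spike_counts.features].to_numpy()
        cals: dict[str, SpikeInCalibration] = {}
        for s in self.spike_counts.samples:
            c = self.spike_counts.values[s].to_numpy(dtype=float)
            cals[s] = SpikeInCalibration(
                sample_id=s,
                correction_factor=fit_correction_factor(mols, c, self.detected_only),
                detection_limit=detection_limit(mols, c),
                n_spikes_detected=int(np.sum(c > 0)),
            )
        return ErccCalibrationResults(self, cals)


class ErccCalibrationResults:
    """Fitted per-sample correction factors and detection limits."""

    def __init__(self, model: ErccCalibrationModel, calibrations: dict[str, SpikeInCalibration]):
        self.model = model
        self.calibrations = calibrations

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "correction_factor": {s: c.correction_factor for s, c in self.calibrations.items()},
                "detection_limit": {s: c.detection_limit for s, c in self.calibrations.items()},
                "n_spikes_detected": {s: c.n_spikes_detected for s, c in self.calibrations.items()},
            }
        ).rename_axis("sample_id")

    def normalize(self, counts: AbundanceTable, meta: SampleMetadata) -> AbsoluteAbundanceTable:
        return normalize_to_per_ml(counts, self.calibrations, meta)

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Spike-in calibration",
            "====================",
            f"samples: {len(df)}   standards: {len(self.model.spike_counts.features)}",
            f"correction factor (counts/molecule): median {df['correction_factor'].median():.4g}, "
            f"range [{df['correction_factor'].min():.4g}, {df['correction_factor'].max():.4g}]",
            f"detection limit (molecules): median {df['detection_limit'].median():.4g}",
            f"spikes detected per sample: median {df['n_spikes_detected'].median():.0f}",
        ]
        return "\n".join(lines)
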