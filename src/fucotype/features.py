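"""Diagnostic-ion feature extraction.

Each (spectrum, glycopeptide) pair is reduced to a 14-dimensional vector of
relative intensities, one slot per diagnostic ion in fixed panel order
(B2, B2F, B3, B3F, B3S, B3SF, Y1, Y1F, Y2, Y2F, Y3, Y3F, Y4, Y4F).

A theoretical ion m/z is matched against the spectrum within +/-0.02 Da and
accepted only when the peak exceeds three times the spectrum noise level
(median peak intensity). Matched intensities are normalised to the spectrum
base peak, so features lie in [0, 1] and are invariant to overall intensity
scaling; an unmatched ion scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .glycan import DIAGNOSTIC_ION_ORDER, GlycopeptideID, diagnostic_ion_set
from .spectra import GsmRecord, Peak, Spectrum


@dataclass(frozen=True)
class ExtractionParams:
    """Peak-matching parameters.

    tolerance: half-width of the m/z match window, Da.
    snr_min: minimum peak intensity as a multiple of the noise level.
    normalization: 'base_peak' (default) divides matched intensities by the
        spectrum base peak; 'matched_sum' divides by the summed intensity of
        the 14 matched ions.
    """

    tolerance: float = 0.02
    snr_min: float = 3.0
    normalization: str = "base_peak"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.snr_min < 0:
            raise ValueError("snr_min must be >= 0")
        if self.normalization not in ("base_peak", "matched_sum"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class FeatureVector:
    """The 14 relative intensities for one GSM, in fixed panel order."""

    values: np.ndarray
    gsm: GsmRecord | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(DIAGNOSTIC_ION_ORDER),):
            raise ValueError(
                f"feature vector must have length {len(DIAGNOSTIC_ION_ORDER)}, "
                f"got shape {self.values.shape}"
            )


def estimate_noise(spectrum: Spectrum) -> float:
    """Noise level of a spectrum: the median intensity over nonzero peaks.

    An empty or all-zero spectrum has noise 0, so every peak passes S/N.
    """
    positive = [p.intensity for p in spectrum.peaks if p.intensity > 0]
    if not positive:
        return 0.0
    return float(np.median(positive))


def match_peak(
    spectrum: Spectrum,
    target_mz: float,
    params: ExtractionParams = ExtractionParams(),
    noise: float | None = None,
) -> Peak | None:
    """Most intense qualifying peak within the tolerance window, or None.

    A peak qualifies when |mz - target| <= tolerance and its intensity is at
    least snr_min * noise. Intensity ties break toward lower m/z.
    """
    if noise is None:
        noise = estimate_noise(spectrum)
    floor = params.snr_min * noise
    best: Peak | None = None
    for p in spectrum.peaks:
        if abs(p.mz - target_mz) > params.tolerance or p.intensity < floor:
            continue
        if best is None or p.intensity > best.intensity:
            best = p  # peaks are sorted by m/z, so '>' keeps the lower-m/z tie
    return best


def extract_features(
    spectrum: Spectrum,
    gp: GlycopeptideID,
    params: ExtractionParams = ExtractionParams(),
    gsm: GsmRecord | None = None,
) -> FeatureVector:
    """Relative intensities of the 14 diagnostic ions for one GSM."""
    raw = np.zeros(len(DIAGNOSTIC_ION_ORDER))
    noise = estimate_noise(spectrum)
    for i, (_, mz) in enumerate(diagnostic_ion_set(gp)):
        peak = match_peak(spectrum, mz, params, noise=noise)
        if peak is not None:
            raw[i] = peak.intensity
    if params.normalization == "base_peak":
        denom = spectrum.base_peak_intensity
    else:
        denom = raw.sum()
    values = raw / denom if denom > 0 else raw
    return FeatureVector(values=values, gsm=gsm)


def extract_feature_table(
    spectra: Sequence[Spectrum],
    gsms: Sequence[GsmRecord],
    params: ExtractionParams = ExtractionParams(),
) -> list[FeatureVector]:
    """Feature vectors for a batch of GSMs; every GSM title must resolve."""
    by_title = {s.title: s for s in spectra}
    missing = [g.spectrum_title for g in gsms if g.spectrum_title not in by_title]
    if missing:
        raise KeyError(
            f"{len(missing)} GSM title(s) not found in spectra, e.g. {missing[:5]}"
        )
    return [
        extract_features(by_title[g.spectrum_title], g.glycopeptide, params, gsm=g)
        for g in gsms
    ]


def feature_matrix(fvs: Sequence[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n, 14) array."""
    return np.vstack([fv.values for fv in fvs]) if fvs else np.empty((0, 14))


def features_to_frame(fvs: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabular view: title, the 14 named feature columns, label if present."""
    rows = []
    for fv in fvs:
        row = {"title": fv.gsm.spectrum_title if fv.gsm else ""}
        row.update(dict(zip(DIAGNOSTIC_ION_ORDER, fv.values)))
        row["label"] = (fv.gsm.manual_label or "") if fv.gsm else ""
        rows.append(row)
    return pd.DataFrame(rows)
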