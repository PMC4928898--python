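"""Classification features for BIS measurement quality.

Thirty of the features are band-averaged signed relative errors between a
measured immittance magnitude and its Cole-fitted counterpart,

    f = < (M(w) - Mfit(w)) / M(w) >  over grid points of one band,

for the six magnitudes R, X, G, B, |Z|, angle(Z) crossed with the five
characteristic-frequency-relative bands (VLF..VHF).  Feature 31 is the
sign of the reactance at the highest measured frequency, which separates
inductive-crossover artifacts from everything else.

Because the errors are relative and the bands are defined relative to the
fitted characteristic frequency, the features are dimensionless and
application-independent: no normalisation of the feature matrix is needed.

Guard rules for the relative errors (the measured magnitude in the
denominator can cross zero for inductive artifacts):

* per-point relative errors are clipped to [-3, +3] before averaging —
  inductive-crossover artifacts drive the reactance (and susceptance)
  denominators through zero, and without a cap those bands would swamp
  the least-squares discriminants; the cap keeps the large-error signal
  while bounding its leverage;
* points whose denominator magnitude falls below 1e-12 times the band's
  median magnitude are excluded from the mean;
* an empty band yields feature value 0 with a zero point count recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cole import Band, band_masks
from .immittance import ImmittanceSet

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "N_FEATURES",
    "MAGNITUDE_ORDER",
    "extract_features",
    "reactance_sign",
    "feature_name",
]

#: Magnitudes in feature-index order: f1-f5 = R by band VLF..VHF, f6-f10 = X,
#: f11-f15 = G, f16-f20 = B, f21-f25 = |Z|, f26-f30 = angle(Z), f31 = sign(X(wmax)).
MAGNITUDE_ORDER = ("r", "x", "g", "b", "zmod", "zang")
N_FEATURES = 31

_BANDS = (Band.VLF, Band.LF, Band.MF, Band.HF, Band.VHF)
_MAG_LABEL = {"r": "R", "x": "X", "g": "G", "b": "B", "zmod": "|Z|", "zang": "angZ"}

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, N_FEATURES + 1))

_CLIP = 3.0
_DENOM_FLOOR = 1e-12


def feature_name(index: int, long: bool = False) -> str:
    """Human-readable name of a feature by 1-based index."""
    if not 1 <= index <= N_FEATURES:
        raise IndexError(f"feature index must be 1..{N_FEATURES}, got {index}")
    if not long:
        return FEATURE_NAMES[index - 1]
    if index == N_FEATURES:
        return "f31 [sign X(wmax)]"
    mag = MAGNITUDE_ORDER[(index - 1) // 5]
    band = _BANDS[(index - 1) % 5]
    return f"f{index} [{_MAG_LABEL[mag]} {band.name}]"


@dataclass(frozen=True)
class FeatureVector:
    """The 31 features of one measurement plus per-band grid-point counts."""

    values: np.ndarray
    band_counts: dict[Band, int]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite feature value")
        object.__setattr__(self, "values", values)

    def __getitem__(self, index: int) -> float:
        """1-based feature access: fv[4] is f4."""
        if not 1 <= index <= N_FEATURES:
            raise IndexError(f"feature index must be 1..{N_FEATURES}")
        return float(self.values[index - 1])


def reactance_sign(measured: ImmittanceSet) -> int:
    """Sign of the reactance at the highest frequency; sign(0) = 0."""
    if len(measured) == 0:
        raise ValueError("empty grid")
    return int(np.sign(measured.x[-1]))


def _band_mean_relative_error(meas: np.ndarray, fit: np.ndarray, mask: np.ndarray) -> float:
    m = meas[mask]
    f = fit[mask]
    if m.size == 0:
        return 0.0
    floor = _DENOM_FLOOR * max(float(np.median(np.abs(m))), 1e-300)
    keep = np.abs(m) > floor
    if not np.any(keep):
        return 0.0
    rel = (m[keep] - f[keep]) / m[keep]
    return float(np.mean(np.clip(rel, -_CLIP, _CLIP)))


def extract_features(measured: ImmittanceSet, fitted: ImmittanceSet,
                     omega_c: float) -> FeatureVector:
    """Compute the 31-feature vector for one measurement.

    Parameters
    ----------
    measured, fitted : ImmittanceSet
        Immittance magnitudes of the measurement and of its Cole fit,
        on the same frequency grid.
    omega_c : float
        Characteristic angular frequency of the fit, used to assign grid
        points to bands.
    """
    if len(measured) == 0:
        raise ValueError("empty grid")
    if len(measured) != len(fitted) or not np.allclose(measured.omega, fitted.omega):
        raise ValueError("measured and fitted grids differ")
    masks = band_masks(measured.omega, omega_c)
    counts = {band: int(np.count_nonzero(m)) for band, m in masks.items()}
    empty = [b.name for b in _BANDS if counts[b] == 0]
    if empty:
        warnings.warn(f"empty band(s) {empty}: features set to 0", stacklevel=2)
    values = np.empty(N_FEATURES)
    k = 0
    for mag in MAGNITUDE_ORDER:
        meas = measured.magnitude(mag)
        fit = fitted.magnitude(mag)
        for band in _BANDS:
            values[k] = _band_mean_relative_error(meas, fit, masks[band])
            k += 1
    values[30] = reactance_sign(measured)
    return FeatureVector(values, counts)
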