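"""Synthetic labeled BIS spectra for all seven measurement-quality classes.

The generator emulates a heterogeneous measurement database: Cole
parameters drawn from application-like profiles, multiplicative
measurement noise on resistance and reactance, and parametric artifact
injectors reproducing the qualitative impedance-plane signatures of the
six error types:

* ``TYPE_A`` — hook effect: a parallel stray capacitance ``Cp`` across
  the load, ``Zm = Z / (1 + j w Cp Z)``, sized at ``wc/2`` so the
  reactance decrement is already under way in the MF band.
* ``TYPE_B`` — capacitive outer tail confined to VHF: an additive
  (R down, X down) deviation growing quadratically above ``6 wc``.
* ``TYPE_C`` — a weaker parallel-capacitance loading anchored at
  ``5 wc``: the same outward-tail geometry as Type-B at the top of the
  spectrum, but the deviation is already noticeable from the HF band.
* ``TYPE_D`` — inner tail: the resistance trend reverses (turns back up)
  over the VHF decade while the reactance is pulled toward, but not
  through, zero.
* ``TYPE_E`` — inductive crossover: the reactance is driven linearly
  through zero in VHF so ``X(wmax) > 0``, resistance stays monotone.
* ``TYPE_F`` — Type-D's resistance reversal combined with Type-E's
  positive reactance at the top frequencies.

Severities are drawn uniformly from per-type ranges whose defaults are
chosen so each signature is well clear of the noise floor (see the
methods note); severity 0 reproduces the clean spectrum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import ErrorClass
from .cole import ColeParameters, ComplexSpectrum, evaluate_cole

__all__ = [
    "ParameterProfile",
    "GeneratorConfig",
    "LabeledSpectrum",
    "SpectraCollection",
    "default_frequency_grid",
    "sample_cole_params",
    "inject_error",
    "add_noise",
    "generate_dataset",
]


def default_frequency_grid(n_points: int = 50, f_min_hz: float = 5e3,
                           f_max_hz: float = 1e6) -> np.ndarray:
    """Log-spaced measurement frequencies in Hz (spectrometer convention)."""
    return np.logspace(np.log10(f_min_hz), np.log10(f_max_hz), n_points)


@dataclass(frozen=True)
class ParameterProfile:
    """Uniform ranges for the Cole parameters of one BIS application.

    ``rinf_frac`` is sampled as a fraction of the drawn ``r0`` so the
    invariant ``R0 > Rinf`` holds by construction; ``fc_hz`` is the
    characteristic frequency in Hz (``tau = 1 / (2 pi fc)``).
    """

    r0: tuple[float, float]
    rinf_frac: tuple[float, float]
    alpha: tuple[float, float]
    fc_hz: tuple[float, float]


#: Application-like profiles.  Magnitudes differ by application; the
#: characteristic frequencies all sit inside the default grid so every
#: band is populated.
DEFAULT_PROFILES: dict[str, ParameterProfile] = {
    "body_composition": ParameterProfile((400.0, 800.0), (0.5, 0.8),
                                         (0.65, 0.8), (20e3, 80e3)),
    "segmental": ParameterProfile((150.0, 400.0), (0.5, 0.8),
                                  (0.65, 0.8), (25e3, 90e3)),
    "cerebral": ParameterProfile((30.0, 90.0), (0.55, 0.8),
                                 (0.6, 0.78), (15e3, 60e3)),
}

DEFAULT_SEVERITY_RANGES: dict[ErrorClass, tuple[float, float]] = {
    ErrorClass.CLEAN: (0.0, 0.0),
    ErrorClass.TYPE_A: (0.70, 1.30),
    ErrorClass.TYPE_B: (0.70, 1.50),
    ErrorClass.TYPE_C: (0.70, 1.50),
    ErrorClass.TYPE_D: (0.30, 0.60),
    ErrorClass.TYPE_E: (0.60, 1.50),
    ErrorClass.TYPE_F: (0.60, 1.50),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic database."""

    freq_hz: np.ndarray = field(default_factory=default_frequency_grid)
    profiles: dict[str, ParameterProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    noise_sd: float = 0.003
    severity_ranges: dict[ErrorClass, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_RANGES))
    class_counts: dict[ErrorClass, int] = field(
        default_factory=lambda: {c: 100 for c in ErrorClass})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        freq = np.asarray(self.freq_hz, dtype=float)
        if np.any(np.diff(freq) <= 0) or np.any(freq <= 0):
            raise ValueError("freq_hz must be positive and strictly increasing")
        object.__setattr__(self, "freq_hz", freq)
        for prof in self.profiles.values():
            for lo, hi in (prof.r0, prof.rinf_frac, prof.alpha, prof.fc_hz):
                if not lo <= hi:
                    raise ValueError("profile ranges must satisfy lo <= hi")
            if not (0 < prof.alpha[0] and prof.alpha[1] <= 1):
                raise ValueError("alpha range must lie in (0, 1]")
            if not (0 < prof.rinf_frac[0] and prof.rinf_frac[1] < 1):
                raise ValueError("rinf_frac range must lie in (0, 1)")

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.freq_hz


@dataclass(frozen=True)
class LabeledSpectrum:
    """One generated measurement with its ground truth."""

    spectrum: ComplexSpectrum
    label: ErrorClass
    params: ColeParameters | None = None
    profile: str | None = None
    severity: float | None = None


@dataclass(frozen=True)
class SpectraCollection:
    """A labeled set of measurements, all on one frequency grid (Hz)."""

    freq_hz: np.ndarray
    samples: tuple[LabeledSpectrum, ...]

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(s.label) for s in self.samples])


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def sample_cole_params(profile: ParameterProfile,
                       rng: np.random.Generator) -> ColeParameters:
    """Draw one valid Cole parameter set from a profile."""
    r0 = _uniform(rng, profile.r0)
    rinf = r0 * _uniform(rng, profile.rinf_frac)
    alpha = _uniform(rng, profile.alpha)
    fc = _uniform(rng, profile.fc_hz)
    return ColeParameters(r0, rinf, alpha, 1.0 / (2.0 * np.pi * fc))


def _ramp(omega: np.ndarray, onset: float, power: float = 1.0) -> np.ndarray:
    """Ramp: 0 below the onset, rising to 1 at the top frequency."""
    top = omega[-1]
    if top <= onset:
        return np.zeros_like(omega)
    r = np.clip((omega - onset) / (top - onset), 0.0, None)
    return r**power


def inject_error(clean: ComplexSpectrum, error_type: ErrorClass,
                 severity: float, params: ColeParameters) -> ComplexSpectrum:
    """Apply one artifact template of the requested type and severity.

    ``params`` supplies the true characteristic frequency anchoring the
    band-localised templates.  ``CLEAN`` (or severity 0) is the identity.
    """
    error_type = ErrorClass(error_type)
    if error_type is ErrorClass.CLEAN or severity == 0.0:
        return clean
    if severity < 0:
        raise ValueError("severity must be >= 0")
    omega = clean.omega
    z = clean.z
    wc = params.omega_c
    r, x = z.real, z.imag
    max_abs_x = float(np.max(np.abs(x)))
    dr_scale = params.r0 - params.rinf

    if error_type in (ErrorClass.TYPE_A, ErrorClass.TYPE_C):
        # parallel stray capacitance across the load, Zm = Z/(1 + jwCpZ).
        # Cp is sized so the loading w*Cp*|Z| reaches the severity at the
        # anchor frequency: 0.5*wc for the Type-A hook (reactance
        # decrement already under way in MF), 5*wc for Type-C (deviation
        # noticeable from HF, dominant in VHF).
        anchor = 0.5 * wc if error_type is ErrorClass.TYPE_A else 5.0 * wc
        z_on = float(np.interp(anchor, omega, np.abs(z)))
        cp = severity / (anchor * z_on)
        zm = z / (1.0 + 1j * omega * cp * z)
        return ComplexSpectrum(omega, zm)
    if error_type is ErrorClass.TYPE_B:
        # capacitive outer tail confined to VHF: the arc extends outward
        # (R down, X down) only above 6*wc, growing quadratically
        tail = severity * max_abs_x * _ramp(omega, 6.0 * wc, power=2.0)
        return ComplexSpectrum(omega, (r - 0.35 * tail) + 1j * (x - tail))
    if error_type is ErrorClass.TYPE_D:
        ramp = _ramp(omega, 5.0 * wc)
        rm = r + severity * dr_scale * ramp
        xm = x * (1.0 - 0.7 * ramp)  # pulled toward zero, never through it
        return ComplexSpectrum(omega, rm + 1j * xm)
    if error_type in (ErrorClass.TYPE_E, ErrorClass.TYPE_F):
        ramp = _ramp(omega, 5.0 * wc)
        # amplitude sized so X(wmax) ends at +severity * |X(wmax)|
        amp = (1.0 + severity) * abs(x[-1])
        xm = x + amp * ramp
        rm = r
        if error_type is ErrorClass.TYPE_F:
            rm = r + severity * dr_scale * ramp
        return ComplexSpectrum(omega, rm + 1j * xm)
    raise ValueError(f"unknown error type {error_type!r}")


def add_noise(spectrum: ComplexSpectrum, noise_sd: float,
              rng: np.random.Generator) -> ComplexSpectrum:
    """Independent multiplicative Gaussian noise on R and X per frequency."""
    if noise_sd == 0:
        return spectrum
    r = spectrum.z.real * (1.0 + noise_sd * rng.standard_normal(len(spectrum)))
    x = spectrum.z.imag * (1.0 + noise_sd * rng.standard_normal(len(spectrum)))
    return ComplexSpectrum(spectrum.omega, r + 1j * x)


def generate_dataset(config: GeneratorConfig | None = None,
                     rng: np.random.Generator | None = None) -> SpectraCollection:
    """Generate the full labeled synthetic database.

    Noise is applied after artifact injection.  With a fixed
    ``config.rng_seed`` (and no external ``rng``) the output is
    bit-reproducible.
    """
    config = config or GeneratorConfig()
    rng = rng or np.random.default_rng(config.rng_seed)
    omega = config.omega
    profile_names = sorted(config.profiles)
    samples: list[LabeledSpectrum] = []
    for error_type in ErrorClass:
        count = config.class_counts.get(error_type, 0)
        for _ in range(count):
            pname = profile_names[rng.integers(len(profile_names))]
            params = sample_cole_params(config.profiles[pname], rng)
            clean = evaluate_cole(params, omega)
            severity = _uniform(rng, config.severity_ranges[error_type])
            corrupted = inject_error(clean, error_type, severity, params)
            noisy = add_noise(corrupted, config.noise_sd, rng)
            samples.append(LabeledSpectrum(noisy, error_type, params,
                                           pname, severity))
    return SpectraCollection(config.freq_hz, tuple(samples))
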