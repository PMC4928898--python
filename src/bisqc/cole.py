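"""Cole impedance model: evaluation, fitting, and characteristic-frequency bands.

The Cole equation

    Z(w) = Rinf + (R0 - Rinf) / (1 + (j*w*tau)**alpha)

describes the complex impedance of biological tissue as a depressed
semicircle in the impedance plane.  ``R0`` and ``Rinf`` are the resistances
at zero and infinite frequency, ``alpha`` the depression exponent and
``tau`` the time constant whose inverse is the characteristic angular
frequency ``omega_c``.  Five frequency bands (VLF..VHF) are defined
relative to ``omega_c`` and anchor all downstream feature extraction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ColeParameters",
    "ComplexSpectrum",
    "Band",
    "ColeFitError",
    "evaluate_cole",
    "cole_impedance",
    "ColeModel",
    "ColeFitResults",
    "fit_cole",
    "band_of",
    "band_masks",
]


@dataclass(frozen=True)
class ColeParameters:
    """The four Cole parameters, all validated on construction.

    Parameters
    ----------
    r0 : float
        Resistance at zero frequency (ohm); must exceed ``rinf``.
    rinf : float
        Resistance at infinite frequency (ohm); strictly positive.
    alpha : float
        Dimensionless depression exponent in (0, 1].
    tau : float
        Time constant (s); ``omega_c = 1 / tau``.
    """

    r0: float
    rinf: float
    alpha: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.r0 > self.rinf > 0):
            raise ValueError(
                f"require R0 > Rinf > 0, got R0={self.r0}, Rinf={self.rinf}"
            )
        if not (0 < self.alpha <= 1):
            raise ValueError(f"require 0 < alpha <= 1, got {self.alpha}")
        if not self.tau > 0:
            raise ValueError(f"require tau > 0, got {self.tau}")

    @property
    def omega_c(self) -> float:
        """Characteristic angular frequency 1/tau (rad/s)."""
        return 1.0 / self.tau

    def as_array(self) -> np.ndarray:
        return np.array([self.r0, self.rinf, self.alpha, self.tau])


@dataclass(frozen=True)
class ComplexSpectrum:
    """One measurement: angular frequencies (rad/s) with complex impedances (ohm).

    ``omega`` must be strictly increasing and non-negative; a zero first
    point is tolerated only so the zero-frequency limit of the Cole
    equation can be represented — fitting and feature extraction require
    all frequencies positive.
    """

    omega: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if omega.ndim != 1 or z.ndim != 1 or omega.size != z.size:
            raise ValueError("omega and z must be 1-d arrays of equal length")
        if omega.size < 2:
            raise ValueError("a spectrum needs at least 2 frequency points")
        if np.any(omega < 0) or np.any(np.diff(omega) <= 0):
            raise ValueError("omega must be non-negative and strictly increasing")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return int(self.omega.size)

    @property
    def resistance(self) -> np.ndarray:
        return self.z.real

    @property
    def reactance(self) -> np.ndarray:
        return self.z.imag

    def scaled(self, k: float) -> "ComplexSpectrum":
        return ComplexSpectrum(self.omega, self.z * k)


class Band(enum.IntEnum):
    """Characteristic-frequency-relative bands, totally ordered VLF < .. < VHF."""

    VLF = 0
    LF = 1
    MF = 2
    HF = 3
    VHF = 4


class ColeFitError(RuntimeError):
    """Raised when the Cole fit cannot converge or the input is degenerate.

    Carries the best iterate reached (``best_params``, possibly None) and
    the residual at that iterate.
    """

    def __init__(self, message: str, best_params: ColeParameters | None = None,
                 residual: float = float("nan")):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


def cole_impedance(params: ColeParameters, omega) -> np.ndarray:
    """Evaluate the Cole equation on an array of angular frequencies.

    ``(j*w*tau)**alpha`` is taken on the principal branch — for w > 0 this
    is ``(w*tau)**alpha * exp(j*alpha*pi/2)`` — so reactances of clean
    spectra are <= 0.  ``omega = 0`` yields exactly ``r0``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")
    mag = (omega * params.tau) ** params.alpha
    jwt_a = mag * np.exp(1j * params.alpha * np.pi / 2.0)
    return params.rinf + (params.r0 - params.rinf) / (1.0 + jwt_a)


def evaluate_cole(params: ColeParameters, omega) -> ComplexSpectrum:
    """Evaluate the Cole equation and wrap the result as a spectrum."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    return ComplexSpectrum(omega, cole_impedance(params, omega))


def band_of(omega: float, omega_c: float) -> Band:
    """Band containing ``omega`` relative to the characteristic frequency.

    VLF: w < wc/5;  LF: wc/5 <= w < wc/2;  MF: wc/2 <= w < 2wc;
    HF: 2wc <= w <= 5wc;  VHF: w > 5wc.  The HF upper edge is inclusive.
    """
    if omega <= 0 or omega_c <= 0:
        raise ValueError("omega and omega_c must be > 0")
    if omega < 0.2 * omega_c:
        return Band.VLF
    if omega < 0.5 * omega_c:
        return Band.LF
    if omega < 2.0 * omega_c:
        return Band.MF
    if omega <= 5.0 * omega_c:
        return Band.HF
    return Band.VHF


def band_masks(omega: np.ndarray, omega_c: float) -> dict[Band, np.ndarray]:
    """Boolean membership masks for all five bands on a frequency grid."""
    omega = np.asarray(omega, dtype=float)
    if omega_c <= 0:
        raise ValueError("omega_c must be > 0")
    e1, e2, e3, e4 = (0.2 * omega_c, 0.5 * omega_c, 2.0 * omega_c,
                      5.0 * omega_c)
    return {
        Band.VLF: omega < e1,
        Band.LF: (omega >= e1) & (omega < e2),
        Band.MF: (omega >= e2) & (omega < e3),
        Band.HF: (omega >= e3) & (omega <= e4),
        Band.VHF: omega > e4,
    }


def _initial_guess(spectrum: ComplexSpectrum) -> np.ndarray:
    r = spectrum.resistance
    x = spectrum.reactance
    r0 = float(np.max(r))
    rinf = float(np.min(r))
    # frequency of the most negative reactance approximates omega_c
    w_peak = float(spectrum.omega[np.argmin(x)])
    tau = 1.0 / w_peak if w_peak > 0 else 1.0 / float(np.median(spectrum.omega))
    return np.array([rinf, max(r0 - rinf, 1e-9 * max(r0, 1.0)), 0.8, tau])


class ColeModel:
    """Fit the Cole equation to a measured impedance spectrum.

    The fit minimises the sum of squared complex residuals
    ``sum |Z(w_i) - Zfit(w_i)|^2`` in the impedance plane, stacking real
    and imaginary parts, with bounded nonlinear least squares over
    ``(Rinf, R0 - Rinf, alpha, tau)`` so the parameter invariants
    (``R0 > Rinf > 0``, ``0 < alpha <= 1``, ``tau > 0``) hold by
    construction.  Residuals are unweighted.

    Examples
    --------
    >>> p = ColeParameters(450, 250, 0.75, 1 / (2 * np.pi * 40e3))
    >>> w = np.logspace(np.log10(2*np.pi*1e3), np.log10(2*np.pi*1e6), 50)
    >>> res = ColeModel(evaluate_cole(p, w)).fit()
    >>> abs(res.params.r0 - 450) < 0.5
    True
    """

    def __init__(self, spectrum: ComplexSpectrum):
        if len(spectrum) < 4:
            raise ValueError("Cole fit needs at least 4 frequency points")
        if np.any(spectrum.omega <= 0):
            raise ValueError("Cole fit requires all omega > 0")
        self.spectrum = spectrum

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        rinf, dr, alpha, tau = x
        p = ColeParameters(rinf + dr, rinf, min(alpha, 1.0), tau)
        dz = cole_impedance(p, self.spectrum.omega) - self.spectrum.z
        return np.concatenate([dz.real, dz.imag])

    def fit(self, max_nfev: int = 1000, tol: float = 1e-10) -> "ColeFitResults":
        """Run the bounded least-squares fit.

        Raises
        ------
        ColeFitError
            If the spectrum is degenerate (constant impedance) or the
            optimiser exhausts its evaluation budget without converging;
            the best iterate reached is attached to the exception.
        """
        z = self.spectrum.z
        omega = self.spectrum.omega
        if np.ptp(z.real) < 1e-12 * max(1.0, abs(z.real[0])) and np.ptp(z.imag) < 1e-12:
            raise ColeFitError("degenerate spectrum: impedance is constant")
        x0 = _initial_guess(self.spectrum)
        scale = max(float(np.max(np.abs(z.real))), 1.0)
        # keep the fitted characteristic frequency within ~1.7 decades of
        # the measured range: avoids runaway tau on strongly corrupted data
        lo = np.array([1e-9 * scale, 1e-9 * scale, 0.01, 1.0 / (50.0 * omega[-1])])
        hi = np.array([np.inf, np.inf, 1.0, 50.0 / omega[0]])
        x0 = np.clip(x0, lo, hi)
        starts = [x0]
        w_mid = float(np.sqrt(omega[0] * omega[-1]))
        for alpha0, tau0 in ((0.5, x0[3]), (0.95, 1.0 / w_mid), (0.7, 1.0 / w_mid)):
            alt = x0.copy()
            alt[2], alt[3] = alpha0, np.clip(tau0, lo[3], hi[3])
            starts.append(alt)
        trials = []
        for start in starts:
            trial = least_squares(
                self._residuals, start, bounds=(lo, hi),
                xtol=tol, ftol=tol, gtol=tol, max_nfev=max_nfev,
                x_scale=np.array([scale, scale, 1.0, start[3]]),
            )
            trials.append((float(np.sum(trial.fun**2)), trial))
            if trial.status != 0:  # converged: no restart needed
                break
        trials.sort(key=lambda t: t[0])
        residual, sol = trials[0]
        rinf, dr, alpha, tau = sol.x
        params = ColeParameters(rinf + dr, rinf, min(alpha, 1.0), tau)
        if sol.status == 0:
            # All restarts exhausted the budget.  If the best costs agree,
            # the optimum sits in a flat parameter valley (typical for
            # strongly corrupted spectra fitting a near-degenerate arc):
            # the cost has converged even though the parameters have not.
            costs = [c for c, _ in trials]
            stationary = (len(costs) > 1 and costs[0] > 0
                          and (costs[1] - costs[0]) / costs[0] < 1e-3)
            if not stationary:
                raise ColeFitError(
                    "Cole fit did not converge within the evaluation budget",
                    best_params=params, residual=residual,
                )
            warnings.warn("Cole fit: flat parameter valley; accepting the "
                          "cost-stationary best iterate", stacklevel=2)
        return ColeFitResults(self, params, residual, sol)


@dataclass
class ColeFitResults:
    """Results of a Cole fit: the parameters, the residual, diagnostics."""

    model: ColeModel
    params: ColeParameters
    residual: float
    optim: object = field(repr=False)

    def predict(self, omega=None) -> ComplexSpectrum:
        """Fitted spectrum on ``omega`` (defaults to the measurement grid)."""
        if omega is None:
            omega = self.model.spectrum.omega
        return evaluate_cole(self.params, omega)

    @property
    def rms_relative_residual(self) -> float:
        """RMS of |Zfit - Z| / |Z| over the grid — a scale-free quality figure."""
        z = self.model.spectrum.z
        dz = self.predict().z - z
        return float(np.sqrt(np.mean((np.abs(dz) / np.abs(z)) ** 2)))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Cole model fit",
            "==============",
            f"  R0      {p.r0:12.4f} ohm",
            f"  Rinf    {p.rinf:12.4f} ohm",
            f"  alpha   {p.alpha:12.6f}",
            f"  tau     {p.tau:12.6e} s",
            f"  fc      {p.omega_c / (2 * np.pi):12.2f} Hz",
            f"  SSR     {self.residual:12.6e} ohm^2",
            f"  rms rel {self.rms_relative_residual:12.6e}",
            f"  points  {len(self.model.spectrum):6d}",
        ]
        return "\n".join(lines)


def fit_cole(spectrum: ComplexSpectrum, **kwargs) -> tuple[ColeParameters, float]:
    """Functional wrapper: fitted parameters and the minimised squared residual."""
    res = ColeModel(spectrum).fit(**kwargs)
    return res.params, res.residual
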