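"""Synthetic data: AR(2) null channels, correlated noise, and Kuramoto oscillators.

Two generators cover the two canonical test beds for synchrony metrics.
The AR(2) process produces channels that are individually autocorrelated
but mutually independent — a realistic null.  Adding one shared Gaussian
draw per time step ("correlated noise") then injects spurious common
variance whose strength is controlled by the noise SD.  The stochastic
Kuramoto model produces genuinely coupled oscillators whose coupling
strength K is the known ground truth for criterion-validity studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MultivariateTimeSeries,
    ParameterError,
    SampleCollection,
    ValidationError,
    as_array,
    validate_collection,
)
from .phase import PhaseMatrix, wrap_phase

__all__ = [
    "ARParams",
    "KuramotoParams",
    "ar_is_stationary",
    "generate_ar",
    "generate_ar_series",
    "add_correlated_noise",
    "generate_kuramoto",
    "sample_kuramoto_collection",
]


@dataclass
class ARParams:
    """Second-order autoregression X_t = c + phi_1 X_{t-1} + phi_2 X_{t-2} + eps_t.

    ``epsilon`` is the standard deviation of the Gaussian innovation added at
    each step.  Defaults (phi_1=0.8, phi_2=-0.2, c=0, epsilon=1) give a
    stationary, smoothly autocorrelated channel.
    """

    phi_1: float = 0.8
    phi_2: float = -0.2
    c: float = 0.0
    epsilon: float = 1.0
    length: int = 1000

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ParameterError(f"length must be >= 3, got {self.length}")
        if self.epsilon < 0:
            raise ParameterError(f"epsilon must be >= 0, got {self.epsilon}")


def ar_is_stationary(phi_1: float, phi_2: float) -> bool:
    """True when both roots of 1 - phi_1 z - phi_2 z^2 lie outside the unit circle.

    Equivalent triangle conditions: phi_2 + phi_1 < 1, phi_2 - phi_1 < 1,
    |phi_2| < 1.
    """
    return (phi_2 + phi_1 < 1) and (phi_2 - phi_1 < 1) and (abs(phi_2) < 1)


def generate_ar(params: ARParams, rng: np.random.Generator) -> np.ndarray:
    """One AR(2) realization of ``params.length`` steps, initialized at 0, 0."""
    if not ar_is_stationary(params.phi_1, params.phi_2):
        warnings.warn(
            f"AR coefficients ({params.phi_1}, {params.phi_2}) are nonstationary; "
            "the series will drift or explode",
            stacklevel=2,
        )
    noise = rng.normal(0.0, params.epsilon, size=params.length)
    x = np.zeros(params.length)
    for t in range(2, params.length):
        x[t] = params.c + params.phi_1 * x[t - 1] + params.phi_2 * x[t - 2] + noise[t]
    return x


def generate_ar_series(
    n_variables: int,
    params: ARParams,
    rng: np.random.Generator,
) -> MultivariateTimeSeries:
    """Stack ``n_variables`` independent AR(2) channels into one recording."""
    if n_variables < 2:
        raise ParameterError("a multivariate series needs >= 2 variables")
    return MultivariateTimeSeries(
        np.vstack([generate_ar(params, rng) for _ in range(n_variables)])
    )


def add_correlated_noise(
    series,
    noise_sd: float,
    rng: np.random.Generator,
) -> MultivariateTimeSeries:
    """Add one shared Gaussian draw per time step to every variable.

    The common-mode term leaves all cross-variable differences untouched but
    induces pairwise correlation ~ s^2/(s^2+1) on standardized independent
    inputs (inputs are expected to be standardized beforehand so noise_sd is
    interpretable as a relative contribution).
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    values = as_array(series)
    common = rng.normal(0.0, noise_sd, size=values.shape[1]) if noise_sd > 0 else 0.0
    interval = series.sample_interval if isinstance(series, MultivariateTimeSeries) else 1.0
    return MultivariateTimeSeries(values + common, sample_interval=interval)


@dataclass
class KuramotoParams:
    """Stochastic Kuramoto system integrated by the Euler method.

    Each oscillator's phase follows
    ``dtheta_i = omega_i + K * r * sin(psi - theta_i) + noise``,
    where r and psi are the modulus and argument of the ensemble's mean unit
    vector, K is the shared coupling strength, and the per-step noise is
    ``alpha * Normal(0, sqrt(d_t))``.  ``d_t`` is the step length in seconds.
    """

    K: float
    omegas: np.ndarray
    initial_phases: np.ndarray
    alpha: float = 0.3
    d_t: float = 0.05
    length: int = 1000

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.initial_phases = np.asarray(self.initial_phases, dtype=float)
        if self.omegas.shape != self.initial_phases.shape or self.omegas.ndim != 1:
            raise ParameterError("omegas and initial_phases must be 1-D and equal length")
        if self.omegas.size < 2:
            raise ParameterError("need >= 2 oscillators")
        if self.length < 2:
            raise ParameterError(f"length must be >= 2, got {self.length}")
        if self.d_t <= 0:
            raise ParameterError(f"d_t must be positive, got {self.d_t}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")


def generate_kuramoto(
    params: KuramotoParams,
    rng: np.random.Generator,
) -> tuple[MultivariateTimeSeries, PhaseMatrix]:
    """Integrate the system and return (amplitudes, true phases).

    Amplitudes are sin(theta), the minimal oscillator observable, so phase
    extraction can be exercised on the amplitudes while metrics that want
    ground truth can use the returned phases directly.
    """
    n = params.omegas.size
    theta = np.empty((n, params.length))
    theta[:, 0] = params.initial_phases
    noise = params.alpha * rng.normal(0.0, np.sqrt(params.d_t), size=(n, params.length - 1))
    for t in range(params.length - 1):
        z = np.exp(1j * theta[:, t]).mean()
        r, psi = np.abs(z), np.angle(z)
        drift = params.omegas + params.K * r * np.sin(psi - theta[:, t])
        theta[:, t + 1] = theta[:, t] + params.d_t * drift + noise[:, t]
    amplitudes = MultivariateTimeSeries(np.sin(theta), sample_interval=params.d_t)
    return amplitudes, PhaseMatrix(wrap_phase(theta), source_note="kuramoto")


def sample_kuramoto_collection(
    n_series: int,
    K: float,
    n_osc: int = 5,
    length: int = 1000,
    omega_scale: float = np.pi,
    alpha: float = 0.3,
    d_t: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[SampleCollection, list[PhaseMatrix]]:
    """Sample of Kuramoto recordings with per-member random frequencies.

    Each member draws fresh natural frequencies from an exponential
    distribution with mean ``omega_scale`` and uniform initial phases on
    (-pi, pi]; distinct frequency sets keep variable-swap surrogates honest
    (repeated frequencies across members would fake synchrony in the
    baseline).
    """
    if n_series < 1:
        raise ParameterError("n_series must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    amplitudes, phases = [], []
    for _ in range(n_series):
        params = KuramotoParams(
            K=K,
            omegas=rng.exponential(omega_scale, size=n_osc),
            initial_phases=rng.uniform(-np.pi, np.pi, size=n_osc),
            alpha=alpha,
            d_t=d_t,
            length=length,
        )
        amp, ph = generate_kuramoto(params, rng)
        amplitudes.append(amp)
        phases.append(ph)
    return validate_collection(amplitudes), phases
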