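"""Synthetic reference signals and RR-like series.

Generators for the processes used to validate multiscale entropy
estimators — Gaussian white noise, 1/f (spectrally synthesized) noise,
periodic signals, stationary AR(1) — plus an RR-interval-like generator
with a positive baseline, slow sinusoidal trend, beat-to-beat noise and
labeled ectopic (premature beat + compensatory pause) interval pairs.

All generators are deterministic under a fixed seed and take no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = ["SynthSpec", "generate", "white_gaussian", "one_over_f",
           "periodic", "ar1", "rr_like", "rr_like_labeled",
           "volatility_modulated_rr"]

KINDS = ("white_gaussian", "one_over_f", "periodic", "ar1", "rr_like")


@dataclass(frozen=True)
class SynthSpec:
    """Declarative description of one synthetic series.

    ``params`` holds kind-specific keyword arguments (sigma, beta,
    period/amplitude, phi, RR baseline/ectopy settings).  The same spec
    (including seed) always produces a bit-identical series.
    """

    kind: str
    n: int
    seed: int = 0
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if not self.n >= 2:
            raise ValueError(f"n must be >= 2, got {self.n!r}")


def generate(spec: SynthSpec) -> np.ndarray:
    """Generate the series described by ``spec``."""
    fn = {"white_gaussian": white_gaussian, "one_over_f": one_over_f,
          "periodic": periodic, "ar1": ar1, "rr_like": rr_like}[spec.kind]
    return fn(spec.n, seed=spec.seed, **spec.params)


def white_gaussian(n: int, sigma: float = 1.0, seed: int = 0) -> np.ndarray:
    """I.i.d. zero-mean Gaussian noise with SD ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    rng = np.random.default_rng(seed)
    return sigma * rng.standard_normal(n)


def one_over_f(n: int, beta: float = 1.0, sigma: float = 1.0,
               seed: int = 0) -> np.ndarray:
    """Noise with power spectrum proportional to 1/f**beta.

    Spectral synthesis: Fourier amplitudes proportional to f**(-beta/2)
    with independent uniform random phases, zero-frequency component set
    to 0, inverse real transform, then the sample SD is normalized to
    ``sigma``.  beta=1 gives classic 1/f (pink) noise with long-range
    correlations; beta=0 recovers white noise, beta=2 a random walk-like
    spectrum.
    """
    if not (0 <= beta <= 2):
        raise ValueError(f"beta must be in [0, 2], got {beta!r}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    # real signal constraints: DC already zero; Nyquist bin real for even n
    if n % 2 == 0:
        spectrum[-1] = amp[-1]
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std(ddof=1)
    return x * (sigma / sd)


def periodic(n: int, period: float = 20.0, amplitude: float = 1.0,
             phase: float = 0.0, seed: int = 0) -> np.ndarray:
    """Deterministic sinusoid sampled at integer indices (seed unused)."""
    if period <= 0 or amplitude <= 0:
        raise ValueError("period and amplitude must be positive")
    i = np.arange(n)
    return amplitude * np.sin(2 * np.pi * i / period + phase)


def ar1(n: int, phi: float = 0.9, sigma: float = 1.0, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) process with coefficient ``phi`` and marginal SD
    ``sigma`` (innovation SD sigma*sqrt(1-phi**2); stationary start)."""
    if not abs(phi) < 1:
        raise ValueError(f"AR coefficient must satisfy |phi| < 1, got {phi!r}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    rng = np.random.default_rng(seed)
    innov_sd = sigma * np.sqrt(1 - phi ** 2)
    eps = innov_sd * rng.standard_normal(n)
    eps[0] = sigma * rng.standard_normal()  # stationary initial value
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -phi], eps)


def rr_like_labeled(n: int, seed: int = 0, baseline: float = 0.8,
                    trend_amplitude: float = 0.05, trend_period: float = 500.0,
                    noise_sd: float = 0.03, ectopy_rate: float = 0.01,
                    short_factor: float = 0.5,
                    long_factor: float = 1.5) -> Tuple[np.ndarray, np.ndarray]:
    """RR-interval-like series with ground-truth ectopy labels.

    The clean series is ``baseline + trend_amplitude*sin(2*pi*i/trend_period)
    + N(0, noise_sd**2)`` (seconds).  Ectopic events are inserted as
    premature-beat signatures: at each event position i the pair
    ``(x_i*short_factor, x_{i+1}*long_factor)`` replaces the clean
    intervals — a short interval followed by a compensatory pause.  Event
    positions are drawn so pairs never overlap.  Returns ``(values,
    is_ectopic)`` where the boolean mask marks both members of each pair.
    """
    if not (0 <= ectopy_rate <= 0.2):
        raise ValueError(f"ectopy rate must be in [0, 0.2], got {ectopy_rate!r}")
    if baseline <= 0 or noise_sd < 0:
        raise ValueError("baseline must be positive and noise_sd non-negative")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    x = baseline + trend_amplitude * np.sin(2 * np.pi * i / trend_period) \
        + noise_sd * rng.standard_normal(n)
    x = np.clip(x, 0.05 * baseline, None)  # intervals stay positive
    labels = np.zeros(n, dtype=bool)
    n_events = int(round(ectopy_rate * n / 2))  # each event spans 2 intervals
    if n_events and n >= 4:
        candidates = rng.permutation(n - 1)
        chosen = []
        taken = np.zeros(n, dtype=bool)
        for c in candidates:
            if not (taken[c] or taken[c + 1]):
                chosen.append(c)
                taken[c] = taken[c + 1] = True
                if len(chosen) == n_events:
                    break
        for c in chosen:
            x[c] *= short_factor
            x[c + 1] *= long_factor
            labels[c] = labels[c + 1] = True
    return x, labels


def rr_like(n: int, seed: int = 0, **kwargs) -> np.ndarray:
    """RR-interval-like series (see :func:`rr_like_labeled`), values only."""
    return rr_like_labeled(n, seed=seed, **kwargs)[0]


def volatility_modulated_rr(n: int, seed: int = 0, kind: str = "one_over_f",
                            baseline: float = 0.8, mean_sd: float = 0.05,
                            log_vol_sd: float = 0.7,
                            phi: float = 0.6) -> np.ndarray:
    """RR-like series whose volatility (local SD) is itself a stochastic
    process of selectable structural complexity.

    ``x_t = baseline + sigma_t * eps_t`` with i.i.d. standard normal
    ``eps`` and log-volatility ``log(sigma_t/mean_sd)`` driven by 1/f
    noise (long-range correlated volatility), AR(1) (short-range
    correlated) or i.i.d. noise (structureless), all with marginal SD
    ``log_vol_sd``.  Used to build cohorts whose variance-coarse-grained
    complexity ordering is known by construction: 1/f volatility has
    structure at every scale, AR(1) only below its correlation time
    (default phi=0.6, i.e. a few beats — short relative to the 10..100
    beat analysis band, so its multiscale structure is intermediate), and
    i.i.d. volatility none.
    """
    rng = np.random.default_rng(seed)
    sub = int(rng.integers(0, 2 ** 31 - 1))
    if kind == "one_over_f":
        h = one_over_f(n, beta=1.0, sigma=log_vol_sd, seed=sub)
    elif kind == "ar1":
        h = ar1(n, phi=phi, sigma=log_vol_sd, seed=sub)
    elif kind == "iid":
        h = white_gaussian(n, sigma=log_vol_sd, seed=sub)
    else:
        raise ValueError(f"unknown volatility kind {kind!r}")
    sigma_t = mean_sd * np.exp(h - h.mean())
    x = baseline + sigma_t * rng.standard_normal(n)
    return np.clip(x, 0.05 * baseline, None)
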