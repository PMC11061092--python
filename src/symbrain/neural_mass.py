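"""Coupled excitatory–inhibitory neural-mass network simulator.

Each cortical region is a lumped two-population model of the alpha-rhythm
type: a main excitatory (pyramidal) population and an inhibitory interneuron
population, coupled through biexponential postsynaptic impulse responses and
a potential-to-rate sigmoid.  Regions are coupled through the structural
connectome: each mass sends its excitatory pulse density, delayed by one
conduction delay and scaled by the global gain ``S_couple`` times the
structural weight, into the excitatory populations of its neighbours.  An
external thalamic drive with randomly fluctuating pulse density ``P(t)``
excites every mass.

The inhibitory firing threshold ``Vd2`` is the excitation-inhibition control
parameter: raising it makes interneurons harder to recruit, lowering
inhibitory output and pushing the network toward excitation dominance.

Numerics: every biexponential kernel h(t) = A(exp(-a t) - exp(-b t)) is
realised as its equivalent critically-stable second-order linear filter
(two first-order states) advanced by fixed-step explicit Euler at the model
sample time, so the continuum impulse response is exact in the dt -> 0
limit and well-behaved at dt = 0.002 s (dt * b_e = 1.21 < 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import StructuralConnectome

__all__ = [
    "ModelParameters",
    "SimulationResult",
    "SimulationDivergedError",
    "impulse_response",
    "pulse_density",
    "simulate",
    "ei_ratio",
    "ei_ratio_curve",
]

#: samples discarded before recording (2 s at dt = 0.002 s), letting the
#: synaptic filters and the delay loop forget the all-zero initial state
DEFAULT_BURN_IN = 1000


class SimulationDivergedError(FloatingPointError):
    """Raised when the network state becomes non-finite during integration."""


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the two-population mass and of the network coupling.

    Defaults are the standard resting-state alpha operating point; ``Vd2``
    (inhibitory firing threshold, mV) and ``S_couple`` (global coupling
    gain) are the two swept parameters of the study design.
    """

    dt: float = 0.002          # sample time, s
    P: float = 480.0           # mean thalamic input pulse density, spikes/s
    noise: float = 1.0         # std of the fluctuation of P(t)
    A_e: float = 1.6           # EPSP amplitude, mV
    A_i: float = 32.0          # IPSP amplitude, mV
    a_e: float = 55.0          # EPSP shape, 1/s
    b_e: float = 605.0         # EPSP shape, 1/s
    a_i: float = 27.5          # IPSP shape, 1/s
    b_i: float = 55.0          # IPSP shape, 1/s
    g: float = 25.0            # sigmoid max-rate parameter, 1/s
    q: float = 0.34            # sigmoid steepness, 1/mV
    Vd1: float = 7.0           # excitatory firing threshold, mV
    Vd2: float = 7.0           # inhibitory firing threshold, mV (swept 6-8)
    C1: float = 32.0           # excitatory -> inhibitory coupling
    C2: float = 3.0            # inhibitory -> excitatory coupling
    S_couple: float = 1.0      # inter-mass gain (swept 0-2)
    T_delay: float = 0.002     # inter-mass conduction delay, s
    N: int = 78                # number of masses

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.b_e > self.a_e > 0 and self.b_i > self.a_i > 0):
            raise ValueError("kernel shapes require b > a > 0")
        n_delay = self.T_delay / self.dt
        if abs(n_delay - round(n_delay)) > 1e-9 or round(n_delay) < 1:
            raise ValueError("T_delay must be a positive integer multiple of dt")

    @property
    def delay_samples(self) -> int:
        return int(round(self.T_delay / self.dt))


@dataclass(frozen=True)
class SimulationResult:
    """Simulated traces: ``eeg`` holds the excitatory membrane-potential
    fluctuations (the model's EEG-like output), ``e_rate``/``i_rate`` the
    excitatory and inhibitory population pulse densities.  All are
    (n_regions, n_samples) arrays recorded after burn-in."""

    eeg: np.ndarray
    e_rate: np.ndarray
    i_rate: np.ndarray
    dt: float
    seed: int
    params: ModelParameters

    @property
    def n_regions(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


def impulse_response(
    tau: float | np.ndarray, A: float, a: float, b: float
) -> float | np.ndarray:
    """Biexponential postsynaptic kernel h(tau) = A(e^{-a tau} - e^{-b tau}).

    Zero for negative lags (causality).  Peaks at tau = ln(b/a)/(b-a).
    """
    tau = np.asarray(tau, dtype=float)
    out = np.where(tau >= 0, A * (np.exp(-a * tau) - np.exp(-b * tau)), 0.0)
    return out if out.ndim else float(out)

def pulse_density(
    Vm: float | np.ndarray, Vd: float, g: float, q: float
) -> float | np.ndarray:
    """Membrane potential to pulse density sigmoid.

    g * exp(q (Vm - Vd)) below threshold, g * (2 - exp(-q (Vm - Vd)))
    above; continuous at Vm = Vd with value g, asymptotes 0 and 2g.
    """
    x = np.asarray(Vm, dtype=float) - Vd
    out = np.where(
        x <= 0,
        g * np.exp(q * np.minimum(x, 0.0)),
        g * (2.0 - np.exp(-q * np.maximum(x, 0.0))),
    )
    return out if out.ndim else float(out)


class _SecondOrderFilter:
    """State-space realisation of the biexponential kernel.

    y'' + (a+b) y' + ab y = A (b-a) x  has impulse response exactly
    A (e^{-at} - e^{-bt}); advanced by explicit Euler.
    """

    def __init__(self, A: float, a: float, b: float, n: int):
        self.gain = A * (b - a)
        self.sum_ab = a + b
        self.prod_ab = a * b
        self.y = np.zeros(n)
        self.z = np.zeros(n)

    def step(self, x: np.ndarray, dt: float) -> np.ndarray:
        y, z = self.y, self.z
        y_new = y + dt * z
        z_new = z + dt * (self.gain * x - self.sum_ab * z - self.prod_ab * y)
        self.y, self.z = y_new, z_new
        return y_new


def simulate(
    params: ModelParameters,
    connectome: StructuralConnectome,
    n_samples: int,
    seed: int,
    burn_in: int = DEFAULT_BURN_IN,
) -> SimulationResult:
    """Integrate the coupled network and record ``n_samples`` post-burn-in.

    The per-region excitatory input is ``P(t)`` (mean ``P`` plus seeded
    Gaussian fluctuations of std ``noise``) plus ``S_couple`` times the
    structurally weighted sum of the neighbours' excitatory pulse densities
    one conduction delay earlier.  Identical (params, connectome, seed)
    reproduce the output bitwise.
    """
    if connectome.n_regions != params.N:
        raise ValueError(
            f"connectome has {connectome.n_regions} regions, params.N = {params.N}"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    n = params.N
    dt = params.dt
    rng = np.random.default_rng(seed)
    W = connectome.weights

    # three synaptic pathways per mass
    epsp_ext = _SecondOrderFilter(params.A_e, params.a_e, params.b_e, n)  # -> Ve
    ipsp_fb = _SecondOrderFilter(params.A_i, params.a_i, params.b_i, n)   # I -> Ve
    epsp_ei = _SecondOrderFilter(params.A_e, params.a_e, params.b_e, n)   # E -> Vi

    delay_buf = np.zeros((params.delay_samples, n))
    buf_pos = 0

    total = burn_in + n_samples
    eeg = np.empty((n, n_samples))
    e_rate = np.empty((n, n_samples))
    i_rate = np.empty((n, n_samples))

    Ve = np.zeros(n)
    Vi = np.zeros(n)
    for t in range(total):
        e_now = pulse_density(Ve, params.Vd1, params.g, params.q)
        i_now = pulse_density(Vi, params.Vd2, params.g, params.q)

        e_delayed = delay_buf[buf_pos].copy()
        delay_buf[buf_pos] = e_now
        buf_pos = (buf_pos + 1) % params.delay_samples

        p_t = params.P + params.noise * rng.standard_normal(n)
        exc_input = p_t + params.S_couple * (W @ e_delayed)

        Ve = epsp_ext.step(exc_input, dt) - ipsp_fb.step(params.C2 * i_now, dt)
        Vi = epsp_ei.step(params.C1 * e_now, dt)

        if not (np.isfinite(Ve).all() and np.isfinite(Vi).all()):
            bad = np.flatnonzero(~(np.isfinite(Ve) & np.isfinite(Vi)))[0]
            raise SimulationDivergedError(
                f"non-finite state at step {t} in region "
                f"{connectome.labels[bad]!r} (index {bad})"
            )

        if t >= burn_in:
            k = t - burn_in
            eeg[:, k] = Ve
            e_rate[:, k] = e_now
            i_rate[:, k] = i_now

    return SimulationResult(
        eeg=eeg, e_rate=e_rate, i_rate=i_rate, dt=dt, seed=seed, params=params
    )


def ei_ratio(result: SimulationResult) -> float:
    """Excitation-inhibition ratio E/(E+I) of one simulation.

    E and I are the time-averaged excitatory and inhibitory pulse densities
    per region; the ratio is formed per region and averaged across regions.
    """
    e = result.e_rate.mean(axis=1)
    i = result.i_rate.mean(axis=1)
    denom = e + i
    if np.any(denom == 0):
        raise ZeroDivisionError("E + I is zero; E-I ratio undefined")
    return float((e / denom).mean())


def ei_ratio_curve(
    e_means: np.ndarray, i_means: np.ndarray
) -> np.ndarray:
    """Sweep-level E-I ratios from per-model mean rates.

    Normalises the excitatory and inhibitory whole-brain mean rates to
    [0, 1] by min-max across the sweep (the display convention of the
    study's rate plots), then returns E_norm/(E_norm + I_norm) per model.
    Degenerate sweeps (constant rates across models) fall back to the raw
    rates.
    """
    e = np.asarray(e_means, dtype=float)
    i = np.asarray(i_means, dtype=float)

    def _minmax(x):
        span = x.max() - x.min()
        if span == 0:
            return x
        return (x - x.min()) / span

    e_n, i_n = _minmax(e), _minmax(i)
    denom = e_n + i_n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, e_n / denom, np.nan)
    return out
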