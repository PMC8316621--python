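"""Stochastic neural-mass network: coupled cortical-column oscillators with
per-node sigmoid gain, integrated with the Euler-Maruyama scheme."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from neurogain.connectome import NormalizedConnectome

__all__ = [
    "JRParameters",
    "GainMap",
    "NoiseSpec",
    "SimulationConfig",
    "NeuralTrace",
    "SimulationDiverged",
    "sigmoid",
    "make_gain_map",
    "simulate",
]


class SimulationDiverged(RuntimeError):
    """Raised when the integrated state becomes non-finite."""


@dataclass
class JRParameters:
    """Column-level constants (PSP amplitudes in mV, rate constants in 1/s).

    ``C4`` defaults to ``0.5 * C`` (widens the oscillatory coupling range);
    the long-range rate constant ``a_bar`` defaults to ``0.5 * a`` (slower
    apical-dendrite EPSPs).
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    a_bar: float | None = None
    C: float = 135.0
    C1: float | None = None
    C2: float | None = None
    C3: float | None = None
    C4: float | None = None
    zeta_max: float = 5.0
    nu_th: float = 6.0
    r1: float = 0.56
    r2: float = 0.56

    def __post_init__(self) -> None:
        if self.a_bar is None:
            self.a_bar = 0.5 * self.a
        if self.C1 is None:
            self.C1 = self.C
        if self.C2 is None:
            self.C2 = 0.8 * self.C
        if self.C3 is None:
            self.C3 = 0.25 * self.C
        if self.C4 is None:
            self.C4 = 0.5 * self.C
        for name in ("A", "B", "a", "b", "a_bar", "C", "C1", "C2", "C3", "C4",
                     "zeta_max", "nu_th", "r1", "r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GainMap:
    """Per-node pyramidal sigmoid slope and the global coupling scalar."""

    r0: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, dtype=float)
        if (self.r0 < 0).any():
            raise ValueError("r0 entries must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class NoiseSpec:
    mu: float = 2.0
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SimulationConfig:
    gain: GainMap
    params: JRParameters = field(default_factory=JRParameters)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    dt: float = 0.001
    duration: float = 660.0
    discard: float = 60.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.discard < self.duration:
            raise ValueError("discard must be smaller than duration")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_discard(self) -> int:
        return int(round(self.discard / self.dt))


@dataclass
class NeuralTrace:
    """EEG-like potentials (mV) and pyramidal firing rates (1/s), nodes x time."""

    nu: np.ndarray
    zeta: np.ndarray
    rate: float


def sigmoid(nu, r, params: JRParameters | None = None):
    """Population sigmoid: ``zeta_max / (1 + exp(r * (nu_th - nu)))``.

    Overflow-safe: the exponent is clamped to +-500.
    """
    if params is None:
        params = JRParameters()
    x = np.clip(np.multiply(r, params.nu_th - np.asarray(nu, dtype=float)), -500.0, 500.0)
    return params.zeta_max / (1.0 + np.exp(x))


def make_gain_map(
    n: int,
    alpha: float,
    base_r0: float,
    targets=(),
    target_r0: float | None = None,
) -> GainMap:
    """Uniform gain map at ``base_r0`` with ``targets`` raised to ``target_r0``."""
    targets = np.asarray(list(targets), dtype=int)
    r0 = np.full(n, float(base_r0))
    if targets.size:
        if target_r0 is None:
            raise ValueError("target_r0 required when targets are given")
        if targets.min() < 0 or targets.max() >= n:
            raise ValueError("target index out of range")
        if np.unique(targets).size != targets.size:
            raise ValueError("duplicate target indices")
        r0[targets] = float(target_r0)
    return GainMap(r0, alpha)


@njit(cache=True)
def _jr_step_block(  # pragma: no cover
    state, Mw, noise_block, out_nu, out_zeta, out_offset,
    dt, A, B, a, b, abar, C1, C2, C3, C4, C, alpha,
    r0, r1, r2, zmax, vth, mu, sigma, keep_from,
):
    n = Mw.shape[0]
    x0, y0, x1, y1, x2, y2, x3, y3 = (
        state[0], state[1], state[2], state[3],
        state[4], state[5], state[6], state[7],
    )
    n_steps = noise_block.shape[0]
    for t in range(n_steps):
        z = Mw @ x3
        for i in range(n):
            nu_i = C2 * x1[i] - C4 * x2[i] + C * alpha * z[i]
            e0 = r0[i] * (vth - nu_i)
            if e0 > 500.0:
                e0 = 500.0
            elif e0 < -500.0:
                e0 = -500.0
            s_pyr = zmax / (1.0 + np.exp(e0))
            e1 = r1 * (vth - C1 * x0[i])
            if e1 > 500.0:
                e1 = 500.0
            elif e1 < -500.0:
                e1 = -500.0
            s_exc = zmax / (1.0 + np.exp(e1))
            e2 = r2 * (vth - C3 * x0[i])
            if e2 > 500.0:
                e2 = 500.0
            elif e2 < -500.0:
                e2 = -500.0
            s_inh = zmax / (1.0 + np.exp(e2))

            dx0 = y0[i]
            dy0 = A * a * s_pyr - 2.0 * a * y0[i] - a * a * x0[i]
            dx1 = y1[i]
            dy1 = A * a * (mu + s_exc) - 2.0 * a * y1[i] - a * a * x1[i]
            dx2 = y2[i]
            dy2 = B * b * s_inh - 2.0 * b * y2[i] - b * b * x2[i]
            dx3 = y3[i]
            dy3 = A * abar * s_pyr - 2.0 * abar * y3[i] - abar * abar * x3[i]

            x0[i] += dt * dx0
            y0[i] += dt * dy0
            x1[i] += dt * dx1
            y1[i] += dt * dy1 + A * a * sigma * dt * noise_block[t, i]
            x2[i] += dt * dx2
            y2[i] += dt * dy2
            x3[i] += dt * dx3
            y3[i] += dt * dy3

            keep = out_offset + t - keep_from
            if keep >= 0:
                out_nu[i, keep] = nu_i
                e = r0[i] * (vth - nu_i)
                if e > 500.0:
                    e = 500.0
                elif e < -500.0:
                    e = -500.0
                out_zeta[i, keep] = zmax / (1.0 + np.exp(e))


def simulate(Mn: NormalizedConnectome, config: SimulationConfig) -> NeuralTrace:
    """Integrate the coupled-column network and return retained traces.

    The stochastic input p(t) is redrawn every step and enters the update
    like the deterministic drive, scaled by dt (the input is treated as
    piecewise constant over the 1 ms step, as in the reference
    implementation of this model family; note the effective noise power is
    therefore tied to the step size). The first ``config.discard`` seconds
    are dropped. Bit-reproducible for a fixed :class:`NoiseSpec` seed.
    """
    n = Mn.n
    if config.gain.r0.shape[0] != n:
        raise ValueError("gain map length does not match connectome size")
    p = config.params
    dt = config.dt
    n_steps = config.n_steps
    n_discard = config.n_discard
    n_keep = n_steps - n_discard

    state = np.zeros((8, n))
    out_nu = np.empty((n, n_keep), dtype=np.float32)
    out_zeta = np.empty((n, n_keep), dtype=np.float32)

    rng = np.random.default_rng(config.noise.seed)
    block = 20_000
    offset = 0
    Mw = np.ascontiguousarray(Mn.weights)
    while offset < n_steps:
        nb = min(block, n_steps - offset)
        noise = rng.standard_normal((nb, n))
        _jr_step_block(
            state, Mw, noise, out_nu, out_zeta, offset,
            dt, p.A, p.B, p.a, p.b, p.a_bar, p.C1, p.C2, p.C3, p.C4, p.C,
            config.gain.alpha, config.gain.r0, p.r1, p.r2,
            p.zeta_max, p.nu_th, config.noise.mu, config.noise.sigma,
            n_discard,
        )
        offset += nb
        if not np.isfinite(state).all():
            raise SimulationDiverged(
                f"non-finite state after {offset * dt:.1f} s "
                f"(alpha={config.gain.alpha}, max r0={config.gain.r0.max()})"
            )
    return NeuralTrace(out_nu, out_zeta, rate=1.0 / dt)
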