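"""The coupled Epileptor network model and its stochastic integrator.

Each brain region is a six-variable Epileptor: a fast discharging
subsystem (x1, y1), a sharp-wave subsystem (x2, y2) with a low-pass
filter variable g, and the slow "permittivity" variable z that gates
seizure onset and offset.  Regions are coupled diffusively through the
structural connectome in the z equation (permittivity coupling): for node
i the coupling term is ``K * Σ_j w(j→i) (x1_i − x1_j)`` over incoming
connections, applied inside the slow-timescale bracket so that a seizing
neighbour (elevated x1_j) slowly drags z_i down towards the saddle-node
at which node i's interictal state disappears.  A node's excitability is
set by its epileptogenicity x0: above the critical value (about −2.06 for
the default currents) it seizes spontaneously, below it it can only be
recruited.

Integration is stochastic Heun (predictor–corrector) with additive
Gaussian noise of standard deviation sigma·sqrt(dt) per step on the x2
and y2 equations only.  A sigma = 0 run is deterministic and
bit-reproducible for a fixed seed (the seed also fixes the small jitter
applied to the initial conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .connectome import Connectome

__all__ = [
    "CRITICAL_X0",
    "X0_EZ",
    "X0_PZ",
    "STATE_VARS",
    "EpileptorParams",
    "Trajectory",
    "IntegrationError",
    "f1",
    "f2",
    "network_rhs",
    "interictal_state",
    "simulate",
    "single_node_connectome",
    "find_critical_x0",
]

#: Critical epileptogenicity: an isolated noise-free Epileptor with
#: x0 above this value seizes spontaneously, below it stays quiet.
CRITICAL_X0 = -2.06

#: Default epileptogenicity of epileptogenic-zone / propagation-zone nodes.
X0_EZ = -1.6
X0_PZ = -2.1

STATE_VARS = ("x1", "y1", "z", "x2", "y2", "g")


class IntegrationError(RuntimeError):
    """State became non-finite during integration."""


@dataclass
class EpileptorParams:
    """Model constants and integration settings.

    Time is measured in dimensionless model units throughout (the slow
    rate ``r`` and the x2-timescale ``tau`` are per unit / in units of
    this time).  ``x0`` may be a scalar (same epileptogenicity
    everywhere) or a length-N vector.
    """

    I1: float = 3.1
    I2: float = 0.45
    r: float = 8e-5
    K: float = 0.2
    tau: float = 10.0
    sigma: float = 0.0025
    x0: float | np.ndarray = X0_PZ
    dt: float = 0.05
    duration: float = 4000.0
    warmup: float = 15.0
    stride: int = 10
    seed: int = 0
    jitter: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not 0 <= self.warmup < self.duration:
            raise ValueError(f"need duration > warmup >= 0, got {self.duration}, {self.warmup}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")

    def x0_vector(self, n: int) -> np.ndarray:
        x0 = np.asarray(self.x0, dtype=float)
        if x0.ndim == 0:
            return np.full(n, float(x0))
        if x0.shape != (n,):
            raise ValueError(f"x0 has length {x0.shape}, expected {n}")
        return x0.copy()

    @classmethod
    def for_network(
        cls,
        n: int,
        ez_nodes: list[int] | tuple[int, ...] = (),
        x0_ez: float = X0_EZ,
        x0_pz: float = X0_PZ,
        **kwargs,
    ) -> "EpileptorParams":
        """Parameters for an N-node run with the given epileptogenic zone."""
        x0 = np.full(n, x0_pz)
        x0[list(ez_nodes)] = x0_ez
        return cls(x0=x0, **kwargs)

    def replace(self, **kwargs) -> "EpileptorParams":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """A simulated network time course.

    ``states`` has shape (samples, 6, N) in the variable order
    ``STATE_VARS``; per-variable views (shape (N, samples)) are exposed as
    properties, and ``lfp`` is the field-potential proxy x2 − x1.
    """

    times: np.ndarray
    states: np.ndarray
    params: EpileptorParams
    connectome_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.states)):
            raise IntegrationError("trajectory contains non-finite values")
        dts = np.diff(self.times)
        if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0])):
            raise ValueError("times must be strictly increasing and uniformly spaced")

    def _var(self, k: int) -> np.ndarray:
        return self.states[:, k, :].T

    @property
    def x1(self) -> np.ndarray:
        return self._var(0)

    @property
    def y1(self) -> np.ndarray:
        return self._var(1)

    @property
    def z(self) -> np.ndarray:
        return self._var(2)

    @property
    def x2(self) -> np.ndarray:
        return self._var(3)

    @property
    def y2(self) -> np.ndarray:
        return self._var(4)

    @property
    def g(self) -> np.ndarray:
        return self._var(5)

    @property
    def lfp(self) -> np.ndarray:
        return self.x2 - self.x1

    @property
    def n_nodes(self) -> int:
        return self.states.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (time, node)."""
        S, _, N = self.states.shape
        rec = {
            "time": np.repeat(self.times, N),
            "node": np.tile(np.arange(N), S),
        }
        for k, name in enumerate(STATE_VARS):
            rec[name] = self.states[:, k, :].ravel()
        rec["lfp"] = rec["x2"] - rec["x1"]
        return pd.DataFrame(rec)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def f1(x1, x2, z):
    """Fast-subsystem nonlinearity: cubic ``x1^3 - 3 x1^2`` for x1 < 0,
    ``(x2 - 0.6 (z - 4)^2) x1`` for x1 >= 0 (both branches vanish at 0)."""
    x1 = np.asarray(x1, dtype=float)
    return np.where(x1 < 0, x1 * x1 * (x1 - 3.0), (np.asarray(x2) - 0.6 * (np.asarray(z) - 4.0) ** 2) * x1)


def f2(x2):
    """Sharp-wave subsystem drive: 0 below −0.25, ``6 (x2 + 0.25)`` above."""
    x2 = np.asarray(x2, dtype=float)
    return np.where(x2 < -0.25, 0.0, 6.0 * (x2 + 0.25))


def network_rhs(
    state: np.ndarray,
    params: EpileptorParams,
    C: Connectome | np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic drift of the coupled network.

    ``state`` has shape (6, N) (or (6,) for a single node).  The
    permittivity coupling for node i runs over its incoming connections,
    ``+K Σ_j w(j→i) (x1_i − x1_j)``, inside the slow bracket; it vanishes
    identically when all nodes share the same state.
    """
    state = np.asarray(state, dtype=float)
    single = state.ndim == 1
    if single:
        state = state[:, None]
    if state.shape[0] != 6:
        raise ValueError(f"state must have 6 variables per node, got shape {state.shape}")
    n = state.shape[1]
    if C is None:
        W = np.zeros((n, n))
    else:
        W = C.weights if isinstance(C, Connectome) else np.asarray(C, dtype=float)
    if W.shape != (n, n):
        raise ValueError(f"connectome has shape {W.shape}, state has {n} nodes")
    x0 = params.x0_vector(n)

    x1, y1, z, x2, y2, g = state
    coupling = params.K * (W.sum(axis=1) * x1 - W @ x1)
    out = np.empty_like(state)
    out[0] = y1 - f1(x1, x2, z) - z + params.I1
    out[1] = 1.0 - 5.0 * x1 * x1 - y1
    slow = 4.0 * (x1 - x0) - z + coupling
    out[2] = params.r * np.where(z < 0, slow - 0.1 * z**7, slow)
    out[3] = -y2 + x2 - x2**3 + params.I2 + 0.002 * g - 0.3 * (z - 3.5)
    out[4] = (-y2 + f2(x2)) / params.tau
    out[5] = -0.01 * (g - 0.1 * x1)
    return out[:, 0] if single else out


# ---------------------------------------------------------------------------
# Initial conditions: interictal vicinity
# ---------------------------------------------------------------------------

def interictal_state(params: EpileptorParams, x0_ref: float = X0_PZ) -> np.ndarray:
    """Interictal resting state of a single Epileptor, with z frozen at
    ``4 (x1* − x0_ref)`` for the reference (propagation-zone)
    epileptogenicity.  All nodes are started here (plus a small seeded
    jitter) so that healthy nodes sit on their stable branch and
    epileptogenic nodes drift into their first seizure quickly."""
    I1, I2 = params.I1, params.I2

    def fast_eq(x1):
        # x1-nullcline combined with y1* = 1 - 5 x1^2 and z = 4(x1 - x0_ref)
        return -(x1**3) - 2.0 * x1**2 + 1.0 + I1 - 4.0 * (x1 - x0_ref)

    x1s = brentq(fast_eq, -4.0, -4.0 / 3.0, xtol=1e-12)
    z0 = 4.0 * (x1s - x0_ref)
    y1s = 1.0 - 5.0 * x1s**2
    gs = 0.1 * x1s

    def x2_eq(x2):
        y2 = 0.0 if x2 < -0.25 else 6.0 * (x2 + 0.25)
        return -y2 + x2 - x2**3 + I2 + 0.002 * gs - 0.3 * (z0 - 3.5)

    x2s = brentq(x2_eq, -4.0, 4.0, xtol=1e-12)
    y2s = 0.0 if x2s < -0.25 else 6.0 * (x2s + 0.25)
    return np.array([x1s, y1s, z0, x2s, y2s, gs])


# ---------------------------------------------------------------------------
# Stochastic Heun integration
# ---------------------------------------------------------------------------

def _rhs_arrays(state, W, rowsum, x0, I1, I2, r, K, tau, out):
    """In-place drift used by the numpy integration path (state (6, N))."""
    x1, y1, z, x2, y2, g = state
    coupling = K * (rowsum * x1 - W @ x1)
    np.subtract(y1, f1(x1, x2, z), out=out[0])
    out[0] += I1 - z
    out[1] = 1.0 - 5.0 * x1 * x1 - y1
    slow = 4.0 * (x1 - x0) - z + coupling
    out[2] = r * np.where(z < 0, slow - 0.1 * z**7, slow)
    out[3] = -y2 + x2 - x2**3 + I2 + 0.002 * g - 0.3 * (z - 3.5)
    out[4] = (-y2 + f2(x2)) / tau
    out[5] = -0.01 * (g - 0.1 * x1)
    return out


def _heun_chunk_numpy(W, rowsum, x0, I1, I2, r, K, tau, sigma, dt,
                      state, eta, step0, stride, samples):
    n_sub = eta.shape[0]
    k1 = np.empty_like(state)
    k2 = np.empty_like(state)
    amp = sigma * np.sqrt(dt)
    for s in range(n_sub):
        _rhs_arrays(state, W, rowsum, x0, I1, I2, r, K, tau, k1)
        pred = state + dt * k1
        if sigma > 0:
            pred[3] += amp * eta[s, 0]
            pred[4] += amp * eta[s, 1]
        _rhs_arrays(pred, W, rowsum, x0, I1, I2, r, K, tau, k2)
        state += 0.5 * dt * (k1 + k2)
        if sigma > 0:
            state[3] += amp * eta[s, 0]
            state[4] += amp * eta[s, 1]
        gstep = step0 + s + 1
        if gstep % stride == 0:
            samples[gstep // stride] = state
    return state


try:  # optional numba acceleration; the numpy path is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _rhs_nb(state, W, rowsum, x0, I1, I2, r, K, tau, out):  # pragma: no cover
        n = state.shape[1]
        x1 = state[0]
        wx = W @ np.ascontiguousarray(x1)
        for i in range(n):
            xi = x1[i]
            y1 = state[1, i]
            z = state[2, i]
            x2 = state[3, i]
            y2 = state[4, i]
            g = state[5, i]
            if xi < 0.0:
                fone = xi * xi * (xi - 3.0)
            else:
                fone = (x2 - 0.6 * (z - 4.0) ** 2) * xi
            cpl = K * (rowsum[i] * xi - wx[i])
            slow = 4.0 * (xi - x0[i]) - z + cpl
            if z < 0.0:
                slow -= 0.1 * z**7
            ftwo = 0.0 if x2 < -0.25 else 6.0 * (x2 + 0.25)
            out[0, i] = y1 - fone - z + I1
            out[1, i] = 1.0 - 5.0 * xi * xi - y1
            out[2, i] = r * slow
            out[3, i] = -y2 + x2 - x2**3 + I2 + 0.002 * g - 0.3 * (z - 3.5)
            out[4, i] = (-y2 + ftwo) / tau
            out[5, i] = -0.01 * (g - 0.1 * xi)
        return out

    @_njit(cache=False)
    def _heun_chunk_numba(W, rowsum, x0, I1, I2, r, K, tau, sigma, dt,
                          state, eta, step0, stride, samples):  # pragma: no cover
        n_sub = eta.shape[0]
        n = state.shape[1]
        k1 = np.empty_like(state)
        k2 = np.empty_like(state)
        pred = np.empty_like(state)
        amp = sigma * np.sqrt(dt)
        for s in range(n_sub):
            _rhs_nb(state, W, rowsum, x0, I1, I2, r, K, tau, k1)
            for v in range(6):
                for i in range(n):
                    pred[v, i] = state[v, i] + dt * k1[v, i]
            if sigma > 0:
                for i in range(n):
                    pred[3, i] += amp * eta[s, 0, i]
                    pred[4, i] += amp * eta[s, 1, i]
            _rhs_nb(pred, W, rowsum, x0, I1, I2, r, K, tau, k2)
            for v in range(6):
                for i in range(n):
                    state[v, i] += 0.5 * dt * (k1[v, i] + k2[v, i])
            if sigma > 0:
                for i in range(n):
                    state[3, i] += amp * eta[s, 0, i]
                    state[4, i] += amp * eta[s, 1, i]
            gstep = step0 + s + 1
            if gstep % stride == 0:
                samples[gstep // stride] = state
        return state

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def simulate(
    C: Connectome | np.ndarray,
    params: EpileptorParams,
    use_numba: bool | None = None,
) -> Trajectory:
    """Integrate the coupled network and return the sampled trajectory.

    Initial conditions are the interictal resting state (z referenced to
    the propagation-zone epileptogenicity) with a uniform jitter of
    amplitude ``params.jitter`` drawn from ``params.seed``; the same seed
    therefore reproduces the run exactly, and a sigma = 0 run is fully
    deterministic.  Output is sampled every ``params.stride`` steps.

    Raises
    ------
    IntegrationError
        If the state blows up; the message names the model time at which
        the first non-finite value appeared.
    """
    W = C.weights if isinstance(C, Connectome) else np.asarray(C, dtype=float)
    n = W.shape[0]
    x0 = params.x0_vector(n)
    rng = np.random.default_rng(params.seed)

    base = interictal_state(params)
    state = np.repeat(base[:, None], n, axis=1)
    state += params.jitter * rng.uniform(-1.0, 1.0, size=state.shape)

    n_steps = int(round(params.duration / params.dt))
    stride = params.stride
    n_samples = n_steps // stride + 1
    samples = np.empty((n_samples, 6, n))
    samples[0] = state
    times = np.arange(n_samples) * (stride * params.dt)

    rowsum = W.sum(axis=1)
    kernel = _heun_chunk_numba if (_HAVE_NUMBA if use_numba is None else use_numba) else _heun_chunk_numpy

    chunk = 8192
    step0 = 0
    args = (params.I1, params.I2, params.r, params.K, params.tau, params.sigma, params.dt)
    while step0 < n_steps:
        n_sub = min(chunk, n_steps - step0)
        if params.sigma > 0:
            eta = rng.standard_normal((n_sub, 2, n))
        else:
            eta = np.zeros((n_sub, 2, n))
        state = kernel(W, rowsum, x0, *args, state, eta, step0, stride, samples)
        if not np.all(np.isfinite(state)):
            t_blow = (step0 + n_sub) * params.dt
            raise IntegrationError(f"integration blew up by t = {t_blow:g} model time units")
        step0 += n_sub

    cid = ""
    if isinstance(C, Connectome):
        cid = C.meta.get("id", "") or f"connectome[{n}]"
    return Trajectory(times=times, states=samples, params=params, connectome_id=cid)


def single_node_connectome() -> Connectome:
    """A one-node network (no connections): the isolated Epileptor."""
    return Connectome(np.zeros((1, 1)), labels=["node_0"], hemisphere=["R"])


# ---------------------------------------------------------------------------
# Critical epileptogenicity by bisection
# ---------------------------------------------------------------------------

def find_critical_x0(
    tolerance: float = 0.01,
    lo: float = -2.2,
    hi: float = -1.6,
    duration: float = 3000.0,
    dt: float = 0.05,
    seed: int = 0,
    **detector_kwargs,
) -> float:
    """Locate the seizing/quiet transition of an isolated Epileptor.

    Runs a noise-free single node at candidate x0 values, classifies each
    run by whether the onset detector fires on the z series within the
    horizon, and bisects between a quiet ``lo`` and a seizing ``hi``
    until the bracket half-width is at most ``tolerance``.  Returns the
    bracket midpoint.
    """
    from .detection import detect_onsets

    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    C = single_node_connectome()

    def seizes(x0_val: float) -> bool:
        params = EpileptorParams(x0=x0_val, sigma=0.0, duration=duration, dt=dt, seed=seed)
        traj = simulate(C, params)
        onsets = detect_onsets(traj.z, traj.times, warmup=params.warmup, **detector_kwargs)
        return not np.isnan(onsets[0])

    if not seizes(hi):
        raise RuntimeError(f"upper bracket x0={hi} did not seize (horizon too short?)")
    if seizes(lo):
        raise RuntimeError(f"lower bracket x0={lo} seized; bracket does not straddle the transition")
    while (hi - lo) / 2.0 > tolerance:
        mid = 0.5 * (lo + hi)
        if seizes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
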