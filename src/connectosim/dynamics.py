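"""Neuronal population dynamics on a connectome.

Three models are provided:

* :func:`simulate_meanfield` — the reduced dynamical mean-field model of a
  spiking attractor network.  Each node i carries a synaptic gating variable
  S_i (fraction of open channels, in [0, 1]) obeying the Langevin equation

      dS_i/dt = -S_i / tau_S + (1 - S_i) * gamma * H(x_i) + sigma * v_i(t)

  with input current (nA)

      x_i = w * J_N * S_i + G * J_N * sum_j C_ij S_j + I_0 + applied_i(t)

  and the population transfer function

      H(x) = (a x - b) / (1 - exp(-d (a x - b)))        [Hz]

  where C is the structural weight matrix, G the global coupling, and v_i
  i.i.d. standard Gaussian white noise.  Integration is Euler-Maruyama on a
  0.1 ms grid by default, sampled every 1 ms.

* :func:`simulate_linear_threshold` — a synchronous discrete-time
  rectified-linear population model with additive Gaussian noise.

* :func:`simulate_sigmoid` — the same with a logistic transfer and leaky
  (decaying) activity.

``calibrate_g`` locates the global coupling at which the low-firing
resting state loses stability (the "edge of the bifurcation"), which is how
the coupling of the mean-field model is pinned to a given connectome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .connectome import Connectome

__all__ = [
    "MeanFieldParams",
    "ThresholdParams",
    "SigmoidParams",
    "SimulationConfig",
    "RateTimeSeries",
    "IntegrationError",
    "CalibrationError",
    "transfer_rate",
    "synaptic_input",
    "simulate_meanfield",
    "simulate_linear_threshold",
    "simulate_sigmoid",
    "calibrate_g",
]


class IntegrationError(RuntimeError):
    """State became non-finite during integration."""


class CalibrationError(RuntimeError):
    """Coupling scan did not bracket a stability change."""


@dataclass
class MeanFieldParams:
    """Parameters of the dynamical mean-field model.

    Defaults are the standard reduced-model values: w local recurrent
    excitation (dimensionless), a/b/d input-output function (Hz/nA, Hz, s),
    gamma kinetic parameter (dimensionless), tau_s synaptic time constant
    (s), j_n synaptic coupling (nA), i_0 overall external input (nA).
    sigma is the noise amplitude and g the global coupling, both of which
    are study-dependent.  ``coupling_sign=+1`` makes the network term
    excitatory; ``-1`` flips it to inhibitory.
    """

    w: float = 0.9
    a: float = 270.0      # Hz/nA
    b: float = 108.0      # Hz
    d: float = 0.154      # s
    gamma: float = 0.641
    tau_s: float = 0.1    # s (100 ms)
    j_n: float = 0.2609   # nA
    i_0: float = 0.3      # nA
    sigma: float = 0.0
    g: float = 0.0
    n: Optional[int] = None
    coupling_sign: float = 1.0

    def validate(self) -> None:
        if self.tau_s <= 0 or self.d <= 0 or self.a <= 0:
            raise ValueError("tau_s, d and a must be positive")
        if self.sigma < 0 or self.g < 0:
            raise ValueError("sigma and g must be non-negative")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")
        if self.coupling_sign not in (1.0, -1.0):
            raise ValueError("coupling_sign must be +1 or -1")


@dataclass
class ThresholdParams:
    """Linear-threshold population model: rectified linear transfer."""

    theta: float = 1.0     # firing threshold on summed input
    gain: float = 1.0
    noise_sd: float = 0.0

    def validate(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SigmoidParams:
    """Sigmoidal population model with activity decay."""

    theta: float = 1.0
    gain: float = 1.0
    decay: float = 0.1     # lambda, per-step leak in [0, 1]
    noise_sd: float = 0.0
    r_max: float = 1.0     # saturation of the per-step drive

    def validate(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Time stepping and reproducibility settings.

    dt is the integration step and sample_interval the output grid (both
    seconds); the defaults (0.1 ms stepping, 1 ms sampling, 10 s duration)
    give exactly 10,000 samples.  ``noise_scaling="sqrt_dt"`` treats the
    noise as white on dS/dt (Euler-Maruyama, increment sigma*sqrt(dt));
    ``"per_step"`` adds sigma per step instead.
    """

    dt: float = 1e-4
    duration: float = 10.0
    sample_interval: float = 1e-3
    seed: int = 0
    initial_s: float | np.ndarray = 0.001
    clamp_s: bool = True
    noise_scaling: str = "sqrt_dt"

    def validate(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        stride = self.sample_interval / self.dt
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError("sample_interval must be an integer multiple of dt")
        n_samp = self.duration / self.sample_interval
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration must be an integer multiple of sample_interval")
        if self.noise_scaling not in ("sqrt_dt", "per_step"):
            raise ValueError("noise_scaling must be 'sqrt_dt' or 'per_step'")

    @property
    def stride(self) -> int:
        return round(self.sample_interval / self.dt)

    @property
    def n_samples(self) -> int:
        return round(self.duration / self.sample_interval)


@dataclass
class RateTimeSeries:
    """Sampled simulation output on a uniform time grid.

    ``rate`` holds per-node population firing rates in Hz (H(x_i) for the
    mean-field model, the activity itself for the discrete models); ``s``
    holds gating variables for the mean-field model and is None otherwise.
    """

    times: np.ndarray                      # (n_samples,) seconds
    rate: np.ndarray                       # (n_samples, n) Hz
    s: Optional[np.ndarray] = None         # (n_samples, n) gating in [0, 1]
    applied_current: Optional[np.ndarray] = None  # (n_samples, n) nA
    lesion_mask: Optional[np.ndarray] = None      # (n,) bool

    @property
    def n_nodes(self) -> int:
        return self.rate.shape[1]

    @property
    def n_samples(self) -> int:
        return self.rate.shape[0]

    def save_npz(self, path) -> None:
        data = {"times": self.times, "rate": self.rate}
        if self.s is not None:
            data["S"] = self.s
        if self.applied_current is not None:
            data["applied_current"] = self.applied_current
        if self.lesion_mask is not None:
            data["lesion_mask"] = self.lesion_mask
        np.savez_compressed(path, **data)

    @classmethod
    def load_npz(cls, path) -> "RateTimeSeries":
        with np.load(path) as z:
            return cls(
                times=z["times"],
                rate=z["rate"],
                s=z["S"] if "S" in z else None,
                applied_current=z["applied_current"] if "applied_current" in z else None,
                lesion_mask=z["lesion_mask"] if "lesion_mask" in z else None,
            )

    def rate_csv(self, path, node_ids=None) -> None:
        import pandas as pd

        cols = node_ids if node_ids is not None else np.arange(1, self.n_nodes + 1)
        df = pd.DataFrame(self.rate, index=self.times, columns=cols)
        df.index.name = "time_s"
        df.to_csv(path)


def transfer_rate(x, params: MeanFieldParams):
    """Population input-output function H(x), Hz for input current x in nA.

    H(x) = (a x - b) / (1 - exp(-d (a x - b))); the removable singularity at
    a x = b evaluates to 1/d.  Total on finite inputs; vector inputs map
    elementwise.
    """
    x_arr = np.asarray(x, dtype=np.float64)
    u = params.a * x_arr - params.b
    du = params.d * u
    small = np.abs(du) < 1e-8
    with np.errstate(over="ignore"):
        denom = -np.expm1(-du)
    # Second-order expansion around the singularity: u/(1-e^{-du}) ~ 1/d + u/2.
    h = np.where(small, 1.0 / params.d + u / 2.0, u / np.where(small, 1.0, denom))
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(h)
    return h


def synaptic_input(s, coupling, params: MeanFieldParams, applied=None):
    """Total input current x_i = w J_N S_i + G J_N (C S)_i + I_0 + applied_i.

    ``coupling`` may be a Connectome, a dense matrix or a scipy sparse
    matrix.  The sign of the network term follows ``params.coupling_sign``.
    """
    s = np.asarray(s, dtype=np.float64)
    c = coupling.weights if isinstance(coupling, Connectome) else coupling
    n = c.shape[0]
    if s.shape != (n,):
        raise ValueError(f"gating vector has shape {s.shape}, expected ({n},)")
    x = params.w * params.j_n * s \
        + params.coupling_sign * params.g * params.j_n * (c @ s) \
        + params.i_0
    if applied is not None:
        x = x + applied
    return x


class _StimulationSchedule:
    """Piecewise-constant applied current from a list of stimulations.

    Window boundaries are snapped once to integration-step indices
    (half-open, [ceil(t_on/dt), ceil(t_off/dt))), so activation decisions are
    integer comparisons free of float-grid drift.
    """

    def __init__(self, stimulations, n, index_of, dt):
        self.windows = []
        for stim in stimulations:
            vec = np.zeros(n)
            vec[index_of(stim.node_set)] += stim.amplitude
            j_on = math.ceil(stim.t_on / dt - 1e-9)
            j_off = math.ceil(stim.t_off / dt - 1e-9)
            self.windows.append((j_on, j_off, vec))
        self.n = n

    def __bool__(self):
        return bool(self.windows)

    def current(self, step: int) -> Optional[np.ndarray]:
        out = None
        for j_on, j_off, vec in self.windows:
            if j_on <= step < j_off:
                out = vec if out is None else out + vec
        return out


def _constant_subranges(schedule, step0: int, stride: int):
    """Split a chunk of ``stride`` steps at stimulation window boundaries.

    Yields (j_start, j_end, applied_vector) with the applied current constant
    on each sub-range; ``applied_vector`` is None where no window is active.
    """
    if not schedule:
        yield 0, stride, None
        return
    cuts = {0, stride}
    for j_on, j_off, _vec in schedule.windows:
        for j in (j_on - step0, j_off - step0):
            if 0 < j < stride:
                cuts.add(int(j))
    bounds = sorted(cuts)
    for j0, j1 in zip(bounds[:-1], bounds[1:]):
        yield j0, j1, schedule.current(step0 + j0)


def _prepare(connectome: Connectome, config: SimulationConfig, protocol):
    """Apply lesions from the protocol, build the stimulation schedule."""
    from .perturbation import Lesion, Stimulation, apply_lesion

    config.validate()
    conn = connectome
    stims = []
    if protocol is not None:
        items = protocol if isinstance(protocol, (list, tuple)) else [protocol]
        for item in items:
            if isinstance(item, Lesion):
                conn = apply_lesion(conn, item)
            elif isinstance(item, Stimulation):
                if not (0.0 <= item.t_on < item.t_off <= config.duration + 1e-12):
                    raise ValueError(
                        f"stimulation window [{item.t_on}, {item.t_off}) outside run"
                    )
                stims.append(item)
            else:
                raise TypeError(f"unsupported protocol item {type(item).__name__}")
    schedule = _StimulationSchedule(stims, conn.n_nodes, conn.index_of, config.dt)
    return conn, schedule


def _initial_state(value, n: int) -> np.ndarray:
    s0 = np.asarray(value, dtype=np.float64)
    if s0.ndim == 0:
        return np.full(n, float(s0))
    if s0.shape != (n,):
        raise ValueError(f"initial state has shape {s0.shape}, expected ({n},)")
    return s0.copy()


def _rng(seed: int) -> np.random.Generator:
    # Counter-based stream: reproducible independently of vectorization order.
    return np.random.Generator(np.random.Philox(seed))


def simulate_meanfield(
    connectome: Connectome,
    params: MeanFieldParams,
    config: SimulationConfig = None,
    protocol=None,
) -> RateTimeSeries:
    """Integrate the mean-field model with Euler-Maruyama stepping.

    The gating state starts at ``config.initial_s`` and is clamped to [0, 1]
    after every step when ``config.clamp_s`` is set.  Samples are taken at
    the end of every sampling interval (times dt*stride, 2*dt*stride, ...),
    recording S, the rate H(x) consistent with the sampled state, and the
    applied current.  Identical seed and inputs give identical output.
    """
    if config is None:
        config = SimulationConfig()
    params.validate()
    if params.n is not None and params.n != connectome.n_nodes:
        raise ValueError(
            f"params.n = {params.n} but connectome has {connectome.n_nodes} nodes"
        )
    conn, schedule = _prepare(connectome, config, protocol)
    n = conn.n_nodes
    c = sparse.csr_matrix(conn.weights)
    indptr = c.indptr.astype(np.int64)
    indices = c.indices.astype(np.int64)
    data = np.ascontiguousarray(c.data, dtype=np.float64)

    dt = config.dt
    stride = config.stride
    n_samples = config.n_samples
    s = _initial_state(config.initial_s, n)
    if config.clamp_s:
        np.clip(s, 0.0, 1.0, out=s)

    wj = params.w * params.j_n
    gj = params.coupling_sign * params.g * params.j_n
    noise_amp = params.sigma * (math.sqrt(dt) if config.noise_scaling == "sqrt_dt" else 1.0)
    rng = _rng(config.seed)

    times = np.arange(1, n_samples + 1) * stride * dt
    s_out = np.empty((n_samples, n))
    rate_out = np.empty((n_samples, n))
    applied_out = np.zeros((n_samples, n)) if schedule else None
    zeros = np.zeros(n)
    no_noise = np.empty((0, n))

    from ._kernels import meanfield_steps

    step = 0
    for k in range(n_samples):
        # Noise for the whole chunk is drawn in one call: the stream order is
        # identical to per-step draws (row-major fill of a single stream).
        noise = rng.standard_normal((stride, n)) if noise_amp > 0.0 else no_noise
        for j0, j1, app in _constant_subranges(schedule, step, stride):
            meanfield_steps(
                s, indptr, indices, data,
                zeros if app is None else app,
                noise[j0:j1] if noise_amp > 0.0 else no_noise,
                j1 - j0,
                wj, gj, params.i_0,
                params.a, params.b, params.d, params.gamma, params.tau_s,
                dt, noise_amp, config.clamp_s,
            )
        step += stride
        if not np.isfinite(s).all():
            raise IntegrationError(f"non-finite state at step {step}")
        # Rate consistent with the sampled state and the current at the sample time.
        app = schedule.current(step) if schedule else None
        x = wj * s + gj * (c @ s) + params.i_0
        if app is not None:
            x = x + app
            applied_out[k] = app
        s_out[k] = s
        rate_out[k] = transfer_rate(x, params)

    return RateTimeSeries(
        times=times,
        rate=rate_out,
        s=s_out,
        applied_current=applied_out,
        lesion_mask=None if conn.lesion_mask is None else conn.lesion_mask.copy(),
    )


def meanfield_window_means(
    connectome: Connectome,
    params: MeanFieldParams,
    config: SimulationConfig,
    runs: Sequence[tuple],
    window: tuple | None = None,
    protocol=None,
):
    """Windowed per-node mean rates for an ensemble of mean-field runs.

    ``runs`` is a sequence of (sigma, seed) pairs; all runs share the
    connectome, protocol and remaining parameters and are integrated
    simultaneously (each with its own noise stream, bit-identical to running
    it alone through :func:`simulate_meanfield`).  Only the running mean of
    the rate over ``window`` (default: the last 2 s) is accumulated, so
    arbitrarily many runs fit in memory.

    Returns ``(means, lesion_mask)`` where ``means`` has shape
    ``(len(runs), n)`` in Hz.
    """
    if config is None:
        config = SimulationConfig()
    params.validate()
    conn, schedule = _prepare(connectome, config, protocol)
    n = conn.n_nodes
    m = len(runs)
    if m == 0:
        raise ValueError("runs must be non-empty")
    c = sparse.csr_matrix(conn.weights)
    indptr = c.indptr.astype(np.int64)
    indices = c.indices.astype(np.int64)
    data = np.ascontiguousarray(c.data, dtype=np.float64)

    dt = config.dt
    stride = config.stride
    n_samples = config.n_samples
    t_end = dt * stride * n_samples
    if window is None:
        window = (max(dt * stride, t_end - 2.0), t_end)

    s = np.empty((n, m))
    s0 = _initial_state(config.initial_s, n)
    for j in range(m):
        s[:, j] = s0
    if config.clamp_s:
        np.clip(s, 0.0, 1.0, out=s)

    wj = params.w * params.j_n
    gj = params.coupling_sign * params.g * params.j_n
    amp_scale = math.sqrt(dt) if config.noise_scaling == "sqrt_dt" else 1.0
    noise_amps = np.array([float(sig) * amp_scale for sig, _ in runs])
    rngs = [_rng(int(seed)) for _, seed in runs]
    any_noise = bool((noise_amps > 0).any())

    zeros = np.zeros(n)
    no_noise = np.empty((0, n, m))
    sums = np.zeros((m, n))
    count = 0

    from ._kernels import meanfield_steps_batch

    step = 0
    noise = np.empty((stride, n, m)) if any_noise else no_noise
    for k in range(n_samples):
        if any_noise:
            for j in range(m):
                if noise_amps[j] > 0.0:
                    noise[:, :, j] = rngs[j].standard_normal((stride, n))
        for j0, j1, app in _constant_subranges(schedule, step, stride):
            meanfield_steps_batch(
                s, indptr, indices, data,
                zeros if app is None else app,
                noise[j0:j1] if any_noise else no_noise,
                j1 - j0,
                wj, gj, params.i_0,
                params.a, params.b, params.d, params.gamma, params.tau_s,
                dt, noise_amps, config.clamp_s,
            )
        step += stride
        t_samp = step * dt
        if not np.isfinite(s).all():
            raise IntegrationError(f"non-finite state at step {step}")
        if window[0] - 1e-12 <= t_samp <= window[1] + 1e-12:
            app = schedule.current(step) if schedule else None
            x = wj * s + gj * (c @ s) + params.i_0
            if app is not None:
                x = x + app[:, None]
            sums += transfer_rate(x, params).T
            count += 1

    if count == 0:
        raise ValueError(f"window {window} contains no samples")
    means = sums / count
    mask = None if conn.lesion_mask is None else conn.lesion_mask.copy()
    return means, mask


def _simulate_discrete(connectome, config, protocol, update):
    """Shared driver for the synchronous discrete-time models."""
    if config is None:
        config = SimulationConfig()
    conn, schedule = _prepare(connectome, config, protocol)
    n = conn.n_nodes
    c = sparse.csr_matrix(conn.weights)
    stride = config.stride
    n_samples = config.n_samples
    dt = config.dt

    r = _initial_state(config.initial_s, n)
    rng = _rng(config.seed)
    times = np.arange(1, n_samples + 1) * stride * dt
    rate_out = np.empty((n_samples, n))
    applied_out = np.zeros((n_samples, n)) if schedule else None

    step = 0
    for k in range(n_samples):
        for _ in range(stride):
            app = schedule.current(step) if schedule else None
            total_in = c @ r
            if app is not None:
                total_in = total_in + app
            r = update(r, total_in, rng)
            step += 1
        if not np.isfinite(r).all():
            raise IntegrationError(f"non-finite state at step {step}")
        if schedule:
            app = schedule.current(step)
            if app is not None:
                applied_out[k] = app
        rate_out[k] = r

    return RateTimeSeries(
        times=times,
        rate=rate_out,
        s=None,
        applied_current=applied_out,
        lesion_mask=None if conn.lesion_mask is None else conn.lesion_mask.copy(),
    )


def simulate_linear_threshold(
    connectome: Connectome,
    params: ThresholdParams,
    config: SimulationConfig = None,
    protocol=None,
) -> RateTimeSeries:
    """Synchronous linear-threshold model.

    Each population sums its inputs and fires only when the sum crosses the
    threshold theta:  a_i(t+1) = gain * max(0, sum_j C_ij a_j + applied_i +
    eps_i - theta), with eps_i Gaussian of sd ``noise_sd``.
    """
    params.validate()

    def update(r, total_in, rng):
        if params.noise_sd > 0.0:
            total_in = total_in + params.noise_sd * rng.standard_normal(r.shape[0])
        return params.gain * np.maximum(0.0, total_in - params.theta)

    return _simulate_discrete(connectome, config, protocol, update)


def simulate_sigmoid(
    connectome: Connectome,
    params: SigmoidParams,
    config: SimulationConfig = None,
    protocol=None,
) -> RateTimeSeries:
    """Sigmoidal model with decay.

    r_i(t+1) = (1 - decay) * r_i(t) + r_max * logistic(gain * (input_i -
    theta)) + noise.
    """
    params.validate()

    def update(r, total_in, rng):
        from scipy.special import expit

        drive = params.r_max * expit(params.gain * (total_in - params.theta))
        out = (1.0 - params.decay) * r + drive
        if params.noise_sd > 0.0:
            out = out + params.noise_sd * rng.standard_normal(r.shape[0])
        return out

    return _simulate_discrete(connectome, config, protocol, update)


def calibrate_g(
    connectome: Connectome,
    params: MeanFieldParams,
    scan_range: tuple[float, float] = (0.1, 20.0),
    tol: float = 0.02,
    r_low: float = 20.0,
    duration: float = 4.0,
    margin: float = 0.0,
    dt: float = 1e-4,
    initial_s: float = 0.001,
) -> float:
    """Locate the coupling at the edge of the low-state bifurcation.

    With noise off, the network is started in the near-zero gating state and
    run for ``duration`` seconds at a trial coupling G.  The low state is
    deemed destabilized when the node-mean firing rate averaged over the
    last 20% of the run exceeds ``r_low`` (default 20 Hz, between the
    low-firing branch at a few Hz and the high-firing branch above 150 Hz).
    Bisection brackets the smallest destabilizing G to within ``tol`` and
    returns the bracket midpoint minus ``margin``.

    Raises :class:`CalibrationError` when the scan range does not bracket a
    stability change (e.g. an uncoupled network never destabilizes).
    """
    lo, hi = scan_range
    if not lo < hi:
        raise ValueError("scan_range must be increasing")
    base = replace(params, sigma=0.0, n=None)
    sample = max(dt, duration / 400.0)
    # Snap the sampling interval to a multiple of dt.
    sample = round(sample / dt) * dt
    n_keep = max(1, round(0.2 * duration / sample))

    def destabilized(g: float) -> bool:
        p = replace(base, g=g)
        cfg = SimulationConfig(
            dt=dt, duration=duration, sample_interval=sample,
            seed=0, initial_s=initial_s,
        )
        series = simulate_meanfield(connectome, p, cfg)
        return float(series.rate[-n_keep:].mean()) > r_low

    lo_unstable = destabilized(lo)
    if lo_unstable or not destabilized(hi):
        side = "already unstable at the lower" if lo_unstable else "still stable at the upper"
        raise CalibrationError(
            f"no bifurcation in range ({lo}, {hi}): low state {side} end"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if destabilized(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) - margin
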