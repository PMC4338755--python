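"""Compiled inner loops for the mean-field integrator.

The Euler-Maruyama stepping of the gating state is the only hot spot of the
package (10^5 steps over ~10^3 nodes per run); it is JIT-compiled with
numba operating directly on the CSR arrays of the coupling matrix.  Noise
is pre-drawn outside the kernel so the random stream is defined by the
numpy Philox generator alone.
"""

from __future__ import annotations

import numba as nb
import numpy as np

__all__ = ["meanfield_steps", "meanfield_steps_batch"]


@nb.njit(cache=True, fastmath=False)
def meanfield_steps(
    s,            # (n,) gating state, updated in place
    indptr,       # CSR structure of the coupling matrix
    indices,
    data,
    app,          # (n,) applied current, nA (zeros when none)
    noise,        # (n_steps, n) pre-drawn standard normals, or (0, 0)
    n_steps,
    wj, gj, i0,   # w*J_N, sign*G*J_N, I_0
    a, b, d, gamma, tau_s,
    dt, noise_amp,
    clamp,
):
    n = s.shape[0]
    y = np.empty(n)
    use_noise = noise_amp > 0.0
    for step in range(n_steps):
        for i in range(n):
            acc = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                acc += data[k] * s[indices[k]]
            y[i] = acc
        for i in range(n):
            x = wj * s[i] + gj * y[i] + i0 + app[i]
            u = a * x - b
            du = d * u
            if abs(du) < 1e-8:
                h = 1.0 / d + 0.5 * u
            else:
                h = u / (1.0 - np.exp(-du))
            si = s[i] + dt * (-s[i] / tau_s + (1.0 - s[i]) * gamma * h)
            if use_noise:
                si += noise_amp * noise[step, i]
            if clamp:
                if si < 0.0:
                    si = 0.0
                elif si > 1.0:
                    si = 1.0
            s[i] = si


@nb.njit(cache=True, fastmath=False)
def meanfield_steps_batch(
    s,            # (n, m) gating state for m independent runs, updated in place
    indptr,
    indices,
    data,
    app,          # (n,) applied current shared across runs
    noise,        # (n_steps, n, m) pre-drawn standard normals, or (0, 0, 0)
    n_steps,
    wj, gj, i0,
    a, b, d, gamma, tau_s,
    dt, noise_amps,  # (m,) per-run noise increments
    clamp,
):
    """Batched Euler-Maruyama stepping.

    Column j evolves exactly as a single run with noise amplitude
    ``noise_amps[j]`` and noise stream ``noise[..., j]`` — the accumulation
    order of the coupling sum per column matches the single-run kernel, so
    results are bit-identical to running each column alone.
    """
    n, m = s.shape
    y = np.empty((n, m))
    any_noise = False
    for j in range(m):
        if noise_amps[j] > 0.0:
            any_noise = True
    for step in range(n_steps):
        for i in range(n):
            for j in range(m):
                y[i, j] = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                w = data[k]
                col = indices[k]
                for j in range(m):
                    y[i, j] += w * s[col, j]
        for i in range(n):
            base = i0 + app[i]
            for j in range(m):
                x = wj * s[i, j] + gj * y[i, j] + base
                u = a * x - b
                du = d * u
                if abs(du) < 1e-8:
                    h = 1.0 / d + 0.5 * u
                else:
                    h = u / (1.0 - np.exp(-du))
                si = s[i, j] + dt * (-s[i, j] / tau_s + (1.0 - s[i, j]) * gamma * h)
                if any_noise and noise_amps[j] > 0.0:
                    si += noise_amps[j] * noise[step, i, j]
                if clamp:
                    if si < 0.0:
                        si = 0.0
                    elif si > 1.0:
                        si = 1.0
                s[i, j] = si
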