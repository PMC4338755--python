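"""Summary statistics over simulated rate time series.

The central quantity is the windowed mean firing rate per node — by
convention the arithmetic mean of the sampled rates over the last 2 s of a
run, where the dynamics has settled around its attractor — and totals of it
over all (non-lesioned) nodes.  Differences of such summaries between
conditions (healthy vs lesioned, post- vs pre-stimulation) are the per-node
ΔFR maps; the time for a perturbed network to re-enter a band around its
baseline gives the return-to-baseline latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome
from .dynamics import (
    MeanFieldParams,
    RateTimeSeries,
    SimulationConfig,
    meanfield_window_means,
    simulate_meanfield,
)

__all__ = [
    "FiringSummary",
    "mean_firing",
    "delta_fr",
    "return_to_baseline",
    "noise_scan",
    "NOT_RETURNED",
]

#: Sentinel return value when activity never re-enters the baseline band.
NOT_RETURNED = float("nan")


@dataclass(frozen=True)
class FiringSummary:
    """Windowed per-node mean firing.

    ``total`` sums the per-node means over non-masked nodes.  ``node_avg_mean``
    and ``node_avg_sd`` are the mean and standard deviation over the window
    of the node-averaged rate trace (used as the baseline band for
    return-to-baseline detection).
    """

    per_node_mean: np.ndarray    # (n,) Hz
    window: tuple                # (t_start, t_end) seconds
    total: float                 # Hz, over non-masked nodes
    lesion_mask: Optional[np.ndarray] = None
    node_avg_mean: float = 0.0
    node_avg_sd: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.per_node_mean.shape[0]

    def to_frame(self, connectome: Connectome | None = None) -> pd.DataFrame:
        n = self.n_nodes
        mask = self.lesion_mask if self.lesion_mask is not None else np.zeros(n, bool)
        df = pd.DataFrame(
            {
                "node_id": connectome.node_ids if connectome is not None else np.arange(1, n + 1),
                "region": connectome.region_labels if connectome is not None else [""] * n,
                "mean_rate_hz": self.per_node_mean,
                "masked": mask,
            }
        )
        return df


def _window_slice(series: RateTimeSeries, window):
    t0, t1 = window
    times = series.times
    lo = times[0] - 1e-12
    if t0 < lo or t1 > times[-1] + 1e-12 or t0 > t1:
        raise ValueError(
            f"window ({t0}, {t1}) outside series span ({times[0]}, {times[-1]})"
        )
    sel = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)  # inclusive endpoints
    return sel


def mean_firing(series: RateTimeSeries, window: tuple | None = None) -> FiringSummary:
    """Per-node mean rate over a window (default: the last 2 s).

    Samples at both window endpoints are included.  Lesioned nodes are
    reported but excluded from ``total``.
    """
    if window is None:
        window = (max(series.times[0], series.times[-1] - 2.0), series.times[-1])
    sel = _window_slice(series, window)
    block = series.rate[sel]
    per_node = block.mean(axis=0)
    mask = series.lesion_mask
    active = per_node if mask is None else per_node[~mask]
    node_avg = block.mean(axis=1) if mask is None else block[:, ~mask].mean(axis=1)
    return FiringSummary(
        per_node_mean=per_node,
        window=(float(window[0]), float(window[1])),
        total=float(active.sum()),
        lesion_mask=None if mask is None else mask.copy(),
        node_avg_mean=float(node_avg.mean()),
        node_avg_sd=float(node_avg.std()),
    )


def delta_fr(summary_a: FiringSummary, summary_b: FiringSummary) -> np.ndarray:
    """Per-node firing-rate difference a - b (Hz).

    Nodes masked in either summary are still reported; combine the masks to
    flag them.  Totals are linear: sum(delta over jointly unmasked nodes)
    equals total_a - total_b when the masks agree.
    """
    if summary_a.n_nodes != summary_b.n_nodes:
        raise ValueError(
            f"summaries have {summary_a.n_nodes} vs {summary_b.n_nodes} nodes"
        )
    return summary_a.per_node_mean - summary_b.per_node_mean


def return_to_baseline(
    series: RateTimeSeries,
    t_offset: float,
    baseline_summary: FiringSummary,
    k_sd: float = 2.0,
    hold_ms: float = 20.0,
) -> float:
    """Latency (ms) for node-averaged activity to re-enter the baseline band.

    The band is ``baseline mean ± k_sd * baseline sd`` of the node-averaged
    rate (from a matched unperturbed run).  The return time is the first
    sample t >= t_offset from which the trace stays inside the band for
    ``hold_ms`` consecutive milliseconds; the result is t - t_offset in ms,
    or :data:`NOT_RETURNED` (NaN) when no such time exists in the series.
    """
    times = series.times
    if not -1e-12 <= t_offset <= times[-1] + 1e-12:
        raise ValueError(f"t_offset {t_offset} outside series span")
    mask = series.lesion_mask
    trace = series.rate.mean(axis=1) if mask is None else series.rate[:, ~mask].mean(axis=1)
    band = k_sd * baseline_summary.node_avg_sd
    inside = np.abs(trace - baseline_summary.node_avg_mean) <= band

    start = int(np.searchsorted(times, t_offset - 1e-12))
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    hold_n = max(1, int(round(hold_ms / 1000.0 / dt)))

    ok = inside[start:]
    m = ok.size
    if m == 0:
        return NOT_RETURNED
    # Length of the run of in-band samples starting at each index; a return
    # needs hold_n consecutive samples (truncated at the series end, so a
    # trace that stays in band through the last sample counts as returned).
    runlen = np.zeros(m + 1, dtype=np.int64)
    for i in range(m - 1, -1, -1):
        runlen[i] = runlen[i + 1] + 1 if ok[i] else 0
    need = np.minimum(hold_n, m - np.arange(m))
    hits = np.nonzero(runlen[:m] >= need)[0]
    if hits.size == 0:
        return NOT_RETURNED
    return float((times[start + hits[0]] - t_offset) * 1000.0)


def noise_scan(
    connectome: Connectome,
    params: MeanFieldParams,
    sigmas: Sequence[float],
    config: SimulationConfig | None = None,
    protocol=None,
    seeds: Sequence[int] | None = None,
    window: tuple | None = None,
) -> pd.DataFrame:
    """Total windowed mean firing as a function of noise amplitude.

    Runs one simulation per (sigma, seed) pair and tabulates the total mean
    firing over the analysis window (default last 2 s).  Returns a DataFrame
    with columns ``sigma``, ``seed``, ``total_rate_hz``.
    """
    if not len(sigmas):
        raise ValueError("sigma list must be non-empty")
    if config is None:
        config = SimulationConfig()
    if seeds is None:
        seeds = [config.seed]
    runs = [(float(sigma), int(seed)) for sigma in sigmas for seed in seeds]
    means, mask = meanfield_window_means(
        connectome, params, config, runs, window=window, protocol=protocol
    )
    active = means if mask is None else means[:, ~mask]
    totals = active.sum(axis=1)
    return pd.DataFrame(
        {
            "sigma": [r[0] for r in runs],
            "seed": [r[1] for r in runs],
            "total_rate_hz": totals,
        }
    )
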