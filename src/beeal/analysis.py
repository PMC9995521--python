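"""Odour-response analysis: spike density functions, glomerular PN
activity, the EAG proxy, monotonicity, and sweep summaries.

The spike density function (SDF) is the spike train convolved with a
Gaussian kernel of width ``sigma`` (default 100 ms),

    SDF(t) = 1/(sigma sqrt(2 pi)) * sum_spikes exp(-(t - t_spike)^2 / (2 sigma^2)),

in Hz for times in seconds.  Time averages of the SDF over a window are
computed in closed form through the Gaussian CDF rather than on a grid.

The monotonicity of a response-versus-concentration profile x over the
tested range (10^-7 .. 10^-1) is

    m = (x(10^-1) - max(x)) / mean(x),

which is <= 0, and 0 exactly when the response is maximal at the highest
concentration (a monotonically growing response).  The EAG proxy is the
total ORN spike count across all receptor types during the stimulus
window, optionally baseline-subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .network import Network
from .odours import OdourProfile, sample_random_odour
from .simulate import SimulationRecord, StimulusProtocol, default_protocol, run

__all__ = [
    "DegenerateResponseError",
    "sdf",
    "windowed_mean_sdf",
    "mean_pn_activity",
    "monotonicity",
    "eag_proxy",
    "ResponseSummary",
    "concentration_sweep",
    "width_monotonicity_correlation",
    "pn_heatmap",
    "DEFAULT_GRID",
]

SDF_SIGMA = 0.100  # s
DEFAULT_GRID = np.logspace(-7, -1, 7)


class DegenerateResponseError(ValueError):
    """Raised when a response curve is identically zero (undefined m)."""


def sdf(spike_times, t_grid, kernel_sigma: float = SDF_SIGMA) -> np.ndarray:
    """Gaussian-kernel spike density function evaluated on `t_grid` (Hz)."""
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    ts = np.asarray(spike_times, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if ts.size == 0:
        return np.zeros_like(t)
    norm = 1.0 / (kernel_sigma * np.sqrt(2.0 * np.pi))
    d = t[None, :] - ts[:, None]
    return norm * np.exp(-(d**2) / (2.0 * kernel_sigma**2)).sum(axis=0)


def windowed_mean_sdf(spike_times, window: tuple[float, float],
                      kernel_sigma: float = SDF_SIGMA) -> float:
    """Exact time-average of the SDF over `window` (Hz).

    Uses the closed-form integral of the Gaussian kernel, so spikes just
    outside the window contribute their overlapping kernel mass.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    ts = np.asarray(spike_times, dtype=float)
    if ts.size == 0:
        return 0.0
    mass = ndtr((t1 - ts) / kernel_sigma) - ndtr((t0 - ts) / kernel_sigma)
    return float(mass.sum() / (t1 - t0))


def mean_pn_activity(
    record: SimulationRecord,
    window: tuple[float, float] | None = None,
    kernel_sigma: float = SDF_SIGMA,
) -> np.ndarray:
    """Per-glomerulus time-averaged PN SDF (Hz per PN) over `window`
    (default: the protocol's stimulus-on interval)."""
    if window is None:
        window = record.protocol.stimulus_window()
    n_glo = int(record.glomeruli.max()) + 1
    n_pn_per_glo = record.n_pn // n_glo
    t, ids = record.spikes("pn")
    glo = record.glomeruli[ids]
    out = np.zeros(n_glo)
    for g in range(n_glo):
        out[g] = windowed_mean_sdf(t[glo == g], window, kernel_sigma)
    return out / n_pn_per_glo


def monotonicity(x) -> float:
    """m = (x at highest concentration − max x) / mean x for a response
    profile `x` ordered by ascending concentration."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need responses at >= 2 concentrations")
    mean = x.mean()
    if mean <= 0:
        raise DegenerateResponseError("response profile has non-positive mean")
    return float((x[-1] - x.max()) / mean)


def eag_proxy(
    record: SimulationRecord,
    window: tuple[float, float] | None = None,
    *,
    baseline_subtract: bool = False,
) -> float:
    """Total ORN spike count across all receptor types within `window`
    (default: the stimulus-on interval) — the model's EAG stand-in.

    With `baseline_subtract`, the expected spontaneous count (rate in the
    pre-stimulus window times the window length) is removed, mirroring an
    evoked EAG deflection.
    """
    if window is None:
        window = record.protocol.stimulus_window()
    t0, t1 = window
    if t0 < 0 or t1 > record.duration:
        raise ValueError("window outside the simulated interval")
    count = float(record.spike_count("orn", window))
    if baseline_subtract:
        b0, b1 = record.protocol.baseline_window()
        if b1 > b0:
            rate = record.spike_count("orn", (b0, b1)) / (b1 - b0)
            count -= rate * (t1 - t0)
    return count


@dataclass
class ResponseSummary:
    """Concentration-sweep result: response curves and monotonicity."""

    grid: np.ndarray                 # tested concentrations, ascending
    curves: pd.DataFrame             # odour x concentration, Hz
    monotonicity: pd.Series          # m per odour
    mode: str                        # 'max' or 'mean' across glomeruli
    sigmas: pd.Series | None = None  # odour profile widths, if known


def _derived_seed(base: int | None, *key: int) -> int:
    return int(np.random.SeedSequence(
        [0 if base is None else int(base), *key]).generate_state(1)[0] % (2**31))


def concentration_sweep(
    odours: Sequence[OdourProfile],
    network: Network,
    grid=DEFAULT_GRID,
    mode: str = "max",
    *,
    noise_seed: int | None = None,
    pre: float = 0.3,
    stimulus: float = 3.0,
    post: float = 0.2,
    hill_n: float = 1.0,
    progress: Callable[[str], None] | None = None,
) -> ResponseSummary:
    """Simulate every odour at every concentration of `grid` and summarise.

    For each run the stimulus-window-averaged PN SDF per glomerulus is
    reduced across glomeruli by `mode` ('max': strongest-responding
    glomerulus; 'mean': average over all), giving the response profile x
    whose monotonicity m is reported.  Each (odour, concentration) run gets
    a distinct noise stream derived from `noise_seed`.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must be sorted ascending")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    reduce = np.max if mode == "max" else np.mean
    curves = np.zeros((len(odours), grid.size))
    for i, od in enumerate(odours):
        if progress is not None:
            progress(od.name)
        for j, c in enumerate(grid):
            proto = default_protocol([od], {od.name: c}, pre=pre,
                                     stimulus=stimulus, post=post,
                                     hill_n=hill_n)
            rec = run(network, proto,
                      noise_seed=_derived_seed(noise_seed, i, j))
            curves[i, j] = reduce(mean_pn_activity(rec))
    names = [od.name for od in odours]
    curves_df = pd.DataFrame(curves, index=names, columns=grid)
    m = pd.Series({name: monotonicity(curves[i])
                   for i, name in enumerate(names)}, name="m")
    sigmas = pd.Series({od.name: od.sigma for od in odours}, name="sigma")
    return ResponseSummary(grid=grid, curves=curves_df, monotonicity=m,
                           mode=mode, sigmas=sigmas)


def width_monotonicity_correlation(
    network: Network,
    n_odours: int = 30,
    seed: int | None = None,
    grid=DEFAULT_GRID,
    mode: str = "max",
    **sweep_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Rank (Spearman) correlation between odour profile width sigma and
    monotonicity m over `n_odours` freshly sampled odours.

    Returns (rho, table of sigma and m per odour).  Broader profiles recruit
    more glomeruli and hence more lateral inhibition at high concentration,
    so rho is expected to be negative.
    """
    if n_odours < 10:
        raise ValueError("need at least 10 odours for a meaningful correlation")
    rng = np.random.default_rng(seed)
    odours = [sample_random_odour(rng, network.spec.n_glo, name=f"rand_{i:03d}")
              for i in range(n_odours)]
    summary = concentration_sweep(odours, network, grid, mode,
                                  noise_seed=_derived_seed(seed, 1),
                                  **sweep_kwargs)
    table = pd.DataFrame({"sigma": summary.sigmas, "m": summary.monotonicity})
    if np.ptp(table["sigma"].to_numpy()) == 0:
        raise ValueError("constant predictor: all odours share one sigma")
    if np.ptp(table["m"].to_numpy()) == 0:
        # e.g. every odour monotonic on a very small network: rho undefined
        return float("nan"), table
    rho = float(stats.spearmanr(table["sigma"], table["m"]).statistic)
    return rho, table


def pn_heatmap(
    records: Mapping[str, SimulationRecord],
    kernel_sigma: float = SDF_SIGMA,
) -> pd.DataFrame:
    """Condition x glomerulus matrix of stimulus-window mean PN activity
    (Hz per PN) — the model's glomerular response map."""
    rows = {name: mean_pn_activity(rec, kernel_sigma=kernel_sigma)
            for name, rec in records.items()}
    n_glo = {v.size for v in rows.values()}
    if len(n_glo) != 1:
        raise ValueError("records come from networks of different sizes")
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"glo_{g:03d}" for g in range(n_glo.pop())])
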