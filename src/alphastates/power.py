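"""Trial-resolved network alpha power and state activation.

Implements the two neural covariates of the behavioral model: P_t
(network-level alpha power in a 500-ms single-taper sliding window,
log-transformed and z-scored within subject) and A_t (whether the
network state is on at any sample of the same window).  Both live on a
40-ms step grid and are aligned to stimulus onsets over the analysis
window from -500 ms to +250 ms.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

__all__ = [
    "NetworkPower",
    "sliding_alpha_power",
    "network_power",
    "activation_indicator",
    "standardize_power",
    "align_to_trials",
]


@dataclasses.dataclass
class NetworkPower:
    """Trial x timepoint neural covariates for one network state.

    ``P`` is raw (positive) window power until ``standardize_power`` is
    applied across the cohort; ``A`` is binary.  ``times`` is the trial-
    relative grid in seconds (first element -0.5; the last grid point
    that fits the 40-ms step is reported explicitly rather than
    assumed).
    """

    P: np.ndarray
    A: np.ndarray
    times: np.ndarray
    trial_index: np.ndarray  # row index into the source trial table
    n_dropped: int = 0

    def activation_counts(self, state: int | str = 0) -> pd.DataFrame:
        """Per-timepoint counts of state-on vs state-off trials."""
        rows = [
            {
                "time": t,
                "state": state,
                "n_A0": int(np.sum(self.A[:, j] == 0)),
                "n_A1": int(np.sum(self.A[:, j] == 1)),
            }
            for j, t in enumerate(self.times)
        ]
        return pd.DataFrame(rows)


def _grid(n_samples: int, fs: float, step_s: float):
    step = int(round(step_s * fs))
    if step < 1:
        raise ValueError("step smaller than one sample")
    return np.arange(0, n_samples, step), step


def sliding_alpha_power(
    ts,
    alpha_cf: float,
    window_s: float = 0.5,
    step_s: float = 0.04,
    halfbw: float = 3.0,
):
    """Single-taper sliding-window power at the individual alpha peak.

    A 500-ms window centered at each grid point is multiplied by the
    first Slepian taper (time-halfbandwidth = halfbw * window_s = 1.5,
    i.e. +/-3 Hz smoothing) and Fourier transformed; power is the
    squared magnitude at the grid frequency nearest ``alpha_cf`` (2 Hz
    spacing for 0.5-s windows, so the readout is within 1 Hz of the
    target, well inside the smoothing bandwidth).  Windows overlapping
    the recording edges are NaN.

    Returns ``(center_samples, power)`` with power of shape
    parcels x n_centers.
    """
    data, fs = ts.data, ts.fs
    n_parcels, n_samples = data.shape
    nwin = int(round(window_s * fs))
    if nwin > n_samples:
        raise ValueError("window longer than the recording")
    if alpha_cf + halfbw >= fs / 2:
        raise ValueError("alpha_cf + halfbw must be below Nyquist")
    centers, _ = _grid(n_samples, fs, step_s)
    half = nwin // 2
    offs = np.arange(nwin) - half
    valid = (centers + offs[0] >= 0) & (centers + offs[-1] < n_samples)
    taper = dpss(nwin, halfbw * window_s)
    fgrid = np.fft.rfftfreq(nwin, 1.0 / fs)
    bin_idx = int(np.argmin(np.abs(fgrid - alpha_cf)))
    # single-bin DFT: dot with the tapered complex exponential
    kernel = taper * np.exp(-2j * np.pi * bin_idx * np.arange(nwin) / nwin)
    power = np.full((n_parcels, centers.size), np.nan)
    cidx = centers[valid][:, None] + offs[None, :]
    for p in range(n_parcels):
        coef = data[p][cidx] @ kernel
        power[p, valid] = np.abs(coef) ** 2
    return centers, power


def network_power(parcel_powers: np.ndarray, nodes) -> np.ndarray:
    """Average parcel power over the critical nodes (NaN-propagating)."""
    nodes = np.asarray(nodes, int)
    if nodes.size == 0:
        raise ValueError("critical node set is empty")
    return np.asarray(parcel_powers, float)[nodes].mean(axis=0)


def activation_indicator(
    viterbi: np.ndarray,
    state: int,
    fs: float,
    window_s: float = 0.5,
    step_s: float = 0.04,
) -> np.ndarray:
    """Any-on indicator of ``state`` over the sliding windows.

    Uses the same centered windows and step grid as the power
    estimator; a window clipped by the recording edge is evaluated on
    its in-bounds part.
    """
    viterbi = np.asarray(viterbi)
    n = viterbi.size
    centers, _ = _grid(n, fs, step_s)
    half = int(round(window_s * fs)) // 2
    on = np.concatenate([[0], np.cumsum(viterbi == state)])
    lo = np.clip(centers - half, 0, n)
    hi = np.clip(centers + half + 1, 0, n)
    return (on[hi] - on[lo] > 0).astype(int)


def standardize_power(P: np.ndarray, groups) -> np.ndarray:
    """Natural log then z-score within each group (subject).

    Raises on non-positive power (log undefined) naming the first
    offending entry, and on degenerate (constant) power within a group.
    NaN entries are ignored for the group statistics and stay NaN.
    """
    P = np.asarray(P, float)
    groups = np.asarray(groups)
    bad = np.flatnonzero(np.ravel(P <= 0))
    if bad.size:
        raise ValueError(f"non-positive power at flat index {bad[0]}; "
                         "cannot log-transform")
    out = np.log(P)
    for g in np.unique(groups):
        sel = groups == g
        vals = out[sel]
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant power within group {g!r}; "
                             "z-score undefined")
        out[sel] = (vals - mu) / sd
    return out


def align_to_trials(
    power: np.ndarray,
    A: np.ndarray,
    centers: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    window: tuple[float, float] = (-0.5, 0.25),
    step_s: float = 0.04,
    drop_warn_fraction: float = 0.1,
) -> NetworkPower:
    """Extract trial x timepoint covariate matrices.

    ``power`` and ``A`` are grid series from ``sliding_alpha_power`` /
    ``activation_indicator`` (``centers`` is their shared sample grid).
    The trial-relative time axis starts at ``window[0]`` and advances
    in ``step_s`` steps up to the last point <= ``window[1]`` (with the
    defaults: 19 points, -0.50 .. +0.22 s).  Trials whose windows reach
    outside the valid grid are dropped and counted; dropping more than
    ``drop_warn_fraction`` of trials escalates the warning.
    """
    power = np.asarray(power, float)
    A = np.asarray(A)
    centers = np.asarray(centers, int)
    onsets = np.asarray(onsets, int)
    step = int(round(step_s * fs))
    n_rel = int(np.floor((window[1] - window[0]) / step_s + 1e-9)) + 1
    rel = np.round(window[0] * fs).astype(int) + step * np.arange(n_rel)
    times = rel / fs
    grid_start = centers[0]
    kept, P_rows, A_rows = [], [], []
    for i, onset in enumerate(onsets):
        want = onset + rel
        gi = np.round((want - grid_start) / step).astype(int)  # nearest grid
        if gi[0] < 0 or gi[-1] >= centers.size:
            continue
        p_row = power[gi]
        if np.any(np.isnan(p_row)):
            continue
        kept.append(i)
        P_rows.append(p_row)
        A_rows.append(A[gi])
    n_dropped = onsets.size - len(kept)
    if n_dropped:
        msg = f"dropped {n_dropped}/{onsets.size} trials outside the power grid"
        if n_dropped > drop_warn_fraction * onsets.size:
            msg += " (exceeds the run-report escalation threshold)"
        warnings.warn(msg)
    if not kept:
        raise ValueError("no trial fits inside the power grid")
    return NetworkPower(
        P=np.stack(P_rows),
        A=np.stack(A_rows),
        times=times,
        trial_index=np.asarray(kept),
        n_dropped=n_dropped,
    )
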