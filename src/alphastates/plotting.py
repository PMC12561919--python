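"""Matplotlib views of the two result objects."""

from __future__ import annotations

import numpy as np


def plot_evoked_states(times, evoked, ax=None, labels=None):
    """Baseline-corrected evoked state probabilities, one line per state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    evoked = np.asarray(evoked)
    for k in range(evoked.shape[0]):
        name = labels[k] if labels else f"state {k}"
        ax.plot(times, evoked[k], label=name)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel(r"$\Delta$ state probability")
    ax.legend(frameon=False)
    return ax


def plot_beta_timecourse(beta_df, terms=("d_prime_A0", "d_prime_A1"), ax=None):
    """Contrast estimates over time with +/-1 SE bands.

    ``beta_df`` is the long-format output of ``beta_timecourse``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for term in terms:
        sub = beta_df[beta_df["term"] == term].sort_values("time_s")
        t = sub["time_s"].to_numpy()
        est = sub["estimate"].to_numpy()
        se = sub["se"].to_numpy()
        ax.plot(t, est, label=term)
        ax.fill_between(t, est - se, est + se, alpha=0.25)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("contrast estimate (probit units)")
    ax.legend(frameon=False)
    return ax
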