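"""Quick-look plots for simulated runs and training sessions."""

from __future__ import annotations

import numpy as np


def plot_channels(truth, optics_series, ax=None):
    """Ground-truth concentrations and the two photodiode channels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax[0].plot(truth.time_s, truth.c_skin, label="c_skin", lw=0.8)
    ax[0].plot(truth.time_s, truth.c_brain, label="c_brain", lw=1.2)
    ax[0].set_ylabel("ΔHb (a.u.)")
    ax[0].legend(loc="upper left", fontsize=8)
    ax[1].plot(optics_series.time_s, optics_series.I_1cm, label="I 1 cm", lw=0.8)
    ax[1].plot(optics_series.time_s, optics_series.I_3cm, label="I 3 cm", lw=0.8)
    ax[1].set_xlabel("time (s)")
    ax[1].set_ylabel("intensity")
    ax[1].legend(loc="upper left", fontsize=8)
    return ax


def plot_session_scores(logs, ax=None):
    """Per-set scores across one or more training days."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    if not isinstance(logs, (list, tuple)):
        logs = [logs]
    scores = [s for log in logs for s in log.scores]
    ax.plot(np.arange(len(scores)), scores, "o-", ms=3)
    ax.axhline(50, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("set")
    ax.set_ylabel("score")
    ax.set_ylim(-2, 102)
    return ax
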