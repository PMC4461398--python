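"""Optional static figures: the (k, tau) activity landscape with the fate boundary."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FATE_DIED
from .threshold import BoundaryClassifier


def landscape(fits: pd.DataFrame, boundary: BoundaryClassifier, ax=None):
    """Scatter of cells in (log10 k, tau) with the analytic fate boundary.

    Dying cells are drawn as filled dots, survivors as crosses; the boundary
    ``tau = theta/(2k) + t0_bar`` separates them.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = fits[~fits.get("discarded", pd.Series(False, index=fits.index)).astype(bool)]
    died = ok["fate"] == FATE_DIED
    log_k = np.log10(ok["k"].to_numpy(float))
    tau = ok["tau"].to_numpy(float)
    ax.scatter(log_k[~died], tau[~died], marker="x", s=18, c="tab:blue", label="survived")
    ax.scatter(log_k[died], tau[died], marker="o", s=12, c="black", label="died")
    kk = np.logspace(log_k.min(), log_k.max(), 200)
    ax.plot(np.log10(kk), boundary.theta / (2 * kk) + boundary.t0_bar,
            c="red", label="fate boundary")
    ax.set_ylim(0, max(tau.max() * 1.05, 100))
    ax.set_xlabel("log10 k (a.u. min$^{-2}$)")
    ax.set_ylabel("tau (min)")
    ax.legend(frameon=False, fontsize=8)
    return ax
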