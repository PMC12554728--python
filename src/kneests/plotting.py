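"""Optional matplotlib figures: SPM panels and mean +/- SD curve overlays.

matplotlib is imported lazily so the analysis stack works without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spm import SPMResult


def plot_spm_comparison(result: SPMResult, mean_a: np.ndarray,
                        sd_a: np.ndarray, mean_b: np.ndarray,
                        sd_b: np.ndarray, path: str | Path,
                        labels: tuple[str, str] = ("protocol I",
                                                   "protocol II"),
                        variable: str = "", units: str = "") -> Path:
    """Two-panel SPM figure: t-curve with the dashed critical threshold and
    shaded significant intervals on top, mean +/- SD waveforms below."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nodes = np.arange(len(result.t_curve))
    fig, (ax_t, ax_c) = plt.subplots(2, 1, figsize=(6, 6), sharex=True,
                                     height_ratios=[1, 1.2])
    finite_t = np.where(np.isfinite(result.t_curve), result.t_curve, 0.0)
    ax_t.plot(nodes, finite_t, color="black", lw=1.2)
    for sign in (1.0, -1.0):
        ax_t.axhline(sign * result.critical_threshold, color="red",
                     ls="--", lw=1.0)
    for cluster in result.clusters:
        ax_t.axvspan(cluster.start, cluster.end, color="0.8", zorder=0)
        ax_c.axvspan(cluster.start, cluster.end, color="0.9", zorder=0)
    ax_t.set_ylabel("SPM{t}")
    ax_t.set_title(f"{variable}  (t* = {result.critical_threshold:.2f}, "
                   f"FWHM = {result.fwhm:.1f})".strip())

    for mean, sd, color, label in ((mean_a, sd_a, "tab:red", labels[0]),
                                   (mean_b, sd_b, "tab:blue", labels[1])):
        ax_c.plot(nodes, mean, color=color, lw=1.4, label=label)
        ax_c.fill_between(nodes, mean - sd, mean + sd, color=color,
                          alpha=0.2, lw=0)
    ax_c.set_xlabel("STS cycle (%)")
    ax_c.set_ylabel(units or "value")
    ax_c.legend(frameon=False, fontsize=9)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
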