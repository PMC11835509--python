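"""Trajectory plots of per-cycle metrics across scenarios."""

from __future__ import annotations

import pandas as pd

METRIC_LABELS = {
    "gain": "Genetic gain (trait units)",
    "variance": "Genetic variance",
    "he": "Expected heterozygosity",
    "n_fixed": "QTLs with favorable allele fixed",
    "n_lost": "QTLs with favorable allele lost",
    "accuracy": "Progeny-mean prediction accuracy",
}


def plot_trajectories(results: dict[str, "pd.DataFrame"], metric: str, ax=None):
    """Plot run-averaged metric trajectories for several labelled scenarios.

    ``results`` maps a scenario label to an aggregate metrics table (as
    produced by :func:`tetracross.run_experiment`, with ``cycle`` and
    ``<metric>_mean`` columns).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    col = f"{metric}_mean"
    for label, agg in results.items():
        if col not in agg.columns:
            raise KeyError(f"aggregate table for {label!r} lacks column {col!r}")
        ax.plot(agg["cycle"], agg[col], marker="o", markersize=3, label=label)
    ax.set_xlabel("Breeding cycle")
    ax.set_ylabel(METRIC_LABELS.get(metric, metric))
    ax.legend(frameon=False, fontsize=8)
    return ax
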