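"""Figure helpers: growth curves and growth-rate curves."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .models import AnchoredParams, GrowthSeries, predict, rate

__all__ = ["plot_growth", "plot_rates"]


def plot_growth(
    curves: Mapping[str, AnchoredParams],
    path: str | Path,
    series: Sequence[GrowthSeries] | GrowthSeries | None = None,
    t_span: tuple[float, float] = (9.0, 82.0),
) -> Path:
    """Observed points (optional) with fitted growth curves overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.linspace(t_span[0], t_span[1], 400)
    if isinstance(series, GrowthSeries):
        series = [series]
    for s in series or []:
        ax.plot(s.times, s.weights, "o", ms=4, label=f"observed {s.label}".strip())
    for name, p in curves.items():
        ax.plot(t, predict(p, t), label=name)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("tumor weight (g)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_rates(
    curves: Mapping[str, AnchoredParams],
    path: str | Path,
    t_span: tuple[float, float] = (9.0, 82.0),
) -> Path:
    """Growth-rate curves dP/dt for one or more fitted models/arms."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.linspace(max(t_span[0], 1e-3), t_span[1], 400)
    for name, p in curves.items():
        ax.plot(t, rate(p, t), label=name)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("growth rate (g/day)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
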