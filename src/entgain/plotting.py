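"""Gain-curve plots (optional; requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .evaluation import GainCurve


def plot_curves(
    curves: Sequence[GainCurve], path: str | Path, title: str = ""
) -> None:
    """Plot PPV / sensitivity / similarity against the weight w2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    markers = {"ppv": "o", "sensitivity": "s", "similarity": "^"}
    for c in curves:
        ws = [w for w, _ in c.points]
        ax.plot(ws, list(c.values), marker=markers.get(c.metric, "o"), label=c.metric)
    ax.set_xlabel("biological-information weight $w_2$")
    ax.set_ylabel("normalized value" if curves and curves[0].normalized else "value")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
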