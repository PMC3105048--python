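"""Figure rendering for accuracy curves (subject-count and window sweeps)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import AccuracyCurve

__all__ = ["plot_curves"]


def plot_curves(
    curves: Mapping[object, AccuracyCurve],
    path: str | Path,
    title: str = "",
    reference_rt_ms: float | None = None,
) -> Path:
    """Mean accuracy +- SD versus the swept parameter, one line per curve.

    If a reference reaction time is given (window sweeps), it is drawn as a
    dashed vertical line: predictions left of it beat the overt response.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for key, curve in curves.items():
        label = curve.method if isinstance(key, str) else f"n={key}"
        ax.plot(curve.x, curve.mean, marker="o", ms=3, label=label)
        ax.fill_between(
            curve.x, curve.mean - curve.sd, curve.mean + curve.sd, alpha=0.2
        )
        xname = curve.x_name
    ax.axhline(0.5, color="gray", lw=0.8, ls=":")
    if reference_rt_ms is not None:
        ax.axvline(reference_rt_ms, color="k", ls="--", lw=1, label="mean RT")
    ax.set_xlabel(xname.replace("_", " "))
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0.35, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
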