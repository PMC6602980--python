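"""Optional plot export: Poincaré scatter with fitted ellipse, SD1/SD2 trends."""

from __future__ import annotations

from pathlib import Path

from .poincare import PoincareDescriptors, PoincarePairs, ellipse_geometry
from .streaming import SlidingWindowTrace


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_poincare(
    pairs: PoincarePairs, desc: PoincareDescriptors, path: str | Path
) -> None:
    """Scatter HR(t) vs HR(t+1) with the SD1/SD2 ellipse and identity line."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs.x, pairs.y, s=6, alpha=0.5, label=f"{len(pairs)} pairs")
    outline = ellipse_geometry(desc).outline()
    ax.plot(outline[:, 0], outline[:, 1], "r-", lw=1.5,
            label=f"SD1={desc.sd1:.2f}, SD2={desc.sd2:.2f}")
    lo = min(pairs.x.min(), pairs.y.min())
    hi = max(pairs.x.max(), pairs.y.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8, label="identity")
    ax.set_xlabel("HR(t) [bpm]")
    ax.set_ylabel("HR(t+1) [bpm]")
    ax.set_aspect("equal")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trace(trace: SlidingWindowTrace, path: str | Path) -> None:
    """SD1 and SD2 against window end time."""
    plt = _axes()
    frame = trace.to_frame()
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(frame["t_end_s"], frame["sd1_bpm"], label="SD1")
    ax.plot(frame["t_end_s"], frame["sd2_bpm"], label="SD2")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("dispersion [bpm]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
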