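"""GRM spectrum and MD diagram plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_grm_spectrum", "plot_md_diagram"]


def plot_grm_spectrum(spectrum: dict[int, int], path, units: str = "monomer units") -> None:
    """Bar plot of repeat-period frequencies."""
    fig, ax = plt.subplots(figsize=(8, 3))
    periods = sorted(spectrum)
    ax.bar(periods, [spectrum[p] for p in periods], width=0.8, color="#3465a4")
    ax.set_xlabel(f"period ({units})")
    ax.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_md_diagram(md_points, path) -> None:
    """Scatter of enumeration index against MD period."""
    xs = [p.enumeration_index for p in md_points if p.period is not None]
    ys = [p.period for p in md_points if p.period is not None]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(xs, ys, s=2, color="#cc0000", alpha=0.5, linewidths=0)
    ax.set_xlabel("monomer enumeration")
    ax.set_ylabel("period (monomer units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
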