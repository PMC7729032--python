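"""Woods plots and difference plots.

A Woods plot draws each peptide as a horizontal bar spanning its residue
interval at the height of its mean deuterated fraction; overlaying two
states (blue = alone, red = in complex, by default) reveals protection as
bars dropping in the complex state. For two-replicate conditions the error
bars show both measured values; with three or more they show mean ± sd.

A difference plot draws delta deuterated fraction per peptide around a zero
line, highlights peptides passing the Welch test, and shades the called
residue intervals.

Vector output is deterministic: identical inputs give identical SVG bytes
(timestamps are stripped and the SVG hash salt is fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.rcParams["svg.hashsalt"] = "hdxdelta"

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["PlotSpec", "woods_plot", "difference_plot", "save_figure"]

DEFAULT_STATE_COLORS = ("#1f77d0", "#d62728")  # blue = alone, red = in complex
SIGNIFICANT_COLOR = "#8c510a"  # brown, as difference-plot highlight
NEUTRAL_COLOR = "#b0b0b0"
REGION_COLOR = "#f7c8d8"  # pink region box


@dataclass
class PlotSpec:
    """What to render and where.

    ``highlight_intervals`` are 1-based inclusive residue intervals shaded
    as boxes (used for called regions). ``out_path`` with an .svg or .png
    suffix selects the format; ``None`` keeps the figure in memory.
    """

    exposure: float
    states: tuple[str, ...] | None = None
    colors: dict[str, str] = field(default_factory=dict)
    highlight_intervals: tuple[tuple[int, int], ...] = ()
    out_path: str | Path | None = None
    title: str = ""
    figsize: tuple[float, float] = (9.0, 3.2)


def save_figure(fig, out_path) -> Path:
    """Save with deterministic bytes (no embedded creation date)."""
    out_path = Path(out_path)
    fig.savefig(out_path, metadata={"Date": None} if out_path.suffix == ".svg" else None)
    return out_path


def _state_color(spec: PlotSpec, state: str, i: int) -> str:
    return spec.colors.get(state, DEFAULT_STATE_COLORS[i % len(DEFAULT_STATE_COLORS)])


def woods_plot(summaries: pd.DataFrame, spec: PlotSpec):
    """Render a Woods plot of per-peptide deuterated fraction.

    Returns the matplotlib Figure (saved to ``spec.out_path`` if given).
    Bars of each state live in one LineCollection gid-tagged
    ``"bars:<state>"`` so they can be introspected or restyled.
    """
    data = summaries[summaries["exposure"] == spec.exposure]
    states = spec.states or tuple(dict.fromkeys(data["state"]))
    data = data[data["state"].isin(states)]
    if data.empty:
        raise ValueError(
            f"no summaries at exposure {spec.exposure} s for states {states}"
        )
    fig, ax = plt.subplots(figsize=spec.figsize)
    for i, state in enumerate(states):
        sub = data[data["state"] == state]
        color = _state_color(spec, state, i)
        segments = [
            [(r.start, r.mean_D), (r.end, r.mean_D)] for r in sub.itertuples()
        ]
        coll = ax.add_collection(
            matplotlib.collections.LineCollection(
                segments, colors=color, linewidths=2.2, label=state
            )
        )
        coll.set_gid(f"bars:{state}")
        # error bars at peptide midpoints: both raw values for n = 2, ±sd otherwise
        xs, lo, hi = [], [], []
        for r in sub.itertuples():
            xs.append((r.start + r.end) / 2)
            if r.n == 2:
                lo.append(min(r.replicate_D))
                hi.append(max(r.replicate_D))
            else:
                lo.append(r.mean_D - r.sd_D)
                hi.append(r.mean_D + r.sd_D)
        err = ax.vlines(xs, lo, hi, colors=color, linewidths=0.8, alpha=0.7)
        err.set_gid(f"errorbars:{state}")
    for a, b in spec.highlight_intervals:
        ax.axvspan(a - 0.5, b + 0.5, color=REGION_COLOR, zorder=0).set_gid("region")
    ax.set_xlim(0, data["end"].max() + 1)
    lo_y = min(-0.05, float(data["mean_D"].min()) - 0.05)
    hi_y = max(1.05, float(data["mean_D"].max()) + 0.05)
    ax.set_ylim(lo_y, hi_y)
    ax.set_xlabel("residue")
    ax.set_ylabel("deuterated fraction")
    ax.set_title(spec.title or f"exposure {spec.exposure:g} s")
    ax.legend(loc="lower right", fontsize=8)
    if spec.out_path:
        save_figure(fig, spec.out_path)
    return fig


def difference_plot(differentials: pd.DataFrame, spec: PlotSpec):
    """Render a difference plot of delta deuterated fraction.

    Significant peptides are drawn in the highlight colour (gid
    ``"diff:significant"``), the rest in grey (gid ``"diff:nonsignificant"``);
    ``spec.highlight_intervals`` (e.g. called regions) appear as shaded
    boxes. Returns the Figure.
    """
    data = differentials[differentials["exposure"] == spec.exposure]
    if data.empty:
        raise ValueError(f"no differentials at exposure {spec.exposure} s")
    fig, ax = plt.subplots(figsize=spec.figsize)
    for a, b in spec.highlight_intervals:
        ax.axvspan(a - 0.5, b + 0.5, color=REGION_COLOR, zorder=0).set_gid("region")
    ax.axhline(0.0, color="black", linewidth=0.8)
    for label, mask, color in (
        ("nonsignificant", ~data["significant"], NEUTRAL_COLOR),
        ("significant", data["significant"], SIGNIFICANT_COLOR),
    ):
        sub = data[mask]
        segments = [
            [(r.start, r.delta_D), (r.end, r.delta_D)] for r in sub.itertuples()
        ]
        coll = ax.add_collection(
            matplotlib.collections.LineCollection(
                segments, colors=color, linewidths=2.2, label=label
            )
        )
        coll.set_gid(f"diff:{label}")
        xs = [(r.start + r.end) / 2 for r in sub.itertuples()]
        err = ax.vlines(
            xs,
            (sub["delta_D"] - sub["se_delta"]).to_numpy(),
            (sub["delta_D"] + sub["se_delta"]).to_numpy(),
            colors=color,
            linewidths=0.8,
            alpha=0.7,
        )
        err.set_gid(f"differr:{label}")
    ax.set_xlim(0, data["end"].max() + 1)
    span = max(0.2, float(np.abs(data["delta_D"]).max()) + 0.1)
    ax.set_ylim(-span, span)
    ax.set_xlabel("residue")
    ax.set_ylabel("Δ deuterated fraction")
    ax.set_title(spec.title or f"exposure {spec.exposure:g} s")
    ax.legend(loc="lower right", fontsize=8)
    if spec.out_path:
        save_figure(fig, spec.out_path)
    return fig
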