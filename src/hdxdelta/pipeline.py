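"""End-to-end orchestration: simulate/load -> quantify -> compare -> call -> plot.

One :class:`RunConfig` drives a full reproducible run. All randomness flows
from a single seed; the analysis path itself is deterministic given its
inputs. The run manifest records input checksums, parameters, package
version and the per-stage counts, so any result file can be traced back to
exactly one configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as hio
from .diffstats import compare_states
from .plots import PlotSpec, difference_plot, woods_plot
from .regions import call_regions, coverage_stats, residue_support
from .simulate import GroundTruth, SimulationConfig, generate_dataset
from .uptake import summarize_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("hdxdelta")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or
    ``input_csv`` (a state-data CSV, optionally validated against ``fasta``)
    provides the measurements.
    """

    out_dir: str | Path
    state_a: str
    state_b: str
    simulation: SimulationConfig | None = None
    input_csv: str | Path | None = None
    fasta: str | Path | None = None
    alpha: float = 0.05
    correction: str | None = None
    min_abs_delta: float = 0.0
    exposures: tuple[float, ...] | None = None  # None: analyse all labelled
    min_support: int = 1
    min_exposures: int = 1
    merge_gap: int = 2
    residue_offset: int = 0
    plot_exposure: float | None = None
    plot_format: str = "svg"
    seed: int | None = None  # overrides simulation.seed
    qc: hio.QCThresholds | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_csv is None):
            raise ValueError(
                "exactly one of simulation / input_csv must be given"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.state_a == self.state_b:
            raise ValueError("the two compared states must differ")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("qc") is not None:
            d["qc"] = hio.QCThresholds(**d["qc"])
        if d.get("exposures") is not None:
            d["exposures"] = tuple(d["exposures"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, float] = {}
    truth: GroundTruth | None = None

    # -- acquire -----------------------------------------------------------
    stage = "simulate" if config.simulation else "load"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim.seed = config.seed
            data, truth = generate_dataset(sim)
            hio.write_state_data(data, out / "data.csv")
            truth.to_json(out / "truth.json")
            residue_offset = config.residue_offset or sim.residue_offset
            protein_length = len(sim.protein_sequence)
        else:
            sequences = hio.read_fasta(config.fasta) if config.fasta else None
            data = hio.read_state_data(config.input_csv, sequences=sequences)
            residue_offset = config.residue_offset
            protein_length = int(data["end"].max())
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc
    counts["rows_read"] = len(data)

    if config.qc is not None:
        try:
            data, removed = hio.apply_qc_filter(data, config.qc)
        except Exception as exc:
            raise PipelineError(f"[qc] {exc}") from exc
        counts["rows_removed_qc"] = sum(removed.values())

    # -- quantify ----------------------------------------------------------
    try:
        summary = summarize_table(data)
        if config.exposures is not None:
            summary = summary[summary["exposure"].isin(config.exposures)]
        hio.write_summary(summary, out / "summary.csv")
    except Exception as exc:
        raise PipelineError(f"[summarize] {exc}") from exc
    counts["peptides"] = summary.groupby(["protein", "start", "end"]).ngroups
    cov, red = coverage_stats(
        summary[["start", "end"]].drop_duplicates(), protein_length
    )
    counts["coverage"] = round(cov, 4)
    counts["redundancy"] = round(red, 2)

    # -- compare -----------------------------------------------------------
    try:
        present = set(summary["state"])
        for s in (config.state_a, config.state_b):
            if s not in present:
                raise ValueError(
                    f"state {s!r} not in data (states: {sorted(present)})"
                )
        diff = compare_states(
            summary[summary["state"] == config.state_a],
            summary[summary["state"] == config.state_b],
            alpha=config.alpha,
            min_abs_delta=config.min_abs_delta,
            correction=config.correction,
        )
        hio.write_differentials(diff, out / "differential.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[compare] {exc}") from exc
    counts["tested"] = len(diff)
    counts["significant"] = int(diff["significant"].sum())

    # -- call regions ------------------------------------------------------
    try:
        profile = residue_support(diff, protein_length)
        regions = call_regions(
            profile,
            min_support=config.min_support,
            min_exposures=config.min_exposures,
            merge_gap=config.merge_gap,
            residue_offset=residue_offset,
        )
        hio.write_regions(regions, out / "regions.tsv")
    except Exception as exc:
        raise PipelineError(f"[regions] {exc}") from exc
    counts["regions"] = len(regions)

    # -- plot --------------------------------------------------------------
    try:
        exposure = config.plot_exposure
        if exposure is None:
            exposure = float(sorted(diff["exposure"].unique())[0])
        boxes = tuple(
            (r.start - residue_offset, r.end - residue_offset) for r in regions
        )
        fmt = config.plot_format
        woods_path = out / f"woods.{fmt}"
        diff_path = out / f"difference.{fmt}"
        fig = woods_plot(
            summary,
            PlotSpec(
                exposure=exposure,
                states=(config.state_b, config.state_a),
                out_path=woods_path,
            ),
        )
        import matplotlib.pyplot as plt

        plt.close(fig)
        fig = difference_plot(
            diff,
            PlotSpec(
                exposure=exposure,
                highlight_intervals=boxes,
                out_path=diff_path,
            ),
        )
        plt.close(fig)
    except Exception as exc:
        raise PipelineError(f"[plot] {exc}") from exc

    artifacts = {
        "summary": out / "summary.csv",
        "differential": out / "differential.csv",
        "regions": out / "regions.tsv",
        "woods_plot": woods_path,
        "difference_plot": diff_path,
    }
    manifest = {
        "version": __version__,
        "seed": config.simulation.seed if config.simulation else config.seed,
        "parameters": {
            "state_a": config.state_a,
            "state_b": config.state_b,
            "alpha": config.alpha,
            "correction": config.correction,
            "min_abs_delta": config.min_abs_delta,
            "min_support": config.min_support,
            "min_exposures": config.min_exposures,
            "merge_gap": config.merge_gap,
            "residue_offset": residue_offset,
        },
        "counts": counts,
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in ([config.input_csv, config.fasta] if config.input_csv else [])
            if p
        },
    }
    if config.simulation is not None:
        manifest["inputs"] = {
            "data.csv": _sha256(out / "data.csv"),
            "truth.json": _sha256(out / "truth.json"),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for name, value in counts.items():
        logger.info("%s: %s", name, value)
    return manifest
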