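"""Readers and writers for the formats the pipeline touches.

The interchange format is a "state data" CSV modelled on the peptide-level
exports of HDX processing software: one row per centroid-mass observation,
identified by protein, state, peptide coordinates, exposure and replicate.
Exposure carries two sentinel values — 0 for the undeuterated control and
-1 for the 24 h out-exchange control. Comma-separated, UTF-8, dot decimal,
mandatory header, masses written at full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .constants import OUT_EXCHANGE_EXPOSURE, UNDEUTERATED_EXPOSURE

__all__ = [
    "StateDataError",
    "STATE_DATA_COLUMNS",
    "read_state_data",
    "write_state_data",
    "validate_state_data",
    "read_fasta",
    "QCThresholds",
    "apply_qc_filter",
    "write_regions",
    "read_regions",
    "write_summary",
    "read_summary",
    "write_differentials",
    "read_differentials",
]

logger = logging.getLogger("hdxdelta")

STATE_DATA_COLUMNS = [
    "protein",
    "state",
    "start",
    "end",
    "sequence",
    "exposure",
    "replicate",
    "centroid_mass",
]

#: Optional identification-level columns the QC filter understands.
QC_COLUMNS = ["intensity", "products_per_aa", "mass_error_ppm"]


class StateDataError(ValueError):
    """A state-data table violates the format or its invariants."""


def validate_state_data(
    df: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    min_replicates: int = 2,
) -> None:
    """Check every table invariant, reporting all violations with row numbers.

    Row numbers refer to data rows of the CSV file (header = line 1).
    """
    problems: list[str] = []
    missing = [c for c in STATE_DATA_COLUMNS if c not in df.columns]
    if missing:
        raise StateDataError(f"missing required columns: {', '.join(missing)}")

    def _rows(mask) -> str:
        return ", ".join(str(i + 2) for i in df.index[mask][:10])

    bad = df["start"] > df["end"]
    if bad.any():
        problems.append(f"start > end at rows {_rows(bad)}")
    bad = df["sequence"].str.len() != (df["end"] - df["start"] + 1)
    if bad.any():
        problems.append(
            f"sequence length does not match coordinates at rows {_rows(bad)}"
        )
    bad = df["replicate"] < 1
    if bad.any():
        problems.append(f"replicate must be a positive integer at rows {_rows(bad)}")

    if sequences is not None:
        for idx, row in df.drop_duplicates(
            ["protein", "start", "end", "sequence"]
        ).iterrows():
            parent = sequences.get(row["protein"])
            if parent is None:
                problems.append(
                    f"row {idx + 2}: protein {row['protein']!r} not in FASTA"
                )
                continue
            expected = parent[row["start"] - 1 : row["end"]]
            if expected != row["sequence"]:
                problems.append(
                    f"row {idx + 2}: peptide {row['sequence']} disagrees with "
                    f"protein {row['protein']} at positions "
                    f"{row['start']}-{row['end']} (expected {expected})"
                )

    key = ["protein", "start", "end", "sequence"]
    per_peptide = df.groupby(key)["exposure"]
    for name, exposures in per_peptide:
        values = set(exposures)
        label = f"{name[0]} {name[1]}-{name[2]}"
        if UNDEUTERATED_EXPOSURE not in values:
            problems.append(f"peptide {label}: no undeuterated (exposure 0) row")
        if OUT_EXCHANGE_EXPOSURE not in values:
            problems.append(f"peptide {label}: no out-exchange (exposure -1) row")

    labelled = df[df["exposure"] > 0]
    counts = labelled.groupby(key + ["state", "exposure"])["replicate"].nunique()
    low = counts[counts < min_replicates]
    for name in low.index[:10]:
        problems.append(
            f"peptide {name[0]} {name[1]}-{name[2]} state {name[4]} at "
            f"{name[5]} s has {low[name]} replicate(s), "
            f"need >= {min_replicates}"
        )

    if problems:
        raise StateDataError(
            "state-data validation failed:\n  " + "\n  ".join(problems)
        )


def read_state_data(
    path,
    sequences: dict[str, str] | None = None,
    validate: bool = True,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Read and (by default) validate a state-data CSV."""
    df = pd.read_csv(path)
    missing = [c for c in STATE_DATA_COLUMNS if c not in df.columns]
    if missing:
        raise StateDataError(
            f"{path}: missing required columns: {', '.join(missing)}"
        )
    df = df.astype(
        {
            "protein": str,
            "state": str,
            "start": int,
            "end": int,
            "sequence": str,
            "exposure": float,
            "replicate": int,
            "centroid_mass": float,
        }
    )
    if validate:
        validate_state_data(df, sequences=sequences, min_replicates=min_replicates)
    return df


def write_state_data(df: pd.DataFrame, path) -> None:
    """Write a state-data CSV (full-precision masses, deterministic bytes)."""
    cols = STATE_DATA_COLUMNS + [c for c in QC_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``.

    Rejects empty files and duplicate record ids.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


@dataclass(frozen=True)
class QCThresholds:
    """Peptide-identification acceptance thresholds.

    ``None`` disables a criterion. Defaults mirror common identification
    acceptance settings: minimum precursor intensity 1000–3000, at least
    0.25–0.3 fragmentation products per residue, and at most 10 ppm parent
    mass error.
    """

    min_intensity: float | None = None
    min_products_per_aa: float | None = None
    max_mass_error_ppm: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_intensity", "min_products_per_aa", "max_mass_error_ppm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


def apply_qc_filter(
    df: pd.DataFrame, thresholds: QCThresholds
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop identification rows failing any configured threshold.

    Returns the filtered table and per-criterion removal counts (a row
    failing several criteria is counted under each). Rows lacking a value in
    a configured column are kept (the criterion cannot be evaluated).
    """
    removed = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    checks = [
        ("min_intensity", "intensity", lambda col, v: col < v),
        ("min_products_per_aa", "products_per_aa", lambda col, v: col < v),
        ("max_mass_error_ppm", "mass_error_ppm", lambda col, v: col.abs() > v),
    ]
    for name, column, fails in checks:
        threshold = getattr(thresholds, name)
        if threshold is None:
            continue
        if column not in df.columns:
            raise ValueError(
                f"threshold {name} configured but column {column!r} absent"
            )
        mask = fails(df[column], threshold).fillna(False)
        counts[name] = int(mask.sum())
        removed |= mask
    kept = df[~removed].copy()
    for name, n in counts.items():
        logger.info("qc filter %s removed %d row(s)", name, n)
    logger.info("qc filter kept %d of %d rows", len(kept), len(df))
    return kept, counts


# ---------------------------------------------------------------------------
# result tables

REGION_COLUMNS = [
    "protein",
    "start",
    "end",
    "direction",
    "n_supporting_peptides",
    "exposures_significant",
    "min_p",
    "label",
]


def write_regions(regions, path) -> None:
    """Write called regions as a TSV, sorted by start.

    The ``label`` column renders the interval in the field's customary
    "aa385–410" notation.
    """
    rows = []
    for r in sorted(regions, key=lambda r: (r.protein, r.start, r.end)):
        rows.append(
            {
                "protein": r.protein,
                "start": r.start,
                "end": r.end,
                "direction": r.direction,
                "n_supporting_peptides": len(r.supporting_peptides),
                "exposures_significant": ";".join(
                    f"{e:g}" for e in sorted(r.exposures_significant)
                ),
                "min_p": r.min_p,
                "label": f"aa{r.start}–{r.end}",
            }
        )
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing region columns: {', '.join(missing)}")
    return df


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write a deuteration summary CSV (replicate values semicolon-joined)."""
    out = summary.copy()
    out["replicate_D"] = out["replicate_D"].map(
        lambda v: ";".join(repr(x) for x in v)
    )
    out.to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["replicate_D"] = df["replicate_D"].map(
        lambda s: tuple(float(x) for x in str(s).split(";"))
    )
    return df


def write_differentials(diff: pd.DataFrame, path) -> None:
    diff.to_csv(path, index=False)


def read_differentials(path) -> pd.DataFrame:
    return pd.read_csv(path)
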