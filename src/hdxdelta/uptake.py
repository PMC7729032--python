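"""Per-peptide deuterated-fraction quantitation.

The core estimator normalises each labelled centroid mass against two
experimental controls measured for the same peptide:

    D = (Mex - Mex0) / (Mex100 - Mex0)

where ``Mex0`` is the average undeuterated peptide mass and ``Mex100`` the
average mass after exhaustive (24 h) exchange. Because back-exchange during
quench/digestion/LC attenuates the labelled sample and the out-exchange
control by the same factor, it cancels in the ratio and D estimates the true
fraction of exchangeable amides that picked up deuterium.

Controls are averaged across replicates and states: the undeuterated mass of
a peptide does not depend on the binding state, and after 24 h even complexed
regions exchange fully, so pooling gives the best-determined denominator and
keeps the two compared states on an identical mass scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CONTROL_MARGIN,
    OUT_EXCHANGE_EXPOSURE,
    PROTON_MASS,
    UNDEUTERATED_EXPOSURE,
)

__all__ = [
    "PeptideRecord",
    "exchangeable_amides",
    "exchangeable_positions",
    "centroid_mass",
    "deuterated_fraction",
    "DeuterationSummary",
    "summarize_replicates",
    "summarize_table",
]

#: Grouping key identifying one peptide within one protein.
PEPTIDE_KEY = ["protein", "start", "end", "sequence"]


def exchangeable_amides(sequence: str) -> int:
    """Number of observable backbone amide hydrogens of a peptide.

    The N-terminal residue's amide back-exchanges too fast to observe and
    proline has no amide hydrogen, so the count is
    ``L - 1 - #{prolines at positions 2..L}``.

    Raises
    ------
    ValueError
        If the peptide is shorter than two residues or has no observable
        amide left (e.g. an all-proline tail).
    """
    if len(sequence) < 2:
        raise ValueError(
            f"peptide {sequence!r} is too short to carry an observable amide"
        )
    n = len(sequence) - 1 - sequence[1:].upper().count("P")
    if n < 1:
        raise ValueError(
            f"peptide {sequence!r} has no exchangeable amide "
            "(every non-terminal residue is proline)"
        )
    return n


def exchangeable_positions(sequence: str, start: int = 1) -> list[int]:
    """1-based residue positions (in parent-protein coordinates when *start*
    is the peptide's first residue) that carry an observable amide."""
    return [
        start + offset
        for offset, aa in enumerate(sequence[1:].upper(), 1)
        if aa != "P"
    ]


@dataclass(frozen=True)
class PeptideRecord:
    """A proteolytic peptide located on its parent protein.

    Coordinates are 1-based inclusive; ``sequence`` must span exactly
    ``end - start + 1`` residues of the parent protein.
    """

    protein: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid peptide coordinates {self.start}-{self.end}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"coordinates {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_exchangeable(self) -> int:
        return exchangeable_amides(self.sequence)

    @property
    def exchangeable_residues(self) -> list[int]:
        """Parent-protein positions of this peptide's observable amides."""
        return exchangeable_positions(self.sequence, self.start)


def centroid_mass(envelope: Sequence[tuple[float, float]], charge: int) -> float:
    """Intensity-weighted centroid of an isotopic envelope as a neutral mass.

    Parameters
    ----------
    envelope:
        ``(m/z, intensity)`` pairs; intensities must be non-negative with a
        positive total.
    charge:
        Positive charge state of the ion.

    Returns
    -------
    float
        ``(weighted mean m/z - proton mass) * charge`` in Da.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    arr = np.asarray(envelope, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] != 2:
        raise ValueError("envelope must be a non-empty list of (m/z, intensity)")
    mz, inten = arr[:, 0], arr[:, 1]
    if (inten < 0).any():
        raise ValueError("negative intensity in envelope")
    total = inten.sum()
    if total <= 0:
        raise ValueError("total envelope intensity is zero")
    weighted_mz = float((mz * inten).sum() / total)
    return (weighted_mz - PROTON_MASS) * charge


def deuterated_fraction(
    mex: float,
    mex0: float,
    mex100: float,
    min_margin: float = DEFAULT_CONTROL_MARGIN,
) -> float:
    """Deuterated fraction ``D = (Mex - Mex0) / (Mex100 - Mex0)``.

    The value is returned exactly as the formula gives it — not clamped to
    [0, 1] — so that replicate noise propagates untouched into downstream
    differential tests.

    Raises
    ------
    ValueError
        If the control separation ``Mex100 - Mex0`` is below *min_margin*
        (an uninformative peptide whose exchange cannot be resolved).
    """
    span = mex100 - mex0
    if span < min_margin:
        raise ValueError(
            f"controls separated by {span:.5f} Da < margin {min_margin:.5f} Da: "
            "peptide carries too little resolvable deuterium"
        )
    return (mex - mex0) / span


@dataclass(frozen=True)
class DeuterationSummary:
    """Replicate-aggregated deuterated fraction for one (peptide, state, exposure)."""

    protein: str
    start: int
    end: int
    sequence: str
    state: str
    exposure: float
    mean_D: float
    sd_D: float
    n: int
    replicate_D: tuple[float, ...] = field(default_factory=tuple)

    @property
    def out_of_range(self) -> bool:
        """Flag means outside the plausible [-0.05, 1.05] band (never clamped)."""
        return not (-0.05 <= self.mean_D <= 1.05)

    def same_peptide(self, other: "DeuterationSummary") -> bool:
        return (
            self.protein == other.protein
            and self.start == other.start
            and self.end == other.end
            and self.sequence == other.sequence
        )


def summarize_replicates(
    masses: Sequence[float],
    mex0: float,
    mex100: float,
    *,
    protein: str = "",
    start: int = 0,
    end: int = 0,
    sequence: str = "",
    state: str = "",
    exposure: float = math.nan,
    min_margin: float = DEFAULT_CONTROL_MARGIN,
) -> DeuterationSummary:
    """Aggregate replicate centroid masses of one condition into a summary.

    The standard deviation uses the n-1 denominator (unbiased variance, as
    assumed by the downstream Welch test); the raw per-replicate D values are
    retained so that two-replicate experiments can be plotted showing both
    measured values rather than a symmetric bar.
    """
    if len(masses) < 2:
        raise ValueError(
            f"need >= 2 replicates for a dispersion estimate, got {len(masses)}"
        )
    d_values = tuple(deuterated_fraction(m, mex0, mex100, min_margin) for m in masses)
    return DeuterationSummary(
        protein=protein,
        start=start,
        end=end,
        sequence=sequence,
        state=state,
        exposure=exposure,
        mean_D=float(np.mean(d_values)),
        sd_D=float(np.std(d_values, ddof=1)),
        n=len(d_values),
        replicate_D=d_values,
    )


def summarize_table(
    data: pd.DataFrame,
    min_margin: float = DEFAULT_CONTROL_MARGIN,
) -> pd.DataFrame:
    """Turn a validated state-data table into a deuteration summary table.

    For every peptide the undeuterated (exposure 0) and out-exchange
    (exposure -1) rows are averaged — across replicates and states — into
    Mex0 and Mex100; every labelled row is then normalised to a per-replicate
    D and the replicates of each (peptide, state, exposure) are aggregated.

    Returns a DataFrame with columns ``protein, start, end, sequence, state,
    exposure, mean_D, sd_D, n, replicate_D, out_of_range``.
    """
    df = data.copy()
    controls0 = (
        df[df["exposure"] == UNDEUTERATED_EXPOSURE]
        .groupby(PEPTIDE_KEY)["centroid_mass"]
        .mean()
        .rename("mex0")
    )
    controls100 = (
        df[df["exposure"] == OUT_EXCHANGE_EXPOSURE]
        .groupby(PEPTIDE_KEY)["centroid_mass"]
        .mean()
        .rename("mex100")
    )
    labelled = df[df["exposure"] > 0].merge(
        controls0.reset_index(), on=PEPTIDE_KEY, how="left"
    ).merge(controls100.reset_index(), on=PEPTIDE_KEY, how="left")
    missing = labelled["mex0"].isna() | labelled["mex100"].isna()
    if missing.any():
        bad = labelled.loc[missing, PEPTIDE_KEY].drop_duplicates()
        raise ValueError(
            "peptides lack control rows: "
            + "; ".join(
                f"{r.protein} {r.start}-{r.end}" for r in bad.itertuples()
            )
        )
    span = labelled["mex100"] - labelled["mex0"]
    narrow = span < min_margin
    if narrow.any():
        bad = labelled.loc[narrow, PEPTIDE_KEY].drop_duplicates()
        raise ValueError(
            "control separation below margin "
            f"{min_margin:.5f} Da for: "
            + "; ".join(f"{r.protein} {r.start}-{r.end}" for r in bad.itertuples())
        )
    labelled["D"] = (labelled["centroid_mass"] - labelled["mex0"]) / span

    grouped = labelled.groupby(PEPTIDE_KEY + ["state", "exposure"], sort=True)["D"]
    summary = grouped.agg(
        mean_D="mean",
        sd_D=lambda x: x.std(ddof=1),
        n="count",
        replicate_D=lambda x: tuple(x),
    ).reset_index()
    if (summary["n"] < 2).any():
        bad = summary[summary["n"] < 2]
        raise ValueError(
            "conditions with fewer than 2 replicates: "
            + "; ".join(
                f"{r.protein} {r.start}-{r.end} {r.state}@{r.exposure}s"
                for r in bad.itertuples()
            )
        )
    summary["out_of_range"] = ~summary["mean_D"].between(-0.05, 1.05)
    return summary
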