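"""Residue-level consolidation of peptide significance into region calls.

A significant peptide supports every residue it actually reports on: its
first residue (unobservable amide) and its prolines are excluded from the
support span. Maximal runs of residues supported by at least
``min_support`` distinct significant peptides in a consistent direction,
significant at at least ``min_exposures`` labelling times, become called
regions; runs separated by at most ``merge_gap`` unsupported residues are
merged. Boundary resolution is inherently peptide-limited: a call can
overhang a true footprint by at most the span of the longest overlapping
peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .uptake import exchangeable_positions

__all__ = [
    "ProtectedRegion",
    "SupportProfile",
    "residue_support",
    "call_regions",
    "coverage_stats",
]

DIRECTIONS = ("protection", "deprotection")


@dataclass(frozen=True)
class ProtectedRegion:
    """A residue interval called as protected or deprotected."""

    protein: str
    start: int
    end: int
    direction: str
    supporting_peptides: tuple[tuple[int, int], ...]
    exposures_significant: tuple[float, ...]
    min_p: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid region {self.start}-{self.end}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return f"aa{self.start}–{self.end}"


@dataclass
class SupportProfile:
    """Per-residue significant-peptide support, split by direction.

    Arrays are indexed so that element ``i`` describes residue ``i + 1``.
    ``exposures[direction][i]`` is the set of exposures at which at least one
    significant peptide covers the residue in that direction.
    """

    protein: str
    length: int
    support: dict[str, np.ndarray]
    exposures: dict[str, list[set]]
    differentials: pd.DataFrame = field(repr=False)


def _support_span(start: int, sequence: str) -> list[int]:
    """Residues a peptide reports on (excludes residue 1 and prolines)."""
    return exchangeable_positions(sequence, start)


def residue_support(
    differentials: pd.DataFrame, protein_length: int
) -> SupportProfile:
    """Count, per residue and direction, distinct significant peptides.

    A peptide significant at several exposures counts once toward the support
    depth; the exposures accumulate separately so that region calling can
    require reproducibility across labelling times.
    """
    proteins = differentials["protein"].unique()
    if len(proteins) != 1:
        raise ValueError(
            f"differentials must cover exactly one protein, got {list(proteins)}"
        )
    support = {d: np.zeros(protein_length, dtype=int) for d in DIRECTIONS}
    exposures: dict[str, list[set]] = {
        d: [set() for _ in range(protein_length)] for d in DIRECTIONS
    }
    sig = differentials[differentials["significant"]]
    for (start, end, sequence, direction), group in sig.groupby(
        ["start", "end", "sequence", "direction"]
    ):
        span = [p for p in _support_span(start, sequence) if p <= protein_length]
        if not span:
            continue
        idx = np.asarray(span) - 1
        support[direction][idx] += 1
        for t in group["exposure"]:
            for i in idx:
                exposures[direction][i].add(float(t))
    return SupportProfile(
        protein=str(proteins[0]),
        length=protein_length,
        support=support,
        exposures=exposures,
        differentials=differentials,
    )


def _runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal True runs (0-based, inclusive), merging gaps <= merge_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 <= merge_gap:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    return [tuple(r) for r in runs]


def call_regions(
    profile: SupportProfile,
    min_support: int = 1,
    min_exposures: int = 1,
    merge_gap: int = 2,
    residue_offset: int = 0,
) -> list[ProtectedRegion]:
    """Call protected/deprotected regions from a residue support profile.

    ``residue_offset`` shifts reported coordinates into full-protein
    numbering when the analysed construct is a fragment; the profile itself
    stays in local coordinates.
    """
    if min_support < 1 or min_exposures < 1 or merge_gap < 0:
        raise ValueError("min_support, min_exposures >= 1 and merge_gap >= 0")
    regions: list[ProtectedRegion] = []
    sig = profile.differentials[profile.differentials["significant"]]
    for direction in DIRECTIONS:
        n_exp = np.array(
            [len(s) for s in profile.exposures[direction]], dtype=int
        )
        mask = (profile.support[direction] >= min_support) & (
            n_exp >= min_exposures
        )
        for lo, hi in _runs(mask, merge_gap):
            start, end = lo + 1, hi + 1  # residue numbering
            overlaps = np.array(
                [
                    any(
                        start <= p <= end
                        for p in _support_span(r.start, r.sequence)
                    )
                    for r in sig.itertuples()
                ],
                dtype=bool,
            )
            rows = sig[(sig["direction"] == direction).to_numpy() & overlaps]
            peptides = tuple(
                sorted(
                    {(int(r.start), int(r.end)) for r in rows.itertuples()}
                )
            )
            regions.append(
                ProtectedRegion(
                    protein=profile.protein,
                    start=start + residue_offset,
                    end=end + residue_offset,
                    direction=direction,
                    supporting_peptides=tuple(
                        (s + residue_offset, e + residue_offset)
                        for s, e in peptides
                    ),
                    exposures_significant=tuple(
                        sorted(set(float(t) for t in rows["exposure"]))
                    ),
                    min_p=float(rows["p_value"].min()) if len(rows) else float("nan"),
                )
            )
    return sorted(regions, key=lambda r: (r.start, r.end, r.direction))


def coverage_stats(peptides, protein_length: int) -> tuple[float, float]:
    """Fraction of residues covered by >= 1 peptide and mean redundancy.

    Accepts a list of objects with ``start``/``end`` attributes (e.g.
    :class:`~hdxdelta.uptake.PeptideRecord`) or a DataFrame with those
    columns. Coverage counts full peptide spans; redundancy is the mean
    number of peptides overlapping each covered residue.
    """
    if isinstance(peptides, pd.DataFrame):
        spans = peptides[["start", "end"]].drop_duplicates().itertuples(index=False)
        spans = [(int(s), int(e)) for s, e in spans]
    else:
        spans = [(p.start, p.end) for p in peptides]
    if not spans:
        raise ValueError("no peptides given")
    depth = np.zeros(protein_length, dtype=int)
    for s, e in spans:
        depth[s - 1 : e] += 1
    covered = depth > 0
    coverage = float(covered.mean())
    redundancy = float(depth[covered].mean()) if covered.any() else 0.0
    return coverage, redundancy
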