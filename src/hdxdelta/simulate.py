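"""Synthetic HDX-MS dataset generator with known ground truth.

Exchange is modelled with single-exponential per-residue Linderstrøm-Lang
kinetics in the EX2 limit: an observable amide at residue ``i`` with
protection factor ``P_i >= 1`` and intrinsic rate ``k_int`` has exchanged a
fraction ``1 - exp(-k_int * t / P_i)`` of the time after exposure ``t``.
A peptide's true uptake is the mean over its observable amides. The measured
centroid mass adds a uniform back-exchange attenuation and Gaussian
replicate noise:

    Mex = M0 + back_exchange * uptake * N_amides * dm(D-H) + N(0, noise_sd)

Because back-exchange multiplies the labelled samples and the out-exchange
control identically, the control-normalised D estimator downstream is exact
in the noise-free limit for any back-exchange in (0, 1].

Digestion is generative — stratified random overlapping windows tuned to a
per-residue redundancy target — not a pepsin specificity model; the analysis
pipeline only needs the statistical structure of an overlapping peptide map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .constants import (
    DEUTERIUM_MASS_SHIFT,
    OUT_EXCHANGE_EXPOSURE,
    UNDEUTERATED_EXPOSURE,
)
from .uptake import PeptideRecord, exchangeable_positions

__all__ = [
    "DigestionParams",
    "Footprint",
    "StateSpec",
    "SimulationConfig",
    "GroundTruth",
    "digest",
    "true_uptake",
    "simulate_measurement",
    "simulate_controls",
    "generate_dataset",
    "random_protein_sequence",
]

AMINO_ACIDS = "ACDEFGHIKLMNQRSTVWY"  # proline handled separately


@lru_cache(maxsize=None)
def monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide (Da), via pyteomics."""
    return float(_pmass.fast_mass(sequence))


def random_protein_sequence(
    length: int, seed: int, proline_freq: float = 0.05
) -> str:
    """Random protein sequence with a realistic ~5% proline frequency."""
    rng = np.random.default_rng(seed)
    aas = rng.choice(list(AMINO_ACIDS), size=length)
    prolines = rng.random(length) < proline_freq
    aas[prolines] = "P"
    # an N-terminal proline would be pointless to special-case downstream
    if aas[0] == "P":
        aas[0] = "A"
    return "".join(aas)


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of the generative peptide map."""

    mean_peptide_length: int = 10
    length_sd: float = 2.5
    target_redundancy: float = 3.0
    min_length: int = 4

    def __post_init__(self) -> None:
        if self.target_redundancy < 1:
            raise ValueError("target_redundancy must be >= 1")
        if self.mean_peptide_length < self.min_length:
            raise ValueError("mean_peptide_length below min_length")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")


@dataclass(frozen=True)
class Footprint:
    """A residue interval whose protection factor is multiplied by *factor*.

    ``factor > 1`` plants protection (slower exchange), ``factor < 1``
    deprotection. Coordinates are 1-based inclusive in local (construct)
    numbering.
    """

    start: int
    end: int
    factor: float = 20.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid footprint interval {self.start}-{self.end}")
        if self.factor <= 0:
            raise ValueError("footprint factor must be > 0")


@dataclass(frozen=True)
class StateSpec:
    """One experimental state: a label plus its protection-factor profile."""

    name: str
    baseline_protection: float = 1.0
    footprints: tuple[Footprint, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline_protection < 1:
            raise ValueError("baseline protection factor must be >= 1")
        object.__setattr__(
            self,
            "footprints",
            tuple(
                fp if isinstance(fp, Footprint) else Footprint(**fp)
                for fp in self.footprints
            ),
        )

    def protection_profile(self, length: int) -> np.ndarray:
        """Per-residue protection factors (index 0 = residue 1)."""
        profile = np.full(length, float(self.baseline_protection))
        for fp in self.footprints:
            if fp.end > length:
                raise ValueError(
                    f"footprint {fp.start}-{fp.end} outside protein of "
                    f"length {length}"
                )
            profile[fp.start - 1 : fp.end] *= fp.factor
        if (profile < 1).any():
            raise ValueError("protection profile drops below 1")
        return profile


@dataclass
class SimulationConfig:
    """Full description of one synthetic two-state HDX experiment.

    ``exposures`` are labelling durations in seconds; the undeuterated and
    24 h out-exchange controls are always generated in addition and carry the
    sentinel exposures 0 and -1. ``residue_offset`` maps local construct
    coordinates to full-protein numbering when the analysed protein is a
    fragment (reports then read e.g. aa329-336); it shifts reported regions
    only, never the data table.
    """

    protein_sequence: str
    states: tuple[StateSpec, ...]
    protein_id: str = "synthetic"
    intrinsic_rate: float = 1.0
    exposures: tuple[float, ...] = (10.0, 60.0, 300.0)
    n_replicates: int = 3
    noise_sd: float = 0.05
    back_exchange: float = 0.7
    digestion: DigestionParams = field(default_factory=DigestionParams)
    residue_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.states = tuple(
            s if isinstance(s, StateSpec) else StateSpec(**s) for s in self.states
        )
        if isinstance(self.digestion, dict):
            self.digestion = DigestionParams(**self.digestion)
        if not self.protein_sequence:
            raise ValueError("protein_sequence is empty")
        if not self.states:
            raise ValueError("at least one state is required")
        if len({s.name for s in self.states}) != len(self.states):
            raise ValueError("state names must be unique")
        if any(t <= 0 for t in self.exposures):
            raise ValueError("exposures must be > 0 s")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not (0 < self.back_exchange <= 1):
            raise ValueError("back_exchange must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.intrinsic_rate <= 0:
            raise ValueError("intrinsic_rate must be > 0")
        # fail early on out-of-range footprints
        for s in self.states:
            s.protection_profile(len(self.protein_sequence))

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposures"] = list(self.exposures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["states"] = tuple(
            StateSpec(
                name=s["name"],
                baseline_protection=s.get("baseline_protection", 1.0),
                footprints=tuple(
                    Footprint(**fp) for fp in s.get("footprints", ())
                ),
            )
            for s in d["states"]
        )
        if "digestion" in d and isinstance(d["digestion"], dict):
            d["digestion"] = DigestionParams(**d["digestion"])
        if "exposures" in d:
            d["exposures"] = tuple(d["exposures"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class GroundTruth:
    """What the simulator planted: the answer key for region recovery.

    ``footprint_intervals`` holds, for every non-reference state compared
    against the first (reference) state, the maximal residue runs whose
    protection factors differ, in full-protein numbering (offset applied),
    with direction "protection" when the state is more protected than the
    reference.
    """

    protein_id: str
    length: int
    residue_offset: int
    footprint_intervals: list[dict]
    protection_profiles: dict[str, list[float]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# digestion


def _ensure_exchangeable(sequence: str, start: int, end: int) -> tuple[int, int]:
    """Grow a window until it carries at least one observable amide."""
    L = len(sequence)
    while not exchangeable_positions(sequence[start - 1 : end], start):
        if end < L:
            end += 1
        elif start > 1:
            start -= 1
        else:
            raise ValueError("protein has no exchangeable amide at all")
    return start, end


def digest(
    sequence: str,
    params: DigestionParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    protein_id: str = "synthetic",
) -> list[PeptideRecord]:
    """Generate an overlapping proteolytic peptide map.

    Windows are drawn with Gaussian lengths around ``mean_peptide_length``
    and starts stratified over the sequence so that the map reaches the
    per-residue ``target_redundancy`` while covering essentially every
    residue; the first window is anchored at residue 1 and the last at the
    C-terminus. Duplicate coordinate pairs are collapsed. Deterministic for
    a fixed seed.
    """
    params = params or DigestionParams()
    L = len(sequence)
    if L == 0:
        raise ValueError("sequence is empty")
    if L < params.mean_peptide_length:
        raise ValueError(
            f"sequence length {L} is shorter than mean_peptide_length "
            f"{params.mean_peptide_length}"
        )
    rng = np.random.default_rng(seed)
    n_pep = max(1, int(round(params.target_redundancy * L / params.mean_peptide_length)))
    lengths = np.rint(
        rng.normal(params.mean_peptide_length, params.length_sd, n_pep)
    ).astype(int)
    lengths = np.clip(lengths, params.min_length, L)

    records: dict[tuple[int, int], PeptideRecord] = {}
    for i in range(n_pep):
        length = int(lengths[i])
        max_start = L - length + 1
        if i == 0:
            start = 1
        elif i == n_pep - 1:
            start = max_start
        else:
            frac = (i + rng.uniform()) / n_pep
            start = 1 + int(frac * (max_start - 1))
        end = start + length - 1
        start, end = _ensure_exchangeable(sequence, start, end)
        records[(start, end)] = PeptideRecord(
            protein=protein_id,
            start=start,
            end=end,
            sequence=sequence[start - 1 : end],
        )
    return [records[k] for k in sorted(records)]


# ---------------------------------------------------------------------------
# exchange kinetics


def true_uptake(
    peptide: PeptideRecord,
    protection_profile: Sequence[float],
    intrinsic_rate: float,
    t: float,
) -> float:
    """Noise-free deuterated fraction of a peptide after exposure *t* seconds.

    Mean over the peptide's observable amides of ``1 - exp(-k_int*t/P_i)``.
    Monotonically non-decreasing in ``t`` and non-increasing in every ``P_i``.
    """
    if t < 0:
        raise ValueError("exposure must be >= 0 s")
    profile = np.asarray(protection_profile, dtype=float)
    if (profile < 1).any():
        raise ValueError("protection factors must be >= 1")
    positions = peptide.exchangeable_residues
    if not positions:
        raise ValueError(
            f"peptide {peptide.start}-{peptide.end} has no exchangeable amide"
        )
    p = profile[np.asarray(positions) - 1]
    return float(np.mean(-np.expm1(-intrinsic_rate * t / p)))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_measurement(
    peptide: PeptideRecord,
    state: StateSpec,
    t: float,
    rng: np.random.Generator | int,
    config: SimulationConfig,
) -> float:
    """One labelled centroid-mass observation (Da) for a replicate."""
    rng = _rng(rng)
    profile = state.protection_profile(len(config.protein_sequence))
    uptake = true_uptake(peptide, profile, config.intrinsic_rate, t)
    m0 = monoisotopic_mass(peptide.sequence)
    offset = (
        config.back_exchange
        * uptake
        * peptide.n_exchangeable
        * DEUTERIUM_MASS_SHIFT
    )
    return m0 + offset + rng.normal(0.0, config.noise_sd)


def simulate_controls(
    peptide: PeptideRecord,
    rng: np.random.Generator | int,
    config: SimulationConfig,
) -> tuple[float, float]:
    """One (undeuterated, out-exchange) control observation pair (Da).

    The out-exchange control has every observable amide exchanged, attenuated
    by the same back-exchange factor as the labelled samples — which is
    exactly what makes the experimental 100% control cancel back-exchange.
    """
    rng = _rng(rng)
    m0 = monoisotopic_mass(peptide.sequence)
    mex0 = m0 + rng.normal(0.0, config.noise_sd)
    mex100 = (
        m0
        + config.back_exchange * peptide.n_exchangeable * DEUTERIUM_MASS_SHIFT
        + rng.normal(0.0, config.noise_sd)
    )
    return mex0, mex100


def _truth_intervals(config: SimulationConfig) -> list[dict]:
    L = len(config.protein_sequence)
    ref = config.states[0]
    ref_profile = ref.protection_profile(L)
    intervals: list[dict] = []
    for state in config.states[1:]:
        ratio = state.protection_profile(L) / ref_profile
        changed = ratio != 1.0
        i = 0
        while i < L:
            if changed[i]:
                j = i
                direction = "protection" if ratio[i] > 1 else "deprotection"
                while (
                    j + 1 < L
                    and changed[j + 1]
                    and (ratio[j + 1] > 1) == (ratio[i] > 1)
                ):
                    j += 1
                intervals.append(
                    {
                        "state_pair": [state.name, ref.name],
                        "start": i + 1 + config.residue_offset,
                        "end": j + 1 + config.residue_offset,
                        "direction": direction,
                    }
                )
                i = j + 1
            else:
                i += 1
    return intervals


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the complete experimental design.

    One row per (peptide, state, exposure, replicate), plus per-replicate
    undeuterated (exposure 0) and out-exchange (exposure -1) control rows for
    every (peptide, state). Identical seed gives an identical table.
    """
    root = np.random.SeedSequence(config.seed)
    digest_seed, noise_seed = root.spawn(2)
    peptides = digest(
        config.protein_sequence,
        config.digestion,
        seed=digest_seed,
        protein_id=config.protein_id,
    )
    rng = np.random.default_rng(noise_seed)
    L = len(config.protein_sequence)
    profiles = {s.name: s.protection_profile(L) for s in config.states}

    rows = []
    for pep in peptides:
        m0 = monoisotopic_mass(pep.sequence)
        n_amides = pep.n_exchangeable
        max_offset = config.back_exchange * n_amides * DEUTERIUM_MASS_SHIFT
        for state in config.states:
            for t in config.exposures:
                u = true_uptake(pep, profiles[state.name], config.intrinsic_rate, t)
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        (
                            pep.protein,
                            state.name,
                            pep.start,
                            pep.end,
                            pep.sequence,
                            float(t),
                            rep,
                            m0 + config.back_exchange * u * n_amides
                            * DEUTERIUM_MASS_SHIFT
                            + rng.normal(0.0, config.noise_sd),
                        )
                    )
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    (
                        pep.protein,
                        state.name,
                        pep.start,
                        pep.end,
                        pep.sequence,
                        UNDEUTERATED_EXPOSURE,
                        rep,
                        m0 + rng.normal(0.0, config.noise_sd),
                    )
                )
                rows.append(
                    (
                        pep.protein,
                        state.name,
                        pep.start,
                        pep.end,
                        pep.sequence,
                        OUT_EXCHANGE_EXPOSURE,
                        rep,
                        m0 + max_offset + rng.normal(0.0, config.noise_sd),
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein",
            "state",
            "start",
            "end",
            "sequence",
            "exposure",
            "replicate",
            "centroid_mass",
        ],
    )
    truth = GroundTruth(
        protein_id=config.protein_id,
        length=L,
        residue_offset=config.residue_offset,
        footprint_intervals=_truth_intervals(config),
        protection_profiles={k: list(v) for k, v in profiles.items()},
    )
    return table, truth
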