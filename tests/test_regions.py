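"""Residue-level support profiles and region calling."""

import numpy as np
import pandas as pd
import pytest

from hdxdelta.regions import (
    ProtectedRegion,
    call_regions,
    coverage_stats,
    residue_support,
)
from hdxdelta.uptake import PeptideRecord


def _diff_row(start, end, sequence, exposure=10.0, significant=True,
              direction="protection", p=0.01):
    return dict(
        protein="prot",
        start=start,
        end=end,
        sequence=sequence,
        exposure=exposure,
        delta_D=-0.3 if direction == "protection" else 0.3,
        se_delta=0.02,
        t_stat=-5.0,
        df=4.0,
        p_value=p,
        p_adjusted=p,
        significant=significant,
        direction=direction,
    )


def _frame(rows):
    return pd.DataFrame(rows)


class TestResidueSupport:
    def test_span_excludes_first_residue(self):
        seq = "A" * 11
        diff = _frame([_diff_row(10, 20, seq)])
        prof = residue_support(diff, 30)
        support = prof.support["protection"]
        assert support[9] == 0  # residue 10: unobservable first amide
        assert (support[10:20] == 1).all()  # residues 11..20
        assert support[20:].sum() == 0

    def test_prolines_are_skipped(self):
        seq = "AAPAA"  # residue 3 of the peptide is proline
        diff = _frame([_diff_row(10, 14, seq)])
        prof = residue_support(diff, 20)
        support = prof.support["protection"]
        assert support[11] == 0  # residue 12 = proline
        assert support[10] == 1 and support[12] == 1 and support[13] == 1

    def test_no_significant_peptides_gives_zero_profile(self):
        diff = _frame([_diff_row(10, 20, "A" * 11, significant=False)])
        prof = residue_support(diff, 30)
        assert prof.support["protection"].sum() == 0
        assert prof.support["deprotection"].sum() == 0

    def test_overlapping_peptides_stack(self):
        diff = _frame(
            [
                _diff_row(10, 20, "A" * 11),
                _diff_row(15, 25, "A" * 11),
            ]
        )
        prof = residue_support(diff, 30)
        support = prof.support["protection"]
        assert (support[15:20] == 2).all()  # residues 16..20
        assert (support[10:15] == 1).all()
        assert (support[20:25] == 1).all()

    def test_multi_exposure_peptide_counts_once(self):
        diff = _frame(
            [
                _diff_row(10, 20, "A" * 11, exposure=10.0),
                _diff_row(10, 20, "A" * 11, exposure=60.0),
            ]
        )
        prof = residue_support(diff, 30)
        assert prof.support["protection"].max() == 1
        assert prof.exposures["protection"][12] == {10.0, 60.0}

    def test_multiple_proteins_rejected(self):
        rows = [_diff_row(10, 20, "A" * 11)]
        rows.append(dict(rows[0], protein="other"))
        with pytest.raises(ValueError, match="one protein"):
            residue_support(_frame(rows), 30)


class TestCallRegions:
    def test_zero_support_gives_empty_list(self):
        diff = _frame([_diff_row(10, 20, "A" * 11, significant=False)])
        prof = residue_support(diff, 30)
        assert call_regions(prof) == []

    def test_single_peptide_region(self):
        diff = _frame([_diff_row(10, 20, "A" * 11)])
        (region,) = call_regions(residue_support(diff, 30))
        assert (region.start, region.end) == (11, 20)
        assert region.direction == "protection"
        assert region.supporting_peptides == ((10, 20),)
        assert region.exposures_significant == (10.0,)
        assert region.min_p == 0.01

    def test_merge_gap_controls_region_fusion(self):
        rows = [
            _diff_row(10, 20, "A" * 11),
            _diff_row(22, 32, "A" * 11),
        ]  # supports 11..20 and 23..32, gap of 2 residues (21, 22)
        prof = residue_support(_frame(rows), 40)
        merged = call_regions(prof, merge_gap=2)
        assert [(r.start, r.end) for r in merged] == [(11, 32)]
        split = call_regions(prof, merge_gap=1)
        assert [(r.start, r.end) for r in split] == [(11, 20), (23, 32)]

    def test_min_support_monotonicity(self):
        rows = [
            _diff_row(10, 20, "A" * 11),
            _diff_row(15, 25, "A" * 11),
            _diff_row(40, 50, "A" * 11, direction="deprotection"),
        ]
        prof = residue_support(_frame(rows), 60)
        loose = call_regions(prof, min_support=1)
        strict = call_regions(prof, min_support=2)
        assert len(strict) <= len(loose)
        for s in strict:
            parents = [
                r for r in loose
                if r.direction == s.direction and r.start <= s.start and r.end >= s.end
            ]
            assert parents, "raising min_support must never enlarge a region"

    def test_min_exposures_requires_reproducibility(self):
        rows = [
            _diff_row(10, 20, "A" * 11, exposure=10.0),
            _diff_row(15, 25, "A" * 11, exposure=10.0),
        ]
        prof = residue_support(_frame(rows), 40)
        assert call_regions(prof, min_exposures=2) == []
        rows.append(_diff_row(10, 20, "A" * 11, exposure=60.0))
        prof = residue_support(_frame(rows), 40)
        assert len(call_regions(prof, min_exposures=2)) == 1

    def test_directions_never_mix(self):
        rows = [
            _diff_row(10, 20, "A" * 11, direction="protection"),
            _diff_row(18, 28, "A" * 11, direction="deprotection"),
        ]
        regions = call_regions(residue_support(_frame(rows), 40))
        directions = {r.direction for r in regions}
        assert directions == {"protection", "deprotection"}
        for r in regions:
            for s, e in r.supporting_peptides:
                assert s <= r.end and e >= r.start

    def test_residue_offset_shifts_reports_only(self):
        diff = _frame([_diff_row(5, 16, "A" * 12)])
        (region,) = call_regions(residue_support(diff, 69), residue_offset=320)
        assert (region.start, region.end) == (326, 336)
        assert region.label == "aa326–336"

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            ProtectedRegion("p", 10, 5, "protection", (), (), 0.1)
        with pytest.raises(ValueError, match="direction"):
            ProtectedRegion("p", 5, 10, "sideways", (), (), 0.1)


class TestCoverageStats:
    def test_single_full_length_peptide(self):
        peps = [PeptideRecord("p", 1, 30, "A" * 30)]
        assert coverage_stats(peps, 30) == (1.0, 1.0)

    def test_two_disjoint_halves(self):
        peps = [
            PeptideRecord("p", 1, 15, "A" * 15),
            PeptideRecord("p", 16, 30, "A" * 15),
        ]
        assert coverage_stats(peps, 30) == (1.0, 1.0)

    def test_hand_enumerated_fixture(self):
        peps = [
            PeptideRecord("p", 1, 10, "A" * 10),
            PeptideRecord("p", 5, 14, "A" * 10),
            PeptideRecord("p", 11, 20, "A" * 10),
            PeptideRecord("p", 15, 24, "A" * 10),
            PeptideRecord("p", 15, 24, "A" * 10),  # duplicate span
        ]
        coverage, redundancy = coverage_stats(peps, 30)
        # residues 1..24 covered; depth sums to 50 over 24 covered residues
        assert coverage == pytest.approx(24 / 30)
        assert redundancy == pytest.approx(50 / 24)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no peptides"):
            coverage_stats([], 30)
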