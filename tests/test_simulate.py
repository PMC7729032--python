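"""Simulator: digestion map, exchange kinetics, measurement model, dataset."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxdelta.constants import DEUTERIUM_MASS_SHIFT
from hdxdelta.io import write_state_data
from hdxdelta.simulate import (
    DigestionParams,
    Footprint,
    SimulationConfig,
    StateSpec,
    digest,
    generate_dataset,
    monoisotopic_mass,
    random_protein_sequence,
    simulate_controls,
    simulate_measurement,
    true_uptake,
)
from hdxdelta.uptake import PeptideRecord

from conftest import make_config


class TestDigest:
    def test_thirty_mer_coverage(self):
        seq = random_protein_sequence(30, seed=8)
        peps = digest(seq, DigestionParams(target_redundancy=3.0), seed=1)
        covered = set()
        for p in peps:
            covered.update(range(p.start, p.end + 1))
        assert len(covered) >= 29

    def test_single_full_length_peptide(self):
        seq = random_protein_sequence(30, seed=8)
        params = DigestionParams(
            mean_peptide_length=30, length_sd=0.0, target_redundancy=1.0
        )
        peps = digest(seq, params, seed=1)
        assert [(p.start, p.end) for p in peps] == [(1, 30)]

    def test_same_seed_is_deterministic(self):
        seq = random_protein_sequence(200, seed=8)
        a = digest(seq, seed=4)
        b = digest(seq, seed=4)
        assert a == b

    def test_coverage_and_redundancy_over_seeds(self):
        """Redundancy-3 maps cover >= 95% of residues, 20 seeds."""
        seq = random_protein_sequence(250, seed=13)
        params = DigestionParams(target_redundancy=3.0)
        for seed in range(20):
            peps = digest(seq, params, seed=seed)
            depth = np.zeros(250)
            for p in peps:
                depth[p.start - 1 : p.end] += 1
            assert (depth > 0).mean() >= 0.95
            redundancy = depth.sum() / 250
            assert abs(redundancy - 3.0) <= 0.6  # within 20% of target

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="mean_peptide_length"):
            digest("AAAA", DigestionParams(mean_peptide_length=10))

    def test_every_peptide_has_an_observable_amide(self):
        seq = random_protein_sequence(150, seed=3)
        for p in digest(seq, seed=0):
            assert p.n_exchangeable >= 1
            assert p.start < p.end


class TestTrueUptake:
    def setup_method(self):
        self.pep = PeptideRecord(protein="p", start=1, end=5, sequence="AAAAA")

    def test_zero_exposure_gives_zero(self):
        assert true_uptake(self.pep, np.ones(5), 1.0, 0.0) == 0.0

    def test_saturation_limit(self):
        assert true_uptake(self.pep, np.ones(5), 1.0, 50.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_single_residue_closed_form(self):
        pep = PeptideRecord(protein="p", start=1, end=2, sequence="AA")
        profile = np.array([1.0, 10.0])
        # k_int = 1/s, P = 10, t = 10 s -> 1 - exp(-1)
        assert true_uptake(pep, profile, 1.0, 10.0) == pytest.approx(
            1 - np.exp(-1), abs=1e-12
        )

    @settings(max_examples=60, derandomize=True)
    @given(
        t1=st.floats(0, 1e4),
        dt=st.floats(0, 1e4),
        p_scale=st.floats(1.0, 100.0),
    )
    def test_monotone_in_time_and_protection(self, t1, dt, p_scale):
        profile = np.array([1.0, 4.0, 2.0, 8.0, 1.0])
        u1 = true_uptake(self.pep, profile, 1.0, t1)
        assert 0.0 <= u1 <= 1.0
        assert true_uptake(self.pep, profile, 1.0, t1 + dt) >= u1 - 1e-12
        assert true_uptake(self.pep, profile * p_scale, 1.0, t1) <= u1 + 1e-12

    def test_no_exchangeable_amide_rejected(self):
        pep = PeptideRecord(protein="p", start=1, end=2, sequence="AP")
        with pytest.raises(ValueError, match="exchangeable"):
            true_uptake(pep, np.ones(2), 1.0, 10.0)


class TestMeasurementModel:
    def test_noise_free_zero_uptake_is_undeuterated_mass(self):
        cfg = make_config(noise_sd=0.0)
        pep = PeptideRecord(protein="toy", start=1, end=6,
                            sequence=cfg.protein_sequence[:6])
        mass = simulate_measurement(pep, cfg.states[0], 0.0, 1, cfg)
        assert mass == pytest.approx(monoisotopic_mass(pep.sequence), abs=1e-9)

    def test_full_uptake_mass_offset_arithmetic(self):
        # back_exchange 0.7, uptake 1, 10 amides -> offset 7 x 1.00627675 Da
        seq = "A" * 11
        cfg = make_config(
            protein_sequence=random_protein_sequence(120, seed=5),
            noise_sd=0.0,
            back_exchange=0.7,
        )
        pep = PeptideRecord(protein="toy", start=1, end=11, sequence=seq)
        mass = simulate_measurement(pep, cfg.states[0], 1e6, 1, cfg)
        offset = mass - monoisotopic_mass(seq)
        assert offset == pytest.approx(7 * DEUTERIUM_MASS_SHIFT, abs=1e-6)

    def test_replicate_scatter_matches_noise_model(self):
        cfg = make_config(noise_sd=0.05)
        pep = PeptideRecord(protein="toy", start=1, end=9,
                            sequence=cfg.protein_sequence[:9])
        rng = np.random.default_rng(12)
        masses = np.array(
            [simulate_measurement(pep, cfg.states[0], 10.0, rng, cfg)
             for _ in range(400)]
        )
        assert masses.std() == pytest.approx(0.05, rel=0.2)
        assert np.abs(masses - masses.mean()).max() < 4 * 0.05 + 0.02

    def test_controls_arithmetic(self):
        seq = "A" * 6  # 5 exchangeable amides
        cfg = make_config(noise_sd=0.0, back_exchange=1.0)
        pep = PeptideRecord(protein="toy", start=1, end=6, sequence=seq)
        mex0, mex100 = simulate_controls(pep, 1, cfg)
        assert mex100 - mex0 == pytest.approx(5.0313838, abs=1e-6)
        cfg2 = make_config(noise_sd=0.0, back_exchange=0.7)
        mex0, mex100 = simulate_controls(pep, 1, cfg2)
        assert mex100 - mex0 == pytest.approx(0.7 * 5 * DEUTERIUM_MASS_SHIFT, abs=1e-9)

    def test_noisy_controls_converge_to_noise_free_value(self):
        cfg = make_config(noise_sd=0.05)
        pep = PeptideRecord(protein="toy", start=1, end=7,
                            sequence=cfg.protein_sequence[:7])
        rng = np.random.default_rng(5)
        pairs = [simulate_controls(pep, rng, cfg) for _ in range(500)]
        mex100 = np.array([b for _, b in pairs])
        noise_free = (
            monoisotopic_mass(pep.sequence)
            + cfg.back_exchange * pep.n_exchangeable * DEUTERIUM_MASS_SHIFT
        )
        assert mex100.std() > 0
        assert mex100.mean() == pytest.approx(noise_free, abs=0.01)


class TestGenerateDataset:
    def test_row_counting(self):
        data, _ = generate_dataset(make_config())
        n_pep = data.groupby(["start", "end"]).ngroups
        labelled = data[data["exposure"] > 0]
        assert len(labelled) == 2 * 3 * 3 * n_pep
        controls = data[data["exposure"] <= 0]
        assert len(controls) == 2 * 2 * 3 * n_pep

    def test_planted_footprint_lowers_uptake_noise_free(self, noise_free_dataset):
        from hdxdelta.uptake import summarize_table

        data, truth = noise_free_dataset
        (iv,) = truth.footprint_intervals
        assert iv["direction"] == "protection"
        summary = summarize_table(data)
        inside = summary[
            (summary["start"] >= iv["start"]) & (summary["end"] <= iv["end"])
        ]
        assert len(inside) > 0
        pivot = inside.pivot_table(
            index=["start", "end", "exposure"], columns="state", values="mean_D"
        )
        assert (pivot["complex"] < pivot["alone"]).all()

    def test_same_seed_gives_byte_identical_csv(self, tmp_path):
        cfg = make_config()
        for name in ("a.csv", "b.csv"):
            data, _ = generate_dataset(make_config())
            write_state_data(data, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_footprint_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_config(
                states=(
                    StateSpec(name="alone"),
                    StateSpec(name="complex", footprints=(Footprint(100, 130, 20.0),)),
                )
            )

    def test_saturation_of_unprotected_residues(self):
        """P = 1 and k_int * t >= 20 leaves no measurable unexchanged amide."""
        pep = PeptideRecord(protein="p", start=1, end=8, sequence="AAAAAAAA")
        assert true_uptake(pep, np.ones(8), 1.0, 20.0) >= 1 - 1e-8

    def test_config_json_round_trip(self, tmp_path):
        cfg = make_config()
        cfg.to_json(tmp_path / "sim.json")
        back = SimulationConfig.from_json(tmp_path / "sim.json")
        assert back == cfg
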