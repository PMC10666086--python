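"""Generator unit and property tests: lineshapes, band structure, binding
model, and the screening/verification study designs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ir2dscreen import (
    PeakSpec,
    RunConfig,
    SampleRecord,
    amide_doublet,
    bound_fraction,
    drug_pattern,
    drug_signal_scale,
    gaussian2d_peak,
    generate_screening_set,
    generate_verification_set,
    injected_signal,
    pattern_map,
    serum_base_map,
    synth_sample,
    thermal_water_map,
)
from ir2dscreen.config import BindingConfig
from ir2dscreen.synth import VERIFICATION_CONCENTRATIONS


class TestGaussianPeak:
    def test_center_cell_equals_amplitude(self, small_grid):
        m = gaussian2d_peak(1660.0, 1640.0, 2.5, 12.0, 6.0, small_grid)
        assert m.value_at(1660.0, 1640.0) == pytest.approx(2.5, abs=1e-12)

    def test_closed_form_along_diagonal(self, small_grid):
        # one grid step along (+1,+1) is a pure diagonal displacement of
        # sqrt(32) cm^-1; the closed form predicts exp(-d^2 / (2 sigma_d^2))
        s = 12.0
        m = gaussian2d_peak(1660.0, 1640.0, 1.0, s, 6.0, small_grid)
        val = m.value_at(1664.0, 1644.0)
        assert val == pytest.approx(np.exp(-32.0 / (2 * s**2)), rel=1e-12)

    def test_matches_per_cell_evaluation_loop(self, small_grid):
        """Vectorised map equals an independent scalar loop (brute-force oracle)."""
        m = gaussian2d_peak(1655.0, 1633.0, -0.7, 9.0, 5.0, small_grid)
        ref = np.empty(small_grid.shape)
        for i, p in enumerate(small_grid.pump_axis):
            for j, w in enumerate(small_grid.probe_axis):
                u = ((p - 1655.0) + (w - 1633.0)) / np.sqrt(2.0)
                v = ((w - 1633.0) - (p - 1655.0)) / np.sqrt(2.0)
                ref[i, j] = -0.7 * np.exp(-(u**2) / (2 * 81.0) - (v**2) / (2 * 25.0))
        assert np.abs(m.amplitudes - ref).max() < 1e-12

    def test_rejects_nonpositive_width(self, small_grid):
        with pytest.raises(ValueError):
            gaussian2d_peak(1660.0, 1660.0, 1.0, 0.0, 5.0, small_grid)


class TestAmideDoublet:
    def test_sign_structure_at_fundamental_and_overtone(self, small_grid):
        peak = PeakSpec(center=1660.0, amplitude=1.0)
        m = amide_doublet(peak, small_grid)
        assert m.value_at(1660.0, 1660.0) < 0
        assert m.value_at(1660.0, 1660.0 - peak.anharmonic_shift) > 0

    @settings(max_examples=25, deadline=None)
    @given(
        center=st.floats(1630, 1680),
        amp=st.floats(0.1, 5.0),
        shift=st.floats(8.0, 24.0),
    )
    def test_every_doublet_has_both_signs(self, small_grid, center, amp, shift):
        peak = PeakSpec(center=center, amplitude=amp, anharmonic_shift=shift)
        m = amide_doublet(peak, small_grid)
        assert m.amplitudes.min() < 0 < m.amplitudes.max()


class TestSerumBase:
    def test_most_negative_cell_near_hsa_band(self, config, grid):
        m = serum_base_map(config, grid)
        i, j = np.unravel_index(np.argmin(m.amplitudes), m.amplitudes.shape)
        step = config.grid.step
        assert abs(grid.pump_axis[i] - 1660.0) <= 2 * step
        assert abs(grid.probe_axis[j] - 1660.0) <= 2 * step

    def test_zero_globulin_reduces_to_hsa_doublet(self, grid):
        cfg = RunConfig()
        cfg.globulin.amplitude = 0.0
        m = serum_base_map(cfg, grid)
        hsa = amide_doublet(
            PeakSpec(center=1660.0, amplitude=1.0, sigma_diag=18.0, sigma_anti=8.0),
            grid,
        )
        assert np.abs(m.amplitudes - hsa.amplitudes).max() < 1e-14

    def test_bit_reproducible(self, config, grid):
        a = serum_base_map(config, grid)
        b = serum_base_map(config, grid)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestDrugPatterns:
    def test_cefazolin_component_centers_match_measurement_points(self):
        pat = drug_pattern("cefazolin")
        centers = {(c[0], c[1]) for c in pat.components}
        assert centers == {(1635.0, 1632.0), (1656.0, 1649.0)}

    def test_patterns_pairwise_distinct(self, grid):
        flats = [
            pattern_map(drug_pattern(d), grid).flatten()
            for d in ("cefazolin", "ibuprofen", "paracetamol", "warfarin")
        ]
        for i in range(len(flats)):
            for j in range(i + 1, len(flats)):
                assert not np.allclose(flats[i], flats[j])

    def test_warfarin_more_similar_to_cefazolin_than_ibuprofen(self, grid):
        def unit(d):
            v = pattern_map(drug_pattern(d), grid).flatten()
            return v / np.linalg.norm(v)

        cef, warf, ibu = unit("cefazolin"), unit("warfarin"), unit("ibuprofen")
        assert cef @ warf > cef @ ibu

    def test_unknown_drug_lists_valid_names(self):
        with pytest.raises(ValueError, match="cefazolin"):
            drug_pattern("aspirin")


class TestThermalMap:
    def test_max_equals_scale_rows_identical_and_linear(self, grid):
        m = thermal_water_map(grid, scale=0.7)
        assert m.amplitudes.max() == pytest.approx(0.7, abs=1e-12)
        assert np.abs(m.amplitudes[0] - m.amplitudes[-1]).max() == 0.0
        m2 = thermal_water_map(grid, scale=1.4)
        assert np.abs(m2.amplitudes - 2 * m.amplitudes).max() < 1e-12

    def test_rejects_nonpositive_scale(self, grid):
        with pytest.raises(ValueError):
            thermal_water_map(grid, scale=0.0)


class TestBoundFraction:
    def test_limits(self):
        p = BindingConfig()
        assert bound_fraction(0.0, p) == pytest.approx(p.f_low, abs=1e-12)
        assert bound_fraction(1e6, p) == pytest.approx(p.f_high, abs=1e-6)

    def test_monotone_nonincreasing_and_bounded(self):
        p = BindingConfig()
        ladder = np.geomspace(1e-4, 100.0, 100)
        f = np.array([bound_fraction(c, p) for c in ladder])
        assert np.all(np.diff(f) <= 1e-12)
        assert np.all((f >= p.f_high - 1e-12) & (f <= p.f_low + 1e-12))

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            bound_fraction(-0.1, BindingConfig())


class TestSynthSample:
    def test_noiseless_serum_is_base_plus_thermal_leak(self, noiseless_config, grid):
        rec = SampleRecord("s1", "Serum", 0.0, 1, path_length_factor=1.0)
        rng = np.random.default_rng(0)
        m250, m5 = synth_sample(rec, noiseless_config, rng, grid)
        expect = (
            serum_base_map(noiseless_config, grid).amplitudes
            + noiseless_config.thermal.leak
            * thermal_water_map(grid, noiseless_config.thermal.scale).amplitudes
        )
        assert np.abs(m250.amplitudes - expect).max() < 1e-12
        assert np.abs(
            m5.amplitudes - thermal_water_map(grid, 1.0).amplitudes
        ).max() < 1e-12

    def test_same_seed_reproduces_maps_exactly(self, config, grid):
        rec = SampleRecord("c1", "Serum+Cefazolin", 1.2, 1, path_length_factor=1.1)
        a = synth_sample(rec, config, np.random.default_rng(7), grid)
        b = synth_sample(rec, config, np.random.default_rng(7), grid)
        assert np.array_equal(a[0].amplitudes, b[0].amplitudes)
        assert np.array_equal(a[1].amplitudes, b[1].amplitudes)

    def test_perturbation_recovery_noiseless(self, noiseless_config, grid):
        """Generator as its own oracle: (drug - serum)/path_factor equals the
        injected signal to 1e-10."""
        serum = SampleRecord("s", "Serum", 0.0, 1)
        rng = np.random.default_rng(0)
        base, _ = synth_sample(serum, noiseless_config, rng, grid)
        for drug, conc in [("Cefazolin", 1.2), ("Warfarin", 0.03)]:
            rec = SampleRecord("d", f"Serum+{drug}", conc, 1, path_length_factor=1.3)
            m250, _ = synth_sample(rec, noiseless_config, rng, grid)
            diff = m250.amplitudes / 1.3 - base.amplitudes
            inj = injected_signal(rec, noiseless_config, grid).amplitudes
            assert np.abs(diff - inj).max() < 1e-10

    def test_sign_structure_of_serum_maps(self, screening):
        for m in screening.maps_250fs:
            assert m.amplitudes.min() < 0 < m.amplitudes.max()


class TestDesigns:
    def test_screening_set_matches_study_design(self, screening):
        labels = screening.labels
        assert len(screening) == 24
        assert labels.count("Serum") == 12
        for drug in ("Cefazolin", "Ibuprofen", "Paracetamol", "Warfarin"):
            assert labels.count(f"Serum+{drug}") == 3
        concs = {r.class_label: r.drug_conc for r in screening.records}
        assert concs["Serum+Cefazolin"] == 1.2
        assert concs["Serum+Warfarin"] == 0.03

    def test_seed_changes_noise_not_design(self, config):
        a = generate_screening_set(config, seed=1)
        b = generate_screening_set(config, seed=2)
        for ra, rb in zip(a.records, b.records):
            assert (ra.sample_id, ra.class_label, ra.drug_conc, ra.replicate_index) == (
                rb.sample_id,
                rb.class_label,
                rb.drug_conc,
                rb.replicate_index,
            )
        assert not np.array_equal(a.maps_250fs[0].amplitudes, b.maps_250fs[0].amplitudes)

    def test_identical_seed_bitwise_identical(self, config):
        a = generate_screening_set(config, seed=3)
        b = generate_screening_set(config, seed=3)
        for ma, mb in zip(a.maps_250fs, b.maps_250fs):
            assert np.array_equal(ma.amplitudes, mb.amplitudes)

    def test_verification_ladder(self, config):
        ds = generate_verification_set(config, seed=1)
        concs = sorted({r.drug_conc for r in ds.records})
        assert len(ds) == 42
        assert len(concs) == 14
        assert concs[0] == 0.0
        assert concs[1] == pytest.approx(0.0006, rel=1e-9)
        assert concs[-1] == pytest.approx(6.0, rel=1e-9)

    def test_drug_signal_scale_nonmonotone_for_two_regime(self):
        """The occupancy-times-bound-fraction signal peaks near the crossover,
        the mechanism behind the U-shaped ratio profile."""
        p = BindingConfig()  # two-regime cefazolin defaults
        s = [drug_signal_scale(c, p) for c in VERIFICATION_CONCENTRATIONS if c > 0]
        s = np.array(s[::-1])  # ascending concentration
        k = int(np.argmax(s))
        assert 0 < k < len(s) - 1
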