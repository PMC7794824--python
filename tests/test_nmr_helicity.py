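"""Random-coil references, secondary chemical shifts and helicity estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mimscout.nmr_helicity import (
    FULL_HELIX_DELTA_PPM, RandomCoilModel, SCSProfile, default_model, helicity,
    random_coil_shifts, scs_profile,
)
from mimscout.sequence_io import ShiftTable
from mimscout.synthetic_data import ShiftSpec, make_shift_table

MYB29_PEPTIDE = "SSTSKLLNKVAARASS"
ASR3_PEPTIDE = "DSLVAVLNKLADAVAK"


def _identity_model():
    base = default_model()
    return RandomCoilModel(base_shift=base.base_shift,
                           neighbor_corrections={},
                           temperature_coefficient={},
                           reference_temperature_C=25.0,
                           ph_delta={}, pka={}, reference_pH=7.0)


def _profile_from_scs(scs_values):
    """Build an SCSProfile directly from SCS values (indices 1..n)."""
    scs = np.asarray(scs_values, float)
    return SCSProfile(residue_indices=np.arange(1, scs.size + 1),
                      residue_codes=tuple("A" * scs.size),
                      scs_ca_ppm=scs, transient_helix=scs > 0.1)


class TestRandomCoilShifts:
    def test_identity_configuration_returns_base_table(self):
        model = _identity_model()
        shifts = random_coil_shifts("ACDW", model, temperature_C=25.0, pH=7.0)
        expected = [model.base_shift[r] for r in "ACDW"]
        assert np.allclose(shifts, expected)

    def test_proline_neighbor_correction_is_additive(self):
        model = default_model()
        with_pro = random_coil_shifts("PGP", model, 25.0, 7.0)
        with_ala = random_coil_shifts("AGA", model, 25.0, 7.0)
        corr = model.neighbor_corrections
        expected_delta = (corr.get(("P", -1), 0.0) + corr.get(("P", 1), 0.0)
                          - corr.get(("A", -1), 0.0) - corr.get(("A", 1), 0.0))
        assert (with_pro[1] - with_ala[1]) == pytest.approx(expected_delta)

    def test_temperature_and_ph_bounds(self):
        with pytest.raises(ValueError):
            random_coil_shifts("AA", temperature_C=-5.0)
        with pytest.raises(ValueError):
            random_coil_shifts("AA", pH=15.0)

    def test_unknown_residue_named_in_error(self):
        model = default_model()
        del model.base_shift["W"]
        with pytest.raises(ValueError, match="W"):
            random_coil_shifts("AWA", model)


class TestSCSProfile:
    def test_round_trip_from_generator_gives_zero_scs(self):
        spec = ShiftSpec(sequence=MYB29_PEPTIDE,
                         helicity_profile=(0.0,) * 16, noise_sd_ppm=0.0)
        table, _ = make_shift_table(spec)
        profile = scs_profile(table, sequence=MYB29_PEPTIDE)
        assert np.allclose(profile.scs_ca_ppm, 0.0, atol=1e-12)
        assert not profile.transient_helix.any()

    def test_scs_is_linear_in_observed_shift(self):
        spec = ShiftSpec(sequence=ASR3_PEPTIDE,
                         helicity_profile=(0.1,) * 16, noise_sd_ppm=0.0)
        table, _ = make_shift_table(spec)
        shifted = ShiftTable(rows=table.rows.assign(
            ca_shift_ppm=table.rows["ca_shift_ppm"] + 0.36),
            temperature_C=table.temperature_C, pH=table.pH)
        a = scs_profile(table, sequence=ASR3_PEPTIDE)
        b = scs_profile(shifted, sequence=ASR3_PEPTIDE)
        assert np.allclose(b.scs_ca_ppm - a.scs_ca_ppm, 0.36)

    def test_sequence_mismatch_names_index(self):
        spec = ShiftSpec(sequence=MYB29_PEPTIDE, start_index=184,
                         helicity_profile=(0.0,) * 16, noise_sd_ppm=0.0)
        table, _ = make_shift_table(spec)
        wrong = MYB29_PEPTIDE[:5] + "W" + MYB29_PEPTIDE[6:]
        with pytest.raises(ValueError, match="189"):
            scs_profile(table, sequence=wrong, sequence_start=184)

    def test_dip_positions_lower_the_core_scs(self):
        """A mid-peptide helix with the L-N dip yields one transient segment
        whose two core residues sit below their neighbors."""
        bump = tuple(0.12 * np.exp(-((i - 7.5) / 4.0) ** 2) for i in range(16))
        spec = ShiftSpec(sequence=MYB29_PEPTIDE, helicity_profile=bump,
                         dip_positions=(6, 7), noise_sd_ppm=0.0, start_index=184)
        table, _ = make_shift_table(spec)
        profile = scs_profile(table, sequence=MYB29_PEPTIDE, sequence_start=184)
        estimate = helicity(profile)
        assert estimate.helix_segment is not None
        lo, hi = estimate.helix_segment
        assert lo <= 190 <= 191 <= hi
        undipped, _ = make_shift_table(ShiftSpec(
            sequence=MYB29_PEPTIDE, helicity_profile=bump, noise_sd_ppm=0.0,
            start_index=184))
        ref = scs_profile(undipped, sequence=MYB29_PEPTIDE, sequence_start=184)
        assert (profile.scs_ca_ppm[6] < ref.scs_ca_ppm[6])
        assert (profile.scs_ca_ppm[7] < ref.scs_ca_ppm[7])


class TestHelicity:
    def test_printed_anchor_pairs(self):
        assert helicity(_profile_from_scs([0.1, 0.75, 0.2])).fractional_helicity \
            == pytest.approx(0.25)
        assert helicity(_profile_from_scs([0.0, 0.36, 0.1])).fractional_helicity \
            == pytest.approx(0.12)

    def test_zero_profile_has_no_segment(self):
        estimate = helicity(_profile_from_scs([0.0] * 8))
        assert estimate.fractional_helicity == 0.0
        assert estimate.helix_segment is None

    def test_segment_is_contiguous_run_containing_peak(self):
        estimate = helicity(_profile_from_scs([0.0, 0.2, 0.5, 0.2, 0.05, 0.3]))
        assert estimate.helix_segment == (2, 4)

    @given(st.lists(st.floats(min_value=-5, max_value=10,
                              allow_nan=False), min_size=1, max_size=30))
    def test_fraction_clamped_to_unit_interval(self, scs):
        estimate = helicity(_profile_from_scs(scs))
        assert 0.0 <= estimate.fractional_helicity <= 1.0

    @given(st.lists(st.floats(min_value=-2, max_value=2, allow_nan=False),
                    min_size=1, max_size=20),
           st.integers(min_value=0, max_value=19),
           st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_every_scs_value(self, scs, pos, bump):
        if pos >= len(scs):
            pos = len(scs) - 1
        base = helicity(_profile_from_scs(scs)).fractional_helicity
        raised = list(scs)
        raised[pos] += bump
        assert helicity(_profile_from_scs(raised)).fractional_helicity >= base

    def test_parameter_recovery_at_experimental_noise(self):
        """True helicity 0.05-0.5 recovered within +-0.02 at sigma=0.02 ppm."""
        for true_h in (0.05, 0.12, 0.25, 0.5):
            estimates = []
            for rep in range(50):
                bump = tuple(true_h * np.exp(-((i - 8) / 4.0) ** 2)
                             for i in range(16))
                table, _ = make_shift_table(ShiftSpec(
                    sequence=MYB29_PEPTIDE, helicity_profile=bump,
                    noise_sd_ppm=0.02, rng_seed=rep))
                profile = scs_profile(table, sequence=MYB29_PEPTIDE)
                estimates.append(helicity(profile).fractional_helicity)
            assert abs(np.mean(estimates) - true_h) <= 0.02

    def test_flat_quarter_profile_reproduces_peak_anchor(self):
        table, true_h = make_shift_table(ShiftSpec(
            sequence=ASR3_PEPTIDE, helicity_profile=(0.25,) * 16,
            noise_sd_ppm=0.0))
        profile = scs_profile(table, sequence=ASR3_PEPTIDE)
        assert profile.scs_ca_ppm.max() == pytest.approx(0.75)
        assert helicity(profile).fractional_helicity == pytest.approx(0.25)
        assert true_h == pytest.approx(0.25)
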