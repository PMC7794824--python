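"""C-alpha secondary chemical shifts and transient-helix fraction estimation.

The secondary chemical shift (SCS) of a residue is its observed C-alpha shift
minus a sequence-corrected random-coil reference.  Positive C-alpha SCS marks
helical propensity; values above 0.1 ppm are called transiently helical.
Fractional helicity is estimated from the peak SCS divided by the full-helix
shift difference of 3.0 ppm, the value at which the two printed anchor pairs
(0.75 ppm -> ~25%, 0.36 ppm -> ~12%) are reproduced exactly.

The packaged random-coil model follows the magnitudes of the standard
intrinsically-disordered-protein reference sets: per-residue base shifts,
additive neighbor corrections for positions -2..+2 (dominated by the
following proline), a small uniform temperature coefficient, and a
Henderson-Hasselbalch pH correction for the ionizable residues.  Synthetic
shift tables in this package are generated from this same model, so secondary
shifts round-trip exactly regardless of which published table edition the
base values follow.  Negative SCS (extended propensity) is reported but never
converted to a strand fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sequence_io import CANONICAL_RESIDUES, ShiftTable

__all__ = [
    "TRANSIENT_HELIX_THRESHOLD_PPM",
    "FULL_HELIX_DELTA_PPM",
    "RandomCoilModel",
    "SCSProfile",
    "HelicityEstimate",
    "default_model",
    "random_coil_shifts",
    "scs_profile",
    "helicity",
]

#: C-alpha SCS above this value is called transiently helical (ppm).
TRANSIENT_HELIX_THRESHOLD_PPM = 0.1

#: C-alpha secondary shift of a fully formed helix (ppm); divides the peak SCS
#: to give fractional helicity and reproduces both printed anchors exactly.
FULL_HELIX_DELTA_PPM = 3.0

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

# Random-coil C-alpha base shifts (ppm) in the magnitude range of the standard
# sequence-corrected IDP reference sets (neutral pH, 25 degC reference).
_BASE_CA_SHIFT = {
    "A": 52.77, "C": 58.46, "D": 54.42, "E": 56.74, "F": 57.91,
    "G": 45.36, "H": 55.92, "I": 61.27, "K": 56.54, "L": 55.23,
    "M": 55.55, "N": 53.33, "P": 63.22, "Q": 55.95, "R": 56.16,
    "S": 58.49, "T": 62.03, "V": 62.37, "W": 57.60, "Y": 58.05,
}

# Additive neighbor corrections, keyed (neighbor residue, offset): the residue
# at position i+offset being that neighbor shifts residue i's C-alpha.  The
# dominant effect is the following proline; unparameterized pairs are 0.
_NEIGHBOR_CORRECTIONS = {
    ("P", +1): -1.85,
    ("P", +2): -0.10,
    ("G", -1): +0.05,
    ("G", +1): +0.05,
}

# Full-deprotonation C-alpha changes (ppm) and pKa values for the pH
# correction of the ionizable residues.
_PH_DELTA = {"D": 1.85, "E": 0.55, "H": 1.30, "C": 2.00}
_PKA = {"D": 3.86, "E": 4.34, "H": 6.45, "C": 8.49}


@dataclass(frozen=True)
class RandomCoilModel:
    """Sequence-corrected random-coil C-alpha reference model.

    ``base_shift`` must cover every canonical residue; the correction tables
    default to 0 where unparameterized.  ``temperature_coefficient`` is in
    ppm per degC relative to ``reference_temperature_C``; the pH correction is
    a Henderson-Hasselbalch interpolation of ``ph_delta`` between the
    protonation states, relative to ``reference_pH``.
    """

    base_shift: dict
    neighbor_corrections: dict = field(default_factory=dict)
    temperature_coefficient: dict = field(default_factory=dict)
    reference_temperature_C: float = 25.0
    ph_delta: dict = field(default_factory=dict)
    pka: dict = field(default_factory=dict)
    reference_pH: float = 7.0

    def __post_init__(self) -> None:
        missing = sorted(_CANONICAL_SET - set(self.base_shift))
        if missing:
            raise ValueError(f"base_shift table missing residue(s) {missing}")


def default_model() -> RandomCoilModel:
    """The packaged random-coil model (see module docstring)."""
    return RandomCoilModel(
        base_shift=dict(_BASE_CA_SHIFT),
        neighbor_corrections=dict(_NEIGHBOR_CORRECTIONS),
        temperature_coefficient={aa: -0.0015 for aa in CANONICAL_RESIDUES},
        reference_temperature_C=25.0,
        ph_delta=dict(_PH_DELTA),
        pka=dict(_PKA),
        reference_pH=7.0,
    )


def _ph_fraction(pka: float, ph: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def random_coil_shifts(sequence: str, model: Optional[RandomCoilModel] = None,
                       temperature_C: float = 5.0, pH: float = 7.0) -> np.ndarray:
    """Predicted random-coil C-alpha shifts (ppm) for each residue.

    Per residue: base shift + neighbor corrections for the residues at
    offsets -2..+2 (neighbors beyond the termini contribute 0) + the
    temperature term + the pH correction.
    """
    if model is None:
        model = default_model()
    if not 0.0 < temperature_C < 100.0:
        raise ValueError(f"temperature_C must be in (0, 100), got {temperature_C}")
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must be in (0, 14), got {pH}")
    sequence = sequence.upper()
    shifts = np.empty(len(sequence))
    dT = temperature_C - model.reference_temperature_C
    for i, residue in enumerate(sequence):
        if residue not in model.base_shift:
            raise ValueError(f"residue {residue!r} missing from the random-coil table")
        value = model.base_shift[residue]
        for offset in (-2, -1, 1, 2):
            j = i + offset
            if 0 <= j < len(sequence):
                value += model.neighbor_corrections.get((sequence[j], offset), 0.0)
        value += model.temperature_coefficient.get(residue, 0.0) * dT
        delta = model.ph_delta.get(residue)
        if delta is not None:
            pka = model.pka.get(residue)
            if pka is not None:
                value += delta * (_ph_fraction(pka, pH)
                                  - _ph_fraction(pka, model.reference_pH))
        shifts[i] = value
    return shifts


@dataclass(frozen=True)
class SCSProfile:
    """Per-residue C-alpha secondary chemical shifts and transient-helix calls."""

    residue_indices: np.ndarray
    residue_codes: tuple
    scs_ca_ppm: np.ndarray
    transient_helix: np.ndarray
    threshold_ppm: float = TRANSIENT_HELIX_THRESHOLD_PPM

    def __len__(self) -> int:
        return self.scs_ca_ppm.size


def scs_profile(shifts: ShiftTable, model: Optional[RandomCoilModel] = None,
                sequence: Optional[str] = None,
                sequence_start: Optional[int] = None) -> SCSProfile:
    """Secondary chemical shifts: observed minus sequence-corrected random coil.

    If ``sequence`` is given it supplies the neighbor context;
    ``sequence_start`` is the residue_index of its first residue (default: the
    table's first index).  Every table row must agree with the sequence at its
    index, otherwise an error names the offending index.  Without a sequence,
    the table must be contiguous and its own residue codes are used.
    """
    if model is None:
        model = default_model()
    rows = shifts.rows
    indices = rows["residue_index"].to_numpy()
    codes = rows["residue_code"].tolist()
    if sequence is None:
        if len(indices) and not (np.diff(indices) == 1).all():
            raise ValueError(
                "shift table is not contiguous; supply the peptide sequence")
        sequence = "".join(codes)
        sequence_start = int(indices[0]) if len(indices) else 1
    else:
        sequence = sequence.upper()
        if sequence_start is None:
            sequence_start = int(indices[0]) if len(indices) else 1
        for idx, code in zip(indices, codes):
            pos = idx - sequence_start
            if not 0 <= pos < len(sequence):
                raise ValueError(f"residue_index {idx} outside the supplied sequence")
            if sequence[pos] != code:
                raise ValueError(
                    f"sequence/table mismatch at residue_index {idx}: "
                    f"table has {code!r}, sequence has {sequence[pos]!r}")
    coil = random_coil_shifts(sequence, model, shifts.temperature_C, shifts.pH)
    positions = indices - sequence_start
    scs = rows["ca_shift_ppm"].to_numpy() - coil[positions]
    return SCSProfile(residue_indices=indices.copy(), residue_codes=tuple(codes),
                      scs_ca_ppm=scs,
                      transient_helix=scs > TRANSIENT_HELIX_THRESHOLD_PPM)


@dataclass(frozen=True)
class HelicityEstimate:
    """Fractional helicity derived from an SCS profile.

    ``helix_segment`` is the (first, last) residue_index of the contiguous
    transient-helix run containing the peak, or ``None`` when the peak does
    not exceed the transient threshold.
    """

    peak_scs_ppm: float
    fractional_helicity: float
    helix_segment: Optional[tuple]


def helicity(profile: SCSProfile, full_helix_delta: float = FULL_HELIX_DELTA_PPM,
             use_segment_mean: bool = False) -> HelicityEstimate:
    """Estimate fractional helicity from an SCS profile.

    The default estimator divides the peak (maximum) SCS by the full-helix
    delta and clamps to [0, 1]; ``use_segment_mean`` instead averages the SCS
    over the transient-helix segment containing the peak.
    """
    if len(profile) == 0:
        raise ValueError("cannot estimate helicity from an empty SCS profile")
    peak_pos = int(np.argmax(profile.scs_ca_ppm))
    peak = float(profile.scs_ca_ppm[peak_pos])
    segment = None
    value = peak
    if peak > profile.threshold_ppm:
        lo = hi = peak_pos
        while lo > 0 and profile.transient_helix[lo - 1]:
            lo -= 1
        while hi + 1 < len(profile) and profile.transient_helix[hi + 1]:
            hi += 1
        segment = (int(profile.residue_indices[lo]), int(profile.residue_indices[hi]))
        if use_segment_mean:
            value = float(profile.scs_ca_ppm[lo:hi + 1].mean())
    fraction = float(np.clip(value / full_helix_delta, 0.0, 1.0))
    return HelicityEstimate(peak_scs_ppm=peak, fractional_helicity=fraction,
                            helix_segment=segment)
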