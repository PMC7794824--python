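"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the study conditions the pipeline is meant to
handle, without any external downloads:

* :func:`make_proteome` — protein records composed of an order-biased segment
  followed by a disorder-biased segment, with a motif instance planted either
  inside the disordered segment with rewritten hydrophilic flanks
  (``r2r3_like``, emulating confirmed motif contexts), inside the ordered
  segment (``trihelix_like``, emulating the false-positive context), or not
  at all (``negative``, rejection-sampled to be free of chance core matches).
* :func:`make_msa` — alignments derived from one ancestral row by i.i.d.
  per-column substitution, with separate rates for motif and flank columns.
* :func:`make_shift_table` — C-alpha shift tables equal to the packaged
  random-coil reference plus a helix contribution scaled by a per-residue
  helicity profile, plus Gaussian noise.

All generators are fully deterministic for a fixed seed.  The composition
vectors are package choices calibrated so the packaged disorder proxy
separates the two segment types by at least 0.2; the substitution model has
no phylogeny — sufficient for testing the conservation contrast, no more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motif_scan import MotifPattern, MotifHit, get_pattern, scan
from .nmr_helicity import FULL_HELIX_DELTA_PPM, RandomCoilModel, default_model, \
    random_coil_shifts
from .sequence_io import CANONICAL_RESIDUES, SequenceRecord, ShiftTable, AlignedSet

__all__ = [
    "IDR_COMPOSITION",
    "ORDERED_COMPOSITION",
    "MOTIF_FLANK_COMPOSITION",
    "ContextSpec",
    "MSASpec",
    "ShiftSpec",
    "make_proteome",
    "make_msa",
    "make_shift_table",
]

#: Disorder-biased segment composition (enriched P, E, S, K, G, Q, R).  No
#: L or A, so the hexamer core pattern cannot arise there by chance.
IDR_COMPOSITION = {
    "P": 0.20, "E": 0.22, "S": 0.18, "K": 0.14, "G": 0.10,
    "Q": 0.06, "R": 0.05, "T": 0.03, "D": 0.01, "N": 0.01,
}

#: Order-biased segment composition (enriched L, V, I, F, W, A).
ORDERED_COMPOSITION = {
    "L": 0.16, "V": 0.13, "I": 0.11, "A": 0.15, "F": 0.09,
    "M": 0.05, "Y": 0.05, "G": 0.06, "T": 0.05, "S": 0.05,
    "W": 0.04, "D": 0.03, "E": 0.02, "Q": 0.02, "C": 0.02,
    "H": 0.01, "N": 0.005, "K": 0.005, "R": 0.005, "P": 0.005,
}

#: Rewritten-flank composition for r2r3_like records: 0.15 of its mass on
#: P/S/T and the rest on small hydrophilic filler, with no R/K/D/E so the
#: planted motif's basic residue dominates the local net charge.
MOTIF_FLANK_COMPOSITION = {
    "P": 0.06, "S": 0.06, "T": 0.03, "G": 0.30, "Q": 0.30, "N": 0.25,
}

_REWRITE_FLANK = 15  # residues rewritten on each side of a planted r2r3 motif
_SEGMENT_MARGIN = 15  # minimum distance of a planted motif from segment edges


def _normalized(composition: dict) -> tuple[np.ndarray, np.ndarray]:
    letters = sorted(composition)
    probs = np.array([composition[a] for a in letters], float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("composition frequencies must be non-negative, sum > 0")
    return np.array(letters), probs / probs.sum()


def _draw(composition: dict, n: int, rng: np.random.Generator) -> str:
    letters, probs = _normalized(composition)
    return "".join(rng.choice(letters, size=n, p=probs))


def _sample_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for allowed in pattern.positions:
        choices = sorted(allowed) if allowed is not None else list(CANONICAL_RESIDUES)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


@dataclass(frozen=True)
class ContextSpec:
    """Parameters of one synthetic sequence-context class.

    ``kind`` selects where (and whether) a motif is planted; ``flank_bias`` is
    the target mean of the ``+PST-RK`` track over the rewritten flanks of
    r2r3_like records (realized through the flank composition).
    """

    kind: str
    idr_length: int = 120
    ordered_length: int = 80
    idr_composition: dict = field(default_factory=lambda: dict(IDR_COMPOSITION))
    ordered_composition: dict = field(default_factory=lambda: dict(ORDERED_COMPOSITION))
    flank_composition: dict = field(default_factory=lambda: dict(MOTIF_FLANK_COMPOSITION))
    motif_pattern: Optional[str] = None
    flank_bias: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("r2r3_like", "trihelix_like", "negative"):
            raise ValueError(f"unknown context kind {self.kind!r}")
        if self.idr_length < 1 or self.ordered_length < 1:
            raise ValueError("segment lengths must be >= 1")

    def pattern(self) -> Optional[MotifPattern]:
        if self.kind == "negative":
            return None
        if self.motif_pattern is not None:
            return get_pattern(self.motif_pattern)
        return get_pattern("strict" if self.kind == "r2r3_like" else "core")


_MAX_REJECTIONS = 1000


def make_proteome(specs: Sequence[ContextSpec], n_per_spec: int, rng_seed: int,
                  ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate synthetic records plus a truth table of planted motif hits.

    Each record is an ordered segment followed by a disordered segment; for
    motif-bearing kinds one pattern instance (residues sampled uniformly from
    the allowed sets) replaces residues at a uniformly chosen in-segment
    position, at least 15 residues from the segment edges.  ``negative``
    records are redrawn (up to 1000 times) until they contain no core-pattern
    match.  The truth table has one row per planted instance (identifier,
    start, end, kind, motif), with 1-based inclusive coordinates.
    """
    if n_per_spec < 1:
        raise ValueError("n_per_spec must be >= 1")
    rng = np.random.default_rng(rng_seed)
    core = get_pattern("core")
    records: list[SequenceRecord] = []
    truth_rows = []
    kind_counts = {}
    for spec in specs:
        kind_counts[spec.kind] = kind_counts.get(spec.kind, 0) + 1
    seen_kinds = {}
    for spec in specs:
        seen_kinds[spec.kind] = seen_kinds.get(spec.kind, 0) + 1
        tag = (spec.kind if kind_counts[spec.kind] == 1
               else f"{spec.kind}{seen_kinds[spec.kind]}")
        for i in range(n_per_spec):
            identifier = f"{tag}_{i + 1:03d}"
            if spec.kind == "negative":
                for _ in range(_MAX_REJECTIONS):
                    seq = (_draw(spec.ordered_composition, spec.ordered_length, rng)
                           + _draw(spec.idr_composition, spec.idr_length, rng))
                    if not scan(seq, core):
                        break
                else:
                    raise RuntimeError(
                        "rejection sampling failed 1000 times; adjust the "
                        "composition so chance core matches are rarer")
                records.append(SequenceRecord(identifier=identifier, residues=seq))
                continue

            ordered = _draw(spec.ordered_composition, spec.ordered_length, rng)
            idr = _draw(spec.idr_composition, spec.idr_length, rng)
            pattern = spec.pattern()
            motif = _sample_motif(pattern, rng)
            m = len(motif)
            if spec.kind == "r2r3_like":
                lo, hi = _SEGMENT_MARGIN, spec.idr_length - m - _SEGMENT_MARGIN
                if hi < lo:
                    raise ValueError("idr_length too short to plant a flanked motif")
                pos = int(rng.integers(lo, hi + 1))  # 0-based within the IDR
                left = _draw(spec.flank_composition, _REWRITE_FLANK, rng)
                right = _draw(spec.flank_composition, _REWRITE_FLANK, rng)
                idr = (idr[:pos - _REWRITE_FLANK] + left + motif + right
                       + idr[pos + m + _REWRITE_FLANK:])
                seq = ordered + idr
                start0 = spec.ordered_length + pos
            else:  # trihelix_like: motif inside the ordered segment
                lo, hi = _SEGMENT_MARGIN, spec.ordered_length - m - _SEGMENT_MARGIN
                if hi < lo:
                    raise ValueError("ordered_length too short to plant a motif")
                pos = int(rng.integers(lo, hi + 1))
                ordered = ordered[:pos] + motif + ordered[pos + m:]
                seq = ordered + idr
                start0 = pos
            records.append(SequenceRecord(identifier=identifier, residues=seq))
            truth_rows.append({"identifier": identifier, "start": start0 + 1,
                               "end": start0 + m, "kind": spec.kind,
                               "motif": motif})
    truth = pd.DataFrame(truth_rows,
                         columns=["identifier", "start", "end", "kind", "motif"])
    return records, truth


@dataclass(frozen=True)
class MSASpec:
    """Parameters of a synthetic alignment with controlled column conservation."""

    n_sequences: int = 20
    n_columns: int = 60
    motif_columns: frozenset = frozenset(range(27, 33))
    motif_substitution_rate: float = 0.05
    flank_substitution_rate: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.motif_substitution_rate, self.flank_substitution_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("substitution rates must lie in [0, 1]")
        if self.motif_columns and (min(self.motif_columns) < 0
                                   or max(self.motif_columns) >= self.n_columns):
            raise ValueError("motif_columns outside the alignment")


def make_msa(spec: MSASpec) -> tuple[AlignedSet, dict]:
    """Generate an alignment from one ancestral row by i.i.d. substitution.

    Every row copies a uniformly sampled ancestral row; each column is
    substituted independently with its column-class rate, the replacement
    drawn uniformly from the other 19 residues.  Returns the alignment and a
    truth dict with the motif/flank column index sets (0-based).
    """
    rng = np.random.default_rng(spec.rng_seed)
    alphabet = np.array(list(CANONICAL_RESIDUES))
    ancestral = rng.integers(20, size=spec.n_columns)
    motif_cols = np.zeros(spec.n_columns, bool)
    motif_cols[sorted(spec.motif_columns)] = True
    rates = np.where(motif_cols, spec.motif_substitution_rate,
                     spec.flank_substitution_rate)
    records = []
    for i in range(spec.n_sequences):
        row = ancestral.copy()
        substitute = rng.random(spec.n_columns) < rates
        # Uniform draw from the other 19 residues.
        offsets = rng.integers(1, 20, size=spec.n_columns)
        row[substitute] = (row[substitute] + offsets[substitute]) % 20
        records.append(SequenceRecord(identifier=f"seq_{i + 1:03d}",
                                      residues="".join(alphabet[row])))
    aln = AlignedSet(records=tuple(records), column_count=spec.n_columns)
    truth = {"motif_columns": frozenset(np.flatnonzero(motif_cols).tolist()),
             "flank_columns": frozenset(np.flatnonzero(~motif_cols).tolist())}
    return aln, truth


@dataclass(frozen=True)
class ShiftSpec:
    """Parameters of a synthetic C-alpha shift table with known helicity.

    ``helicity_profile`` gives the per-residue helical population in [0, 1];
    ``dip_positions`` (0-based positions in the sequence) have their local
    helicity multiplied by 0.8, emulating the small dip observed at the
    motif's L-N core residues.  ``start_index`` numbers the first residue.
    """

    sequence: str
    helicity_profile: tuple
    dip_positions: Optional[tuple] = None
    noise_sd_ppm: float = 0.02
    temperature_C: float = 5.0
    pH: float = 7.0
    rng_seed: int = 0
    start_index: int = 1

    def __post_init__(self) -> None:
        if len(self.helicity_profile) != len(self.sequence):
            raise ValueError("helicity_profile length must equal sequence length")
        profile = np.asarray(self.helicity_profile, float)
        if (profile < 0).any() or (profile > 1).any():
            raise ValueError("helicity_profile values must lie in [0, 1]")
        if self.noise_sd_ppm < 0:
            raise ValueError("noise_sd_ppm must be >= 0")


_DIP_FACTOR = 0.8


def make_shift_table(spec: ShiftSpec, model: Optional[RandomCoilModel] = None,
                     ) -> tuple[ShiftTable, float]:
    """Generate a shift table from the random-coil model plus a helix term.

    Observed C-alpha = random coil + helicity_profile * 3.0 ppm + Gaussian
    noise.  Returns the table and the true (peak) helicity after applying the
    dip factor.
    """
    if model is None:
        model = default_model()
    rng = np.random.default_rng(spec.rng_seed)
    profile = np.asarray(spec.helicity_profile, float).copy()
    if spec.dip_positions is not None:
        for pos in spec.dip_positions:
            if not 0 <= pos < profile.size:
                raise ValueError(f"dip position {pos} outside the sequence")
            profile[pos] *= _DIP_FACTOR
    coil = random_coil_shifts(spec.sequence, model, spec.temperature_C, spec.pH)
    observed = coil + profile * FULL_HELIX_DELTA_PPM
    if spec.noise_sd_ppm > 0:
        observed = observed + rng.normal(0.0, spec.noise_sd_ppm, size=observed.size)
    rows = pd.DataFrame({
        "residue_index": np.arange(len(spec.sequence)) + spec.start_index,
        "residue_code": list(spec.sequence.upper()),
        "ca_shift_ppm": observed,
    })
    table = ShiftTable(rows=rows, temperature_C=spec.temperature_C, pH=spec.pH)
    return table, float(profile.max()) if profile.size else 0.0
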