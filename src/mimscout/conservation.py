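"""Alignment-column conservation and the motif-vs-flank contrast statistic.

Column conservation follows the strict >50% consensus convention used in
shaded-alignment figures: a column has a consensus residue only when one
residue occupies strictly more than half of its non-gap entries.  The
motif-vs-flank contrast formalizes the visual observation that a genuine
short linear motif stands out as more conserved than the rapidly evolving
region around it: it is the difference in mean identity fraction between
motif columns and flank columns, with significance from a label-permutation
null (columns exchangeable between the two sets).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .sequence_io import GAP, MASK, AlignedSet

__all__ = [
    "DEFAULT_SIMILARITY_GROUPS",
    "ColumnConservation",
    "ConservationContrast",
    "column_conservation",
    "motif_flank_contrast",
]

#: Standard physicochemical partition of the 20 residues used for the
#: "similar" call; configurable because shading tools do not publish theirs.
DEFAULT_SIMILARITY_GROUPS = ("AVLIM", "FWY", "ST", "KR", "DE", "NQ", "C", "G", "P", "H")


@dataclass(frozen=True)
class ColumnConservation:
    """Conservation summary of one alignment column.

    ``identity_fraction`` is the plurality-residue share of the non-gap
    entries (0 for all-gap columns), so it is defined for every column.
    ``consensus_residue`` is set only under the strict >50% rule.  The class
    is ``consensus-identical`` when every non-gap residue equals the
    consensus, ``consensus-similar`` when every non-gap residue is at least
    similar to it, ``unconserved`` when a consensus exists but some residues
    are dissimilar, and ``no-consensus`` otherwise.
    """

    consensus_residue: Optional[str]
    identity_fraction: float
    similarity_fraction: float
    column_class: str


@dataclass(frozen=True)
class ConservationContrast:
    """Motif-vs-flank conservation contrast with a permutation p-value."""

    motif_mean: float
    flank_mean: float
    contrast: float
    permutation_p: float
    permutations: int


def _group_lookup(similarity_groups: Sequence[str]) -> dict:
    lookup = {}
    for group in similarity_groups:
        for residue in group:
            lookup[residue.upper()] = group
    return lookup


def column_conservation(msa: AlignedSet,
                        similarity_groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
                        ) -> list[ColumnConservation]:
    """Per-column conservation of an alignment (>=2 sequences required).

    Gaps (and masked residues) are excluded from the denominator; all-gap
    columns are classed ``no-consensus`` with identity 0.
    """
    if len(msa.records) < 2:
        raise ValueError("conservation is undefined for a single-sequence alignment")
    lookup = _group_lookup(similarity_groups)
    out = []
    for col in range(msa.column_count):
        entries = [r for r in msa.column(col) if r not in (GAP, MASK)]
        if not entries:
            out.append(ColumnConservation(None, 0.0, 0.0, "no-consensus"))
            continue
        counts = Counter(entries)
        top = max(counts.values())
        modal = min(r for r, c in counts.items() if c == top)  # deterministic ties
        n = len(entries)
        identity = top / n
        group = lookup.get(modal, modal)
        similar = sum(c for r, c in counts.items()
                      if r == modal or lookup.get(r, r) == group)
        similarity = similar / n
        if identity > 0.5:
            if identity == 1.0:
                cls = "consensus-identical"
            elif similarity == 1.0:
                cls = "consensus-similar"
            else:
                cls = "unconserved"
            out.append(ColumnConservation(modal, identity, similarity, cls))
        else:
            out.append(ColumnConservation(None, identity, similarity, "no-consensus"))
    return out


def motif_flank_contrast(msa: AlignedSet, motif_columns: Iterable[int],
                         flank_columns: Iterable[int], permutations: int = 1000,
                         seed_rng: int = 0,
                         similarity_groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS,
                         ) -> ConservationContrast:
    """Contrast motif-column vs flank-column identity with a permutation null.

    Column indices are 0-based.  The statistic is
    ``mean(identity[motif]) - mean(identity[flank])``; the p-value is
    ``(1 + #{permuted contrasts >= observed}) / (1 + permutations)`` under
    random relabeling of the pooled columns, so it is never exactly 0.
    """
    motif = sorted(set(motif_columns))
    flank = sorted(set(flank_columns))
    if not motif or not flank:
        raise ValueError("motif and flank column sets must both be non-empty")
    overlap = set(motif) & set(flank)
    if overlap:
        raise ValueError(f"motif and flank column sets overlap: {sorted(overlap)}")
    for col in motif + flank:
        if not 0 <= col < msa.column_count:
            raise ValueError(f"column index {col} outside alignment of width "
                             f"{msa.column_count}")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")

    conservation = column_conservation(msa, similarity_groups)
    identity = np.array([c.identity_fraction for c in conservation])
    motif_mean = float(identity[motif].mean())
    flank_mean = float(identity[flank].mean())
    observed = motif_mean - flank_mean

    pooled = identity[motif + flank]
    n, k = pooled.size, len(motif)
    rng = np.random.default_rng(seed_rng)
    # Vectorized label permutations: the first k entries of each random order
    # play the role of the motif columns.
    order = np.argsort(rng.random((permutations, n)), axis=1)
    perm_motif = pooled[order[:, :k]].mean(axis=1)
    total = pooled.sum()
    perm_flank = (total - perm_motif * k) / (n - k)
    perm_contrast = perm_motif - perm_flank
    exceed = int(np.count_nonzero(perm_contrast >= observed - 1e-12))
    p = (1 + exceed) / (1 + permutations)
    return ConservationContrast(motif_mean=motif_mean, flank_mean=flank_mean,
                                contrast=observed, permutation_p=p,
                                permutations=permutations)
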