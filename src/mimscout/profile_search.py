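"""Position-specific scoring models with empirical significance.

A seed alignment of ungapped motif-region windows (the 6-residue motif plus
0-20 flanking residues on each side) is turned into a log-odds profile, which
is slid over a sequence database.  Window scores are converted to E-values
against an empirical null built from per-sequence shuffles of the database
itself, and significant hits are fed back into the seed for iterative
refinement, in the spirit of iterative profile search tools.

Significance is empirical rather than analytic: the null distribution is the
score distribution over windows of Fisher-Yates-shuffled database sequences
(default 100,000 windows), with the tail beyond the observed 99th percentile
extrapolated by an exponential fit to the top 1% of null scores.  The E-value
of a window score ``s`` is ``N_windows * P_null(score >= s)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .motif_scan import MotifHit
from .sequence_io import CANONICAL_RESIDUES, MASK, SequenceRecord

__all__ = [
    "NEUTRAL",
    "SeedAlignment",
    "ProfileModel",
    "ProfileHit",
    "FlankSweepResult",
    "build_seed",
    "estimate_profile",
    "database_background",
    "uniform_background",
    "score_windows",
    "search",
    "flank_sweep",
]

#: Neutral padding symbol for seed windows truncated by sequence termini.
#: It contributes background frequencies when counting and scores 0 bits.
NEUTRAL = MASK

_ALPHABET = CANONICAL_RESIDUES
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_NEUTRAL_INDEX = len(_ALPHABET)  # sentinel row scored 0 bits

MAX_FLANK = 20


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(r, _NEUTRAL_INDEX) for r in residues),
                       dtype=np.int64, count=len(residues))


@dataclass(frozen=True)
class SeedAlignment:
    """Equal-length ungapped motif-region windows used to estimate a profile.

    Each member has length ``6 + 2*flank`` (motif length + flanks); members
    truncated by sequence termini are padded with :data:`NEUTRAL`.
    ``motif_offset`` is the 1-based start of the motif within each member.
    """

    members: tuple[str, ...]
    flank: int
    motif_offset: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a seed alignment needs at least one member")
        width = len(self.members[0])
        for m in self.members:
            if len(m) != width:
                raise ValueError("seed members must share one length")

    @property
    def width(self) -> int:
        return len(self.members[0])


@dataclass(frozen=True)
class ProfileModel:
    """A per-column log2-odds matrix over the 20 canonical residues.

    ``log_odds`` has shape (length, 21); the last column is the neutral symbol,
    fixed at 0 bits.  ``member_windows`` records the windows the profile was
    estimated from, so iterative search can append hits and re-estimate.
    """

    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    member_windows: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Recover the (length, 20) column probability matrix."""
        return np.exp2(self.log_odds[:, :20]) * self.background[None, :]


@dataclass(frozen=True)
class ProfileHit:
    """A significant profile match (1-based window start)."""

    sequence_id: str
    start: int
    score: float
    evalue: float
    iteration_found: int


def build_seed(records: Sequence[SequenceRecord], core_hits: Sequence[MotifHit],
               flank: int) -> SeedAlignment:
    """Extract motif-plus-flank windows around each hit.

    Windows reaching past a sequence terminus are padded with the neutral
    symbol, which contributes background frequencies to its columns.
    """
    if not 0 <= flank <= MAX_FLANK:
        raise ValueError(f"flank must be within 0-{MAX_FLANK}, got {flank}")
    if not core_hits:
        raise ValueError("cannot build a seed alignment from an empty hit list")
    by_id = {r.identifier: r for r in records}
    members = []
    for hit in core_hits:
        try:
            rec = by_id[hit.sequence_id]
        except KeyError:
            raise ValueError(f"hit references unknown record {hit.sequence_id!r}")
        if hit.start < 1 or hit.end > len(rec.residues):
            raise ValueError(
                f"hit {hit.start}-{hit.end} lies outside record {rec.identifier!r}")
        lo = hit.start - 1 - flank
        hi = hit.end + flank  # slice end, 0-based exclusive
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(rec.residues))
        members.append(NEUTRAL * left_pad
                       + rec.residues[max(0, lo):min(len(rec.residues), hi)]
                       + NEUTRAL * right_pad)
    return SeedAlignment(members=tuple(members), flank=flank, motif_offset=flank + 1)


def uniform_background() -> np.ndarray:
    """Uniform residue frequencies (1/20 each)."""
    return np.full(20, 1.0 / 20.0)


def database_background(records: Iterable[SequenceRecord]) -> np.ndarray:
    """Residue frequencies of a database, add-one smoothed so none is zero."""
    counts = np.ones(20)
    for rec in records:
        enc = _encode(rec.residues)
        counts += np.bincount(enc[enc < 20], minlength=20)
    return counts / counts.sum()


def estimate_profile(seed: SeedAlignment, pseudocount: float = 0.5,
                     background: Optional[np.ndarray] = None) -> ProfileModel:
    """Estimate a log-odds profile from a seed alignment.

    Column probabilities are ``(count(aa) + pad*q(aa) + pseudocount*q(aa)) /
    (members + pseudocount)``: each real residue adds one count, each neutral
    pad adds the background vector, and a Jeffreys-style pseudocount smooths
    the rest.  Probabilities in every column sum to 1.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    q = uniform_background() if background is None else np.asarray(background, float)
    if q.shape != (20,) or not math.isclose(q.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 20-vector of frequencies summing to 1")
    if (q <= 0).any():
        raise ValueError("background frequencies must all be positive")
    width = seed.width
    counts = np.zeros((width, 20))
    for member in seed.members:
        enc = _encode(member)
        real = enc < 20
        counts[np.flatnonzero(real), enc[real]] += 1.0
        counts[~real] += q[None, :]
    probs = (counts + pseudocount * q[None, :]) / (len(seed.members) + pseudocount)
    log_odds = np.zeros((width, 21))
    log_odds[:, :20] = np.log2(probs / q[None, :])
    return ProfileModel(log_odds=log_odds, background=q, pseudocount=pseudocount,
                        member_windows=tuple(seed.members))


def score_windows(model: ProfileModel, residues: str) -> np.ndarray:
    """Score every length-L window of ``residues``; returns an array of bits."""
    enc = _encode(residues)
    length = len(model)
    if enc.size < length:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, length)
    return model.log_odds[np.arange(length)[None, :], windows].sum(axis=1)


def _null_scores(model: ProfileModel, shuffled: Sequence[np.ndarray]) -> np.ndarray:
    length = len(model)
    cols = np.arange(length)[None, :]
    parts = []
    for enc in shuffled:
        if enc.size < length:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, length)
        parts.append(model.log_odds[cols, windows].sum(axis=1))
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def _tail_pvalues(scores: np.ndarray, null: np.ndarray) -> np.ndarray:
    """P(null >= s): empirical below the 99th percentile, exponential beyond.

    The exponential rate is the mean excess of the top 1% of null scores over
    the 99th-percentile threshold, so the p-value is continuous and monotone
    non-increasing in the score.
    """
    null_sorted = np.sort(null)
    m = null_sorted.size
    s0 = float(np.quantile(null_sorted, 0.99))
    excess = null_sorted[null_sorted > s0] - s0
    p0 = excess.size / m
    beta = float(excess.mean()) if excess.size else 0.0
    counts = m - np.searchsorted(null_sorted, scores, side="left")
    p_emp = counts / m
    if beta > 0 and p0 > 0:
        p_tail = p0 * np.exp(-(scores - s0) / beta)
        return np.where(scores > s0, np.minimum(p_emp + 0.0, p_tail), p_emp)
    return np.where(scores > s0, np.maximum(p_emp, 1.0 / m / 10.0), p_emp)


def search(db: Sequence[SequenceRecord], model: ProfileModel,
           exclude_taxa: Iterable[str] = (), evalue_cutoff: float = 1e-3,
           max_iterations: int = 5, seed_rng: int = 0,
           null_windows: int = 100_000) -> list[ProfileHit]:
    """Iteratively search a database with a profile, reporting significant hits.

    Records whose taxon is in ``exclude_taxa`` are removed first (taxonomy
    restriction, e.g. excluding Brassicales).  Each round scores every window,
    assigns empirical E-values against a shuffled-database null, and keeps
    windows with ``evalue <= evalue_cutoff``; hit windows are appended to the
    profile's member windows and the profile re-estimated, until the hit set
    stops changing or ``max_iterations`` is reached.  Hits carry the first
    iteration (1-based) at which they appeared.  Deterministic for a fixed
    ``seed_rng``.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    excluded = frozenset(exclude_taxa)
    kept = [r for r in db if r.taxon not in excluded]
    if not kept:
        raise ValueError("database is empty after taxonomy exclusion")

    rng = np.random.default_rng(seed_rng)
    length = len(model)
    encoded = [( r.identifier, _encode(r.residues)) for r in kept]
    n_windows = sum(max(0, enc.size - length + 1) for _, enc in encoded)
    if n_windows == 0:
        return []
    # Fixed set of per-sequence Fisher-Yates shuffles, reused (rescored) at
    # every iteration so significance is comparable across rounds.
    shuffled: list[np.ndarray] = []
    total = 0
    while total < null_windows:
        for _, enc in encoded:
            if enc.size < length:
                continue
            shuffled.append(rng.permutation(enc))
            total += enc.size - length + 1
            if total >= null_windows:
                break

    current = model
    first_seen: dict[tuple[str, int], int] = {}
    previous: Optional[frozenset] = None
    results: dict[tuple[str, int], ProfileHit] = {}
    for iteration in range(1, max_iterations + 1):
        null = _null_scores(current, shuffled)
        hit_keys = []
        results = {}
        for seq_id, enc in encoded:
            if enc.size < length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, length)
            scores = current.log_odds[np.arange(length)[None, :], windows].sum(axis=1)
            pvals = _tail_pvalues(scores, null)
            evalues = n_windows * pvals
            for idx in np.flatnonzero(evalues <= evalue_cutoff):
                key = (seq_id, int(idx) + 1)
                first_seen.setdefault(key, iteration)
                hit_keys.append(key)
                results[key] = ProfileHit(
                    sequence_id=seq_id, start=int(idx) + 1,
                    score=float(scores[idx]), evalue=float(evalues[idx]),
                    iteration_found=first_seen[key])
        hit_set = frozenset(hit_keys)
        if hit_set == previous or iteration == max_iterations:
            break
        previous = hit_set
        # Append hit windows to the seed and re-estimate the profile.
        by_id = {r.identifier: r for r in kept}
        new_members = list(current.member_windows) or []
        for seq_id, start in sorted(hit_set):
            new_members.append(by_id[seq_id].residues[start - 1:start - 1 + length])
        if not new_members:
            break
        seed = SeedAlignment(members=tuple(new_members),
                             flank=(length - 6) // 2 if length >= 6 else 0,
                             motif_offset=max(1, (length - 6) // 2 + 1))
        current = estimate_profile(seed, pseudocount=current.pseudocount,
                                   background=current.background)
    return sorted(results.values(), key=lambda h: (h.sequence_id, h.start))


@dataclass(frozen=True)
class FlankSweepResult:
    """Per-flank search results plus their union and intersection."""

    rows: tuple[tuple[int, int, tuple[ProfileHit, ...]], ...]

    @property
    def union(self) -> frozenset:
        out: set = set()
        for _, _, hits in self.rows:
            out |= {(h.sequence_id, h.start) for h in hits}
        return frozenset(out)

    @property
    def intersection(self) -> frozenset:
        sets = [{(h.sequence_id, h.start) for h in hits} for _, _, hits in self.rows]
        if not sets:
            return frozenset()
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return frozenset(out)


def flank_sweep(records: Sequence[SequenceRecord], core_hits: Sequence[MotifHit],
                db: Sequence[SequenceRecord], flanks: Sequence[int],
                pseudocount: float = 0.5, background: Optional[np.ndarray] = None,
                **search_kwargs) -> FlankSweepResult:
    """Run build_seed / estimate_profile / search once per flank length."""
    for flank in flanks:
        if not 0 <= flank <= MAX_FLANK:
            raise ValueError(f"flank values must be within 0-{MAX_FLANK}, got {flank}")
    bg = database_background(db) if background is None else background
    rows = []
    for flank in flanks:
        seed = build_seed(records, core_hits, flank)
        model = estimate_profile(seed, pseudocount=pseudocount, background=bg)
        hits = search(db, model, **search_kwargs)
        rows.append((flank, len(hits), tuple(hits)))
    return FlankSweepResult(rows=tuple(rows))
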