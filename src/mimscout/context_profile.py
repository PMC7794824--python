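"""Sliding-window compositional tracks and the three-feature MIM-context call.

A confirmed MIM sits in a characteristic sequence context, summarized by
three features of its host protein:

1. a local dip toward order (the motif itself) within a large intrinsically
   disordered region (IDR),
2. an overall positive net charge of the motif region (``+RK-DE`` track), and
3. flanks biased toward small, hydrophilic, disorder-promoting residues with
   few positives (``+PST-RK`` track).

Composition tracks report ``(count(plus) - count(minus)) / covered`` over a
sliding window (default 15 residues); near the termini the window is truncated
and the denominator is the number of residues actually covered.

Disorder is approximated by a composition-scale proxy: the window mean of the
TOP-IDP per-residue disorder propensity scale, min-max rescaled to [0, 1].
This is a documented stand-in for dedicated disorder predictors, adequate for
contrasting disorder- vs order-biased segments, not a reimplementation of any
of them.  The IDR call uses a broad window (default 21); the local-order dip
is measured on a short window (default 7, comparable to the motif length),
because a 21-residue window cannot resolve a 6-residue feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .motif_scan import MotifHit
from .sequence_io import SequenceRecord

__all__ = [
    "TOP_IDP",
    "RK_DE",
    "PST_RK",
    "CompositionTrack",
    "DisorderProxyTrack",
    "ContextThresholds",
    "ContextSignature",
    "composition_track",
    "disorder_proxy",
    "context_tracks",
    "classify_context",
]

#: TOP-IDP disorder-propensity composition scale (higher = more
#: disorder-promoting).  Proline tops the scale; tryptophan is lowest.
TOP_IDP = {
    "A": 0.060, "C": -0.020, "D": 0.192, "E": 0.736, "F": -0.697,
    "G": 0.166, "H": 0.303, "I": -0.486, "K": 0.586, "L": -0.326,
    "M": -0.397, "N": 0.007, "P": 0.987, "Q": 0.318, "R": 0.180,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}
_SCALE_MIN = min(TOP_IDP.values())
_SCALE_MAX = max(TOP_IDP.values())

#: Residue sets of the two standard tracks.
RK_DE = (frozenset("RK"), frozenset("DE"))
PST_RK = (frozenset("PST"), frozenset("RK"))


def _residues_of(sequence: Union[SequenceRecord, str]) -> str:
    return sequence.residues if isinstance(sequence, SequenceRecord) else str(sequence)


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of ``values`` over a centered window, truncated at the termini."""
    half = window // 2
    n = values.size
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")


@dataclass(frozen=True)
class CompositionTrack:
    """Per-residue sliding-window residue-set fractions in [-1, 1]."""

    name: str
    plus_set: frozenset
    minus_set: frozenset
    window: int
    values: np.ndarray

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DisorderProxyTrack:
    """Per-residue disorder proxy in [0, 1] (window mean of a rescaled scale)."""

    values: np.ndarray
    window: int
    scale_name: str = "TOP-IDP (min-max rescaled)"

    def __len__(self) -> int:
        return self.values.size


def composition_track(sequence: Union[SequenceRecord, str], plus_set, minus_set,
                      window: int = 15, name: Optional[str] = None) -> CompositionTrack:
    """Sliding-window ``(plus - minus) / covered`` fractions for a sequence.

    ``plus_set`` and ``minus_set`` must be disjoint; the window must be odd.
    Masked (``X``) residues count toward the denominator but to neither set.
    """
    _check_window(window)
    plus = frozenset(plus_set)
    minus = frozenset(minus_set)
    if plus & minus:
        raise ValueError(f"plus and minus sets overlap: {sorted(plus & minus)}")
    residues = _residues_of(sequence)
    signs = np.fromiter(((1.0 if r in plus else -1.0 if r in minus else 0.0)
                         for r in residues), dtype=float, count=len(residues))
    if name is None:
        name = f"+{''.join(sorted(plus))}-{''.join(sorted(minus))}"
    values = _windowed_mean(signs, window) if len(residues) else np.zeros(0)
    return CompositionTrack(name=name, plus_set=plus, minus_set=minus,
                            window=window, values=values)


def disorder_proxy(sequence: Union[SequenceRecord, str],
                   window: int = 21) -> DisorderProxyTrack:
    """Composition-scale disorder proxy track in [0, 1].

    Per-residue TOP-IDP values are min-max rescaled over the scale's range and
    averaged over a centered window (truncated at the termini).  Masked
    residues take the scale midpoint.
    """
    _check_window(window)
    residues = _residues_of(sequence)
    span = _SCALE_MAX - _SCALE_MIN
    mid = 0.5
    scaled = np.fromiter(
        (((TOP_IDP[r] - _SCALE_MIN) / span) if r in TOP_IDP else mid
         for r in residues), dtype=float, count=len(residues))
    values = _windowed_mean(scaled, window) if len(residues) else np.zeros(0)
    return DisorderProxyTrack(values=values, window=window)


@dataclass(frozen=True)
class ContextThresholds:
    """Tunable thresholds of the context signature (package defaults).

    The source analysis describes the three features qualitatively; these
    quantitative cut-offs are this package's own, exposed in configuration.
    """

    dip_depth: float = 0.05       # minimum proxy drop motif vs. surroundings
    surround: int = 25            # residues on each side used for the dip baseline
    idr_cut: float = 0.5          # proxy level counted as disordered
    idr_min_length: int = 30      # minimum IDR run length (residues)
    flank_width: int = 15         # flank extent for the +PST-RK feature
    charge_halo: int = 5          # extension of the motif span for net charge
    track_window: int = 15        # composition-track window
    proxy_window: int = 21        # broad proxy window (IDR call)
    local_window: int = 7         # short proxy window (order-dip call)


DEFAULT_THRESHOLDS = ContextThresholds()


@dataclass(frozen=True)
class ContextSignature:
    """The three-feature context call for one motif hit.

    ``overall_call`` is true iff the local-order dip lies within an IDR
    context and the net-charge and flank-bias features both hold.
    """

    order_dip: bool
    dip_depth: float
    idr_context: bool
    idr_length: int
    net_charge_positive: bool
    mean_rk_de: float
    flank_bias: bool
    mean_pst_rk: float
    overall_call: bool
    truncated: bool = False


def context_tracks(sequence: Union[SequenceRecord, str],
                   thresholds: ContextThresholds = DEFAULT_THRESHOLDS) -> dict:
    """Compute the four tracks classify_context needs, keyed by role."""
    return {
        "proxy": disorder_proxy(sequence, thresholds.proxy_window),
        "local_proxy": disorder_proxy(sequence, thresholds.local_window),
        "rk_de": composition_track(sequence, *RK_DE, window=thresholds.track_window),
        "pst_rk": composition_track(sequence, *PST_RK, window=thresholds.track_window),
    }


def _idr_run(proxy: np.ndarray, lo: int, hi: int, cut: float) -> int:
    """Length of the maximal run of proxy >= cut containing [lo, hi); 0 if none."""
    above = proxy >= cut
    if not above[lo:hi].all():
        return 0
    run_lo = lo
    while run_lo > 0 and above[run_lo - 1]:
        run_lo -= 1
    run_hi = hi
    while run_hi < above.size and above[run_hi]:
        run_hi += 1
    return run_hi - run_lo


def classify_context(sequence: Union[SequenceRecord, str], hit: MotifHit,
                     proxy: Optional[DisorderProxyTrack] = None,
                     local_proxy: Optional[DisorderProxyTrack] = None,
                     rk_de: Optional[CompositionTrack] = None,
                     pst_rk: Optional[CompositionTrack] = None,
                     thresholds: ContextThresholds = DEFAULT_THRESHOLDS,
                     ) -> ContextSignature:
    """Evaluate the three-feature MIM-context signature for one hit.

    * order dip: the short-window proxy averaged over the hit span must lie at
      least ``dip_depth`` below its average over the surrounding +-``surround``
      residues (span excluded);
    * IDR context: the hit must sit inside a maximal run of broad-window proxy
      >= ``idr_cut`` of length >= ``idr_min_length``;
    * net charge: mean ``+RK-DE`` over the span +- ``charge_halo`` must be
      positive;
    * flank bias: mean ``+PST-RK`` over the two ``flank_width``-residue flanks
      must be positive.

    Tracks not supplied are computed from ``sequence`` with the thresholds'
    windows.  Hits near a terminus are evaluated on the residues available and
    flagged ``truncated``.
    """
    residues = _residues_of(sequence)
    n = len(residues)
    if not 1 <= hit.start <= hit.end <= n:
        raise ValueError(f"hit {hit.start}-{hit.end} outside sequence of length {n}")
    if proxy is None:
        proxy = disorder_proxy(residues, thresholds.proxy_window)
    if local_proxy is None:
        local_proxy = disorder_proxy(residues, thresholds.local_window)
    if rk_de is None:
        rk_de = composition_track(residues, *RK_DE, window=thresholds.track_window)
    if pst_rk is None:
        pst_rk = composition_track(residues, *PST_RK, window=thresholds.track_window)
    for track in (proxy, local_proxy, rk_de, pst_rk):
        if len(track) != n:
            raise ValueError("tracks must be computed on the same sequence")

    lo, hi = hit.start - 1, hit.end  # 0-based half-open span

    span_mean = float(local_proxy.values[lo:hi].mean())
    left = local_proxy.values[max(0, lo - thresholds.surround):lo]
    right = local_proxy.values[hi:hi + thresholds.surround]
    surround_vals = np.concatenate([left, right])
    truncated = (left.size < thresholds.surround or right.size < thresholds.surround)
    if surround_vals.size:
        depth = float(surround_vals.mean()) - span_mean
    else:
        depth = 0.0
    order_dip = depth >= thresholds.dip_depth

    idr_length = _idr_run(proxy.values, lo, hi, thresholds.idr_cut)
    idr_context = idr_length >= thresholds.idr_min_length

    halo_lo = max(0, lo - thresholds.charge_halo)
    halo_hi = min(n, hi + thresholds.charge_halo)
    mean_rk_de = float(rk_de.values[halo_lo:halo_hi].mean())
    net_charge_positive = mean_rk_de > 0.0

    fw = thresholds.flank_width
    flank_vals = np.concatenate([pst_rk.values[max(0, lo - fw):lo],
                                 pst_rk.values[hi:hi + fw]])
    truncated = truncated or flank_vals.size < 2 * fw
    mean_pst_rk = float(flank_vals.mean()) if flank_vals.size else 0.0
    flank_bias = mean_pst_rk > 0.0

    overall = bool(order_dip and idr_context and net_charge_positive and flank_bias)
    return ContextSignature(
        order_dip=bool(order_dip), dip_depth=depth,
        idr_context=bool(idr_context), idr_length=int(idr_length),
        net_charge_positive=bool(net_charge_positive), mean_rk_de=mean_rk_de,
        flank_bias=bool(flank_bias), mean_pst_rk=mean_pst_rk,
        overall_call=overall, truncated=bool(truncated))
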