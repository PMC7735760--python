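"""Nucleosome dyads, repeat lengths and autocorrelograms from posterior tracks.

Dyad calling follows the in vitro recipe: a 133-bp centred rolling mean of
the (lightly smoothed) posterior track, local minima at least 147 bp apart,
minima resolved greedily from the deepest up.  Periodicity on single
molecules is read out through a lagged Pearson autocorrelogram whose length
is exactly half the track length: at lag k the two compared windows are
``track[0:L-k)`` and ``track[k:L)``, so lags beyond L/2 would compare
windows shorter than half the molecule and are not computed.  A peak search
over the autocorrelogram between 120 and 350 bp yields the single-molecule
nucleosome repeat length (NRL); molecules where no peak clears the
prominence threshold are recorded with ``peak_found=False`` rather than
dropped, since missing peaks are themselves informative (irregular fibres
fail more often).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, find_peaks

logger = logging.getLogger(__name__)

IN_VITRO_SMOOTH = 5  # bp rolling mean before dyad calling
IN_VIVO_SMOOTH = 33  # bp rolling mean before autocorrelograms / averaging


@dataclass
class DyadCallSet:
    molecule_id: str
    dyads: np.ndarray
    pairwise_nrls: np.ndarray = field(default=None)  # type: ignore[assignment]
    averaged_nrl: float = np.nan

    def __post_init__(self) -> None:
        self.dyads = np.asarray(self.dyads, dtype=int)
        if self.dyads.size and np.any(np.diff(self.dyads) <= 0):
            raise ValueError("dyads must be strictly increasing")
        if self.pairwise_nrls is None:
            self.pairwise_nrls, self.averaged_nrl = nrl_from_dyads(self.dyads)


@dataclass
class Autocorrelogram:
    molecule_id: str
    values: np.ndarray  # indexed by lag 0 .. floor(L/2) - 1
    n_used: np.ndarray  # overlapping observation pairs per lag


@dataclass
class NrlCall:
    molecule_id: str
    nrl_lag: int | None
    peak_found: bool


def rolling_mean_nan(
    x: np.ndarray, window: int, min_count: int = 1
) -> np.ndarray:
    """Centred NaN-aware rolling mean, same length as the input.

    The mean at each position is taken over the observed (finite) values in
    the centred window, truncated at the track ends; positions whose window
    holds fewer than ``min_count`` observations are NaN.
    """
    x = np.asarray(x, dtype=float)
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    n = x.size
    if window > n:
        logger.warning("window %d exceeds track length %d: all-missing output",
                       window, n)
        return np.full(n, np.nan)
    valid = np.isfinite(x)
    v = np.where(valid, x, 0.0)
    hw = window // 2
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cc = np.concatenate([[0], np.cumsum(valid)])
    idx = np.arange(n)
    lo = np.maximum(idx - hw, 0)
    hi = np.minimum(idx + hw + 1, n)
    sums = cs[hi] - cs[lo]
    cnts = cc[hi] - cc[lo]
    out = np.full(n, np.nan)
    ok = cnts >= max(min_count, 1)
    out[ok] = sums[ok] / cnts[ok]
    return out


def _trough_centroid(
    s: np.ndarray, p: int, halfspan: int = 40, frac: float = 0.25
) -> int:
    """Refine a minimum to the weighted centroid of its trough.

    Positions within ``halfspan`` of the minimum whose smoothed value lies
    in the bottom ``frac`` of the local range contribute with weight equal
    to their depth below that cutoff; for a symmetric (or flat-bottomed)
    trough the centroid is its centre, so noiseless geometry is unchanged.
    The span is shrunk symmetrically where the observed run around the
    minimum is truncated (track ends, missing windows), so edge troughs are
    not pulled toward their one observed flank.
    """
    left = p
    while left - 1 >= 0 and np.isfinite(s[left - 1]):
        left -= 1
    right = p
    while right + 1 < s.size and np.isfinite(s[right + 1]):
        right += 1
    halfspan = min(halfspan, p - left, right - p)
    lo, hi = p - halfspan, p + halfspan + 1
    ys = s[lo:hi]
    xs = np.arange(lo, hi)
    fin = np.isfinite(ys)
    ys, xs = ys[fin], xs[fin]
    if ys.size == 0:
        return p
    mn, mx = ys.min(), ys.max()
    w = np.maximum(mn + frac * (mx - mn) - ys, 0.0)
    if w.sum() == 0.0:
        return p
    return int(np.rint((xs * w).sum() / w.sum()))


def call_dyads(
    track: np.ndarray,
    window: int = 133,
    min_separation: int = 147,
    edge_margin: int = 73,
    rel_depth: float = 0.6,
    refine: bool = True,
    molecule_id: str = "",
) -> DyadCallSet:
    """Local minima of the ``window``-bp rolling mean, >= min_separation apart.

    Candidate minima (plateau midpoints) are accepted greedily in increasing
    order of smoothed value — ties broken leftmost — subject to the pairwise
    distance constraint; minima within ``edge_margin`` (half a nucleosome
    footprint by default) of either end are excluded as partial-nucleosome
    artifacts.  Minima shallower than ``rel_depth`` of the smoothed track's
    range (measured from its deepest point) are rejected: a dip that stays
    near the methylated level is accessible DNA, not a nucleosome.  Both the
    depth rule and the optional trough-centroid refinement are invariant to
    adding a constant to the track.  An empty call set is a valid outcome.
    """
    track = np.asarray(track, dtype=float)
    if track.size < window:
        raise ValueError(f"track length {track.size} < window {window}")
    s = rolling_mean_nan(track, window)
    hw = window // 2
    if hw:  # positions without a full window carry truncated means: exclude
        s[:hw] = np.nan
        s[track.size - hw:] = np.nan
    neg = np.where(np.isfinite(s), -s, -np.inf)
    peaks, _ = find_peaks(neg)  # plateau midpoints, ends never included
    n = track.size
    peaks = peaks[(peaks >= edge_margin) & (peaks <= n - 1 - edge_margin)]
    if peaks.size and np.isfinite(s).any():
        smin, smax = np.nanmin(s), np.nanmax(s)
        if smax > smin:
            cutoff = smin + rel_depth * (smax - smin)
            peaks = peaks[s[peaks] <= cutoff]
    order = sorted(peaks, key=lambda p: (s[p], p))
    accepted: list[int] = []
    for p in order:
        if all(abs(p - q) >= min_separation for q in accepted):
            accepted.append(int(p))
    dyads = np.sort(accepted)
    if refine and dyads.size:
        refined = np.array([_trough_centroid(s, int(p)) for p in dyads])
        # keep a refinement only where the spacing contract survives it
        ok = np.ones(dyads.size, dtype=bool)
        for i in range(dyads.size):
            for j in (i - 1, i + 1):
                if 0 <= j < dyads.size and abs(refined[i] - refined[j]) < min_separation:
                    ok[i] = False
        dyads = np.sort(np.where(ok, refined, dyads))
    return DyadCallSet(molecule_id, dyads)


def nrl_from_dyads(dyads: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise adjacent-dyad distances and the single-molecule average.

    The averaged NRL is ``(last - first) / (n - 1)``; with fewer than two
    dyads both results are missing.
    """
    dyads = np.asarray(dyads, dtype=int)
    if dyads.size < 2:
        return np.empty(0, dtype=int), np.nan
    pairwise = np.diff(dyads)
    averaged = float(dyads[-1] - dyads[0]) / (dyads.size - 1)
    return pairwise, averaged


def _acg_dense(x: np.ndarray, n_lags: int, min_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """All-lags Pearson autocorrelation for a fully observed track, O(L log L)."""
    L = x.size
    k = np.arange(n_lags)
    n = (L - k).astype(float)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cq = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = cs[L - k]              # sum over x[0 : L-k]
    s2 = cs[L] - cs[k]          # sum over x[k : L]
    q1 = cq[L - k]
    q2 = cq[L] - cq[k]
    conv = fftconvolve(x, x[::-1])  # conv[L-1-k] = sum_i x[i] * x[i+k]
    sp = conv[L - 1 - k]
    cov = sp - s1 * s2 / n
    var1 = q1 - s1 * s1 / n
    var2 = q2 - s2 * s2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var1 * var2)
    tiny = 1e-12 * n
    r[(var1 <= tiny) | (var2 <= tiny)] = np.nan
    r[n < min_pairs] = np.nan
    return r, (L - k)


def autocorrelogram(
    track: np.ndarray,
    molecule_id: str = "",
    min_pairs: int = 10,
) -> Autocorrelogram:
    """Lagged self-correlation of a smoothed track; length exactly ``L // 2``.

    For lag k the Pearson correlation between ``track[0:L-k)`` and
    ``track[k:L)`` is computed over positions where both copies are
    observed; lags with fewer than ``min_pairs`` overlapping observations
    are missing rather than extrapolated.  ``n_used`` records the pair count
    per lag.  A track with zero variance over its observed positions is an
    error.
    """
    track = np.asarray(track, dtype=float)
    L = track.size
    if L < 4:
        raise ValueError("track too short for an autocorrelogram")
    obs = np.isfinite(track)
    if obs.sum() < 2 or np.nanvar(track) == 0.0:
        raise ValueError("constant track: autocorrelogram undefined")
    n_lags = L // 2
    x = track - np.nanmean(track)  # Pearson is shift-invariant; better conditioning

    if obs.all():
        values, n_used = _acg_dense(x, n_lags, min_pairs)
    else:
        values = np.full(n_lags, np.nan)
        n_used = np.zeros(n_lags, dtype=int)
        for k in range(n_lags):
            a = x[: L - k]
            b = x[k:]
            m = np.isfinite(a) & np.isfinite(b)
            cnt = int(m.sum())
            n_used[k] = cnt
            if cnt < min_pairs:
                continue
            av = a[m]
            bv = b[m]
            va = av.var()
            vb = bv.var()
            if va <= 0.0 or vb <= 0.0:
                continue
            values[k] = ((av - av.mean()) * (bv - bv.mean())).mean() / np.sqrt(va * vb)
    if np.isfinite(values[0]) or n_used[0] >= min_pairs:
        values[0] = 1.0
    return Autocorrelogram(molecule_id, values, np.asarray(n_used))


def find_nrl_peak(
    acg: Autocorrelogram,
    lag_range: tuple[int, int] = (120, 350),
    prominence: float = 0.03,
    height: float | None = 0.1,
) -> NrlCall:
    """First secondary peak of the autocorrelogram inside ``lag_range``.

    The peak lag is the single-molecule NRL estimate.  Missing lags are
    linearly interpolated before peak finding; a peak must clear both the
    prominence threshold and (when set) a minimum correlation ``height``,
    so molecules without coherent periodicity are returned with
    ``peak_found=False`` — never an error.
    """
    v = np.asarray(acg.values, dtype=float)
    fin = np.isfinite(v)
    if fin.sum() < 3:
        return NrlCall(acg.molecule_id, None, False)
    idx = np.arange(v.size)
    vi = np.interp(idx, idx[fin], v[fin])
    peaks, _ = find_peaks(vi, prominence=prominence, height=height)
    lo, hi = lag_range
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    if peaks.size == 0:
        return NrlCall(acg.molecule_id, None, False)
    return NrlCall(acg.molecule_id, int(peaks[0]), True)
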