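"""Percent-identity profiling along an aligned MAT idiomorph pair.

The mating-type (MAT) locus of heterothallic fungi carries one of two
idiomorphs — highly dissimilar allelic sequences flanked by conserved
genes.  In a pairwise alignment of the two idiomorphs the per-window
identity drops from ~98-99% in the flanks to ~48% inside the idiomorphic
region, and a single-sequence indel sits just 3' of the divergent core;
the 3' end of that indel marks the 3' idiomorph boundary.

Windows are 100 alignment columns sliding in 10-column steps.  Columns
gapped in either sequence are excluded from the identity denominator;
windows with fewer than half their columns comparable are reported
missing (the "white gap" over the indel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NoIdiomorphError(ValueError):
    """The identity track contains no low-identity region."""


@dataclass
class IdentityTrack:
    """Sliding-window percent identity along an alignment.

    ``df`` columns: ``start`` (alignment column of the window start),
    ``center``, ``identity`` (percent, NaN when too few comparable
    columns), ``n_compared``.
    """

    df: pd.DataFrame
    window: int
    step: int


@dataclass
class IdiomorphBoundaries:
    """Called idiomorph extent on alignment coordinates.

    ``start5`` is the 5' boundary column; ``end3`` the 3' boundary
    (half-open, at the 3' end of the boundary indel when one is found).
    ``length_bp`` is the ungapped length of the first (MAT1-1-like)
    sequence between the boundaries.  ``indels`` lists detected
    single-sequence gap runs as ``(start, end, seq_index)``.
    """

    start5: int
    end3: int
    length_bp: int
    indel: tuple[int, int, int] | None
    indels: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def indel_length(self) -> int:
        return 0 if self.indel is None else self.indel[1] - self.indel[0]


def sliding_identity(
    pair: tuple[str, str], window: int = 100, step: int = 10,
    min_comparable_fraction: float = 0.5,
) -> IdentityTrack:
    """Percent identity in overlapping windows of alignment columns.

    Identity = matching columns / compared columns x 100, where a column
    is compared only if neither sequence is gapped there.  Windows with
    fewer than ``min_comparable_fraction`` of their columns comparable
    get a missing (NaN) identity.
    """
    a, b = (np.frombuffer(s.upper().encode(), dtype="S1") for s in pair)
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    if window > len(a):
        raise ValueError("window longer than the alignment")
    gap = b"-"
    comparable = (a != gap) & (b != gap)
    match = comparable & (a == b)
    # windowed sums via cumulative sums
    cc = np.concatenate([[0], np.cumsum(comparable)])
    cm = np.concatenate([[0], np.cumsum(match)])
    starts = np.arange(0, len(a) - window + 1, step)
    n_comp = cc[starts + window] - cc[starts]
    n_match = cm[starts + window] - cm[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(n_comp > 0, 100.0 * n_match / np.maximum(n_comp, 1), np.nan)
    ident[n_comp < min_comparable_fraction * window] = np.nan
    df = pd.DataFrame(
        {
            "start": starts,
            "center": starts + window // 2,
            "identity": ident,
            "n_compared": n_comp,
        }
    )
    return IdentityTrack(df=df, window=window, step=step)


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    arr = np.frombuffer(seq.encode(), dtype="S1") == b"-"
    if not arr.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], arr.view(np.int8), [0]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _refine_changepoint(
    match: np.ndarray, comparable: np.ndarray, lo: int, hi: int
) -> int:
    """Column that best splits [lo, hi) into a high-identity left part
    and a low-identity right part (least-squares two-segment fit on the
    per-column match indicator over comparable columns)."""
    idx = np.arange(lo, hi)
    ok = comparable[lo:hi]
    y = match[lo:hi].astype(float)
    cols = idx[ok]
    y = y[ok]
    if len(y) < 4:
        return lo
    best_cost, best_col = np.inf, lo
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csq = np.concatenate([[0.0], np.cumsum(y * y)])
    n = len(y)
    for split in range(1, n):
        nl, nr = split, n - split
        sl, sr = csum[split], csum[n] - csum[split]
        # SSE of a constant fit on each side
        cost = (csq[split] - sl * sl / nl) + (csq[n] - csq[split] - sr * sr / nr)
        # require the left mean to exceed the right (high -> low drop)
        if sl / nl <= sr / nr:
            continue
        if cost < best_cost:
            best_cost, best_col = cost, int(cols[split])
    return best_col


def call_boundaries(
    track: IdentityTrack,
    pair: tuple[str, str],
    high_id: float = 90.0,
    low_id: float = 60.0,
    min_indel: int = 20,
) -> IdiomorphBoundaries:
    """Call the idiomorph boundaries and length from an identity track.

    The coarse 5' boundary is the first window center whose identity
    falls below ``low_id`` after a run above ``high_id``; it is then
    refined to the column where the per-column match rate drops, by a
    two-segment least-squares fit over the surrounding window.  The 3'
    boundary is the 3' end of the single-sequence gap run (length >=
    ``min_indel``) closest past the end of the low-identity region; when
    no such indel exists the 3' changepoint is refined symmetrically.
    The idiomorph length is reported on the ungapped coordinates of the
    first (MAT1-1-like) sequence.

    Raises :class:`NoIdiomorphError` when the track never drops below
    ``low_id`` after a high-identity run.
    """
    df = track.df
    ident = df["identity"].to_numpy()
    centers = df["center"].to_numpy()
    seen_high = False
    coarse5_i = None
    for i, val in enumerate(ident):
        if np.isfinite(val) and val >= high_id:
            seen_high = True
        elif np.isfinite(val) and val < low_id and seen_high:
            coarse5_i = i
            break
    if coarse5_i is None:
        raise NoIdiomorphError("no idiomorph detected: identity never drops")
    low_mask = np.isfinite(ident) & (ident < low_id)
    low_end_center = int(centers[np.flatnonzero(low_mask)[-1]])

    a, b = pair
    arr_a = np.frombuffer(a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(b.upper().encode(), dtype="S1")
    gap = b"-"
    comparable = (arr_a != gap) & (arr_b != gap)
    match = comparable & (arr_a == arr_b)

    coarse5 = int(centers[coarse5_i])
    lo = max(0, coarse5 - track.window)
    hi = min(len(a), coarse5 + track.window)
    start5 = _refine_changepoint(match, comparable, lo, hi)

    indels = [
        (s, e, 0) for s, e in _gap_runs(a) if e - s >= min_indel
    ] + [(s, e, 1) for s, e in _gap_runs(b) if e - s >= min_indel]
    indels.sort()
    candidates = [iv for iv in indels if iv[0] >= start5]
    indel = None
    if candidates:
        # the boundary indel is the gap run nearest the end of the
        # low-identity region
        indel = min(candidates, key=lambda iv: (abs(iv[0] - low_end_center), -(iv[1] - iv[0])))
        end3 = indel[1]
    else:
        # no indel: refine the low -> high rise around the track's 3' edge
        lo = max(start5, low_end_center - track.window)
        hi = min(len(a), low_end_center + track.window)
        rev_match = match[::-1]
        rev_comp = comparable[::-1]
        n = len(a)
        col = _refine_changepoint(rev_match, rev_comp, n - hi, n - lo)
        end3 = n - col
    if end3 <= start5:
        raise NoIdiomorphError("degenerate boundaries")
    length_bp = int(np.sum(arr_a[start5:end3] != gap))
    return IdiomorphBoundaries(
        start5=int(start5), end3=int(end3), length_bp=length_bp,
        indel=indel, indels=indels,
    )


def interval_mean_identity(track: IdentityTrack, start: int, end: int) -> float:
    """Mean per-window identity over windows centered in [start, end);
    used to report intermediate-identity plateaus."""
    sel = (track.df["center"] >= start) & (track.df["center"] < end)
    vals = track.df.loc[sel, "identity"]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no windows with identity in the interval")
    return float(vals.mean())
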