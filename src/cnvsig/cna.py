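"""Array-CGH preprocessing, circular binary segmentation and alteration calling.

Circular binary segmentation (CBS) partitions a noisy log-ratio profile into
constant-mean segments.  The change statistic compares the mean inside an arc
``(i, j]`` of the (circularised) profile against the mean of the rest with a
pooled-variance two-sample t; the best arc is kept when a permutation test on
the profile rejects homogeneity, and the procedure recurses on the pieces.
Wrap-around arcs are equivalent to the complement of a linear arc, so the scan
over linear arcs covers the circle.

Segment means at or above ``gain_threshold`` (default +0.2 log2) are called
gains, at or below ``loss_threshold`` (default -0.2) losses; boundaries are
inclusive.  Missing clones are removed before segmentation and reported as
``missing`` calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GAIN, LOSS, MISSING, NORMAL, CloneMap

_EPS = 1e-12


@dataclass(frozen=True)
class Segment:
    """Half-open clone-index interval [start, end) with a constant fitted mean."""

    start: int
    end: int
    mean: float
    n_clones: int
    chromosome: int | None = None


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_acgh(
    replicate_matrices: Sequence[pd.DataFrame],
    clone_blacklist: Sequence[str] = (),
) -> pd.DataFrame:
    """Average replicate spots per clone and median-centre each sample.

    All replicates must share clone ids and sample ids.  Entries missing in
    every replicate stay missing (NaN); blacklisted (polymorphic, unmapped or
    absent) clones are dropped.  Each sample column is centred so its median
    log2 ratio is zero.
    """
    if len(replicate_matrices) == 0:
        raise ValueError("need at least one replicate matrix")
    first = replicate_matrices[0]
    for rep in replicate_matrices[1:]:
        if not rep.index.equals(first.index) or not rep.columns.equals(first.columns):
            raise ValueError("replicates must share clone ids and sample ids")
    stacked = np.stack([rep.to_numpy(dtype=float) for rep in replicate_matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices stay NaN
        averaged = np.nanmean(stacked, axis=0)
    out = pd.DataFrame(averaged, index=first.index, columns=first.columns)
    out = out.drop(index=[c for c in clone_blacklist if c in out.index])
    out = out.sub(out.median(axis=0, skipna=True), axis=1)
    return out


# ---------------------------------------------------------------------------
# arc statistic and exhaustive scan
# ---------------------------------------------------------------------------

def arc_statistic(profile: np.ndarray, i: int, j: int) -> float:
    """|t| comparing the arc ``profile[i:j]`` against the remaining clones.

    Pooled-variance two-sample t, returned as an absolute value (symmetric in
    group exchange).  Degenerate case: zero pooled variance gives +inf when
    the group means differ and 0 when they coincide.
    """
    x = np.asarray(profile, dtype=float)
    n = len(x)
    if not (0 <= i < j <= n):
        raise ValueError("need 0 <= i < j <= n")
    if i == 0 and j == n:
        raise ValueError("both groups must be non-empty")
    arc, rest = x[i:j], np.concatenate([x[:i], x[j:]])
    k, m = len(arc), len(rest)
    diff = arc.mean() - rest.mean()
    ssw = ((arc - arc.mean()) ** 2).sum() + ((rest - rest.mean()) ** 2).sum()
    scale = abs(x).max() + 1.0
    if ssw <= _EPS * scale ** 2 * n or n <= 2:
        return float("inf") if abs(diff) > 1e-9 * scale else 0.0
    pooled = ssw / (n - 2)
    return abs(diff) / np.sqrt(pooled * (1.0 / k + 1.0 / m))


@lru_cache(maxsize=64)
def _arc_index_arrays(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.triu_indices(n + 1, k=max(1, min_width))
    keep = ~((ii == 0) & (jj == n))
    width = jj - ii
    keep &= (width >= min_width) & (n - width >= min_width)
    return ii[keep], jj[keep]


def _max_arc_batch(profiles: np.ndarray, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised max |t| arc per row of ``profiles`` (shape B x n).

    Returns (stat, i, j) arrays of length B.
    """
    B, n = profiles.shape
    ii, jj = _arc_index_arrays(n, min_width)
    if len(ii) == 0:
        return np.zeros(B), np.zeros(B, int), np.full(B, n, int)
    c1 = np.concatenate([np.zeros((B, 1)), np.cumsum(profiles, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((B, 1)), np.cumsum(profiles ** 2, axis=1)], axis=1)
    S, Q = c1[:, -1:], c2[:, -1:]
    k = (jj - ii).astype(float)
    m = n - k
    s = c1[:, jj] - c1[:, ii]
    q = c2[:, jj] - c2[:, ii]
    mean1 = s / k
    mean2 = (S - s) / m
    ssw = (q - s ** 2 / k) + ((Q - q) - (S - s) ** 2 / m)
    ssw = np.maximum(ssw, 0.0)
    diff = np.abs(mean1 - mean2)
    scale = np.abs(profiles).max(axis=1, keepdims=True) + 1.0
    degenerate = ssw <= _EPS * scale ** 2 * n
    if n > 2:
        denom = np.sqrt(ssw / (n - 2) * (1.0 / k + 1.0 / m))
    else:
        denom = np.zeros_like(ssw)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.where(degenerate, np.where(diff > 1e-9 * scale, np.inf, 0.0), t)
    best = np.argmax(t, axis=1)
    rows = np.arange(B)
    return t[rows, best], ii[best], jj[best]


def max_arc_split(profile: np.ndarray, min_width: int = 1) -> tuple[int, int, float]:
    """Arc ``(i, j]`` attaining the maximum arc statistic, by exhaustive scan."""
    x = np.asarray(profile, dtype=float)[None, :]
    stat, i, j = _max_arc_batch(x, min_width)
    return int(i[0]), int(j[0]), float(stat[0])


# ---------------------------------------------------------------------------
# recursive CBS
# ---------------------------------------------------------------------------

def _node_rng(seed: int | None, offset: int, length: int) -> np.random.Generator:
    # Node-local stream: the permutations used at a (sub)segment depend only on
    # (seed, absolute offset, length), never on how the recursion reached it.
    entropy = 0 if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy,
                                                        spawn_key=(offset, length)))


def cbs_segment(
    profile: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
    chromosome: int | None = None,
    merge_tol: float = 1e-9,
) -> list[Segment]:
    """Segment one chromosome's profile of one sample by recursive CBS.

    At each node the maximal arc statistic is referred to its permutation null
    (``n_perm`` shuffles of the node's values, add-one p-value estimator
    (r+1)/(n_perm+1)); when p < ``alpha`` the node is split at the arc
    boundaries and the pieces are segmented recursively.  Adjacent output
    segments whose means agree to within ``merge_tol`` are merged.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable permutation p-values")
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("profile must be a non-empty 1-D array")
    if np.isnan(x).any():
        raise ValueError("remove missing values before segmentation")

    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_width or n < 2 or np.ptp(seg) == 0:
            return
        i, j, stat = max_arc_split(seg, min_width)
        if stat <= 0:
            return
        rng = _node_rng(seed, lo, n)
        # Sequential permutation test with exact early stopping: once r exceed-
        # ances guarantee (r+1)/(n_perm+1) >= alpha, the no-split decision is
        # already the full-run decision, so remaining shuffles are skipped.
        r, done = 0, 0
        stop_r = alpha * (n_perm + 1) - 1
        batch = max(50, n_perm // 4)
        while done < n_perm:
            b = min(batch, n_perm - done)
            perms = rng.permuted(np.broadcast_to(seg, (b, n)), axis=1)
            null_stat, _, _ = _max_arc_batch(perms, min_width)
            r += int(np.count_nonzero(null_stat >= stat))
            done += b
            if r > stop_r:
                return
        p = (r + 1) / (n_perm + 1)
        if p >= alpha:
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        for c in cuts:
            boundaries.append(c)
        pieces = [lo] + cuts + [hi]
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, len(x))
    cuts = [0] + sorted(boundaries) + [len(x)]
    segments = [Segment(a, b, float(x[a:b].mean()), b - a, chromosome)
                for a, b in zip(cuts[:-1], cuts[1:])]
    # merge adjacent segments with (numerically) identical means
    merged: list[Segment] = []
    for seg in segments:
        if merged and abs(merged[-1].mean - seg.mean) < merge_tol:
            prev = merged.pop()
            vals = x[prev.start:seg.end]
            merged.append(Segment(prev.start, seg.end, float(vals.mean()),
                                  seg.end - prev.start, chromosome))
        else:
            merged.append(seg)
    return merged


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_segments(
    segments: Sequence[Segment],
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
) -> list[str]:
    """Per-clone states for one segmented profile (inclusive thresholds)."""
    if not gain_threshold > 0 or not loss_threshold < 0:
        raise ValueError("need gain_threshold > 0 > loss_threshold")
    states: list[str] = []
    for seg in segments:
        if seg.mean >= gain_threshold:
            state = GAIN
        elif seg.mean <= loss_threshold:
            state = LOSS
        else:
            state = NORMAL
        states.extend([state] * seg.n_clones)
    return states


def segment_matrix(
    matrix: pd.DataFrame,
    clone_map: CloneMap,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | None = None,
) -> dict[str, list[Segment]]:
    """CBS for every sample and chromosome of a clones x samples matrix.

    Missing clones are dropped per sample before segmentation; the returned
    ``Segment`` indices refer to positions in the reduced (non-missing)
    per-chromosome profile.  Use :func:`call_alterations` to map back onto the
    full clone set.
    """
    chrom_of = clone_map.frame.set_index("clone_id")["chromosome"]
    per_sample: dict[str, list[Segment]] = {}
    for s_idx, sample in enumerate(matrix.columns):
        col = matrix[sample]
        segs: list[Segment] = []
        for chrom in clone_map.chromosomes():
            vals = col[chrom_of.reindex(col.index) == chrom].dropna().to_numpy()
            if len(vals) == 0:
                continue
            node_seed = None if seed is None else seed + 1_000_003 * s_idx + chrom
            segs.extend(cbs_segment(vals, alpha=alpha, n_perm=n_perm,
                                    min_width=min_width, seed=node_seed,
                                    chromosome=chrom))
        per_sample[sample] = segs
    return per_sample


def call_alterations(
    matrix: pd.DataFrame,
    clone_map: CloneMap,
    segments_by_sample: dict[str, list[Segment]],
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
) -> pd.DataFrame:
    """Gain/normal/loss/missing call per clone and sample.

    ``segments_by_sample`` must come from :func:`segment_matrix` on the same
    matrix; missing input entries come back as ``missing`` calls.
    """
    chrom_of = clone_map.frame.set_index("clone_id")["chromosome"]
    calls = pd.DataFrame(MISSING, index=matrix.index, columns=matrix.columns)
    for sample, segments in segments_by_sample.items():
        col = matrix[sample]
        by_chrom: dict[int, list[Segment]] = {}
        for seg in segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            mask = (chrom_of.reindex(col.index) == chrom) & col.notna()
            clone_ids = col.index[mask]
            states = call_segments(sorted(segs, key=lambda s: s.start),
                                   gain_threshold, loss_threshold)
            if len(states) != len(clone_ids):
                raise ValueError("segments do not partition the non-missing clones")
            calls.loc[clone_ids, sample] = states
    return calls


def threshold_calls(
    matrix: pd.DataFrame,
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
) -> pd.DataFrame:
    """Direct per-entry thresholding (no segmentation); handy for noiseless data."""
    if not gain_threshold > 0 or not loss_threshold < 0:
        raise ValueError("need gain_threshold > 0 > loss_threshold")
    vals = matrix.to_numpy(dtype=float)
    out = np.full(vals.shape, NORMAL, dtype=object)
    out[vals >= gain_threshold] = GAIN
    out[vals <= loss_threshold] = LOSS
    out[np.isnan(vals)] = MISSING
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def concordance(calls_a: pd.Series | Sequence[str], calls_b: pd.Series | Sequence[str]) -> float:
    """Percent agreement between two call vectors at mutually non-missing positions.

    Reported to one decimal, mirroring cross-platform concordance rates.
    """
    a = pd.Series(list(calls_a))
    b = pd.Series(list(calls_b))
    if len(a) != len(b):
        raise ValueError("call vectors must have equal length")
    usable = (a != MISSING) & (b != MISSING)
    if usable.sum() == 0:
        raise ValueError("no mutually non-missing positions to compare")
    agree = (a[usable] == b[usable]).sum()
    return round(100.0 * agree / usable.sum(), 1)
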