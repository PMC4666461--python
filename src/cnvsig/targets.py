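"""Target-gene nomination: probe mapping, SAM permutation screen, fold filters.

For each outcome-associated region, expression probes mapping inside the
interval are tested for differential expression between tumours carrying the
alteration and tumours with normal copy number using a SAM-style moderated
t statistic d_i = (mean_altered - mean_normal) / (s_i + s0), where s_i is the
per-probe pooled standard error and s0 a small positive "fudge" constant that
damps the statistic for probes with tiny scatter.  Significance is assessed by
permuting group labels: at a threshold on |d| the estimated false discovery
rate is the average (over permutations) number of null statistics exceeding
the threshold divided by the observed exceedance count, and the selected set
is the loosest threshold whose FDR estimate drops below the target (10% by
default).  Probes passing the screen are retained as target genes when their
fold change runs in the direction expected from the alteration — above 2x
against copy-neutral tumours, or above 3x against normal testis references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .association import GenomicRegion
from .cohort import GAIN, LOSS


# ---------------------------------------------------------------------------
# probe -> region mapping
# ---------------------------------------------------------------------------

def map_probes_to_region(annotation: pd.DataFrame, region: GenomicRegion) -> list[str]:
    """Probe ids with ``start_mb <= position <= end_mb`` on the region chromosome.

    Probes without genomic coordinates are skipped (their count is recorded on
    the function as ``map_probes_to_region.n_unmapped`` after each call).
    """
    unmapped = annotation["position_mb"].isna() | annotation["chromosome"].isna()
    map_probes_to_region.n_unmapped = int(unmapped.sum())
    usable = annotation[~unmapped]
    hit = usable[(usable["chromosome"] == region.chromosome)
                 & (usable["position_mb"] >= region.start_mb)
                 & (usable["position_mb"] <= region.end_mb)]
    return list(hit["probe_id"])


# ---------------------------------------------------------------------------
# SAM screen
# ---------------------------------------------------------------------------

@dataclass
class SamResult:
    d: pd.Series                  # moderated t per probe
    numerator: pd.Series          # group mean difference (altered - normal copy)
    s: pd.Series                  # per-probe pooled standard error
    s0: float
    threshold_table: pd.DataFrame  # threshold, n_called, null_exceed, fdr
    selected: list[str]
    threshold: float               # chosen |d| cutoff; inf when nothing selected
    n_permutations: int
    exhaustive: bool
    seed: int | None = None


def _group_stats(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (numerator, s) for group1 = mask columns vs group2 = rest."""
    n1 = int(mask.sum())
    n2 = X.shape[1] - n1
    g1, g2 = X[:, mask], X[:, ~mask]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    ss = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = ss / (n1 + n2 - 2)
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return m1 - m2, s


def _safe_d(numer: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """d = numer/(s+s0) with the degenerate all-constant probe mapped to 0/inf."""
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0),
                     np.where(numer == 0, 0.0, np.sign(numer) * np.inf))
    return d


def choose_s0(numerator: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor: the percentile of {s_i} minimising the coefficient of
    variation of the |d| scatter across windows of s.

    Candidate s0 values are the 0th..100th percentiles of s in steps of 5; the
    probes are windowed by quantiles of s and the median absolute deviation of
    d within each window summarises its scatter.  Degenerate inputs (too few
    probes for at least two windows) fall back to the median of s.
    """
    m = len(s)
    n_windows = min(10, m // 3)
    if m < 6 or n_windows < 2 or np.allclose(s, s[0]):
        return float(np.median(s))
    order = np.argsort(s, kind="mergesort")
    bins = np.array_split(order, n_windows)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best, best_cv = float(np.median(s)), math.inf
    for s0 in candidates:
        d = _safe_d(numerator, s, s0)
        mads = np.array([np.median(np.abs(d[b] - np.median(d[b]))) for b in bins])
        mu = mads.mean()
        if mu <= 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv - 1e-12:
            best_cv, best = cv, float(s0)
    return best


def _null_masks(n: int, n1: int, n_perm: int,
                rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Label assignments for the permutation null.

    Exhaustive (every assignment of n1 of n samples to group 1) when that
    count does not exceed ``n_perm``; otherwise ``n_perm`` random shuffles.
    """
    total = comb(n, n1, exact=True)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), n1)):
            masks[row, list(idx)] = True
        return masks, True
    masks = np.zeros((n_perm, n), dtype=bool)
    for row in range(n_perm):
        masks[row, rng.choice(n, size=n1, replace=False)] = True
    return masks, False


def sam_screen(
    expression: pd.DataFrame,
    altered: Sequence[str] | pd.Series,
    n_perm: int = 1000,
    fdr_target: float = 0.10,
    seed: int | None = None,
    s0: float | None = None,
    null_summary: str = "mean",
) -> SamResult:
    """SAM permutation screen of probes (rows) for a two-group contrast.

    ``altered`` is either a boolean Series over the columns or a list of
    column names forming the altered group.  The selected set is the loosest
    |d| threshold at which the estimated FDR first drops below ``fdr_target``;
    when no threshold qualifies the selection is empty (a valid outcome).

    ``null_summary`` chooses how permutation exceedance counts are summarised
    into the FDR numerator: ``'mean'`` (expected false calls, the default) or
    ``'median'``.
    """
    if null_summary not in ("mean", "median"):
        raise ValueError("null_summary must be 'mean' or 'median'")
    if isinstance(altered, pd.Series):
        mask = altered.reindex(expression.columns).fillna(False).to_numpy(dtype=bool)
    else:
        mask = expression.columns.isin(list(altered))
    n = expression.shape[1]
    n1 = int(mask.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least 2 samples per group")
    X = expression.to_numpy(dtype=float)
    numer, s = _group_stats(X, mask)
    if s0 is None:
        s0 = choose_s0(numer, s)
    d = _safe_d(numer, s, s0)

    rng = np.random.default_rng(seed)
    masks, exhaustive = _null_masks(n, n1, n_perm, rng)
    abs_null = np.empty((len(masks), X.shape[0]))
    for row, m_ in enumerate(masks):
        nm, sm = _group_stats(X, m_)
        abs_null[row] = np.abs(_safe_d(nm, sm, s0))

    abs_d = np.abs(d)
    thresholds = np.unique(abs_d)
    # exceedance counts: observed and per-permutation, at every threshold
    n_called = (abs_d[None, :] >= thresholds[:, None]).sum(axis=1)
    null_counts = (abs_null[None, :, :] >= thresholds[:, None, None]).sum(axis=2)
    summary = np.mean if null_summary == "mean" else np.median
    null_exceed = summary(null_counts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0, np.minimum(1.0, null_exceed / n_called), np.nan)

    table = pd.DataFrame({"threshold": thresholds, "n_called": n_called,
                          "null_exceed": null_exceed, "fdr": fdr})
    passing = table[(table["n_called"] > 0) & (table["fdr"] < fdr_target)]
    if len(passing):
        cutoff = float(passing["threshold"].iloc[0])
        selected = list(expression.index[abs_d >= cutoff])
    else:
        cutoff, selected = math.inf, []
    return SamResult(
        d=pd.Series(d, index=expression.index),
        numerator=pd.Series(numer, index=expression.index),
        s=pd.Series(s, index=expression.index),
        s0=float(s0), threshold_table=table, selected=selected,
        threshold=cutoff, n_permutations=len(masks), exhaustive=exhaustive,
        seed=seed)


# ---------------------------------------------------------------------------
# fold changes and target selection
# ---------------------------------------------------------------------------

def fold_changes(
    expression: pd.DataFrame,
    altered_samples: Sequence[str],
    without_samples: Sequence[str],
    normal_samples: Sequence[str],
    alteration_type: str,
) -> pd.DataFrame:
    """Oriented linear-scale fold changes per probe.

    Group means are anti-logged means of the log2 intensities.  Folds are
    oriented in the alteration's expected direction — carrier over comparator
    for gains, comparator over carrier for losses — so that a value > 1 always
    means "changed the right way".
    """
    if min(len(altered_samples), len(without_samples), len(normal_samples)) == 0:
        raise ValueError("all three groups must be non-empty")
    lin = np.exp2(expression.astype(float))
    mean_alt = lin[list(altered_samples)].mean(axis=1)
    mean_wo = lin[list(without_samples)].mean(axis=1)
    mean_norm = lin[list(normal_samples)].mean(axis=1)
    for name, series in (("altered", mean_alt), ("without", mean_wo),
                         ("normals", mean_norm)):
        if not np.isfinite(series).all() or (series <= 0).any():
            raise ValueError(f"non-positive or non-finite linear mean in {name} group")
    if alteration_type == GAIN:
        vs_without = mean_alt / mean_wo
        vs_normals = mean_alt / mean_norm
    elif alteration_type == LOSS:
        vs_without = mean_wo / mean_alt
        vs_normals = mean_norm / mean_alt
    else:
        raise ValueError("alteration_type must be 'gain' or 'loss'")
    return pd.DataFrame({"fold_vs_without": vs_without,
                         "fold_vs_normals": vs_normals})


@dataclass
class TargetGeneSet:
    """Probes passing the SAM screen plus a directional fold-change filter."""

    region_label: str
    alteration_type: str
    endpoint: str | None
    table: pd.DataFrame  # probe_id, fold_vs_without, fold_vs_normals, passes_2x, passes_3x

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])


def select_targets(
    sam_result: SamResult,
    folds: pd.DataFrame,
    region: GenomicRegion,
    endpoint: str | None = None,
    two_x: float = 2.0,
    three_x: float = 3.0,
) -> TargetGeneSet:
    """Retain SAM-significant probes with oriented fold strictly above a cutoff.

    A probe is kept when its oriented fold versus copy-neutral tumours exceeds
    ``two_x`` OR its oriented fold versus normal testes exceeds ``three_x``.
    Oriented folds <= 1 (change in the wrong direction) can never pass.
    """
    rows = []
    for probe in sam_result.selected:
        if probe not in folds.index:
            continue
        f2 = float(folds.at[probe, "fold_vs_without"])
        f3 = float(folds.at[probe, "fold_vs_normals"])
        p2, p3 = f2 > two_x, f3 > three_x
        if p2 or p3:
            rows.append({"probe_id": probe, "fold_vs_without": f2,
                         "fold_vs_normals": f3, "passes_2x": p2, "passes_3x": p3})
    table = pd.DataFrame(rows, columns=["probe_id", "fold_vs_without",
                                        "fold_vs_normals", "passes_2x", "passes_3x"])
    return TargetGeneSet(region.label, region.alteration_type, endpoint, table)


def combine_gene_sets(*probe_sets: dict[str, set[str]] | Sequence[str]
                      ) -> dict[str, set[str]]:
    """Union of probe sets with provenance retained per probe.

    Accepts plain iterables of probe ids or {probe -> provenance set} maps;
    returns {probe -> set of provenance tags} (iterables contribute the tag
    ``set()`` merged with whatever other sets carry).
    """
    out: dict[str, set[str]] = {}
    for ps in probe_sets:
        if isinstance(ps, dict):
            items = ps.items()
        else:
            items = ((p, set()) for p in ps)
        for probe, prov in items:
            out.setdefault(probe, set()).update(prov)
    return out


def endpoint_gene_set(target_sets: Sequence[TargetGeneSet], endpoint: str
                      ) -> dict[str, set[str]]:
    """Pool per-region target sets of one endpoint into {probe -> {endpoint}}."""
    out: dict[str, set[str]] = {}
    for ts in target_sets:
        for probe in ts.probe_ids:
            out.setdefault(probe, set()).add(endpoint)
    return out
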