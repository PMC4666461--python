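"""Clone-by-clone outcome association and genomic region aggregation.

Endpoints
---------
Two binary endpoints are supported.  Two-year disease-free survival (2yDFS):
good means no evidence of disease 24 months after the start of treatment,
poor means never disease free or recurrence within 24 months.  Five-year
disease-specific survival (5yDSS): good means alive five years after initial
treatment, poor means dead of disease within five years; patients censored
alive before 60 months are ineligible and excluded from testing.

Each clone's alteration status (gain and loss tested separately when both
occur) is cross-tabulated against the endpoint over eligible, non-missing
patients and tested with Fisher's exact test.  Significant clones of the same
alteration type on the same chromosome are chained into genomic regions as
long as consecutive significant clones are within a proximity cutoff
(default 11.5 Mb, chosen conservatively to bridge missing or excluded clones
and large inter-clone gaps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GAIN, LOSS, MISSING, CloneMap

ENDPOINT_2YDFS = "2yDFS"
ENDPOINT_5YDSS = "5yDSS"

GOOD = "good"
POOR = "poor"
INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: alteration status (rows) against outcome (columns).

    a = altered & poor, b = altered & good, c = not altered & poor,
    d = not altered & good; missing-call and ineligible patients excluded.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class CloneAssociation:
    clone_id: str
    chromosome: int
    position_mb: float
    alteration_type: str
    table: ContingencyTable
    p_value: float
    odds_ratio: float
    ci_low: float   # NaN when the OR is infinite
    ci_high: float


@dataclass
class GenomicRegion:
    """Outcome-associated interval built from chained significant clones."""

    chromosome: int
    start_mb: float
    end_mb: float
    alteration_type: str
    clone_ids: list[str]
    n_altered_patients: int
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    representative_clone: str
    single_clone: bool = field(default=False)

    @property
    def label(self) -> str:
        return f"chr{self.chromosome}:{self.start_mb:g}-{self.end_mb:g}:{self.alteration_type}"


# ---------------------------------------------------------------------------
# endpoint labels
# ---------------------------------------------------------------------------

def derive_endpoint_labels(records: pd.DataFrame, endpoint: str) -> pd.Series:
    """good/poor/ineligible label per patient for one endpoint.

    ``records`` is a frame as produced by the cohort module (one row per
    patient with follow-up months, event flags and optional recurrence time).
    Contradictory flag combinations raise.
    """
    if endpoint not in (ENDPOINT_2YDFS, ENDPOINT_5YDSS):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    labels = {}
    for pid, row in records.iterrows():
        followup = float(row["followup_months"])
        event = bool(row["disease_event_flag"])
        death = bool(row["death_from_disease_flag"])
        never_free = bool(row["never_disease_free_flag"])
        rec = row.get("recurrence_months", np.nan)
        rec = np.nan if pd.isna(rec) else float(rec)
        if death and not event:
            raise ValueError(f"{pid}: disease death without a disease event")
        if never_free and not event:
            raise ValueError(f"{pid}: never disease free implies a disease event")
        if not np.isnan(rec) and not event:
            raise ValueError(f"{pid}: recurrence recorded without a disease event")
        if endpoint == ENDPOINT_2YDFS:
            poor = never_free or (not np.isnan(rec) and rec <= 24.0) \
                or (death and followup <= 24.0)
            if poor:
                labels[pid] = POOR
            elif followup >= 24.0:
                labels[pid] = GOOD
            else:
                labels[pid] = INELIGIBLE
        else:
            if death and followup <= 60.0:
                labels[pid] = POOR
            elif followup >= 60.0:
                labels[pid] = GOOD
            else:
                labels[pid] = INELIGIBLE
    return pd.Series(labels, name=endpoint)


# ---------------------------------------------------------------------------
# Fisher test and odds ratio
# ---------------------------------------------------------------------------

def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided exact p: sum of hypergeometric probabilities <= observed's.

    A zero row or column margin means the test is undefined; p = 1 is
    returned by convention with a warning.
    """
    t = table
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        warnings.warn("zero margin in 2x2 table; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def odds_ratio(table: ContingencyTable, method: str = "woolf",
               confidence: float = 0.95) -> tuple[float, float, float]:
    """Sample odds ratio ad/(bc) with a confidence interval.

    b = 0 or c = 0 gives an infinite OR with the interval reported absent
    (NaN, NaN).  ``method='woolf'`` uses the log-normal interval with a
    Haldane-Anscombe 0.5 continuity correction applied only when some cell is
    zero but the OR is finite; ``method='exact'`` uses the exact conditional
    interval.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b == 0 or c == 0:
        return math.inf, math.nan, math.nan
    if a == 0 or d == 0:
        or_hat = 0.0
    else:
        or_hat = (a * d) / (b * c)
    if method == "exact":
        res = stats.contingency.odds_ratio(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=confidence)
        return or_hat, float(ci.low), float(ci.high)
    if method != "woolf":
        raise ValueError("method must be 'woolf' or 'exact'")
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    la = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = math.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(0.5 + confidence / 2)
    return or_hat, math.exp(la - z * se), math.exp(la + z * se)


# ---------------------------------------------------------------------------
# per-clone association scan
# ---------------------------------------------------------------------------

def clone_association(
    calls: pd.DataFrame,
    labels: pd.Series,
    clone_id: str,
    alteration_type: str,
    clone_map: CloneMap | None = None,
) -> CloneAssociation | None:
    """Association of one clone's alteration status with the endpoint.

    Only eligible patients with a non-missing call enter the 2x2 table;
    clones with no altered patient are skipped (None returned).
    """
    row = calls.loc[clone_id]
    eligible = labels[labels.isin([GOOD, POOR])]
    common = row.index.intersection(eligible.index)
    row = row[common]
    lab = eligible[common]
    usable = row != MISSING
    row, lab = row[usable], lab[usable]
    altered = row == alteration_type
    if altered.sum() == 0:
        return None
    t = ContingencyTable(
        a=int(((altered) & (lab == POOR)).sum()),
        b=int(((altered) & (lab == GOOD)).sum()),
        c=int((~altered & (lab == POOR)).sum()),
        d=int((~altered & (lab == GOOD)).sum()),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = fisher_exact(t)
    or_hat, lo, hi = odds_ratio(t)
    chrom, pos = -1, math.nan
    if clone_map is not None:
        rec = clone_map.frame.set_index("clone_id").loc[clone_id]
        chrom, pos = int(rec["chromosome"]), float(rec["position_mb"])
    return CloneAssociation(clone_id, chrom, pos, alteration_type, t, p, or_hat, lo, hi)


def associate_all(
    calls: pd.DataFrame,
    labels: pd.Series,
    clone_map: CloneMap,
    alteration_types: Sequence[str] = (GAIN, LOSS),
) -> pd.DataFrame:
    """Fisher scan over every clone and alteration type with >= 1 altered patient.

    Returns one row per (clone, type), sorted by chromosome and position.
    """
    if not labels.isin([GOOD, POOR]).any():
        raise ValueError("no eligible patients for this endpoint")
    info = clone_map.frame.set_index("clone_id")
    eligible = labels[labels.isin([GOOD, POOR])]
    common = calls.columns.intersection(eligible.index)
    sub = calls[common].to_numpy(dtype=object)
    poor_vec = (eligible[common] == POOR).to_numpy(dtype=float)
    good_vec = 1.0 - poor_vec
    nonmissing = sub != MISSING

    @lru_cache(maxsize=None)
    def _test(a: int, b: int, c: int, d: int):
        t = ContingencyTable(a, b, c, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact(t)
        return (p, *odds_ratio(t))

    rows = []
    for alt in alteration_types:
        altered = (sub == alt)
        not_altered = nonmissing & ~altered
        a_col = altered @ poor_vec
        b_col = altered @ good_vec
        c_col = not_altered @ poor_vec
        d_col = not_altered @ good_vec
        for ci, clone_id in enumerate(calls.index):
            if clone_id not in info.index:
                continue
            a, b = int(a_col[ci]), int(b_col[ci])
            if a + b == 0:
                continue
            c, d = int(c_col[ci]), int(d_col[ci])
            p, or_hat, lo, hi = _test(a, b, c, d)
            rows.append({
                "clone_id": clone_id,
                "chromosome": int(info.at[clone_id, "chromosome"]),
                "position_mb": float(info.at[clone_id, "position_mb"]),
                "alteration_type": alt,
                "a": a, "b": b, "c": c, "d": d,
                "n_altered": a + b,
                "p_value": p,
                "odds_ratio": or_hat,
                "ci_low": lo, "ci_high": hi,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["chromosome", "position_mb", "alteration_type"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# region aggregation
# ---------------------------------------------------------------------------

def build_regions(
    associations: pd.DataFrame,
    clone_map: CloneMap,
    alpha: float = 0.05,
    max_gap_mb: float = 11.5,
    min_clones: int = 1,
    representative: str = "min_p",
) -> list[GenomicRegion]:
    """Chain significant clones (p < alpha) into regions by the proximity rule.

    Consecutive significant clones of the same alteration type on the same
    chromosome are merged while their gap is <= ``max_gap_mb``.  Region
    boundaries are the first/last clone positions (closed interval, Mb); the
    region-level p/OR/CI come from a representative clone — the clone with
    minimal p (``'min_p'``, ties to the smaller position) or the clone with
    the most altered patients (``'max_altered'``).  Regions with fewer than
    ``min_clones`` clones are dropped; single-clone regions are flagged.
    """
    if representative not in ("min_p", "max_altered"):
        raise ValueError("representative must be 'min_p' or 'max_altered'")
    if len(associations) == 0:
        return []
    sig = associations[associations["p_value"] < alpha]
    regions: list[GenomicRegion] = []
    for (chrom, alt), grp in sig.groupby(["chromosome", "alteration_type"]):
        grp = grp.sort_values("position_mb")
        if not grp["position_mb"].is_monotonic_increasing:
            raise ValueError("associations must be sortable by position")
        chains: list[list[int]] = []
        prev_pos = None
        for idx, pos in zip(grp.index, grp["position_mb"]):
            if prev_pos is None or pos - prev_pos > max_gap_mb:
                chains.append([idx])
            else:
                chains[-1].append(idx)
            prev_pos = pos
        for chain in chains:
            block = grp.loc[chain]
            if len(block) < min_clones:
                continue
            if representative == "min_p":
                rep = block.sort_values(["p_value", "position_mb"]).iloc[0]
            else:
                rep = block.sort_values(["n_altered", "position_mb"],
                                        ascending=[False, True]).iloc[0]
            regions.append(GenomicRegion(
                chromosome=int(chrom),
                start_mb=float(block["position_mb"].min()),
                end_mb=float(block["position_mb"].max()),
                alteration_type=str(alt),
                clone_ids=list(block["clone_id"]),
                n_altered_patients=int(rep["n_altered"]),
                p_value=float(rep["p_value"]),
                odds_ratio=float(rep["odds_ratio"]),
                ci_low=float(rep["ci_low"]),
                ci_high=float(rep["ci_high"]),
                representative_clone=str(rep["clone_id"]),
                single_clone=len(block) == 1,
            ))
    regions.sort(key=lambda r: (r.chromosome, r.start_mb, r.alteration_type))
    return regions


def region_gap_stats(regions: Sequence[GenomicRegion], clone_map: CloneMap
                     ) -> tuple[float, float]:
    """Median and mean gap (Mb) between consecutive clones inside regions.

    Gaps are pooled over all regions with at least two clones.
    """
    positions = clone_map.positions()
    gaps: list[float] = []
    for region in regions:
        pos = np.sort(positions.reindex(region.clone_ids).to_numpy())
        if len(pos) >= 2:
            gaps.extend(np.diff(pos).tolist())
    if not gaps:
        raise ValueError("no multi-clone regions; gap statistics undefined")
    return float(np.median(gaps)), float(np.mean(gaps))


def region_table(regions: Sequence[GenomicRegion]) -> pd.DataFrame:
    """Report rows in the conventional region-table layout; infinite OR
    printed INF with the CI as N/A."""
    rows = []
    for r in regions:
        inf = math.isinf(r.odds_ratio)
        rows.append({
            "Chr": r.chromosome,
            "Region (in Mb)": f"{r.start_mb:g}-{r.end_mb:g}",
            "No.": r.n_altered_patients,
            "Alt.": r.alteration_type,
            "P Value": round(r.p_value, 3),
            "OR": "INF" if inf else f"{r.odds_ratio:.2f}",
            "95% C.I.": "N/A" if inf else f"{r.ci_low:.2f}-{r.ci_high:.2f}",
            "Clones": len(r.clone_ids),
            "Single clone": r.single_clone,
        })
    columns = ["Chr", "Region (in Mb)", "No.", "Alt.", "P Value", "OR",
               "95% C.I.", "Clones", "Single clone"]
    return pd.DataFrame(rows, columns=columns)
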