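"""Synthetic germ-cell-tumour cohorts with planted copy-number/outcome structure.

The generator emulates the statistical structure of a two-cohort NSGCT study:
a training cohort with ~1 Mb BAC array-CGH log-ratio profiles plus expression,
an expression-only validation cohort split over two array batches (the second
carrying a multiplicative per-gene batch effect), and a small panel of normal
testis reference samples.  Outcome-associated gain/loss regions are planted in
patient subsets; expression probes inside those regions track copy number with
a configurable fold shift ("dosage" probes); poor outcome follows a logistic
model in the carrier indicators, with an infinite log-odds effect available to
emulate regions where every altered patient had a poor outcome.

Everything is seed-deterministic: the same seed reproduces the cohort
byte-for-byte, and full ground truth (carrier indicators, dosage probe ids,
region intervals) is returned alongside the data so each downstream stage of
the pipeline can be benchmarked against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

GAIN = "gain"
LOSS = "loss"
MISSING = "missing"
NORMAL = "normal"

_RISK_LEVELS = ("good", "intermediate", "poor")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class CloneMap:
    """Ordered genomic positions of array clones.

    Thin wrapper around a DataFrame with columns ``clone_id``, ``chromosome``
    and ``position_mb``.  Positions must be strictly increasing within each
    chromosome and clone ids unique.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"clone_id", "chromosome", "position_mb"}
        if not required.issubset(frame.columns):
            raise ValueError(f"clone map needs columns {sorted(required)}")
        frame = frame.reset_index(drop=True)
        if frame["clone_id"].duplicated().any():
            raise ValueError("clone ids must be unique")
        if (frame["position_mb"] < 0).any():
            raise ValueError("positions must be non-negative")
        for _, grp in frame.groupby("chromosome"):
            pos = grp["position_mb"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        self.frame = frame

    @property
    def clone_ids(self) -> pd.Index:
        return pd.Index(self.frame["clone_id"])

    def __len__(self) -> int:
        return len(self.frame)

    def chromosomes(self) -> list[int]:
        return sorted(self.frame["chromosome"].unique())

    def chromosome_frame(self, chromosome: int) -> pd.DataFrame:
        return self.frame[self.frame["chromosome"] == chromosome]

    def clones_in(self, chromosome: int, start_mb: float, end_mb: float) -> pd.DataFrame:
        """Clones with ``start_mb <= position <= end_mb`` (closed interval)."""
        sub = self.chromosome_frame(chromosome)
        return sub[(sub["position_mb"] >= start_mb) & (sub["position_mb"] <= end_mb)]

    def positions(self) -> pd.Series:
        return self.frame.set_index("clone_id")["position_mb"]


@dataclass(frozen=True)
class RegionSpec:
    """A planted outcome-associated copy-number region.

    ``effect_log_odds`` is the poor-outcome log-odds increment for carriers;
    ``math.inf`` makes every carrier a poor-outcome patient (infinite odds
    ratio).
    """

    chromosome: int
    start_mb: float
    end_mb: float
    alteration_type: str
    prevalence: float
    effect_log_odds: float

    def __post_init__(self):
        if self.start_mb >= self.end_mb:
            raise ValueError("start_mb must be < end_mb")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if self.alteration_type not in (GAIN, LOSS):
            raise ValueError("alteration_type must be 'gain' or 'loss'")

    @property
    def label(self) -> str:
        return f"chr{self.chromosome}:{self.start_mb:g}-{self.end_mb:g}:{self.alteration_type}"


@dataclass
class OutcomeRecord:
    """Raw follow-up record from which endpoint labels are derived."""

    patient_id: str
    followup_months: float
    disease_event_flag: bool
    death_from_disease_flag: bool
    never_disease_free_flag: bool
    recurrence_months: float | None
    igcccg_risk: str
    batch: str

    def __post_init__(self):
        if self.followup_months < 0:
            raise ValueError("followup_months must be non-negative")
        if self.igcccg_risk not in _RISK_LEVELS:
            raise ValueError(f"igcccg_risk must be one of {_RISK_LEVELS}")


def records_to_frame(records: Sequence[OutcomeRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in records])
    return frame.set_index("patient_id", drop=False)


def frame_to_records(frame: pd.DataFrame) -> list[OutcomeRecord]:
    out = []
    for _, row in frame.iterrows():
        rec = row.get("recurrence_months", np.nan)
        out.append(OutcomeRecord(
            patient_id=str(row["patient_id"]),
            followup_months=float(row["followup_months"]),
            disease_event_flag=bool(row["disease_event_flag"]),
            death_from_disease_flag=bool(row["death_from_disease_flag"]),
            never_disease_free_flag=bool(row["never_disease_free_flag"]),
            recurrence_months=None if pd.isna(rec) else float(rec),
            igcccg_risk=str(row["igcccg_risk"]),
            batch=str(row["batch"]),
        ))
    return out


# ---------------------------------------------------------------------------
# clone map and probe annotation
# ---------------------------------------------------------------------------

def build_clone_map(n_clones_per_chrom: Sequence[int], spacing_mb: float = 1.0) -> CloneMap:
    """Evenly spaced clones: chromosome ``c`` gets clones at spacing, 2*spacing, ...

    Deterministic; chromosome numbering starts at 1.
    """
    if spacing_mb <= 0:
        raise ValueError("spacing_mb must be positive")
    if len(n_clones_per_chrom) == 0:
        raise ValueError("need at least one chromosome")
    rows = []
    for c, n in enumerate(n_clones_per_chrom, start=1):
        if n <= 0:
            raise ValueError("each chromosome needs at least one clone")
        for i in range(n):
            rows.append({
                "clone_id": f"BAC-{c}-{i + 1:04d}",
                "chromosome": c,
                "position_mb": spacing_mb * (i + 1),
            })
    return CloneMap(pd.DataFrame(rows))


def build_probe_annotation(
    clone_map: CloneMap,
    regions: Sequence[RegionSpec],
    probes_per_chrom: int = 30,
    dosage_probes_per_region: int = 4,
    n_unmapped: int = 2,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expression probe annotation with planted dosage probes inside each region.

    Background probes sit on an even grid per chromosome; each region gets
    ``dosage_probes_per_region`` extra probes spaced inside its interval.
    A few probes without genomic coordinates (position NaN) exercise the
    unannotated-probe bookkeeping downstream.

    Returns (annotation frame, {region label -> dosage probe ids}).
    """
    rows = []
    gene_no = 0
    for chrom in clone_map.chromosomes():
        sub = clone_map.chromosome_frame(chrom)
        lo, hi = sub["position_mb"].min(), sub["position_mb"].max()
        for i, pos in enumerate(np.linspace(lo, hi, probes_per_chrom)):
            gene_no += 1
            rows.append({
                "probe_id": f"P{chrom}_{i + 1:03d}",
                "chromosome": chrom,
                "position_mb": round(float(pos), 4),
                "gene_symbol": f"GENE{gene_no}",
            })
    dosage: dict[str, list[str]] = {}
    for r_idx, region in enumerate(regions, start=1):
        ids = []
        span = region.end_mb - region.start_mb
        inner = np.linspace(region.start_mb + 0.1 * span, region.end_mb - 0.1 * span,
                            dosage_probes_per_region)
        for j, pos in enumerate(inner):
            gene_no += 1
            pid = f"D{r_idx}_{j + 1:02d}"
            rows.append({
                "probe_id": pid,
                "chromosome": region.chromosome,
                "position_mb": round(float(pos), 4),
                "gene_symbol": f"TARGET{gene_no}",
            })
            ids.append(pid)
        dosage[region.label] = ids
    for k in range(n_unmapped):
        rows.append({"probe_id": f"U_{k + 1:02d}", "chromosome": np.nan,
                     "position_mb": np.nan, "gene_symbol": f"UNMAPPED{k + 1}"})
    frame = pd.DataFrame(rows)
    if frame["probe_id"].duplicated().any():
        raise ValueError("probe ids collide; adjust naming")
    return frame, dosage


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def draw_carriers(regions: Sequence[RegionSpec], sample_ids: Sequence[str],
                  rng: np.random.Generator) -> pd.DataFrame:
    """Independent Bernoulli(prevalence) carrier indicators, regions x samples."""
    data = {r.label: rng.random(len(sample_ids)) < r.prevalence for r in regions}
    return pd.DataFrame(data, index=list(sample_ids)).T


def copy_number_from_carriers(
    clone_map: CloneMap,
    regions: Sequence[RegionSpec],
    carriers: pd.DataFrame,
    gain_shift: float = 0.4,
    loss_shift: float = -0.6,
    noise_sd: float = 0.15,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Log2-ratio matrix (clones x samples) for fixed carrier indicators.

    Carrier samples have their region clones shifted by ``gain_shift`` /
    ``loss_shift``; i.i.d. Gaussian noise and independent clone-by-sample
    missingness (NaN) are layered on top.
    """
    rng = np.random.default_rng() if rng is None else rng
    sample_ids = list(carriers.columns)
    n_clones, n_samples = len(clone_map), len(sample_ids)
    mat = np.zeros((n_clones, n_samples))
    clone_index = pd.Index(clone_map.clone_ids)
    for region in regions:
        in_region = clone_map.clones_in(region.chromosome, region.start_mb, region.end_mb)
        if len(in_region) == 0:
            raise ValueError(f"region {region.label} covers no clones of the map")
        rows = clone_index.get_indexer(in_region["clone_id"])
        shift = gain_shift if region.alteration_type == GAIN else loss_shift
        carrier_cols = np.flatnonzero(carriers.loc[region.label].to_numpy())
        mat[np.ix_(rows, carrier_cols)] += shift
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat[mask] = np.nan
    return pd.DataFrame(mat, index=clone_index, columns=sample_ids)


def simulate_copy_number(
    clone_map: CloneMap,
    regions: Sequence[RegionSpec],
    n_samples: int,
    seed: int | None = None,
    sample_prefix: str = "S",
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw carriers and the corresponding log-ratio matrix in one shot.

    Returns ``(log_ratio_matrix, carriers)``; see
    :func:`copy_number_from_carriers` for the noise/missingness keywords.
    """
    for region in regions:
        if len(clone_map.clones_in(region.chromosome, region.start_mb, region.end_mb)) == 0:
            raise ValueError(f"region {region.label} lies outside the clone map")
    rng = np.random.default_rng(seed)
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]
    carriers = draw_carriers(regions, sample_ids, rng)
    matrix = copy_number_from_carriers(clone_map, regions, carriers, rng=rng, **kwargs)
    return matrix, carriers


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    regions: Sequence[RegionSpec],
    carriers: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    dosage_probe_ids: dict[str, list[str]],
    baseline: pd.Series,
    dosage_fold: float = 2.5,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Log2 expression (probes x samples) with dosage probes tracking copy number.

    Dosage probes shift by ``log2(dosage_fold)`` in carriers — up for gains,
    down for losses; all other probes are exchangeable between carrier groups.
    ``baseline`` is the per-probe log2 baseline shared across batches so that
    repeated calls (training / validation / normals) stay on one scale.
    """
    if dosage_fold < 1:
        raise ValueError("dosage_fold must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    probe_ids = pd.Index(probe_annotation["probe_id"])
    if not probe_ids.equals(pd.Index(baseline.index)):
        baseline = baseline.reindex(probe_ids)
        if baseline.isna().any():
            raise ValueError("baseline missing for some probes")
    sample_ids = list(carriers.columns)
    mat = np.tile(baseline.to_numpy()[:, None], (1, len(sample_ids))).astype(float)
    shift = math.log2(dosage_fold)
    for region in regions:
        sign = 1.0 if region.alteration_type == GAIN else -1.0
        rows = probe_ids.get_indexer(dosage_probe_ids.get(region.label, []))
        rows = rows[rows >= 0]
        carrier_cols = np.flatnonzero(carriers.loc[region.label].to_numpy())
        if len(rows) and len(carrier_cols):
            mat[np.ix_(rows, carrier_cols)] += sign * shift
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    return pd.DataFrame(mat, index=probe_ids, columns=sample_ids)


def simulate_normals(
    probe_annotation: pd.DataFrame,
    baseline: pd.Series,
    n_normals: int,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Normal-testis reference expression: baseline plus noise, no alterations."""
    rng = np.random.default_rng() if rng is None else rng
    probe_ids = pd.Index(probe_annotation["probe_id"])
    cols = [f"N{i + 1:02d}" for i in range(n_normals)]
    base = baseline.reindex(probe_ids).to_numpy()[:, None]
    mat = np.tile(base, (1, n_normals))
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    return pd.DataFrame(mat, index=probe_ids, columns=cols)


def apply_batch_effect(
    expression: pd.DataFrame,
    batch_factors: pd.Series,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Multiplicative per-gene scaling on the linear scale for selected samples.

    ``batch_factors`` are linear-scale factors (must be positive); on the log2
    matrix this is an additive per-gene offset of ``log2(factor)``.  Samples
    not listed are untouched.
    """
    factors = batch_factors.reindex(expression.index)
    if factors.isna().any():
        raise ValueError("batch factor missing for some probes")
    if (factors <= 0).any():
        raise ValueError("batch factors must be positive")
    out = expression.copy()
    cols = list(expression.columns) if samples is None else list(samples)
    out.loc[:, cols] = out.loc[:, cols].add(np.log2(factors), axis=0)
    return out


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def simulate_outcomes(
    carriers: pd.DataFrame,
    regions: Sequence[RegionSpec],
    baseline_poor_rate: float,
    seed: int | np.random.Generator | None = None,
    censor_rate: float = 0.0,
    batch: str = "train",
    never_free_fraction: float = 0.3,
) -> pd.DataFrame:
    """Outcome records with poor-outcome odds following planted carrier status.

    Poor-outcome probability is ``logistic(logit(baseline) + sum effects)``
    over carried regions; an infinite effect makes every carrier poor.  Poor
    patients either are never disease free or recur within two years, and die
    of disease before five years; good patients are disease free, with a
    ``censor_rate`` fraction censored alive between 2 and 5 years (ineligible
    for the five-year endpoint).
    """
    if not 0 < baseline_poor_rate < 1:
        raise ValueError("baseline_poor_rate must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = {r.label: r.effect_log_odds for r in regions}
    base_logit = math.log(baseline_poor_rate / (1 - baseline_poor_rate))
    rows = []
    for patient in carriers.columns:
        logit = base_logit
        for label, effect in effects.items():
            if carriers.at[label, patient]:
                logit += effect
        p_poor = 1.0 if math.isinf(logit) and logit > 0 else 1 / (1 + math.exp(-logit))
        poor = rng.random() < p_poor
        if poor:
            never_free = rng.random() < never_free_fraction
            if never_free:
                recurrence = np.nan
            else:
                recurrence = rng.uniform(3.0, 22.0)
            lo = 6.0 if never_free else recurrence + 2.0
            death = rng.uniform(lo, 58.0)
            rec = dict(followup_months=death, disease_event_flag=True,
                       death_from_disease_flag=True, never_disease_free_flag=never_free,
                       recurrence_months=recurrence)
        else:
            if rng.random() < censor_rate:
                followup = rng.uniform(25.0, 59.0)
            else:
                followup = rng.uniform(61.0, 120.0)
            rec = dict(followup_months=followup, disease_event_flag=False,
                       death_from_disease_flag=False, never_disease_free_flag=False,
                       recurrence_months=np.nan)
        risk_p = (0.3, 0.3, 0.4) if poor else (0.7, 0.2, 0.1)
        rec.update(patient_id=patient, batch=batch,
                   igcccg_risk=_RISK_LEVELS[rng.choice(3, p=risk_p)])
        rows.append(rec)
    frame = pd.DataFrame(rows).set_index("patient_id", drop=False)
    return frame[["patient_id", "followup_months", "disease_event_flag",
                  "death_from_disease_flag", "never_disease_free_flag",
                  "recurrence_months", "igcccg_risk", "batch"]]


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def default_regions() -> list[RegionSpec]:
    """Three planted regions spanning the prevalence/effect range of interest.

    The conditional log-odds effects are set so that the *marginal*
    carrier-versus-rest odds ratios (after dilution by co-carried regions)
    land in the strongly-penetrant range the approach is designed to detect:
    around 13-15 for the two finite regions, plus one region with an infinite
    effect where every carrier has poor outcome (the infinite-OR case).
    """
    return [
        RegionSpec(1, 10.0, 20.0, LOSS, prevalence=0.25, effect_log_odds=4.5),
        RegionSpec(2, 25.0, 33.0, GAIN, prevalence=0.18, effect_log_odds=4.5),
        RegionSpec(3, 5.0, 12.0, GAIN, prevalence=0.15, effect_log_odds=math.inf),
    ]


@dataclass
class StudyConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    n_train: int = 53
    n_val: int = 54
    n_normals: int = 6
    n_chromosomes: int = 4
    clones_per_chrom: int = 50
    spacing_mb: float = 1.0
    regions: list[RegionSpec] = field(default_factory=default_regions)
    probes_per_chrom: int = 30
    dosage_probes_per_region: int = 4
    dosage_fold: float = 2.5
    expr_noise_sd: float = 0.5
    baseline_log2_range: tuple[float, float] = (6.0, 10.0)
    gain_shift: float = 0.4
    loss_shift: float = -0.6
    cn_noise_sd: float = 0.15
    missing_rate: float = 0.02
    baseline_poor_rate: float = 0.05
    batch_log2_sd: float = 0.3
    censor_rate: float = 0.09

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [asdict(r) for r in self.regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = [RegionSpec(**r) for r in d["regions"]]
        if "baseline_log2_range" in d:
            d["baseline_log2_range"] = tuple(d["baseline_log2_range"])
        return cls(**d)


@dataclass
class Study:
    """A simulated two-cohort study plus full ground truth."""

    config: StudyConfig
    seed: int
    clone_map: CloneMap
    regions: list[RegionSpec]
    probe_annotation: pd.DataFrame
    dosage_probe_ids: dict[str, list[str]]
    baseline: pd.Series
    train_cn: pd.DataFrame
    train_carriers: pd.DataFrame
    val_carriers: pd.DataFrame
    train_expr: pd.DataFrame
    val_expr: pd.DataFrame            # batch effect applied to val2 columns
    val_expr_clean: pd.DataFrame      # before the batch effect
    normal_expr: pd.DataFrame
    train_outcomes: pd.DataFrame
    val_outcomes: pd.DataFrame
    batch_factors: pd.Series

    @property
    def val_batches(self) -> pd.Series:
        return self.val_outcomes["batch"]


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> Study:
    """Generate the full training/validation/normals study deterministically."""
    config = StudyConfig() if config is None else config
    streams = [np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
               for k in range(8)]
    (rng_cn, rng_expr, rng_out, rng_base, rng_batch, rng_valcar, rng_norm, _) = streams

    clone_map = build_clone_map([config.clones_per_chrom] * config.n_chromosomes,
                                config.spacing_mb)
    regions = list(config.regions)
    annotation, dosage_ids = build_probe_annotation(
        clone_map, regions, config.probes_per_chrom, config.dosage_probes_per_region)
    probe_ids = pd.Index(annotation["probe_id"])
    lo, hi = config.baseline_log2_range
    baseline = pd.Series(rng_base.uniform(lo, hi, len(probe_ids)), index=probe_ids)

    train_ids = [f"T{i + 1:03d}" for i in range(config.n_train)]
    val_ids = [f"V{i + 1:03d}" for i in range(config.n_val)]
    train_carriers = draw_carriers(regions, train_ids, rng_cn)
    val_carriers = draw_carriers(regions, val_ids, rng_valcar)

    train_cn = copy_number_from_carriers(
        clone_map, regions, train_carriers,
        gain_shift=config.gain_shift, loss_shift=config.loss_shift,
        noise_sd=config.cn_noise_sd, missing_rate=config.missing_rate, rng=rng_cn)

    train_expr = simulate_expression(regions, train_carriers, annotation, dosage_ids,
                                     baseline, config.dosage_fold,
                                     config.expr_noise_sd, rng_expr)
    val_expr_clean = simulate_expression(regions, val_carriers, annotation, dosage_ids,
                                         baseline, config.dosage_fold,
                                         config.expr_noise_sd, rng_expr)
    normal_expr = simulate_normals(annotation, baseline, config.n_normals,
                                   config.expr_noise_sd, rng_norm)

    train_outcomes = simulate_outcomes(train_carriers, regions,
                                       config.baseline_poor_rate, rng_out,
                                       censor_rate=0.0, batch="train")
    n_val1 = config.n_val // 2
    val_outcomes = simulate_outcomes(val_carriers, regions,
                                     config.baseline_poor_rate, rng_out,
                                     censor_rate=config.censor_rate, batch="val1")
    val_outcomes.loc[val_outcomes.index[n_val1:], "batch"] = "val2"

    batch_factors = pd.Series(
        np.exp2(rng_batch.normal(0.0, config.batch_log2_sd, len(probe_ids))),
        index=probe_ids)
    val2_ids = list(val_outcomes.index[val_outcomes["batch"] == "val2"])
    val_expr = apply_batch_effect(val_expr_clean, batch_factors, val2_ids)

    return Study(config=config, seed=seed, clone_map=clone_map, regions=regions,
                 probe_annotation=annotation, dosage_probe_ids=dosage_ids,
                 baseline=baseline, train_cn=train_cn,
                 train_carriers=train_carriers, val_carriers=val_carriers,
                 train_expr=train_expr, val_expr=val_expr,
                 val_expr_clean=val_expr_clean, normal_expr=normal_expr,
                 train_outcomes=train_outcomes, val_outcomes=val_outcomes,
                 batch_factors=batch_factors)
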