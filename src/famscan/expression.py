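"""Stress-expression evidence aggregation and qRT-PCR fold-change analysis.

Two evidence streams are aggregated: microarray records (GEO sample series)
and EST library records, each naming the family genes they support under a
stress condition.  qRT-PCR quantification cycles are converted to relative
expression with the Livak 2^-ddCt method: technical replicates are averaged
in Cq space, dCt = Cq_target - Cq_reference per sample, ddCt = dCt_treated
- dCt_control, and biological replicates are summarized in fold space
(mean +/- SD of per-replicate 2^-ddCt).  Amplification efficiency is fixed
at perfect doubling.

Response thresholds follow common qPCR practice for this family:
fold >= 2 up-regulated, fold <= 0.5 down-regulated, fold >= 20 highly
up-regulated; a gene highly up-regulated under all profiled stresses is
flagged multi-stress responsive.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

UP_FOLD = 2.0
DOWN_FOLD = 0.5
HIGH_UP_FOLD = 20.0

RESPONSE_NONE = "none"
RESPONSE_UP = "up"
RESPONSE_DOWN = "down"
RESPONSE_HIGH_UP = "high_up"


@dataclass(frozen=True)
class EvidenceRecord:
    record_id: str
    gene_ids: Tuple[str, ...]
    source_id: str
    condition: str

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"evidence record {self.record_id} names no genes")

    @property
    def source_kind(self) -> str:
        return "microarray" if self.source_id.strip().upper().startswith("GSM") else "est"


@dataclass
class EvidenceSummary:
    microarray_genes: List[str]
    est_genes: List[str]
    est_record_count: int
    est_library_count: int

    @property
    def microarray_gene_count(self) -> int:
        return len(self.microarray_genes)

    @property
    def est_gene_count(self) -> int:
        return len(self.est_genes)

    @property
    def per_kind_sum(self) -> int:
        """Sum of per-kind distinct gene counts (double-counts shared genes)."""
        return self.microarray_gene_count + self.est_gene_count

    @property
    def union_genes(self) -> List[str]:
        return sorted(set(self.microarray_genes) | set(self.est_genes))

    @property
    def union_count(self) -> int:
        return len(self.union_genes)


def read_evidence_csv(path: str | Path) -> List[EvidenceRecord]:
    """Evidence CSV columns: record_id, genes (';'-separated), source_id,
    condition."""
    df = pd.read_csv(path, dtype=str)
    records = []
    for idx, row in df.iterrows():
        genes = tuple(g.strip() for g in str(row["genes"]).split(";") if g.strip())
        records.append(
            EvidenceRecord(
                record_id=str(row["record_id"]),
                gene_ids=genes,
                source_id=str(row["source_id"]),
                condition=str(row["condition"]),
            )
        )
    return records


def summarize_evidence(records: Sequence[EvidenceRecord]) -> EvidenceSummary:
    """Distinct induced/preferentially-expressed genes per evidence kind.

    Both the per-kind sum and the deduplicated union are exposed on the
    summary: published family surveys often report the per-kind sum, which
    double-counts genes supported by both microarray and EST evidence.
    """
    micro: set = set()
    est: set = set()
    est_records = 0
    est_libraries: set = set()
    for rec in records:
        if rec.source_kind == "microarray":
            micro.update(rec.gene_ids)
        else:
            est.update(rec.gene_ids)
            est_records += 1
            est_libraries.add(rec.source_id)
    return EvidenceSummary(
        microarray_genes=sorted(micro),
        est_genes=sorted(est),
        est_record_count=est_records,
        est_library_count=len(est_libraries),
    )


@dataclass
class QpcrMeasurement:
    """Cq values for one gene x condition x timepoint.

    Arrays are (biological x technical) replicates; treated and control
    samples must share the replicate layout.
    """

    gene: str
    condition: str
    timepoint_h: float
    target_treated: np.ndarray
    reference_treated: np.ndarray
    target_control: np.ndarray
    reference_control: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            "target_treated": self.target_treated,
            "reference_treated": self.reference_treated,
            "target_control": self.target_control,
            "reference_control": self.reference_control,
        }
        shape = None
        for name, arr in arrays.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.gene}: non-finite Cq in {name}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"{self.gene}: ragged replicate structure in {name}")


@dataclass
class FoldChangeEstimate:
    fold: float  # mean over biological replicates
    sd: float  # SD over biological replicates (0 with a single replicate)
    replicate_folds: np.ndarray


def delta_delta_ct(m: QpcrMeasurement) -> FoldChangeEstimate:
    """Livak 2^-ddCt fold change for one measurement.

    Technical replicates are averaged in Cq space within each biological
    replicate; ddCt and the fold change are computed per biological
    replicate and summarized as mean +/- SD in fold space.
    """
    dct_treated = m.target_treated.mean(axis=1) - m.reference_treated.mean(axis=1)
    dct_control = m.target_control.mean(axis=1) - m.reference_control.mean(axis=1)
    ddct = dct_treated - dct_control
    folds = np.power(2.0, -ddct)
    sd = float(folds.std(ddof=1)) if folds.size > 1 else 0.0
    return FoldChangeEstimate(fold=float(folds.mean()), sd=sd, replicate_folds=folds)


def classify_fold(fold: float) -> str:
    if fold <= 0:
        raise ValueError("fold changes must be positive")
    if fold >= HIGH_UP_FOLD:
        return RESPONSE_HIGH_UP
    if fold >= UP_FOLD:
        return RESPONSE_UP
    if fold <= DOWN_FOLD:
        return RESPONSE_DOWN
    return RESPONSE_NONE


@dataclass
class FoldChangeProfile:
    """Per-gene, per-condition fold-change time series."""

    gene: str
    condition: str
    timepoints_h: List[float]
    folds: List[float]
    sds: List[float]

    @property
    def classes(self) -> List[str]:
        return [classify_fold(f) for f in self.folds]

    @property
    def responsive(self) -> bool:
        return any(c != RESPONSE_NONE for c in self.classes)

    @property
    def highly_responsive(self) -> bool:
        return any(c == RESPONSE_HIGH_UP for c in self.classes)

    def log2_folds(self) -> np.ndarray:
        return np.log2(np.asarray(self.folds))


def classify_response(
    profiles: Sequence[FoldChangeProfile],
) -> Dict[str, Dict[str, object]]:
    """Cohort-level response calls from per-condition profiles.

    Returns, per gene: responsive/highly-responsive condition lists and the
    multi-stress flag (highly up-regulated under every profiled condition).
    """
    by_gene: Dict[str, List[FoldChangeProfile]] = defaultdict(list)
    all_conditions: set = set()
    for p in profiles:
        by_gene[p.gene].append(p)
        all_conditions.add(p.condition)
    out: Dict[str, Dict[str, object]] = {}
    for gene in sorted(by_gene):
        gene_profiles = by_gene[gene]
        responsive = sorted(p.condition for p in gene_profiles if p.responsive)
        highly = sorted(p.condition for p in gene_profiles if p.highly_responsive)
        out[gene] = {
            "responsive_conditions": responsive,
            "highly_responsive_conditions": highly,
            "multi_stress": bool(all_conditions) and set(highly) == all_conditions,
        }
    return out


@dataclass
class ConcordanceResult:
    r: float
    concordant: bool
    per_condition_r: Dict[str, float]
    n_points: int


def tandem_profile_concordance(
    profiles_a: Sequence[FoldChangeProfile],
    profiles_b: Sequence[FoldChangeProfile],
    min_points: int = 6,
    r_threshold: float = 0.8,
) -> ConcordanceResult:
    """Expression-profile concordance of a tandem gene pair.

    Pearson correlation of log2 fold changes over the shared
    condition x timepoint grid, concatenated across conditions; the pair is
    concordant when r >= ``r_threshold``.  Per-condition correlations are
    reported alongside (NaN where a condition has < 3 shared points).
    """
    grid_a = {
        (p.condition, t): f for p in profiles_a for t, f in zip(p.timepoints_h, p.folds)
    }
    grid_b = {
        (p.condition, t): f for p in profiles_b for t, f in zip(p.timepoints_h, p.folds)
    }
    shared = sorted(set(grid_a) & set(grid_b))
    if len(shared) < min_points:
        raise ValueError(
            f"only {len(shared)} shared measurement points; need >= {min_points}"
        )
    xs = np.log2([grid_a[k] for k in shared])
    ys = np.log2([grid_b[k] for k in shared])
    r = float(stats.pearsonr(xs, ys).statistic)
    per_condition: Dict[str, float] = {}
    for cond in sorted({c for c, _ in shared}):
        keys = [k for k in shared if k[0] == cond]
        if len(keys) >= 3:
            per_condition[cond] = float(
                stats.pearsonr(
                    np.log2([grid_a[k] for k in keys]), np.log2([grid_b[k] for k in keys])
                ).statistic
            )
        else:
            per_condition[cond] = float("nan")
    return ConcordanceResult(
        r=r, concordant=r >= r_threshold, per_condition_r=per_condition, n_points=len(shared)
    )


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    """Tidy Cq table: gene, condition, timepoint_h, bio_rep, tech_rep,
    target_cq, reference_cq.  Timepoint 0 rows are the untreated control."""
    df = pd.read_csv(path)
    required = {
        "gene",
        "condition",
        "timepoint_h",
        "bio_rep",
        "tech_rep",
        "target_cq",
        "reference_cq",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def _cq_matrix(sub: pd.DataFrame, column: str) -> np.ndarray:
    pivot = sub.pivot_table(index="bio_rep", columns="tech_rep", values=column)
    if pivot.isna().any().any():
        raise ValueError("ragged replicate structure in Cq table")
    return pivot.to_numpy()


def profiles_from_cq(df: pd.DataFrame, control_timepoint: float = 0.0) -> List[FoldChangeProfile]:
    """Fold-change profiles for every gene x condition in a tidy Cq table."""
    profiles: List[FoldChangeProfile] = []
    for (gene, condition), sub in df.groupby(["gene", "condition"], sort=True):
        control = sub[sub["timepoint_h"] == control_timepoint]
        if control.empty:
            raise ValueError(f"{gene}/{condition}: no control (t={control_timepoint}) rows")
        tgt_ctl = _cq_matrix(control, "target_cq")
        ref_ctl = _cq_matrix(control, "reference_cq")
        timepoints: List[float] = []
        folds: List[float] = []
        sds: List[float] = []
        for tp in sorted(sub["timepoint_h"].unique()):
            if tp == control_timepoint:
                continue
            treated = sub[sub["timepoint_h"] == tp]
            est = delta_delta_ct(
                QpcrMeasurement(
                    gene=gene,
                    condition=condition,
                    timepoint_h=float(tp),
                    target_treated=_cq_matrix(treated, "target_cq"),
                    reference_treated=_cq_matrix(treated, "reference_cq"),
                    target_control=tgt_ctl,
                    reference_control=ref_ctl,
                )
            )
            timepoints.append(float(tp))
            folds.append(est.fold)
            sds.append(est.sd)
        profiles.append(
            FoldChangeProfile(
                gene=gene, condition=condition, timepoints_h=timepoints, folds=folds, sds=sds
            )
        )
    return profiles
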