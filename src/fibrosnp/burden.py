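"""Risk-allele assignment and cumulative burden comparison.

An allele is a risk allele when its SNP is nominally associated
(p <= 0.05) and carrying it increases the odds of severe fibrosis: the
variant allele when the estimated OR/RR exceeds 1, otherwise the
wild-type allele (protective variants make the wild type the risk
factor).  Each patient scores 0, 1 or 2 risk-allele copies per model
SNP; the summed burden is compared between cases and controls with the
Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .association import AssociationResult
from .cohort import Cohort, SnpDef


@dataclass(frozen=True)
class RiskAllele:
    """One risk-model entry: which allele of a SNP carries risk."""

    rs_id: str
    risk_allele: str
    is_variant: bool  # True when the risk allele is allele 2


@dataclass
class GroupStats:
    """Box-plot summary of one group's burden scores."""

    n: int
    median: float
    q1: float
    q3: float
    p10: float
    p90: float
    min: int
    max: int


@dataclass
class BurdenResult:
    scores: np.ndarray  # per-patient, NaN where a model genotype was missing
    case_stats: GroupStats
    control_stats: GroupStats
    u_statistic: float  # U for the case group
    p_value: float
    n_excluded: int = 0
    excluded_patients: tuple[str, ...] = field(default_factory=tuple)


def assign_risk_alleles(
    results: Sequence[AssociationResult],
    panel: Sequence[SnpDef],
    alpha: float = 0.05,
) -> list[RiskAllele]:
    """Build the risk model from association results.

    Keeps SNPs with p <= alpha and a defined, directional effect
    (OR/RR != 1); effect > 1 marks the variant allele as risk, effect
    < 1 the wild-type allele.  An effect of exactly 1 has no direction
    and is excluded.
    """
    by_rs = {s.rs_id: s for s in panel}
    model: list[RiskAllele] = []
    for r in results:
        if r.p_value is None or r.p_value > alpha:
            continue
        if r.effect_type not in ("OR", "RR") or r.effect is None or r.effect == 1.0:
            continue
        snp = by_rs[r.rs_id]
        if r.effect > 1.0:
            model.append(RiskAllele(r.rs_id, snp.allele2, is_variant=True))
        else:
            model.append(RiskAllele(r.rs_id, snp.allele1, is_variant=False))
    return model


def burden_scores(cohort: Cohort, model: Sequence[RiskAllele]) -> np.ndarray:
    """Per-patient risk-allele counts, summed over the model SNPs.

    A variant risk allele contributes the dosage, a wild-type risk
    allele 2 - dosage.  Patients missing a genotype at any model SNP
    get a NaN score (flag-and-exclude; no imputation by default).
    """
    if not model:
        raise ValueError("empty risk model")
    cols = [cohort.snp_index(m.rs_id) for m in model]
    dos = cohort.dosage[:, cols]
    contrib = np.where([m.is_variant for m in model], dos, 2.0 - dos)
    return contrib.sum(axis=1)  # NaN propagates


def burden_scores_imputed(cohort: Cohort, model: Sequence[RiskAllele]) -> np.ndarray:
    """Variant of :func:`burden_scores` that mean-imputes missing dosages.

    Missing dosages are replaced by the per-SNP mean dosage over called
    patients before scoring.  Opt-in only; the default pipeline excludes
    incomplete patients instead.
    """
    if not model:
        raise ValueError("empty risk model")
    cols = [cohort.snp_index(m.rs_id) for m in model]
    dos = cohort.dosage[:, cols].copy()
    means = np.nanmean(dos, axis=0)
    idx = np.where(np.isnan(dos))
    dos[idx] = means[idx[1]]
    contrib = np.where([m.is_variant for m in model], dos, 2.0 - dos)
    return contrib.sum(axis=1)


def mann_whitney_test(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Uses the exact null distribution when there are no ties and
    n1 * n2 <= 10_000; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # degenerate: every observation tied; no evidence either way
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and x.size * y.size <= 10_000) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _group_stats(scores: np.ndarray) -> GroupStats:
    return GroupStats(
        n=scores.size,
        median=float(np.median(scores)),
        q1=float(np.percentile(scores, 25)),
        q3=float(np.percentile(scores, 75)),
        p10=float(np.percentile(scores, 10)),
        p90=float(np.percentile(scores, 90)),
        min=int(scores.min()),
        max=int(scores.max()),
    )


def burden_compare(cohort: Cohort, model: Sequence[RiskAllele]) -> BurdenResult:
    """Score every patient and compare case vs control burden.

    Produces box-plot statistics per group (median, quartiles, 10th and
    90th percentiles, range) and the two-sided Mann-Whitney comparison.
    Patients with a missing genotype at a model SNP are flagged and
    excluded from the comparison.
    """
    scores = burden_scores(cohort, model)
    case = cohort.case_mask
    ok = ~np.isnan(scores)
    excluded = tuple(
        p.patient_id for p, keep in zip(cohort.patients, ok) if not keep
    )
    cs = scores[case & ok]
    ks = scores[~case & ok]
    u, p = mann_whitney_test(cs, ks)
    return BurdenResult(
        scores=scores,
        case_stats=_group_stats(cs),
        control_stats=_group_stats(ks),
        u_statistic=u,
        p_value=p,
        n_excluded=len(excluded),
        excluded_patients=excluded,
    )
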