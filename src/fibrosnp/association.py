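"""Per-SNP 2x2 allele-level association statistics.

Effect size is the variant-allele odds ratio, OR = (b*c)/(a*d) for the
table (a, b; c, d) of case/control allele-1/allele-2 counts, with a
Woolf (log-normal) confidence interval.  When the OR is undefined
because no control carries the variant (d = 0) while cases do, the
risk ratio of case status among variant-allele versus wild-type-allele
carriers is reported instead, with a Katz interval.  Significance uses
the uncorrected Pearson chi-square test when Cochran's criterion holds
(every expected cell count >= 5, no zero margin) and the two-sided
Fisher exact test otherwise.  Bonferroni correction divides alpha by a
configurable number of comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .cohort import AlleleTable, Cohort, SnpDef, count_all_tables

EffectType = Literal["OR", "RR", "zero", "undefined"]
TestName = Literal["chi_square", "fisher_exact", "none"]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class AssociationResult:
    """Full association record for one SNP."""

    rs_id: str
    gene: str
    table: AlleleTable
    effect_type: EffectType
    effect: float | None
    ci_low: float | None
    ci_high: float | None
    test_used: TestName
    p_value: float | None
    significant_nominal: bool
    significant_bonferroni: bool

    def __post_init__(self) -> None:
        if None not in (self.effect, self.ci_low, self.ci_high):
            if not self.ci_low <= self.effect <= self.ci_high:
                raise ValueError(
                    f"{self.rs_id}: CI ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket effect {self.effect}"
                )
        if self.significant_bonferroni and not self.significant_nominal:
            raise ValueError(f"{self.rs_id}: Bonferroni-significant but not nominal")


def _cells(table: AlleleTable | Sequence[int]) -> tuple[int, int, int, int]:
    if isinstance(table, AlleleTable):
        return table.cells
    a, b, c, d = table
    return int(a), int(b), int(c), int(d)


def odds_ratio_woolf(
    table: AlleleTable | Sequence[int], conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Variant-allele odds ratio with Woolf log-interval.

    OR = (b*c)/(a*d); CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Requires all four cells positive; zero cells are dispatched elsewhere
    (see :func:`estimate_effect`).
    """
    a, b, c, d = _cells(table)
    if min(a, b, c, d) <= 0:
        raise ValueError("Woolf odds ratio needs all four cells > 0")
    or_ = (b * c) / (a * d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(0.5 + conf_level / 2))
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, lo, hi


def risk_ratio_katz(
    table: AlleleTable | Sequence[int], conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Risk ratio of case status for variant- vs wild-type-allele carriers.

    RR = [b/(b+d)] / [a/(a+c)] with the Katz log-interval
    CI = exp(ln RR +/- z * sqrt(1/b - 1/(b+d) + 1/a - 1/(a+c))).
    Used as the fallback effect when d = 0 makes the OR infinite.
    """
    a, b, c, d = _cells(table)
    if b <= 0:
        raise ValueError("risk ratio fallback needs case variant count b > 0")
    if a <= 0:
        raise ValueError("risk ratio needs case wild-type count a > 0")
    rr = (b / (b + d)) / (a / (a + c))
    se = math.sqrt(1 / b - 1 / (b + d) + 1 / a - 1 / (a + c))
    z = float(stats.norm.ppf(0.5 + conf_level / 2))
    lo = math.exp(math.log(rr) - z * se)
    hi = math.exp(math.log(rr) + z * se)
    return rr, lo, hi


def expected_counts(table: AlleleTable | Sequence[int]) -> np.ndarray:
    """Expected cell counts under independence, E = row * col / N."""
    a, b, c, d = _cells(table)
    m = np.array([[a, b], [c, d]], dtype=float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty table")
    return np.outer(m.sum(1), m.sum(0)) / n


def pearson_chi2(
    table: AlleleTable | Sequence[int], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table (1 df).

    No Yates continuity correction by default; pass ``correction=True``
    for the corrected statistic.  Raises ValueError on a zero margin
    (the caller should fall through to Fisher's exact test).
    """
    a, b, c, d = _cells(table)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("zero margin: chi-square not applicable")
    stat, p, _, _ = stats.chi2_contingency(
        [[a, b], [c, d]], correction=correction
    )
    return float(stat), float(p)


def fisher_exact_two_sided(
    table: AlleleTable | Sequence[int], convention: str = "min_likelihood"
) -> float:
    """Two-sided Fisher exact p-value.

    ``min_likelihood`` (default) sums hypergeometric point probabilities
    <= that of the observed table; ``doubling`` doubles the smaller
    one-sided tail (capped at 1) -- the convention of some legacy 2x2
    calculators.  Degenerate margins give p = 1.
    """
    a, b, c, d = _cells(table)
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    if convention == "min_likelihood":
        return float(stats.fisher_exact([[a, b], [c, d]])[1])
    if convention == "doubling":
        n = a + b + c + d
        hg = stats.hypergeom(n, a + b, a + c)
        lower = float(hg.cdf(a))
        upper = float(hg.sf(a - 1))
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown Fisher convention {convention!r}")


def choose_test(table: AlleleTable | Sequence[int]) -> TestName:
    """Cochran's applicability rule for the allele chi-square.

    chi_square iff no margin is zero and every expected cell count is
    >= 5; fisher_exact otherwise.  Deterministic.
    """
    a, b, c, d = _cells(table)
    if min(a + b, c + d, a + c, b + d) == 0:
        return "fisher_exact"
    if (expected_counts(table) >= 5).all():
        return "chi_square"
    return "fisher_exact"


@dataclass(frozen=True)
class EffectEstimate:
    effect_type: EffectType
    effect: float | None
    ci_low: float | None
    ci_high: float | None


def estimate_effect(
    table: AlleleTable | Sequence[int],
    conf_level: float = 0.95,
    haldane: bool = False,
) -> EffectEstimate:
    """Dispatch the effect estimate by the zero-cell pattern.

    * all cells > 0 -> OR with Woolf CI;
    * variant in cases only (b > 0, d = 0) -> RR with Katz CI;
    * variant in controls only (b = 0, d > 0) -> effect_type "zero",
      effect 0, no CI (the conventional rendering for such rows);
    * no variant anywhere (b = d = 0) -> undefined.

    ``haldane=True`` instead adds 0.5 to every cell and always reports a
    continuity-corrected OR; it is offered for sensitivity analyses and
    never used by the default pipeline.
    """
    a, b, c, d = _cells(table)
    if haldane:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (bb * cc) / (aa * dd)
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        z = float(stats.norm.ppf(0.5 + conf_level / 2))
        return EffectEstimate(
            "OR", or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
        )
    if b == 0 and d == 0:
        return EffectEstimate("undefined", None, None, None)
    if b == 0:
        return EffectEstimate("zero", 0.0, None, None)
    if d == 0:
        if a == 0:
            return EffectEstimate("undefined", None, None, None)
        return EffectEstimate("RR", *risk_ratio_katz(table, conf_level))
    if a == 0 or c == 0:
        # wild-type allele absent in one group: neither OR nor the RR
        # fallback is defined; does not occur with a majority allele 1
        return EffectEstimate("undefined", None, None, None)
    return EffectEstimate("OR", *odds_ratio_woolf(table, conf_level))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def hwe_exact_test(genotype_counts: Sequence[int]) -> float:
    """Exact Hardy-Weinberg equilibrium test (two-sided, conditional).

    ``genotype_counts`` is (n_AA, n_Aa, n_aa).  Enumerates every
    heterozygote count compatible with the observed allele counts and
    sums the conditional probabilities <= that of the observed count
    (the standard exact HWE test).  Monomorphic samples give p = 1.
    """
    n_aa_, n_ab, n_bb = (int(x) for x in genotype_counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    n_a = 2 * n_aa_ + n_ab  # copies of the first allele
    n_b = 2 * n_bb + n_ab
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_ab = h | n, n_a) up to a shared constant; genotype counts
    # implied by h heterozygotes are (n_a - h)/2 and (n_b - h)/2
    g_aa = (n_a - hets) // 2
    g_bb = (n_b - hets) // 2
    lp = hets * math.log(2) - gammaln(g_aa + 1) - gammaln(hets + 1) - gammaln(g_bb + 1)
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    p_obs = probs[hets == n_ab]
    if p_obs.size == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def associate_tables(
    panel: Sequence[SnpDef],
    tables: Sequence[AlleleTable],
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    conf_level: float = 0.95,
    chi2_correction: bool = False,
    fisher_convention: str = "min_likelihood",
) -> list[AssociationResult]:
    """Run the per-SNP association stage on precomputed allele tables.

    ``bonferroni_m`` defaults to the number of SNPs with any variant
    allele observed (monomorphic markers contribute no comparison).
    Nominal significance is p <= alpha; Bonferroni significance is the
    strict p < alpha/m.  Degenerate SNPs never abort the panel.
    """
    if len(panel) != len(tables):
        raise ValueError(f"panel has {len(panel)} SNPs but {len(tables)} tables")
    if bonferroni_m is None:
        bonferroni_m = sum(1 for t in tables if t.b + t.d > 0)
        bonferroni_m = max(bonferroni_m, 1)
    threshold = bonferroni_threshold(alpha, bonferroni_m)

    results: list[AssociationResult] = []
    for snp, t in zip(panel, tables):
        est = estimate_effect(t, conf_level=conf_level)
        if t.b + t.d == 0 or t.n_alleles == 0:
            # monomorphic or empty: no test is meaningful
            test: TestName = "none"
            p: float | None = None
        else:
            test = choose_test(t)
            if test == "chi_square":
                _, p = pearson_chi2(t, correction=chi2_correction)
            else:
                p = fisher_exact_two_sided(t, convention=fisher_convention)
        sig = p is not None and p <= alpha
        sig_bonf = p is not None and p < threshold
        results.append(
            AssociationResult(
                rs_id=snp.rs_id,
                gene=snp.gene,
                table=t,
                effect_type=est.effect_type,
                effect=est.effect,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                test_used=test,
                p_value=p,
                significant_nominal=sig,
                significant_bonferroni=sig and sig_bonf,
            )
        )
    return results


def associate_all(
    cohort: Cohort,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    conf_level: float = 0.95,
    chi2_correction: bool = False,
    fisher_convention: str = "min_likelihood",
) -> list[AssociationResult]:
    """Allele-count and test every panel SNP of a cohort, in panel order."""
    return associate_tables(
        cohort.panel,
        count_all_tables(cohort),
        alpha=alpha,
        bonferroni_m=bonferroni_m,
        conf_level=conf_level,
        chi2_correction=chi2_correction,
        fisher_convention=fisher_convention,
    )
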