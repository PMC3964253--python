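"""Independent brute-force oracles used to verify the statistical core.

Everything here is deliberately naive: exact integer hypergeometric
enumeration, explicit expected-count loops, and full permutation
enumeration.  None of it shares code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over margin-preserving tables.

    Sums exact rational hypergeometric point probabilities that do not
    exceed the observed table's (minimum-likelihood convention).
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if min(row1, row2, col1, b + d) == 0:
        return 1.0
    denom = comb(n, col1)

    def prob(x: int) -> Fraction:
        # x = cell (1,1); requires max(0, col1-row2) <= x <= min(row1, col1)
        return Fraction(comb(row1, x) * comb(row2, col1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return float(total)


def chi2_statistic_expected_loop(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square via an explicit E = row*col/N loop."""
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    n = sum(rows)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def mann_whitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Valid for tie-free data; returns (U of the first sample, p).
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "tie-free data required"
    n1 = len(x)

    def u_of(subset) -> float:
        rest = [v for i, v in enumerate(pooled) if i not in subset]
        chosen = [pooled[i] for i in subset]
        return sum(1 for xi in chosen for yi in rest if xi > yi)

    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    n1n2 = n1 * (len(pooled) - n1)
    # two-sided: as extreme in either direction around n1*n2/2
    dev_obs = abs(u_obs - n1n2 / 2)
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(subset) - n1n2 / 2) >= dev_obs - 1e-9:
            count += 1
    return float(u_obs), count / total


def burden_score_allele_tally(genotype_alleles, risk_alleles) -> int:
    """Score a patient by directly counting risk-allele tokens.

    ``genotype_alleles`` maps rs_id -> (allele, allele);
    ``risk_alleles`` maps rs_id -> risk allele token.
    """
    score = 0
    for rs, risk in risk_alleles.items():
        score += sum(1 for al in genotype_alleles[rs] if al == risk)
    return score


def hwe_exact_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p via exact rational conditional probabilities."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if n == 0 or na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def prob(h: int) -> Fraction:
        gaa = (na - h) // 2
        gbb = (nb - h) // 2
        from math import factorial

        return Fraction(
            factorial(n) * 2**h,
            factorial(gaa) * factorial(h) * factorial(gbb),
        )

    hets = list(range(rare % 2, rare + 1, 2))
    weights = {h: prob(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)
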