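"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator inverts the retrospective case-control model the
association stage estimates: per SNP, control genotypes are drawn under
Hardy-Weinberg equilibrium at a base variant-allele frequency q, and
case genotypes at the frequency implied by applying a per-allele odds
ratio to the control allele odds,

    case allele odds = OR * q / (1 - q),

so the simulator's OR is exactly the estimand of the Woolf odds ratio.
SNPs are independent (the analysis is marginal; no linkage
disequilibrium).  Fibrosis grades are drawn from a per-group mixture;
the default histogram (17, 54, 36 | 38, 10 over grades 0-2 | 3-4)
matches the 155-patient reference cohort, as do the default group
sizes 48 cases / 107 controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets
from .association import associate_all
from .cohort import Cohort, PatientRecord, SnpDef

#: grade mixture of the reference cohort, normalised per group
_H = datasets.NPC_GRADE_HISTOGRAM
DEFAULT_CONTROL_GRADE_PROBS = tuple(h / sum(_H[:3]) for h in _H[:3])  # grades 0-2
DEFAULT_CASE_GRADE_PROBS = tuple(h / sum(_H[3:]) for h in _H[3:])  # grades 3-4


@dataclass(frozen=True)
class SnpSimSpec:
    """Simulation parameters for one SNP.

    vaf is the control-group variant-allele (allele 2) frequency in
    [0, 1]; odds_ratio is the per-allele case-control odds ratio
    (1 = null SNP).
    """

    rs_id: str
    vaf: float
    odds_ratio: float = 1.0
    gene: str = "SIM"
    allele1: str = "A"
    allele2: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"{self.rs_id}: vaf {self.vaf} outside [0, 1]")
        if self.odds_ratio < 0:
            raise ValueError(f"{self.rs_id}: odds ratio must be >= 0")
        if self.odds_ratio != 1.0 and self.vaf in (0.0, 1.0):
            raise ValueError(
                f"{self.rs_id}: a monomorphic SNP (vaf={self.vaf}) cannot "
                "carry an allele-frequency shift (odds ratio != 1)"
            )

    @property
    def case_vaf(self) -> float:
        """Variant-allele frequency implied in cases."""
        if self.vaf in (0.0, 1.0):
            return self.vaf
        odds = self.odds_ratio * self.vaf / (1.0 - self.vaf)
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class SimConfig:
    panel: tuple[SnpSimSpec, ...]
    n_cases: int = datasets.NPC_N_CASES
    n_controls: int = datasets.NPC_N_CONTROLS
    control_grade_probs: tuple[float, ...] = DEFAULT_CONTROL_GRADE_PROBS
    case_grade_probs: tuple[float, ...] = DEFAULT_CASE_GRADE_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "panel", tuple(self.panel))
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both groups must be non-empty")
        for name, probs, k in (
            ("control_grade_probs", self.control_grade_probs, 3),
            ("case_grade_probs", self.case_grade_probs, 2),
        ):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be {k} probabilities summing to 1")


def sample_genotypes_hwe(vaf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. variant-allele dosages under HWE at allele frequency vaf."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"allele frequency {vaf} outside [0, 1]")
    return rng.binomial(2, vaf, size=n)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw a case-control cohort per ``config``; fully seeded."""
    rng = np.random.default_rng(config.seed)
    n_ca, n_co = config.n_cases, config.n_controls
    dosage = np.empty((n_ca + n_co, len(config.panel)), dtype=float)
    for j, snp in enumerate(config.panel):
        dosage[:n_ca, j] = sample_genotypes_hwe(snp.case_vaf, n_ca, rng)
        dosage[n_ca:, j] = sample_genotypes_hwe(snp.vaf, n_co, rng)
    case_grades = rng.choice([3, 4], size=n_ca, p=config.case_grade_probs)
    control_grades = rng.choice([0, 1, 2], size=n_co, p=config.control_grade_probs)
    grades = np.concatenate([case_grades, control_grades])
    width = len(str(n_ca + n_co))
    patients = tuple(
        PatientRecord(patient_id=f"P{i + 1:0{width}d}", fibrosis_grade=int(g))
        for i, g in enumerate(grades)
    )
    panel = tuple(
        SnpDef(gene=s.gene, rs_id=s.rs_id, allele1=s.allele1, allele2=s.allele2)
        for s in config.panel
    )
    return Cohort(panel=panel, patients=patients, dosage=dosage)


def npc_sim_panel(effects: bool = True) -> tuple[SnpSimSpec, ...]:
    """Simulation panel mirroring the reference cohort's 45 SNPs.

    Control vafs come from the published control allele counts.  With
    ``effects=True`` the six significant SNPs carry the odds ratios
    estimated from the published tables; otherwise every SNP is null.
    """
    panel: list[SnpSimSpec] = []
    for snp, table in zip(datasets.npc_panel(), datasets.npc_allele_tables()):
        vaf = table.d / (table.c + table.d)
        or_ = 1.0
        if effects and snp.rs_id in datasets.NPC_SIGNIFICANT_RS_IDS:
            or_ = (table.b * table.c) / (table.a * table.d)
        panel.append(
            SnpSimSpec(
                rs_id=snp.rs_id,
                vaf=vaf,
                odds_ratio=or_,
                gene=snp.gene,
                allele1=snp.allele1,
                allele2=snp.allele2,
            )
        )
    return tuple(panel)


def type1_power_experiment(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP rejection frequency at ``alpha`` across simulated cohorts.

    Replicate r uses seed ``config.seed + r``.  Returns one row per SNP
    with the number of replicates decided by each test, the rejection
    rate and its binomial Monte-Carlo standard error.  For null SNPs
    the rate estimates the type-I error; for effect SNPs, power.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    k = len(config.panel)
    rejected = np.zeros(k, dtype=int)
    chi2_used = np.zeros(k, dtype=int)
    chi2_rejected = np.zeros(k, dtype=int)
    fisher_used = np.zeros(k, dtype=int)
    tested = np.zeros(k, dtype=int)
    for r in range(n_reps):
        cfg = SimConfig(
            panel=config.panel,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            control_grade_probs=config.control_grade_probs,
            case_grade_probs=config.case_grade_probs,
            seed=config.seed + r,
        )
        results = associate_all(simulate_cohort(cfg), alpha=alpha)
        for j, res in enumerate(results):
            if res.p_value is None:
                continue
            tested[j] += 1
            rej = res.p_value <= alpha
            rejected[j] += rej
            if res.test_used == "chi_square":
                chi2_used[j] += 1
                chi2_rejected[j] += rej
            else:
                fisher_used[j] += 1
    rate = np.divide(rejected, tested, out=np.zeros(k), where=tested > 0)
    chi2_rate = np.divide(
        chi2_rejected, chi2_used, out=np.full(k, np.nan), where=chi2_used > 0
    )
    mc_se = np.sqrt(np.clip(rate * (1 - rate), 0, None) / np.maximum(tested, 1))
    return pd.DataFrame(
        {
            "rs_id": [s.rs_id for s in config.panel],
            "odds_ratio": [s.odds_ratio for s in config.panel],
            "vaf": [s.vaf for s in config.panel],
            "n_tested": tested,
            "n_chi2": chi2_used,
            "n_fisher": fisher_used,
            "rejection_rate": rate,
            "chi2_rejection_rate": chi2_rate,
            "mc_se": mc_se,
        }
    )
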