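"""Pipeline orchestration and report rendering.

``run_pipeline`` chains simulate/load -> associate -> assign risk
alleles -> burden comparison and writes plain TSV artifacts plus a
human-readable association table.  Report formatting follows the
conventions of clinical 2x2 association tables: counts with integer
percentages, effects as ``X.XX (L-H)``, ``0`` for a variant seen only
in controls, an en-dash for monomorphic rows, ``<0.01`` for small
p-values, ``*`` marking Fisher-tested rows and ``**`` marking the
risk-ratio fallback.  All rounding happens at the formatting layer;
TSV outputs keep full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .association import AssociationResult, associate_all
from .burden import assign_risk_alleles, burden_compare
from .cohort import (
    Cohort,
    allele_percentages,
    genotype_counts,
    read_genotype_table,
    read_panel,
    read_phenotype_table,
    write_genotype_table,
    write_panel,
    write_phenotype_table,
)
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

EN_DASH = "–"


@dataclass
class PipelineConfig:
    """Inputs and policies for one pipeline run.

    Provide either the three input paths or a :class:`SimConfig`.
    ``bonferroni_m=None`` divides alpha by the number of SNPs with any
    variant allele observed.
    """

    out_dir: str | Path
    genotypes: str | Path | None = None
    phenotypes: str | Path | None = None
    panel: str | Path | None = None
    sim: SimConfig | None = None
    alpha: float = 0.05
    bonferroni_m: int | None = None
    chi2_correction: bool = False
    fisher_convention: str = "min_likelihood"
    min_carriers: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        have_paths = all(
            x is not None for x in (self.genotypes, self.phenotypes, self.panel)
        )
        if (self.sim is None) == (not have_paths):
            raise ValueError(
                "provide either a simulation config or all three input paths"
            )


# ---------------------------------------------------------------------------
# formatting


def _fmt_pct(p: float | None) -> str:
    if p is None:
        return EN_DASH
    return f"{p:g}"


def _fmt_effect(r: AssociationResult) -> str:
    if r.effect_type == "undefined":
        return EN_DASH
    if r.effect_type == "zero":
        return "0"
    eff = f"{round_half_away(r.effect, 2):.2f}"
    lo = f"{round_half_away(r.ci_low, 2):.2f}"
    hi = f"{round_half_away(r.ci_high, 2):.2f}"
    mark = "**" if r.effect_type == "RR" else ""
    return f"{eff}{mark} ({lo}{EN_DASH}{hi})"


def _fmt_p(r: AssociationResult) -> str:
    if r.p_value is None:
        return EN_DASH
    mark = "*" if r.test_used == "fisher_exact" else ""
    if r.p_value < 0.01:
        return "<0.01" + mark
    return f"{round_half_away(r.p_value, 2):.2f}" + mark


def format_association_table(results: Sequence[AssociationResult]) -> str:
    """Render association results as a fixed-width text table.

    Layout mirrors the conventional allele-frequency table: per-group
    counts with percentages, the effect with its 95% CI, and the
    p-value; footnotes explain the ``*``/``**`` markers.
    """
    header = (
        "gene",
        "rs_id",
        "alleles",
        "case A1 n (%)",
        "ctrl A1 n (%)",
        "case A2 n (%)",
        "ctrl A2 n (%)",
        "effect (95% CI)",
        "P",
    )
    rows = [header]
    for r in results:
        pa, pb, pc, pd_ = allele_percentages(r.table)
        rows.append(
            (
                r.gene,
                r.rs_id,
                "",
                f"{r.table.a} ({_fmt_pct(pa)})",
                f"{r.table.c} ({_fmt_pct(pc)})",
                f"{r.table.b} ({_fmt_pct(pb)})",
                f"{r.table.d} ({_fmt_pct(pd_)})",
                _fmt_effect(r),
                _fmt_p(r),
            )
        )
    widths = [max(len(str(row[i])) for row in rows) for i in range(len(header))]
    lines = [
        "  ".join(str(cell).ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    ]
    lines.append("")
    lines.append("* two-tailed Fisher's exact test (chi-square not applicable)")
    lines.append("** risk ratio (odds ratio undefined: no control variant allele)")
    return "\n".join(lines) + "\n"


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Association results as a full-precision DataFrame (TSV-ready)."""
    recs = []
    for r in results:
        pa, pb, pc, pd_ = allele_percentages(r.table)
        recs.append(
            {
                "rs_id": r.rs_id,
                "gene": r.gene,
                "case_allele1": r.table.a,
                "case_allele2": r.table.b,
                "control_allele1": r.table.c,
                "control_allele2": r.table.d,
                "case_allele1_pct": pa,
                "case_allele2_pct": pb,
                "control_allele1_pct": pc,
                "control_allele2_pct": pd_,
                "effect_type": r.effect_type,
                "effect": r.effect,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "test_used": r.test_used,
                "p_value": r.p_value,
                "significant_nominal": r.significant_nominal,
                "significant_bonferroni": r.significant_bonferroni,
            }
        )
    return pd.DataFrame.from_records(recs)


def results_from_frame(df: pd.DataFrame) -> list[AssociationResult]:
    """Rebuild :class:`AssociationResult` records from a saved association TSV.

    Lets downstream stages (risk model, formatted report) be re-run from
    intermediate artifacts with the same outcome as a single-pass run.
    """
    from .cohort import AlleleTable

    results = []
    for rec in df.to_dict("records"):
        def _opt(v):
            return None if pd.isna(v) else float(v)

        results.append(
            AssociationResult(
                rs_id=rec["rs_id"],
                gene=rec["gene"],
                table=AlleleTable(
                    a=int(rec["case_allele1"]),
                    b=int(rec["case_allele2"]),
                    c=int(rec["control_allele1"]),
                    d=int(rec["control_allele2"]),
                ),
                effect_type=rec["effect_type"],
                effect=_opt(rec["effect"]),
                ci_low=_opt(rec["ci_low"]),
                ci_high=_opt(rec["ci_high"]),
                test_used=rec["test_used"],
                p_value=_opt(rec["p_value"]),
                significant_nominal=bool(rec["significant_nominal"]),
                significant_bonferroni=bool(rec["significant_bonferroni"]),
            )
        )
    return results


def genotype_distribution_report(
    cohort: Cohort, min_carriers: int = 5
) -> pd.DataFrame:
    """Per-SNP genotype histograms split by fibrosis severity group.

    Includes only SNPs carried (dosage >= 1) by at least
    ``min_carriers`` patients, the usual filter for presenting
    genotype distributions of informative markers.
    """
    if min_carriers < 0:
        raise ValueError("min_carriers must be >= 0")
    case = cohort.case_mask
    recs = []
    for j, snp in enumerate(cohort.panel):
        col = cohort.dosage[:, j]
        carriers = int(np.nansum(col >= 1))
        if carriers < min_carriers:
            continue
        ca = genotype_counts(cohort, j, case)
        co = genotype_counts(cohort, j, ~case)
        recs.append(
            {
                "rs_id": snp.rs_id,
                "gene": snp.gene,
                "n_carriers": carriers,
                "case_hom_allele1": ca[0],
                "case_het": ca[1],
                "case_hom_allele2": ca[2],
                "control_hom_allele1": co[0],
                "control_het": co[1],
                "control_hom_allele2": co[2],
            }
        )
    return pd.DataFrame.from_records(
        recs,
        columns=[
            "rs_id",
            "gene",
            "n_carriers",
            "case_hom_allele1",
            "case_het",
            "case_hom_allele2",
            "control_hom_allele1",
            "control_het",
            "control_hom_allele2",
        ],
    )


# ---------------------------------------------------------------------------
# pipeline


def _load_or_simulate(config: PipelineConfig) -> Cohort:
    if config.sim is not None:
        return simulate_cohort(config.sim)
    panel = read_panel(config.panel)
    phenotype = read_phenotype_table(config.phenotypes)
    return read_genotype_table(config.genotypes, panel, phenotype)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run simulate/load -> associate -> risk model -> burden, write reports.

    Returns a mapping of artifact names to paths.  With an empty risk
    model (no significant SNP) the burden stage is skipped with a
    notice in the run log.  Identical config and seed give
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict = {"alpha": config.alpha, "min_carriers": config.min_carriers}

    stage = "load"
    try:
        cohort = _load_or_simulate(config)
        if config.sim is not None:
            log["input"] = {
                "simulated": True,
                "seed": config.sim.seed,
                "n_cases": config.sim.n_cases,
                "n_controls": config.sim.n_controls,
                "n_snps": len(config.sim.panel),
            }
            write_panel(cohort.panel, out / "panel.tsv")
            write_phenotype_table(cohort, out / "phenotype.tsv")
            write_genotype_table(cohort, out / "genotypes.tsv")
            artifacts.update(
                panel=out / "panel.tsv",
                phenotype=out / "phenotype.tsv",
                genotypes=out / "genotypes.tsv",
            )
        else:
            log["input"] = {
                "simulated": False,
                "genotypes": str(config.genotypes),
                "phenotypes": str(config.phenotypes),
                "panel": str(config.panel),
            }

        stage = "associate"
        results = associate_all(
            cohort,
            alpha=config.alpha,
            bonferroni_m=config.bonferroni_m,
            chi2_correction=config.chi2_correction,
            fisher_convention=config.fisher_convention,
        )
        m_used = config.bonferroni_m
        if m_used is None:
            m_used = max(sum(1 for r in results if r.table.b + r.table.d > 0), 1)
        log["bonferroni_m"] = m_used
        af = association_frame(results)
        af.to_csv(out / "association.tsv", sep="\t", index=False)
        (out / "association_table.txt").write_text(format_association_table(results))
        artifacts["association"] = out / "association.tsv"
        artifacts["association_table"] = out / "association_table.txt"
        log["n_significant_nominal"] = int(af["significant_nominal"].sum())
        log["n_significant_bonferroni"] = int(af["significant_bonferroni"].sum())

        gd = genotype_distribution_report(cohort, config.min_carriers)
        gd.to_csv(out / "genotype_distribution.tsv", sep="\t", index=False)
        artifacts["genotype_distribution"] = out / "genotype_distribution.tsv"

        stage = "risk_model"
        model = assign_risk_alleles(results, cohort.panel, alpha=config.alpha)
        pd.DataFrame(
            [{"rs_id": m.rs_id, "risk_allele": m.risk_allele} for m in model],
            columns=["rs_id", "risk_allele"],
        ).to_csv(out / "risk_model.tsv", sep="\t", index=False)
        artifacts["risk_model"] = out / "risk_model.tsv"

        if not model:
            log["burden"] = "skipped: empty risk model (no significant SNP)"
            logger.info("burden stage skipped: empty risk model")
        else:
            stage = "burden"
            burden = burden_compare(cohort, model)
            rows = [
                {
                    "patient_id": p.patient_id,
                    "group": p.group,
                    "score": "" if np.isnan(s) else int(s),
                }
                for p, s in zip(cohort.patients, burden.scores)
            ]
            pd.DataFrame(rows).to_csv(out / "burden.tsv", sep="\t", index=False)
            artifacts["burden"] = out / "burden.tsv"
            log["burden"] = {
                "n_model_snps": len(model),
                "case_median": burden.case_stats.median,
                "case_range": [burden.case_stats.min, burden.case_stats.max],
                "control_median": burden.control_stats.median,
                "control_range": [
                    burden.control_stats.min,
                    burden.control_stats.max,
                ],
                "u_statistic": burden.u_statistic,
                "p_value": burden.p_value,
                "n_excluded": burden.n_excluded,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = out / "run_log.json"
    return artifacts
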