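"""Cohort containers and genotype/phenotype I/O.

A cohort couples a SNP panel with per-patient variant-allele dosages
(0/1/2 copies of allele 2, NaN = missing) and an RTOG/EORTC fibrosis
grade per patient.  Grade 3-4 patients are the radiosensitive cases,
grade 0-2 the controls; association works on the 2x2 table of allele
counts per group.

File dialects (all tab-separated, plain text):

* genotype table -- header ``patient_id`` then one rs-identifier per
  column; cells ``0``/``1``/``2``/``NA``.
* phenotype table -- ``patient_id<TAB>fibrosis_grade`` with grade 0-4.
* panel table -- ``gene<TAB>rs_id<TAB>allele1<TAB>allele2`` where
  allele 1 is the majority (wild-type) and allele 2 the minority
  (variant) allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import round_half_away

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


class ParseError(ValueError):
    """Malformed input file (bad cell, duplicate id, unknown column)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a cohort invariant."""


@dataclass(frozen=True)
class SnpDef:
    """One panel entry.

    allele1 is the majority/wild-type allele, allele2 the
    minority/variant allele; dosage counts copies of allele2.
    """

    gene: str
    rs_id: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValidationError(
                f"{self.rs_id}: allele1 and allele2 must differ "
                f"(both {self.allele1!r})"
            )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    fibrosis_grade: int
    group: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "group", grade_to_group(self.fibrosis_grade, self.patient_id)
        )


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table for one SNP.

    a/b = case allele-1/allele-2 counts, c/d = the control counts.
    Margins a+b and c+d equal twice the non-missing patients per group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative allele count in {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n_alleles(self) -> int:
        return self.a + self.b + self.c + self.d


def grade_to_group(grade: int, patient_id: str | None = None) -> str:
    """Dichotomize an RTOG/EORTC fibrosis grade: 3-4 -> case, 0-2 -> control."""
    if not isinstance(grade, (int, np.integer)) or isinstance(grade, bool):
        raise ValidationError(
            f"fibrosis grade must be an integer 0-4, got {grade!r}"
            + (f" for patient {patient_id}" if patient_id else "")
        )
    if not 0 <= grade <= 4:
        raise ValidationError(
            f"fibrosis grade {grade} out of range 0-4"
            + (f" for patient {patient_id}" if patient_id else "")
        )
    return CASE if grade >= 3 else CONTROL


@dataclass
class Cohort:
    """Patients x SNPs dosage matrix plus phenotype.

    ``dosage`` is a float array (n_patients, n_snps) holding 0/1/2 or
    NaN for a missing genotype call.
    """

    panel: tuple[SnpDef, ...]
    patients: tuple[PatientRecord, ...]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        self.patients = tuple(self.patients)
        self.dosage = np.asarray(self.dosage, dtype=float)
        rs_ids = [s.rs_id for s in self.panel]
        if len(set(rs_ids)) != len(rs_ids):
            dupes = sorted({r for r in rs_ids if rs_ids.count(r) > 1})
            raise ValidationError(f"duplicate rs_id in panel: {dupes}")
        pids = [p.patient_id for p in self.patients]
        if len(set(pids)) != len(pids):
            dupes = sorted({p for p in pids if pids.count(p) > 1})
            raise ValidationError(f"duplicate patient_id: {dupes}")
        if self.dosage.shape != (len(self.patients), len(self.panel)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.patients)}, {len(self.panel)})"
            )
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(obs[~np.isin(obs, (0.0, 1.0, 2.0))]))
            raise ValidationError(f"dosage values outside {{0,1,2,NA}}: {bad}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_snps(self) -> int:
        return len(self.panel)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([p.group == CASE for p in self.patients])

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return self.n_patients - self.n_cases

    def snp_index(self, rs_id: str) -> int:
        for i, s in enumerate(self.panel):
            if s.rs_id == rs_id:
                return i
        raise KeyError(rs_id)


# ---------------------------------------------------------------------------
# readers / writers


def read_panel(path: str | Path) -> tuple[SnpDef, ...]:
    """Read a panel TSV (``gene  rs_id  allele1  allele2`` with header)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty panel file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["gene", "rs_id", "allele1", "allele2"]
    if header != expected:
        raise ParseError(f"{path}:1: header {header} != {expected}")
    panel: list[SnpDef] = []
    seen: set[str] = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
        gene, rs_id, a1, a2 = (f.strip() for f in fields)
        if rs_id in seen:
            raise ParseError(f"{path}:{ln}: duplicate rs_id {rs_id}")
        seen.add(rs_id)
        panel.append(SnpDef(gene=gene, rs_id=rs_id, allele1=a1, allele2=a2))
    return tuple(panel)


def read_phenotype_table(path: str | Path) -> dict[str, int]:
    """Read ``patient_id<TAB>fibrosis_grade``; grades must be integers 0-4."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty phenotype file")
    header = lines[0].split("\t")
    if header != ["patient_id", "fibrosis_grade"]:
        raise ParseError(
            f"{path}:1: header {header} != ['patient_id', 'fibrosis_grade']"
        )
    grades: dict[str, int] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{ln}: expected 2 columns, got {len(fields)}")
        pid, g = fields[0].strip(), fields[1].strip()
        if pid in grades:
            raise ParseError(f"{path}:{ln}: duplicate patient_id {pid}")
        # a missing grade is a hard error: grading is the case definition
        try:
            grade = int(g)
        except ValueError:
            raise ParseError(
                f"{path}:{ln}: fibrosis grade for patient {pid} is {g!r}, "
                "expected an integer 0-4"
            ) from None
        grade_to_group(grade, pid)
        grades[pid] = grade
    return grades


def read_genotype_table(
    path: str | Path,
    panel: Sequence[SnpDef],
    phenotype: dict[str, int] | str | Path,
) -> Cohort:
    """Read a genotype TSV into a validated :class:`Cohort`.

    Columns must be a subset-free match of the panel rs_ids (same set,
    any order); cells are 0/1/2/NA.  ``phenotype`` is either the mapping
    returned by :func:`read_phenotype_table` or a path to one.  Row
    order of the file is preserved.
    """
    path = Path(path)
    if not isinstance(phenotype, dict):
        phenotype = read_phenotype_table(phenotype)
    panel = tuple(panel)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if header[:1] != ["patient_id"]:
        raise ParseError(f"{path}:1: first column must be patient_id")
    rs_by_id = {s.rs_id: i for i, s in enumerate(panel)}
    cols = header[1:]
    unknown = [c for c in cols if c not in rs_by_id]
    if unknown:
        raise ParseError(f"{path}:1: unknown rs_id column(s) {unknown}")
    if len(set(cols)) != len(cols):
        raise ParseError(f"{path}:1: duplicate rs_id column")
    missing_cols = [s.rs_id for s in panel if s.rs_id not in cols]
    if missing_cols:
        raise ParseError(f"{path}:1: panel rs_id(s) absent from file: {missing_cols}")
    col_to_snp = [rs_by_id[c] for c in cols]

    patients: list[PatientRecord] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(fields)}"
            )
        pid = fields[0].strip()
        if pid in seen:
            raise ParseError(f"{path}:{ln}: duplicate patient_id {pid}")
        seen.add(pid)
        if pid not in phenotype:
            raise ValidationError(
                f"{path}:{ln}: patient {pid} has no fibrosis grade; "
                "patients without phenotype are rejected, not dropped"
            )
        row = np.full(len(panel), np.nan)
        for j, cell in enumerate(fields[1:]):
            cell = cell.strip()
            if cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise ParseError(
                    f"{path}:{ln}: invalid dosage {cell!r} in column {cols[j]}"
                )
            row[col_to_snp[j]] = float(cell)
        patients.append(PatientRecord(patient_id=pid, fibrosis_grade=phenotype[pid]))
        rows.append(row)
    dosage = np.vstack(rows) if rows else np.empty((0, len(panel)))
    return Cohort(panel=panel, patients=tuple(patients), dosage=dosage)


def write_panel(panel: Sequence[SnpDef], path: str | Path) -> None:
    lines = ["gene\trs_id\tallele1\tallele2"]
    lines += [f"{s.gene}\t{s.rs_id}\t{s.allele1}\t{s.allele2}" for s in panel]
    Path(path).write_text("\n".join(lines) + "\n")


def write_phenotype_table(cohort: Cohort, path: str | Path) -> None:
    lines = ["patient_id\tfibrosis_grade"]
    lines += [f"{p.patient_id}\t{p.fibrosis_grade}" for p in cohort.patients]
    Path(path).write_text("\n".join(lines) + "\n")


def write_genotype_table(cohort: Cohort, path: str | Path) -> None:
    lines = ["patient_id\t" + "\t".join(s.rs_id for s in cohort.panel)]
    for p, row in zip(cohort.patients, cohort.dosage):
        cells = ["NA" if np.isnan(x) else str(int(x)) for x in row]
        lines.append(p.patient_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, panel: Sequence[SnpDef], phenotype) -> Cohort:
    """Read genotypes from a VCF, matching biallelic records by ID.

    Requires cyvcf2 (optional dependency).  GT fields map to allele-2
    dosage; records whose REF/ALT are the panel alleles swapped are
    flipped; multi-allelic records and half-missing genotypes become NA
    with a logged warning.  Panel SNPs absent from the VCF stay NA.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the cyvcf2 package") from exc

    if not isinstance(phenotype, dict):
        phenotype = read_phenotype_table(phenotype)
    panel = tuple(panel)
    rs_by_id = {s.rs_id: i for i, s in enumerate(panel)}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for pid in samples:
        if pid not in phenotype:
            raise ValidationError(f"VCF sample {pid} has no fibrosis grade")
    dosage = np.full((len(samples), len(panel)), np.nan)
    for rec in vcf:
        j = rs_by_id.get(rec.ID)
        if j is None:
            continue
        snp = panel[j]
        if len(rec.ALT) != 1:
            logger.warning("%s: multi-allelic record, genotypes set to NA", rec.ID)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if (ref, alt) == (snp.allele1, snp.allele2):
            flip = False
        elif (ref, alt) == (snp.allele2, snp.allele1):
            flip = True
        else:
            logger.warning(
                "%s: REF/ALT %s/%s do not match panel alleles %s/%s; NA",
                rec.ID, ref, alt, snp.allele1, snp.allele2,
            )
            continue
        for i, gt in enumerate(rec.genotypes):
            alleles = [g for g in gt[:-1]]
            if any(a < 0 for a in alleles) or len(alleles) != 2:
                logger.warning("%s sample %s: missing/half call -> NA",
                               rec.ID, samples[i])
                continue
            d = sum(alleles)
            dosage[i, j] = 2 - d if flip else d
    patients = tuple(
        PatientRecord(patient_id=pid, fibrosis_grade=phenotype[pid])
        for pid in samples
    )
    return Cohort(panel=panel, patients=patients, dosage=dosage)


# ---------------------------------------------------------------------------
# allele counting


def count_alleles(cohort: Cohort, snp_index: int) -> AlleleTable:
    """Tally the 2x2 allele-count table for one SNP.

    Missing genotypes are excluded per SNP (complete-case per marker);
    a group with no called genotypes yields zero margins and a warning.
    """
    if not 0 <= snp_index < cohort.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range")
    col = cohort.dosage[:, snp_index]
    case = cohort.case_mask
    obs = ~np.isnan(col)
    b = int(col[case & obs].sum())
    a = 2 * int((case & obs).sum()) - b
    d = int(col[~case & obs].sum())
    c = 2 * int((~case & obs).sum()) - d
    if (case & obs).sum() == 0 or (~case & obs).sum() == 0:
        logger.warning(
            "%s: all genotypes missing in one group; zero-margin table",
            cohort.panel[snp_index].rs_id,
        )
    return AlleleTable(a=a, b=b, c=c, d=d)


def count_all_tables(cohort: Cohort) -> list[AlleleTable]:
    return [count_alleles(cohort, j) for j in range(cohort.n_snps)]


def allele_percentages(
    table: AlleleTable,
) -> tuple[float | None, float | None, float | None, float | None]:
    """Each count as percent of its group allele total, report-rounded.

    Rounding is half-away-from-zero to the integer, except that a count
    which is neither 0 nor the full margin never collapses to 0 or 100:
    such boundary values are kept at 0.5 granularity (213/214 -> 99.5,
    1/214 -> 0.5), mirroring conventional table rendering.  A zero
    group margin makes both of its percentages undefined (None).
    """

    def pct(n: int, total: int) -> float | None:
        if total == 0:
            return None
        p = 100.0 * n / total
        r = round_half_away(p)
        if (r == 100.0 and n < total) or (r == 0.0 and n > 0):
            half = round_half_away(p * 2.0) / 2.0  # nearest 0.5
            return min(max(half, 0.5), 99.5)
        return r

    case_total = table.a + table.b
    ctrl_total = table.c + table.d
    return (
        pct(table.a, case_total),
        pct(table.b, case_total),
        pct(table.c, ctrl_total),
        pct(table.d, ctrl_total),
    )


def genotype_counts(
    cohort: Cohort, snp_index: int, mask: np.ndarray | None = None
) -> tuple[int, int, int]:
    """(n_hom_allele1, n_het, n_hom_allele2) over non-missing patients."""
    col = cohort.dosage[:, snp_index]
    if mask is not None:
        col = col[mask]
    obs = col[~np.isnan(col)]
    return (int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()))
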