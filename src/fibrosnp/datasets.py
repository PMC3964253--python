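"""Reference allele counts for the 45-SNP nasopharyngeal-carcinoma panel.

The package was built around a 155-patient nasopharyngeal-carcinoma
radiotherapy cohort (48 radiosensitive cases with grade 3-4 fibrosis,
107 controls with grade 0-2) genotyped for 45 SNPs across 11 candidate
genes of the DNA-damage response (ATM, XRCC1, XRCC3, XRCC4, XRCC5,
PRKDC, LIG4, TP53, HDM2, CDKN1A, TGFB1).  Individual genotypes for that
cohort were never deposited, but the group-level 2x2 allele-count
tables are public, which makes them usable both as an end-to-end
fixture for the association stage and as the frequency spectrum the
simulator emulates.

Each row: gene, rs_id, allele1 (majority/wild-type), allele2
(minority/variant), then the allele counts a = case allele-1,
b = case allele-2, c = control allele-1, d = control allele-2.
"""

from __future__ import annotations

from .cohort import AlleleTable, SnpDef

# fmt: off
_ROWS: tuple[tuple[str, str, str, str, int, int, int, int], ...] = (
    ("CDKN1A", "rs1801270",  "C",   "A",   74, 22, 157, 57),
    ("TP53",   "rs1042522",  "G",   "C",   52, 44, 112, 102),
    ("TP53",   "rs1800371",  "C",   "T",   96,  0, 213,  1),
    ("ATM",    "rs1801516",  "G",   "A",   82, 14, 202, 12),
    ("ATM",    "rs1801673",  "A",   "T",   96,  0, 214,  0),
    ("HDM2",   "rs7484572",  "G",   "C",   96,  0, 214,  0),
    ("HDM2",   "rs2279744",  "T",   "G",   71, 25, 125, 89),
    ("HDM2",   "rs1196333",  "T",   "A",   95,  1, 198, 16),
    ("TGFB1",  "rs9282871",  "G",   "A",   95,  1, 213,  1),
    ("TGFB1",  "rs1982073",  "C",   "T",   40, 56, 102, 112),
    ("TGFB1",  "rs1800471",  "G",   "C",   92,  4, 207,  7),
    ("TGFB1",  "rs4987025",  "C",   "T",   96,  0, 214,  0),
    ("TGFB1",  "rs1800469",  "C",   "T",   67, 29, 122, 92),
    ("TGFB1",  "rs11466314", "G",   "A",   96,  0, 213,  1),
    ("TGFB1",  "rs35318502", "C",   "T",   96,  0, 214,  0),
    ("TGFB1",  "rs8179182",  "ref", "del", 94,  2, 214,  0),
    ("TGFB1",  "rs35383147", "C",   "A",   96,  0, 214,  0),
    ("TGFB1",  "rs34233206", "ref", "ins", 96,  0, 214,  0),
    ("TGFB1",  "rs1800472",  "C",   "T",   92,  4, 199, 15),
    ("TGFB1",  "rs11466334", "C",   "T",   95,  1, 213,  1),
    ("XRCC1",  "rs2271980",  "G",   "A",   96,  0, 214,  0),
    ("XRCC1",  "rs25487",    "G",   "A",   83, 13, 155, 59),
    ("XRCC1",  "rs3213368",  "C",   "T",   87,  9, 193, 21),
    ("XRCC1",  "rs2139720",  "G",   "A",   88,  8, 190, 24),
    ("XRCC1",  "rs3213369",  "C",   "T",   96,  0, 213,  1),
    ("XRCC3",  "rs41285494", "G",   "A",   96,  0, 214,  0),
    ("XRCC3",  "rs861539",   "G",   "A",   55, 41, 133, 81),
    ("XRCC3",  "rs3212112",  "A",   "C",   95,  1, 213,  1),
    ("XRCC3",  "rs3212113",  "C",   "T",   96,  0, 214,  0),
    ("XRCC4",  "rs2974446",  "A",   "C",   96,  0, 214,  0),
    ("XRCC4",  "rs3734091",  "G",   "T",   95,  1, 213,  1),
    ("XRCC5",  "rs41296835", "A",   "G",   96,  0, 213,  1),
    ("XRCC5",  "rs1051677",  "T",   "C",   89,  7, 178, 36),
    ("XRCC5",  "rs41437350", "G",   "T",   96,  0, 214,  0),
    ("XRCC5",  "rs1051685",  "A",   "G",   85, 11, 195, 19),
    ("PRKDC",  "rs7830743",  "T",   "C",   93,  3, 197, 17),
    ("PRKDC",  "rs8178228",  "A",   "G",   96,  0, 214,  0),
    ("LIG4",   "rs1805384",  "T",   "C",   90,  6, 200, 14),
    ("LIG4",   "rs1805383",  "C",   "A",   96,  0, 214,  0),
    ("LIG4",   "rs4987182",  "C",   "T",   93,  3, 209,  5),
    ("LIG4",   "rs1805389",  "C",   "T",   95,  1, 206,  8),
    ("LIG4",   "rs1805388",  "C",   "T",   91,  5, 195, 19),
    ("LIG4",   "rs2232636",  "G",   "A",   96,  0, 214,  0),
    ("LIG4",   "rs2232641",  "G",   "A",   96,  0, 214,  0),
    ("LIG4",   "rs3093766",  "A",   "G",   96,  0, 214,  0),
)
# fmt: on

#: rs_ids reported as significantly associated in the reference cohort.
NPC_SIGNIFICANT_RS_IDS = frozenset(
    {
        "rs1801516",  # ATM, variant allele deleterious
        "rs2279744",  # HDM2
        "rs1196333",  # HDM2
        "rs1800469",  # TGFB1
        "rs25487",    # XRCC1
        "rs1051677",  # XRCC5
    }
)

#: fibrosis-grade histogram of the reference cohort (grades 0..4)
NPC_GRADE_HISTOGRAM = (17, 54, 36, 38, 10)

NPC_N_CASES = 48
NPC_N_CONTROLS = 107


def npc_panel() -> tuple[SnpDef, ...]:
    """The 45-SNP candidate-gene panel, in published order."""
    return tuple(
        SnpDef(gene=g, rs_id=rs, allele1=a1, allele2=a2)
        for g, rs, a1, a2, *_ in _ROWS
    )


def npc_allele_tables() -> list[AlleleTable]:
    """The 45 published 2x2 allele-count tables (cases 96, controls 214 alleles)."""
    return [AlleleTable(a=a, b=b, c=c, d=d) for *_, a, b, c, d in _ROWS]


def npc_control_vaf() -> dict[str, float]:
    """Control-group variant-allele frequency per SNP, d / (c + d)."""
    return {rs: d / (c + d) for _, rs, _, _, _, _, c, d in _ROWS}
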