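"""Reference marginals of the 493-patient operation-centric OSCC cohort.

These are the per-category patient counts of the hospital registry cohort
the synthetic generator emulates, split by the 36-month survival dichotomy
(271 patients above, 222 at or below).  For several attributes the category
counts fall short of the cohort size; the shortfall is registry missingness
and is reproduced as missing values, never imputed.

Also defined here are the eleven item/joint count constraints that pin down
the deterministic four-attribute benchmark transaction set for the >36-month
stratum (see :func:`clinrules.synthetic.build_reference_fixture`).
"""

from __future__ import annotations

#: attribute -> list of (category, n in >36 stratum, n in <=36 stratum).
#: Categories are at raw level where the generator samples raw values
#: (age, sizes and node counts are drawn inside the stated bin).
STRATUM_GT36 = 271
STRATUM_LE36 = 222

REFERENCE_MARGINALS: dict[str, list[tuple[str, int, int]]] = {
    "age_group": [
        ("<30", 3, 4),
        ("30~50", 125, 103),
        ("50~70", 129, 107),
        (">70", 14, 8),
    ],
    "primary_site": [
        ("Lip", 24, 12),
        ("Cheek mucosa", 103, 81),
        ("Gum", 25, 17),
        ("Tongue", 88, 87),
        ("Mouth floor", 11, 8),
        ("Palate", 3, 2),
        ("Retromolar", 15, 12),
        ("Vestibule", 1, 1),
        ("Nonspecific", 1, 2),
    ],
    "laterality": [
        ("00", 22, 15),
        ("01", 123, 107),
        ("02", 123, 100),
        ("03", 3, 0),
        ("04", 0, 0),
    ],
    "grade": [
        ("01", 156, 131),
        ("02", 60, 63),
        ("03", 5, 2),
        ("04", 1, 0),
        ("09", 49, 26),
    ],
    "nodes_group": [
        ("<5", 160, 125),
        ("5~10", 45, 28),
        (">10", 65, 69),
    ],
    "clinical_stage": [
        ("0", 0, 4),
        ("1", 79, 62),
        ("2", 47, 26),
        ("3", 69, 62),
        ("4", 50, 32),
    ],
    "pathologic_stage": [
        ("0", 2, 0),
        ("1", 112, 103),
        ("2", 52, 40),
        ("3", 15, 16),
        ("4", 24, 34),
    ],
    "clinical_size_group": [
        ("<2 cm", 100, 62),
        ("2~4 cm", 134, 110),
        (">4 cm", 19, 14),
    ],
    "pathology_size_group": [
        ("<2 cm", 114, 83),
        ("2~4 cm", 94, 89),
        (">4 cm", 14, 11),
    ],
    "op_group": [
        ("01", 238, 147),
        ("02", 14, 13),
        ("03", 19, 62),
    ],
}

#: The four attributes of the multivariate rule analysis, in canonical order.
ANALYSIS_ATTRIBUTES = ("grade", "clinical_stage_group", "primary_site", "group")

#: Benchmark fixture constraints for the >36-month stratum (N = 271):
#: each key is a subset of the four analysis items (grade=02, tongue,
#: early clinical stage, OP) and maps to its exact transaction count.
#: These eleven counts are the complete count surface of the published
#: top-10 rule ranking; all other cells of the joint distribution are free.
FIXTURE_CONSTRAINTS: dict[frozenset[str], int] = {
    frozenset(): 271,
    frozenset({"grade=02"}): 60,
    frozenset({"primary_site=tongue"}): 88,
    frozenset({"grade=02", "clinical_stage_group=early"}): 49,
    frozenset({"grade=02", "group=OP"}): 55,
    frozenset({"primary_site=tongue", "clinical_stage_group=early"}): 70,
    frozenset({"primary_site=tongue", "group=OP"}): 78,
    frozenset({"primary_site=tongue", "clinical_stage_group=early", "group=OP"}): 65,
    frozenset({"grade=02", "clinical_stage_group=early", "group=OP"}): 46,
    frozenset({"grade=02", "primary_site=tongue", "clinical_stage_group=early"}): 27,
    frozenset(
        {"grade=02", "primary_site=tongue", "clinical_stage_group=early", "group=OP"}
    ): 27,
}
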