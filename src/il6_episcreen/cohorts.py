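"""Cohort (tumor-type) labels and the default pan-cancer registry.

The default registry carries the 33 TCGA tumor-type abbreviations used
throughout the pan-cancer screens, keyed by the short uppercase code
(e.g. ``KIRC``) with a human-readable display name.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class CohortLabel:
    """A tumor-type cohort: short uppercase code plus display name."""

    code: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("cohort code must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


#: The 33 TCGA tumor types of the pan-cancer study, code -> display name.
DEFAULT_COHORTS: dict[str, CohortLabel] = {
    code: CohortLabel(code, name)
    for code, name in [
        ("LAML", "Acute Myeloid Leukemia"),
        ("ACC", "Adrenocortical Cancer"),
        ("CHOL", "Bile Duct Cancer"),
        ("BLCA", "Bladder Cancer"),
        ("BRCA", "Breast Cancer"),
        ("CESC", "Cervical Cancer"),
        ("COAD", "Colon Cancer"),
        ("UCEC", "Endometrioid Cancer"),
        ("ESCA", "Esophageal Cancer"),
        ("GBM", "Glioblastoma"),
        ("HNSC", "Head and Neck Cancer"),
        ("KICH", "Kidney Chromophobe"),
        ("KIRC", "Kidney Clear Cell Carcinoma"),
        ("KIRP", "Kidney Papillary Cell Carcinoma"),
        ("DLBC", "Large B-cell Lymphoma"),
        ("LIHC", "Liver Cancer"),
        ("LGG", "Lower Grade Glioma"),
        ("LUAD", "Lung Adenocarcinoma"),
        ("LUSC", "Lung Squamous Cell Carcinoma"),
        ("SKCM", "Melanoma"),
        ("MESO", "Mesothelioma"),
        ("UVM", "Ocular melanomas"),
        ("OV", "Ovarian Cancer"),
        ("PAAD", "Pancreatic Cancer"),
        ("PCPG", "Pheochromocytoma and Paraganglioma"),
        ("PRAD", "Prostate Cancer"),
        ("READ", "Rectal Cancer"),
        ("SARC", "Sarcoma"),
        ("STAD", "Stomach Cancer"),
        ("TGCT", "Testicular Cancer"),
        ("THYM", "Thymoma"),
        ("THCA", "Thyroid Cancer"),
        ("UCS", "Uterine Carcinosarcoma"),
    ]
}


#: Printed tumor (TCGA) and normal (GTEx) sample counts per cohort,
#: code -> (n_tumor, n_normal); these are the study's sample sizes and the
#: defaults the full-study simulator reproduces.
COHORT_SAMPLE_SIZES: dict[str, tuple[int, int]] = {
    "LAML": (173, 337),
    "ACC": (77, 128),
    "CHOL": (36, 110),
    "BLCA": (407, 9),
    "BRCA": (1099, 179),
    "CESC": (306, 10),
    "COAD": (290, 308),
    "UCEC": (181, 78),
    "ESCA": (182, 653),
    "GBM": (166, 1141),
    "HNSC": (520, 55),
    "KICH": (197, 29),
    "KIRC": (531, 29),
    "KIRP": (289, 29),
    "DLBC": (47, 337),
    "LIHC": (371, 110),
    "LGG": (523, 1141),
    "LUAD": (515, 288),
    "LUSC": (498, 288),
    "SKCM": (469, 556),
    "MESO": (87, 288),
    "UVM": (79, 556),
    "OV": (427, 88),
    "PAAD": (179, 167),
    "PCPG": (182, 128),
    "PRAD": (496, 100),
    "READ": (93, 308),
    "SARC": (262, 396),
    "STAD": (414, 174),
    "TGCT": (154, 165),
    "THYM": (119, 337),
    "THCA": (512, 279),
    "UCS": (57, 78),
}


def default_registry() -> list[CohortLabel]:
    """Return the bundled 33-cohort registry as a list."""
    return list(DEFAULT_COHORTS.values())
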