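"""Example call catalogue: a published-style set of CNV and cn-LOH records
from a 10-patient paired coronary/mammary artery CGH+SNP cohort (hg19),
shipped as strings in ISCN array nomenclature together with the lengths
printed alongside them.

Used as a realistic fixture for the ISCN parser, the interval arithmetic
and the cn-LOH span filter.  One cn-LOH record (8p11.1-p11.21) prints a
length of 2,627,000 bp while its coordinates give end - start + 1 =
2,626,960; the coordinate-derived value is authoritative here and the
40 bp disagreement is preserved as-is.  The CNV table likewise carries 16
records even though the accompanying prose counts 15 regions; all 16 are
kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .array_io import IscnRecord, parse_iscn


@dataclass(frozen=True)
class CatalogueEntry:
    iscn: str
    printed_length_bp: int
    patient_ids: tuple

    @property
    def record(self) -> IscnRecord:
        return parse_iscn(self.iscn)

    @property
    def derived_length_bp(self) -> int:
        return self.record.interval.length


#: CNV records (copy number x1 or x3), shared by the CAP and IMA samples
#: of the patients listed.
CNV_CATALOGUE: tuple = (
    CatalogueEntry("arr[hg19]1p22.2 (89474710–89479067)×3", 4358, (1, 2, 5, 7, 8, 9, 10)),
    CatalogueEntry("arr[hg19]1p21.1 (104115870–104120646)×1", 4777, (2, 3, 4, 6, 7, 8, 10)),
    CatalogueEntry("arr[hg19]1q31.3 (196748499–196800758)×1", 52260, (2, 3, 4, 7)),
    CatalogueEntry("arr[hg19]2q13 (110849200–110980342)×1", 131143, (4,)),
    CatalogueEntry("arr[hg19]2q37.3 (242865920–243076752)×1", 210833, (4,)),
    CatalogueEntry("arr[hg19]3p21.1 (53028096–53059285)×1", 31190, (1, 7)),
    CatalogueEntry("arr[hg19]7q33 (133764157–133812235)×1", 48079, (1,)),
    CatalogueEntry("arr[hg19] 9p21.1 (28591992–28758126)×1", 166135, (7,)),
    CatalogueEntry("arr[hg19]10q21.1 (56457621–56465378)×3", 7758, (2,)),
    CatalogueEntry("arr[hg19]10q21.3 (68078402–68109984)×1", 31583, (1,)),
    CatalogueEntry("arr[hg19]10q24.31 (101911972–101944947)×3", 32976, (10,)),
    CatalogueEntry("arr[hg19]12q24.11 (109547804–109661604)×3", 113801, (4,)),
    CatalogueEntry("arr[hg19]16q13.11–q13.12 (15048751–15122499)×1", 73749, (4,)),
    CatalogueEntry("arr[hg19]16q22.1 (70152776–70190625)×3", 37850, (4, 10)),
    CatalogueEntry("arr[hg19]17p11.2 (21736281–22154574)×3", 418294, (10,)),
    CatalogueEntry("arr[hg19]22q11.23 (24347959–24376216)×1", 28258, (3,)),
)

#: Copy-neutral LOH records ("x2 hmz"), in paired arterial samples of
#: 4 of the 10 patients.
CNLOH_CATALOGUE: tuple = (
    CatalogueEntry("arr[hg19]7q21.12–q21.13 (86765642–89595238)×2 hmz", 2829597, (1,)),
    CatalogueEntry("arr[hg19]11p12 (37110535–40336165)×2 hmz", 3225631, (1,)),
    CatalogueEntry("arr[hg19]18q12.1–q12.2 (29841532–33526175)×2 hmz", 3684644, (1,)),
    CatalogueEntry("arr[hg19]6q15 (90703280–92347529)×2 hmz", 1644250, (2,)),
    CatalogueEntry("arr[hg19]8p11.1–p11.21 (40893397–43520356)×2 hmz", 2627000, (2,)),
    CatalogueEntry("arr[hg19]8q11.1–q11.21 (46940022–49990006)×2 hmz", 3049985, (2,)),
    CatalogueEntry("arr[hg19]17q23.1–q24.1 (57734690–64120329)×2 hmz", 6385640, (3,)),
    CatalogueEntry("arr[hg19]9p21.2 (26038217–27819206)×2 hmz", 1780990, (7,)),
)

ALL_CATALOGUE: tuple = CNV_CATALOGUE + CNLOH_CATALOGUE

#: the one entry whose printed length disagrees with its coordinates (by 40 bp)
DISCREPANT_ENTRY = CNLOH_CATALOGUE[4]

#: recurrence arithmetic of the cohort the catalogue summarises: 55 of the
#: 90 shared CNVs were seen in more than one patient.
COHORT_TOTAL_CNVS = 90
COHORT_RECURRENT_CNVS = 55
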