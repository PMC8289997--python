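"""Fixtures encoding the study's printed report tables.

Two report tables are public and small enough to re-key by hand: the
known-gene screen output (clinical-panel variants and their carriers) and
the high-risk screen output (very rare, high-CADD variants segregating in
WES-3/WES-4 families).  :func:`build_table_fixture` reconstructs, for
either table, a complete 24-family / 59-sample cohort in which exactly the
printed carriers are carriers and every other call is homozygous
reference, together with the printed annotation rows — so running the
corresponding screen on the fixture must reproduce the printed rows and
nothing else.

The shared-variant fixture encodes the carrier pattern reported for the
recurrently observed FANCM stop-gain allele (both members of one WES-2
family, two of four members of a WES-4 family, and one member in each of
two further WES-2 families).  Its MMAF and CADD values are synthetic
stand-ins chosen inside the reported qualifying ranges (MMAF < 0.01,
CADD > 25); the report prints the ranges, not the values.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from famseg.annotation import AnnotationRow
from famseg.cohort import HET, HOM_ALT, HOM_REF, CohortGenotypes, Family
from famseg.simulate import SimulationConfig, _make_families

#: (gene, chrom, pos, ref, alt, dbsnp, function, change, clinvar, mmaf,
#:  acmg, cadd, {family: (carriers...)})
_TABLE1_ROWS = [
    ("MSH2", "2", 47703548, "G", "T", "rs755920849", "Missense",
     "NM_000251:exon13:c.G2048T:p.G683V", "Uncertain significance",
     0.0, "3", 32.0, {"Br2": ("Br2.2", "Br2.4")}),
    ("NBN", "8", 90983460, "G", "A", "rs34767364", "Missense",
     "NM_002485:exon6:c.C643T:p.R215W",
     "Conflicting interpretation of pathogenicity",
     0.006, "3", 26.0, {"Br24": ("Br24.1",)}),
    ("ATM", "11", 108188118, "C", "G", "rs767406075", "Missense",
     "NM_000051:exon43:c.C6217G:p.L2073V", "Uncertain significance",
     6.0e-05, "3", 28.3, {"Br22": ("Br22.1", "Br22.2")}),
    ("PALB2", "16", 23637556, "C", "A", "rs753153576", "Splicing",
     "NM_024675:exon7:c.2748+1G>T", "Pathogenic/likely pathogenic",
     1.5e-05, "5", 26.1, {"Br4": ("Br4.1",)}),
    ("RAD51C", "17", 56787304, "G", "A", "rs147241704", "Missense",
     "NM_058216:exon5:c.G790A:p.G264S",
     "Conflicting interpretations of pathogenicity",
     0.005, "2", 23.4, {"Br5": ("Br5.2",)}),
    ("BRIP1", "17", 59821942, "T", "GGA", "rs786203384", "Insert",
     "NM_032043:exon15:c.2108delTinsGGA:p.Lys703fs", "Pathogenic",
     0.0, "5", None, {"Br16": ("Br16.2",)}),
    ("CHEK2", "22", 29091824, "G", "A", "rs587780167", "Missense",
     "NM_007194:exon11:c.C1133T:p.T378I", "Uncertain significance",
     2.0e-04, "3", 23.4, {"Br16": ("Br16.2",)}),
    ("CHEK2", "22", 29091857, "C", "-", "rs555607708", "Deletion",
     "NM_007194:exon11:c.1100delC:p.T367fs",
     "Conflicting interpretations of pathogenicity",
     0.008, "3", None,
     {"Br15": ("Br15.2",), "Br7": ("Br7.3",), "Br1": ("Br1.1", "Br1.3")}),
]

#: (gene, chrom, pos, ref, alt, dbsnp, function, change, mmaf, cadd, family)
_TABLE3_ROWS = [
    ("ZNF563", "19", 12429950, "G", "A", "rs143701013", "Stopgain",
     "NM_145276:exon4:c.C889T:p.R297X", 3.0e-04, 33.0, "Br3"),
    ("PTPRF", "1", 44086600, "T", "C", None, "Missense",
     "NM_130440:exon31:c.T5429C:p.I1810T", 0.0, 27.9, "Br5"),
    ("PIWIL2", "8", 22161596, "G", "A", None, "Missense",
     "NM_001135721:exon11:c.G1244A:p.G415D", 0.0, 29.0, "Br5"),
    ("FANK1", "10", 127693544, "TG", "-", "rs769623079", "Deletion",
     "NM_145235:exon7:c.631_632del:p.C211fs", 1.5e-05, None, "Br5"),
    ("SBNO2", "19", 1112229, "G", "A", "rs745886953", "Missense",
     "NM_001100122:exon19:c.C2416T:p.R806C", 3.0e-04, 28.6, "Br5"),
    ("ZNF862", "7", 149557832, "G", "A", None, "Missense",
     "NM_001099220:exon7:c.G1583A:p.C528Y", 0.0, 25.7, "Br6"),
    ("ASIC3", "7", 150746421, "A", "G", "rs201385813", "Missense",
     "NM_004769:exon1:c.A449G:p.Y150C", 2.0e-04, 25.2, "Br6"),
    ("BMPER", "7", 34192769, "A", "C", "rs758133020", "Missense",
     "NM_133468:exon16:c.A1942C:p.N648H", 5.0e-04, 25.9, "Br6"),
    ("HYPK", "15", 44093970, "A", "G", "rs200501830", "Missense",
     "NM_016400:exon4:c.A356G:p.N119S", 4.0e-04, 25.8, "Br6"),
    ("EMX1", "2", 73161012, "C", "A", "rs766243607", "Missense",
     "NM_004097:exon3:c.C802A:p.H268N", 1.0e-04, 26.7, "Br7"),
    ("EPPK1", "8", 144942386, "C", "T", "rs201157982", "Missense",
     "NM_031308:exon2:c.G5036A:p.R1679H", 5.0e-04, 31.0, "Br7"),
    ("KIF26A", "14", 104618716, "C", "T", "rs759188299", "Missense",
     "NM_015656:exon3:c.C653T:p.T218M", 5.0e-04, 25.7, "Br7"),
    ("PRR14", "16", 30666219, "C", "T", "rs576330025", "Missense",
     "NM_024031:exon8:c.C928T:p.R310C", 9.0e-04, 29.9, "Br7"),
    ("PHLDB3", "19", 44005948, "G", "T", "rs773676224", "Missense",
     "NM_198850:exon4:c.C472A:p.L158M", 5.0e-04, 25.8, "Br7"),
    ("LIG1", "19", 48643245, "G", "C", "rs760308186", "Missense",
     "NM_001289064:exon10:c.C866G:p.A289G", 5.0e-04, 28.3, "Br7"),
    ("ANKRA2", "5", 72850162, "C", "T", None, "Missense",
     "NM_023039:exon7:c.G790A:p.V264I", 0.0, 28.5, "Br8"),
    ("ARAP1", "11", 72415241, "G", "A", "rs770843799", "Missense",
     "NM_015242:exon12:c.C1213T:p.R405C", 6.7e-05, 28.4, "Br8"),
    ("EOMES", "3", 27761701, "T", "G", "rs745642069", "Missense",
     "NM_001278182:exon2:c.A997C:p.K333Q", 3.0e-04, 26.3, "Br9"),
    ("DAAM2", "6", 39869622, "C", "T", "rs553394639", "Missense",
     "NM_001201427:exon25:c.C3016T:p.R1006W", 4.0e-04, 28.6, "Br9"),
    ("YLPM1", "14", 75248152, "A", "T", "rs45550132", "Missense",
     "NM_019589:exon4:c.A1406T:p.Y469F", 2.0e-04, 26.0, "Br9"),
    ("GALC", "14", 88434679, "G", "A", "rs756352952", "Missense",
     "NM_001201401:exon7:c.C839T:p.S280F", 1.0e-04, 33.0, "Br9"),
    ("GIPC3", "19", 3586860, "G", "T", "rs775765891", "Missense",
     "NM_133261:exon3:c.G460T:p.G154C", 7.7e-05, 28.8, "Br9"),
]

#: Homozygote carriers called out in the report text (variant label ->
#: sample): the ZNF563 stop-gain had one homozygous carrier in its family.
_TABLE3_HOMOZYGOTES = {("19", 12429950): "Br3.1"}


def study_families() -> list[Family]:
    """The 24-family / 59-sample cohort layout: Br1-Br3 WES-4s, Br4-Br9
    WES-3s, Br10-Br23 WES-2s, Br24 WES-1s, members named ``BrN.k``."""
    return _make_families(SimulationConfig())


def _af_map(mmaf: float) -> dict[str, float]:
    # one panel carrying exactly the folded maximum; 0 = absent everywhere
    return {"ExAC": mmaf} if mmaf > 0 else {}


def _assemble(
    annotations: list[AnnotationRow],
    carrier_map: list[dict[str, tuple[str, ...]]],
    homozygotes: Optional[dict[tuple[str, int], str]] = None,
) -> tuple[list[AnnotationRow], list[Family], CohortGenotypes]:
    families = study_families()
    samples = [s for fam in families for s in fam.members]
    sindex = {s: j for j, s in enumerate(samples)}
    homozygotes = homozygotes or {}
    keys = [row.key for row in annotations]
    calls = np.full((len(keys), len(samples)), HOM_REF, dtype=np.int8)
    for i, (row, fam_carriers) in enumerate(zip(annotations, carrier_map)):
        hom_sample = homozygotes.get((row.key.chrom, row.key.pos))
        for carriers in fam_carriers.values():
            for sample in carriers:
                calls[i, sindex[sample]] = (
                    HOM_ALT if sample == hom_sample else HET
                )
    cohort = CohortGenotypes(variants=keys, samples=samples, calls=calls)
    return annotations, families, cohort


def build_table_fixture(
    table_id: str,
) -> tuple[list[AnnotationRow], list[Family], CohortGenotypes]:
    """Reconstruct the cohort behind one printed report table.

    ``table_id`` is ``"table1"`` (known-gene screen: 8 variants, 10
    variant-family observations, 13 carrier observations across 9 families)
    or ``"table3"`` (high-risk screen: 22 variants in 22 genes segregating
    in 6 WES-3/WES-4 families).  Listed carriers are het (hom-alt where the
    report states a homozygote); every other call is hom-ref, so BC_GF is 1
    for every fixture variant.
    """
    tid = table_id.strip().lower().replace(" ", "")
    if tid == "table1":
        annotations = []
        carrier_map = []
        for (gene, chrom, pos, ref, alt, dbsnp, func, change, clinvar,
             mmaf, acmg, cadd, carriers) in _TABLE1_ROWS:
            annotations.append(
                AnnotationRow(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, dbsnp_id=dbsnp,
                    gene=gene, function_raw=func, change=change,
                    af_by_panel=_af_map(mmaf), cadd_phred=cadd,
                    clinvar_raw=clinvar, acmg_raw=acmg,
                )
            )
            carrier_map.append(carriers)
        return _assemble(annotations, carrier_map)
    if tid == "table3":
        families = {f.family_id: f for f in study_families()}
        annotations = []
        carrier_map = []
        for (gene, chrom, pos, ref, alt, dbsnp, func, change,
             mmaf, cadd, family_id) in _TABLE3_ROWS:
            annotations.append(
                AnnotationRow(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, dbsnp_id=dbsnp,
                    gene=gene, function_raw=func, change=change,
                    af_by_panel=_af_map(mmaf), cadd_phred=cadd,
                )
            )
            # high-risk variants segregate: every sequenced member carries
            carrier_map.append({family_id: families[family_id].members})
        return _assemble(annotations, carrier_map, homozygotes=_TABLE3_HOMOZYGOTES)
    raise ValueError(f"unknown table fixture {table_id!r} (use 'table1' or 'table3')")


#: Reported carrier pattern of the FANCM stop-gain allele: family -> samples.
_SHARED_PATTERN = {
    "Br21": ("Br21.1", "Br21.2"),  # both members of a WES-2 family
    "Br3": ("Br3.1", "Br3.2"),     # two of four members of a WES-4 family
    "Br18": ("Br18.1",),
    "Br23": ("Br23.1",),
}


def build_shared_variant_fixture() -> tuple[list[AnnotationRow], list[Family], CohortGenotypes]:
    """Cohort carrying the reported FANCM-pattern shared variant plus two
    decoys the shared-variant scan must reject.

    The FANCM-like stop-gain has carriers in four families (6 carriers) and
    synthetic qualifying scores (MMAF 1.7e-3 < 0.01, CADD 36 > 25).  Decoy
    1 qualifies on scores but spans only two families; decoy 2 spans four
    families but has CADD 20, below the strict threshold.
    """
    annotations = [
        AnnotationRow(
            chrom="14", pos=45658326, ref="C", alt="T", dbsnp_id="rs147021911",
            gene="FANCM", function_raw="stopgain",
            change="NM_020937:exon20:c.C5101T:p.Q1701X",
            af_by_panel={"SweGen": 1.7e-3}, cadd_phred=36.0,
        ),
        AnnotationRow(
            chrom="4", pos=3076603, ref="G", alt="C", dbsnp_id="rs1065746",
            gene="HTT", function_raw="nonsynonymous SNV",
            change="NM_002111:exon23:c.G3244C:p.D1082H",
            af_by_panel={"ExAC": 4.0e-3}, cadd_phred=27.0,
        ),
        AnnotationRow(
            chrom="17", pos=56356678, ref="C", alt="T", dbsnp_id="rs149133270",
            gene="MPO", function_raw="nonsynonymous SNV",
            change="NM_000250:exon8:c.G1379A:p.R460Q",
            af_by_panel={"ExAC": 2.0e-3}, cadd_phred=20.0,
        ),
    ]
    carrier_map = [
        dict(_SHARED_PATTERN),
        {"Br20": ("Br20.1", "Br20.2"), "Br8": ("Br8.1", "Br8.2")},  # 2 families only
        {"Br24": ("Br24.1",), "Br1": ("Br1.2",), "Br2": ("Br2.1",),
         "Br9": ("Br9.3",)},  # 4 families but CADD at threshold, not above
    ]
    return _assemble(annotations, carrier_map)
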