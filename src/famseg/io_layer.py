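"""Readers and writers for the external file formats.

Formats handled here:

* multi-sample **VCF** (v4.x) via cyvcf2, with multi-allelic sites
  decomposed into biallelic records on read;
* the **family file**, a PED-like tab-separated dialect without parental
  columns (only affected carriers were sequenced): columns ``family_id``,
  ``sample_id``, ``affected``, ``degree_class``;
* the **annotation table**, ANNOVAR-style TSV with one allele-frequency
  column per population panel (``AF_<panel>``) and columns ``Chr``,
  ``Pos``, ``Ref``, ``Alt``, ``avsnp150``, ``Gene``, ``ExonicFunc``,
  ``Change``, ``CADD_phred``, ``CLNSIG``, ``ACMG``;
* tab-separated candidate/recurrence/shared reports.

Empty cells and the literals ``na``/``NA``/``.`` read as absent, never as
zero.  All writers are deterministic: rerunning on the same input produces
a byte-identical file.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from famseg.annotation import AnnotationRow
from famseg.cohort import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortGenotypes,
    Family,
    VariantKey,
)
from famseg.cross_family import CohortSummary, RecurrentGene, SharedVariant
from famseg.tiers import CandidateCall

PathLike = Union[str, Path]

_ABSENT = {"", "na", "n/a", "nan", "."}


def _absent(cell: Optional[str]) -> bool:
    return cell is None or cell.strip().lower() in _ABSENT


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: PathLike) -> CohortGenotypes:
    """Read a multi-sample VCF into a genotype matrix.

    Multi-allelic sites are decomposed: a site with ALT ``A,T`` yields two
    biallelic records at the same position, and each sample's call for
    record *k* is the count of its alleles equal to *k* (any no-call allele
    makes the whole genotype missing).  Sample order is preserved.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for record in vcf:
        gts = record.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in enumerate(record.ALT, start=1):
            key = VariantKey.make(record.CHROM, record.POS, record.REF, alt)
            row = np.empty(len(samples), dtype=np.int8)
            for j, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    row[j] = MISSING
                else:
                    row[j] = sum(1 for a in alleles if a == alt_index)
            variants.append(key)
            rows.append(row)
    vcf.close()
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return CohortGenotypes(variants=variants, samples=samples, calls=calls)


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(cohort: CohortGenotypes, path: PathLike) -> None:
    """Write the genotype matrix as a minimal VCFv4.2 (one biallelic record
    per variant, GT field only).  Read -> write round-trips calls exactly."""
    seen: dict[str, None] = {}
    for key in cohort.variants:
        seen.setdefault(key.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID={chrom}>" for chrom in seen),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.samples),
    ]
    for i, key in enumerate(cohort.variants):
        gts = "\t".join(_GT_STRING[int(c)] for c in cohort.calls[i])
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Family file
# ---------------------------------------------------------------------------

FAMILY_FILE_COLUMNS = ["family_id", "sample_id", "affected", "degree_class"]

_DEGREE_ORDER = {"1st": 1, "2nd": 2, "3rd": 3, "4th": 4}


def read_family_file(path: PathLike) -> list[Family]:
    """Read the family file and group samples into Family objects.

    The WES class is derived as the number of sequenced members; the degree
    span is the most distant ``degree_class`` label among them.  Duplicate
    (family, sample) rows are an error.
    """
    families: dict[str, list[str]] = {}
    degrees: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(FAMILY_FILE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"family file missing columns: {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            fam_id = row["family_id"].strip()
            sample_id = row["sample_id"].strip()
            if not fam_id or not sample_id:
                raise ValueError(f"family file line {line_no}: empty id")
            pair = (fam_id, sample_id)
            if pair in seen:
                raise ValueError(
                    f"family file line {line_no}: duplicate sample {sample_id!r} "
                    f"in family {fam_id!r}"
                )
            seen.add(pair)
            families.setdefault(fam_id, []).append(sample_id)
            degrees.setdefault(fam_id, []).append(row["degree_class"].strip())
    out = []
    for fam_id, members in families.items():
        span = max(degrees[fam_id], key=lambda d: _DEGREE_ORDER.get(d, 0))
        out.append(Family(family_id=fam_id, members=tuple(members), degree_span=span))
    return out


def write_family_file(families: Sequence[Family], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FAMILY_FILE_COLUMNS)
        for fam in families:
            for sample in fam.members:
                writer.writerow([fam.family_id, sample, "1", fam.degree_span])


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

ANNOTATION_FIXED_COLUMNS = [
    "Chr",
    "Pos",
    "Ref",
    "Alt",
    "avsnp150",
    "Gene",
    "ExonicFunc",
    "Change",
    "CADD_phred",
    "CLNSIG",
    "ACMG",
]

DEFAULT_PANELS = ["ExAC", "200Danes", "SweGen", "1000G"]


def read_annotation_table(path: PathLike) -> list[AnnotationRow]:
    """Read an ANNOVAR-style annotation TSV.

    Any column named ``AF_<panel>`` is treated as a population panel; empty
    AF/CADD/ClinVar cells are preserved as absent (an all-absent AF row
    yields MMAF 0 downstream, which is the defined value for an allele seen
    in no panel).
    """
    rows: list[AnnotationRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        missing = {"Chr", "Pos", "Ref", "Alt", "Gene", "ExonicFunc"} - set(fields)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        af_columns = [c for c in fields if c.startswith("AF_")]
        for row in reader:
            af_by_panel = {}
            for col in af_columns:
                if not _absent(row.get(col)):
                    af_by_panel[col[3:]] = float(row[col])
            rows.append(
                AnnotationRow(
                    chrom=row["Chr"].strip(),
                    pos=int(row["Pos"]),
                    ref=row["Ref"].strip(),
                    alt=row["Alt"].strip(),
                    dbsnp_id=None if _absent(row.get("avsnp150")) else row["avsnp150"].strip(),
                    gene=row["Gene"].strip(),
                    function_raw=row["ExonicFunc"].strip(),
                    change=(row.get("Change") or "").strip(),
                    af_by_panel=af_by_panel,
                    cadd_phred=None if _absent(row.get("CADD_phred")) else float(row["CADD_phred"]),
                    clinvar_raw=None if _absent(row.get("CLNSIG")) else row["CLNSIG"].strip(),
                    acmg_raw=None if _absent(row.get("ACMG")) else row["ACMG"].strip(),
                )
            )
    return rows


def _fmt(value, nd: int = 6) -> str:
    if value is None:
        return "na"
    if isinstance(value, float):
        return repr(round(value, 10))
    return str(value)


def write_annotation_table(
    rows: Iterable[AnnotationRow], path: PathLike, panels: Optional[Sequence[str]] = None
) -> None:
    rows = list(rows)
    if panels is None:
        panels = sorted({p for r in rows for p in r.af_by_panel}) or DEFAULT_PANELS
    header = ANNOTATION_FIXED_COLUMNS[:8] + [f"AF_{p}" for p in panels] + [
        "CADD_phred",
        "CLNSIG",
        "ACMG",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in rows:
            writer.writerow(
                [
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.dbsnp_id or "na",
                    r.gene,
                    r.function_raw,
                    r.change,
                ]
                + [
                    _fmt(r.af_by_panel.get(p)) if p in r.af_by_panel else ""
                    for p in panels
                ]
                + [_fmt(r.cadd_phred), r.clinvar_raw or "", r.acmg_raw or ""]
            )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "Gene",
    "Location",
    "Ref",
    "Alt",
    "SNPid",
    "Function",
    "Change",
    "ClinVar",
    "MMAF",
    "CADD",
    "Tier",
    "Family",
    "Carriers",
    "HomozygousCarriers",
    "Provenance",
]


def write_candidate_report(calls: Sequence[CandidateCall], path: PathLike) -> None:
    """Write one tab-separated row per (variant, family) call.

    Columns mirror the clinical report layout (gene, location, alleles,
    dbSNP id, function, transcript change, ClinVar, MMAF, CADD) plus the
    carrier list and a per-criterion ``criterion=observed:pass`` audit
    column.  Rows are sorted by (chrom, pos, alt, family); rerunning on the
    same calls yields a byte-identical file.
    """
    from famseg.tiers import sort_calls

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for call in sort_calls(calls):
            v = call.variant
            prov = ";".join(
                f"{name}={_fmt(obs)}:{'pass' if ok else 'FAIL'}"
                for name, (ok, obs) in call.provenance.items()
            )
            writer.writerow(
                [
                    v.gene,
                    f"chr{v.key.chrom}:{v.key.pos}",
                    v.key.ref,
                    v.key.alt,
                    v.dbsnp_id or "na",
                    v.function_class.value,
                    v.change,
                    v.clinvar_class.value,
                    _fmt(v.mmaf),
                    _fmt(v.cadd),
                    call.tier,
                    call.family_id,
                    ",".join(call.carriers),
                    ",".join(call.homozygous_carriers),
                    prov,
                ]
            )


def write_recurrent_gene_report(genes: Sequence[RecurrentGene], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Gene", "NVariants", "NFamilies", "Variants", "Families"])
        for g in genes:
            writer.writerow(
                [
                    g.gene,
                    g.n_variants,
                    g.n_families_total,
                    ";".join(k.label() for k in g.variants),
                    ";".join(
                        ",".join(g.families_by_variant[k]) for k in g.variants
                    ),
                ]
            )


def write_shared_variant_report(shared: Sequence[SharedVariant], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["Gene", "Location", "Ref", "Alt", "MMAF", "CADD", "NFamilies", "NCarriers", "CarriersByFamily"]
        )
        for s in shared:
            v = s.variant
            writer.writerow(
                [
                    v.gene,
                    f"chr{v.key.chrom}:{v.key.pos}",
                    v.key.ref,
                    v.key.alt,
                    _fmt(v.mmaf),
                    _fmt(v.cadd),
                    s.n_families,
                    s.n_carriers,
                    ";".join(
                        f"{fam}:{','.join(samples)}"
                        for fam, samples in s.carriers_by_family.items()
                    ),
                ]
            )


def write_cohort_summary(summary: CohortSummary, path: PathLike) -> None:
    """Write the function-class x WES-class cross-tab as TSV."""
    df = summary.table.copy()
    df.index.name = "FunctionClass"
    df.to_csv(path, sep="\t")
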