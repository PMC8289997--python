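"""Synthetic family-cohort generator.

Because the real cohort's genotype data is access-controlled, the pipeline
is exercised on a simulated stand-in that reproduces the study's shape:
24 families of affected relatives, 59 sequenced patients split 3/6/14/1
into WES-4s/WES-3s/WES-2s/WES-1s classes, a background of rare and common
exome variants, annotation fields (per-panel allele frequencies, CADD,
function class, ClinVar strings), genotype missingness, and one planted
risk variant per family that segregates by construction.

Model choices:

* **Founders and background sites** follow Hardy–Weinberg equilibrium with
  independent sites (no linkage disequilibrium) — the screens filter sites
  independently, so LD would add nothing to what the tests probe.
* **Background genotypes** are drawn independently per sample from the
  site's allele frequency (genotype probabilities (1-p)^2, 2p(1-p), p^2).
  Within-family relatedness is modelled separately by the gene-drop
  machinery (:func:`gene_drop_family`), which transmits founder alleles
  with probability 1/2 per meiosis down a schematic pedigree; that is what
  the chance-segregation analysis uses.
* **Planted variants** are heterozygous in every sequenced member of their
  target family (dominant-inheritance framing) and annotated to satisfy
  their declared tier's thresholds by construction.
* **Missingness** is applied uniformly at random per (variant, sample)
  after carrier assignment.

All randomness flows through one ``numpy`` Generator seeded from the
config; identical configs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from famseg.annotation import (
    AnnotationRow,
    FunctionClass,
    VariantRecord,
    annotation_to_record,
)
from famseg.cohort import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortGenotypes,
    Family,
    VariantKey,
)
from famseg.tiers import HIGH_RISK_TIER, NOVEL_CANDIDATE_TIER, TierSpec

PathLike = Union[str, Path]

#: Raw function labels emitted into the synthetic annotation table, with
#: the study-like class mix: mostly missense, a thin tail of truncating
#: classes, and a large non-qualifying remainder (synonymous etc.).
_FUNCTION_LABELS = [
    ("nonsynonymous SNV", 0.50),
    ("synonymous SNV", 0.40),
    ("stopgain", 0.03),
    ("splicing", 0.02),
    ("frameshift deletion", 0.03),
    ("frameshift insertion", 0.02),
]

_CLINVAR_LABELS = [
    (None, 0.90),
    ("Uncertain significance", 0.04),
    ("Conflicting interpretations of pathogenicity", 0.02),
    ("Benign", 0.02),
    ("Likely benign", 0.01),
    ("Pathogenic", 0.005),
    ("Likely pathogenic", 0.005),
]


@dataclass(frozen=True)
class MmafMixture:
    """Mixture for background population frequencies: a point mass at 0
    (allele absent from every panel), a log-uniform rare component and a
    uniform common component."""

    p_zero: float = 0.25
    p_rare: float = 0.55
    rare_low: float = 1e-5
    rare_high: float = 0.01
    common_low: float = 0.01
    common_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.p_zero and 0 <= self.p_rare and self.p_zero + self.p_rare <= 1):
            raise ValueError("mixture weights must be probabilities summing to <= 1")

    @property
    def p_common(self) -> float:
        return 1.0 - self.p_zero - self.p_rare

    def draw(self, rng: np.random.Generator) -> float:
        u = rng.random()
        if u < self.p_zero:
            return 0.0
        if u < self.p_zero + self.p_rare:
            return float(
                math.exp(rng.uniform(math.log(self.rare_low), math.log(self.rare_high)))
            )
        return float(rng.uniform(self.common_low, self.common_high))


@dataclass(frozen=True)
class PlantedSpec:
    """Annotation ranges a planted variant is drawn from; must satisfy the
    declared tier's thresholds or the config is rejected."""

    tier: TierSpec
    mmaf_high: float
    cadd_low: float
    cadd_high: float = 40.0

    def __post_init__(self) -> None:
        if self.mmaf_high >= self.tier.mmaf_max:
            raise ValueError(
                f"planted MMAF upper bound {self.mmaf_high} does not satisfy "
                f"tier {self.tier.name} (requires < {self.tier.mmaf_max})"
            )
        if self.cadd_low <= self.tier.cadd_min:
            raise ValueError(
                f"planted CADD lower bound {self.cadd_low} does not satisfy "
                f"tier {self.tier.name} (requires > {self.tier.cadd_min})"
            )


PLANT_NOVEL = PlantedSpec(tier=NOVEL_CANDIDATE_TIER, mmaf_high=5e-3, cadd_low=22.0)
PLANT_HIGH_RISK = PlantedSpec(tier=HIGH_RISK_TIER, mmaf_high=5e-4, cadd_low=26.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and noise parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 24 families (three WES-4s, six
    WES-3s, fourteen WES-2s, one WES-1s; 59 sequenced patients), rare
    variants under the MMAF mixture, ~2% missing genotypes, and one planted
    segregating risk variant per family (high-risk spec in WES-3/4
    families, novel-candidate spec elsewhere).
    """

    n_families: int = 24
    wes_class_distribution: Mapping[int, int] = field(
        default_factory=lambda: {4: 3, 3: 6, 2: 14, 1: 1}
    )
    n_background_variants: int = 400
    mmaf_mixture: MmafMixture = field(default_factory=MmafMixture)
    missingness: float = 0.02
    n_planted_per_family: int = 1
    plant_novel: PlantedSpec = PLANT_NOVEL
    plant_high_risk: PlantedSpec = PLANT_HIGH_RISK
    cadd_missing_rate: float = 0.02
    frameshift_cadd_missing_rate: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.wes_class_distribution.values()) != self.n_families:
            raise ValueError("wes_class_distribution must account for every family")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError(f"missingness rate {self.missingness} outside [0, 1)")
        if self.n_background_variants < 0 or self.n_planted_per_family < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one simulated variant (the acceptance surface for
    planted-call recovery)."""

    key: VariantKey
    planted: bool
    target_family: Optional[str]
    expected_tier: str  # "NovelCandidate" | "HighRisk" | "none"


@dataclass
class SimulatedCohort:
    """All four key-consistent outputs of one simulation run."""

    cohort: CohortGenotypes
    families: list[Family]
    annotations: list[AnnotationRow]
    truth: list[TruthRow]
    config: SimulationConfig

    def variant_records(self) -> dict[VariantKey, VariantRecord]:
        return {row.key: annotation_to_record(row) for row in self.annotations}

    def write(self, out_dir: PathLike) -> dict[str, Path]:
        """Emit genotypes.vcf, families.tsv, annotations.tsv, truth.tsv."""
        import csv

        from famseg.io_layer import (
            write_annotation_table,
            write_family_file,
            write_vcf,
        )

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "genotypes.vcf",
            "families": out / "families.tsv",
            "annotations": out / "annotations.tsv",
            "truth": out / "truth.tsv",
        }
        write_vcf(self.cohort, paths["vcf"])
        write_family_file(self.families, paths["families"])
        write_annotation_table(self.annotations, paths["annotations"])
        with open(paths["truth"], "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["Chr", "Pos", "Ref", "Alt", "Planted", "TargetFamily", "ExpectedTier"])
            for row in self.truth:
                writer.writerow(
                    [
                        row.key.chrom,
                        row.key.pos,
                        row.key.ref,
                        row.key.alt,
                        int(row.planted),
                        row.target_family or "",
                        row.expected_tier,
                    ]
                )
        return paths


# ---------------------------------------------------------------------------
# Pedigrees and gene drop
# ---------------------------------------------------------------------------

#: parent map: individual -> (parent_a, parent_b); founders map to None.
Pedigree = dict[str, Optional[tuple[str, str]]]

_DEGREE_TO_EXTRA_MEIOSES = {"1st": 0, "2nd": 1, "3rd": 2, "4th": 3}


def build_schematic_pedigree(family: Family) -> Pedigree:
    """Schematic pedigree placing sequenced members around one founder
    couple at the meiotic distance implied by the family's degree span.

    The first member is a child of the founders.  Each further member is a
    sibling for a 1st-degree span, or hangs ``k`` extra meioses below a
    sibling for a span of degree ``k+1`` (child of a sibling = 2nd degree,
    grandchild = 3rd, ...).  Real pedigrees are richer; this is the minimal
    structure consistent with the degree labels, and it is labelled
    schematic wherever it is used.
    """
    extra = _DEGREE_TO_EXTRA_MEIOSES.get(family.degree_span, 0)
    fid = family.family_id
    ped: Pedigree = {f"{fid}__fA": None, f"{fid}__fB": None}
    founders = (f"{fid}__fA", f"{fid}__fB")
    members = list(family.members)
    ped[members[0]] = founders
    for idx, member in enumerate(members[1:], start=1):
        if extra == 0:
            ped[member] = founders
            continue
        # a dedicated sibling branch, extended by `extra` meioses
        anchor = f"{fid}__sib{idx}"
        ped[anchor] = founders
        for step in range(extra - 1):
            spouse = f"{fid}__sp{idx}_{step}"
            child = f"{fid}__d{idx}_{step}"
            ped[spouse] = None
            ped[child] = (anchor, spouse)
            anchor = child
        spouse = f"{fid}__sp{idx}_last"
        ped[spouse] = None
        ped[member] = (anchor, spouse)
    return ped


def _drop_alleles(
    ped: Pedigree, allele_freq: float, rng: np.random.Generator
) -> dict[str, int]:
    """Draw founder allele counts from HWE and transmit one allele per
    parent (probability 1/2 per meiosis) in topological order."""
    counts: dict[str, int] = {}

    def resolve(person: str) -> int:
        if person in counts:
            return counts[person]
        parents = ped[person]
        if parents is None:
            g = int(rng.binomial(2, allele_freq))
        else:
            g = 0
            for parent in parents:
                pg = resolve(parent)
                # transmit the alt allele with probability pg / 2
                g += int(rng.random() < pg / 2.0)
        counts[person] = g
        return g

    for person in ped:
        resolve(person)
    return counts


def gene_drop_family(
    family: Family,
    allele_freq: float,
    rng: np.random.Generator,
    pedigree: Optional[Pedigree] = None,
) -> dict[str, bool]:
    """Gene-drop one biallelic site through a family's pedigree.

    Founder genotypes are drawn at ``allele_freq`` under HWE; every meiosis
    transmits each founder allele with probability 1/2.  Returns carrier
    flags (>= 1 alternate allele) for the sequenced members only.
    """
    if not (0.0 <= allele_freq <= 1.0):
        raise ValueError(f"allele frequency {allele_freq} outside [0, 1]")
    ped = pedigree if pedigree is not None else build_schematic_pedigree(family)
    counts = _drop_alleles(ped, allele_freq, rng)
    return {m: counts[m] > 0 for m in family.members}


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _make_families(config: SimulationConfig) -> list[Family]:
    """Br1..BrN with the configured WES-class mix, largest classes first
    (matches the study's naming: Br1-3 WES-4s, Br4-9 WES-3s, ...)."""
    spans = {4: "3rd", 3: "2nd", 2: "1st", 1: "1st"}
    families = []
    idx = 1
    for wes_class in sorted(config.wes_class_distribution, reverse=True):
        for _ in range(config.wes_class_distribution[wes_class]):
            fid = f"Br{idx}"
            members = tuple(f"{fid}.{k}" for k in range(1, wes_class + 1))
            families.append(Family(fid, members, degree_span=spans[wes_class]))
            idx += 1
    return families


_BASES = ("A", "C", "G", "T")


def _random_snv(rng: np.random.Generator, chrom: str, pos: int) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _draw_from(pairs, rng: np.random.Generator):
    labels = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs], dtype=float)
    probs = probs / probs.sum()
    return labels[int(rng.choice(len(labels), p=probs))]


def _panel_afs(
    mmaf: float, rng: np.random.Generator, panels: Sequence[str]
) -> dict[str, float]:
    """Panel AFs whose folded maximum equals ``mmaf`` exactly: one random
    panel carries the max, others carry smaller values or are absent."""
    if mmaf == 0.0:
        return {}
    order = list(rng.permutation(len(panels)))
    afs = {panels[order[0]]: mmaf}
    for j in order[1:]:
        if rng.random() < 0.5:
            afs[panels[j]] = float(rng.uniform(0.0, mmaf))
    return afs


def simulate_cohort(
    config: SimulationConfig, panels: Sequence[str] = ("ExAC", "200Danes", "SweGen", "1000G")
) -> SimulatedCohort:
    """Generate one synthetic cohort: genotypes, annotations, family file
    and truth table, all keyed consistently.

    Background sites are assigned genotypes independently per sample under
    HWE at the site's frequency; planted sites are heterozygous in every
    member of their target family and annotated inside their declared
    tier's thresholds.  Missingness is applied last.  Identical configs
    (including the seed) yield identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    families = _make_families(config)
    samples = [s for fam in families for s in fam.members]
    n_samples = len(samples)

    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    annotations: list[AnnotationRow] = []
    truth: list[TruthRow] = []
    used_pos: set[tuple[str, int]] = set()

    def fresh_position() -> tuple[str, int]:
        while True:
            chrom = str(int(rng.integers(1, 23)))
            pos = int(rng.integers(10_000, 50_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                return chrom, pos

    # -- background sites ---------------------------------------------------
    for i in range(config.n_background_variants):
        chrom, pos = fresh_position()
        ref, alt = _random_snv(rng, chrom, pos)
        mmaf = config.mmaf_mixture.draw(rng)
        function_raw = _draw_from(_FUNCTION_LABELS, rng)
        fclass = {
            "frameshift deletion": FunctionClass.FRAMESHIFT_DELETION,
            "frameshift insertion": FunctionClass.FRAMESHIFT_INSERTION,
        }.get(function_raw)
        if fclass is not None:  # represent indels as indels
            if fclass is FunctionClass.FRAMESHIFT_DELETION:
                ref, alt = ref + _BASES[rng.integers(4)], ref
            else:
                ref, alt = ref, ref + _BASES[rng.integers(4)]
        miss_rate = (
            config.frameshift_cadd_missing_rate
            if fclass is not None
            else config.cadd_missing_rate
        )
        cadd = None if rng.random() < miss_rate else float(np.round(rng.uniform(0.0, 40.0), 1))
        clinvar = _draw_from(_CLINVAR_LABELS, rng)
        # cohort allele frequency: the panel MMAF when seen, else a rare
        # cohort-private frequency so MMAF-0 variants still occur in samples
        af = mmaf if mmaf > 0 else float(
            math.exp(rng.uniform(math.log(1e-4), math.log(2e-3)))
        )
        genotype_probs = np.array([(1 - af) ** 2, 2 * af * (1 - af), af**2])
        row = rng.choice(
            np.array([HOM_REF, HET, HOM_ALT], dtype=np.int8),
            size=n_samples,
            p=genotype_probs / genotype_probs.sum(),
        ).astype(np.int8)
        key = VariantKey.make(chrom, pos, ref, alt)
        variants.append(key)
        rows.append(row)
        annotations.append(
            AnnotationRow(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                dbsnp_id=f"rs9{i:06d}" if rng.random() < 0.8 else None,
                gene=f"GENE{i:04d}",
                function_raw=function_raw,
                change=f"c.{int(rng.integers(1, 5000))}{ref}>{alt}",
                af_by_panel=_panel_afs(mmaf, rng, panels),
                cadd_phred=cadd,
                clinvar_raw=clinvar,
            )
        )
        truth.append(TruthRow(key, planted=False, target_family=None, expected_tier="none"))

    # -- planted segregating risk variants ----------------------------------
    sample_index = {s: j for j, s in enumerate(samples)}
    for fam in families:
        for k in range(config.n_planted_per_family):
            spec = config.plant_high_risk if fam.wes_class >= 3 else config.plant_novel
            chrom, pos = fresh_position()
            ref, alt = _random_snv(rng, chrom, pos)
            # log-uniform MMAF inside the tier bound, with a point mass at 0
            if rng.random() < 0.2:
                mmaf = 0.0
            else:
                mmaf = float(
                    math.exp(rng.uniform(math.log(1e-5), math.log(spec.mmaf_high)))
                )
            cadd = float(np.round(rng.uniform(spec.cadd_low, spec.cadd_high), 1))
            row = np.full(n_samples, HOM_REF, dtype=np.int8)
            for member in fam.members:
                row[sample_index[member]] = HET
            key = VariantKey.make(chrom, pos, ref, alt)
            variants.append(key)
            rows.append(row)
            annotations.append(
                AnnotationRow(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    dbsnp_id=None,
                    gene=f"PLT_{fam.family_id}_{k}",
                    function_raw="nonsynonymous SNV",
                    change=f"c.{int(rng.integers(1, 5000))}{ref}>{alt}",
                    af_by_panel=_panel_afs(mmaf, rng, panels),
                    cadd_phred=cadd,
                    clinvar_raw=None,
                )
            )
            truth.append(
                TruthRow(
                    key,
                    planted=True,
                    target_family=fam.family_id,
                    expected_tier=spec.tier.name,
                )
            )

    calls = np.vstack(rows) if rows else np.empty((0, n_samples), dtype=np.int8)

    # -- missingness, applied after carrier assignment ----------------------
    if config.missingness > 0 and calls.size:
        mask = rng.random(calls.shape) < config.missingness
        calls[mask] = MISSING

    cohort = CohortGenotypes(variants=variants, samples=samples, calls=calls)
    return SimulatedCohort(
        cohort=cohort,
        families=families,
        annotations=annotations,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Chance segregation
# ---------------------------------------------------------------------------

def expected_chance_segregating(
    config: SimulationConfig,
    wes_class: int,
    n_replicates: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of how many *background* variants pass the
    novel-candidate screen in one family of the given WES class by chance.

    Each replicate draws ``config.n_background_variants`` annotated sites,
    gene-drops them through a schematic pedigree of ``wes_class`` siblings,
    and counts sites where every member carries the allele and the
    annotation thresholds (MMAF < 0.01, CADD > 20 with the frameshift
    exemption) pass.  Returns (mean, sd) over replicates.  The count is
    monotone non-increasing in ``wes_class``: every extra sequenced member
    is one more chance for segregation to fail, which is the small-family
    ascertainment bias the high-risk tier guards against.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not (1 <= wes_class <= 4):
        raise ValueError("wes_class must be in 1..4")
    rng = np.random.default_rng(seed)
    fam = Family(
        "SIM", tuple(f"SIM.{k}" for k in range(1, wes_class + 1)), degree_span="1st"
    )
    ped = build_schematic_pedigree(fam)
    tier = NOVEL_CANDIDATE_TIER
    counts = np.zeros(n_replicates)
    for r in range(n_replicates):
        hits = 0
        for _ in range(config.n_background_variants):
            mmaf = config.mmaf_mixture.draw(rng)
            function_raw = _draw_from(_FUNCTION_LABELS, rng)
            fclass = {
                "frameshift deletion": FunctionClass.FRAMESHIFT_DELETION,
                "frameshift insertion": FunctionClass.FRAMESHIFT_INSERTION,
            }.get(function_raw, FunctionClass.OTHER)
            miss_rate = (
                config.frameshift_cadd_missing_rate
                if fclass in (FunctionClass.FRAMESHIFT_DELETION, FunctionClass.FRAMESHIFT_INSERTION)
                else config.cadd_missing_rate
            )
            cadd = None if rng.random() < miss_rate else float(rng.uniform(0.0, 40.0))
            if not mmaf < tier.mmaf_max:
                continue
            if cadd is None:
                if fclass not in (
                    FunctionClass.FRAMESHIFT_DELETION,
                    FunctionClass.FRAMESHIFT_INSERTION,
                ):
                    continue
            elif not cadd > tier.cadd_min:
                continue
            af = mmaf if mmaf > 0 else 1e-3
            flags = gene_drop_family(fam, af, rng, pedigree=ped)
            if all(flags.values()):
                hits += 1
        counts[r] = hits
    return float(counts.mean()), float(counts.std(ddof=1)) if n_replicates > 1 else 0.0
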