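"""YAML configuration: tier thresholds, the clinical gene panel, panels and
family exclusions.

The defaults reproduce the study's printed values; a config file overrides
any subset of them.  Example::

    panels: [ExAC, 200Danes, SweGen, 1000G]
    known_gene_panel: [ATM, BRCA1, BRCA2, ...]
    excluded_families: [Br4, Br16]
    tiers:
      KnownGene:  {bc_gf_min: 0.8, mmaf_max: 0.2,  cadd_min: 20}
      NovelCandidate: {bc_gf_min: 0.8, mmaf_max: 0.01, cadd_min: 20}
      HighRisk:   {bc_gf_min: 0.8, mmaf_max: 0.001, cadd_min: 25,
                   eligible_wes_classes: [3, 4]}
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from famseg.tiers import (
    HIGH_RISK_TIER,
    KNOWN_GENE_PANEL,
    KNOWN_GENE_TIER,
    NOVEL_CANDIDATE_TIER,
    TierSpec,
)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and panels for a full screening run."""

    known_gene_tier: TierSpec = KNOWN_GENE_TIER
    novel_tier: TierSpec = NOVEL_CANDIDATE_TIER
    high_risk_tier: TierSpec = HIGH_RISK_TIER
    known_gene_panel: frozenset[str] = KNOWN_GENE_PANEL
    panels: tuple[str, ...] = ("ExAC", "200Danes", "SweGen", "1000G")
    excluded_families: tuple[str, ...] = ()
    shared_min_families: int = 3
    shared_mmaf_max: float = 0.01
    shared_cadd_min: float = 25.0
    strong_missense_cadd_min: float = 30.0


DEFAULT_CONFIG = AnalysisConfig()


def _tier_from_mapping(base: TierSpec, data: dict) -> TierSpec:
    kwargs = {}
    for field_name in ("bc_gf_min", "mmaf_max", "cadd_min", "require_segregation"):
        if field_name in data:
            kwargs[field_name] = data[field_name]
    if "eligible_wes_classes" in data:
        value = data["eligible_wes_classes"]
        kwargs["eligible_wes_classes"] = (
            None if value is None else frozenset(int(x) for x in value)
        )
    return replace(base, **kwargs)


def load_config(path: Optional[PathLike] = None) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; missing keys keep their defaults."""
    if path is None:
        return DEFAULT_CONFIG
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = DEFAULT_CONFIG
    tiers = data.get("tiers", {})
    kwargs = {}
    if "KnownGene" in tiers:
        kwargs["known_gene_tier"] = _tier_from_mapping(cfg.known_gene_tier, tiers["KnownGene"])
    if "NovelCandidate" in tiers:
        kwargs["novel_tier"] = _tier_from_mapping(cfg.novel_tier, tiers["NovelCandidate"])
    if "HighRisk" in tiers:
        kwargs["high_risk_tier"] = _tier_from_mapping(cfg.high_risk_tier, tiers["HighRisk"])
    if "known_gene_panel" in data:
        kwargs["known_gene_panel"] = frozenset(data["known_gene_panel"])
    if "panels" in data:
        kwargs["panels"] = tuple(data["panels"])
    if "excluded_families" in data:
        kwargs["excluded_families"] = tuple(data["excluded_families"])
    for key in ("shared_min_families", "shared_mmaf_max", "shared_cadd_min",
                "strong_missense_cadd_min"):
        if key in data:
            kwargs[key] = data[key]
    return replace(cfg, **kwargs)


def save_config(config: AnalysisConfig, path: PathLike) -> None:
    data = {
        "panels": list(config.panels),
        "known_gene_panel": sorted(config.known_gene_panel),
        "excluded_families": list(config.excluded_families),
        "shared_min_families": config.shared_min_families,
        "shared_mmaf_max": config.shared_mmaf_max,
        "shared_cadd_min": config.shared_cadd_min,
        "strong_missense_cadd_min": config.strong_missense_cadd_min,
        "tiers": {
            tier.name: {
                "bc_gf_min": tier.bc_gf_min,
                "mmaf_max": tier.mmaf_max,
                "cadd_min": tier.cadd_min,
                "require_segregation": tier.require_segregation,
                "eligible_wes_classes": (
                    sorted(tier.eligible_wes_classes)
                    if tier.eligible_wes_classes
                    else None
                ),
            }
            for tier in (config.known_gene_tier, config.novel_tier, config.high_risk_tier)
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
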