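"""Lab-tunable thresholds.

All quality gates and frequency cut-offs the workflow consults live here, with
defaults matching the published consensus values: VAF validated down to 5% at
several hundred reads, a recurrence artefact fraction of 10% of samples, an
ethnic MAF of >0.1% (with ≥2000 interrogated alleles) for Likely Benign and
≥1% for Benign, and "close to 50% / 100%" germline VAF bands quantified as
[0.40, 0.60] and [0.90, 1.00]. VAFs and MAFs are fractions in [0, 1]
internally; rendering as percent happens only at the report surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml


@dataclass(frozen=True)
class SiteOverride:
    """Validated per-site relaxation of the VAF/depth gates.

    e.g. BRAF V600E in hairy-cell leukaemia is reliably called below the
    panel-wide 5% VAF floor after dedicated validation.
    """

    gene: str
    change: str  # one-letter shorthand or cDNA HGVS
    vaf_min: Optional[float] = None
    depth_min: Optional[int] = None


@dataclass
class LabConfig:
    vaf_min: float = 0.05
    depth_min: int = 500
    site_overrides: list[SiteOverride] = field(default_factory=list)
    recurrence_fraction: float = 0.10
    recurrence_blacklist: frozenset[str] = frozenset()
    str_stutter_thresholds: dict[str, float] = field(default_factory=dict)
    maf_likely_benign: float = 0.001
    maf_benign: float = 0.01
    min_allele_number: int = 2000
    germline_het_band: tuple[float, float] = (0.40, 0.60)
    germline_hom_band: tuple[float, float] = (0.90, 1.00)
    regional_benign_min_samples: int = 3
    cebpa_bzip_span: tuple[int, int] = (278, 358)

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_min < 1.0:
            raise ValueError("vaf_min must lie in (0,1)")
        if not 0.0 < self.maf_likely_benign < self.maf_benign <= 1.0:
            raise ValueError("need 0 < maf_likely_benign < maf_benign <= 1")
        if self.depth_min < 0:
            raise ValueError("depth_min must be non-negative")

    def gates_for(self, gene: str, changes: list[str]) -> tuple[float, int]:
        """Effective (vaf_min, depth_min) after site overrides."""
        vaf, depth = self.vaf_min, self.depth_min
        for ov in self.site_overrides:
            if ov.gene == gene and ov.change in changes:
                if ov.vaf_min is not None:
                    vaf = ov.vaf_min
                if ov.depth_min is not None:
                    depth = ov.depth_min
        return vaf, depth

    def in_germline_band(self, vaf: float) -> bool:
        lo1, hi1 = self.germline_het_band
        lo2, hi2 = self.germline_hom_band
        return lo1 <= vaf <= hi1 or lo2 <= vaf <= hi2

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "LabConfig":
        """Load from a flat YAML mapping mirroring the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in (
            "vaf_min", "depth_min", "recurrence_fraction", "maf_likely_benign",
            "maf_benign", "min_allele_number", "regional_benign_min_samples",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "recurrence_blacklist" in raw:
            kwargs["recurrence_blacklist"] = frozenset(raw["recurrence_blacklist"])
        if "str_stutter_thresholds" in raw:
            kwargs["str_stutter_thresholds"] = dict(raw["str_stutter_thresholds"])
        if "site_overrides" in raw:
            kwargs["site_overrides"] = [SiteOverride(**o) for o in raw["site_overrides"]]
        for key in ("germline_het_band", "germline_hom_band", "cebpa_bzip_span"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "vaf_min": self.vaf_min,
            "depth_min": self.depth_min,
            "site_overrides": [vars(o) for o in self.site_overrides],
            "recurrence_fraction": self.recurrence_fraction,
            "recurrence_blacklist": sorted(self.recurrence_blacklist),
            "str_stutter_thresholds": dict(sorted(self.str_stutter_thresholds.items())),
            "maf_likely_benign": self.maf_likely_benign,
            "maf_benign": self.maf_benign,
            "min_allele_number": self.min_allele_number,
            "germline_het_band": list(self.germline_het_band),
            "germline_hom_band": list(self.germline_hom_band),
            "regional_benign_min_samples": self.regional_benign_min_samples,
            "cebpa_bzip_span": list(self.cebpa_bzip_span),
        }
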