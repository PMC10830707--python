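"""Domain types for stable-isotope diet studies of shoreline consumers.

The central objects are individual tissue samples (:class:`IsotopeRecord`,
:class:`LizardRecord`), diet-source endmember summaries
(:class:`SourceDistribution`) and tissue-diet trophic discrimination factors
(:class:`DiscriminationFactor`).  Isotope values are delta notation in per mil
(d13C relative to VPDB, d15N relative to air N2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "HABITATS",
    "TISSUES",
    "QC_FLAGS",
    "IsotopeRecord",
    "LizardRecord",
    "SourceDistribution",
    "DiscriminationFactor",
    "CLAW",
    "SKIN",
    "ALPHA_TERRESTRIAL",
]

HABITATS = frozenset({"beach", "coastal_forest", "inland_forest"})
TISSUES = frozenset({"lizard_tail", "arthropod", "plant", "algae"})
QC_FLAGS = frozenset({"pass", "flagged_retained", "fail"})
ENVIRONMENTS = frozenset({"marine", "terrestrial"})
SEXES = frozenset({"F", "M"})

# physically plausible delta ranges for C3/marine food webs (per mil)
_D13C_RANGE = (-45.0, 5.0)
_D15N_RANGE = (-10.0, 30.0)


@dataclass
class IsotopeRecord:
    """One tissue sample's carbon/nitrogen isotope measurement with metadata.

    ``cn_ratio`` is the elemental C:N weight-percent ratio used as a tissue
    quality-control proxy; it is optional for plant and algae composites.
    ``environment`` marks diet-source samples as marine or terrestrial.
    """

    sample_id: str
    site: str
    habitat: str
    tissue: str
    d13C: float
    d15N: float
    cn_ratio: Optional[float] = None
    qc_flag: str = "pass"
    environment: Optional[str] = None
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.qc_flag not in QC_FLAGS:
            raise ValueError(f"unknown qc_flag {self.qc_flag!r}")
        if self.environment is not None and self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        lo, hi = _D13C_RANGE
        if not lo < self.d13C < hi:
            raise ValueError(f"d13C {self.d13C} outside ({lo}, {hi}) per mil")
        lo, hi = _D15N_RANGE
        if not lo < self.d15N < hi:
            raise ValueError(f"d15N {self.d15N} outside ({lo}, {hi}) per mil")
        if self.cn_ratio is not None and not self.cn_ratio > 0:
            raise ValueError("cn_ratio must be positive when present")

    def with_qc(self, flag: str) -> "IsotopeRecord":
        return replace(self, qc_flag=flag)


@dataclass
class LizardRecord(IsotopeRecord):
    """A lizard tail-tip sample plus body measurements.

    ``body_condition`` is the residual of the pooled regression of body mass
    on SVL cubed (a fat-storage index); it is unset until computed.
    """

    sex: Optional[str] = None
    svl: Optional[float] = None   # snout-vent length, mm
    mass: Optional[float] = None  # g
    body_condition: Optional[float] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.svl is not None and not self.svl > 0:
            raise ValueError("svl must be > 0 mm")
        if self.mass is not None and not self.mass > 0:
            raise ValueError("mass must be > 0 g")


@dataclass(frozen=True)
class SourceDistribution:
    """Endmember summary for one diet source: mean/SD per isotope, sample size."""

    name: str  # "marine" or "terrestrial"
    mu_C: float
    mu_N: float
    sd_C: float = 0.0
    sd_N: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.name not in ENVIRONMENTS:
            raise ValueError(f"source name must be marine/terrestrial, got {self.name!r}")
        if self.sd_C < 0 or self.sd_N < 0:
            raise ValueError("source SDs must be >= 0")
        if self.n < 1:
            raise ValueError("source n must be >= 1")


def check_mixing_geometry(marine: SourceDistribution, terrestrial: SourceDistribution) -> None:
    """Valid two-source carbon geometry requires the marine endmember above the
    terrestrial one (marine food webs are 13C-enriched relative to C3 plants)."""
    if not marine.mu_C > terrestrial.mu_C:
        raise ValueError(
            f"marine mu_C ({marine.mu_C}) must exceed terrestrial mu_C ({terrestrial.mu_C})"
        )


@dataclass(frozen=True)
class DiscriminationFactor:
    """Tissue-diet trophic discrimination (Delta) for carbon and nitrogen.

    ``dN_mean``/``dN_sd`` may be omitted for the single-isotope terrestrial
    correction used by the algebraic marine-fraction estimator.
    """

    tissue_model: str
    dC_mean: float
    dC_sd: float = 0.0
    dN_mean: Optional[float] = None
    dN_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tissue_model not in {"claw", "skin", "alpha_terrestrial"}:
            raise ValueError(f"unknown tissue_model {self.tissue_model!r}")
        if self.dC_sd < 0 or (self.dN_sd is not None and self.dN_sd < 0):
            raise ValueError("discrimination SDs must be >= 0")


# published discrimination values for small insectivorous lizards:
# claw keratin Delta13C/Delta15N, skin Delta13C (skin Delta15N never reached
# equilibrium in the source feeding trial, so the claw value is reused).
CLAW = DiscriminationFactor("claw", dC_mean=1.2, dC_sd=0.4, dN_mean=0.7, dN_sd=0.3)
SKIN = DiscriminationFactor("skin", dC_mean=-0.8, dC_sd=0.5, dN_mean=0.7, dN_sd=0.3)
# bulk plant-to-consumer carbon offset used by the algebraic estimator
ALPHA_TERRESTRIAL = DiscriminationFactor("alpha_terrestrial", dC_mean=3.8)
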