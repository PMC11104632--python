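"""Hemifield agreement scoring between perimetry and the noise-field test.

The patient draws the shadows they perceive while viewing the noise;
each drawn region is described by the quadrants it covers, its centroid
eccentricity, whether it lies temporally, whether it straddles the
horizontal meridian, and whether it is isolated from every other
region.  Scoring proceeds in two steps:

1. regions matching the physiological blind spot (isolated, temporal,
   straddling the horizontal meridian, centroid near 15 degrees) are
   excluded — a healthy observer may perceive the blind spot, and it
   must not count as a defect;
2. the remaining regions are collapsed to superior/inferior hemifield
   flags and compared with the perimetric hemifield flags:
   *Agreement* — both tests abnormal in exactly the same hemifields;
   *PartialAgreement* — abnormal areas coincide in one hemifield but
   not the other; *NoAgreement* — the abnormal hemifields differ
   entirely; *NoResponse* — nothing reproducible was drawn.

Agreement and PartialAgreement together constitute subjective
*detection* of the field abnormality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, FrozenSet

from .errors import InputError, NotApplicableError
from .visual_field import Laterality


class Quadrant(str, Enum):
    SUP_NASAL = "sup_nasal"
    SUP_TEMPORAL = "sup_temporal"
    INF_NASAL = "inf_nasal"
    INF_TEMPORAL = "inf_temporal"

    @property
    def superior(self) -> bool:
        return self in (Quadrant.SUP_NASAL, Quadrant.SUP_TEMPORAL)


class AgreementCategory(str, Enum):
    AGREEMENT = "agreement"
    PARTIAL_AGREEMENT = "partial_agreement"
    NO_AGREEMENT = "no_agreement"
    NO_RESPONSE = "no_response"

    @property
    def detected(self) -> bool:
        """Subjective detection = agreement or partial agreement."""
        return self in (AgreementCategory.AGREEMENT,
                        AgreementCategory.PARTIAL_AGREEMENT)


@dataclass(frozen=True)
class AgreementOutcome:
    category: AgreementCategory

    @property
    def detected(self) -> bool:
        return self.category.detected


@dataclass(frozen=True)
class ShadowRegion:
    """One contiguous drawn shadow."""

    quadrants: FrozenSet[Quadrant]
    centroid_ecc_deg: float
    temporal: bool = False
    isolated: bool = False
    straddles_horizontal: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "quadrants", frozenset(self.quadrants))
        if not self.quadrants:
            raise InputError("a shadow region must cover >= 1 quadrant")
        if self.centroid_ecc_deg < 0:
            raise InputError("centroid eccentricity must be >= 0")


@dataclass(frozen=True)
class ShadowRecord:
    """All shadows one eye reported for one noise type."""

    responded: bool
    reproducible: bool
    regions: tuple = ()
    laterality: Laterality = Laterality.OD

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if not self.responded and self.regions:
            raise InputError("a non-responding record cannot carry regions")


#: Default tolerance around the 15-degree blind-spot eccentricity.
BLIND_SPOT_ECC_DEG = 15.0
BLIND_SPOT_TOL_DEG = 5.0


def exclude_blind_spot_regions(record: ShadowRecord,
                               center_deg: float = BLIND_SPOT_ECC_DEG,
                               tol_deg: float = BLIND_SPOT_TOL_DEG) -> ShadowRecord:
    """Drop regions that look like the physiological blind spot.

    A region is excluded only when it is simultaneously isolated,
    temporal, straddling the horizontal meridian, and centred within
    ``tol_deg`` of ``center_deg`` eccentricity.  Idempotent.
    """
    kept = tuple(
        r for r in record.regions
        if not (r.isolated and r.temporal and r.straddles_horizontal
                and abs(r.centroid_ecc_deg - center_deg) <= tol_deg)
    )
    return replace(record, regions=kept)


def shadow_hemifield_flags(record: ShadowRecord) -> Dict[str, bool]:
    """Union of region quadrants per hemifield."""
    sup = any(q.superior for r in record.regions for q in r.quadrants)
    inf = any(not q.superior for r in record.regions for q in r.quadrants)
    return {"superior": sup, "inferior": inf}


def categorize_agreement(vf_flags: Dict[str, bool],
                         shadow: ShadowRecord) -> AgreementOutcome:
    """Four-way agreement category for one eye and one noise type.

    ``vf_flags`` are the perimetric hemifield abnormality flags; the
    shadow record must already have blind-spot regions excluded.
    Raises :class:`NotApplicableError` when the field is normal in both
    hemifields (normal/preperimetric eyes are tallied separately, as
    false positives or correct negatives).
    """
    vs, vi = bool(vf_flags["superior"]), bool(vf_flags["inferior"])
    if not (vs or vi):
        raise NotApplicableError(
            "agreement categories are defined only for abnormal fields")
    if not shadow.responded or not shadow.reproducible or not shadow.regions:
        return AgreementOutcome(AgreementCategory.NO_RESPONSE)
    flags = shadow_hemifield_flags(shadow)
    ss, si = flags["superior"], flags["inferior"]
    coincide = (vs and ss) + (vi and si)  # hemifields abnormal in both tests
    if coincide == 0:
        return AgreementOutcome(AgreementCategory.NO_AGREEMENT)
    if (vs, vi) == (ss, si):
        return AgreementOutcome(AgreementCategory.AGREEMENT)
    return AgreementOutcome(AgreementCategory.PARTIAL_AGREEMENT)
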