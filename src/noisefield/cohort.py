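"""Cohort fixtures and synthetic cohort/record generation.

Three sources of per-eye records are provided so every downstream
analysis is testable without patient data:

* :func:`expand_from_counts` deterministically unrolls a count fixture
  (per-stage agreement outcome tallies for both noise conditions, the
  both-detected total, and the preference tally) into ordered per-eye
  records.  The packaged fixture carries the study's published counts;
  its paired structure is the unique one consistent with the marginals
  — every analog-detected eye was also CG-detected (no analog-only
  detections), which the loader verifies rather than assumes.
* :func:`simulate_cohort` draws seeded multinomial cohorts from
  per-stage paired-outcome probabilities (a Monte-Carlo stand-in for a
  study population).
* :func:`synth_vf_and_shadow` generates a matching (visual field,
  shadow drawing) pair that scores exactly a requested agreement
  category, for end-to-end tests of the classification chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .agreement import (AgreementCategory, Quadrant, ShadowRecord,
                        ShadowRegion, categorize_agreement,
                        exclude_blind_spot_regions)
from .errors import FixtureError, GenerationError, InputError
from .visual_field import (LAYOUT, GHTResult, Laterality, PDCategory, Stage,
                           VFResult, find_qualifying_clusters)

OUTCOMES = ("agreement", "partial_agreement", "no_agreement", "no_response")
DETECTED = ("agreement", "partial_agreement")
STAGES = ("M1", "M2", "M3", "M4")
PREFERENCES = ("cg", "same", "analog")


@dataclass(frozen=True)
class EyeRecord:
    """One eye's paired noise-field outcome."""

    eye_id: str
    group: str                 # normal | ppg | glaucoma
    stage: Optional[str]       # M1..M4, glaucoma only
    cg_outcome: str            # AgreementCategory value
    analog_outcome: str
    preference: Optional[str] = None  # cg | same | analog, both-detected only

    def __post_init__(self) -> None:
        if self.group not in ("normal", "ppg", "glaucoma"):
            raise InputError(f"unknown group: {self.group!r}")
        if (self.stage is not None) != (self.group == "glaucoma"):
            raise InputError("stage must be present iff group is glaucoma")
        if self.stage is not None and self.stage not in STAGES:
            raise InputError(f"unknown stage: {self.stage!r}")
        for name in ("cg_outcome", "analog_outcome"):
            if getattr(self, name) not in OUTCOMES:
                raise InputError(f"unknown {name}: {getattr(self, name)!r}")
        both = self.cg_outcome in DETECTED and self.analog_outcome in DETECTED
        if (self.preference is not None) != both:
            raise InputError(
                "preference must be present iff both outcomes are detections")
        if self.preference is not None and self.preference not in PREFERENCES:
            raise InputError(f"unknown preference: {self.preference!r}")


@dataclass
class CountFixture:
    """Validated per-group / per-stage outcome counts."""

    groups: Dict[str, dict]    # normal/ppg: n + outcome counts per noise
    glaucoma: Dict[str, dict]  # per stage: counts + both_detected + preference

    def validate(self) -> None:
        for name, g in self.groups.items():
            for noise in ("cg", "analog"):
                total = sum(g[noise][o] for o in OUTCOMES)
                if total != g["n"]:
                    raise FixtureError(
                        f"{name}/{noise}: outcome counts sum to {total}, "
                        f"expected n = {g['n']}")
        for stage, g in self.glaucoma.items():
            for noise in ("cg", "analog"):
                total = sum(g[noise][o] for o in OUTCOMES)
                if total != g["n"]:
                    raise FixtureError(
                        f"glaucoma {stage}/{noise}: outcome counts sum to "
                        f"{total}, expected n = {g['n']}")
            cg_det = sum(g["cg"][o] for o in DETECTED)
            an_det = sum(g["analog"][o] for o in DETECTED)
            both = g["both_detected"]
            if both > min(cg_det, an_det):
                raise FixtureError(
                    f"glaucoma {stage}: both_detected {both} exceeds a "
                    f"marginal ({cg_det} CG, {an_det} analog)")
            if both != an_det:
                raise FixtureError(
                    f"glaucoma {stage}: paired structure requires every "
                    f"analog-detected eye to be CG-detected "
                    f"(both_detected {both} != analog-detected {an_det})")
            pref = g.get("preference")
            if pref is not None and sum(pref.values()) != both:
                raise FixtureError(
                    f"glaucoma {stage}: preference counts sum to "
                    f"{sum(pref.values())}, expected both_detected = {both}")

    @property
    def total_eyes(self) -> int:
        return (sum(g["n"] for g in self.groups.values())
                + sum(g["n"] for g in self.glaucoma.values()))


def load_study_fixture() -> CountFixture:
    """The packaged count fixture (validated on load)."""
    text = resources.files("noisefield.data").joinpath(
        "study_counts.json").read_text()
    raw = json.loads(text)
    fixture = CountFixture(groups=raw["groups"], glaucoma=raw["glaucoma"])
    fixture.validate()
    return fixture


def _paired_outcomes(g: dict) -> List[Tuple[str, str]]:
    """Canonical pairing of CG and analog outcomes for one stratum.

    CG outcomes are laid out in fixed order (agreement, partial,
    no-agreement, no-response); analog detections are assigned to the
    leading CG-detected slots (agreement first), the remaining slots
    receive the analog non-detections in fixed order.  Any assignment
    consistent with the marginals yields identical statistics; this one
    is deterministic and reproducible.
    """
    cg_list = [o for o in OUTCOMES for _ in range(g["cg"][o])]
    cg_det = sum(g["cg"][o] for o in DETECTED)
    both = g.get("both_detected", 0)
    an_det_list = [o for o in DETECTED for _ in range(g["analog"][o])]
    an_rest = (["no_agreement"] * g["analog"]["no_agreement"]
               + ["no_response"] * (g["analog"]["no_response"]
                                    - (cg_det - both)))
    an_list = (an_det_list
               + ["no_response"] * (cg_det - both)
               + an_rest)
    if len(an_list) != len(cg_list):
        raise FixtureError("marginals do not pair up")
    return list(zip(cg_list, an_list))


def expand_from_counts(fixture: CountFixture) -> List[EyeRecord]:
    """Deterministically expand a count fixture into per-eye records.

    Ordering is stable: normal, ppg, then glaucoma stages M1..M4; within
    a stratum eyes are ordered by (CG outcome, analog outcome) as laid
    out by the canonical pairing, and preferences are assigned to the
    both-detected eyes in fixed order (cg, same, analog).
    """
    fixture.validate()
    records: List[EyeRecord] = []
    for group in ("normal", "ppg"):
        if group not in fixture.groups:
            continue
        g = fixture.groups[group]
        for i, (cg, an) in enumerate(_paired_outcomes({**g, "both_detected": 0})):
            records.append(EyeRecord(
                eye_id=f"{group}-{i:04d}", group=group, stage=None,
                cg_outcome=cg, analog_outcome=an))
    for stage in STAGES:
        if stage not in fixture.glaucoma:
            continue
        g = fixture.glaucoma[stage]
        pref = g.get("preference", {"cg": 0, "same": 0, "analog": 0})
        pref_list = [p for p in PREFERENCES for _ in range(pref[p])]
        pref_iter = iter(pref_list)
        for i, (cg, an) in enumerate(_paired_outcomes(g)):
            both = cg in DETECTED and an in DETECTED
            records.append(EyeRecord(
                eye_id=f"glaucoma-{stage}-{i:04d}", group="glaucoma",
                stage=stage, cg_outcome=cg, analog_outcome=an,
                preference=next(pref_iter) if both else None))
    return records


# ---------------------------------------------------------------------------
# Stochastic cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    stage_probs: Dict[str, Dict[Tuple[str, str], float]],
    n_per_stage: Dict[str, int],
    seed: int,
    preference_probs: Optional[Dict[str, Sequence[float]]] = None,
) -> List[EyeRecord]:
    """Seeded multinomial cohort draws.

    ``stage_probs[stage]`` maps paired outcomes ``(cg, analog)`` to
    probabilities summing to 1 (tolerance 1e-9).  Eyes detected by both
    noises get a preference drawn from ``preference_probs[stage]``
    (cg/same/analog shares; uniform by default).  The same seed always
    reproduces the same cohort.
    """
    rng = np.random.default_rng(seed)
    records: List[EyeRecord] = []
    for stage in sorted(n_per_stage):
        probs = stage_probs[stage]
        pairs = sorted(probs)
        pvec = np.array([probs[p] for p in pairs], dtype=float)
        if abs(pvec.sum() - 1.0) > 1e-9:
            raise InputError(
                f"stage {stage}: outcome probabilities sum to {pvec.sum()}")
        for cg, an in pairs:
            if cg not in OUTCOMES or an not in OUTCOMES:
                raise InputError(f"unknown outcome pair: {(cg, an)!r}")
            if an in DETECTED and cg not in DETECTED:
                pass  # analog-only detections are legal in simulation
        counts = rng.multinomial(n_per_stage[stage], pvec)
        pshare = np.asarray((preference_probs or {}).get(stage, (1 / 3,) * 3),
                            dtype=float)
        pshare = pshare / pshare.sum()
        i = 0
        for (cg, an), k in zip(pairs, counts):
            both = cg in DETECTED and an in DETECTED
            for _ in range(k):
                pref = (PREFERENCES[rng.choice(3, p=pshare)] if both else None)
                records.append(EyeRecord(
                    eye_id=f"glaucoma-{stage}-{i:04d}", group="glaucoma",
                    stage=stage, cg_outcome=cg, analog_outcome=an,
                    preference=pref))
                i += 1
    return records


# ---------------------------------------------------------------------------
# Synthetic visual fields and shadow drawings
# ---------------------------------------------------------------------------

#: Qualifying-cluster size per stage (defect extent grows with severity;
#: depth-of-defect realism is out of scope).
_CLUSTER_SIZE = {"M1": 3, "M2": 6, "M3": 10}
#: MD sampling interval per stage (dB).
_MD_RANGE = {"M1": (-5.5, -0.5), "M2": (-12.0, -6.0),
             "M3": (-19.5, -12.5), "M4": (-30.0, -20.0)}

_INTERIOR = [i for i, p in enumerate(LAYOUT)
             if not p.edge and not p.blind_spot]


def _grow_cluster(rng: np.random.Generator, superior: bool, size: int) -> List[int]:
    """Random connected set of `size` non-edge points in one hemifield."""
    candidates = [i for i in _INTERIOR
                  if (LAYOUT[i].y_deg > 0) == superior]
    coords = {(LAYOUT[i].x_deg, LAYOUT[i].y_deg): i for i in candidates}
    for _ in range(50):
        start = candidates[rng.integers(len(candidates))]
        comp = [start]
        frontier = {start}
        while len(comp) < size:
            grow = []
            for i in frontier:
                x, y = LAYOUT[i].x_deg, LAYOUT[i].y_deg
                for dx in (-6, 0, 6):
                    for dy in (-6, 0, 6):
                        j = coords.get((x + dx, y + dy))
                        if j is not None and j not in comp:
                            grow.append(j)
            if not grow:
                break
            pick = grow[rng.integers(len(grow))]
            comp.append(pick)
            frontier.add(pick)
        if len(comp) == size:
            return comp
    raise GenerationError(f"could not grow a {size}-point hemifield cluster")


def _synth_vf(rng: np.random.Generator, stage: str, laterality: Laterality,
              hemifields: Tuple[bool, bool]) -> VFResult:
    sup, inf = hemifields
    md = float(rng.uniform(*_MD_RANGE[stage]))
    if stage == "M4":
        return VFResult.from_categories(
            laterality, {}, md_db=md, psd_p_lt_5pct=True,
            ght=GHTResult.OUTSIDE_NORMAL_LIMITS, pd_map_shown=False)
    size = _CLUSTER_SIZE[stage]
    categories: Dict[Tuple[int, int], PDCategory] = {}
    for superior, flagged in ((True, sup), (False, inf)):
        if not flagged:
            continue
        members = _grow_cluster(rng, superior, size)
        for k, i in enumerate(members):
            cat = PDCategory.LT1 if k == 0 else PDCategory.LT5
            categories[(LAYOUT[i].x_deg, LAYOUT[i].y_deg)] = cat
    return VFResult.from_categories(
        laterality, categories, md_db=md,
        psd_p_lt_5pct=bool(rng.random() < 0.5),
        ght=GHTResult.OUTSIDE_NORMAL_LIMITS, pd_map_shown=True)


def _shadow_region(rng: np.random.Generator, superior: bool) -> ShadowRegion:
    quad = (Quadrant.SUP_NASAL, Quadrant.SUP_TEMPORAL) if superior \
        else (Quadrant.INF_NASAL, Quadrant.INF_TEMPORAL)
    q = quad[rng.integers(2)]
    return ShadowRegion(
        quadrants=frozenset({q}),
        centroid_ecc_deg=float(rng.uniform(4.0, 25.0)),
        temporal=q in (Quadrant.SUP_TEMPORAL, Quadrant.INF_TEMPORAL),
        isolated=False, straddles_horizontal=False)


def _blind_spot_region() -> ShadowRegion:
    return ShadowRegion(
        quadrants=frozenset({Quadrant.SUP_TEMPORAL, Quadrant.INF_TEMPORAL}),
        centroid_ecc_deg=15.0, temporal=True, isolated=True,
        straddles_horizontal=True)


def synth_vf_and_shadow(
    stage: str,
    target_category: AgreementCategory,
    laterality: Laterality = Laterality.OD,
    seed: int = 0,
    include_blind_spot: bool = False,
) -> Tuple[VFResult, ShadowRecord]:
    """Generate a (visual field, shadow record) pair scoring exactly
    ``target_category``.

    The visual field always satisfies the abnormality criteria for its
    stage.  For stage M4 the pattern-deviation map is withheld and the
    field is treated as abnormal in both hemifields (see
    ``m4_hemifield_flags``); a NoAgreement target is then impossible —
    any drawn shadow coincides with at least one abnormal hemifield —
    and raises :class:`GenerationError`.
    """
    if stage not in STAGES:
        raise GenerationError(f"unknown stage: {stage!r}")
    target = AgreementCategory(target_category)
    rng = np.random.default_rng(seed)

    if stage == "M4":
        if target is AgreementCategory.NO_AGREEMENT:
            raise GenerationError(
                "stage M4 fields are abnormal in both hemifields; "
                "no drawn shadow can disagree entirely")
        vf_flags = (True, True)
    else:
        choices = {
            AgreementCategory.AGREEMENT: [(True, False), (False, True), (True, True)],
            AgreementCategory.PARTIAL_AGREEMENT: [(True, True)],
            AgreementCategory.NO_AGREEMENT: [(True, False), (False, True)],
            AgreementCategory.NO_RESPONSE: [(True, False), (False, True), (True, True)],
        }[target]
        vf_flags = choices[rng.integers(len(choices))]

    vf = _synth_vf(rng, stage, laterality, vf_flags)

    if target is AgreementCategory.NO_RESPONSE:
        shadow = ShadowRecord(responded=False, reproducible=False,
                              regions=(), laterality=laterality)
        return vf, shadow

    vs, vi = vf_flags
    if target is AgreementCategory.AGREEMENT:
        shadow_flags = (vs, vi)
    elif target is AgreementCategory.PARTIAL_AGREEMENT:
        # drop one abnormal hemifield from the drawing
        shadow_flags = (True, False) if rng.random() < 0.5 else (False, True)
    else:  # NO_AGREEMENT: draw only in the normal hemifield
        shadow_flags = (not vs, not vi)

    regions = [
        _shadow_region(rng, superior)
        for superior, flagged in ((True, shadow_flags[0]),
                                  (False, shadow_flags[1]))
        if flagged
    ]
    if include_blind_spot:
        regions.append(_blind_spot_region())
    shadow = ShadowRecord(responded=True, reproducible=True,
                          regions=tuple(regions), laterality=laterality)

    # closure check: the generated pair must score as requested
    flags = {"superior": vf_flags[0], "inferior": vf_flags[1]}
    scored = categorize_agreement(flags, exclude_blind_spot_regions(shadow))
    if scored.category is not target:
        raise GenerationError(
            f"internal error: generated pair scored {scored.category}, "
            f"target {target}")
    return vf, shadow


def m4_hemifield_flags() -> Dict[str, bool]:
    """Hemifield convention for severely depressed fields whose PD map
    is withheld: both hemifields are treated as abnormal."""
    return {"superior": True, "inferior": True}
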