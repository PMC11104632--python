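"""Humphrey 30-2 visual-field modelling and abnormality classification.

A 30-2 result is 76 test points on a 6-degree lattice offset 3 degrees
from the meridians.  Internally every point is stored in a
*temporal-positive* frame (+x temporal, +y superior) regardless of
laterality, so that the blind spot always sits at (+15, +/-3) and the
nasal extreme column at x = -27; chart coordinates in files are
converted on load/save.

Classification follows the standard three-pronged definition of a
glaucomatous field (Anderson & Patella):

1. a cluster of >= 3 contiguous non-edge points depressed at p < 5% on
   the pattern-deviation plot, at least one at p < 1%, evaluated within
   each hemifield — up to two nasal-edge points may count toward the
   cluster size;
2. pattern standard deviation significant at p < 5%;
3. glaucoma hemifield test outside normal limits.

Severity staging uses mean deviation: M1 (early) MD > -6 dB, M2
(moderate) -12 <= MD <= -6, M3 (advanced) MD < -12, and M4 (severe)
for fields so depressed that the analyzer withholds the pattern
deviation map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import InputError

GRID_STEP_DEG = 6


class PDCategory(IntEnum):
    """Pattern-deviation probability category of one point.

    Ordered by strictness: ``GE5`` (not depressed) < ``LT5`` < ``LT2``
    < ``LT1`` < ``LT0_5``.  "Significant" means stricter than ``GE5``.
    """

    GE5 = 0
    LT5 = 1
    LT2 = 2
    LT1 = 3
    LT0_5 = 4

    @property
    def significant(self) -> bool:
        return self is not PDCategory.GE5


_PD_NAMES = {
    PDCategory.GE5: "ge5pct",
    PDCategory.LT5: "lt5pct",
    PDCategory.LT2: "lt2pct",
    PDCategory.LT1: "lt1pct",
    PDCategory.LT0_5: "lt0_5pct",
}
_PD_FROM_NAME = {v: k for k, v in _PD_NAMES.items()}


class Laterality(str, Enum):
    OD = "OD"  # right eye
    OS = "OS"  # left eye


class GHTResult(str, Enum):
    WITHIN_NORMAL_LIMITS = "within_normal_limits"
    OUTSIDE_NORMAL_LIMITS = "outside_normal_limits"
    BORDERLINE = "borderline"
    OTHER = "other"


class Stage(str, Enum):
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"


@dataclass(frozen=True)
class LayoutPoint:
    x_deg: int  # temporal-positive
    y_deg: int
    edge: bool
    nasal_edge: bool
    blind_spot: bool


def load_layout() -> Tuple[LayoutPoint, ...]:
    """The packaged canonical 30-2 layout (76 points, temporal-positive)."""
    text = resources.files("noisefield.data").joinpath(
        "hfa30_2_layout.json").read_text()
    raw = json.loads(text)
    return tuple(LayoutPoint(p["x_deg"], p["y_deg"], p["edge"],
                             p["nasal_edge"], p["blind_spot"])
                 for p in raw["points"])


LAYOUT: Tuple[LayoutPoint, ...] = load_layout()
_LAYOUT_INDEX: Dict[Tuple[int, int], int] = {
    (p.x_deg, p.y_deg): i for i, p in enumerate(LAYOUT)
}


@dataclass(frozen=True)
class VFPoint:
    """One 30-2 test point (temporal-positive coordinates)."""

    x_deg: int
    y_deg: int
    pd_category: PDCategory
    is_edge: bool
    is_nasal_edge: bool
    is_blind_spot: bool


@dataclass
class VFResult:
    """One eye's 30-2 outcome: per-point PD categories plus the global
    indices consumed from the instrument printout (MD, PSD significance,
    GHT label, reliability rates)."""

    laterality: Laterality
    points: List[VFPoint]
    md_db: float
    psd_p_lt_5pct: bool = False
    ght: GHTResult = GHTResult.WITHIN_NORMAL_LIMITS
    fp_rate: Optional[float] = None
    fn_rate: Optional[float] = None
    pd_map_shown: bool = True

    def __post_init__(self) -> None:
        if len(self.points) != len(LAYOUT):
            raise InputError(
                f"a 30-2 result has {len(LAYOUT)} points, got {len(self.points)}"
            )
        got = {(p.x_deg, p.y_deg) for p in self.points}
        want = set(_LAYOUT_INDEX)
        if got != want:
            raise InputError("points do not match the canonical 30-2 layout")

    @classmethod
    def from_categories(cls, laterality: Laterality,
                        categories: Dict[Tuple[int, int], PDCategory],
                        md_db: float, **kwargs) -> "VFResult":
        """Build a result from a sparse {(x, y): category} mapping in
        temporal-positive coordinates; unlisted points are normal."""
        unknown = set(categories) - set(_LAYOUT_INDEX)
        if unknown:
            raise InputError(f"coordinates outside the 30-2 layout: {sorted(unknown)}")
        pts = [VFPoint(lp.x_deg, lp.y_deg,
                       categories.get((lp.x_deg, lp.y_deg), PDCategory.GE5),
                       lp.edge, lp.nasal_edge, lp.blind_spot)
               for lp in LAYOUT]
        return cls(laterality=laterality, points=pts, md_db=md_db, **kwargs)


@dataclass
class Cluster:
    """A connected component of significantly depressed points within
    one hemifield, with its counted size after the nasal-edge cap."""

    member_indices: Tuple[int, ...]
    hemifield: str  # "superior" or "inferior"
    n_counted: int
    has_lt1pct: bool

    @property
    def qualifies(self) -> bool:
        return self.n_counted >= 3 and self.has_lt1pct


def reliability_ok(fp_rate: Optional[float], fn_rate: Optional[float]) -> bool:
    """Reliability filter: exclude results with false positives >= 15%
    or false negatives >= 33%.  Absent rates are treated as acceptable."""
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if rate is not None and not 0.0 <= rate <= 1.0:
            raise InputError(f"{name} outside [0, 1]: {rate}")
    if fp_rate is not None and fp_rate >= 0.15:
        return False
    if fn_rate is not None and fn_rate >= 0.33:
        return False
    return True


def _adjacent(a: VFPoint, b: VFPoint) -> bool:
    # 8-neighbourhood on the 6-degree lattice, never across the
    # horizontal meridian (hemifields are evaluated separately)
    dx = abs(a.x_deg - b.x_deg)
    dy = abs(a.y_deg - b.y_deg)
    return dx <= GRID_STEP_DEG and dy <= GRID_STEP_DEG and (dx or dy) \
        and (a.y_deg > 0) == (b.y_deg > 0)


def find_qualifying_clusters(vf: VFResult) -> List[Cluster]:
    """Qualifying pattern-deviation clusters per hemifield.

    A component is built from significant (p < 5%) points under
    8-adjacency within one hemifield, excluding the blind spot.  Its
    counted size is the number of non-edge members plus at most two
    nasal-edge members; other edge points keep components connected but
    never add to the size.  It qualifies with counted size >= 3 and at
    least one member at p < 1%.
    """
    if not vf.pd_map_shown:
        raise InputError("pattern deviation map not shown; clusters undefined")
    clusters: List[Cluster] = []
    for hemi, sign in (("superior", 1), ("inferior", -1)):
        nodes = [i for i, p in enumerate(vf.points)
                 if p.pd_category.significant and not p.is_blind_spot
                 and (p.y_deg > 0) == (sign > 0)]
        seen: Set[int] = set()
        for start in nodes:
            if start in seen:
                continue
            comp = [start]
            seen.add(start)
            queue = [start]
            while queue:
                cur = queue.pop()
                for j in nodes:
                    if j not in seen and _adjacent(vf.points[cur], vf.points[j]):
                        seen.add(j)
                        comp.append(j)
                        queue.append(j)
            members = sorted(comp)
            non_edge = sum(1 for i in members if not vf.points[i].is_edge)
            nasal = sum(1 for i in members if vf.points[i].is_nasal_edge)
            counted = non_edge + min(2, nasal)
            has_lt1 = any(vf.points[i].pd_category >= PDCategory.LT1
                          for i in members)
            cluster = Cluster(member_indices=tuple(members), hemifield=hemi,
                              n_counted=counted, has_lt1pct=has_lt1)
            if cluster.qualifies:
                clusters.append(cluster)
    return clusters


def anderson_patella(vf: VFResult) -> Tuple[bool, FrozenSet[str]]:
    """Abnormality decision: any of {qualifying cluster, PSD p < 5%,
    GHT outside normal limits}.  With the PD map withheld the cluster
    branch cannot be evaluated and is skipped; PSD and GHT still apply.
    Returns ``(abnormal, criteria_met)``."""
    met: Set[str] = set()
    if vf.pd_map_shown and find_qualifying_clusters(vf):
        met.add("cluster")
    if vf.psd_p_lt_5pct:
        met.add("psd")
    if vf.ght is GHTResult.OUTSIDE_NORMAL_LIMITS:
        met.add("ght")
    return bool(met), frozenset(met)


def hemifield_abnormal(vf: VFResult) -> Dict[str, bool]:
    """Per-hemifield abnormality: a hemifield is abnormal iff it holds
    at least one qualifying cluster."""
    clusters = find_qualifying_clusters(vf)
    return {
        "superior": any(c.hemifield == "superior" for c in clusters),
        "inferior": any(c.hemifield == "inferior" for c in clusters),
    }


def stage_classify(md_db: float, pd_map_shown: bool) -> Stage:
    """MD-based severity stage; M4 whenever the PD map is withheld
    (severely depressed field), otherwise M1/M2/M3 by the MD bounds
    with both boundaries (-6, -12) belonging to M2."""
    import math

    if not math.isfinite(md_db):
        raise InputError(f"MD must be finite, got {md_db}")
    if not pd_map_shown:
        return Stage.M4
    if md_db > -6.0:
        return Stage.M1
    if md_db >= -12.0:
        return Stage.M2
    return Stage.M3


def estimate_axial_length(equivalent_sphere_diopters: float) -> float:
    """Axial length surrogate when biometry is unavailable:
    ``24 + 0.333 * |ES|`` mm, with ES the spherical equivalent."""
    import math

    if not math.isfinite(equivalent_sphere_diopters):
        raise InputError("equivalent sphere must be finite")
    return 24.0 + 0.333 * abs(equivalent_sphere_diopters)


# ---------------------------------------------------------------------------
# JSON round-trips (chart coordinates: +x is the patient's right on the
# printout; temporal = +x for OD, -x for OS)
# ---------------------------------------------------------------------------

def _chart_to_temporal(x_chart: int, laterality: Laterality) -> int:
    return x_chart if laterality is Laterality.OD else -x_chart


def vf_to_dict(vf: VFResult) -> dict:
    return {
        "laterality": vf.laterality.value,
        "md": vf.md_db,
        "psd_p_lt_5": vf.psd_p_lt_5pct,
        "ght": vf.ght.value,
        "fp": vf.fp_rate,
        "fn": vf.fn_rate,
        "pd_shown": vf.pd_map_shown,
        "points": [
            {"x": _chart_to_temporal(p.x_deg, vf.laterality),
             "y": p.y_deg, "pd": _PD_NAMES[p.pd_category]}
            for p in vf.points
        ],
    }


def vf_from_dict(data: dict) -> VFResult:
    try:
        laterality = Laterality(data["laterality"])
        categories: Dict[Tuple[int, int], PDCategory] = {}
        for p in data.get("points", []):
            cat = _PD_FROM_NAME.get(p["pd"])
            if cat is None:
                raise InputError(f"unknown pd category: {p['pd']!r}")
            x = _chart_to_temporal(int(p["x"]), laterality)
            categories[(x, int(p["y"]))] = cat
        return VFResult.from_categories(
            laterality,
            categories,
            md_db=float(data["md"]),
            psd_p_lt_5pct=bool(data.get("psd_p_lt_5", False)),
            ght=GHTResult(data.get("ght", "within_normal_limits")),
            fp_rate=data.get("fp"),
            fn_rate=data.get("fn"),
            pd_map_shown=bool(data.get("pd_shown", True)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        if isinstance(exc, InputError):
            raise
        raise InputError(f"malformed visual field record: {exc}") from exc


def read_vf_json(path) -> VFResult:
    return vf_from_dict(json.loads(Path(path).read_text()))


def write_vf_json(vf: VFResult, path) -> None:
    Path(path).write_text(json.dumps(vf_to_dict(vf), indent=2))
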