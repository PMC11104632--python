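"""File round-trips: cohort CSV, shadow-record JSON, run manifests."""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .agreement import Quadrant, ShadowRecord, ShadowRegion
from .cohort import OUTCOMES, PREFERENCES, STAGES, EyeRecord
from .errors import InputError
from .visual_field import Laterality

COHORT_COLUMNS = ("eye_id", "group", "stage", "cg_outcome",
                  "analog_outcome", "preference")


def write_cohort_csv(records: Sequence[EyeRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow([r.eye_id, r.group, r.stage or "",
                             r.cg_outcome, r.analog_outcome,
                             r.preference or ""])


def read_cohort_csv(path) -> List[EyeRecord]:
    """Parse a cohort CSV, naming the offending row and column on error."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise InputError(f"{path}: empty file, expected a header") from exc
        if tuple(header) != COHORT_COLUMNS:
            missing = set(COHORT_COLUMNS) - set(header)
            raise InputError(
                f"{path}: bad header {header!r}"
                + (f" (missing columns {sorted(missing)})" if missing else ""))
        records: List[EyeRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise InputError(f"{path}:{lineno}: expected "
                                 f"{len(COHORT_COLUMNS)} fields, got {len(row)}")
            vals = dict(zip(COHORT_COLUMNS, row))
            for col, allowed in (("group", ("normal", "ppg", "glaucoma")),
                                 ("stage", STAGES + ("",)),
                                 ("cg_outcome", OUTCOMES),
                                 ("analog_outcome", OUTCOMES),
                                 ("preference", PREFERENCES + ("",))):
                if vals[col] not in allowed:
                    raise InputError(
                        f"{path}:{lineno}: column {col!r}: "
                        f"invalid value {vals[col]!r}")
            try:
                records.append(EyeRecord(
                    eye_id=vals["eye_id"], group=vals["group"],
                    stage=vals["stage"] or None,
                    cg_outcome=vals["cg_outcome"],
                    analog_outcome=vals["analog_outcome"],
                    preference=vals["preference"] or None))
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Shadow-record JSON
# ---------------------------------------------------------------------------

def shadow_to_dict(record: ShadowRecord) -> dict:
    return {
        "responded": record.responded,
        "reproducible": record.reproducible,
        "laterality": record.laterality.value,
        "regions": [
            {"quadrants": sorted(q.value for q in r.quadrants),
             "ecc": r.centroid_ecc_deg,
             "temporal": r.temporal,
             "straddles": r.straddles_horizontal,
             "isolated": r.isolated}
            for r in record.regions
        ],
    }


def shadow_from_dict(data: dict) -> ShadowRecord:
    try:
        regions = tuple(
            ShadowRegion(
                quadrants=frozenset(Quadrant(q) for q in r["quadrants"]),
                centroid_ecc_deg=float(r["ecc"]),
                temporal=bool(r.get("temporal", False)),
                isolated=bool(r.get("isolated", False)),
                straddles_horizontal=bool(r.get("straddles", False)))
            for r in data.get("regions", []))
        return ShadowRecord(
            responded=bool(data["responded"]),
            reproducible=bool(data["reproducible"]),
            regions=regions,
            laterality=Laterality(data.get("laterality", "OD")))
    except (KeyError, ValueError, TypeError) as exc:
        if isinstance(exc, InputError):
            raise
        raise InputError(f"malformed shadow record: {exc}") from exc


def read_shadow_json(path) -> ShadowRecord:
    return shadow_from_dict(json.loads(Path(path).read_text()))


def write_shadow_json(record: ShadowRecord, path) -> None:
    Path(path).write_text(json.dumps(shadow_to_dict(record), indent=2))


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(outdir, command: str, config: dict,
                       seed: Optional[int],
                       inputs: Sequence = ()) -> Path:
    """Record what a run did: command, config, seed, package version,
    and checksums of the input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "inputs": [{"file": str(p), "sha256": sha256_of(p)} for p in inputs],
    }
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
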