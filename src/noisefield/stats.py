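"""Exact and classical statistics for paired detection cohorts.

The analyses here are the ones a paired screening comparison needs:

* exact McNemar test on the discordant pairs ``(b, c)`` of two
  screening conditions applied to the same eyes;
* exact two-sided binomial test (used for the "which noise was easier"
  preference question);
* Pearson chi-square over a detection-by-stage table with cellwise
  adjusted standardized residuals;
* exact (Clopper–Pearson) binomial confidence intervals for detection
  rates, sensitivity, and specificity;
* report builders that turn a cohort of per-eye records into the
  stage-wise detection and preference tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .agreement import AgreementCategory
from .errors import InputError

STAGES = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class PairedDetectionCounts:
    """2x2 paired outcome of two screening conditions on the same eyes."""

    both: int
    cg_only: int      # b: detected by CG noise only
    analog_only: int  # c: detected by analog noise only
    neither: int

    def __post_init__(self) -> None:
        for name in ("both", "cg_only", "analog_only", "neither"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.both + self.cg_only + self.analog_only + self.neither


@dataclass(frozen=True)
class PreferenceCounts:
    cg_better: int
    same: int
    analog_better: int

    def __post_init__(self) -> None:
        for name in ("cg_better", "same", "analog_better"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.cg_better + self.same + self.analog_better


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar test on discordant pair counts.

    Under H0 the ``n = b + c`` discordant pairs split Binomial(n, 1/2);
    the p-value is ``min(1, 2 * P(X <= min(b, c)))``, and 1 when there
    are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise InputError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of ``k`` successes in ``n`` trials.

    At ``p0 = 1/2`` the distribution is symmetric and the equal-tails
    sum equals doubling the smaller tail, capped at 1.  For other null
    proportions the minimum-likelihood two-sided convention is used.
    """
    if not 0 <= k <= n:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if p0 == 0.5:
        tail = min(k, n - k)
        return float(min(1.0, 2.0 * sps.binom.cdf(tail, n, 0.5)))
    return float(sps.binomtest(k, n, p0).pvalue)


def chi2_adjusted_residuals(
    table: Sequence[Sequence[float]],
) -> Tuple[float, int, float, np.ndarray]:
    """Pearson chi-square (no continuity correction) with adjusted
    standardized residuals.

    The residual for cell (i, j) is
    ``(O - E) / sqrt(E * (1 - row_i/N) * (1 - col_j/N))``; under
    independence each is approximately standard normal, so cells with
    ``|r| > 1.96`` drive the overall association.
    Returns ``(chi2, df, p, residuals)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InputError("need a table with >= 2 rows and >= 2 columns")
    if (obs < 0).any():
        raise InputError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise InputError("every row and column margin must be positive")
    n = obs.sum()
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    denom = np.sqrt(expected
                    * (1.0 - rows[:, None] / n)
                    * (1.0 - cols[None, :] / n))
    resid = (obs - expected) / denom
    return float(chi2), int(df), float(p), resid


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Exact (Beta-quantile) binomial confidence interval for x/n."""
    if n < 1 or not 0 <= x <= n:
        raise InputError(f"need 0 <= x <= n and n >= 1, got x={x}, n={n}")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


# ---------------------------------------------------------------------------
# Cohort-level report builders
# ---------------------------------------------------------------------------

@dataclass
class StageDetectionRow:
    """One row of the detection table (one stage or a pooled group)."""

    stage: str
    n_eyes: int
    detected: int
    rate: float
    ci_low: float
    ci_high: float
    adjusted_residual: Optional[float] = None
    residual_p: Optional[float] = None
    subset: Optional[str] = None
    mcnemar_b: Optional[int] = None
    mcnemar_c: Optional[int] = None
    mcnemar_p: Optional[float] = None


@dataclass
class NoiseDetectionTable:
    rows: List[StageDetectionRow]
    chi2: float
    chi2_df: int
    chi2_p: float
    specificity_x: int
    specificity_n: int

    @property
    def specificity(self) -> float:
        return self.specificity_x / self.specificity_n

    def row(self, stage: str) -> StageDetectionRow:
        for r in self.rows:
            if r.stage == stage:
                return r
        raise KeyError(stage)


@dataclass
class DetectionReport:
    cg: NoiseDetectionTable
    analog: NoiseDetectionTable
    n_glaucoma: int
    n_ppg: int
    n_normal: int
    ppg_detected_cg: int
    ppg_detected_analog: int


def _subset_labels(residuals: Sequence[float], crit: float = 1.96) -> List[str]:
    """Homogeneous-subset letters from residual significance.

    Stages whose detected-cell residual is not significantly high share
    subset "a" (the low group); those not significantly low share "b".
    With no significant cell at all, every stage shares one subset.
    """
    if all(abs(r) < crit for r in residuals):
        return ["a"] * len(residuals)
    labels = []
    for r in residuals:
        parts = []
        if r < crit:
            parts.append("a")
        if r > -crit:
            parts.append("b")
        labels.append(",".join(parts))
    return labels


def _outcome(record, noise: str) -> AgreementCategory:
    cat = getattr(record, f"{noise}_outcome")
    return AgreementCategory(cat)


def detection_table(records: Sequence, conf: float = 0.95) -> DetectionReport:
    """Build the stage-wise detection report from per-eye records.

    Records need attributes ``group`` ("normal"/"ppg"/"glaucoma"),
    ``stage`` (M1..M4 for glaucoma), and ``cg_outcome`` /
    ``analog_outcome`` (agreement categories).  For each noise the
    report carries per-stage rows plus pooled M3+M4 and Total rows,
    the detection-by-stage chi-square with adjusted residuals, the
    exact McNemar p per row, and specificity over the normal eyes
    (proportion with no reproducible shadow, i.e. a no-response
    outcome).
    """
    records = list(records)
    if not records:
        raise InputError("empty cohort")
    glaucoma = [r for r in records if r.group == "glaucoma"]
    normal = [r for r in records if r.group == "normal"]
    ppg = [r for r in records if r.group == "ppg"]

    by_stage = {s: [r for r in glaucoma if r.stage == s] for s in STAGES}
    pooled: Dict[str, List] = {"M3+M4": by_stage["M3"] + by_stage["M4"],
                               "Total": glaucoma}

    tables: Dict[str, NoiseDetectionTable] = {}
    for noise in ("cg", "analog"):
        det = {s: sum(_outcome(r, noise).detected for r in by_stage[s])
               for s in STAGES}
        n = {s: len(by_stage[s]) for s in STAGES}
        contingency = [[det[s] for s in STAGES],
                       [n[s] - det[s] for s in STAGES]]
        chi2, df, chi2_p, resid = chi2_adjusted_residuals(contingency)
        subsets = _subset_labels(list(resid[0]))
        rows: List[StageDetectionRow] = []
        for j, s in enumerate(STAGES):
            lo, hi = clopper_pearson(det[s], n[s], conf)
            b = sum(_outcome(r, "cg").detected
                    and not _outcome(r, "analog").detected
                    for r in by_stage[s])
            c = sum(_outcome(r, "analog").detected
                    and not _outcome(r, "cg").detected
                    for r in by_stage[s])
            rows.append(StageDetectionRow(
                stage=s, n_eyes=n[s], detected=det[s],
                rate=det[s] / n[s], ci_low=lo, ci_high=hi,
                adjusted_residual=float(resid[0, j]),
                residual_p=float(2 * sps.norm.sf(abs(resid[0, j]))),
                subset=subsets[j],
                mcnemar_b=b, mcnemar_c=c, mcnemar_p=mcnemar_exact(b, c)))
        for label, grp in pooled.items():
            d = sum(_outcome(r, noise).detected for r in grp)
            lo, hi = clopper_pearson(d, len(grp), conf)
            b = sum(_outcome(r, "cg").detected
                    and not _outcome(r, "analog").detected for r in grp)
            c = sum(_outcome(r, "analog").detected
                    and not _outcome(r, "cg").detected for r in grp)
            rows.append(StageDetectionRow(
                stage=label, n_eyes=len(grp), detected=d,
                rate=d / len(grp), ci_low=lo, ci_high=hi,
                mcnemar_b=b, mcnemar_c=c, mcnemar_p=mcnemar_exact(b, c)))
        spec_x = sum(_outcome(r, noise) is AgreementCategory.NO_RESPONSE
                     for r in normal)
        tables[noise] = NoiseDetectionTable(
            rows=rows, chi2=chi2, chi2_df=df, chi2_p=chi2_p,
            specificity_x=spec_x, specificity_n=len(normal))

    return DetectionReport(
        cg=tables["cg"], analog=tables["analog"],
        n_glaucoma=len(glaucoma), n_ppg=len(ppg), n_normal=len(normal),
        ppg_detected_cg=sum(_outcome(r, "cg").detected for r in ppg),
        ppg_detected_analog=sum(_outcome(r, "analog").detected for r in ppg),
    )


@dataclass
class PreferenceRow:
    stage: str
    n_eyes: int
    counts: PreferenceCounts
    cg_rate: float
    same_rate: float
    analog_rate: float
    binom_p: float


def preference_table(per_stage: Dict[str, PreferenceCounts]) -> List[PreferenceRow]:
    """Stage rows plus a total row for the ease-of-recognition question.

    Each row reports the three shares and the exact binomial p-value on
    the discordant preferences (CG-better vs analog-better).
    """
    rows: List[PreferenceRow] = []
    order = [s for s in STAGES if s in per_stage]
    order += [s for s in per_stage if s not in STAGES]
    total = PreferenceCounts(
        cg_better=sum(per_stage[s].cg_better for s in order),
        same=sum(per_stage[s].same for s in order),
        analog_better=sum(per_stage[s].analog_better for s in order),
    )
    for label, counts in [(s, per_stage[s]) for s in order] + [("Total", total)]:
        n = counts.total
        if n == 0:
            rows.append(PreferenceRow(label, 0, counts, 0.0, 0.0, 0.0, 1.0))
            continue
        rows.append(PreferenceRow(
            stage=label, n_eyes=n, counts=counts,
            cg_rate=counts.cg_better / n,
            same_rate=counts.same / n,
            analog_rate=counts.analog_better / n,
            binom_p=binom_two_sided(
                counts.cg_better, counts.cg_better + counts.analog_better)
            if counts.cg_better + counts.analog_better else 1.0,
        ))
    return rows


def preference_counts_from_records(records: Sequence) -> Dict[str, PreferenceCounts]:
    """Tally preferences per stage over eyes detected by both noises."""
    tally: Dict[str, Dict[str, int]] = {}
    for r in records:
        if getattr(r, "preference", None) is None:
            continue
        stage = r.stage
        d = tally.setdefault(stage, {"cg": 0, "same": 0, "analog": 0})
        if r.preference not in d:
            raise InputError(f"unknown preference value: {r.preference!r}")
        d[r.preference] += 1
    return {s: PreferenceCounts(v["cg"], v["same"], v["analog"])
            for s, v in tally.items()}
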