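"""Bowel-motility indices from label tracks.

Two indices per recording:

* **SSI** (sound-to-sound interval): the gap from the end of one bowel
  sound to the start of the next. A file with ``n`` events yields ``n-1``
  intervals, summarized as mean +/- SD. No interval is inferred before the
  first or after the last event.
* **SD** (sound duration): the total bowel-sound time in the file.

Agreement between annotated and predicted tracks is quantified by Pearson
correlation of the per-file index values, with a two-sided p-value from the
t distribution on n-2 degrees of freedom (p < 0.05 taken as significant).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .intervals import IntervalTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SsiSummary:
    """Per-file SSI list and its mean +/- SD (None when < 2 events)."""

    ssi_list: Tuple[float, ...]
    mean: Optional[float]
    sd: Optional[float]
    n_events: int


def _require_disjoint(track: IntervalTrack, op: str) -> None:
    if not track.is_disjoint(tol=1e-9):
        raise ValidationError(
            f"{op}: track has overlapping intervals; apply unify_intervals first"
        )


def compute_ssi(track: IntervalTrack) -> SsiSummary:
    """Sound-to-sound intervals: ``start_{i+1} - end_i`` over consecutive events."""
    _require_disjoint(track, "compute_ssi")
    ivs = track.intervals
    gaps = tuple(b.start_s - a.end_s for a, b in zip(ivs, ivs[1:]))
    if gaps:
        mean = float(np.mean(gaps))
        sd = float(np.std(gaps))
    else:
        mean = sd = None
    return SsiSummary(ssi_list=gaps, mean=mean, sd=sd, n_events=len(ivs))


def compute_sd(track: IntervalTrack) -> float:
    """Total bowel-sound duration in seconds (sum of interval lengths)."""
    _require_disjoint(track, "compute_sd")
    return float(sum(iv.duration_s for iv in track.intervals))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided p-value; r is None for degenerate input."""

    r: Optional[float]
    p_value: Optional[float]
    n: int
    n_excluded: int = 0


def correlate(actual: Sequence[Optional[float]],
              predicted: Sequence[Optional[float]]) -> CorrelationResult:
    """Pearson correlation of paired per-file values.

    Pairs with an undefined value on either side (None/NaN, e.g. a file with
    fewer than two events has no SSI) are excluded pairwise with a logged
    count. Fewer than 3 surviving pairs is an error; zero variance on either
    side yields an undefined-marker r.
    """
    if len(actual) != len(predicted):
        raise ValidationError("actual/predicted vectors differ in length")

    def ok(v) -> bool:
        return v is not None and math.isfinite(v)

    pairs = [(a, p) for a, p in zip(actual, predicted) if ok(a) and ok(p)]
    n_excluded = len(actual) - len(pairs)
    if n_excluded:
        log.info("correlate: excluded %d file pair(s) with undefined values", n_excluded)
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 defined pairs for a correlation, have {len(pairs)}"
        )
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(None, None, n=len(pairs), n_excluded=n_excluded)
    res = scipy.stats.pearsonr(a, b)
    return CorrelationResult(float(res.statistic), float(res.pvalue),
                             n=len(pairs), n_excluded=n_excluded)


@dataclass(frozen=True)
class MotilityReport:
    """Cohort-level agreement between annotated and predicted tracks.

    ``per_file`` has one row per recording with actual/predicted event
    counts, SSI summaries and SD totals; ``ssi_correlation`` and
    ``sd_correlation`` compare the per-file reductions.
    """

    per_file: pd.DataFrame
    ssi_correlation: CorrelationResult
    sd_correlation: CorrelationResult
    reduction: str = "mean"


def _reduce_ssi(summary: SsiSummary, reduction: str) -> Optional[float]:
    if not summary.ssi_list:
        return None
    if reduction == "mean":
        return summary.mean
    if reduction == "median":
        return float(np.median(summary.ssi_list))
    raise ValidationError(f"reduction: {reduction!r} is not 'mean' or 'median'")


def motility_report(
    actual: Dict[str, IntervalTrack],
    predicted: Dict[str, IntervalTrack],
    reduction: str = "mean",
) -> MotilityReport:
    """Build the per-file motility table and truth-vs-prediction correlations.

    ``actual`` and ``predicted`` map file/clip ids to unified tracks; ids
    present in only one of the two are an error.
    """
    if set(actual) != set(predicted):
        raise ValidationError(
            "actual and predicted track sets cover different files: "
            f"{sorted(set(actual) ^ set(predicted))}"
        )
    rows = []
    ssi_a, ssi_p, sd_a, sd_p = [], [], [], []
    for fid in sorted(actual):
        sa, sp = compute_ssi(actual[fid]), compute_ssi(predicted[fid])
        da, dp = compute_sd(actual[fid]), compute_sd(predicted[fid])
        ra, rp = _reduce_ssi(sa, reduction), _reduce_ssi(sp, reduction)
        ssi_a.append(ra)
        ssi_p.append(rp)
        sd_a.append(da)
        sd_p.append(dp)
        rows.append({
            "file_id": fid,
            "n_events_actual": sa.n_events,
            "n_events_predicted": sp.n_events,
            "ssi_actual_s": ra,
            "ssi_predicted_s": rp,
            "ssi_sd_actual_s": sa.sd,
            "ssi_sd_predicted_s": sp.sd,
            "sd_actual_s": da,
            "sd_predicted_s": dp,
        })
    return MotilityReport(
        per_file=pd.DataFrame(rows).set_index("file_id"),
        ssi_correlation=correlate(ssi_a, ssi_p),
        sd_correlation=correlate(sd_a, sd_p),
        reduction=reduction,
    )
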