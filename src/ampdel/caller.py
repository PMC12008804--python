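"""Focal-deletion calling at a target locus.

Three evidence pathways, mirroring how amplification-embedded deletions
are found in consensus tumor copy-number data:

* ``scna`` — a segment-level copy-loss event: a maximal run of segments
  at least ``rel_loss_delta`` copies below both flanking segments, with a
  boundary within ``proximity_bp`` of the locus, overlapping the locus,
  and spanning less than ``max_event_bp``.
* ``rescued`` — no segment-level call, but a deletion-consistent SV
  junction pair bounds an interval with a commensurate read-depth drop
  whose step locations match the breakends (automated stand-in for manual
  review of tumor/normal depth plots).
* ``relative_loss`` — locus copy number at least ``rel_loss_delta``
  below the neighbor gene; flagged non-focal and excluded from the
  carrier set used by downstream statistics.

Amplification status (any overlapping segment with total copy number
strictly above ``amp_cn_threshold``) is computed irrespective of any
concomitant focal deletion.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CopyNumberSegment, GeneLocus, ReadDepthTrack, SVJunction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the deletion caller (bp unless noted)."""

    proximity_bp: int = 50_000       # max breakpoint distance from the locus
    max_event_bp: int = 100_000      # focal size cap (exclusive)
    rel_loss_delta: float = 0.5      # copies below flanks to count as loss
    amp_cn_threshold: float = 2.0    # amplification iff total CN strictly above
    rescue_drop_frac: float = 0.2    # min fractional depth drop inside vs flank
    rescue_flank_bp: int = 50_000    # flank width for the depth baseline
    junction_match_bp: int = 1_000   # max step-to-breakend distance

    def __post_init__(self):
        for name in ("proximity_bp", "max_event_bp", "rescue_flank_bp", "junction_match_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rel_loss_delta <= 0:
            raise ValueError("rel_loss_delta must be positive")
        if not 0.0 < self.rescue_drop_frac < 1.0:
            raise ValueError("rescue_drop_frac must be in (0,1)")


@dataclass(frozen=True)
class FocalDeletionCall:
    sample: str
    chrom: str
    start: int
    end: int
    evidence_class: str  # 'scna' | 'rescued' | 'relative_loss'
    cn_inside: float
    cn_flank: float
    junction_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.evidence_class not in ("scna", "rescued", "relative_loss"):
            raise ValueError(f"unknown evidence class {self.evidence_class!r}")

    @property
    def focal(self) -> bool:
        return self.evidence_class in ("scna", "rescued")

    @property
    def span(self) -> int:
        return self.end - self.start


def locus_cn(segments: Sequence[CopyNumberSegment], locus: GeneLocus) -> float:
    """Overlap-length-weighted mean total copy number across the locus.

    Uncovered bases are excluded from the weighting; returns NaN when no
    segment overlaps the locus at all.
    """
    num = den = 0.0
    for seg in segments:
        if seg.chrom != locus.chrom:
            continue
        ov = seg.overlap(locus.start, locus.end)
        if ov:
            num += seg.total_cn * ov
            den += ov
    return num / den if den else float("nan")


def is_amplified(
    segments: Sequence[CopyNumberSegment], locus: GeneLocus, params: CallerParams
) -> bool:
    """True iff any segment with total CN strictly above the threshold
    overlaps the locus, irrespective of concomitant focal deletions."""
    return any(
        seg.chrom == locus.chrom
        and seg.overlap(locus.start, locus.end) > 0
        and seg.total_cn > params.amp_cn_threshold
        for seg in segments
    )


def _loss_events(segs: list[CopyNumberSegment], delta: float) -> list[tuple[int, int]]:
    """Maximal runs of segments below both flanking segments by >= delta.

    Returns (i, j) index pairs into ``segs`` (run inclusive); the run's
    flanks are segs[i-1] and segs[j+1].
    """
    n = len(segs)
    cn = [s.total_cn for s in segs]

    def qualifies(i: int, j: int) -> bool:
        if i < 1 or j > n - 2:
            return False
        run_max = max(cn[i : j + 1])
        return run_max <= min(cn[i - 1], cn[j + 1]) - delta

    # all qualifying runs not extendable in either direction; nested events
    # (a deeper loss inside a broader one) are each reported
    events = []
    for i in range(1, n - 1):
        for j in range(i, n - 1):
            if qualifies(i, j) and not qualifies(i - 1, j) and not qualifies(i, j + 1):
                events.append((i, j))
    return events


def call_scna_focal_deletions(
    segments: Sequence[CopyNumberSegment],
    junctions: Sequence[SVJunction],
    locus: GeneLocus,
    params: CallerParams,
) -> list[FocalDeletionCall]:
    """Segment-level focal-deletion calls for one sample at one locus."""
    segs = sorted(
        (s for s in segments if s.chrom == locus.chrom), key=lambda s: s.start
    )
    if not segs:
        return []
    sample = segs[0].sample
    calls = []
    for i, j in _loss_events(segs, params.rel_loss_delta):
        start, end = segs[i].start, segs[j].end
        span = end - start
        if span >= params.max_event_bp:
            continue
        if max(0, min(end, locus.end) - max(start, locus.start)) == 0:
            continue
        if min(locus.distance_to(start), locus.distance_to(end)) > params.proximity_bp:
            continue
        run = segs[i : j + 1]
        num = sum(s.total_cn * (s.end - s.start) for s in run)
        den = sum(s.end - s.start for s in run)
        cn_inside = num / den
        cn_flank = (segs[i - 1].total_cn + segs[j + 1].total_cn) / 2.0
        support = tuple(
            jn.name
            for jn in junctions
            if jn.is_deletion_consistent()
            and jn.chrom1 == locus.chrom
            and abs(jn.pos1 - start) <= params.junction_match_bp
            and abs(jn.pos2 - end) <= params.junction_match_bp
        )
        calls.append(
            FocalDeletionCall(
                sample, locus.chrom, start, end, "scna", cn_inside, cn_flank, support
            )
        )
    return calls


STEP_WINDOW_BP = 10_000   # changepoint search half-window around a breakend
STEP_LR_SLACK = 10.0      # SSE slack, in units of residual variance


def _step_at_breakend(
    track: ReadDepthTrack,
    breakend: int,
    match_bp: int,
    lo: int | None = None,
    hi: int | None = None,
) -> bool:
    """Test whether the depth step near ``breakend`` lies within
    ``match_bp`` of it.

    Fits a one-step piecewise-constant model to the bins within
    +/- STEP_WINDOW_BP of the breakend (clipped to [lo, hi] so that only
    one true step can fall in the window) and accepts when the best
    changepoint within match_bp of the breakend fits essentially as well
    as the unconstrained best — a likelihood-ratio location test, robust
    to the bin-level jitter of the argmax under counting noise.
    """
    w_lo = breakend - STEP_WINDOW_BP if lo is None else max(lo, breakend - STEP_WINDOW_BP)
    w_hi = breakend + STEP_WINDOW_BP if hi is None else min(hi, breakend + STEP_WINDOW_BP)
    idx = np.flatnonzero((track.starts >= w_lo) & (track.ends <= w_hi))
    if len(idx) < 4:
        return False
    x = track.ratios[idx]
    edges = track.starts[idx]
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    k = np.arange(1, n)
    s1, q1 = csum[:-1], csq[:-1]
    s2, q2 = csum[-1] - s1, csq[-1] - q1
    sse = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
    best = float(sse.min())
    near = np.abs(edges[1:] - breakend) <= match_bp
    if not near.any():
        return False
    best_near = float(sse[near].min())
    sigma2 = max(best, 0.0) / max(n - 2, 1)
    tol = 1e-9 * (float(csq[-1]) + 1.0)  # rounding floor for noiseless tracks
    return best_near - best <= STEP_LR_SLACK * sigma2 + tol


def rescue_from_depth(
    junctions: Sequence[SVJunction],
    depth: ReadDepthTrack,
    locus: GeneLocus,
    params: CallerParams,
) -> list[FocalDeletionCall]:
    """Read-depth rescue: call deletions from deletion-consistent junction
    pairs bounding a depth drop, when no segment-level call exists."""
    wstart, wend = locus.effective_window()
    candidates = [
        j
        for j in junctions
        if j.is_deletion_consistent()
        and j.chrom1 == locus.chrom
        and j.span is not None
        and 0 < j.span < params.max_event_bp
        and min(j.pos2, wend) > max(j.pos1, wstart)
    ]
    calls = []
    for jn in candidates:
        start, end = jn.pos1, jn.pos2
        flank_lo = (start - params.rescue_flank_bp, start)
        flank_hi = (end, end + params.rescue_flank_bp)
        if not (depth.covers(*flank_lo) and depth.covers(*flank_hi) and depth.covers(start, end)):
            logger.warning(
                "depth track for %s does not cover candidate %s:%d-%d plus flanks; skipped",
                jn.sample, locus.chrom, start, end,
            )
            continue
        # exclude other candidate intervals from the flank baseline
        others = [(o.pos1, o.pos2) for o in candidates if o is not jn]

        def _flank_mean(lo: int, hi: int) -> float:
            ov = np.clip(np.minimum(depth.ends, hi) - np.maximum(depth.starts, lo), 0, None)
            weights = ov.astype(float)
            for os_, oe in others:
                inside = (depth.starts >= os_) & (depth.ends <= oe)
                weights[inside] = 0.0
            total = weights.sum()
            return float((depth.ratios * weights).sum() / total) if total else float("nan")

        flank = np.nanmean([_flank_mean(*flank_lo), _flank_mean(*flank_hi)])
        inside = depth.mean_ratio(start, end)
        if math.isnan(flank) or math.isnan(inside) or flank <= 0:
            continue
        if inside > (1.0 - params.rescue_drop_frac) * flank:
            continue
        if not _step_at_breakend(depth, start, params.junction_match_bp, hi=end):
            continue
        if not _step_at_breakend(depth, end, params.junction_match_bp, lo=start):
            continue
        calls.append(
            FocalDeletionCall(
                jn.sample, locus.chrom, start, end, "rescued",
                cn_inside=2.0 * inside, cn_flank=2.0 * flank,
                junction_names=(jn.name,),
            )
        )
    return calls


def call_relative_loss(
    segments: Sequence[CopyNumberSegment],
    target: GeneLocus,
    neighbor: GeneLocus,
    params: CallerParams,
) -> list[FocalDeletionCall]:
    """Copy loss of the target relative to its neighbor gene; non-focal."""
    if not segments:
        return []
    sample = segments[0].sample
    cn_t = locus_cn(segments, target)
    cn_n = locus_cn(segments, neighbor)
    if math.isnan(cn_t) or math.isnan(cn_n):
        logger.warning("sample %s: missing CN at target or neighbor; skipped", sample)
        return []
    if cn_t <= cn_n - params.rel_loss_delta:
        return [
            FocalDeletionCall(
                sample, target.chrom, target.start, target.end,
                "relative_loss", cn_inside=cn_t, cn_flank=cn_n,
            )
        ]
    return []


@dataclass
class CallerResult:
    calls: list[FocalDeletionCall]
    amplified: dict[str, bool]  # per-sample amplification status at target

    def carriers(self) -> list[str]:
        return sorted({c.sample for c in self.calls if c.focal})

    def by_class(self) -> dict[str, int]:
        out = {"scna": 0, "rescued": 0, "relative_loss": 0}
        for c in self.calls:
            out[c.evidence_class] += 1
        return out


def run_caller(
    segments_by_sample: dict[str, list[CopyNumberSegment]],
    junctions_by_sample: dict[str, list[SVJunction]],
    depth_by_sample: dict[str, ReadDepthTrack],
    target: GeneLocus,
    neighbor: GeneLocus,
    params: CallerParams | None = None,
) -> CallerResult:
    """Run all pathways cohort-wide.

    The rescue pathway is only consulted for junction intervals not
    already explained by an scna call (evidence classes partition);
    relative-loss calls are only emitted for samples with no focal call.
    """
    params = params or CallerParams()
    all_samples = sorted(set(segments_by_sample) | set(junctions_by_sample))
    calls: list[FocalDeletionCall] = []
    amplified: dict[str, bool] = {}
    for sample in all_samples:
        segs = segments_by_sample.get(sample, [])
        juncs = junctions_by_sample.get(sample, [])
        amplified[sample] = is_amplified(segs, target, params)
        scna_calls = call_scna_focal_deletions(segs, juncs, target, params)
        calls.extend(scna_calls)
        track = depth_by_sample.get(sample)
        if track is not None:
            rescued = rescue_from_depth(juncs, track, target, params)
            for call in rescued:
                overlaps_scna = any(
                    min(call.end, c.end) > max(call.start, c.start) for c in scna_calls
                )
                if not overlaps_scna:
                    calls.append(call)
        if not any(c.sample == sample and c.focal for c in calls):
            calls.extend(call_relative_loss(segs, target, neighbor, params))
    return CallerResult(calls, amplified)
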