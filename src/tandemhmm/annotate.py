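"""Turn a decoded state path into scored, labeled repeat-region annotations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decode import DecodedPath, NR, decode_windowed, viterbi_decode
from .model import ModelParams

__all__ = ["RepeatRegion", "path_to_regions", "score_region", "merge_window_overlaps",
           "annotate_sequence"]


@dataclass
class RepeatRegion:
    """An annotated repeat span.

    ``start``/``end`` are 0-based half-open sequence coordinates; ``start``
    has already been adjusted down by one period (clamped at 0) because the
    first unit of a repeat precedes the first position a backward-looking
    state can recognize.  ``raw_start`` keeps the unadjusted path position
    for scoring and splitting.  ``score`` is in nats.
    """

    start: int
    end: int
    period: int
    score: float = 0.0
    pvalue: float | None = None
    unit: str = ""
    subrepeats: list = field(default_factory=list)
    raw_start: int = -1
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.raw_start < 0:
            self.raw_start = min(self.start + self.period, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def path_to_regions(path: DecodedPath, params: ModelParams | None = None) -> list[RepeatRegion]:
    """Maximal non-background runs of the path, filtered and start-adjusted.

    Each run of positions not labeled non-repetitive becomes a region whose
    period is that of its governing repetitive state.  Runs spanning fewer
    than ``min_unit`` full units (measured on the raw path span) are
    dropped; surviving regions have their start moved to
    ``max(0, start - p)``.
    """
    params = params or path.params
    kinds = path.kind
    if len(kinds) == 0:
        return []
    nonbg = kinds != NR
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(nonbg.astype(np.int8)))
    regions = []
    bounds = np.concatenate(([0], edges + 1, [len(kinds)]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if not nonbg[b0]:
            continue
        p = int(path.period[b0])
        if b1 - b0 < params.min_unit * p:
            continue
        region = RepeatRegion(
            start=max(0, int(b0) - p), end=int(b1), period=p, raw_start=int(b0)
        )
        region.score = score_region(region, path)
        regions.append(region)
    regions.sort(key=lambda r: r.start)
    return regions


def score_region(region: RepeatRegion, path: DecodedPath) -> float:
    """Region score in nats: summed log T + log(E/E0) over the raw span.

    Computed both as the sum of per-position contributions and as the
    difference of the path's cumulative log-score at the region's ends; the
    two formulations must agree (they are the same telescoping sum).
    """
    t0, t1 = region.raw_start, region.end
    if t1 <= t0:
        return 0.0
    if t1 > len(path):
        raise ValueError("region extends past the decoded path")
    by_sum = float(np.sum(path.contributions()[t0:t1]))
    by_diff = float(path.cumulative_log[t1 - 1] - (path.cumulative_log[t0 - 1] if t0 > 0 else 0.0))
    if abs(by_sum - by_diff) > 1e-6:
        raise AssertionError(
            f"score formulations disagree: sum={by_sum} diff={by_diff}"
        )
    return by_diff


def merge_window_overlaps(regions: list[RepeatRegion], path: DecodedPath | None = None) -> list[RepeatRegion]:
    """Merge overlapping regions of equal period into single spans.

    Regions coming from adjacent decode windows can double-annotate a repeat
    that crosses the window boundary; overlapping annotations with the same
    period become one region over the union (re-scored over the union when a
    path covering it is supplied).  Overlapping regions of different periods
    are both kept.
    """
    if not regions:
        return []
    out: list[RepeatRegion] = []
    for reg in sorted(regions, key=lambda r: (r.start, r.period)):
        merged = False
        for prev in out:
            if prev.period == reg.period and reg.start < prev.end and reg.end > prev.start:
                prev.end = max(prev.end, reg.end)
                prev.raw_start = min(prev.raw_start, reg.raw_start)
                if path is not None:
                    prev.score = score_region(prev, path)
                else:
                    prev.score = max(prev.score, reg.score)
                merged = True
                break
        if not merged:
            out.append(replace(reg, subrepeats=list(reg.subrepeats)))
    return sorted(out, key=lambda r: (r.start, r.period))


def annotate_sequence(
    sequence,
    params: ModelParams | None = None,
    *,
    windowed: bool = True,
    plan=None,
    threads: int = 1,
    split: bool = True,
    split_val: float | None = None,
    fit=None,
    sequence_id: str = "",
) -> list[RepeatRegion]:
    """Full annotation pipeline: decode, extract regions, split, score.

    With ``fit`` (a :class:`~tandemhmm.stats.ScoreDistFit`), every region
    also receives a P-value.
    """
    params = params or ModelParams()
    if windowed:
        path = decode_windowed(sequence, params, plan=plan, threads=threads)
    else:
        path = viterbi_decode(sequence, params)
    regions = path_to_regions(path, params)
    if split:
        from .split import split_region

        for region in regions:
            split_region(region, path, split_val=split_val)
    if fit is not None:
        from .stats import pvalue

        for region in regions:
            region.pvalue = pvalue(region.score, fit)
    for region in regions:
        region.sequence_id = sequence_id
    return regions
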