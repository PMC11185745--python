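"""Null score distribution and P-values for repeat annotations.

Annotation scores observed on random (non-repetitive) sequence follow, to a
good approximation, a location-scale exponential distribution.  Fitting
(location mu, scale sigma) to scores from a long random sequence, and
letting omega be the fraction of letters annotated repetitive in that
sequence, the P-value of a region with score s is

    P = omega * exp((mu - s) / sigma)

clamped at 1 (the raw formula exceeds 1 for s < mu).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model import ModelParams

__all__ = ["ScoreDistFit", "fit_exponential", "pvalue", "calibrate", "default_fit"]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScoreDistFit:
    """(mu, sigma, omega): location/scale of the exponential fit to null
    annotation scores and the repetitive fraction of null sequence."""

    mu: float
    sigma: float
    omega: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")


def fit_exponential(scores, anchor_quantile: float = 0.0) -> tuple[float, float]:
    """Maximum-likelihood location-scale exponential fit.

    mu is the sample minimum and sigma the mean excess over it.  A
    degenerate sample (all scores equal) has no valid scale and is rejected.

    With ``anchor_quantile`` > 0 the location is anchored at that sample
    quantile instead of the minimum and the scale is the mean excess of the
    scores at or above it; by memorylessness this estimator is still exact
    for a true location-scale exponential while being robust to a soft (or
    outlying) lower edge.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 scores to fit")
    if anchor_quantile:
        mu = float(np.quantile(scores, anchor_quantile, method="lower"))
        excess = scores[scores >= mu]
    else:
        mu = float(scores.min())
        excess = scores
    sigma = float(excess.mean() - mu)
    if sigma <= 0:
        raise ValueError("degenerate fit: zero scale (all scores equal)")
    return mu, sigma


def pvalue(score: float, fit: ScoreDistFit) -> float:
    """P-value of an annotation score under the fitted null; decreasing in s."""
    return min(1.0, fit.omega * math.exp((fit.mu - score) / fit.sigma))


def calibrate(
    null_length: int,
    params: ModelParams | None = None,
    seed: int = 0,
    *,
    threads: int = 1,
    plan=None,
    min_annotations: int = 1000,
    return_regions: bool = False,
):
    """Fit the null score distribution by annotating random sequence.

    Generates a seeded random sequence at the model's background
    composition, annotates it with the model, and returns the
    :class:`ScoreDistFit` (optionally together with the null regions).
    Warns when the null yields fewer than ``min_annotations`` regions.
    """
    import warnings

    from .annotate import annotate_sequence
    from .simulate import random_sequence

    params = params or ModelParams()
    seq = random_sequence(null_length, params.at_richness, seed)
    if plan is None and null_length > 1:
        # large windows keep the per-window overhead negligible on long nulls
        from .decode import plan_windows
        from .model import explicit_state_count

        plan = plan_windows(null_length, explicit_state_count(params),
                            min(200_000, null_length), k=params.k)
    regions = annotate_sequence(seq, params, plan=plan, threads=threads, split=False)
    if not regions:
        raise CalibrationError("no annotations on null sequence; cannot calibrate")
    if len(regions) < min_annotations:
        warnings.warn(
            f"only {len(regions)} null annotations (< {min_annotations}); "
            "the exponential fit may be unstable", stacklevel=2)
    covered = sum(len(r) for r in regions)
    omega = min(1.0, covered / null_length)
    # the null's lower edge is soft (short regions near the reporting
    # threshold), so the fit is anchored at the 5% quantile
    mu, sigma = fit_exponential([r.score for r in regions], anchor_quantile=0.05)
    fit = ScoreDistFit(mu=mu, sigma=sigma, omega=omega)
    return (fit, regions) if return_regions else fit


def default_fit() -> ScoreDistFit:
    """The packaged default P-value parameters (--ploc/--pscale/--pfreq).

    Produced by running :func:`calibrate` with the shipped default model on
    10 Mb of random sequence; the generating seed and scale are recorded
    alongside the values in the packaged JSON.
    """
    with resources.files("tandemhmm.data").joinpath("default_pvalue.json").open() as fh:
        d = json.load(fh)
    return ScoreDistFit(mu=d["ploc"], sigma=d["pscale"], omega=d["pfreq"])
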