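"""One-sample summaries of log2 odds ratios across experiments."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AggregateSummary", "one_sample_summary", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    """Fewer than two values: mean/sd/p across experiments is undefined."""


@dataclass
class AggregateSummary:
    """Table-row summary: n / mean / sd / two-tailed p of log2 odds ratios."""

    callset: str
    assay_class: str
    stratum: str  # near | far | delta
    n: int
    mean: float
    sd: float
    t: float
    p: float
    degenerate: bool = False  # sd == 0 with non-zero mean: p not computable


def one_sample_summary(
    values,
    *,
    callset: str = "",
    assay_class: str = "",
    stratum: str = "",
) -> AggregateSummary:
    """Two-tailed one-sample Student's t-test of ``values`` against zero.

    Sample standard deviation uses the n−1 denominator; df = n − 1.  A zero
    sd with non-zero mean (all values identical, off zero) is flagged as
    degenerate instead of reporting an infinite t.
    """
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n < 2:
        raise InsufficientDataError(f"need ≥ 2 values, got {n}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            t, p, degenerate = 0.0, 1.0, False
        else:
            t, p, degenerate = math.inf, math.nan, True
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
        degenerate = False
    return AggregateSummary(
        callset=callset,
        assay_class=assay_class,
        stratum=stratum,
        n=n,
        mean=mean,
        sd=sd,
        t=t,
        p=p,
        degenerate=degenerate,
    )
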