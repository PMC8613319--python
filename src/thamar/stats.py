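"""Paired Wilcoxon signed-rank test with an exact small-sample distribution.

All study cells involve at most 18 pellet pairs, so the exact null
distribution of the signed-rank statistic W (sum of ranks of the positive
differences) is used by default: conditioning on the observed absolute
values, each of the 2^n sign assignments is equally likely under the null,
and the distribution of W is built by a subset-sum convolution over the
(mid)ranks — equivalent to full enumeration but polynomial-time.  Ties get
midranks; zero differences are dropped (Wilcoxon's rule) or kept through
ranking and then discarded (Pratt's rule).  Above n = 20 a tie-corrected
normal approximation with continuity correction takes over.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank", "PairedSample", "compare_all"]

EXACT_MAX_N = 20


@dataclass(frozen=True)
class PairedSample:
    """Per-pair differences entering the signed-rank test."""

    differences: tuple[float, ...]
    zeros_policy: str = "wilcoxon"

    def __post_init__(self) -> None:
        d = tuple(float(v) for v in self.differences)
        if len(d) < 1:
            raise ValueError("need at least one difference")
        if not all(math.isfinite(v) for v in d):
            raise ValueError("differences must be finite")
        if self.zeros_policy not in ("wilcoxon", "pratt"):
            raise ValueError("zeros_policy must be 'wilcoxon' or 'pratt'")
        object.__setattr__(self, "differences", d)

    @property
    def n(self) -> int:
        return len(self.differences)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = sum of positive-difference ranks; NaN if degenerate
    p_value: float
    n_used: int  # pairs contributing after zero handling
    method: str  # "exact", "normal_approx" or "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p via subset-sum convolution over the ranks.

    Midranks are half-integers; doubling makes every achievable W an
    integer index.  ``dist[s]`` counts sign assignments with 2*W == s.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w))
    p_low = float(dist[: w2 + 1].sum())
    p_high = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def _normal_approx_p(d: np.ndarray, ranks: np.ndarray, w: float) -> float:
    n = d.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # midrank tie correction
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    return float(2.0 * _sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    sample: PairedSample | Sequence[float],
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    mode
        "exact" enumerates the conditional null distribution (all sign
        assignments of the observed absolute values), "normal_approx" uses
        the tie-corrected large-sample normal with continuity correction,
        and "auto" switches from exact to the approximation above n = 20.

    All differences equal to zero is a degenerate, not erroneous, outcome:
    the test has nothing to rank and reports p = 1 with a NaN statistic.
    """
    if not isinstance(sample, PairedSample):
        sample = PairedSample(tuple(sample))
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError("mode must be 'exact', 'normal_approx' or 'auto'")

    d = np.asarray(sample.differences, dtype=float)
    if sample.zeros_policy == "wilcoxon":
        d_used = d[d != 0.0]
        if d_used.size == 0:
            return WilcoxonResult(math.nan, 1.0, 0, "degenerate")
        ranks = _sps.rankdata(np.abs(d_used))
    else:  # pratt: rank with zeros included, then drop the zero ranks
        if not np.any(d != 0.0):
            return WilcoxonResult(math.nan, 1.0, 0, "degenerate")
        all_ranks = _sps.rankdata(np.abs(d))
        keep = d != 0.0
        d_used = d[keep]
        ranks = all_ranks[keep]

    n = d_used.size
    w = float(np.sum(ranks[d_used > 0]))
    if n == 1:
        warnings.warn(
            "signed-rank test on a single pair has no power (p >= 1)",
            RuntimeWarning,
            stacklevel=2,
        )
    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "normal_approx"
    if mode == "exact":
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        p = _normal_approx_p(d_used, ranks, w)
        method = "normal_approx"
    return WilcoxonResult(w, min(max(p, 0.0), 1.0), int(n), method)


def compare_all(records, references=None, alpha: float = 0.05, mode: str = "ratio_of_means"):
    """Both relative-MAR tables with a per-cell significance flag.

    Thin orchestration over the metrics layer: each cell already carries the
    paired signed-rank p over its per-pellet normalized deviations; this
    adds the two-sided alpha = 0.05 decision column.
    """
    from .metrics import build_tables

    tables = build_tables(records, references, mode)
    out = []
    for table in tables:
        table = table.copy()
        table["significant"] = table["p_value"] < alpha
        out.append(table)
    return tuple(out)
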