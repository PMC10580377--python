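"""Intermutation distances and penalized changepoint segmentation.

The mutation landscape of a chromosome is summarised as the ordered sequence
of intermutation distances (IMDs): the distance of each variant to its
closest upstream neighbour, with the first variant measured from the start
of the chromosome.  One *pseudo-IMD* — the distance from the last variant to
the chromosome end — closes the sequence so that the IMDs of a chromosome
sum exactly to its length in base pairs.

Regions of elevated mutation rate are found by penalized changepoint
detection on the IMD sequence under an exponential observation model: each
segment is scored by twice its negative maximized exponential log-likelihood
(additive constants dropped), and every additional segment pays a BIC-style
penalty of ``2 * ln(n)``.  The default search, :func:`pelt`, returns the
exact penalized optimum; binary segmentation, segment neighborhoods,
at-most-one-change, and an unpruned dynamic program (the test oracle) are
provided for comparison.

Implementation note: :func:`pelt` solves the same optimisation as classic
PELT but prunes *functionally*: in ``z = log(segment mean)`` space every
candidate's cost curve ``a + 2b*exp(-z) + 2c*z`` is convex, so the dynamic
program only tracks the lower envelope of the candidate curves (typically a
few dozen pieces) instead of scanning every admissible previous changepoint.
This keeps whole-chromosome sequences (10^5 observations and more) tractable
while remaining exact; :func:`_pelt_quadratic` retains the classic
inequality-pruned O(n^2) scan for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np

__all__ = [
    "ImdSequence",
    "ChangepointParams",
    "ChangepointResult",
    "compute_imd",
    "exp_segment_cost",
    "bic_penalty",
    "pelt",
    "binseg",
    "segneigh",
    "amoc",
    "brute_force_partition",
    "segment_observations",
]

SEARCH_ALGORITHMS = ("pelt", "binseg", "segneigh", "amoc")


@dataclass(frozen=True)
class ImdSequence:
    """Ordered IMD observations of one chromosome, plus the pseudo-IMD.

    Attributes
    ----------
    chromosome : str
        Chromosome identifier.
    positions : ndarray of int
        Strictly increasing 1-based variant start positions.
    imds : ndarray of int
        ``imds[0] = positions[0]``; ``imds[i] = positions[i] - positions[i-1]``.
    pseudo_imd : int
        ``chromosome_length - positions[-1]`` (may be 0 at the boundary).
    chromosome_length : int
        Total chromosome length in base pairs.
    """

    chromosome: str
    positions: np.ndarray
    imds: np.ndarray
    pseudo_imd: int
    chromosome_length: int

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def observations(self) -> np.ndarray:
        """IMDs followed by the pseudo-IMD, as floats for segmentation.

        A pseudo-IMD of 0 (last variant on the final base) is replaced by 1
        so the exponential cost stays defined; this boundary case cannot
        change which variants are segmented together.
        """
        obs = np.empty(len(self.imds) + 1, dtype=np.float64)
        obs[:-1] = self.imds
        obs[-1] = self.pseudo_imd if self.pseudo_imd > 0 else 1
        return obs


@dataclass(frozen=True)
class ChangepointParams:
    """Configuration of the changepoint search.

    ``penalty_value`` is the per-changepoint penalty beta (``None`` selects
    the BIC value ``2*ln(n)``); ``min_seg_len`` is the minimum number of
    observations per segment (default 2, the smallest length for which an
    exponential rate is a meaningful fit); ``max_segments`` bounds the
    segment budget of the binseg/segneigh searches.
    """

    search: str = "pelt"
    penalty_value: float | None = None
    min_seg_len: int = 2
    max_segments: int | None = None

    def __post_init__(self) -> None:
        if self.search not in SEARCH_ALGORITHMS:
            raise ValueError(
                f"unknown search {self.search!r}; expected one of {SEARCH_ALGORITHMS}"
            )
        if self.penalty_value is not None and self.penalty_value <= 0:
            raise ValueError("penalty_value must be positive")
        if self.min_seg_len < 1:
            raise ValueError("min_seg_len must be >= 1")

    def resolve_penalty(self, n: int) -> float:
        if self.penalty_value is not None:
            return float(self.penalty_value)
        return bic_penalty(n)


@dataclass(frozen=True)
class ChangepointResult:
    """Changepoints as 1-based indices of each segment's last observation.

    The final index always equals the sequence length, so ``changepoints``
    has one entry per segment.  ``total_objective`` is the penalized
    objective ``sum(segment cost + beta)`` of the returned segmentation.
    """

    changepoints: tuple[int, ...]
    total_objective: float

    @property
    def n_segments(self) -> int:
        return len(self.changepoints)


def compute_imd(
    positions: Sequence[int] | np.ndarray,
    chromosome_length: int,
    chromosome: str = "",
) -> ImdSequence:
    """Intermutation distances of sorted variant positions on one chromosome.

    ``imds[0]`` is the distance from the chromosome start (position 0) to the
    first variant; the pseudo-IMD closes the chromosome so that
    ``pseudo_imd + sum(imds) == chromosome_length`` holds exactly.

    Raises
    ------
    ValueError
        If ``positions`` is empty, not strictly increasing, or exceeds
        ``chromosome_length``.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        raise ValueError("empty position list: chromosome has no variants")
    if pos.size > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")
    if pos[0] < 1:
        raise ValueError("positions are 1-based; got position < 1")
    if pos[-1] > chromosome_length:
        raise ValueError(
            f"position {pos[-1]} exceeds chromosome length {chromosome_length}"
        )
    imds = np.empty_like(pos)
    imds[0] = pos[0]
    imds[1:] = np.diff(pos)
    pseudo = int(chromosome_length - pos[-1])
    return ImdSequence(
        chromosome=chromosome,
        positions=pos,
        imds=imds,
        pseudo_imd=pseudo,
        chromosome_length=int(chromosome_length),
    )


def exp_segment_cost(prefix_sums: np.ndarray, a: int, b: int) -> float:
    """Exponential segment cost ``2*m*(ln S - ln m)`` for observations a..b.

    ``prefix_sums`` is the cumulative-sum array with leading 0, i.e.
    ``prefix_sums[i] = sum(obs[:i])``; ``a`` and ``b`` are 1-based inclusive
    observation indices.  The cost equals twice the negative maximized
    exponential log-likelihood of the segment with additive constants
    dropped, so costs are comparable across segmentations.
    """
    if not 1 <= a <= b:
        raise ValueError("require 1 <= a <= b")
    m = b - a + 1
    s = prefix_sums[b] - prefix_sums[a - 1]
    if s <= 0:
        raise ValueError("segment sum must be positive for exponential cost")
    return 2.0 * m * (math.log(s) - math.log(m))


def bic_penalty(n: int) -> float:
    """BIC per-changepoint penalty ``2*ln(n)``.

    Each extra segment introduces one free exponential rate and one
    changepoint location, hence two parameters at ``ln(n)`` apiece.
    """
    if n < 2:
        raise ValueError("BIC penalty requires sequence length >= 2")
    return 2.0 * math.log(n)


def _prefix_sums(observations: np.ndarray) -> np.ndarray:
    cs = np.empty(observations.size + 1, dtype=np.float64)
    cs[0] = 0.0
    np.cumsum(observations, out=cs[1:])
    return cs


def _validate_observations(observations) -> np.ndarray:
    obs = np.asarray(observations, dtype=np.float64)
    if obs.ndim != 1:
        raise ValueError("observations must be one-dimensional")
    if obs.size and obs.min() <= 0:
        raise ValueError("all observations must be positive")
    return obs


def _penalized_objective(cs: np.ndarray, cps: Sequence[int], beta: float) -> float:
    total = 0.0
    a = 1
    for b in cps:
        total += exp_segment_cost(cs, a, b) + beta
        a = b + 1
    return total


def _result(cs: np.ndarray, cps: Sequence[int], beta: float) -> ChangepointResult:
    cps = tuple(int(c) for c in cps)
    return ChangepointResult(
        changepoints=cps, total_objective=_penalized_objective(cs, cps, beta)
    )


def _single_segment_result(cs: np.ndarray, beta: float) -> ChangepointResult:
    n = cs.size - 1
    if n == 0:
        return ChangepointResult(changepoints=(), total_objective=0.0)
    return _result(cs, (n,), beta)


# ---------------------------------------------------------------------------
# PELT via functional pruning.
#
# Candidate t's contribution to the DP, as a function of the last segment's
# mean mu, is F[t] + beta + 2*(S/mu + c*log(mu)) with S, c the sum and count
# of observations past t (twice the negative exponential log-likelihood at
# mean mu; its minimum over mu exceeds the profiled cost used elsewhere by
# the constant 2c, which cancels between candidates).  In z = log(mu) this is
# a + 2b*exp(-z) + 2c*z: convex, so the pointwise minimum over candidates is
# a piecewise envelope whose pieces are intervals.  Candidates that vanish
# from the envelope can never be optimal again and are dropped.
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _fpop_root(da, db, dc, lo, hi, flo, fhi):  # pragma: no cover
    """Root of da + 2*db*exp(-z) + 2*dc*z in [lo, hi] (signs of flo/fhi differ).

    Safeguarded Newton iteration: steps falling outside the bracket fall
    back to bisection.
    """
    z = 0.5 * (lo + hi)
    for _ in range(200):
        f = da + 2.0 * db * math.exp(-z) + 2.0 * dc * z
        if (f > 0.0) == (flo > 0.0):
            lo = z
        else:
            hi = z
        df = -2.0 * db * math.exp(-z) + 2.0 * dc
        if df != 0.0:
            zn = z - f / df
        else:
            zn = 0.5 * (lo + hi)
        if not (lo < zn < hi):
            zn = 0.5 * (lo + hi)
        if abs(zn - z) < 1e-13 * (1.0 + abs(z)):
            return zn
        z = zn
    return z


@numba.njit(cache=True)
def _fpop_core(x, cs, beta, minseg, zmin, zmax):  # pragma: no cover
    n = x.shape[0]
    F = np.empty(n + 1)
    F[0] = 0.0
    for i in range(1, min(minseg, n + 1)):
        F[i] = np.inf
    prev = np.zeros(n + 1, np.int64)
    maxp = 16384
    zl = np.empty(maxp)
    zr = np.empty(maxp)
    pa = np.empty(maxp)
    pb = np.empty(maxp)
    pc = np.empty(maxp)
    pt = np.empty(maxp, np.int64)
    nzl = np.empty(maxp)
    nzr = np.empty(maxp)
    npa = np.empty(maxp)
    npb = np.empty(maxp)
    npc = np.empty(maxp)
    npt = np.empty(maxp, np.int64)
    npieces = 0
    for s in range(1, n + 1):
        tau = s - minseg
        if tau >= 0 and (tau == 0 or tau >= minseg) and np.isfinite(F[tau]):
            # candidate curve over the minseg-1 points tau+1 .. s-1
            ha = F[tau] + beta
            hb = cs[s - 1] - cs[tau]
            hc = float(minseg - 1)
            if npieces == 0:
                zl[0] = zmin
                zr[0] = zmax
                pa[0] = ha
                pb[0] = hb
                pc[0] = hc
                pt[0] = tau
                npieces = 1
            else:
                # new envelope = pointwise min(current envelope, candidate curve)
                k = 0
                for i in range(npieces):
                    lo = zl[i]
                    hi = zr[i]
                    da = pa[i] - ha
                    db = pb[i] - hb
                    dc = pc[i] - hc
                    flo = da + 2.0 * db * math.exp(-lo) + 2.0 * dc * lo
                    fhi = da + 2.0 * db * math.exp(-hi) + 2.0 * dc * hi
                    # the difference curve is monotone except across its
                    # single critical point, so it has at most two roots
                    zc = -np.inf
                    if (db > 0.0 and dc > 0.0) or (db < 0.0 and dc < 0.0):
                        zc = math.log(db / dc)
                    nroots = 0
                    r1 = 0.0
                    r2 = 0.0
                    if lo < zc < hi:
                        fc = da + 2.0 * db * math.exp(-zc) + 2.0 * dc * zc
                        if (fc > 0.0) != (flo > 0.0):
                            r1 = _fpop_root(da, db, dc, lo, zc, flo, fc)
                            nroots += 1
                        if (fc > 0.0) != (fhi > 0.0):
                            r2 = _fpop_root(da, db, dc, zc, hi, fc, fhi)
                            if nroots == 0:
                                r1 = r2
                            nroots += 1
                    else:
                        if (flo > 0.0) != (fhi > 0.0):
                            r1 = _fpop_root(da, db, dc, lo, hi, flo, fhi)
                            nroots += 1
                    b0 = lo
                    for j in range(nroots + 1):
                        if j == 0 and nroots >= 1:
                            b1 = r1
                        elif j == 1 and nroots == 2:
                            b1 = r2
                        else:
                            b1 = hi
                        if b1 <= b0 + 1e-12:
                            b0 = b1
                            continue
                        zm = 0.5 * (b0 + b1)
                        dm = da + 2.0 * db * math.exp(-zm) + 2.0 * dc * zm
                        if dm <= 0.0:
                            wa, wb, wc, wt = pa[i], pb[i], pc[i], pt[i]
                        else:
                            wa, wb, wc, wt = ha, hb, hc, tau
                        if k > 0 and npt[k - 1] == wt and nzr[k - 1] == b0:
                            nzr[k - 1] = b1
                        else:
                            if k >= maxp:
                                raise RuntimeError("changepoint envelope overflow")
                            nzl[k] = b0
                            nzr[k] = b1
                            npa[k] = wa
                            npb[k] = wb
                            npc[k] = wc
                            npt[k] = wt
                            k += 1
                        b0 = b1
                for i in range(k):
                    zl[i] = nzl[i]
                    zr[i] = nzr[i]
                    pa[i] = npa[i]
                    pb[i] = npb[i]
                    pc[i] = npc[i]
                    pt[i] = npt[i]
                npieces = k
        # extend every candidate's segment by observation s
        xs = x[s - 1]
        for i in range(npieces):
            pb[i] += xs
            pc[i] += 1.0
        if s < minseg or npieces == 0:
            if s >= minseg:
                F[s] = np.inf
            continue
        best = np.inf
        argt = 0
        for i in range(npieces):
            zstar = math.log(pb[i] / pc[i])
            if zstar < zl[i]:
                zstar = zl[i]
            elif zstar > zr[i]:
                zstar = zr[i]
            v = pa[i] + 2.0 * pb[i] * math.exp(-zstar) + 2.0 * pc[i] * zstar
            if v < best or (v == best and pt[i] < argt):
                best = v
                argt = pt[i]
        F[s] = best
        prev[s] = argt
    return F, prev


@numba.njit(cache=True)
def _pelt_quadratic_core(cs, beta, minseg):  # pragma: no cover
    """Classic PELT: O(n^2) scan with inequality pruning (constant K=0)."""
    n = cs.shape[0] - 1
    F = np.empty(n + 1)
    F[0] = -beta
    prev = np.zeros(n + 1, np.int64)
    cand = np.empty(n + 1, np.int64)
    vals = np.empty(n + 1)
    ncand = 0
    for s in range(minseg, n + 1):
        tau = s - minseg
        if tau == 0 or tau >= minseg:
            cand[ncand] = tau
            ncand += 1
        best = np.inf
        argt = 0
        for i in range(ncand):
            t = cand[i]
            m = s - t
            v = F[t] + 2.0 * m * (np.log(cs[s] - cs[t]) - np.log(m))
            vals[i] = v
            if v < best:
                best = v
                argt = t
        F[s] = best + beta
        prev[s] = argt
        k = 0
        for i in range(ncand):
            if vals[i] <= best + beta:
                cand[k] = cand[i]
                k += 1
        ncand = k
    return F, prev


def _traceback(prev: np.ndarray, n: int) -> tuple[int, ...]:
    cps = [n]
    t = int(prev[n])
    while t > 0:
        cps.append(t)
        t = int(prev[t])
    return tuple(reversed(cps))


def pelt(observations, params: ChangepointParams | None = None) -> ChangepointResult:
    """Exact penalized changepoint search (PELT with functional pruning).

    Minimises ``sum over segments of [cost + beta]`` over all segmentations
    whose segments each contain at least ``min_seg_len`` observations; the
    result is identical to unpruned optimal partitioning.
    """
    params = params or ChangepointParams()
    obs = _validate_observations(observations)
    n = obs.size
    cs = _prefix_sums(obs)
    beta = params.resolve_penalty(max(n, 2))
    if n < 2 * params.min_seg_len:
        return _single_segment_result(cs, beta)
    zmin = math.log(obs.min()) - 2.0
    zmax = math.log(cs[n]) + 2.0
    _, prev = _fpop_core(obs, cs, beta, params.min_seg_len, zmin, zmax)
    return _result(cs, _traceback(prev, n), beta)


def _pelt_quadratic(
    observations, params: ChangepointParams | None = None
) -> ChangepointResult:
    """Inequality-pruned O(n^2) PELT; cross-check for the envelope solver."""
    params = params or ChangepointParams()
    obs = _validate_observations(observations)
    n = obs.size
    cs = _prefix_sums(obs)
    beta = params.resolve_penalty(max(n, 2))
    if n < 2 * params.min_seg_len:
        return _single_segment_result(cs, beta)
    _, prev = _pelt_quadratic_core(cs, beta, params.min_seg_len)
    return _result(cs, _traceback(prev, n), beta)


def brute_force_partition(
    observations, params: ChangepointParams | None = None
) -> ChangepointResult:
    """Unpruned optimal partitioning (O(n^2)); the oracle for `pelt`.

    Pure-Python dynamic program with the same tie-breaking (smallest
    admissible previous endpoint wins ties); intended for short sequences.
    """
    params = params or ChangepointParams()
    obs = _validate_observations(observations)
    n = obs.size
    minseg = params.min_seg_len
    cs = _prefix_sums(obs)
    beta = params.resolve_penalty(max(n, 2))
    if n < 2 * minseg:
        return _single_segment_result(cs, beta)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    for s in range(minseg, n + 1):
        best = np.inf
        argt = 0
        for t in range(0, s - minseg + 1):
            if t != 0 and t < minseg:
                continue
            if not np.isfinite(F[t]):
                continue
            m = s - t
            v = F[t] + 2.0 * m * (math.log(cs[s] - cs[t]) - math.log(m))
            if v < best:
                best = v
                argt = t
        F[s] = best + beta
        prev[s] = argt
    return _result(cs, _traceback(prev, n), beta)


def _split_gains(cs: np.ndarray, a: int, b: int, minseg: int):
    """Cost reduction of every admissible single split of observations a..b."""
    whole = exp_segment_cost(cs, a, b)
    t = np.arange(a + minseg - 1, b - minseg + 1)
    if t.size == 0:
        return t, np.empty(0)
    ml = t - a + 1
    mr = b - t
    sl = cs[t] - cs[a - 1]
    sr = cs[b] - cs[t]
    left = 2.0 * ml * (np.log(sl) - np.log(ml))
    right = 2.0 * mr * (np.log(sr) - np.log(mr))
    return t, whole - (left + right)


def binseg(observations, params: ChangepointParams | None = None) -> ChangepointResult:
    """Greedy binary segmentation: recursively apply the best single split.

    At each round the split with the largest cost reduction over all current
    segments is applied if the reduction exceeds the penalty beta.  Fast but
    only approximate: on adversarial inputs the greedy first split can be
    suboptimal, so the objective is >= the PELT objective.
    """
    params = params or ChangepointParams(search="binseg")
    obs = _validate_observations(observations)
    n = obs.size
    minseg = params.min_seg_len
    cs = _prefix_sums(obs)
    beta = params.resolve_penalty(max(n, 2))
    if n < 2 * minseg:
        return _single_segment_result(cs, beta)
    bounds = [(1, n)]
    max_segs = params.max_segments or n
    while len(bounds) < max_segs:
        best_gain, best_i, best_t = -np.inf, -1, -1
        for i, (a, b) in enumerate(bounds):
            if b - a + 1 < 2 * minseg:
                continue
            t, gains = _split_gains(cs, a, b, minseg)
            if t.size == 0:
                continue
            j = int(np.argmin(-gains))  # first maximum -> earliest split on ties
            if gains[j] > best_gain:
                best_gain, best_i, best_t = float(gains[j]), i, int(t[j])
        if best_i < 0 or best_gain <= beta:
            break
        a, b = bounds[best_i]
        bounds[best_i : best_i + 1] = [(a, best_t), (best_t + 1, b)]
    return _result(cs, [b for _, b in bounds], beta)


def segneigh(observations, params: ChangepointParams | None = None) -> ChangepointResult:
    """Segment-neighborhood search: exact optimum over <= Q segments.

    Dynamic program in O(Q n^2); with an unbounded budget and the same
    penalty it attains the same objective as PELT.  Intended for short
    sequences or small budgets.
    """
    params = params or ChangepointParams(search="segneigh")
    obs = _validate_observations(observations)
    n = obs.size
    minseg = params.min_seg_len
    cs = _prefix_sums(obs)
    beta = params.resolve_penalty(max(n, 2))
    if n < 2 * minseg:
        return _single_segment_result(cs, beta)
    q_max = min(params.max_segments or n // minseg, n // minseg)
    D = np.full((q_max + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    arg = np.zeros((q_max + 1, n + 1), dtype=np.int64)
    for q in range(1, q_max + 1):
        for s in range(q * minseg, n + 1):
            best, argt = np.inf, 0
            for t in range((q - 1) * minseg, s - minseg + 1):
                if not np.isfinite(D[q - 1, t]):
                    continue
                v = D[q - 1, t] + exp_segment_cost(cs, t + 1, s)
                if v < best:
                    best, argt = v, t
            D[q, s] = best
            arg[q, s] = argt
    objectives = np.full(q_max + 1, np.inf)
    for q in range(1, q_max + 1):
        if np.isfinite(D[q, n]):
            objectives[q] = D[q, n] + q * beta
    q_star = int(np.argmin(objectives))  # first minimum -> fewest segments on ties
    cps = []
    s = n
    for q in range(q_star, 0, -1):
        cps.append(s)
        s = int(arg[q, s])
    return _result(cs, list(reversed(cps)), beta)


def amoc(observations, params: ChangepointParams | None = None) -> ChangepointResult:
    """At-most-one-change: the best single changepoint, if it pays for itself."""
    params = params or ChangepointParams(search="amoc")
    obs = _validate_observations(observations)
    n = obs.size
    minseg = params.min_seg_len
    cs = _prefix_sums(obs)
    beta = params.resolve_penalty(max(n, 2))
    if n < 2 * minseg:
        return _single_segment_result(cs, beta)
    t, gains = _split_gains(cs, 1, n, minseg)
    j = int(np.argmin(-gains))
    if gains[j] > beta:
        return _result(cs, (int(t[j]), n), beta)
    return _result(cs, (n,), beta)


_SEARCH_FUNCS = {
    "pelt": pelt,
    "binseg": binseg,
    "segneigh": segneigh,
    "amoc": amoc,
}


def segment_observations(observations, params: ChangepointParams) -> ChangepointResult:
    """Dispatch to the search algorithm named in ``params.search``."""
    return _SEARCH_FUNCS[params.search](observations, params)
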