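"""Saliency/intensity matching between stimulus conditions, and the paired
statistics (two-tailed t and JZS Bayes factor) that certify a match.

Two procedures are implemented:

* subject-level counterbalancing — select a subgroup of subjects whose
  per-subject rating differences (pain minus the other modality) cancel as
  closely as possible, taking all subjects of the minority sign plus an
  equal-sized subset of the majority sign;
* trial-level greedy matching — pair each laser (pain) trial with the
  unused electrical (touch) trial whose rating is closest, within a
  tolerance of ±0.5 rating units; lasers with no admissible partner are
  discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import integrate, stats
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TrialPairing", "MatchReport",
    "select_counterbalanced_subjects", "match_trials_greedy",
    "match_trials_optimal", "validate_match", "jzs_bf01",
]


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def jzs_bf01(t: float, n: int, scale: float = 1.0) -> float:
    """Jeffreys-Zellner-Siow Bayes factor BF01 (null over alternative) for a
    one-sample / paired t statistic.

    The alternative places a zero-centered Cauchy prior of width ``scale``
    on the standardized effect size, equivalent to integrating over
    g ~ scaled inverse-chi-square(1). BF01 > 1 favors the null. The default
    scale of 1.0 corresponds to the original "unit-information" JZS prior.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if scale <= 0:
        raise ValueError("prior scale must be positive")
    nu = n - 1
    t2 = float(t) ** 2
    null_ml = (1 + t2 / nu) ** (-(nu + 1) / 2)
    r2 = scale ** 2

    def integrand(g):
        c = 1 + n * g * r2
        return (c ** -0.5 * (1 + t2 / (c * nu)) ** (-(nu + 1) / 2)
                * (2 * math.pi) ** -0.5 * g ** -1.5 * math.exp(-1 / (2 * g)))

    alt_ml, err = integrate.quad(integrand, 0, np.inf, limit=300)
    if not np.isfinite(alt_ml) or alt_ml <= 0 or err > 1e-6 * alt_ml + 1e-12:
        raise RuntimeError(
            f"JZS quadrature did not converge (value={alt_ml}, err={err})")
    return null_ml / alt_ml


# ---------------------------------------------------------------------------
# subject counterbalancing
# ---------------------------------------------------------------------------

def select_counterbalanced_subjects(diffs: dict, exhaustive_limit: int = 20
                                    ) -> list:
    """Choose the subject subgroup that counterbalances rating differences.

    ``diffs`` maps subject id -> mean rating difference (pain minus the other
    modality). All subjects of the minority sign are kept, plus an
    equal-sized subset of the majority sign minimizing |sum of selected
    differences| (exhaustively when the majority group has at most
    ``exhaustive_limit`` members, greedily beyond). Ties break toward the
    smaller subset variance, then the lexicographically smallest ids.
    """
    ids = sorted(diffs)
    neg = [i for i in ids if diffs[i] < 0]
    pos = [i for i in ids if diffs[i] > 0]
    zero = [i for i in ids if diffs[i] == 0]
    if not neg or not pos:
        raise ValueError("counterbalancing impossible: all differences share one sign")
    minority, majority = (neg, pos) if len(neg) <= len(pos) else (pos, neg)
    k = len(minority)
    base = sum(diffs[i] for i in minority)
    if len(majority) <= exhaustive_limit:
        best = None
        for combo in combinations(majority, k):
            s = abs(base + sum(diffs[i] for i in combo))
            var = float(np.var([diffs[i] for i in combo])) if k else 0.0
            key = (round(s, 12), round(var, 12), combo)
            if best is None or key < best[0]:
                best = (key, combo)
        chosen = list(best[1])
    else:
        # greedy: repeatedly take the majority subject best cancelling the residual
        chosen, resid, pool = [], base, list(majority)
        for _ in range(k):
            nxt = min(pool, key=lambda i: (abs(resid + diffs[i]), i))
            chosen.append(nxt)
            resid += diffs[nxt]
            pool.remove(nxt)
    return sorted(minority + chosen + zero)


# ---------------------------------------------------------------------------
# trial matching
# ---------------------------------------------------------------------------

@dataclass
class TrialPairing:
    """Laser-electrical trial pairs with their absolute rating differences,
    plus the laser trials discarded for lack of an admissible partner."""

    pairs: list = field(default_factory=list)  # (laser_id, electrical_id, |diff|)
    discarded_lasers: list = field(default_factory=list)
    tol: float = 0.5

    @property
    def max_difference(self) -> float:
        return max((d for *_, d in self.pairs), default=0.0)

    def assert_valid(self) -> None:
        used = [e for _, e, _ in self.pairs]
        if len(used) != len(set(used)):
            raise AssertionError("an electrical trial was reused")
        if self.max_difference > self.tol + 1e-12:
            raise AssertionError("a pair exceeds the rating tolerance")


def match_trials_greedy(laser_ratings, electrical_ratings,
                        tol: float = 0.5) -> TrialPairing:
    """Pair each laser trial with the closest unused electrical trial whose
    rating lies within ±``tol``.

    Laser trials are processed in descending rating order; rating ties among
    candidate electrical trials break toward the lower trial id. Unmatched
    lasers are discarded.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    laser = np.asarray(laser_ratings, dtype=float)
    elec = np.asarray(electrical_ratings, dtype=float)
    order = sorted(range(len(laser)), key=lambda i: (-laser[i], i))
    used = np.zeros(len(elec), dtype=bool)
    pairing = TrialPairing(tol=tol)
    for li in order:
        cand = [(abs(elec[ei] - laser[li]), ei)
                for ei in range(len(elec))
                if not used[ei] and abs(elec[ei] - laser[li]) <= tol]
        if not cand:
            pairing.discarded_lasers.append(li)
            continue
        d, ei = min(cand)
        used[ei] = True
        pairing.pairs.append((li, ei, d))
    pairing.pairs.sort()
    pairing.discarded_lasers.sort()
    return pairing


def match_trials_optimal(laser_ratings, electrical_ratings,
                         tol: float = 0.5) -> TrialPairing:
    """Assignment-problem matcher (maximum pairs, then minimum total
    |difference|); a sensitivity check for the greedy procedure."""
    laser = np.asarray(laser_ratings, dtype=float)
    elec = np.asarray(electrical_ratings, dtype=float)
    nl, ne = len(laser), len(elec)
    if nl == 0 or ne == 0:
        return TrialPairing(discarded_lasers=list(range(nl)), tol=tol)
    diff = np.abs(laser[:, None] - elec[None, :])
    big = tol * max(nl, ne) * 1e6 + 1e6  # dominates any admissible total
    cost = np.where(diff <= tol, diff, big)
    rows, cols = linear_sum_assignment(cost)
    pairing = TrialPairing(tol=tol)
    for li, ei in zip(rows, cols):
        if diff[li, ei] <= tol:
            pairing.pairs.append((int(li), int(ei), float(diff[li, ei])))
        else:
            pairing.discarded_lasers.append(int(li))
    pairing.discarded_lasers.extend(set(range(nl)) - {li for li, *_ in pairing.pairs}
                                    - set(pairing.discarded_lasers))
    pairing.pairs.sort()
    pairing.discarded_lasers.sort()
    return pairing


# ---------------------------------------------------------------------------
# match validation
# ---------------------------------------------------------------------------

@dataclass
class MatchReport:
    t: float
    df: int
    p: float
    bf01: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("t", "df", "p", "bf01", "mean_a", "sd_a", "mean_b", "sd_b")}


def validate_match(a, b, scale: float = 1.0) -> MatchReport:
    """Two-tailed paired t-test plus the JZS BF01 certifying that paired
    values ``a`` and ``b`` do not differ."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1D arrays")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero-variance differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return MatchReport(t=float(t), df=n - 1, p=float(p),
                       bf01=jzs_bf01(float(t), n, scale=scale),
                       mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                       mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)))
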