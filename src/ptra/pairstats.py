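"""Ordered event-pair statistics with age/sex-matched resampled controls.

For an ordered pair of event labels (A, B) and a lag window of
``[lo, hi)`` days, the outcome rate among patients exposed to A
(anchored at each patient's *first* A) is

    OR_exposed = p_AB / (p_AB + p_AnotB)

where ``p_AB`` counts exposed patients with at least one B whose lag
after the anchor falls in the window.  An equal number of never-exposed
patients, matched for age and sex, is drawn at random; their outcome
rate ``OR_unexposed = p_ĀB / (p_ĀB + p_ĀB̄)`` uses a pseudo-anchor
placed at the calendar date where the control's age equals the matched
case's age at exposure (clamped into the control's follow-up).  The
relative risk is the ratio of the two rates; repeating the control draw
``n_resamples`` times yields an empirical p-value

    p = (1 + #{resamples with RR <= 1}) / (n_resamples + 1).

Pairs are retained when RR > 1 and p < 0.01 (both thresholds are
configurable; setting them to 0 and 1 turns the pipeline into a plain
pair-counting mode).  When a pair and its reverse both exceed RR 1, an
exact binomial test on the per-patient temporal order selects the more
prominent direction.
"""

from __future__ import annotations

import datetime as dt
import math
import random
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binomtest

from .cohort_io import Cohort, Sex
from .events import DiagnosticEvent

__all__ = [
    "TimeRange",
    "STUDY_WINDOWS",
    "PairCounts",
    "PairResult",
    "MatchingPolicy",
    "MatchingError",
    "EventIndex",
    "exposed_set",
    "outcome_rate_exposed",
    "sample_matched_controls",
    "relative_risk",
    "empirical_pair_test",
    "pair_table",
    "significance_filter",
    "direction_counts",
    "select_direction",
    "run_pair_analysis",
    "results_to_frame",
]


@dataclass(frozen=True)
class TimeRange:
    """Half-open lag window [lo, hi) in days after the anchor event."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid time range [{self.lo}, {self.hi})")

    def __str__(self) -> str:
        return f"[{self.lo},{self.hi})d"


#: The three standard observation windows: 0-1 y, 0-2 y and 1-5 y.
STUDY_WINDOWS: tuple[TimeRange, ...] = (
    TimeRange(0, 365),
    TimeRange(0, 730),
    TimeRange(365, 1826),
)


@dataclass(frozen=True)
class PairCounts:
    p_AB: int
    p_AnotB: int
    p_notA_B: int
    p_notA_notB: int

    def __post_init__(self) -> None:
        if self.p_AB + self.p_AnotB != self.p_notA_B + self.p_notA_notB:
            raise ValueError("matched control sample must equal the exposed count")


@dataclass(frozen=True)
class MatchingPolicy:
    """Control-matching configuration.

    Controls must never have event A; they match their case on sex and
    on age at anchor within ``age_tolerance_years``.  On exhaustion the
    age band is widened (x2, x4) and finally dropped; sex is never
    relaxed.  All draws are deterministic given ``seed``.

    Controls are drawn independently per case (with replacement across
    cases) by default: each matched control then contributes an
    independent Bernoulli outcome, so the resampled control count has
    the same dispersion as the exposed count and the empirical p-value
    stays calibrated.  Without-replacement draws from a finite pool are
    hypergeometric-underdispersed, which makes the test anti-conservative
    when the pool is not much larger than the exposed set; set
    ``with_replacement=False`` to get distinct-patient control sets at
    that price.
    """

    age_tolerance_years: float = 5.0
    match_sex: bool = True
    with_replacement: bool = True
    relax_on_exhaustion: bool = True
    seed: int = 0


@dataclass(frozen=True)
class PairResult:
    event_a: str
    event_b: str
    window: TimeRange
    counts: PairCounts  # from the first resample
    rr_mean: float
    rr_sd: float
    p_empirical: float
    n_patients: int  # = p_AB
    n_resamples: int
    frac_infinite: float = 0.0
    patients: frozenset[str] = frozenset()  # exposed patients with the outcome
    direction_flag: str = ""


class MatchingError(RuntimeError):
    """No admissible control exists for some exposed case."""


# ---------------------------------------------------------------------------
# Event index


class EventIndex:
    """Per-patient, per-label sorted event dates plus matching metadata.

    Dates are stored as proleptic-Gregorian ordinals so window checks
    reduce to integer searchsorted.  All cohort patients are indexed —
    including those without events — since they form the control pool.
    """

    def __init__(self, cohort: Cohort, events: Iterable[DiagnosticEvent], level: str = "sub"):
        self.level = level
        self.patient_ids: list[str] = [p.patient_id for p in cohort]
        self._pos = {pid: i for i, pid in enumerate(self.patient_ids)}
        n = len(self.patient_ids)
        self.birth = np.empty(n, dtype=np.int64)
        self.sex = np.empty(n, dtype=np.int8)  # 1 = female
        self.first_visit = np.empty(n, dtype=np.int64)
        self.last_visit = np.empty(n, dtype=np.int64)
        for i, p in enumerate(cohort):
            self.birth[i] = p.birth_date.toordinal()
            self.sex[i] = 1 if p.sex is Sex.FEMALE else 0
            self.first_visit[i] = (p.baseline_date or p.birth_date).toordinal()
            self.last_visit[i] = (p.last_visit_date or p.birth_date).toordinal()

        per_label: dict[str, dict[int, list[int]]] = {}
        for e in events:
            per_label.setdefault(e.label(level), {}).setdefault(
                self._pos[e.patient_id], []
            ).append(e.date.toordinal())
        self.dates: dict[str, dict[int, np.ndarray]] = {
            lab: {i: np.array(sorted(ds), dtype=np.int64) for i, ds in by_pat.items()}
            for lab, by_pat in per_label.items()
        }

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def position(self, patient_id: str) -> int:
        return self._pos[patient_id]

    def labels(self) -> list[str]:
        return sorted(self.dates)

    def patients_with(self, label: str) -> dict[int, np.ndarray]:
        return self.dates.get(label, {})


def _has_in_window(dates: np.ndarray, anchor: int, window: TimeRange) -> bool:
    i = int(np.searchsorted(dates, anchor + window.lo, side="left"))
    return i < len(dates) and dates[i] < anchor + window.hi


# ---------------------------------------------------------------------------
# Exposed side


def exposed_set(index: EventIndex, a: str) -> dict[str, dt.date]:
    """Patients with >= 1 event A, anchored at their first A."""
    return {
        index.patient_ids[i]: dt.date.fromordinal(int(ds[0]))
        for i, ds in index.patients_with(a).items()
    }


def outcome_rate_exposed(
    index: EventIndex, a: str, b: str, window: TimeRange
) -> tuple[int, int, float, frozenset[str]]:
    """(p_AB, p_AnotB, rate, patients-with-outcome) for the exposed side."""
    a_pat = index.patients_with(a)
    if not a_pat:
        raise ValueError(f"no patient is exposed to {a!r}; outcome rate undefined")
    b_pat = index.patients_with(b)
    hits = []
    for i, ds in a_pat.items():
        bd = b_pat.get(i)
        if bd is not None and _has_in_window(bd, int(ds[0]), window):
            hits.append(index.patient_ids[i])
    p_ab = len(hits)
    p_anotb = len(a_pat) - p_ab
    return p_ab, p_anotb, p_ab / len(a_pat), frozenset(hits)


def relative_risk(counts: PairCounts) -> float:
    """Ratio of exposed to unexposed outcome rates.

    An unexposed rate of zero yields ``inf`` (flagged upstream and
    counted as RR > 1 in the empirical tally), or ``nan`` if the
    exposed rate is also zero.
    """
    exposed = counts.p_AB / (counts.p_AB + counts.p_AnotB)
    n_unexp = counts.p_notA_B + counts.p_notA_notB
    unexposed = counts.p_notA_B / n_unexp if n_unexp else 0.0
    if unexposed == 0.0:
        return math.inf if exposed > 0 else math.nan
    return exposed / unexposed


# ---------------------------------------------------------------------------
# Matched-control machinery


def _pair_seed(seed: int, a: str, b: str, window: TimeRange) -> int:
    crc = zlib.crc32(f"{a}|{b}|{window.lo}|{window.hi}".encode())
    return (seed * 2654435761 + crc) % (2**31)


class _Matcher:
    """Precomputed candidate structure for one exposure label A.

    Stage 0 requires the control's follow-up to cover the case's age
    exactly (no clamping, zero age difference) *and* to leave at least
    the case's own effective observation window after the pseudo-anchor,
    so case and control observe the outcome over identical window
    lengths.  Later stages allow the age-aligned anchor to fall up to
    tol / 2 tol / 4 tol outside the follow-up (clamped in, bounding the
    age mismatch), then drop the age constraint, and as a last resort
    drop the residual-coverage requirement; sex is never relaxed.
    """

    def __init__(
        self,
        index: EventIndex,
        a: str,
        policy: MatchingPolicy,
        window: TimeRange | None = None,
    ):
        self.index = index
        self.policy = policy
        self.window = window
        a_pat = index.patients_with(a)
        self.case_idx = np.array(sorted(a_pat), dtype=np.int64)
        self.anchors = np.array([int(a_pat[i][0]) for i in self.case_idx], dtype=np.int64)
        # age of each case at anchor, in days since birth
        self.case_age_days = self.anchors - index.birth[self.case_idx]
        # effective observed window end per case: the case cannot show
        # an outcome at a lag beyond their own remaining follow-up
        residual = index.last_visit[self.case_idx] - self.anchors
        if window is not None:
            self.case_obs_hi = np.minimum(window.hi, residual)
        else:
            self.case_obs_hi = np.zeros(len(self.case_idx), dtype=np.int64)
        exposed_mask = np.zeros(index.n_patients, dtype=bool)
        exposed_mask[self.case_idx] = True
        self.pool_idx = np.flatnonzero(~exposed_mask)
        if len(self.pool_idx) == 0:
            raise MatchingError(f"every patient is exposed to {a!r}; no control pool")
        tol = policy.age_tolerance_years * 365.25
        if policy.relax_on_exhaustion:
            plan = [(0.0, True), (tol, True), (2 * tol, True), (4 * tol, True),
                    (None, True), (None, False)]
        else:
            plan = [(0.0, True), (tol, True)]
        self._stages = [self._eligibility(t, r) for t, r in plan]
        # scarcest cases pick first (deterministic tie-break by position)
        self._order = sorted(
            range(len(self.case_idx)), key=lambda i: (len(self._stages[0][i]), i)
        )

    def _eligibility(self, tol_days: float | None, residual: bool) -> list[list[int]]:
        """Per-case candidate lists (positions into pool_idx)."""
        idx = self.index
        pool = self.pool_idx
        out: list[list[int]] = []
        for k, (age_days, ci) in enumerate(zip(self.case_age_days, self.case_idx)):
            pa = idx.birth[pool] + age_days  # unclamped pseudo-anchors
            ok = np.ones(len(pool), dtype=bool)
            if self.policy.match_sex:
                ok &= idx.sex[pool] == idx.sex[ci]
            if tol_days is not None:
                ok &= (pa >= idx.first_visit[pool] - tol_days) & (
                    pa <= idx.last_visit[pool] + tol_days
                )
            if residual and self.window is not None:
                clamped = np.clip(pa, idx.first_visit[pool], idx.last_visit[pool])
                ok &= idx.last_visit[pool] - clamped >= self.case_obs_hi[k]
            out.append(np.flatnonzero(ok).tolist())
        return out

    def pseudo_anchor(self, case_pos: int, pool_pos: int) -> int:
        """Age-aligned anchor, clamped into the control's follow-up."""
        idx = self.index
        j = self.pool_idx[pool_pos]
        pa = int(idx.birth[j] + self.case_age_days[case_pos])
        return int(min(max(pa, idx.first_visit[j]), idx.last_visit[j]))

    def draw(self, rng: random.Random) -> list[int]:
        """One matched control set: pool position per case.

        Scarcest cases pick first; without replacement unless the
        policy says otherwise.
        """
        order = self._order
        chosen: list[int] = [-1] * len(self.case_idx)
        used: set[int] = set()
        replace_ok = self.policy.with_replacement
        for i in order:
            picked = -1
            for stage, cands in enumerate(s[i] for s in self._stages):
                if not cands:
                    continue
                for _ in range(16):
                    j = cands[rng.randrange(len(cands))]
                    if replace_ok or j not in used:
                        picked = j
                        break
                else:
                    avail = cands if replace_ok else [j for j in cands if j not in used]
                    if avail:
                        picked = avail[rng.randrange(len(avail))]
                if picked >= 0:
                    break
            if picked < 0:
                pid = self.index.patient_ids[self.case_idx[i]]
                raise MatchingError(
                    f"control pool exhausted for case {pid} "
                    f"(sex={'F' if self.index.sex[self.case_idx[i]] else 'M'}, "
                    f"age={self.case_age_days[i] / 365.25:.1f} y)"
                )
            chosen[i] = picked
            if not replace_ok:
                used.add(picked)
        return chosen

    def outcome_matrix(self, b: str, window: TimeRange) -> np.ndarray:
        """Bool matrix [case, pool]: does this control show B in window?

        Each control is observed over its case's *effective* window
        [lo, min(hi, case residual follow-up)), mirroring the window the
        case itself could have shown the outcome in.
        """
        idx = self.index
        b_pat = idx.patients_with(b)
        n_case, n_pool = len(self.case_idx), len(self.pool_idx)
        out = np.zeros((n_case, n_pool), dtype=bool)
        pa = idx.birth[self.pool_idx][None, :] + self.case_age_days[:, None]
        pa = np.clip(pa, idx.first_visit[self.pool_idx][None, :],
                     idx.last_visit[self.pool_idx][None, :])
        obs_hi = (
            self.case_obs_hi if self.window is not None
            else np.full(n_case, window.hi, dtype=np.int64)
        )
        for col, j in enumerate(self.pool_idx):
            bd = b_pat.get(int(j))
            if bd is None:
                continue
            col_pa = pa[:, col]
            k = np.searchsorted(bd, col_pa + window.lo, side="left")
            valid = k < len(bd)
            hit = np.zeros(n_case, dtype=bool)
            hit[valid] = bd[k[valid]] < col_pa[valid] + obs_hi[valid]
            out[:, col] = hit
        return out


def sample_matched_controls(
    index: EventIndex,
    exposed: Mapping[str, dt.date],
    a: str,
    policy: MatchingPolicy,
    rng: random.Random | None = None,
    window: TimeRange | None = None,
) -> list[tuple[str, dt.date]]:
    """Draw one age/sex-matched never-exposed control per exposed case.

    Returns (patient_id, pseudo-anchor date) pairs, one per case, in
    case order.  ``exposed`` must equal :func:`exposed_set` for ``a``.
    Passing ``window`` additionally requires controls to be observable
    over each case's effective outcome window.
    """
    matcher = _Matcher(index, a, policy, window=window)
    rng = rng or random.Random(policy.seed)
    chosen = matcher.draw(rng)
    return [
        (
            index.patient_ids[matcher.pool_idx[j]],
            dt.date.fromordinal(matcher.pseudo_anchor(i, j)),
        )
        for i, j in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# The empirical pair test


def _empirical_from_matcher(
    matcher: _Matcher,
    index: EventIndex,
    a: str,
    b: str,
    window: TimeRange,
    policy: MatchingPolicy,
    n_resamples: int,
) -> PairResult:
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    p_ab, p_anotb, exposed_rate, hit_patients = outcome_rate_exposed(index, a, b, window)
    n_exposed = p_ab + p_anotb
    outcome = matcher.outcome_matrix(b, window)
    rng = random.Random(_pair_seed(policy.seed, a, b, window))
    case_range = np.arange(n_exposed)

    rrs = np.empty(n_resamples)
    first_counts: PairCounts | None = None
    for r in range(n_resamples):
        chosen = matcher.draw(rng)
        n_ctrl_b = int(outcome[case_range, chosen].sum())
        counts = PairCounts(p_ab, p_anotb, n_ctrl_b, n_exposed - n_ctrl_b)
        if first_counts is None:
            first_counts = counts
        rrs[r] = relative_risk(counts)

    # nan (0/0) counts as RR <= 1; inf counts as RR > 1.
    le_one = np.sum(np.isnan(rrs) | (rrs <= 1.0))
    p_emp = (1 + int(le_one)) / (n_resamples + 1)
    finite = rrs[np.isfinite(rrs)]
    frac_inf = float(np.isinf(rrs).mean())
    rr_mean = float(finite.mean()) if len(finite) else math.inf
    rr_sd = float(finite.std(ddof=0)) if len(finite) else math.nan
    assert first_counts is not None
    return PairResult(
        event_a=a,
        event_b=b,
        window=window,
        counts=first_counts,
        rr_mean=rr_mean,
        rr_sd=rr_sd,
        p_empirical=p_emp,
        n_patients=p_ab,
        n_resamples=n_resamples,
        frac_infinite=frac_inf,
        patients=hit_patients,
    )


def empirical_pair_test(
    index: EventIndex,
    a: str,
    b: str,
    window: TimeRange,
    policy: MatchingPolicy | None = None,
    n_resamples: int = 10_000,
) -> PairResult:
    """RR of (A -> B) over ``n_resamples`` matched-control draws.

    Deterministic given ``policy.seed`` (each pair derives its own
    stream, so results do not depend on evaluation order).
    """
    policy = policy or MatchingPolicy()
    matcher = _Matcher(index, a, policy, window=window)
    return _empirical_from_matcher(matcher, index, a, b, window, policy, n_resamples)


def pair_table(
    index: EventIndex,
    window: TimeRange,
    policy: MatchingPolicy | None = None,
    n_resamples: int = 10_000,
    labels: Sequence[str] | None = None,
    min_pair_patients: int = 1,
) -> list[PairResult]:
    """All ordered pairs over ``labels`` (default: every indexed label).

    Pairs whose exposed-with-outcome count ``p_AB`` falls below
    ``min_pair_patients`` are skipped before resampling; they could
    never survive the downstream minimum-patient filter.
    """
    policy = policy or MatchingPolicy()
    labels = list(labels) if labels is not None else index.labels()
    results: list[PairResult] = []
    matchers: dict[str, _Matcher] = {}
    for a in labels:
        if not index.patients_with(a):
            continue
        for b in labels:
            if b == a or not index.patients_with(b):
                continue
            p_ab, *_ = outcome_rate_exposed(index, a, b, window)
            if p_ab < min_pair_patients:
                continue
            if a not in matchers:
                matchers[a] = _Matcher(index, a, policy, window=window)
            results.append(
                _empirical_from_matcher(
                    matchers[a], index, a, b, window, policy, n_resamples
                )
            )
    return results


# ---------------------------------------------------------------------------
# Filtering and direction selection


def significance_filter(
    results: Iterable[PairResult],
    rr_threshold: float = 1.0,
    p_threshold: float = 0.01,
) -> list[PairResult]:
    """Keep pairs with rr_mean > rr_threshold and p < p_threshold.

    Thresholds (0, 1) reproduce the count-everything mode: nothing is
    dropped.
    """
    results = list(results)
    if rr_threshold <= 0 and p_threshold >= 1:
        return results
    return [
        r
        for r in results
        if (math.isinf(r.rr_mean) or r.rr_mean > rr_threshold)
        and r.p_empirical < p_threshold
    ]


def direction_counts(index: EventIndex, a: str, b: str) -> tuple[int, int]:
    """(n_forward, n_reverse) over patients with both events.

    Forward means the patient's first A strictly precedes their first
    B; same-day firsts are ties and are dropped.
    """
    a_pat = index.patients_with(a)
    b_pat = index.patients_with(b)
    n_f = n_r = 0
    for i, ad in a_pat.items():
        bd = b_pat.get(i)
        if bd is None:
            continue
        if ad[0] < bd[0]:
            n_f += 1
        elif bd[0] < ad[0]:
            n_r += 1
    return n_f, n_r


def select_direction(
    forward: PairResult,
    reverse: PairResult,
    index: EventIndex | None = None,
    counts: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> list[PairResult]:
    """Pick the prominent direction when a pair and its reverse both pass.

    A two-sided exact binomial test compares how many patients show A
    strictly before B versus the opposite order (ties dropped).  If the
    test is significant at ``alpha`` the majority direction is kept;
    otherwise the direction with the larger RR is kept, flagged
    ``unresolved``.  When only one direction has RR > 1, it is kept
    without a test.
    """
    if (forward.event_a, forward.event_b) != (reverse.event_b, reverse.event_a):
        raise ValueError("forward and reverse must describe the same unordered pair")
    if forward.window != reverse.window:
        raise ValueError("forward and reverse must share the window")
    fwd_gt1 = math.isinf(forward.rr_mean) or forward.rr_mean > 1
    rev_gt1 = math.isinf(reverse.rr_mean) or reverse.rr_mean > 1
    if not (fwd_gt1 and rev_gt1):
        if fwd_gt1:
            return [forward]
        if rev_gt1:
            return [reverse]
        return []
    if counts is None:
        if index is None:
            raise ValueError("need either precomputed counts or an EventIndex")
        counts = direction_counts(index, forward.event_a, forward.event_b)
    n_f, n_r = counts
    if n_f + n_r > 0:
        p = binomtest(n_f, n_f + n_r, 0.5, alternative="two-sided").pvalue
        if p < alpha:
            winner = forward if n_f > n_r else reverse
            return [replace(winner, direction_flag="binomial")]
    winner = forward if forward.rr_mean >= reverse.rr_mean else reverse
    return [replace(winner, direction_flag="unresolved")]


def run_pair_analysis(
    index: EventIndex,
    window: TimeRange,
    policy: MatchingPolicy | None = None,
    n_resamples: int = 10_000,
    rr_threshold: float = 1.0,
    p_threshold: float = 0.01,
    min_pair_patients: int = 1,
    labels: Sequence[str] | None = None,
    select_directions: bool = True,
) -> list[PairResult]:
    """Full pair stage: test all pairs, filter, select directions.

    ``select_directions=False`` keeps both directions of every
    surviving pair, as in the count-everything mode.
    """
    results = pair_table(
        index,
        window,
        policy=policy,
        n_resamples=n_resamples,
        labels=labels,
        min_pair_patients=min_pair_patients,
    )
    kept = significance_filter(results, rr_threshold, p_threshold)
    if not select_directions:
        return kept
    by_pair = {(r.event_a, r.event_b): r for r in kept}
    out: list[PairResult] = []
    seen: set[frozenset[str]] = set()
    for r in kept:
        key = frozenset((r.event_a, r.event_b))
        if key in seen:
            continue
        rev = by_pair.get((r.event_b, r.event_a))
        if rev is None:
            out.append(r)
        else:
            seen.add(key)
            out.extend(select_direction(r, rev, index=index))
    return out


def results_to_frame(results: Iterable[PairResult], cohort_size: int) -> "pd.DataFrame":
    """Delimited-table view of pair results."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "event_a": r.event_a,
                "event_b": r.event_b,
                "window_lo_days": r.window.lo,
                "window_hi_days": r.window.hi,
                "n_patients": r.n_patients,
                "pct_of_cohort": 100.0 * r.n_patients / cohort_size if cohort_size else 0.0,
                "rr_mean": r.rr_mean,
                "rr_sd": r.rr_sd,
                "p_empirical": r.p_empirical,
                "n_resamples": r.n_resamples,
                "direction_flag": r.direction_flag,
            }
            for r in results
        ],
        columns=[
            "event_a", "event_b", "window_lo_days", "window_hi_days",
            "n_patients", "pct_of_cohort", "rr_mean", "rr_sd",
            "p_empirical", "n_resamples", "direction_flag",
        ],
    )
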