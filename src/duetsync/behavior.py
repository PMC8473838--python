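"""Trial-level error exclusion and behavioral synchrony measures.

A melody repetition is kept only if its played pitch sequence aligns to the
template without insertions or deletions: added or deleted tones disrupt the
timing of the pitch sequence, whereas a substituted pitch (wrong key, right
time) does not and is retained.  Retained repetitions yield quarter-note
level inter-onset intervals (IOIs) -- half notes are split at their temporal
midpoint and off-beat eighth notes are dropped -- from which performance
rates (Hz = 1000 / mean IOI in ms) and leader-follower onset asynchronies
(normalized by the mean duet IOI) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import PerformanceTrial
from .melody import COUNT_IN_EVENTS, MelodySpec

__all__ = [
    "ErrorClassification",
    "IOISeries",
    "AsynchronyResult",
    "classify_pitch_errors",
    "apply_error_filter",
    "quarter_level_iois",
    "duet_asynchronies",
    "aggregate_asynchronies",
    "detuning_vs_asynchrony",
    "duet_rate_regression",
    "RegressionResult",
]

# Alignment scoring: biased so that one substitution (-0.25) is cheaper than
# an insertion+deletion pair (-2); ties resolve toward substitution.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -0.25
INDEL_SCORE = -1.0


@dataclass
class ErrorClassification:
    """Outcome of aligning a played pitch stream to the melody template."""

    status: str                    # clean | substitution_only | excluded
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    reason: str | None = None
    matched_event_index: np.ndarray | None = None  # template index per played event

    @property
    def retained(self) -> bool:
        return self.status in ("clean", "substitution_only")


def _align(played: np.ndarray, template: np.ndarray) -> tuple[np.ndarray, int, int, int]:
    """Global (Needleman-Wunsch) alignment of played pitches to the template.

    Returns (matched_index per played event with -1 for insertions,
    n_substitutions, n_insertions, n_deletions).  Traceback ties break
    toward the diagonal (substitution) move.
    """
    n, m = len(played), len(template)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = INDEL_SCORE * np.arange(n + 1)
    score[0, :] = INDEL_SCORE * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(played[i - 1] == template, MATCH_SCORE, MISMATCH_SCORE)
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] + INDEL_SCORE,
                score[i, j - 1] + INDEL_SCORE,
            )
    matched = np.full(n, -1, dtype=int)
    n_sub = n_ins = n_del = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (
                MATCH_SCORE if played[i - 1] == template[j - 1] else MISMATCH_SCORE
            )
            if np.isclose(score[i, j], diag):  # prefer substitution on ties
                matched[i - 1] = j - 1
                if played[i - 1] != template[j - 1]:
                    n_sub += 1
                i, j = i - 1, j - 1
                continue
        if i > 0 and np.isclose(score[i, j], score[i - 1, j] + INDEL_SCORE):
            n_ins += 1  # played tone with no template counterpart
            i -= 1
        else:
            n_del += 1  # template tone never played
            j -= 1
    return matched, n_sub, n_ins, n_del


def classify_pitch_errors(
    trial: PerformanceTrial, melody: MelodySpec
) -> ErrorClassification:
    """Classify a repetition as clean, substitution-only, or excluded.

    Any insertion or deletion in the optimal alignment excludes the
    repetition; pitch substitutions alone retain it.  The alignment's
    template indices are returned so asynchrony pairing survives
    substitutions.  Follower repetitions that legitimately start at the 9th
    tone (the leader's count-in) are aligned against the truncated template.
    """
    if trial.n_events == 0:
        return ErrorClassification(status="excluded", reason="empty")
    template = np.array(melody.pitches, dtype=int)
    offset = 0
    first_nominal = int(trial.events["nominal_event_index"].iloc[0])
    if first_nominal == COUNT_IN_EVENTS:
        template = template[COUNT_IN_EVENTS:]
        offset = COUNT_IN_EVENTS
    matched, n_sub, n_ins, n_del = _align(trial.played_pitches, template)
    matched = np.where(matched >= 0, matched + offset, -1)
    if n_ins or n_del:
        return ErrorClassification(
            status="excluded", n_substitutions=n_sub,
            n_insertions=n_ins, n_deletions=n_del, reason="indel",
            matched_event_index=matched,
        )
    status = "substitution_only" if n_sub else "clean"
    return ErrorClassification(
        status=status, n_substitutions=n_sub, matched_event_index=matched
    )


def apply_error_filter(
    trials: list[PerformanceTrial], melody: MelodySpec
) -> tuple[list[PerformanceTrial], list[PerformanceTrial]]:
    """Split repetitions into (retained, excluded) and write match indices."""
    retained, excluded = [], []
    for tr in trials:
        cls = classify_pitch_errors(tr, melody)
        if cls.retained:
            ev = tr.events.copy()
            ev["matched_event_index"] = cls.matched_event_index
            retained.append(tr.with_events(ev, classification=cls.status))
        else:
            excluded.append(tr.with_events(tr.events, classification="excluded"))
    return retained, excluded


@dataclass
class IOISeries:
    """Quarter-note-level inter-onset intervals of one repetition."""

    values: np.ndarray  # ms, all > 0

    @property
    def mean_ioi_ms(self) -> float:
        return float(np.mean(self.values))

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.mean_ioi_ms


def quarter_level_iois(trial: PerformanceTrial, melody: MelodySpec) -> IOISeries:
    """Beat-level IOIs: off-beat eighths dropped, half notes midpoint-split.

    Each half note spans two beats, so a virtual onset is interpolated at
    the temporal midpoint between the half note's onset and the next played
    beat onset, yielding two equal IOIs where the notation has one long one.
    """
    ev = trial.events
    matched = np.asarray(ev["matched_event_index"], dtype=int)
    if np.all(matched < 0):
        raise ValueError("trial has no matched event indices; run the error filter first")
    onsets = trial.onsets_ms
    beat_onsets: list[float] = []
    pending_half: float | None = None
    for onset, idx in zip(onsets, matched):
        if idx < 0:
            continue
        event = melody.events[idx]
        if not event.is_on_beat:
            continue  # off-beat eighths excluded from rate computation
        if pending_half is not None:
            beat_onsets.append(0.5 * (pending_half + onset))
            pending_half = None
        beat_onsets.append(onset)
        if event.beat_value == 2:
            pending_half = onset
    if len(beat_onsets) < 2:
        raise ValueError("too short: fewer than 2 beat-level onsets")
    iois = np.diff(np.asarray(beat_onsets))
    if np.any(iois <= 0):
        raise ValueError("non-positive beat-level IOI")
    return IOISeries(values=iois)


@dataclass
class AsynchronyResult:
    """Leader-minus-follower onset asynchrony, as a proportion of duet IOI."""

    signed_mean: float
    absolute_mean: float
    n_events: int
    signed_mean_ms: float
    absolute_mean_ms: float
    mean_duet_ioi_ms: float


def duet_asynchronies(
    leader: PerformanceTrial, follower: PerformanceTrial, melody: MelodySpec
) -> AsynchronyResult:
    """Tone-onset asynchronies for one co-performed melody repetition.

    Asynchronies are computed over tones both partners played (matched via
    the alignment indices, so a substitution does not desynchronize the
    pairing), normalized by this repetition's mean duet IOI -- the average
    of the two performers' quarter-note-level mean IOIs.
    """
    ml = {int(i): t for t, i in zip(leader.onsets_ms, leader.events["matched_event_index"]) if i >= 0}
    mf = {int(i): t for t, i in zip(follower.onsets_ms, follower.events["matched_event_index"]) if i >= 0}
    common = sorted(set(ml) & set(mf))
    if not common:
        raise ValueError("no co-performed events between leader and follower")
    diffs = np.array([ml[i] - mf[i] for i in common])
    ioi = 0.5 * (
        quarter_level_iois(leader, melody).mean_ioi_ms
        + quarter_level_iois(follower, melody).mean_ioi_ms
    )
    return AsynchronyResult(
        signed_mean=float(np.mean(diffs) / ioi),
        absolute_mean=float(np.mean(np.abs(diffs)) / ioi),
        n_events=len(common),
        signed_mean_ms=float(np.mean(diffs)),
        absolute_mean_ms=float(np.mean(np.abs(diffs))),
        mean_duet_ioi_ms=ioi,
    )


def aggregate_asynchronies(results: list[AsynchronyResult]) -> AsynchronyResult:
    """Condition-level mean of per-repetition asynchrony results."""
    if not results:
        raise ValueError("no asynchrony results to aggregate")
    return AsynchronyResult(
        signed_mean=float(np.mean([r.signed_mean for r in results])),
        absolute_mean=float(np.mean([r.absolute_mean for r in results])),
        n_events=int(np.sum([r.n_events for r in results])),
        signed_mean_ms=float(np.mean([r.signed_mean_ms for r in results])),
        absolute_mean_ms=float(np.mean([r.absolute_mean_ms for r in results])),
        mean_duet_ioi_ms=float(np.mean([r.mean_duet_ioi_ms for r in results])),
    )


def detuning_vs_asynchrony(summary: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Spearman correlation of solo-rate detuning with signed duet asynchrony.

    ``summary`` needs one row per pair x condition with columns
    ``condition``, ``leader_solo_ioi_ms``, ``follower_solo_ioi_ms`` and
    ``signed_asynchrony``.  The detuning is Leader solo mean IOI minus
    Follower solo mean IOI; a positive correlation means slower leaders lag
    further behind their partner.
    """
    out = {}
    for condition, grp in summary.groupby("condition"):
        if len(grp) < 4:
            raise ValueError(f"need at least 4 pairs per condition, got {len(grp)}")
        detuning = grp["leader_solo_ioi_ms"] - grp["follower_solo_ioi_ms"]
        asym = grp["signed_asynchrony"]
        if detuning.nunique() == 1 or asym.nunique() == 1:
            raise ValueError("constant input: rank correlation undefined")
        rho, p = stats.spearmanr(detuning, asym)
        out[condition] = {"rho": float(rho), "p": float(p), "n": int(len(grp))}
    return out


@dataclass
class RegressionResult:
    beta_leader: float
    beta_follower: float
    r_squared: float
    f_pvalue: float
    n: int


def duet_rate_regression(
    leader_solo_rate: np.ndarray,
    follower_solo_rate: np.ndarray,
    duet_rate: np.ndarray,
) -> RegressionResult:
    """OLS predicting duet rate from both partners' solo rates (standardized).

    Standardized coefficients quantify how strongly each partner's
    spontaneous rate sets the duet tempo; a leader-paced duet shows
    ``beta_leader`` near 1 and ``beta_follower`` near 0.
    """
    import statsmodels.api as sm

    x1 = np.asarray(leader_solo_rate, float)
    x2 = np.asarray(follower_solo_rate, float)
    y = np.asarray(duet_rate, float)
    if len(y) < 4:
        raise ValueError("need at least 4 pairs")

    def z(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("constant predictor or outcome")
        return (v - v.mean()) / sd

    X = sm.add_constant(np.column_stack([z(x1), z(x2)]))
    if np.linalg.cond(X) > 1e8:
        raise ValueError("collinear predictors")
    fit = sm.OLS(z(y), X).fit()
    return RegressionResult(
        beta_leader=float(fit.params[1]),
        beta_follower=float(fit.params[2]),
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n=len(y),
    )
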