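"""Foot-strike candidate detection and post-processing heuristics.

A foot strike at the pelvis shows as a peak in the anterior-posterior (AP)
acceleration.  This module provides a baseline AP-peak candidate detector
(externally supplied candidate labels are accepted through the same path)
and two cleanup heuristics:

* **extra-prediction removal** — when several consecutive candidates crowd
  one AP peak, only the candidate nearest the peak apex is kept;
* **missed-step insertion** — an inter-strike gap at least ``gap_factor``
  (default 1.5) times the immediately preceding inter-strike duration is
  flagged, and a strike is inserted at the largest AP local maximum inside
  the gap, outside an adaptive locking period ``L`` on either side.  ``L``
  is ``locking_fraction`` x the trial's median inter-strike duration,
  recomputed once per insertion pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from gaitconf.errors import ValidationError
from gaitconf.preprocess import UniformTrial

logger = logging.getLogger(__name__)

SOURCES = ("detected", "external", "inserted")


@dataclass
class FootStrikeSeries:
    """Ordered foot-strike sample indices with provenance and side labels."""

    strikes: np.ndarray  # sample indices, strictly increasing
    source: np.ndarray  # per strike: detected / external / inserted
    sides: np.ndarray = field(default=None)  # left / right / unassigned

    def __post_init__(self) -> None:
        self.strikes = np.asarray(self.strikes, dtype=int)
        self.source = np.asarray(self.source, dtype=object)
        if self.sides is None:
            self.sides = np.full(self.strikes.size, "unassigned", dtype=object)
        self.sides = np.asarray(self.sides, dtype=object)
        if self.strikes.size and not np.all(np.diff(self.strikes) > 0):
            raise ValidationError("strike indices must be strictly increasing")
        if self.source.size != self.strikes.size or self.sides.size != self.strikes.size:
            raise ValidationError("source/sides must match strikes in length")
        bad = set(self.source) - set(SOURCES)
        if bad:
            raise ValidationError(f"unknown strike sources: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.strikes.size)

    def validate_against(self, trial: UniformTrial) -> None:
        if self.strikes.size and (
            self.strikes[0] < 0 or self.strikes[-1] >= trial.n_samples
        ):
            raise ValidationError("strike indices out of trial range")

    def times(self, rate: float) -> np.ndarray:
        return self.strikes / rate

    @classmethod
    def from_indices(cls, indices, source: str = "detected") -> "FootStrikeSeries":
        indices = np.asarray(indices, dtype=int)
        return cls(indices, np.full(indices.size, source, dtype=object))


@dataclass(frozen=True)
class CleanupConfig:
    gap_factor: float = 1.5
    locking_fraction: float = 0.5  # of the trial's median inter-strike duration
    max_insert_passes: int = 10

    def __post_init__(self) -> None:
        if self.gap_factor <= 1:
            raise ValidationError("gap_factor must be > 1")
        if not 0 < self.locking_fraction < 1:
            raise ValidationError("locking_fraction must be in (0, 1)")


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateau midpoints included)."""
    peaks, _ = signal.find_peaks(x)
    return peaks


def detect_candidates(
    trial: UniformTrial, prominence_factor: float = 0.3
) -> FootStrikeSeries:
    """Baseline candidate detector: prominent local maxima of the AP channel.

    The prominence threshold adapts to the trial: ``prominence_factor`` x the
    AP standard deviation.  A constant AP channel yields an empty series.
    """
    ap = trial.ap
    sd = float(np.std(ap))
    if sd == 0.0:
        return FootStrikeSeries.from_indices([])
    peaks, _ = signal.find_peaks(ap, prominence=prominence_factor * sd)
    return FootStrikeSeries.from_indices(peaks, source="detected")


def _nearest_apex_groups(
    candidates: np.ndarray, apexes: np.ndarray
) -> dict[int, list[int]]:
    """Assign each candidate to its nearest AP apex; ties go to the earlier apex."""
    groups: dict[int, list[int]] = {}
    pos = np.searchsorted(apexes, candidates)
    for cand, p in zip(candidates, pos):
        left = apexes[p - 1] if p > 0 else None
        right = apexes[p] if p < apexes.size else None
        if left is None:
            apex = right
        elif right is None:
            apex = left
        else:
            apex = left if cand - left <= right - cand else right
        groups.setdefault(int(apex), []).append(int(cand))
    return groups


def remove_extra_predictions(
    candidates: FootStrikeSeries,
    trial: UniformTrial,
    cfg: CleanupConfig | None = None,
) -> FootStrikeSeries:
    """Collapse runs of candidates crowding one AP peak to a single strike.

    Candidates sharing a nearest AP apex form one neighborhood; the member
    closest to the apex survives, with equidistant ties broken toward the
    earlier candidate.
    """
    if len(candidates) == 0:
        return candidates
    candidates.validate_against(trial)
    apexes = _local_maxima(trial.ap)
    if apexes.size == 0:
        return candidates
    keep_mask = np.zeros(len(candidates), dtype=bool)
    index_of = {int(s): i for i, s in enumerate(candidates.strikes)}
    for apex, members in _nearest_apex_groups(candidates.strikes, apexes).items():
        # min() on (distance, candidate) keeps the earlier candidate on ties
        best = min(members, key=lambda c: (abs(c - apex), c))
        keep_mask[index_of[best]] = True
    return FootStrikeSeries(
        candidates.strikes[keep_mask],
        candidates.source[keep_mask],
        candidates.sides[keep_mask],
    )


def _locking_samples(strikes: np.ndarray, cfg: CleanupConfig) -> int:
    durations = np.diff(strikes)
    return max(1, int(round(cfg.locking_fraction * float(np.median(durations)))))


def flag_gaps(strikes: np.ndarray, gap_factor: float) -> np.ndarray:
    """Indices i such that the gap (strike i -> i+1) is >= gap_factor x the
    previous gap.  The first gap has no predecessor and is never flagged."""
    d = np.diff(strikes)
    if d.size < 2:
        return np.array([], dtype=int)
    return np.flatnonzero(d[1:] >= gap_factor * d[:-1]) + 1


def insert_missed_steps(
    strikes: FootStrikeSeries,
    trial: UniformTrial,
    cfg: CleanupConfig | None = None,
) -> FootStrikeSeries:
    """Insert strikes at AP peaks inside abnormally long inter-strike gaps.

    Runs repeated passes (each pass recomputes the adaptive locking period)
    until no gap is flagged or ``max_insert_passes`` is reached.  With fewer
    than 3 strikes the series is returned unchanged with a warning.
    """
    cfg = cfg or CleanupConfig()
    if len(strikes) < 3:
        logger.warning(
            "trial %r: %d strikes, too few for missed-step insertion",
            trial.participant_id,
            len(strikes),
        )
        return strikes
    strikes.validate_against(trial)
    apexes = _local_maxima(trial.ap)
    ap = trial.ap
    idx = strikes.strikes.copy()
    src = list(strikes.source)
    for _ in range(cfg.max_insert_passes):
        L = _locking_samples(idx, cfg)
        flagged = flag_gaps(idx, cfg.gap_factor)
        inserted: list[int] = []
        for g in flagged:
            lo, hi = idx[g] + L, idx[g + 1] - L
            window = apexes[(apexes >= lo) & (apexes <= hi)]
            if window.size == 0:
                continue
            inserted.append(int(window[np.argmax(ap[window])]))
        inserted = [i for i in inserted if i not in set(idx)]
        if not inserted:
            break
        idx = np.concatenate([idx, inserted])
        src = src + ["inserted"] * len(inserted)
        order = np.argsort(idx)
        idx = idx[order]
        src = [src[i] for i in order]
    return FootStrikeSeries(idx, np.asarray(src, dtype=object))


def _enforce_min_separation(
    series: FootStrikeSeries, trial: UniformTrial, cfg: CleanupConfig
) -> FootStrikeSeries:
    """Drop the weaker of any strike pair closer than the locking period."""
    if len(series) < 3:
        return series
    ap = trial.ap
    idx = list(series.strikes)
    src = list(series.source)
    changed = True
    while changed and len(idx) >= 3:
        changed = False
        L = _locking_samples(np.asarray(idx), cfg)
        for i in range(len(idx) - 1):
            if idx[i + 1] - idx[i] < L:
                drop = i if ap[idx[i]] < ap[idx[i + 1]] else i + 1
                del idx[drop], src[drop]
                changed = True
                break
    return FootStrikeSeries(np.asarray(idx, dtype=int), np.asarray(src, dtype=object))


def clean_footstrikes(
    candidates: FootStrikeSeries,
    trial: UniformTrial,
    cfg: CleanupConfig | None = None,
) -> FootStrikeSeries:
    """Full cleanup: extra-prediction removal, missed-step insertion, and a
    final minimum-separation pass; result sorted and deduplicated."""
    cfg = cfg or CleanupConfig()
    out = remove_extra_predictions(candidates, trial, cfg)
    out = insert_missed_steps(out, trial, cfg)
    # dedupe (insertion already avoids duplicates; belt and braces)
    _, unique_idx = np.unique(out.strikes, return_index=True)
    out = FootStrikeSeries(out.strikes[unique_idx], out.source[unique_idx])
    return _enforce_min_separation(out, trial, cfg)


def match_strikes(
    predicted_times: np.ndarray,
    true_times: np.ndarray,
    tolerance_s: float = 0.1,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of strike times within a tolerance.

    Returns (true positives, false positives, false negatives); used to
    score detection/cleanup against generator ground truth.
    """
    predicted = np.sort(np.asarray(predicted_times, dtype=float))
    truth = np.sort(np.asarray(true_times, dtype=float))
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for p in predicted:
        j = np.searchsorted(truth, p)
        best, best_d = -1, tolerance_s
        for k in (j - 1, j):
            if 0 <= k < truth.size and not used[k] and abs(truth[k] - p) <= best_d:
                best, best_d = k, abs(truth[k] - p)
        if best >= 0:
            used[best] = True
            tp += 1
    fp = predicted.size - tp
    fn = truth.size - tp
    return tp, int(fp), int(fn)


def strike_f1(
    predicted_times: np.ndarray, true_times: np.ndarray, tolerance_s: float = 0.1
) -> float:
    tp, fp, fn = match_strikes(predicted_times, true_times, tolerance_s)
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def read_strikes_csv(path) -> FootStrikeSeries:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("sample_index", "source", "side"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return FootStrikeSeries(
        df["sample_index"].to_numpy(int),
        df["source"].to_numpy(object),
        df["side"].to_numpy(object),
    )


def write_strikes_csv(series: FootStrikeSeries, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"sample_index": series.strikes, "source": series.source, "side": series.sides}
    ).to_csv(path, index=False)
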