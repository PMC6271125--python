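"""Extraction-time profiles: containers, CSV I/O, normalization, hold-out selection.

A profile is one replicate's series of (extraction time, GC peak area) pairs
for one compound under one condition (matrix + temperature).  Profiles arrive
in triplicate; the triplicate of one compound/condition is a
:class:`ReplicateSet`.  The CSV schema is::

    compound,condition,replicate,time_min,peak_area

Peak areas are normalized per run by the area at the final sampling time,
which the model treats as the equilibrium point, so every normalized run ends
at exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["compound", "condition", "replicate", "time_min", "peak_area"]

__all__ = [
    "CSV_COLUMNS",
    "ExtractionProfile",
    "ReplicateSet",
    "ProfileValidationError",
    "read_profiles",
    "write_profiles",
    "normalize_profile",
    "normalize_set",
    "observed_peak",
    "has_interior_peak",
    "select_validation_point",
]


class ProfileValidationError(ValueError):
    """Malformed profile data (schema, grouping, or ordering problems)."""


@dataclass(frozen=True)
class ExtractionProfile:
    """One replicate's extraction-time profile.

    ``holdout_index``, when set, marks the validation sample that is excluded
    from every fitting residual; ``fitting_times``/``fitting_areas`` give the
    fitting view.
    """

    compound: str
    condition: str
    replicate_id: int
    times: np.ndarray
    areas: np.ndarray
    normalized: bool = False
    holdout_index: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "areas", areas)
        if times.ndim != 1 or times.shape != areas.shape:
            raise ProfileValidationError("times and areas must be 1-D and aligned")
        if len(times) < 2:
            raise ProfileValidationError("a profile needs at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise ProfileValidationError(
                f"times must be strictly increasing ({self._label()})"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(areas))):
            raise ProfileValidationError(f"non-finite values in {self._label()}")
        if np.any(areas < 0):
            raise ProfileValidationError(f"negative peak area in {self._label()}")
        if self.normalized and abs(areas[-1] - 1.0) > 1e-9:
            raise ProfileValidationError(
                f"normalized profile must end at 1, got {areas[-1]} ({self._label()})"
            )
        if self.holdout_index is not None and not (
            0 <= self.holdout_index < len(times)
        ):
            raise ProfileValidationError("holdout_index out of range")

    def _label(self) -> str:
        return f"{self.compound}/{self.condition}/rep{self.replicate_id}"

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def holdout(self) -> tuple[float, float] | None:
        if self.holdout_index is None:
            return None
        i = self.holdout_index
        return float(self.times[i]), float(self.areas[i])

    @property
    def _fitting_mask(self) -> np.ndarray:
        mask = np.ones(self.n_points, dtype=bool)
        if self.holdout_index is not None:
            mask[self.holdout_index] = False
        return mask

    @property
    def fitting_times(self) -> np.ndarray:
        return self.times[self._fitting_mask]

    @property
    def fitting_areas(self) -> np.ndarray:
        return self.areas[self._fitting_mask]


@dataclass(frozen=True)
class ReplicateSet:
    """The triplicate profiles of one compound/condition."""

    profiles: tuple[ExtractionProfile, ...]

    def __post_init__(self) -> None:
        profiles = tuple(
            sorted(self.profiles, key=lambda p: p.replicate_id)
        )
        object.__setattr__(self, "profiles", profiles)
        if len(profiles) != 3:
            raise ProfileValidationError(
                f"a replicate set needs exactly 3 replicates, got {len(profiles)}"
                + (f" for {profiles[0]._label()}" if profiles else "")
            )
        keys = {(p.compound, p.condition) for p in profiles}
        if len(keys) != 1:
            raise ProfileValidationError(
                f"replicates mix compounds/conditions: {sorted(keys)}"
            )
        ids = [p.replicate_id for p in profiles]
        if len(set(ids)) != 3:
            raise ProfileValidationError(
                f"duplicate replicate ids {ids} for {profiles[0]._label()}"
            )

    @property
    def compound(self) -> str:
        return self.profiles[0].compound

    @property
    def condition(self) -> str:
        return self.profiles[0].condition

    @property
    def label(self) -> str:
        return f"{self.compound} @ {self.condition}"


def read_profiles(path) -> list[ReplicateSet]:
    """Read a profiles CSV into grouped, time-sorted replicate sets.

    Rows with non-finite peak areas are dropped with a logged reason.  Missing
    columns, groups without exactly three replicates, or duplicate times
    within a replicate raise :class:`ProfileValidationError` naming the
    offending group.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileValidationError(f"missing columns {missing} in {path}")
    bad = ~np.isfinite(pd.to_numeric(df["peak_area"], errors="coerce"))
    if bad.any():
        logger.warning(
            "dropping %d rows with non-finite peak_area from %s", int(bad.sum()), path
        )
        df = df[~bad]
    sets: list[ReplicateSet] = []
    for (compound, condition), group in df.groupby(
        ["compound", "condition"], sort=True
    ):
        reps = sorted(group["replicate"].unique())
        if len(reps) != 3:
            raise ProfileValidationError(
                f"{compound} @ {condition}: expected 3 replicates, found {len(reps)}"
            )
        profiles = []
        for rid in reps:
            sub = group[group["replicate"] == rid]
            times = sub["time_min"].to_numpy(dtype=float)
            if len(np.unique(times)) != len(times):
                raise ProfileValidationError(
                    f"{compound} @ {condition} rep {rid}: duplicate times"
                )
            order = np.argsort(times)
            if not np.all(order == np.arange(len(times))):
                logger.info(
                    "%s @ %s rep %s: times were unsorted; sorting", compound, condition, rid
                )
            profiles.append(
                ExtractionProfile(
                    compound=str(compound),
                    condition=str(condition),
                    replicate_id=int(rid),
                    times=times[order],
                    areas=sub["peak_area"].to_numpy(dtype=float)[order],
                )
            )
        sets.append(ReplicateSet(tuple(profiles)))
    if not sets:
        raise ProfileValidationError(f"no profile rows found in {path}")
    return sets


def write_profiles(sets: Iterable[ReplicateSet], path) -> Path:
    """Write replicate sets back to the CSV schema (inverse of read_profiles)."""
    rows = []
    for rs in sets:
        for p in rs.profiles:
            for t, a in zip(p.times, p.areas):
                rows.append(
                    {
                        "compound": p.compound,
                        "condition": p.condition,
                        "replicate": p.replicate_id,
                        "time_min": t,
                        "peak_area": a,
                    }
                )
    path = Path(path)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return path


def normalize_profile(profile: ExtractionProfile) -> ExtractionProfile:
    """Divide all areas by the area at the final sampling time of the run.

    The final sample is treated as the equilibrium point, so the normalized
    run ends at exactly 1.  Idempotent on already-normalized profiles.
    """
    last = profile.areas[-1]
    if last <= 0:
        raise ProfileValidationError(
            f"cannot normalize {profile._label()}: final area is {last}"
        )
    return ExtractionProfile(
        compound=profile.compound,
        condition=profile.condition,
        replicate_id=profile.replicate_id,
        times=profile.times,
        areas=profile.areas / last,
        normalized=True,
        holdout_index=profile.holdout_index,
    )


def normalize_set(rs: ReplicateSet) -> tuple[ReplicateSet, dict[int, float]]:
    """Normalize every replicate; returns the set plus per-replicate divisors."""
    divisors = {p.replicate_id: float(p.areas[-1]) for p in rs.profiles}
    return ReplicateSet(tuple(normalize_profile(p) for p in rs.profiles)), divisors


def observed_peak(profile: ExtractionProfile) -> tuple[float, float]:
    """The sample of maximal area; ties broken by earliest time."""
    i = int(np.argmax(profile.areas))
    return float(profile.times[i]), float(profile.areas[i])


def has_interior_peak(profile: ExtractionProfile) -> bool:
    """False when the maximum sits at the last sample (monotone rising run)."""
    return int(np.argmax(profile.areas)) < profile.n_points - 1


def select_validation_point(rs: ReplicateSet, default_time: float) -> ReplicateSet:
    """Mark the hold-out validation sample in every replicate.

    The sample at ``default_time`` is withheld unless it coincides with that
    replicate's observed peak, in which case the latest non-peak sample is
    taken instead.  ``default_time`` must exist in every replicate's grid.
    """
    out = []
    for p in rs.profiles:
        idx = np.flatnonzero(np.isclose(p.times, default_time))
        if idx.size == 0:
            raise ProfileValidationError(
                f"{p._label()}: validation time {default_time} not sampled; "
                f"available times: {p.times.tolist()}"
            )
        i = int(idx[0])
        peak_i = int(np.argmax(p.areas))
        if i == peak_i:
            candidates = [j for j in range(p.n_points - 1, -1, -1) if j != peak_i]
            i = candidates[0]
            logger.info(
                "%s: default validation point is the observed peak; "
                "holding out t=%g instead",
                p._label(),
                p.times[i],
            )
        out.append(
            ExtractionProfile(
                compound=p.compound,
                condition=p.condition,
                replicate_id=p.replicate_id,
                times=p.times,
                areas=p.areas,
                normalized=p.normalized,
                holdout_index=i,
            )
        )
    return ReplicateSet(tuple(out))
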