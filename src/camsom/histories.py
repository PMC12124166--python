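"""Detection histories and covariate preparation for camera-trap surveys.

Turns timestamped detection records into the species x station matrix of
occasion-level detection counts consumed by the multispecies abundance
model, bins a continuous deployment into fixed-length occasions, and
standardizes station covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "OccasionCalendar",
    "DetectionHistory",
    "load_focal_species",
    "scale_distances",
    "build_occasions",
    "build_history",
    "augment_history",
]


def load_focal_species() -> pd.DataFrame:
    """Load the bundled focal-species trait table.

    Columns: ``code``, ``scientific_name``, ``english_name``, ``taxon``,
    ``game`` (0/1), ``mass_kg``, ``recorded`` (0/1, whether the species
    appeared on camera in the original survey).
    """
    with resources.files("camsom.data").joinpath("focal_species.csv").open() as fh:
        traits = pd.read_csv(fh)
    if traits["code"].duplicated().any():
        raise ValueError("species codes must be unique")
    if (traits["mass_kg"] <= 0).any():
        raise ValueError("body masses must be positive")
    return traits


def scale_distances(distances) -> np.ndarray:
    """Standardize distances to mean 0 and SD 1 (sample SD, n-1 divisor).

    The transform is affine, so ordering is preserved and an already
    standardized input is returned unchanged (up to floating error).

    Raises
    ------
    ValueError
        If fewer than 2 values or all values identical (zero SD).
    """
    x = np.asarray(distances, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 distances to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant distance vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class OccasionCalendar:
    """Ordered, non-overlapping [start, end) day windows of a deployment."""

    starts: np.ndarray
    ends: np.ndarray
    partial: np.ndarray  # True where a window is shorter than the nominal length

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        partial = np.asarray(self.partial, dtype=bool)
        if not (len(starts) == len(ends) == len(partial)):
            raise ValueError("calendar arrays must have equal length")
        if np.any(ends <= starts):
            raise ValueError("each window must have end > start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("windows must be ordered and non-overlapping")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "partial", partial)

    @property
    def n_occasions(self) -> int:
        return len(self.starts)

    def assign(self, days) -> np.ndarray:
        """Map day offsets to occasion indices; -1 for days outside all windows."""
        days = np.asarray(days, dtype=float)
        idx = np.searchsorted(self.starts, days, side="right") - 1
        idx = np.where(
            (idx >= 0) & (days < self.ends[np.clip(idx, 0, self.n_occasions - 1)]),
            idx,
            -1,
        )
        return idx

    def retained(self, partial_policy: str) -> np.ndarray:
        if partial_policy == "keep":
            return np.ones(self.n_occasions, dtype=bool)
        if partial_policy == "drop":
            return ~self.partial
        raise ValueError(f"unknown partial_policy {partial_policy!r}")


def build_occasions(start_day: float, n_days: int, occasion_length: int) -> OccasionCalendar:
    """Bin ``n_days`` of continuous deployment into consecutive occasions.

    A trailing remainder shorter than ``occasion_length`` becomes a window
    flagged ``partial`` (e.g. 49 days at length 5 -> 9 full windows plus a
    4-day partial tenth).
    """
    if occasion_length < 1 or n_days < occasion_length:
        raise ValueError("need n_days >= occasion_length >= 1")
    edges = np.arange(start_day, start_day + n_days + occasion_length, occasion_length)
    edges = np.clip(edges, None, start_day + n_days)
    edges = np.unique(edges)
    starts, ends = edges[:-1], edges[1:]
    partial = (ends - starts) < occasion_length
    return OccasionCalendar(starts=starts, ends=ends, partial=partial)


@dataclass
class DetectionHistory:
    """Occasion-binned detection counts.

    ``Y[i, j]`` is the number of retained occasions with at least one record
    of species ``i`` at station ``j``; ``V[j]`` is the number of retained
    occasions at station ``j``.
    """

    Y: np.ndarray
    V: np.ndarray
    species: list[str]
    stations: list[str]
    augmented: np.ndarray = field(default=None)  # type: ignore[assignment]
    calendar: OccasionCalendar | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=int)
        self.V = np.asarray(self.V, dtype=int)
        if self.augmented is None:
            self.augmented = np.zeros(self.Y.shape[0], dtype=bool)
        self.augmented = np.asarray(self.augmented, dtype=bool)
        if self.Y.shape != (len(self.species), len(self.stations)):
            raise ValueError("Y must be (n_species, n_stations)")
        if self.V.shape != (len(self.stations),):
            raise ValueError("V must have one entry per station")
        if np.any(self.V < 1):
            raise ValueError("every station needs at least one occasion")
        if np.any(self.Y < 0) or np.any(self.Y > self.V[None, :]):
            raise ValueError("need 0 <= Y_ij <= V_j")
        if len(self.augmented) != self.Y.shape[0]:
            raise ValueError("augmented flags must match species rows")

    @property
    def n_species(self) -> int:
        return self.Y.shape[0]

    @property
    def n_stations(self) -> int:
        return self.Y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Y, index=self.species, columns=self.stations)
        df.index.name = "species"
        return df


def build_history(
    records: pd.DataFrame,
    stations: pd.DataFrame,
    species: pd.DataFrame,
    calendar: OccasionCalendar,
    partial_policy: str = "keep",
    survey_start=None,
) -> DetectionHistory:
    """Collapse timestamped records into a :class:`DetectionHistory`.

    Multiple records of a species within one occasion count once (the model
    consumes detection/nondetection per occasion). Species with no records
    appear as all-zero rows, so the matrix always covers the full focal list.

    Parameters
    ----------
    records
        Columns ``station_id``, ``species_code``, ``datetime`` (parseable
        timestamps). May be empty.
    stations
        Must contain ``station_id``; row order fixes the column order of Y.
    species
        Must contain ``code``; row order fixes the row order of Y.
    calendar
        Occasion windows in days since ``survey_start``.
    partial_policy
        ``"keep"`` retains a trailing partial occasion, ``"drop"`` discards
        it (and any records falling inside it).
    survey_start
        Timestamp of day 0. Defaults to midnight of the earliest record.
    """
    station_ids = list(stations["station_id"])
    species_codes = list(species["code"])
    retained = calendar.retained(partial_policy)
    V_j = int(retained.sum())
    if V_j < 1:
        raise ValueError("partial policy retained no occasions")

    S, J = len(species_codes), len(station_ids)
    Y = np.zeros((S, J), dtype=int)
    V = np.full(J, V_j, dtype=int)

    if len(records):
        st_index = {s: k for k, s in enumerate(station_ids)}
        sp_index = {s: k for k, s in enumerate(species_codes)}
        ts = pd.to_datetime(records["datetime"])
        if survey_start is None:
            survey_start = ts.min().normalize()
        else:
            survey_start = pd.Timestamp(survey_start)
        days = (ts - survey_start) / pd.Timedelta(days=1)

        bad_station = [i for i, s in zip(records.index, records["station_id"]) if s not in st_index]
        bad_species = [i for i, s in zip(records.index, records["species_code"]) if s not in sp_index]
        occ = calendar.assign(days.to_numpy())
        bad_time = list(records.index[occ < 0])
        problems = []
        if bad_station:
            problems.append(f"unknown station_id at rows {bad_station[:10]}")
        if bad_species:
            problems.append(f"unknown species_code at rows {bad_species[:10]}")
        if bad_time:
            problems.append(f"timestamp outside sampling window at rows {bad_time[:10]}")
        if problems:
            raise ValueError("; ".join(problems))

        keep = retained[occ]
        seen = set()
        for sp, st, k, ok in zip(records["species_code"], records["station_id"], occ, keep):
            if ok:
                seen.add((sp_index[sp], st_index[st], int(k)))
        for i, j, _k in seen:
            Y[i, j] += 1

    return DetectionHistory(
        Y=Y,
        V=V,
        species=species_codes,
        stations=station_ids,
        augmented=np.zeros(S, dtype=bool),
        calendar=calendar,
    )


def augment_history(history: DetectionHistory, n_aug: int, prefix: str = "Aug") -> DetectionHistory:
    """Append ``n_aug`` all-zero rows for hypothetical undetected species.

    The added rows are flagged ``augmented``; observed rows are untouched.
    With ``n_aug = 0`` this returns an equivalent copy.
    """
    if n_aug < 0:
        raise ValueError("n_aug must be >= 0")
    S, J = history.Y.shape
    Y = np.vstack([history.Y, np.zeros((n_aug, J), dtype=int)])
    species = list(history.species) + [f"{prefix}{k + 1:02d}" for k in range(n_aug)]
    augmented = np.concatenate([history.augmented, np.ones(n_aug, dtype=bool)])
    return DetectionHistory(
        Y=Y,
        V=history.V.copy(),
        species=species,
        stations=list(history.stations),
        augmented=augmented,
        calendar=history.calendar,
    )
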