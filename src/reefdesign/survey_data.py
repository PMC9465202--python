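"""Survey data model, file I/O, covariate transforms, and interrupted
time-series covariate construction.

The monitoring data are long-format binomial counts of hard-coral point
intercepts: at each survey time, each site contributes a count ``y`` of
coral-positive points out of ``n`` photo points (1250 by default, from
50 images x 5 transects x 5 points).  Sites are nested in reef locations
(three sites in each of seven reefs, labelled SL1..SL4 and SS1..SS3).
Disturbance covariates are recorded per survey interval for the whole
reef system (a 0/1 bleaching indicator and cyclone exposure in hours of
damaging waves) and per reef location as exposure dummies.

A mass bleaching event interrupted the coral-cover trend in 1998; its
immediate (level) and ongoing (slope) impact is modelled with interrupted
time-series covariates BLE98 (post-event step) and Time98 (years since
the event), built here by :func:`build_its`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REEFS",
    "SITES_PER_REEF",
    "DEFAULT_TRIALS",
    "SurveyDataError",
    "ITSCovariates",
    "CenteringInfo",
    "HistoricalDataset",
    "load_survey_tables",
    "transform_cyclone_hours",
    "center",
    "build_its",
]

#: Canonical reef-location labels, in frozen order.
REEFS: tuple[str, ...] = ("SL1", "SL2", "SL3", "SL4", "SS1", "SS2", "SS3")

#: Sites are indexed 1..3 within each reef location.
SITES_PER_REEF: int = 3

#: Photo points per site survey: 50 images x 5 transects x 5 points.
DEFAULT_TRIALS: int = 1250

SURVEY_COLUMNS = ("reef", "site", "time", "y", "n")
COVARIATE_COLUMNS = ("time", "bleaching", "cyclone_hours")
DUMMY_COLUMNS = ("reef", "cyclone_loc", "severe_cyclone_loc", "bleaching_loc")

#: Covariates that are centered on their historical means.
CENTERED_COVARIATES = ("time", "bleaching", "sqrt_cyclone", "interaction")


class SurveyDataError(ValueError):
    """Raised when survey tables violate the data contract."""


@dataclasses.dataclass(frozen=True)
class ITSCovariates:
    """Interrupted time-series covariates at one survey time.

    ``ble98`` is the post-event step indicator; ``time98`` is years
    elapsed since the event (0 before and at the event time).
    """

    ble98: int
    time98: float

    def __post_init__(self) -> None:
        if self.ble98 not in (0, 1):
            raise SurveyDataError(f"ble98 must be 0/1, got {self.ble98}")
        if self.time98 < 0:
            raise SurveyDataError(f"time98 must be >= 0, got {self.time98}")
        if self.time98 > 0 and self.ble98 != 1:
            raise SurveyDataError("time98 > 0 requires ble98 = 1")


def build_its(time: float, event_time: float) -> ITSCovariates:
    """Interrupted time-series covariates for a survey at ``time``.

    Before ``event_time`` both covariates are zero.  At and after the
    event the step indicator is 1 and ``time98`` grows linearly with
    survey time, so the first post-event survey has ``(1, 0.0)``: the
    event occurred between surveys and the post-event survey registers
    the level change with no elapsed recovery time yet.
    """
    if time < event_time:
        return ITSCovariates(0, 0.0)
    return ITSCovariates(1, float(time - event_time))


def transform_cyclone_hours(hours: float) -> float:
    """Square-root transform for cyclone-exposure hours.

    Exposure hours are counts spanning a large range; the square root
    linearizes their relationship with the logit of coral cover.
    Centering is applied separately (see :func:`center`).
    """
    if hours < 0:
        raise SurveyDataError(f"cyclone hours must be >= 0, got {hours}")
    return math.sqrt(hours)


class CenteringInfo:
    """Per-covariate centering constants frozen on the historical data.

    Constants are means over the historical survey times.  Once frozen
    they are reused unchanged when covariates are evaluated at future
    times, so extrapolated design points live on the same model scale
    as the fitted data.
    """

    def __init__(self, means: Mapping[str, float] | None = None) -> None:
        self._means: dict[str, float] = dict(means or {})
        self.frozen: bool = means is not None

    @classmethod
    def from_historical(cls, table: pd.DataFrame) -> "CenteringInfo":
        """Compute and freeze constants from a historical covariate table.

        ``table`` must carry columns time, bleaching, sqrt_cyclone and
        interaction (one row per survey time).
        """
        means = {name: float(table[name].mean()) for name in CENTERED_COVARIATES}
        return cls(means)

    def mean(self, name: str) -> float:
        if not self.frozen:
            raise SurveyDataError("centering constants have not been frozen yet")
        try:
            return self._means[name]
        except KeyError:
            raise SurveyDataError(f"no centering constant for covariate {name!r}") from None

    @property
    def means(self) -> dict[str, float]:
        return dict(self._means)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CenteringInfo) and self._means == other._means

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CenteringInfo({self._means!r}, frozen={self.frozen})"


def center(values: Iterable[float], centering: CenteringInfo, name: str) -> np.ndarray:
    """Center ``values`` with the frozen constant for covariate ``name``.

    Historical rows then have mean ~0; future rows reuse the frozen
    constant, so a future value 5 with frozen mean 2 maps to 3.
    """
    if not centering.frozen:
        raise SurveyDataError(
            "centering must be frozen on historical data before use"
        )
    return np.asarray(values, dtype=float) - centering.mean(name)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyDataError(f"{what} table is missing column(s) {missing}")


class HistoricalDataset:
    """Validated container for the historical survey and covariate tables.

    Parameters
    ----------
    surveys
        Long table with columns reef, site, time, y, n.
    covariates
        Whole-of-reef time-varying covariates: time, bleaching,
        cyclone_hours (one row per survey time).
    dummies
        Per-reef disturbance-exposure dummies: reef, cyclone_loc,
        severe_cyclone_loc, bleaching_loc, optionally with a time
        column.  With a time column the dummies describe the exposure
        of each reef location in the interval before each survey (one
        row per reef and survey time); without one they are static
        reef attributes broadcast over all surveys.
    event_time
        Disturbance time for the interrupted time-series terms.  If
        omitted it defaults to the first survey time whose interval
        bleaching indicator is 1 (the first post-event survey).
    nested_severity
        If True (default) a severe-cyclone dummy of 1 requires the
        cyclone dummy to be 1 as well (nested severity coding).
    """

    def __init__(
        self,
        surveys: pd.DataFrame,
        covariates: pd.DataFrame,
        dummies: pd.DataFrame,
        event_time: float | None = None,
        nested_severity: bool = True,
    ) -> None:
        self.surveys = surveys.reset_index(drop=True).copy()
        self.covariates = (
            covariates.sort_values("time").reset_index(drop=True).copy()
        )
        self.dummies = dummies.reset_index(drop=True).copy()
        self.dummies_time_varying = "time" in self.dummies.columns
        self.nested_severity = nested_severity
        self._validate()
        if event_time is None:
            bleached = self.covariates.loc[self.covariates["bleaching"] == 1, "time"]
            if bleached.empty:
                raise SurveyDataError(
                    "event_time not given and no bleaching interval recorded"
                )
            event_time = float(bleached.min())
        self.event_time = float(event_time)
        self.centering = CenteringInfo.from_historical(self.covariate_model_table())

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        _require_columns(self.surveys, SURVEY_COLUMNS, "survey")
        _require_columns(self.covariates, COVARIATE_COLUMNS, "covariate")
        _require_columns(self.dummies, DUMMY_COLUMNS, "dummy")

        s = self.surveys
        bad = s.index[(s["y"] < 0) | (s["y"] > s["n"])].tolist()
        if bad:
            raise SurveyDataError(
                f"survey rows {bad} violate 0 <= y <= n: "
                f"{s.loc[bad, ['reef', 'site', 'time', 'y', 'n']].to_dict('records')}"
            )
        if (s["n"] <= 0).any():
            bad = s.index[s["n"] <= 0].tolist()
            raise SurveyDataError(f"survey rows {bad} have non-positive n")
        dup = s.duplicated(subset=["reef", "site", "time"], keep=False)
        if dup.any():
            dup_rows = s.loc[dup, ["reef", "site", "time"]].to_dict("records")
            raise SurveyDataError(f"duplicate (reef, site, time) rows: {dup_rows}")

        unknown = sorted(set(s["reef"]) - set(self.dummies["reef"]))
        if unknown:
            raise SurveyDataError(
                f"survey reefs {unknown} missing from the dummy table"
            )
        if self.dummies_time_varying:
            dup = self.dummies.duplicated(subset=["reef", "time"])
            if dup.any():
                raise SurveyDataError("dummy table has duplicate (reef, time) rows")
            pairs = set(zip(self.dummies["reef"], self.dummies["time"]))
            missing = sorted(
                {(r, t) for r, t in zip(s["reef"], s["time"])} - pairs
            )
            if missing:
                raise SurveyDataError(
                    f"dummy table is missing (reef, time) rows {missing[:5]}"
                )
        elif self.dummies["reef"].duplicated().any():
            raise SurveyDataError("dummy table has duplicate reef rows")

        c = self.covariates
        if not c["bleaching"].isin([0, 1]).all():
            raise SurveyDataError("bleaching indicator must be 0/1")
        if (c["cyclone_hours"] < 0).any():
            raise SurveyDataError("cyclone_hours must be >= 0")
        if c["time"].duplicated().any():
            raise SurveyDataError("covariate table has duplicate times")

        for col in ("cyclone_loc", "severe_cyclone_loc", "bleaching_loc"):
            if not self.dummies[col].isin([0, 1]).all():
                raise SurveyDataError(f"dummy column {col} must be 0/1")
        if self.nested_severity:
            viol = self.dummies.loc[
                (self.dummies["severe_cyclone_loc"] == 1)
                & (self.dummies["cyclone_loc"] == 0),
                "reef",
            ].tolist()
            if viol:
                raise SurveyDataError(
                    f"severe_cyclone_loc=1 without cyclone_loc=1 for reefs {viol} "
                    "(nested severity coding)"
                )

        missing_times = sorted(set(s["time"]) - set(c["time"]))
        if missing_times:
            raise SurveyDataError(
                f"survey times {missing_times} have no covariate row"
            )

    # -- derived views ------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        """Sorted unique survey times (decimal years)."""
        return np.sort(self.surveys["time"].unique())

    @property
    def last_time(self) -> float:
        return float(self.times[-1])

    @property
    def units(self) -> list[tuple[str, int]]:
        """All (reef, site) sampling units in frozen order."""
        reefs = [r for r in REEFS if r in set(self.surveys["reef"])]
        extra = sorted(set(self.surveys["reef"]) - set(REEFS))
        sites = sorted(self.surveys["site"].unique())
        return [(r, s) for r in reefs + extra for s in sites]

    def covariate_model_table(self) -> pd.DataFrame:
        """Covariate table on the model scale, one row per survey time.

        Adds sqrt_cyclone (square-root transformed hours) and the
        bleaching x sqrt-cyclone interaction column; both raw, before
        centering.
        """
        out = self.covariates.copy()
        out["sqrt_cyclone"] = np.sqrt(out["cyclone_hours"].to_numpy(dtype=float))
        out["interaction"] = out["bleaching"] * out["sqrt_cyclone"]
        return out

    def its_table(self) -> pd.DataFrame:
        """BLE98/Time98 interrupted time-series covariates per survey time."""
        rows = [
            dataclasses.asdict(build_its(t, self.event_time))
            for t in self.covariates["time"]
        ]
        out = pd.DataFrame(rows)
        out.insert(0, "time", self.covariates["time"].to_numpy())
        return out

    # -- I/O ----------------------------------------------------------

    def write_tables(self, directory: str | Path) -> dict[str, Path]:
        """Write survey/covariates/dummies CSVs; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "survey": directory / "survey.csv",
            "covariates": directory / "covariates.csv",
            "dummies": directory / "dummies.csv",
        }
        self.surveys.to_csv(paths["survey"], index=False)
        self.covariates.to_csv(paths["covariates"], index=False)
        self.dummies.to_csv(paths["dummies"], index=False)
        return paths

    def __len__(self) -> int:
        return len(self.surveys)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"HistoricalDataset({len(self)} records, "
            f"{len(self.units)} units, {len(self.times)} times, "
            f"event_time={self.event_time})"
        )


def load_survey_tables(
    survey_path: str | Path,
    covariate_path: str | Path,
    dummy_path: str | Path,
    event_time: float | None = None,
) -> HistoricalDataset:
    """Read and validate the three CSV tables into a HistoricalDataset.

    Columns: survey ``reef,site,time,y,n``; covariates
    ``time,bleaching,cyclone_hours``; dummies
    ``reef,cyclone_loc,severe_cyclone_loc,bleaching_loc``.  All times
    are decimal years.  Rows violating the invariants are rejected with
    row-level diagnostics; missing covariate times are a join error.
    """
    for p in (survey_path, covariate_path, dummy_path):
        if not Path(p).exists():
            raise SurveyDataError(f"input file not found: {p}")
    surveys = pd.read_csv(survey_path)
    covariates = pd.read_csv(covariate_path)
    dummies = pd.read_csv(dummy_path)
    return HistoricalDataset(surveys, covariates, dummies, event_time=event_time)
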