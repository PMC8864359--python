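"""Domain types and CSV I/O for the three data sources of the analysis.

The analysis consumes three inputs:

* detection/non-detection histories aggregated per site-year (a "site" is an
  atlas pentad): how many times the site was visited in a year and on how many
  of those visits the species was detected;
* an annual rainfall covariate (standardized mean daily rainfall);
* tracking-survival records for individual birds (days at risk, death flag).

On disk everything is plain CSV with an explicit header; one row is one
site-year (detections pre-aggregated), one rain year, or one tracked bird.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteYearRecord",
    "DetectionDataset",
    "RainYear",
    "TrackingRecord",
    "VitalRates",
    "ModelParams",
    "PopulationVector",
    "read_detections",
    "write_detections",
    "read_rain",
    "write_rain",
    "standardize_rain",
    "read_tracking",
    "write_tracking",
]


@dataclass(frozen=True)
class SiteYearRecord:
    """One site-year detection summary: J visits, d detections."""

    site_id: str
    year: int
    visits: int
    detections: int

    def __post_init__(self) -> None:
        if self.visits < 1:
            raise ValueError(
                f"site {self.site_id}, year {self.year}: visits must be >= 1, "
                f"got {self.visits}"
            )
        if not 0 <= self.detections <= self.visits:
            raise ValueError(
                f"site {self.site_id}, year {self.year}: detections "
                f"({self.detections}) must lie in [0, visits={self.visits}]"
            )


@dataclass
class DetectionDataset:
    """A collection of site-year records with a contiguous 0-based year index.

    ``years[t]`` maps the model's year index ``t = 0..T-1`` back to calendar
    years; the index covers every distinct year present in ``records``.
    """

    records: list[SiteYearRecord]
    min_visits_filter: int = 1
    years: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records: detection dataset is empty")
        bad = [r for r in self.records if r.visits < self.min_visits_filter]
        if bad:
            raise ValueError(
                f"{len(bad)} records have visits < min_visits_filter="
                f"{self.min_visits_filter}; filter before constructing"
            )
        self.years = sorted({r.year for r in self.records})

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_sites(self) -> int:
        return len({r.site_id for r in self.records})

    def year_index(self, year: int) -> int:
        return self.years.index(year)

    def filtered(self, min_visits: int) -> "DetectionDataset":
        """Return a dataset keeping records with at least ``min_visits`` visits.

        Idempotent: filtering twice at the same threshold is a no-op.
        """
        kept = [r for r in self.records if r.visits >= min_visits]
        if not kept:
            raise ValueError(f"no records: all visits < {min_visits}")
        return DetectionDataset(records=kept, min_visits_filter=min_visits)

    # --- array views used by the likelihood ---------------------------------

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(detections, visits, year_index) as integer arrays, one entry per record.

        Cached: the record list is treated as immutable once constructed.
        """
        cached = getattr(self, "_arrays", None)
        if cached is None:
            d = np.array([r.detections for r in self.records], dtype=np.int64)
            j = np.array([r.visits for r in self.records], dtype=np.int64)
            yi = {y: t for t, y in enumerate(self.years)}
            t = np.array([yi[r.year] for r in self.records], dtype=np.int64)
            cached = (d, j, t)
            object.__setattr__(self, "_arrays", cached)
        return cached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [r.site_id for r in self.records],
                "year": [r.year for r in self.records],
                "visits": [r.visits for r in self.records],
                "detections": [r.detections for r in self.records],
            }
        )


@dataclass(frozen=True)
class RainYear:
    """Rainfall covariate for one year.

    ``covariate`` is the standardized annual mean daily rainfall (unitless,
    mean 0 / sd 1 across the study years); ``raw_mm_per_day`` keeps the
    untransformed value when known.
    """

    year: int
    covariate: float
    raw_mm_per_day: float | None = None

    def __post_init__(self) -> None:
        if self.raw_mm_per_day is not None and self.raw_mm_per_day < 0:
            raise ValueError(f"year {self.year}: raw rainfall must be >= 0")


@dataclass(frozen=True)
class TrackingRecord:
    """One tracked bird: days at risk and whether it died during tracking."""

    bird_id: str
    exposure_days: float
    died: bool

    def __post_init__(self) -> None:
        if self.exposure_days <= 0:
            raise ValueError(f"bird {self.bird_id}: exposure_days must be > 0")


@dataclass(frozen=True)
class VitalRates:
    """Survival and fecundity parameters of the stage-structured life cycle.

    phi1
        fledgling annual survival (first year of life), in (0, 1).
    phi2
        sub-adult/adult annual survival, in (0, 1); constrained above phi1.
    beta0, beta1
        intercept and rainfall slope of fecundity on the logit scale.
    sigma_gamma
        sd of the annual fecundity random effect (logit scale), >= 0.
    """

    phi1: float
    phi2: float
    beta0: float
    beta1: float
    sigma_gamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.phi1 < self.phi2 < 1.0):
            raise ValueError(
                f"survival constraint 0 < phi1 < phi2 < 1 violated: "
                f"phi1={self.phi1}, phi2={self.phi2}"
            )
        if self.sigma_gamma < 0:
            raise ValueError(f"sigma_gamma must be >= 0, got {self.sigma_gamma}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector for one posterior draw (or one truth).

    r
        per-individual detection probability, in (0, 1).
    mu0
        initial mean abundance per site, > 0.
    psi
        negative-binomial over-dispersion (variance mu + mu^2/psi), > 0.
    vital
        the VitalRates block.
    gamma
        annual fecundity random effects, one per modelled year transition.
    """

    r: float
    mu0: float
    psi: float
    vital: VitalRates
    gamma: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"r must be in (0,1), got {self.r}")
        if self.mu0 <= 0:
            raise ValueError(f"mu0 must be > 0, got {self.mu0}")
        if self.psi <= 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))


@dataclass(frozen=True)
class PopulationVector:
    """Stage-structured population state: fledglings, sub-adults, adults."""

    n_fledgling: float
    n_subadult: float
    n_adult: float

    def __post_init__(self) -> None:
        if min(self.n_fledgling, self.n_subadult, self.n_adult) < 0:
            raise ValueError("population components must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_fledgling, self.n_subadult, self.n_adult])

    @property
    def total(self) -> float:
        return self.n_fledgling + self.n_subadult + self.n_adult


# --- CSV readers / writers --------------------------------------------------


def read_detections(path, min_visits: int = 5) -> DetectionDataset:
    """Read a site-year detections CSV and drop site-years with few visits.

    The file needs columns ``site,year,visits,detections``. Records with
    ``visits < min_visits`` are removed (atlas lists from barely-visited
    pentads carry almost no information about abundance).
    """
    frame = pd.read_csv(path)
    required = {"site", "year", "visits", "detections"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError(f"{path}: no records")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            rec = SiteYearRecord(
                site_id=str(row.site),
                year=int(row.year),
                visits=int(row.visits),
                detections=int(row.detections),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, data row {i + 1}: {exc}") from exc
        if rec.visits >= min_visits:
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: no records with visits >= {min_visits}")
    dataset = DetectionDataset(records=records, min_visits_filter=min_visits)
    logger.info(
        "read %d site-years (%d sites, %d years) from %s; kept visits >= %d",
        len(records), dataset.n_sites, dataset.n_years, path, min_visits,
    )
    return dataset


def write_detections(dataset: DetectionDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def standardize_rain(raw: list[RainYear]) -> list[RainYear]:
    """Standardize raw mm/day values to mean 0 and sd 1 across the given years.

    Uses the sample sd (denominator n-1). Raises if fewer than two years are
    supplied or the series is constant.
    """
    if len(raw) < 2:
        raise ValueError("need >= 2 years of rainfall to standardize")
    values = np.array([
        r.raw_mm_per_day if r.raw_mm_per_day is not None else r.covariate
        for r in raw
    ], dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("rainfall series is constant; cannot standardize")
    z = (values - values.mean()) / sd
    return [
        RainYear(year=r.year, covariate=float(zi), raw_mm_per_day=float(v))
        for r, zi, v in zip(raw, z, values)
    ]


def read_rain(path, standardized: bool = True) -> list[RainYear]:
    """Read a rainfall CSV with columns ``year,rain``.

    ``standardized=True`` declares the ``rain`` column to already be the
    covariate; otherwise it is raw mm/day and gets standardized here.
    """
    frame = pd.read_csv(path)
    if not {"year", "rain"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns year,rain")
    if frame.empty:
        raise ValueError(f"{path}: no records")
    if standardized:
        return [
            RainYear(year=int(y), covariate=float(v))
            for y, v in zip(frame["year"], frame["rain"])
        ]
    raw = [
        RainYear(year=int(y), covariate=float("nan"), raw_mm_per_day=float(v))
        for y, v in zip(frame["year"], frame["rain"])
    ]
    return standardize_rain(raw)


def write_rain(series: list[RainYear], path, raw: bool = False) -> None:
    values = [
        (r.raw_mm_per_day if raw else r.covariate) for r in series
    ]
    pd.DataFrame({"year": [r.year for r in series], "rain": values}).to_csv(
        path, index=False
    )


def read_tracking(path) -> list[TrackingRecord]:
    """Read a tracking CSV with columns ``bird,exposure_days,died``."""
    frame = pd.read_csv(path)
    if not {"bird", "exposure_days", "died"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns bird,exposure_days,died")
    if frame.empty:
        raise ValueError(f"{path}: no records")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                TrackingRecord(
                    bird_id=str(row.bird),
                    exposure_days=float(row.exposure_days),
                    died=bool(int(row.died)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, data row {i + 1}: {exc}") from exc
    return records


def write_tracking(records: list[TrackingRecord], path) -> None:
    pd.DataFrame(
        {
            "bird": [r.bird_id for r in records],
            "exposure_days": [r.exposure_days for r in records],
            "died": [int(r.died) for r in records],
        }
    ).to_csv(path, index=False)
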