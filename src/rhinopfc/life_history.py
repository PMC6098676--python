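"""Individual life-history registry for a closed megaherbivore population.

The central quantity is the annual proportion of females calving (PFC): the
number of births during a calendar year divided by the number of females that
were *adult during any part of that year*.  A female is adult once she has
calved, or once she reaches seven years of age without calving; adulthood is
never revoked.  The module also provides an end-of-year census summary by
sex and stage (calf / subadult / adult), recovery of integer birth counts
from rounded published PFC values, and classification of PFC values against
du Toit's reproductive-performance benchmark bands for black rhinoceros.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

CALF = "calf"
SUBADULT = "subadult"
ADULT = "adult"
STAGES = (CALF, SUBADULT, ADULT)

EXIT_CAUSES = ("death", "export", "censored")

#: Minimum spacing between successive calvings of one female, months.
GESTATION_MONTHS = 15

DAYS_PER_YEAR = 365.25


class RegistryError(ValueError):
    """A life-history record violates a structural invariant."""


class OutOfRangeError(ValueError):
    """A date falls outside an individual's lifespan."""


class UndefinedPFCError(ValueError):
    """PFC is undefined: no adult female was present during the year."""


class ConsistencyError(ValueError):
    """A rounded PFC value is inconsistent with any integer birth count."""


def add_months(date: dt.date, months: int) -> dt.date:
    """Calendar-aware month shift; the day is clamped to the month length."""
    y, m = divmod(date.month - 1 + months, 12)
    year, month = date.year + y, m + 1
    # clamp day (e.g. Jan 31 + 1 month -> Feb 28)
    for day in (date.day, 30, 29, 28):
        try:
            return dt.date(year, month, day)
        except ValueError:
            continue
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class StageConfig:
    """Conventions needed for stage classification beyond the adult rule.

    The calf/subadult boundary and the male adult age are census conventions
    only — PFC never depends on them.  Imported animals with unknown birth
    dates receive a nominal (imputed) age at entry per entry stage so that
    later stage transitions are well defined.
    """

    calf_subadult_age: float = 3.5
    adult_age_female: float = 7.0
    adult_age_male: float = 7.0
    imputed_entry_age: dict = field(
        default_factory=lambda: {CALF: 1.75, SUBADULT: 5.25, ADULT: 10.0}
    )


DEFAULT_STAGE_CONFIG = StageConfig()


@dataclass(frozen=True)
class LifeHistoryRecord:
    """One individual's dated demographic events.

    ``birth_date`` may be None for imported animals of unknown age, in which
    case ``entry_stage`` plus the configured imputed entry ages determine an
    effective birth date.  ``calving_dates`` is strictly increasing with
    successive dates at least 15 months apart (the gestation bound); it is
    empty for males.
    """

    individual_id: str
    sex: str
    birth_date: dt.date | None
    entry_date: dt.date
    entry_stage: str = CALF
    exit_date: dt.date | None = None
    exit_cause: str | None = None
    calving_dates: tuple[dt.date, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RegistryError(f"{self.individual_id}: bad sex {self.sex!r}")
        if self.entry_stage not in STAGES:
            raise RegistryError(
                f"{self.individual_id}: bad entry_stage {self.entry_stage!r}"
            )
        if self.exit_cause is not None and self.exit_cause not in EXIT_CAUSES:
            raise RegistryError(
                f"{self.individual_id}: bad exit_cause {self.exit_cause!r}"
            )
        if self.birth_date is not None and self.entry_date < self.birth_date:
            raise RegistryError(f"{self.individual_id}: entry before birth")
        if self.exit_date is not None and self.exit_date < self.entry_date:
            raise RegistryError(f"{self.individual_id}: exit before entry")
        if self.sex == MALE and self.calving_dates:
            raise RegistryError(f"{self.individual_id}: male with calvings")
        for a, b in zip(self.calving_dates, self.calving_dates[1:]):
            if b <= a:
                raise RegistryError(
                    f"{self.individual_id}: calving dates not increasing"
                )
            if b < add_months(a, GESTATION_MONTHS):
                raise RegistryError(
                    f"{self.individual_id}: calvings {a} and {b} closer than "
                    f"{GESTATION_MONTHS} months"
                )
        for c in self.calving_dates:
            if c < self.entry_date:
                raise RegistryError(f"{self.individual_id}: calving before entry")
            if self.exit_date is not None and c > self.exit_date:
                raise RegistryError(f"{self.individual_id}: calving after exit")

    @property
    def is_import(self) -> bool:
        """True when the animal entered the population other than by birth."""
        return self.birth_date is None or self.entry_date != self.birth_date

    def effective_birth_date(self, config: StageConfig = DEFAULT_STAGE_CONFIG) -> dt.date:
        """Birth date, imputed from entry stage when unknown (flagged via
        :attr:`is_import` and ``birth_date is None``)."""
        if self.birth_date is not None:
            return self.birth_date
        age_years = config.imputed_entry_age[self.entry_stage]
        return self.entry_date - dt.timedelta(days=round(age_years * DAYS_PER_YEAR))

    def age_years(self, date: dt.date, config: StageConfig = DEFAULT_STAGE_CONFIG) -> float:
        return (date - self.effective_birth_date(config)).days / DAYS_PER_YEAR

    def adult_onset_date(self, config: StageConfig = DEFAULT_STAGE_CONFIG) -> dt.date:
        """Earliest date at which the individual counts as adult."""
        age = config.adult_age_female if self.sex == FEMALE else config.adult_age_male
        by_age = self.effective_birth_date(config) + dt.timedelta(
            days=round(age * DAYS_PER_YEAR)
        )
        if self.sex == FEMALE and self.calving_dates:
            return min(by_age, self.calving_dates[0])
        return by_age


def classify_stage(
    record: LifeHistoryRecord,
    date: dt.date,
    config: StageConfig = DEFAULT_STAGE_CONFIG,
) -> str:
    """Stage of one individual on one date.

    Females are adult iff they have calved on or before ``date`` or have
    reached the configured adult age (default seven years).  The
    calf/subadult split is a census convention (default 3.5 years).
    """
    if date < record.entry_date or (
        record.exit_date is not None and date > record.exit_date
    ):
        raise OutOfRangeError(
            f"{record.individual_id}: {date} outside [{record.entry_date}, "
            f"{record.exit_date}]"
        )
    if date >= record.adult_onset_date(config):
        return ADULT
    if record.age_years(date, config) < config.calf_subadult_age:
        return CALF
    return SUBADULT


def _presence_in_year(record: LifeHistoryRecord, year: int) -> tuple[dt.date, dt.date] | None:
    """Overlap of the individual's lifespan with calendar ``year``, or None."""
    start = max(record.entry_date, dt.date(year, 1, 1))
    end = dt.date(year, 12, 31)
    if record.exit_date is not None:
        end = min(end, record.exit_date)
    return (start, end) if start <= end else None


def adult_female_count(
    registry: list[LifeHistoryRecord],
    year: int,
    config: StageConfig = DEFAULT_STAGE_CONFIG,
) -> int:
    """Number of females who were adult during any part of ``year``.

    Includes females who matured, died, or were exported mid-year, per the
    part-year counting rule.
    """
    n = 0
    for r in registry:
        if r.sex != FEMALE:
            continue
        span = _presence_in_year(r, year)
        if span is None:
            continue
        if r.adult_onset_date(config) <= span[1]:
            n += 1
    return n


def compute_pfc(
    registry: list[LifeHistoryRecord],
    years: range,
    config: StageConfig = DEFAULT_STAGE_CONFIG,
) -> pd.DataFrame:
    """Annual PFC series: births / part-year adult-female count.

    Returns a DataFrame indexed by year with columns ``births``,
    ``adult_female_count`` and ``pfc``.  A year with zero adult females makes
    PFC undefined and raises :class:`UndefinedPFCError` rather than emitting
    0 or NaN.
    """
    rows = []
    for year in years:
        denom = adult_female_count(registry, year, config)
        if denom < 1:
            raise UndefinedPFCError(f"no adult female present in {year}")
        births = sum(
            1
            for r in registry
            if r.sex == FEMALE
            for c in r.calving_dates
            if c.year == year
        )
        rows.append((year, births, denom, births / denom))
    out = pd.DataFrame(rows, columns=["year", "births", "adult_female_count", "pfc"])
    return out.set_index("year")


def births_from_census(pfc: float, n_adult_females: int) -> int:
    """Recover the integer birth count behind a rounded published PFC value.

    Asserts that ``round(pfc * n)`` reproduces ``pfc`` to within half a count,
    i.e. that the published proportion is consistent with some integer
    numerator.
    """
    if not 0.0 <= pfc <= 1.0:
        raise ValueError(f"pfc {pfc} outside [0, 1]")
    if n_adult_females < 1:
        raise ValueError("need at least one adult female")
    x = int(round(pfc * n_adult_females))
    if abs(pfc - x / n_adult_females) >= 0.5 / n_adult_females:
        raise ConsistencyError(
            f"pfc={pfc} inconsistent with an integer count out of {n_adult_females}"
        )
    return x


_CELLS = [f"{s[0]}_{st}" for s in SEXES for st in STAGES]
CENSUS_COLUMNS = (
    ["pfc"]
    + _CELLS
    + [f"{c}_imports" for c in _CELLS]
    + [f"{c}_exports" for c in _CELLS]
)


def census_summary(
    registry: list[LifeHistoryRecord],
    years: range,
    config: StageConfig = DEFAULT_STAGE_CONFIG,
) -> pd.DataFrame:
    """End-of-year sex-by-stage composition with import/export annotations.

    An individual is counted in year ``y`` when present on 31 December
    (entered on or before, not yet exited).  Imports are tallied in their
    entry year at their entry-date stage; exports in their exit year at their
    exit-date stage.
    """
    cols = _CELLS + [f"{c}_imports" for c in _CELLS] + [f"{c}_exports" for c in _CELLS]
    table = pd.DataFrame(0, index=pd.Index(list(years), name="year"), columns=cols)
    for r in registry:
        for year in years:
            eoy = dt.date(year, 12, 31)
            if r.entry_date <= eoy and (r.exit_date is None or r.exit_date > eoy):
                cell = f"{r.sex[0]}_{classify_stage(r, eoy, config)}"
                table.loc[year, cell] += 1
        if r.is_import and r.entry_date.year in table.index:
            st = classify_stage(r, r.entry_date, config)
            table.loc[r.entry_date.year, f"{r.sex[0]}_{st}_imports"] += 1
        if (
            r.exit_cause == "export"
            and r.exit_date is not None
            and r.exit_date.year in table.index
        ):
            st = classify_stage(r, r.exit_date, config)
            table.loc[r.exit_date.year, f"{r.sex[0]}_{st}_exports"] += 1
    return table


def census_totals(census: pd.DataFrame) -> pd.Series:
    """Total population size per year (all six sex-by-stage cells)."""
    return census[_CELLS].sum(axis=1)


# du Toit's benchmark bands for '% of cows with calf of that year'.
# 0.40 deliberately belongs to 'mod-good': values were "never consistently at
# least 0.4, the threshold for good to excellent".
BENCHMARK_BANDS = (
    ("very poor-poor", 0.0, 0.29),
    ("poor-mod", 0.29, 0.33),
    ("mod-good", 0.33, 0.40),
    ("good-excellent", 0.40, 1.0),
)


def classify_benchmark(pfc: float) -> str:
    """du Toit benchmark band containing a PFC value.

    Bands: [0, 0.29) very poor-poor; [0.29, 0.33) poor-mod; [0.33, 0.40]
    mod-good; (0.40, 1] good-excellent.
    """
    if not 0.0 <= pfc <= 1.0:
        raise ValueError(f"pfc {pfc} outside [0, 1]")
    if pfc < 0.29:
        return "very poor-poor"
    if pfc < 0.33:
        return "poor-mod"
    if pfc <= 0.40:
        return "mod-good"
    return "good-excellent"


def registry_from_census_year(
    year: int, n_adult_females: int, births: int
) -> list[LifeHistoryRecord]:
    """Synthetic single-year registry with a prescribed PFC numerator and
    denominator.

    Builds ``n_adult_females`` females already adult throughout ``year`` (born
    ten years earlier) and assigns one mid-year calving to each of ``births``
    of them, so ``compute_pfc`` over ``[year]`` returns ``births / n``.
    Used to round-trip published census rows through the PFC computation.
    """
    if births > n_adult_females:
        raise ValueError("more births than adult females")
    registry = []
    for i in range(n_adult_females):
        born = dt.date(year - 10, 1, 1)
        calvings = ()
        if i < births:
            # stagger days to keep dates distinct across females
            calvings = (dt.date(year, 6, 1 + (i % 28)),)
        registry.append(
            LifeHistoryRecord(
                individual_id=f"synth-{year}-f{i}",
                sex=FEMALE,
                birth_date=born,
                entry_date=born,
                entry_stage=CALF,
                calving_dates=calvings,
            )
        )
    return registry


def validate_registry(registry: list[LifeHistoryRecord]) -> None:
    """Re-run record-level invariants and check id uniqueness."""
    seen = set()
    for r in registry:
        if r.individual_id in seen:
            raise RegistryError(f"duplicate id {r.individual_id}")
        seen.add(r.individual_id)
        # dataclass __post_init__ already validated; re-validate defensively
        replace(r)


__all__ = [
    "LifeHistoryRecord",
    "StageConfig",
    "DEFAULT_STAGE_CONFIG",
    "RegistryError",
    "OutOfRangeError",
    "UndefinedPFCError",
    "ConsistencyError",
    "add_months",
    "classify_stage",
    "adult_female_count",
    "compute_pfc",
    "births_from_census",
    "census_summary",
    "census_totals",
    "classify_benchmark",
    "registry_from_census_year",
    "validate_registry",
    "BENCHMARK_BANDS",
    "CENSUS_COLUMNS",
    "GESTATION_MONTHS",
    "FEMALE",
    "MALE",
    "CALF",
    "SUBADULT",
    "ADULT",
]
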