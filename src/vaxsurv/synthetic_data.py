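"""Synthetic observational health data with known vaccine-outcome effects.

This module generates the simulated "database" on which every surveillance
design is evaluated: persons with latent confounders, observation periods,
outpatient visits, vaccinations with confounded uptake, and first-occurrence
outcome records.

The confounding structure is deliberately minimal — two latent scalars per
person:

* ``frailty``: a positive multiplier on all outcome rates (mean 1 on the
  natural scale). Frail people can be made both sicker and more likely to be
  vaccinated and to visit, which induces the between-person confounding that
  historical-comparator and case-control designs cannot remove.
* ``health_seeking``: a standard-normal score raising both the outpatient
  visit rate and the vaccination propensity, emulating care-seeking behaviour
  captured (visits) and not captured (propensity) in the data.

Outcome events follow an inhomogeneous Poisson process per person and
outcome: rate = baseline x frailty x seasonal term, multiplied by
exp(true log rate ratio) during the 1-28 day time-at-risk window after each
vaccination. Negative-control outcomes have true rate ratio 1. Only the
first event per (person, outcome) is kept, mirroring first-occurrence outcome
definitions in claims analyses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import i0

from ._dates import DAYS_PER_YEAR, day_of_year, month_ends, to_day, to_iso

__all__ = [
    "SimulationConfig",
    "OutcomeDefinition",
    "EventTables",
    "confounded_scenario",
    "make_outcome_definitions",
    "simulate_population",
    "simulate_vaccinations",
    "simulate_outcomes",
    "simulate_tables",
    "write_tables",
    "read_tables",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic surveillance scenario.

    Rates are per person-year; dates may be ISO strings, ``datetime.date`` or
    integer days since 1970-01-01. The default calendar mirrors a 9-month
    pandemic-vaccination campaign with the preceding year as historic period.
    """

    n_persons: int = 10_000
    study_start: object = "2009-09-01"
    study_end: object = "2010-05-31"
    historic_start: object = "2008-09-01"
    historic_end: object = "2009-05-31"
    tar_start_day: int = 1
    tar_end_day: int = 28
    n_negative_controls: int = 93
    n_positive_controls: int = 0  # per entry of true_log_rr_positive
    baseline_rate: float = 0.02  # median outcome rate, events / person-year
    baseline_rate_spread: float = 0.5  # s.d. of log baseline rate across outcomes
    visit_rate: float = 2.5  # outpatient visits / person-year at latent scores 0
    frailty_sd: float = 0.0  # s.d. of log frailty (0 = no frailty heterogeneity)
    health_seeking_strength: float = 0.0  # effect of the score on visits & uptake
    frailty_uptake_strength: float = 0.0  # effect of log frailty on uptake
    frailty_visit_strength: float = 0.0  # effect of log frailty on visit rate
    seasonal_amplitude: float = 0.0  # log-scale amplitude of the seasonal sinusoid
    seasonal_peak_day: int = 15  # day of year at which outcome rates peak
    uptake_curve: Sequence[float] | None = None  # per-study-month vaccination hazard
    true_log_rr_positive: Sequence[float] = ()
    two_dose_fraction: float = 0.0
    dose_gap_days: int = 60
    eligible_fraction: float = 0.95  # fraction observed >= 365 d before study start
    female_fraction: float = 0.53
    age_range: tuple[float, float] = (18.0, 80.0)  # years at study start
    seed: int = 0

    # resolved integer-day views -------------------------------------------------
    @property
    def study_window(self) -> tuple[int, int]:
        return to_day(self.study_start), to_day(self.study_end)

    @property
    def historic_window(self) -> tuple[int, int]:
        return to_day(self.historic_start), to_day(self.historic_end)

    @property
    def study_month_ends(self) -> np.ndarray:
        return month_ends(*self.study_window)

    def resolved_uptake_curve(self) -> np.ndarray:
        n_months = len(self.study_month_ends)
        if self.uptake_curve is None:
            # pulse-shaped campaign: uptake rises quickly then decays
            m = np.arange(n_months)
            curve = 0.12 * np.exp(-0.5 * ((m - 1.5) / 2.0) ** 2)
        else:
            curve = np.asarray(self.uptake_curve, dtype=float)
            if len(curve) != n_months:
                raise ValueError(
                    f"uptake_curve has {len(curve)} entries but the study period "
                    f"spans {n_months} calendar months"
                )
        return curve

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        hs, he = self.historic_window
        ss, se = self.study_window
        if not (hs <= he < ss <= se):
            raise ValueError("historic period must precede the study period")
        if not (1 <= self.tar_start_day <= self.tar_end_day):
            raise ValueError("need 1 <= tar_start_day <= tar_end_day")
        if self.n_negative_controls < 2:
            raise ValueError("need >= 2 negative controls to fit systematic error")
        for name in ("baseline_rate", "visit_rate", "frailty_sd", "two_dose_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(self.resolved_uptake_curve() < 0):
            raise ValueError("uptake_curve entries must be >= 0")
        if any(lr < 0 for lr in self.true_log_rr_positive):
            raise ValueError("injected positive effects must have log RR >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["uptake_curve"] = None if self.uptake_curve is None else list(self.uptake_curve)
        d["true_log_rr_positive"] = list(self.true_log_rr_positive)
        d["age_range"] = list(self.age_range)
        for k in ("study_start", "study_end", "historic_start", "historic_end"):
            d[k] = to_iso(to_day(d[k]))
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["age_range"] = tuple(d["age_range"])
        d["true_log_rr_positive"] = tuple(d["true_log_rr_positive"])
        if d["uptake_curve"] is not None:
            d["uptake_curve"] = tuple(d["uptake_curve"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def confounded_scenario(
    n_persons: int = 20_000,
    n_negative_controls: int = 93,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """The standard confounded surveillance scenario.

    A pandemic-style campaign with modest coverage (~15-20%), where frailty
    raises outpatient-visit propensity more strongly than vaccination uptake
    and a latent health-seeking score drives both. Under these conditions the
    between-person designs show their characteristic biases — historical
    comparator and case-control positively biased, the cohort design biased
    with a sign that flips with the comparator index-date anchor — while the
    self-controlled designs stay near the null.
    """
    months = np.arange(9)
    uptake = tuple(0.04 * np.exp(-0.5 * ((months - 1.5) / 2.0) ** 2))
    params = dict(
        n_persons=n_persons,
        n_negative_controls=n_negative_controls,
        baseline_rate=0.02,
        frailty_sd=0.8,
        health_seeking_strength=0.7,
        frailty_uptake_strength=0.8,
        frailty_visit_strength=1.5,
        seasonal_amplitude=0.0,
        uptake_curve=uptake,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass(frozen=True)
class OutcomeDefinition:
    """One control outcome: its baseline rate and true log rate ratio.

    Negative controls carry ``true_log_rr == 0`` (true rate ratio 1);
    injected positives carry the log of the effect multiplier applied during
    the time-at-risk window.
    """

    outcome_id: str
    baseline_rate: float
    true_log_rr: float = 0.0

    @property
    def true_effect_size(self) -> float:
        return float(np.exp(self.true_log_rr))


@dataclass
class EventTables:
    """The simulated database: five flat event tables (pandas DataFrames)."""

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    visits: pd.DataFrame
    vaccinations: pd.DataFrame
    outcomes: pd.DataFrame


def _rng_for(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator so stages can be re-run in isolation."""
    digest = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def make_outcome_definitions(config: SimulationConfig) -> list[OutcomeDefinition]:
    """Negative controls plus any injected positives, with seeded baseline rates.

    Baseline rates are log-normal around ``baseline_rate`` to emulate the
    prevalence spread of a real negative-control list.
    """
    rng = _rng_for(config, "outcome_defs")
    defs: list[OutcomeDefinition] = []
    log_rates = rng.normal(
        np.log(config.baseline_rate), config.baseline_rate_spread, config.n_negative_controls
    )
    for i, lr in enumerate(log_rates):
        defs.append(OutcomeDefinition(f"NC_{i:03d}", float(np.exp(lr)), 0.0))
    for log_rr in config.true_log_rr_positive:
        rr = np.exp(log_rr)
        log_rates = rng.normal(
            np.log(config.baseline_rate), config.baseline_rate_spread, config.n_positive_controls
        )
        for i, lr in enumerate(log_rates):
            defs.append(
                OutcomeDefinition(f"PC_{rr:g}_{i:03d}", float(np.exp(lr)), float(log_rr))
            )
    return defs


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw persons, observation periods and outpatient visits.

    Returns ``(persons, observation_periods, visits)``. Visit dates follow a
    homogeneous Poisson process per person whose rate scales with the latent
    health-seeking score and (optionally) log frailty; visits are generated
    from one year before the historic period through the study end, the span
    any design's lookback can touch.
    """
    config.validate()
    rng = _rng_for(config, "population")
    n = config.n_persons
    hs_start, _ = config.historic_window
    ss, se = config.study_window

    person_id = np.arange(n)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    lo, hi = config.age_range
    age_at_start = rng.uniform(lo, hi, n)
    birth_date = (ss - age_at_start * DAYS_PER_YEAR).astype(int)
    health_seeking = rng.normal(0.0, 1.0, n)
    # mean-1 lognormal frailty
    frailty = np.exp(rng.normal(-0.5 * config.frailty_sd**2, config.frailty_sd, n))

    # observation periods: most persons enter well before the historic period,
    # a (1 - eligible_fraction) share enters during it or later
    earliest = hs_start - 365
    eligible = rng.random(n) < config.eligible_fraction
    start = np.where(
        eligible,
        earliest - rng.integers(0, 730, n),
        rng.integers(ss - 364, ss + (se - ss) // 2, n),
    )
    # light right-censoring within the study period
    dropout = rng.random(n) < 0.05
    end = np.where(dropout, rng.integers(ss, se + 1, n), se)
    end = np.maximum(end, start)

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_date": birth_date,
            "frailty": frailty,
            "health_seeking": health_seeking,
        }
    )
    periods = pd.DataFrame({"person_id": person_id, "start": start, "end": end})

    # visits over the observed slice of [earliest, study_end]
    v_lo = np.maximum(start, earliest)
    v_hi = np.minimum(end, se)
    span_years = np.maximum(v_hi - v_lo + 1, 0) / DAYS_PER_YEAR
    lam = config.visit_rate * np.exp(
        config.health_seeking_strength * health_seeking
        + config.frailty_visit_strength * np.log(frailty)
    )
    n_visits = rng.poisson(lam * span_years)
    pid = np.repeat(person_id, n_visits)
    lo_rep = np.repeat(v_lo, n_visits)
    hi_rep = np.repeat(v_hi, n_visits)
    dates = rng.integers(lo_rep, hi_rep + 1) if len(pid) else np.array([], dtype=int)
    visits = pd.DataFrame({"person_id": pid, "date": dates}).sort_values(
        ["person_id", "date"], ignore_index=True
    )
    return persons, periods, visits


def simulate_vaccinations(
    persons: pd.DataFrame,
    periods: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Draw vaccination dates under confounded monthly uptake.

    The per-person hazard of vaccination in study month m is
    ``uptake_curve[m] * exp(health_seeking_strength * score
    + frailty_uptake_strength * log frailty)`` (clipped to [0, 0.95]).
    A configured fraction receives a second dose ``dose_gap_days`` later;
    nobody is vaccinated more than twice, and all doses lie inside both the
    study period and the person's observation period.
    """
    rng = _rng_for(config, "vaccinations")
    ss, se = config.study_window
    mends = config.study_month_ends
    mstarts = np.r_[ss, mends[:-1] + 1]
    curve = config.resolved_uptake_curve()

    mult = np.exp(
        config.health_seeking_strength * persons["health_seeking"].to_numpy()
        + config.frailty_uptake_strength * np.log(persons["frailty"].to_numpy())
    )
    hazards = np.clip(np.outer(mult, curve), 0.0, 0.95)  # persons x months
    u = rng.random(hazards.shape)
    hit = u < hazards
    first_month = np.where(hit.any(axis=1), hit.argmax(axis=1), -1)

    obs_start = periods["start"].to_numpy()
    obs_end = periods["end"].to_numpy()
    take = first_month >= 0
    m = first_month[take]
    lo = np.maximum(mstarts[m], obs_start[take])
    hi = np.minimum(mends[m], obs_end[take])
    ok = lo <= hi
    pid = persons["person_id"].to_numpy()[take][ok]
    d1 = rng.integers(lo[ok], hi[ok] + 1) if ok.any() else np.array([], dtype=int)

    records = [pd.DataFrame({"person_id": pid, "date": d1, "dose_number": 1})]
    if config.two_dose_fraction > 0 and len(pid):
        second = rng.random(len(pid)) < config.two_dose_fraction
        d2 = d1[second] + config.dose_gap_days
        keep = (d2 <= se) & (d2 <= obs_end[take][ok][second])
        records.append(
            pd.DataFrame(
                {"person_id": pid[second][keep], "date": d2[keep], "dose_number": 2}
            )
        )
    vacc = pd.concat(records, ignore_index=True)
    return vacc.sort_values(["person_id", "dose_number"], ignore_index=True)


def _seasonal_weights(config: SimulationConfig, span_start: int, span_end: int) -> np.ndarray:
    """Daily rate multipliers over [span_start, span_end], mean ~1 over a year."""
    days = np.arange(span_start, span_end + 1)
    phase = 2 * np.pi * (day_of_year(days) - config.seasonal_peak_day) / DAYS_PER_YEAR
    w = np.exp(config.seasonal_amplitude * np.cos(phase))
    return w / i0(config.seasonal_amplitude)  # E[exp(A cos U)] = I0(A)


def simulate_outcomes(
    persons: pd.DataFrame,
    periods: pd.DataFrame,
    vaccinations: pd.DataFrame,
    outcome_definitions: Sequence[OutcomeDefinition],
    config: SimulationConfig,
    first_only: bool = True,
) -> pd.DataFrame:
    """Draw outcome events over the historic-through-study span.

    Per person and outcome the event process is inhomogeneous Poisson with
    rate baseline x frailty x season, boosted by the true rate ratio inside
    each vaccination's time-at-risk window. The boost is realised by
    superposition: a baseline process over the whole span plus an independent
    excess process at rate (RR - 1) x baseline inside time-at-risk, which is
    exact for RR >= 1. With ``first_only`` (the default) only the first event
    per (person, outcome) is kept.
    """
    rng = _rng_for(config, "outcomes")
    span_start = config.historic_window[0]
    span_end = config.study_window[1]
    w = _seasonal_weights(config, span_start, span_end)
    cumw = np.r_[0.0, np.cumsum(w)]  # cumw[j] = weight-days before span_start + j

    obs_start = np.maximum(periods["start"].to_numpy(), span_start)
    obs_end = np.minimum(periods["end"].to_numpy(), span_end)
    frailty = persons["frailty"].to_numpy()
    pid_all = persons["person_id"].to_numpy()
    valid = obs_start <= obs_end
    lo_idx = obs_start - span_start
    hi_idx = obs_end - span_start + 1
    exposure_wdays = np.where(valid, cumw[np.clip(hi_idx, 0, None)] - cumw[np.clip(lo_idx, 0, None)], 0.0)

    # time-at-risk segments (for outcomes with RR > 1)
    if len(vaccinations):
        v_pid = vaccinations["person_id"].to_numpy()
        v_pos = np.searchsorted(pid_all, v_pid)  # person_id is 0..n-1 sorted
        t_lo = vaccinations["date"].to_numpy() + config.tar_start_day
        t_hi = np.minimum(
            vaccinations["date"].to_numpy() + config.tar_end_day, obs_end[v_pos]
        )
        t_lo = np.clip(t_lo - span_start, 0, len(w))
        t_hi = np.clip(t_hi - span_start + 1, 0, len(w))
        tar_wdays = np.maximum(cumw[t_hi] - cumw[t_lo], 0.0)
    else:
        v_pos = np.array([], dtype=int)
        t_lo = t_hi = np.array([], dtype=int)
        tar_wdays = np.array([], dtype=float)

    def _sample_days(lo_w: np.ndarray, hi_w: np.ndarray, counts: np.ndarray) -> np.ndarray:
        """Sample event days from the seasonal density restricted per segment."""
        lo_rep = np.repeat(lo_w, counts)
        hi_rep = np.repeat(hi_w, counts)
        u = rng.uniform(lo_rep, hi_rep)
        return span_start + np.searchsorted(cumw, u, side="right") - 1

    frames = []
    for od in outcome_definitions:
        lam = od.baseline_rate * frailty * exposure_wdays / DAYS_PER_YEAR
        n_base = rng.poisson(lam)
        days = _sample_days(cumw[lo_idx], cumw[hi_idx], n_base * valid)
        pid = np.repeat(pid_all, n_base * valid)
        if od.true_log_rr > 0 and len(v_pos):
            excess_lam = (
                od.baseline_rate
                * frailty[v_pos]
                * (np.exp(od.true_log_rr) - 1.0)
                * tar_wdays
                / DAYS_PER_YEAR
            )
            n_x = rng.poisson(excess_lam)
            days_x = _sample_days(cumw[t_lo], cumw[t_hi], n_x)
            pid = np.r_[pid, np.repeat(v_pid, n_x)]
            days = np.r_[days, days_x]
        frames.append(pd.DataFrame({"person_id": pid, "outcome_id": od.outcome_id, "date": days}))

    events = pd.concat(frames, ignore_index=True)
    if first_only and len(events):
        events = (
            events.groupby(["person_id", "outcome_id"], as_index=False, sort=False)["date"]
            .min()
            .loc[:, ["person_id", "outcome_id", "date"]]
        )
    return events.sort_values(["outcome_id", "person_id"], ignore_index=True)


def simulate_tables(
    config: SimulationConfig,
    outcome_definitions: Sequence[OutcomeDefinition] | None = None,
) -> tuple[EventTables, list[OutcomeDefinition]]:
    """Run the full generator and return the event tables plus outcome truth."""
    if outcome_definitions is None:
        outcome_definitions = make_outcome_definitions(config)
    persons, periods, visits = simulate_population(config)
    vacc = simulate_vaccinations(persons, periods, config)
    outcomes = simulate_outcomes(persons, periods, vacc, outcome_definitions, config)
    return EventTables(persons, periods, visits, vacc, outcomes), list(outcome_definitions)


# ---------------------------------------------------------------------------
# delimited-file interface

_TABLE_FILES = {
    "persons": "person.csv",
    "observation_periods": "observation_period.csv",
    "visits": "visit_occurrence.csv",
    "vaccinations": "vaccination.csv",
    "outcomes": "outcome.csv",
}
_DATE_COLS = {"birth_date", "start", "end", "date"}


def write_tables(tables: EventTables, directory, config: SimulationConfig | None = None) -> None:
    """Write the five tables as CSV with ISO-8601 dates, plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        df = getattr(tables, attr).copy()
        for col in df.columns:
            if col in _DATE_COLS:
                df[col] = df[col].map(to_iso)
        df.to_csv(directory / fname, index=False)
    if config is not None:
        (directory / "config.json").write_text(config.to_json())
        manifest = {"seed": config.seed, "config_hash": config.config_hash()}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_tables(directory) -> EventTables:
    directory = Path(directory)
    loaded = {}
    for attr, fname in _TABLE_FILES.items():
        df = pd.read_csv(directory / fname)
        for col in df.columns:
            if col in _DATE_COLS:
                df[col] = df[col].map(to_day)
        loaded[attr] = df
    return EventTables(**loaded)
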