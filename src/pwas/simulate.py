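"""Synthetic prescription-registry generator with planted trigger effects.

The generator emulates the linkable national-register inputs the screening
pipeline consumes: a dispensing table (patient, ATC-style drug code,
dispense day) and a first-AMI event table (patient, index day, hospital or
death ascertainment, age, sex), for one "country" per call.  Two calls
sharing ``planted_effects`` emulate two countries with common true
triggering effects.

Data-generating model (a stand-in — the real registers are observational
and publish no generative model):

* Dispensing.  Each drug has a use prevalence; among users, *acute* drugs
  dispense as a homogeneous point process (``acute_rate`` per patient-year,
  uniform days over the observation window), while *chronic* drugs start at
  a uniformly drawn initiation day and refill every
  ``refill_interval_days +/- refill_jitter_days`` until the end of
  observation, without stopping.  Persistence-to-the-end is deliberate: it
  reproduces the upward "persistent user bias" of near-periodic refills in
  a case-crossover contrast, whereas acute drugs are stationary and
  unbiased under a null effect.
* Events.  Day ``t`` carries a discrete hazard
  ``baseline_hazard * prod_j RR_j ** [drug j dispensed in (t - W, t)]``
  with trigger window ``W = trigger_window_days``; the first event day (if
  any) becomes the patient's AMI, so the planted rate ratio equals the
  case-crossover estimand when the analysis case window matches ``W``.
  Events before day 42 are discarded (the longest control window must fit
  inside observation); a warning is raised if the design degenerates
  (> 50% of patients lost this way).

Dates are integer day offsets, 0-based, from a per-country epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DrugProfile",
    "SimulationConfig",
    "generate_registry",
    "planted_truth",
    "make_profiles",
    "screening_config",
    "write_registry",
    "read_dispensings",
    "read_events",
    "read_truth",
    "TABLE1_AGE_BINS",
    "TABLE1_AGE_PROBS",
]

# Age distribution of AMI cases in a Nordic national-register cohort:
# (low, high) year bins with sampling probabilities, plus the male fraction.
TABLE1_AGE_BINS = [(18, 29), (30, 39), (40, 49), (50, 59), (60, 69),
                   (70, 79), (80, 89), (90, 99), (100, 105)]
TABLE1_AGE_PROBS = [0.001, 0.004, 0.023, 0.076, 0.169, 0.252, 0.355,
                    0.119, 0.001]
MALE_FRACTION = 0.536


@dataclass
class DrugProfile:
    """Dispensing behaviour of one drug.

    acute: homogeneous dispensing at ``acute_rate`` per patient-year among
    users.  chronic: periodic refills every ``refill_interval_days`` with
    uniform integer jitter ``+/- refill_jitter_days`` from a uniformly
    drawn initiation day to the end of observation.
    """

    use_prevalence: float
    mode: str = "acute"
    acute_rate: float = 0.0
    refill_interval_days: int = 0
    refill_jitter_days: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.use_prevalence <= 1.0:
            raise ValueError("use_prevalence must be in [0, 1]")
        if self.mode not in ("acute", "chronic"):
            raise ValueError("mode must be 'acute' or 'chronic'")
        if self.mode == "acute" and self.acute_rate < 0:
            raise ValueError("acute_rate must be nonnegative")
        if self.mode == "chronic" and self.refill_interval_days <= 0:
            raise ValueError("refill_interval_days must be positive for "
                             "chronic drugs")
        if self.refill_jitter_days < 0:
            raise ValueError("refill_jitter_days must be nonnegative")


@dataclass
class SimulationConfig:
    """Full specification of one synthetic country registry."""

    n_patients: int
    drug_profiles: Dict[str, DrugProfile]
    observation_days: int = 3650
    planted_effects: Dict[str, float] = field(default_factory=dict)
    trigger_window_days: int = 7
    baseline_hazard: float = 1e-4
    age_bins: list = field(default_factory=lambda: list(TABLE1_AGE_BINS))
    age_probs: list = field(default_factory=lambda: list(TABLE1_AGE_PROBS))
    male_fraction: float = MALE_FRACTION
    death_fraction: float = 0.17
    country_label: str = "SIM"
    seed: int = 0

    @property
    def n_drugs(self) -> int:
        return len(self.drug_profiles)

    def validate(self) -> None:
        if self.n_patients <= 0 or self.observation_days <= 42:
            raise ValueError("need n_patients > 0 and observation_days > 42")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.trigger_window_days <= 0:
            raise ValueError("trigger_window_days must be positive")
        if not 0.0 <= self.death_fraction <= 1.0:
            raise ValueError("death_fraction must be in [0, 1]")
        for code, rr in self.planted_effects.items():
            if rr <= 0:
                raise ValueError(f"planted rate ratio for {code} must be > 0")
            if code not in self.drug_profiles:
                raise ValueError(f"planted effect for unknown drug {code}")
        if abs(sum(self.age_probs) - 1.0) > 1e-6:
            raise ValueError("age_probs must sum to 1")


def planted_truth(config: SimulationConfig) -> Dict[str, float]:
    """True rate ratio per drug (implicit 1.0 for unlisted drugs)."""
    return {code: float(config.planted_effects.get(code, 1.0))
            for code in config.drug_profiles}


def _atc_like_codes(n: int) -> list:
    """Deterministic ATC-5th-level-shaped codes (letter 2digit 2letter 2digit)."""
    groups = "ABCDGHJLMNPRSV"
    codes = []
    for i in range(n):
        g = groups[i % len(groups)]
        codes.append(f"{g}{(i // len(groups)) % 100:02d}XA{i % 100 + 1:02d}")
    return codes


def make_profiles(n_drugs: int, mode: str = "acute",
                  use_prevalence: float = 0.8, acute_rate: float = 6.0,
                  refill_interval_days: int = 90,
                  refill_jitter_days: int = 7) -> Dict[str, DrugProfile]:
    """Uniform drug universe with ATC-like codes."""
    prof = DrugProfile(use_prevalence=use_prevalence, mode=mode,
                       acute_rate=acute_rate,
                       refill_interval_days=refill_interval_days if mode == "chronic" else 0,
                       refill_jitter_days=refill_jitter_days if mode == "chronic" else 0)
    return {code: replace(prof) for code in _atc_like_codes(n_drugs)}


def screening_config(n_patients: int = 20_000, n_drugs: int = 40,
                     planted: Optional[Dict[int, float]] = None,
                     seed: int = 0, country_label: str = "SIM",
                     use_prevalence: float = 0.5, acute_rate: float = 4.0,
                     baseline_hazard: float = 2e-4,
                     observation_days: int = 1460) -> SimulationConfig:
    """Desk-scale acute-drug screening test bed.

    The defaults emulate a high-risk elderly cohort followed for four
    years: each drug is used by half the cohort at ~4 dispensings per
    user-year, and the baseline event hazard (~7%/year) yields roughly a
    quarter of the cohort as first-event cases, so every drug accrues a
    few hundred discordant pairs — enough for a per-drug log-RR standard
    error near 0.1.  ``planted`` maps drug *indices* (position in the
    generated universe) to rate ratios; drug codes are deterministic, so
    two configs with the same ``planted`` share true effects (two-country
    emulation).
    """
    profiles = make_profiles(n_drugs, mode="acute",
                             use_prevalence=use_prevalence,
                             acute_rate=acute_rate)
    codes = list(profiles)
    effects = {codes[i]: rr for i, rr in (planted or {}).items()}
    return SimulationConfig(
        n_patients=n_patients, drug_profiles=profiles,
        observation_days=observation_days, planted_effects=effects,
        baseline_hazard=baseline_hazard, country_label=country_label,
        seed=seed)


def chronic_config(n_patients: int = 20_000,
                   refill_interval_days: int = 14,
                   refill_jitter_days: int = 2,
                   use_prevalence: float = 0.6,
                   baseline_hazard: float = 2e-4,
                   observation_days: int = 1095,
                   seed: int = 0,
                   country_label: str = "SIM") -> SimulationConfig:
    """Single chronic periodic-refill drug under a null effect.

    Users initiate therapy at a uniform day and refill on a near-periodic
    schedule until the end of observation, so the prevalence of use grows
    over calendar time.  Looking back from an event, recent initiators can
    be exposed in the case window but not yet in the earlier control
    window; the reverse cannot happen (nobody stops), which inflates the
    discordant ratio above 1 even at a true rate ratio of 1 — the
    persistent-user bias of case-crossover contrasts for chronically
    refilled drugs.
    """
    profiles = {"C01XA01": DrugProfile(
        use_prevalence=use_prevalence, mode="chronic",
        refill_interval_days=refill_interval_days,
        refill_jitter_days=refill_jitter_days)}
    return SimulationConfig(
        n_patients=n_patients, drug_profiles=profiles,
        observation_days=observation_days,
        baseline_hazard=baseline_hazard, seed=seed,
        country_label=country_label)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_dispensings(config: SimulationConfig, rng: np.random.Generator
                      ) -> pd.DataFrame:
    n, T = config.n_patients, config.observation_days
    codes = list(config.drug_profiles)
    pid_parts, code_parts, day_parts = [], [], []
    for ci, (code, prof) in enumerate(config.drug_profiles.items()):
        users = np.flatnonzero(rng.random(n) < prof.use_prevalence)
        if users.size == 0:
            continue
        if prof.mode == "acute":
            lam = prof.acute_rate * T / 365.0
            counts = rng.poisson(lam, users.size)
            total = int(counts.sum())
            if total == 0:
                continue
            pids = np.repeat(users, counts)
            days = rng.integers(0, T, total)
        else:
            start = rng.integers(0, T, users.size)
            interval = prof.refill_interval_days
            jit = prof.refill_jitter_days
            max_refills = T // interval + 2
            k = np.arange(max_refills)
            sched = start[:, None] + k[None, :] * interval
            if jit > 0:
                sched = sched + rng.integers(-jit, jit + 1,
                                             sched.shape)
            sched[:, 0] = start  # initiation day itself is not jittered
            valid = (sched >= 0) & (sched < T) & (
                start[:, None] + k[None, :] * interval < T)
            pids = np.repeat(users, valid.sum(axis=1))
            days = sched[valid]
        pid_parts.append(pids)
        code_parts.append(np.full(pids.size, ci, dtype=np.int32))
        day_parts.append(days)
    if not pid_parts:
        return pd.DataFrame({"patient_id": np.array([], np.int64),
                             "drug_code": pd.Categorical([], categories=codes),
                             "dispense_date": np.array([], np.int64)})
    pids = np.concatenate(pid_parts).astype(np.int64)
    drug_idx = np.concatenate(code_parts)
    days = np.concatenate(day_parts).astype(np.int64)
    order = np.lexsort((days, drug_idx, pids))
    return pd.DataFrame({
        "patient_id": pids[order],
        "drug_code": pd.Categorical.from_codes(drug_idx[order], codes),
        "dispense_date": days[order]})


def _draw_event_days(config: SimulationConfig, dispensings: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    """First event day per patient (-1 if none), by daily Bernoulli hazard."""
    n, T = config.n_patients, config.observation_days
    W = config.trigger_window_days
    h0 = config.baseline_hazard
    event_day = np.full(n, -1, dtype=np.int64)

    planted = {c: r for c, r in config.planted_effects.items() if r != 1.0}
    if not planted:
        # constant hazard: the first-event day is geometric
        p0 = 1.0 - np.exp(-h0)
        first = rng.geometric(p0, n) - 1
        return np.where(first < T, first, -1).astype(np.int64)
    disp_by_drug = {}
    if planted:
        sub = dispensings[dispensings["drug_code"].isin(planted)]
        for code, grp in sub.groupby("drug_code", observed=True):
            disp_by_drug[code] = (grp["patient_id"].to_numpy(np.int64),
                                  grp["dispense_date"].to_numpy(np.int64))

    chunk = max(256, int(8e6 // T))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        log_mult = np.zeros((m, T))
        for code, rr in planted.items():
            if code not in disp_by_drug:
                continue
            pids, days = disp_by_drug[code]
            sel = (pids >= lo) & (pids < hi)
            if not sel.any():
                continue
            rows, starts = pids[sel] - lo, days[sel]
            # dispensing on day s elevates hazard on days s+1 .. s+W
            acc = np.zeros((m, T + 1), dtype=np.int32)
            a = np.minimum(starts + 1, T)
            b = np.minimum(starts + 1 + W, T)
            np.add.at(acc, (rows, a), 1)
            np.add.at(acc, (rows, b), -1)
            exposed = np.cumsum(acc[:, :T], axis=1) > 0
            log_mult += np.log(rr) * exposed
        p = 1.0 - np.exp(-h0 * np.exp(log_mult))
        hits = rng.random((m, T)) < p
        any_hit = hits.any(axis=1)
        first = np.argmax(hits, axis=1)
        event_day[lo:hi][any_hit] = first[any_hit]
    return event_day


def generate_registry(config: SimulationConfig
                      ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """Generate (dispensing table, event table, planted-truth map).

    Identical config (including seed) gives byte-identical tables.
    Patients whose first event falls before day 42 are dropped from the
    event table (their later history is censored by the first-event rule).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    dispensings = _draw_dispensings(config, rng)
    event_day = _draw_event_days(config, dispensings, rng)

    early = (event_day >= 0) & (event_day < 42)
    if early.sum() > 0.5 * config.n_patients:
        warnings.warn(
            "more than half of all patients had their first event before "
            "day 42; the hazard is too high for this design", RuntimeWarning)
    keep = np.flatnonzero(event_day >= 42)

    bins = np.asarray(config.age_bins)
    bin_idx = rng.choice(len(bins), size=keep.size, p=config.age_probs)
    ages = rng.integers(bins[bin_idx, 0], bins[bin_idx, 1] + 1)
    sexes = np.where(rng.random(keep.size) < config.male_fraction,
                     "male", "female")
    sources = np.where(rng.random(keep.size) < config.death_fraction,
                       "death", "hospital")
    events = pd.DataFrame({
        "patient_id": keep.astype(np.int64),
        "index_date": event_day[keep],
        "source": sources,
        "age_years": ages.astype(np.int64),
        "sex": sexes,
    })
    return dispensings, events, planted_truth(config)


# ---------------------------------------------------------------------------
# text I/O (tab-separated, header row)
# ---------------------------------------------------------------------------


def write_registry(dispensings: pd.DataFrame, events: pd.DataFrame,
                   truth: Dict[str, float], outdir, label: str) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dispensings.to_csv(outdir / f"{label}_dispensing.tsv", sep="\t",
                       index=False)
    events.to_csv(outdir / f"{label}_events.tsv", sep="\t", index=False)
    pd.DataFrame({"drug_code": list(truth), "true_rr": list(truth.values())}
                 ).to_csv(outdir / f"{label}_truth.tsv", sep="\t",
                          index=False)


def read_dispensings(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"patient_id": np.int64, "drug_code": str,
                            "dispense_date": np.int64})
    return df[["patient_id", "drug_code", "dispense_date"]]


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"patient_id": np.int64, "index_date": np.int64,
                            "source": str, "age_years": np.int64, "sex": str})
    return df[["patient_id", "index_date", "source", "age_years", "sex"]]


def read_truth(path) -> Dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_code": str})
    return dict(zip(df["drug_code"], df["true_rr"].astype(float)))
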