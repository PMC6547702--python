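"""Case-crossover exposure construction from registry tables.

Each AMI patient serves as their own control: drug dispensing during a
case window shortly before the index date (default offsets 1..7 days
before, inclusive) is compared with an earlier control window of equal
length (default 15..21), separated by a wash-out gap.  Day 0 — the index
date itself — is never part of any window, since same-day dispensing is
ambiguous between cause and consequence of the event.

The module turns (dispensing, event) tables into per-patient binary
case/control exposure bits, applies the eligibility filters (hospital-only
ascertainment, prior-year prescription requirement, age dichotomization),
and reduces the pairs to the sufficient statistics of the 1:1 conditional
likelihood: the pair-difference matrix and the per-drug discordant counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "EligibilityFilters",
    "ExposureMatrix",
    "DifferenceMatrix",
    "DiscordantCounts",
    "EmptyAnalysisError",
    "build_exposures",
    "difference_matrix",
    "discordant_counts",
    "write_exposure_summary",
]

DISPENSING_COLUMNS = ["patient_id", "drug_code", "dispense_date"]
EVENT_COLUMNS = ["patient_id", "index_date", "source", "age_years", "sex"]


class EmptyAnalysisError(ValueError):
    """Raised when no informative pairs remain after filtering."""


@dataclass(frozen=True)
class WindowSpec:
    """Inclusive day-offset windows before the index date.

    Offsets count whole days before the index date (offset 1 = the day
    before).  The default is the 7-day design (case 1..7, control 15..21,
    wash-out 8..14); the extended sensitivity design is 1..14 / 29..42.
    """

    case_range: Tuple[int, int] = (1, 7)
    control_range: Tuple[int, int] = (15, 21)

    def __post_init__(self) -> None:
        c0, c1 = self.case_range
        k0, k1 = self.control_range
        if not (1 <= c0 <= c1 and k0 <= k1):
            raise ValueError("window ranges must be increasing, offsets >= 1")
        if c1 - c0 != k1 - k0:
            raise ValueError("case and control windows must have equal length")
        if k0 <= c1:
            raise ValueError("control window must lie strictly earlier "
                             "(larger offsets) than the case window")

    @property
    def washout_range(self) -> Tuple[int, int]:
        return (self.case_range[1] + 1, self.control_range[0] - 1)

    @property
    def max_offset(self) -> int:
        return self.control_range[1]

    def swapped(self) -> "WindowSpec":
        """Control-as-case variant (used to audit window symmetry)."""
        obj = object.__new__(WindowSpec)
        object.__setattr__(obj, "case_range", self.control_range)
        object.__setattr__(obj, "control_range", self.case_range)
        return obj


EXTENDED_WINDOWS = WindowSpec(case_range=(1, 14), control_range=(29, 42))


@dataclass
class EligibilityFilters:
    """Conjunctive patient-level filters.

    ``require_prior_year_rx`` keeps only patients with at least one
    dispensing at offsets 1..365 before the index date (the Swedish-register
    style requirement).  ``age_split_at``/``age_side`` keep the subgroup
    below ('lt') or at/above ('ge') the cut.
    """

    hospital_only: bool = False
    require_prior_year_rx: bool = False
    age_split_at: Optional[int] = None
    age_side: str = "lt"

    def __post_init__(self) -> None:
        if self.age_side not in ("lt", "ge"):
            raise ValueError("age_side must be 'lt' or 'ge'")


@dataclass
class ExposureMatrix:
    """Per-patient, per-drug binary exposure bits for both windows."""

    patients: np.ndarray
    drugs: np.ndarray
    case_bits: np.ndarray      # (n_patients, n_drugs) uint8
    control_bits: np.ndarray

    def __post_init__(self) -> None:
        n, p = len(self.patients), len(self.drugs)
        if self.case_bits.shape != (n, p) or self.control_bits.shape != (n, p):
            raise ValueError("bit matrices must be patients x drugs")


@dataclass
class DifferenceMatrix:
    """Informative pair differences d = case_bits - control_bits.

    Rows with all-zero differences (non-informative pairs) are removed;
    ``patients`` maps the remaining rows back to their identifiers.
    """

    patients: np.ndarray
    drugs: np.ndarray
    d: np.ndarray  # (n_informative, n_drugs) int8 in {-1, 0, 1}

    @property
    def n_pairs(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class DiscordantCounts:
    """Per-drug discordant-pair counts (case-only / control-only)."""

    drug_code: str
    n10: int
    n01: int


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns {missing}")
    if events["patient_id"].duplicated().any():
        dup = events.loc[events["patient_id"].duplicated(), "patient_id"]
        raise ValueError(
            f"duplicate patients in events table (first episode only "
            f"expected): e.g. {dup.iloc[0]!r}")
    return events


def build_exposures(dispensings: pd.DataFrame, events: pd.DataFrame,
                    window: WindowSpec | None = None,
                    filters: EligibilityFilters | None = None
                    ) -> ExposureMatrix:
    """Construct the case/control exposure matrix.

    A bit is set iff the patient has >= 1 dispensing of the drug with
    ``index_date - dispense_date`` inside the inclusive window range.
    Patients failing the eligibility filters are dropped, then patients
    with no dispensing in either window, then drug columns with no exposed
    period in either window.  Dispensings for patients absent from the
    events table are ignored (count logged).
    """
    window = window or WindowSpec()
    filters = filters or EligibilityFilters()
    events = _check_events(events)

    ev = events
    if filters.hospital_only:
        ev = ev[ev["source"] == "hospital"]
    if filters.age_split_at is not None:
        if filters.age_side == "lt":
            ev = ev[ev["age_years"] < filters.age_split_at]
        else:
            ev = ev[ev["age_years"] >= filters.age_split_at]

    merged = dispensings.merge(
        ev[["patient_id", "index_date"]], on="patient_id", how="inner")
    n_orphan = dispensings["patient_id"].nunique() - merged["patient_id"].nunique()
    if n_orphan > 0:
        logger.info("ignored dispensings for %d patients absent from the "
                    "event table (or removed by filters)", n_orphan)
    offset = merged["index_date"] - merged["dispense_date"]

    if filters.require_prior_year_rx:
        prior = merged.loc[(offset >= 1) & (offset <= 365), "patient_id"]
        keep = set(prior.unique())
        mask = merged["patient_id"].isin(keep)
        merged, offset = merged[mask], offset[mask]

    c0, c1 = window.case_range
    k0, k1 = window.control_range
    in_case = (offset >= c0) & (offset <= c1)
    in_control = (offset >= k0) & (offset <= k1)

    windowed = merged[in_case | in_control]
    if windowed.empty:
        return ExposureMatrix(
            patients=np.array([], dtype=object),
            drugs=np.array([], dtype=object),
            case_bits=np.zeros((0, 0), np.uint8),
            control_bits=np.zeros((0, 0), np.uint8))

    patients, pat_idx = np.unique(windowed["patient_id"].to_numpy(),
                                  return_inverse=False), None
    drugs = np.unique(windowed["drug_code"].to_numpy())
    pat_idx = pd.Index(patients).get_indexer(windowed["patient_id"])
    drug_idx = pd.Index(drugs).get_indexer(windowed["drug_code"])

    case_bits = np.zeros((len(patients), len(drugs)), np.uint8)
    control_bits = np.zeros_like(case_bits)
    m_case = in_case[in_case | in_control].to_numpy()
    case_bits[pat_idx[m_case], drug_idx[m_case]] = 1
    control_bits[pat_idx[~m_case], drug_idx[~m_case]] = 1
    logger.info("exposure matrix: %d patients x %d drugs (case window %s, "
                "control window %s)", len(patients), len(drugs),
                window.case_range, window.control_range)
    return ExposureMatrix(patients=patients, drugs=drugs,
                          case_bits=case_bits, control_bits=control_bits)


def difference_matrix(exposures: ExposureMatrix) -> DifferenceMatrix:
    """Reduce exposures to informative pair differences.

    Raises :class:`EmptyAnalysisError` when no pair is informative, so an
    empty analysis never masquerades as a successful one.
    """
    d = exposures.case_bits.astype(np.int8) - exposures.control_bits.astype(np.int8)
    informative = (d != 0).any(axis=1)
    if not informative.any():
        raise EmptyAnalysisError(
            "no informative pairs: every patient is concordant in both "
            "windows for every drug")
    return DifferenceMatrix(patients=exposures.patients[informative],
                            drugs=exposures.drugs,
                            d=d[informative])


def discordant_counts(exposures: ExposureMatrix) -> pd.DataFrame:
    """Per-drug 2x2 window-concordance table.

    Returns a DataFrame (drug_code, n10, n01, n11, n00): case-only,
    control-only, both-window, neither-window patient counts.  For every
    drug the four counts sum to the number of retained patients.
    """
    c = exposures.case_bits.astype(np.int64)
    k = exposures.control_bits.astype(np.int64)
    n10 = (c * (1 - k)).sum(axis=0)
    n01 = ((1 - c) * k).sum(axis=0)
    n11 = (c * k).sum(axis=0)
    n00 = len(exposures.patients) - n10 - n01 - n11
    return pd.DataFrame({
        "drug_code": exposures.drugs, "n10": n10, "n01": n01,
        "n11": n11, "n00": n00})


def write_exposure_summary(exposures: ExposureMatrix, path) -> None:
    """Write the per-drug exposure summary as tab-separated text."""
    discordant_counts(exposures).to_csv(path, sep="\t", index=False)
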