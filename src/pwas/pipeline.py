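"""End-to-end pharmacopoeia-wide screening runs.

One run ingests (or simulates) two or more country registries, builds
case-crossover exposures per country, runs BOLASSO selection, intersects
the per-country selected drug sets, combines the refit estimates of the
common hits with a fixed-effect model, and writes tab-separated reports
plus a machine-readable summary.  The summary records the per-stage
funnel: drugs dispensed overall, drugs dispensed in either analysis
window, drugs selected per country, and the common-hit count.

Sensitivity variants mirror the published design: ``extended_windows``
(case 1..14, control 29..42), ``hospital_only`` (exclude out-of-hospital
deaths), and the age subgroups ``age_lt80`` / ``age_ge80``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .bolasso import (BootstrapSpec, SelectionResult, bolasso_select,
                      write_selection_report)
from .clogit import SolverConfig
from .exposure import (EXTENDED_WINDOWS, EligibilityFilters,
                       EmptyAnalysisError, WindowSpec, build_exposures,
                       difference_matrix, discordant_counts,
                       write_exposure_summary)
from .meta import CountryEstimate, MetaEstimate, common_hits, fixed_effect
from .simulate import (SimulationConfig, generate_registry,
                       read_dispensings, read_events, screening_config)

logger = logging.getLogger(__name__)

__all__ = ["CountrySource", "RunConfig", "RunArtifacts", "run_pwas",
           "make_report", "VARIANTS", "apply_variant"]

VARIANTS = ("main", "extended_windows", "hospital_only", "age_lt80",
            "age_ge80")


@dataclass
class CountrySource:
    """One country's input: registry file paths or a simulation config."""

    label: str
    dispensings_path: Optional[str] = None
    events_path: Optional[str] = None
    sim: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        file_mode = self.dispensings_path is not None and self.events_path is not None
        if file_mode == (self.sim is not None):
            raise ValueError(
                f"country {self.label!r}: give either both registry paths "
                "or a simulation config")


@dataclass
class RunConfig:
    countries: List[CountrySource]
    window: WindowSpec = field(default_factory=WindowSpec)
    filters: EligibilityFilters = field(default_factory=EligibilityFilters)
    solver: SolverConfig = field(default_factory=SolverConfig)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    outdir: Optional[str] = None
    variant: str = "main"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if len(self.countries) < 2:
            raise ValueError("need at least two countries")


def apply_variant(window: WindowSpec, filters: EligibilityFilters,
                  variant: str):
    """Variant presets override window/filters consistently."""
    filters = dataclasses.replace(filters)
    if variant == "extended_windows":
        window = EXTENDED_WINDOWS
    elif variant == "hospital_only":
        filters.hospital_only = True
    elif variant == "age_lt80":
        filters.age_split_at, filters.age_side = 80, "lt"
    elif variant == "age_ge80":
        filters.age_split_at, filters.age_side = 80, "ge"
    return window, filters


def _config_hash(config: RunConfig) -> str:
    # hash the scientific configuration only — where outputs land must not
    # change the provenance identity of a run
    canonical = dataclasses.replace(config, outdir=None)
    return hashlib.sha256(repr(canonical).encode()).hexdigest()[:16]


@dataclass
class CountryArtifacts:
    label: str
    n_patients_in: int
    n_drugs_dispensed: int
    n_patients_retained: int
    n_drugs_either_window: int
    counts: pd.DataFrame            # drug_code, n10, n01, n11, n00
    selection: SelectionResult


@dataclass
class RunArtifacts:
    config: RunConfig
    config_hash: str
    countries: List[CountryArtifacts]
    common: List[str]
    combined: List[MetaEstimate]
    summary: Dict


def _country_seed(master: int, k: int) -> int:
    children = np.random.SeedSequence(master).spawn(k + 1)
    return int(children[k].generate_state(1)[0] % (2**31))


def _load_country(src: CountrySource, run_seed: int, k: int):
    if src.sim is not None:
        sim = dataclasses.replace(
            src.sim, seed=_country_seed(run_seed, k),
            country_label=src.label)
        dispensings, events, _ = generate_registry(sim)
    else:
        dispensings = read_dispensings(src.dispensings_path)
        events = read_events(src.events_path)
    return dispensings, events


def run_pwas(config: RunConfig) -> RunArtifacts:
    """Execute the full screening pipeline for all configured countries."""
    window, filters = apply_variant(config.window, config.filters,
                                    config.variant)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    per_country: List[CountryArtifacts] = []
    for k, src in enumerate(config.countries):
        stage = f"country {src.label}"
        dispensings, events = _load_country(src, config.seed, k)
        logger.info("%s: %d dispensing rows, %d events", stage,
                    len(dispensings), len(events))
        exposures = build_exposures(dispensings, events, window, filters)
        counts = discordant_counts(exposures)
        try:
            D = difference_matrix(exposures)
        except EmptyAnalysisError:
            raise EmptyAnalysisError(f"{stage}: no informative pairs")
        sel = bolasso_select(
            D,
            dataclasses.replace(config.bootstrap,
                                seed=_country_seed(config.seed, 1000 + k)),
            config.solver)
        art = CountryArtifacts(
            label=src.label,
            n_patients_in=len(events),
            n_drugs_dispensed=int(dispensings["drug_code"].nunique()),
            n_patients_retained=len(exposures.patients),
            n_drugs_either_window=len(exposures.drugs),
            counts=counts,
            selection=sel)
        per_country.append(art)
        logger.info("%s: %d/%d patients retained, %d/%d drugs in either "
                    "window, %d selected", stage, art.n_patients_retained,
                    art.n_patients_in, art.n_drugs_either_window,
                    art.n_drugs_dispensed, len(sel.selected))
        if outdir:
            write_exposure_summary(exposures,
                                   outdir / f"{src.label}_exposures.tsv")
            write_selection_report(sel, outdir / f"{src.label}_selection.tsv")

    common = sorted(common_hits([c.selection for c in per_country]))
    combined: List[MetaEstimate] = []
    for code in common:
        ests = []
        for art in per_country:
            refit = art.selection.refit
            idx = np.flatnonzero(refit.drugs == code)
            if idx.size != 1:
                continue
            j = int(idx[0])
            if not (np.isfinite(refit.beta[j]) and np.isfinite(refit.se[j])
                    and refit.se[j] > 0):
                logger.warning("%s: degenerate refit in %s, excluded from "
                               "combination", code, art.label)
                continue
            ests.append(CountryEstimate(
                drug_code=code, log_rr=float(refit.beta[j]),
                se=float(refit.se[j]), country_label=art.label))
        if len(ests) == len(per_country):
            combined.append(fixed_effect(ests, config.solver.z_level))
        else:
            logger.warning("%s: skipped in combined table (incomplete "
                           "country estimates)", code)

    summary = {
        "pwas_version": _version,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "variant": config.variant,
        "case_window": list(window.case_range),
        "control_window": list(window.control_range),
        "common_hit_count": len(common),
        "common_hits": common,
        "countries": {
            art.label: {
                "patients_in": art.n_patients_in,
                "patients_retained": art.n_patients_retained,
                "drugs_dispensed": art.n_drugs_dispensed,
                "drugs_either_window": art.n_drugs_either_window,
                "selected_count": int(len(art.selection.selected)),
            } for art in per_country
        },
    }
    artifacts = RunArtifacts(config=config, config_hash=summary["config_hash"],
                             countries=per_country, common=common,
                             combined=combined, summary=summary)
    if outdir:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report = make_report(artifacts)
        report.to_csv(outdir / "combined_report.tsv", sep="\t", index=False)
    return artifacts


def make_report(artifacts: RunArtifacts) -> pd.DataFrame:
    """Combined-hit report, one row per common drug (published-table layout).

    Columns: ATC code, per-country discordant counts and refit RR (95% CI),
    and the fixed-effect combined RR (95% CI); sorted by ATC code.
    """
    rows = []
    combined_by_code = {m.drug_code: m for m in artifacts.combined}
    for code in artifacts.common:
        row = {"atc_code": code}
        for art in artifacts.countries:
            lbl = art.label
            sub = art.counts[art.counts["drug_code"] == code]
            row[f"{lbl}_n10"] = int(sub["n10"].iloc[0]) if len(sub) else 0
            row[f"{lbl}_n01"] = int(sub["n01"].iloc[0]) if len(sub) else 0
            refit = art.selection.refit
            idx = np.flatnonzero(refit.drugs == code)
            if idx.size == 1 and np.isfinite(refit.beta[idx[0]]):
                j = int(idx[0])
                row[f"{lbl}_rr"] = round(float(np.exp(refit.beta[j])), 4)
                row[f"{lbl}_ci_low"] = round(float(refit.ci_low[j]), 4)
                row[f"{lbl}_ci_high"] = round(float(refit.ci_high[j]), 4)
            else:
                row[f"{lbl}_rr"] = row[f"{lbl}_ci_low"] = \
                    row[f"{lbl}_ci_high"] = float("nan")
        m = combined_by_code.get(code)
        row["combined_rr"] = round(m.rr, 4) if m else float("nan")
        row["combined_ci_low"] = round(m.ci_low, 4) if m else float("nan")
        row["combined_ci_high"] = round(m.ci_high, 4) if m else float("nan")
        rows.append(row)
    cols = ["atc_code"]
    for art in artifacts.countries:
        cols += [f"{art.label}_{c}" for c in
                 ("n10", "n01", "rr", "ci_low", "ci_high")]
    cols += ["combined_rr", "combined_ci_low", "combined_ci_high"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# flat YAML run configuration
# ---------------------------------------------------------------------------


def config_from_yaml(path) -> RunConfig:
    """Build a :class:`RunConfig` from a flat YAML document.

    File mode uses ``countryK_label`` / ``countryK_dispensings`` /
    ``countryK_events`` keys (K = 1, 2, ...).  Simulation mode sets
    ``simulate: true`` with ``n_patients``, ``n_drugs`` and an optional
    ``planted`` map of drug index -> rate ratio shared by both countries.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    seed = int(doc.get("seed", 0))
    countries: List[CountrySource] = []
    if doc.get("simulate"):
        planted = {int(k): float(v)
                   for k, v in (doc.get("planted") or {}).items()}
        n_countries = int(doc.get("n_countries", 2))
        for k in range(n_countries):
            label = doc.get(f"country{k + 1}_label", f"SIM{k + 1}")
            sim = screening_config(
                n_patients=int(doc.get("n_patients", 8000)),
                n_drugs=int(doc.get("n_drugs", 40)),
                planted=planted, country_label=label,
                use_prevalence=float(doc.get("use_prevalence", 0.8)),
                acute_rate=float(doc.get("acute_rate", 6.0)),
                baseline_hazard=float(doc.get("baseline_hazard", 1e-4)),
                observation_days=int(doc.get("observation_days", 3650)))
            countries.append(CountrySource(label=label, sim=sim))
    else:
        k = 1
        while f"country{k}_dispensings" in doc:
            countries.append(CountrySource(
                label=doc.get(f"country{k}_label", f"C{k}"),
                dispensings_path=doc[f"country{k}_dispensings"],
                events_path=doc[f"country{k}_events"]))
            k += 1
    window = WindowSpec(
        case_range=tuple(doc.get("case_window", (1, 7))),
        control_range=tuple(doc.get("control_window", (15, 21))))
    filters = EligibilityFilters(
        hospital_only=bool(doc.get("hospital_only", False)),
        require_prior_year_rx=bool(doc.get("require_prior_year_rx", False)),
        age_split_at=doc.get("age_split_at"),
        age_side=doc.get("age_side", "lt"))
    lambda_mode = doc.get("lambda_mode", "per_bootstrap_cv")
    if not isinstance(lambda_mode, str):
        lambda_mode = float(lambda_mode)
    bootstrap = BootstrapSpec(
        n_bootstrap=int(doc.get("n_bootstrap", 100)),
        consensus=float(doc.get("consensus", 1.0)),
        lambda_mode=lambda_mode, seed=seed)
    solver = SolverConfig(
        tol=float(doc.get("tol", 1e-8)),
        max_iter=int(doc.get("max_iter", 10_000)),
        n_lambda=int(doc.get("n_lambda", 100)),
        lambda_min_ratio=float(doc.get("lambda_min_ratio", 1e-3)),
        cv_folds=int(doc.get("cv_folds", 5)))
    return RunConfig(countries=countries, window=window, filters=filters,
                     solver=solver, bootstrap=bootstrap,
                     outdir=doc.get("outdir"),
                     variant=doc.get("variant", "main"), seed=seed)
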