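"""Synthetic cohort generator emulating the study's data structure.

The generator produces a pediatric ALL consolidation cohort: each patient
receives four HD-MTX courses of 5 g/m^2 infused over 24 h, has plasma levels
drawn at 24/42/48 h (plus 6-hourly samples while above the delayed-excretion
threshold), carries genotypes at six transporter SNPs drawn under
Hardy-Weinberg equilibrium, and is followed for severe hematological (HEM)
and gastrointestinal (GI) toxicity and for relapse.

The statistical structure the downstream analyses assume is built in
explicitly and is pure configuration:

- age and the ABCC4 rs7317112 GG genotype act multiplicatively on clearance
  (older patients eliminate more slowly; GG homozygotes faster);
- the ABCC2 rs717620 T allele (dominant coding) raises the odds of severe
  toxicity on a logistic scale, with an additional slope on the log mean
  end-of-infusion level;
- relapse times are exponential (optionally Weibull) with proportional
  hazards for the SLCO1B1 rs4149056 C allele (dominant, protective), age >=
  10 years, and clearance in the cohort's lowest quartile.

Population kinetic means are calibrated so the noise-free cohort reproduces
the study's observed medians (24 h level ~41 uM, 42 h ~0.54 uM, 48 h
~0.39 uM, clearance ~160-170 mL/min/m^2); see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List

import numpy as np
import pandas as pd

from . import pk
from .exceptions import InvalidInputError
from .pk import PKParameters, protocol_schedule

#: Candidate transporter SNP panel: (gene, major allele, minor allele,
#: default minor-allele frequency).  MAFs follow the cohort's genotype
#: distributions where derivable and European-ancestry values otherwise;
#: they are configuration, not fixture truth.
SNP_PANEL: Dict[str, dict] = {
    "rs4149056": {"gene": "SLCO1B1", "major": "T", "minor": "C", "maf": 0.167},
    "rs2306283": {"gene": "SLCO1B1", "major": "A", "minor": "G", "maf": 0.417},
    "rs1045642": {"gene": "ABCB1", "major": "A", "minor": "G", "maf": 0.475},
    "rs717620": {"gene": "ABCC2", "major": "C", "minor": "T", "maf": 0.179},
    "rs9895420": {"gene": "ABCC3", "major": "T", "minor": "A", "maf": 0.156},
    "rs7317112": {"gene": "ABCC4", "major": "A", "minor": "G", "maf": 0.274},
}

#: Post-infusion level (uM) above which 6-hourly monitoring continues.
DELAYED_EXCRETION_THRESHOLD_UM = 0.5
#: Assay lower limit of quantitation (uM); lower draws are flagged BLQ.
LLOQ_UM = 0.05


@dataclass
class CohortConfig:
    """All knobs of the generator.  Defaults emulate the study conditions."""

    n: int = 200
    seed: int = 0

    # demographics: log-uniform ages give the observed young-skewed cohort
    age_min: float = 1.0
    age_max: float = 18.0
    male_fraction: float = 0.554

    mafs: Dict[str, float] = field(
        default_factory=lambda: {k: v["maf"] for k, v in SNP_PANEL.items()}
    )

    # dosing protocol
    n_courses: int = 4
    dose_g_m2: float = 5.0

    # population kinetics (per-m^2), calibrated to the observed medians
    pop_V: float = 9.03
    pop_ke: float = 1.12
    pop_kcp: float = 0.05
    pop_kpc: float = 0.06

    # inter-patient / inter-occasion variability (CV of the log-normal
    # multipliers) and assay residual CV
    iiv_cv: Dict[str, float] = field(
        default_factory=lambda: {"V": 0.15, "ke": 0.28, "kcp": 0.25, "kpc": 0.25}
    )
    iov_cv: Dict[str, float] = field(
        default_factory=lambda: {"V": 0.05, "ke": 0.17, "kcp": 0.10, "kpc": 0.10}
    )
    assay_cv: float = 0.10

    # covariate effects on clearance (applied to ke)
    age_logcl_slope: float = -0.023  # per year on ln(CL); negative = slower in teens
    age_ref_years: float = 5.0
    abcc4_gg_cl_multiplier: float = 1.3  # recessive effect of rs7317112 GG

    # toxicity model (per-patient logistic)
    hem_baseline: float = 0.377  # P(severe HEM) for rs717620 CC at the ref level
    hem_or_abcc2: float = 4.6    # dominant OR of the rs717620 T allele
    gi_baseline: float = 0.075
    gi_or_abcc2: float = 5.0
    level_log10_slope: float = 1.0   # per log10(mean 24 h uM) on both logits
    level_ref_um: float = 41.0

    # relapse model (proportional hazards)
    relapse_baseline_hazard: float = 0.021  # events per year, reference group
    hr_slco1b1: float = 0.27   # dominant rs4149056 C-carrier vs TT
    hr_age_ge10: float = 2.39
    hr_cl_q1: float = 2.3      # true mean clearance in the cohort's lowest quartile
    age_cutoff: float = 10.0
    weibull_shape: float = 1.0  # 1.0 = exponential
    followup_min_years: float = 4.0
    followup_max_years: float = 7.0

    # sampling design
    base_sample_times: tuple = (24.0, 42.0, 48.0)
    extra_monitoring_interval_h: float = 6.0
    max_monitoring_h: float = 96.0

    # optional protocol deviations, off by default
    dose_reduction_enabled: bool = False
    dose_reduction_fraction: float = 0.4
    per_course_tox_prob: float = 0.12
    clearance_drift_per_course: float = 1.0  # >1 = faster elimination in late courses

    def __post_init__(self):
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")
        for snp, maf in self.mafs.items():
            if not (0.0 <= maf <= 0.5):
                raise InvalidInputError(f"MAF for {snp} must be in [0, 0.5], got {maf}")
        for d in (self.iiv_cv, self.iov_cv):
            if any(v < 0 for v in d.values()):
                raise InvalidInputError("variability CVs must be >= 0")
        if self.assay_cv < 0:
            raise InvalidInputError("assay CV must be >= 0")


@dataclass
class PatientRecord:
    """One simulated patient: the unit of every association analysis."""

    patient_id: str
    age_years: float
    sex: str  # "M" / "F"
    genotypes: Dict[str, int]  # minor-allele counts 0/1/2
    course_params: List[PKParameters]
    course_doses_g_m2: List[float]
    sample_rows: List[dict]  # keys: course, dose_g_m2, time_h, conc_um, blq_flag
    true_mean_clearance: float
    true_mean_level_24h_um: float
    severe_hem: bool = False
    severe_gi: bool = False
    followup_years: float = float("nan")
    relapse: bool = False

    @property
    def samples(self) -> pd.DataFrame:
        """Tidy per-sample table for this patient."""
        return pd.DataFrame(self.sample_rows)


def _lognormal_multiplier(rng, cv, size=None):
    """Mean-1 log-normal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, size)


def draw_genotypes(maf, n, rng) -> np.ndarray:
    """Hardy-Weinberg genotype draws: minor-allele counts Binomial(2, maf)."""
    if not (0.0 <= maf <= 0.5):
        raise InvalidInputError(f"MAF must be in [0, 0.5], got {maf}")
    return rng.binomial(2, maf, size=n)


def _course_parameters(age, genotypes, config, rng):
    """True kinetics per course: patient x occasion log-normal variation
    times the deterministic covariate multipliers on elimination."""
    cl_mult = np.exp(config.age_logcl_slope * (age - config.age_ref_years))
    if genotypes.get("rs7317112", 0) == 2:
        cl_mult *= config.abcc4_gg_cl_multiplier
    patient_mult = {
        k: _lognormal_multiplier(rng, config.iiv_cv[k]) for k in ("V", "ke", "kcp", "kpc")
    }
    params = []
    for course in range(config.n_courses):
        occ = {k: _lognormal_multiplier(rng, config.iov_cv[k]) for k in patient_mult}
        drift = config.clearance_drift_per_course ** course
        params.append(
            PKParameters(
                V=config.pop_V * patient_mult["V"] * occ["V"],
                ke=config.pop_ke * patient_mult["ke"] * occ["ke"] * cl_mult * drift,
                kcp=config.pop_kcp * patient_mult["kcp"] * occ["kcp"],
                kpc=config.pop_kpc * patient_mult["kpc"] * occ["kpc"],
            )
        )
    return params


def simulate_courses(age, genotypes, config, rng):
    """Simulate the four courses of one patient.

    Returns ``(course_params, course_doses, sample_rows, true_levels_24h)``
    where the rows each describe one drawn plasma level (course, time_h,
    conc_um, blq_flag).  Sampling follows the protocol: 24/42/48 h, then
    6-hourly while the (noisy) level stays above the delayed-excretion
    threshold.
    """
    course_params = _course_parameters(age, genotypes, config, rng)
    rows = []
    doses = []
    true_levels_24h = []
    dose = config.dose_g_m2
    reduced = False
    for course_idx, params in enumerate(course_params, start=1):
        if config.dose_reduction_enabled and reduced:
            course_dose = dose * (1.0 - config.dose_reduction_fraction)
        else:
            course_dose = dose
        doses.append(course_dose)
        schedule = protocol_schedule(course_dose * 1000.0)
        times = list(config.base_sample_times)
        true_um = pk.concentration(params, schedule, np.array(times), units="uM")
        true_levels_24h.append(
            float(pk.concentration(params, schedule, schedule.end_of_infusion_h, units="uM"))
        )
        obs_um = true_um * _lognormal_multiplier(rng, config.assay_cv, len(times))
        # extend monitoring while the last observed level is above threshold
        t = times[-1]
        while obs_um[-1] > DELAYED_EXCRETION_THRESHOLD_UM and t < config.max_monitoring_h:
            t += config.extra_monitoring_interval_h
            true_next = pk.concentration(params, schedule, t, units="uM")
            obs_next = true_next * _lognormal_multiplier(rng, config.assay_cv)
            times.append(t)
            obs_um = np.append(obs_um, obs_next)
        for ti, ci in zip(times, obs_um):
            blq = ci < LLOQ_UM
            rows.append(
                {
                    "course": course_idx,
                    "dose_g_m2": course_dose,
                    "time_h": float(ti),
                    "conc_um": float(LLOQ_UM if blq else ci),
                    "blq_flag": bool(blq),
                }
            )
        if config.dose_reduction_enabled and not reduced:
            if rng.random() < config.per_course_tox_prob:
                reduced = True
    return course_params, doses, rows, true_levels_24h


def simulate_outcomes(patient: PatientRecord, config: CohortConfig, rng, cl_in_q1: bool):
    """Draw toxicity flags and the (possibly censored) relapse time in place.

    Severe HEM/GI are Bernoulli on a logistic scale with a dominant rs717620
    term and a slope on log10 mean end-of-infusion level; relapse time is
    exponential (or Weibull) under proportional hazards with dominant
    rs4149056, age >= cutoff, and clearance-Q1 terms, censored at a uniform
    follow-up horizon.
    """
    dom_abcc2 = 1.0 if patient.genotypes.get("rs717620", 0) >= 1 else 0.0
    level_term = config.level_log10_slope * (
        np.log10(patient.true_mean_level_24h_um) - np.log10(config.level_ref_um)
    )
    for flag, base, or_ in (
        ("severe_hem", config.hem_baseline, config.hem_or_abcc2),
        ("severe_gi", config.gi_baseline, config.gi_or_abcc2),
    ):
        logit = np.log(base / (1 - base)) + np.log(or_) * dom_abcc2 + level_term
        p = 1.0 / (1.0 + np.exp(-logit))
        setattr(patient, flag, bool(rng.random() < p))

    hr = 1.0
    if patient.genotypes.get("rs4149056", 0) >= 1:
        hr *= config.hr_slco1b1
    if patient.age_years >= config.age_cutoff:
        hr *= config.hr_age_ge10
    if cl_in_q1:
        hr *= config.hr_cl_q1
    rate = config.relapse_baseline_hazard * hr
    shape = config.weibull_shape
    u = rng.random()
    # inverse-CDF draw; Weibull with scale chosen so shape=1 is exponential(rate)
    event_time = (-np.log(u)) ** (1.0 / shape) / rate
    censor_time = rng.uniform(config.followup_min_years, config.followup_max_years)
    if event_time <= censor_time:
        patient.relapse = True
        patient.followup_years = float(event_time)
    else:
        patient.relapse = False
        patient.followup_years = float(censor_time)
    return patient


class Cohort:
    """A simulated cohort plus tidy views of it."""

    def __init__(self, patients: List[PatientRecord], config: CohortConfig):
        self.records = patients
        self.config = config

    @property
    def patients(self) -> pd.DataFrame:
        """One row per patient: covariates, genotypes, outcomes, true PK."""
        rows = []
        for p in self.records:
            row = {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "severe_hem": int(p.severe_hem),
                "severe_gi": int(p.severe_gi),
                "followup_years": p.followup_years,
                "relapse": int(p.relapse),
                "true_mean_cl": p.true_mean_clearance,
                "true_mean_level_24h_um": p.true_mean_level_24h_um,
            }
            for snp in SNP_PANEL:
                row[snp] = p.genotypes[snp]
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def concentrations(self) -> pd.DataFrame:
        """Long format: patient_id, course, dose_g_m2, time_h, conc_um, blq_flag."""
        rows = []
        for p in self.records:
            for r in p.sample_rows:
                rows.append({"patient_id": p.patient_id, **r})
        out = pd.DataFrame(rows)
        return out[["patient_id", "course", "dose_g_m2", "time_h", "conc_um", "blq_flag"]]


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> Cohort:
    """Run the full generator: demographics -> genotypes -> PK -> outcomes.

    Reproducible: the whole cohort is a deterministic function of the config
    (including its seed).
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = CohortConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)

    n = config.n
    ages = np.exp(rng.uniform(np.log(config.age_min), np.log(config.age_max), n))
    sexes = np.where(rng.random(n) < config.male_fraction, "M", "F")
    geno = {snp: draw_genotypes(config.mafs[snp], n, rng) for snp in config.mafs}

    patients = []
    for i in range(n):
        genotypes = {snp: int(geno[snp][i]) for snp in geno}
        params, doses, rows, true_levels = simulate_courses(ages[i], genotypes, config, rng)
        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                age_years=float(ages[i]),
                sex=str(sexes[i]),
                genotypes=genotypes,
                course_params=params,
                course_doses_g_m2=doses,
                sample_rows=rows,
                true_mean_clearance=float(np.mean([pk.clearance_of(p) for p in params])),
                true_mean_level_24h_um=float(np.mean(true_levels)),
            )
        )

    cl = np.array([p.true_mean_clearance for p in patients])
    q1_cut = np.quantile(cl, 0.25)
    for p in patients:
        simulate_outcomes(p, config, rng, cl_in_q1=bool(p.true_mean_clearance <= q1_cut))
    return Cohort(patients, config)
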