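"""Seedable synthetic EHR-shaped cohorts with known ground truth.

The generator emulates the tables the phenotyping and association stages
consume — participants, longitudinal labs, diagnosis codes, medication
records and a genotype dosage matrix — with planted truth everywhere a
downstream stage estimates something:

* genotypes are Hardy-Weinberg draws, dosage ~ Binomial(2, EAF);
* case status is logistic in the planted per-allele log-odds effects, with
  the intercept solved so the marginal prevalence hits its target (default
  0.31, the case share of the analytic cohort this generator emulates);
* lab series are inverse-designed against the phenotyping rules: planted
  cases carry a qualifying elevated-ALT pair (≥183 d, ≤730 d apart), planted
  controls stay at or below the control ceiling, and a configurable fraction
  sits in the intermediate ALT band;
* metabolic risk factors are drawn at status-conditional base rates matching
  the study cohort's case/control marginals, then expressed as the labs,
  codes and prescriptions the rule engine looks for;
* chart adjudication is simulated as two raters with set sensitivity and
  specificity against truth.

All randomness descends from one integer seed through spawned NumPy
generators, so every table is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import (
    AGE_MEAN,
    AGE_SD,
    ANCESTRY_PROPORTIONS,
    ALT_CASE_THRESHOLD,
    ALT_CONTROL_CEILING,
    ConfigError,
    DEFAULT_VARIANT_TABLE,
    FRACTION_FEMALE,
    METABOLIC_RATES,
    MIN_GAP_DAYS,
    TARGET_PREVALENCE,
)

ANCESTRIES = ("EU", "AA", "LA")


# ---------------------------------------------------------------------------
# Variants and genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """One biallelic variant: identity, effect allele, per-ancestry effect
    allele frequency, and the log-odds effect planted on case status."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    eaf: float | Mapping[str, float]
    planted_beta: float = 0.0

    def __post_init__(self) -> None:
        freqs = self.eaf.values() if isinstance(self.eaf, Mapping) else [self.eaf]
        for f in freqs:
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{self.rsid}: EAF {f} outside [0, 1]")
        if not np.isfinite(self.planted_beta):
            raise ConfigError(f"{self.rsid}: planted_beta not finite")

    def eaf_for(self, ancestry: str) -> float:
        if isinstance(self.eaf, Mapping):
            try:
                return float(self.eaf[ancestry])
            except KeyError:
                raise ConfigError(
                    f"{self.rsid}: no EAF configured for ancestry {ancestry!r}")
        return float(self.eaf)


def default_variants() -> list[VariantSpec]:
    """The 16-variant replication panel with planted odds ratios."""
    return [
        VariantSpec(v["rsid"], v["chrom"], v["pos"], v["effect_allele"],
                    v["eaf"], float(np.log(v["planted_or"])))
        for v in DEFAULT_VARIANT_TABLE
    ]


def variants_from_table(table: pd.DataFrame | str | Path) -> list[VariantSpec]:
    """Read a variant annotation table (rsid, chrom, pos, effect_allele,
    eaf, beta) from a DataFrame or a delimited file."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    return [VariantSpec(str(r.rsid), str(r.chrom), int(r.pos),
                        str(r.effect_allele), float(r.eaf), float(r.beta))
            for r in table.itertuples(index=False)]


@dataclass
class DosageMatrix:
    """Participants × variants effect-allele dosages in [0, 2]."""

    dosages: pd.DataFrame          # index: participant id, columns: rsid
    variants: list[VariantSpec]

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("column count does not match variant count")
        vals = self.dosages.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosage outside [0, 2]")

    @property
    def betas(self) -> np.ndarray:
        return np.array([v.planted_beta for v in self.variants])


def sample_genotypes(variants: Sequence[VariantSpec], n: int, ancestry: str,
                     seed: int | np.random.Generator,
                     ids: Sequence | None = None) -> DosageMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, EAF) per variant."""
    rng = np.random.default_rng(seed)
    cols = {}
    for v in variants:
        cols[v.rsid] = rng.binomial(2, v.eaf_for(ancestry), size=n)
    index = pd.Index(ids if ids is not None else range(n), name="id")
    return DosageMatrix(pd.DataFrame(cols, index=index), list(variants))


# ---------------------------------------------------------------------------
# Case-status planting
# ---------------------------------------------------------------------------

def solve_intercept(genetic_score: np.ndarray, target_prevalence: float) -> float:
    """Intercept for which mean(expit(intercept + score)) equals the target."""
    if not 0 < target_prevalence < 1:
        raise ConfigError(f"prevalence {target_prevalence} outside (0, 1)")

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + genetic_score))) - target_prevalence

    lo = float(logit(target_prevalence) - np.max(genetic_score, initial=0.0) - 1)
    hi = float(logit(target_prevalence) - np.min(genetic_score, initial=0.0) + 1)
    return float(brentq(gap, lo, hi))


def assign_case_status(dosages: DosageMatrix,
                       covariates: pd.DataFrame | None = None,
                       intercept: float | None = None,
                       target_prevalence: float = TARGET_PREVALENCE,
                       covariate_betas: Mapping[str, float] | None = None,
                       seed: int | np.random.Generator = 0) -> pd.Series:
    """Plant case labels: P(case) = expit(intercept + Σ dosage·β [+ covariates]).

    Covariate effects default to zero (pure genotype planting). When
    ``intercept`` is None it is solved numerically so the realised-score
    marginal prevalence equals ``target_prevalence``.
    """
    rng = np.random.default_rng(seed)
    score = dosages.dosages.to_numpy() @ dosages.betas
    if covariate_betas:
        if covariates is None:
            raise ConfigError("covariate_betas given without covariates")
        for name, beta in covariate_betas.items():
            score = score + beta * covariates[name].to_numpy(dtype=float)
    if intercept is None:
        intercept = solve_intercept(score, target_prevalence)
    p = expit(intercept + score)
    labels = rng.random(len(p)) < p
    return pd.Series(labels, index=dosages.dosages.index, name="case")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the cohort the phenotype was developed in: ~73/20/7%
    EU/AA/LA ancestry, 8.4% female, age 64.5 ± 13.1, 31% case prevalence,
    and status-conditional metabolic risk-factor rates from the published
    case/control marginals.
    """

    n_per_ancestry: dict[str, int] = field(
        default_factory=lambda: {"EU": 3640, "AA": 1010, "LA": 350})
    target_prevalence: float = TARGET_PREVALENCE
    fraction_female: float = FRACTION_FEMALE
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    audit_c_p: dict[str, float] = field(
        default_factory=lambda: {"male": 0.25, "female": 0.18})
    metabolic_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(METABOLIC_RATES))
    indeterminate_fraction: float = 0.15
    exclusion_fraction: float = 0.05
    statin_rate: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_ancestry.values()):
            raise ConfigError("ancestry counts must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")

    @classmethod
    def with_total(cls, n_total: int, seed: int = 0, **kwargs) -> "SimulationConfig":
        """Split a total sample size by the default ancestry proportions."""
        counts = {a: max(1, int(round(n_total * p)))
                  for a, p in ANCESTRY_PROPORTIONS.items()}
        return cls(n_per_ancestry=counts, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Participants and latent metabolic truth
# ---------------------------------------------------------------------------

def _participant_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:06d}" for i in range(1, n + 1)], name="id")


def emit_participants(config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, PCs and AUDIT-C for the configured ancestry counts."""
    ancestries = np.concatenate([
        np.repeat(a, n) for a, n in config.n_per_ancestry.items()])
    n = len(ancestries)
    sex = np.where(rng.random(n) < config.fraction_female, "female", "male")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 20, 99)
    audit_p = np.where(sex == "male",
                       config.audit_c_p["male"], config.audit_c_p["female"])
    audit_c = rng.binomial(12, audit_p)
    df = pd.DataFrame({
        "id": _participant_ids(n),
        "sex": sex,
        "age_at_enrollment": np.round(age, 1),
        "ancestry": ancestries,
        "audit_c": audit_c,
    })
    for i in range(1, 11):
        df[f"pc{i}"] = np.round(rng.normal(0.0, 1.0, n), 4)
    return df


def draw_metabolic_profile(truth: pd.Series, config: SimulationConfig,
                           seed: int | np.random.Generator) -> pd.DataFrame:
    """Latent metabolic risk factors at status-conditional base rates,
    plus the evidence route each factor will be expressed through."""
    rng = np.random.default_rng(seed)
    n = len(truth)
    is_case = truth.to_numpy(dtype=bool)
    prof = pd.DataFrame(index=truth.index)
    for factor, (rate_case, rate_control) in config.metabolic_rates.items():
        rate = np.where(is_case, rate_case, rate_control)
        prof[factor] = rng.random(n) < rate
    # T2D dominates prediabetes by definition
    prof["prediabetes"] &= ~prof["t2d"]
    prof["dl_route"] = np.where(
        prof["dyslipidemia"],
        rng.choice(["tg", "hdl", "fibrate"], size=n, p=[0.5, 0.3, 0.2]),
        "none")
    prof["prediab_route"] = np.where(
        prof["prediabetes"], rng.choice(["lab", "code"], size=n), "none")
    prof["t2d_code"] = prof["t2d"] & (rng.random(n) < 0.6)
    prof["t2d_lab"] = prof["t2d"] & (rng.random(n) < 0.7)
    prof["statin"] = rng.random(n) < config.statin_rate
    return prof


# ---------------------------------------------------------------------------
# Longitudinal labs
# ---------------------------------------------------------------------------

def _alt_series(stratum: str, sex: str, rng: np.random.Generator
                ) -> list[tuple[float, int]]:
    """(value, day) ALT draws consistent with the planted stratum."""
    thr = ALT_CASE_THRESHOLD[sex]
    ceil = ALT_CONTROL_CEILING[sex]
    n_extra = int(rng.integers(2, 6))
    extra_days = rng.integers(-900, 1, size=n_extra)
    if stratum == "case":
        d2 = -int(rng.integers(0, 101))
        gap = int(rng.integers(MIN_GAP_DAYS, 601))
        pair = [(thr + 1.0 + rng.gamma(1.5, 8.0), d2 - gap),
                (thr + 1.0 + rng.gamma(1.5, 8.0), d2)]
        extras = [(rng.uniform(10.0, thr), int(d)) for d in extra_days]
        return pair + extras
    if stratum == "control":
        return [(rng.uniform(8.0, ceil), int(d)) for d in extra_days] + [
            (rng.uniform(8.0, ceil), -int(rng.integers(0, 400)))]
    if stratum == "indeterminate":
        band_day = -int(rng.integers(0, 701))
        band = [(rng.uniform(ceil + 0.1, thr), band_day)]
        return band + [(rng.uniform(8.0, ceil), int(d)) for d in extra_days]
    raise ValueError(f"unknown planted stratum {stratum!r}")


def emit_lab_series(truth: pd.Series, participants: pd.DataFrame,
                    config: SimulationConfig,
                    seed: int | np.random.Generator,
                    profile: pd.DataFrame | None = None,
                    planted_stratum: pd.Series | None = None) -> pd.DataFrame:
    """Long-format labs table (id, analyte, value, unit, day, time_of_day).

    ALT trajectories are i.i.d. noise around a status-dependent level with
    the qualifying structure planted; the other analytes are single
    enrollment-adjacent measurements expressing the latent metabolic flags.
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = draw_metabolic_profile(truth, config, rng)
    if planted_stratum is None:
        planted_stratum = pd.Series(
            np.where(truth.to_numpy(dtype=bool), "case", "control"),
            index=truth.index)

    sexes = participants.set_index("id")["sex"]
    rows: list[tuple] = []
    for pid in truth.index:
        sex = sexes[pid]
        stratum = planted_stratum[pid]
        flags = profile.loc[pid]

        alts = _alt_series(stratum, sex, rng)
        for value, day in alts:
            rows.append((pid, "alt", round(value, 1), "U/L", day, None))
        alt_ref = max(v for v, _ in alts)

        def near_enrollment() -> int:
            return -int(rng.integers(0, 120))

        ast = max(8.0, rng.normal(0.75 * alt_ref, 6.0))
        rows.append((pid, "ast", round(ast, 1), "U/L", near_enrollment(), None))
        plt = float(np.clip(rng.normal(243.0, 65.0), 80.0, 600.0))
        rows.append((pid, "platelets", round(plt, 0), "1e9/L", near_enrollment(), None))
        alb = float(np.clip(rng.normal(4.1, 0.35), 2.5, 5.5))
        rows.append((pid, "albumin", round(alb, 2), "g/dL", near_enrollment(), None))

        bmi = rng.uniform(30.0, 45.0) if flags["obesity"] else rng.uniform(19.0, 29.5)
        rows.append((pid, "bmi", round(bmi, 1), "kg/m2", near_enrollment(), None))

        if flags["t2d"] and flags["t2d_lab"]:
            hba1c = rng.uniform(6.5, 9.5)
        elif flags["prediabetes"] and flags["prediab_route"] == "lab":
            hba1c = rng.uniform(5.7, 6.49)
        else:
            hba1c = rng.uniform(4.8, 5.6)
        rows.append((pid, "hba1c", round(hba1c, 2), "%", near_enrollment(), None))

        glucose = rng.uniform(110, 260) if flags["t2d"] else rng.uniform(75, 125)
        rows.append((pid, "glucose", round(glucose, 0), "mg/dL",
                     near_enrollment(), None))

        if flags["dl_route"] == "tg":
            tg, tod = rng.uniform(155.0, 400.0), "07:30"
        else:
            tg, tod = rng.uniform(60.0, 145.0), "10:15"
        rows.append((pid, "tg", round(tg, 0), "mg/dL", near_enrollment(), tod))

        hdl_floor = 40.0 if sex == "male" else 50.0
        if flags["dl_route"] == "hdl":
            hdl = rng.uniform(20.0, hdl_floor - 2.0)
        else:
            hdl = rng.uniform(hdl_floor + 1.0, 85.0)
        rows.append((pid, "hdl", round(hdl, 0), "mg/dL", near_enrollment(), None))

    return pd.DataFrame(rows, columns=["id", "analyte", "value", "unit",
                                       "day", "time_of_day"])


# ---------------------------------------------------------------------------
# Diagnosis codes and medications
# ---------------------------------------------------------------------------

_HTN_CODE_POOL = [("ICD9", "401.9"), ("ICD10", "I10"), ("ICD10", "I11.9")]
_DL_CODE_PAIR = [("ICD9", "272.0"), ("ICD10", "E78.5")]
_T2D_CODE_POOL = [("ICD9", "250.00"), ("ICD10", "E11.9")]
_PREDIAB_CODE_POOL = [("ICD9", "790.21"), ("ICD10", "R73.9")]
_EXCLUSION_CODE_POOL = [("ICD9", "571.2"), ("ICD10", "K70.30"),
                        ("ICD10", "B18.2"), ("ICD9", "070.54"),
                        ("ICD10", "F10.20")]


def emit_codes_and_meds(truth: pd.Series, config: SimulationConfig,
                        seed: int | np.random.Generator,
                        profile: pd.DataFrame | None = None,
                        planted_excluded: pd.Series | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diagnosis-code and medication tables expressing the latent flags.

    Exclusionary liver-disease codes go to the planted-excluded subset; HTN,
    dyslipidemia, T2D and prediabetes evidence follows each participant's
    assigned route. Planted T2D always includes two diabetes-medication days
    so the flag survives the type-1-pattern exclusion on the code route.
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = draw_metabolic_profile(truth, config, rng)
    if planted_excluded is None:
        planted_excluded = pd.Series(
            rng.random(len(truth)) < config.exclusion_fraction, index=truth.index)

    code_rows: list[tuple] = []
    med_rows: list[tuple] = []

    def day() -> int:
        return -int(rng.integers(0, 1500))

    def distinct_days(k: int) -> list[int]:
        return [-int(d) for d in rng.choice(1500, size=k, replace=False)]

    for pid in truth.index:
        flags = profile.loc[pid]
        if planted_excluded[pid]:
            system, code = _EXCLUSION_CODE_POOL[
                int(rng.integers(len(_EXCLUSION_CODE_POOL)))]
            code_rows.append((pid, system, code, day()))
        if flags["hypertension"]:
            for _ in range(int(rng.integers(1, 4))):
                system, code = _HTN_CODE_POOL[int(rng.integers(len(_HTN_CODE_POOL)))]
                code_rows.append((pid, system, code, day()))
        if flags["dl_route"] == "hdl":
            for (system, code), d in zip(_DL_CODE_PAIR, distinct_days(2)):
                code_rows.append((pid, system, code, d))
        if flags["dl_route"] == "fibrate":
            med_rows.append((pid, "fibrate", day()))
        if flags["t2d"]:
            for d in distinct_days(2):
                med_rows.append((pid, "diabetes_oral", d))
            if flags["t2d_code"]:
                system, code = _T2D_CODE_POOL[int(rng.integers(len(_T2D_CODE_POOL)))]
                code_rows.append((pid, system, code, day()))
        if flags["prediab_route"] == "code":
            system, code = _PREDIAB_CODE_POOL[
                int(rng.integers(len(_PREDIAB_CODE_POOL)))]
            code_rows.append((pid, system, code, day()))
        if flags["statin"]:
            med_rows.append((pid, "statin", day()))

    codes = pd.DataFrame(code_rows, columns=["id", "system", "code", "day"])
    meds = pd.DataFrame(med_rows, columns=["id", "drug_class", "day"])
    return codes, meds


# ---------------------------------------------------------------------------
# Simulated chart adjudication
# ---------------------------------------------------------------------------

@dataclass
class AdjudicationResult:
    """Simulated chart review: per-participant truth and rater calls."""

    calls: pd.DataFrame     # columns: id, truth, rater1, rater2, ...
    n_raters: int

    def rater_table(self, i: int = 1, j: int = 2) -> np.ndarray:
        from .validation import crosstab
        return crosstab(self.calls[f"rater{i}"], self.calls[f"rater{j}"])

    def vs_truth(self, i: int = 1) -> np.ndarray:
        from .validation import crosstab
        return crosstab(self.calls[f"rater{i}"], self.calls["truth"])


def simulate_adjudication(truth: pd.Series, rater_sensitivity: float,
                          rater_specificity: float, n_raters: int = 2,
                          seed: int | np.random.Generator = 0
                          ) -> AdjudicationResult:
    """Each rater calls NAFLD independently given truth, with the stated
    sensitivity and specificity."""
    for name, value in (("sensitivity", rater_sensitivity),
                        ("specificity", rater_specificity)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"rater {name} {value} outside [0, 1]")
    rng = np.random.default_rng(seed)
    t = truth.to_numpy(dtype=bool)
    data = {"id": truth.index, "truth": t}
    for r in range(1, n_raters + 1):
        p_positive = np.where(t, rater_sensitivity, 1.0 - rater_specificity)
        data[f"rater{r}"] = rng.random(len(t)) < p_positive
    return AdjudicationResult(pd.DataFrame(data).reset_index(drop=True), n_raters)


# ---------------------------------------------------------------------------
# Whole-cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    participants: pd.DataFrame
    labs: pd.DataFrame
    codes: pd.DataFrame
    meds: pd.DataFrame
    dosages: DosageMatrix
    truth: pd.DataFrame          # id, case, planted_stratum, planted_excluded
    config: SimulationConfig
    intercept: float

    def write_tables(self, outdir: str | Path) -> dict[str, str]:
        """Write the five standard tables, variant annotations, truth and a
        manifest recording config + seed. Returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "participants": self.participants,
            "labs": self.labs,
            "codes": self.codes,
            "meds": self.meds,
            "dosages": self.dosages.dosages.reset_index(),
            "truth": self.truth,
            "variants": pd.DataFrame([{
                "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
                "effect_allele": v.effect_allele,
                "eaf": v.eaf if not isinstance(v.eaf, Mapping) else json.dumps(dict(v.eaf)),
                "beta": v.planted_beta} for v in self.dosages.variants]),
        }
        for name, df in tables.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = str(path)
        manifest = {"config": asdict(self.config), "intercept": self.intercept}
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, default=str)
        paths["manifest"] = str(outdir / "manifest.json")
        return paths


def generate_cohort(config: SimulationConfig,
                    variants: Sequence[VariantSpec] | None = None) -> Cohort:
    """Generate a full synthetic cohort from one seed.

    Subsystem generators are spawned from the config seed, so e.g. the lab
    table is reproducible independently of how many codes were drawn.
    """
    if variants is None:
        variants = default_variants()
    ss = np.random.SeedSequence(config.seed)
    (s_participants, s_genotypes, s_status, s_profile,
     s_labs, s_codes, s_strata) = ss.spawn(7)

    participants = emit_participants(config, np.random.default_rng(s_participants))

    geno_streams = s_genotypes.spawn(len(config.n_per_ancestry))
    blocks = []
    offset = 0
    for stream, (ancestry, n) in zip(geno_streams, config.n_per_ancestry.items()):
        ids = participants["id"].iloc[offset:offset + n]
        blocks.append(sample_genotypes(variants, n, ancestry,
                                       np.random.default_rng(stream), ids=ids).dosages)
        offset += n
    dosages = DosageMatrix(pd.concat(blocks), list(variants))

    score = dosages.dosages.to_numpy() @ dosages.betas
    intercept = solve_intercept(score, config.target_prevalence)
    case = assign_case_status(dosages, intercept=intercept,
                              seed=np.random.default_rng(s_status))

    rng_strata = np.random.default_rng(s_strata)
    planted_stratum = pd.Series(
        np.where(case.to_numpy(), "case", "control"), index=case.index)
    indet = rng_strata.random(len(case)) < config.indeterminate_fraction
    planted_stratum[indet] = "indeterminate"
    planted_excluded = pd.Series(
        rng_strata.random(len(case)) < config.exclusion_fraction,
        index=case.index)

    profile = draw_metabolic_profile(case, config, np.random.default_rng(s_profile))
    labs = emit_lab_series(case, participants, config,
                           np.random.default_rng(s_labs),
                           profile=profile, planted_stratum=planted_stratum)
    codes, meds = emit_codes_and_meds(case, config,
                                      np.random.default_rng(s_codes),
                                      profile=profile,
                                      planted_excluded=planted_excluded)

    truth = pd.DataFrame({
        "id": case.index,
        "case": case.to_numpy(),
        "planted_stratum": planted_stratum.to_numpy(),
        "planted_excluded": planted_excluded.to_numpy(),
    })
    return Cohort(participants, labs, codes, meds, dosages, truth,
                  config, intercept)
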