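"""Rule-based NAFLD phenotyping from longitudinal EHR-shaped tables.

The primary "ALT-threshold" phenotype calls a participant a case when ALT was
elevated above a sex-specific threshold (>40 U/L men, >30 U/L women) at two
time points at least six months apart and no more than two years apart, any
time before enrollment, with no diagnosis code for another liver disease or
alcohol-use disorder. Controls have every pre-enrollment ALT at or below a
sex-specific ceiling (30/20 U/L); the intermediate band is dropped from the
analytic cohort as "indeterminate". Metabolic-mode definitions (ALT-metabolic
and the sensitivity phenotypes) additionally require one or more metabolic
risk factors (obesity, dyslipidemia, T2D, prediabetes).

Time is integer days relative to enrollment; day 0 counts as pre-enrollment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import (
    ALT_CASE_THRESHOLD,
    ALT_CONTROL_CEILING,
    ABALT_CASE_THRESHOLD,
    ABALT_CONTROL_CEILING,
    AUDIT_C_MISUSE_CUTOFF,
    BMI_OBESE,
    ConfigError,
    DIABETES_MED_CLASSES,
    DKA_CODES,
    DL_CODES,
    EXCLUSION_CODES,
    FIBRATE_CLASSES,
    GLUCOSE_T2D,
    HBA1C_PREDIABETES,
    HBA1C_T2D,
    HDL_DL,
    HTN_CODES,
    MIN_GAP_DAYS,
    PREDIABETES_CODES,
    T1D_BMI,
    T1D_ONSET_AGE,
    T2D_CODES,
    TG_CUTOFF_HOUR,
    TG_DL,
    WINDOW_DAYS,
)


class PhenotypeError(ValueError):
    """Raised when a participant cannot be classified (e.g. missing sex)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named case/control rule over longitudinal ALT plus optional
    metabolic requirements.

    ``required_factors`` lists metabolic flags a case must carry;
    ``factor_mode`` is ``"any"`` (at least one of the listed factors) or
    ``"all"`` (every listed factor). An empty set means a pure ALT rule.
    """

    name: str
    case_threshold: Mapping[str, float]
    control_ceiling: Mapping[str, float]
    min_gap_days: int = MIN_GAP_DAYS
    window_days: int = WINDOW_DAYS
    required_factors: frozenset[str] = frozenset()
    factor_mode: str = "any"

    def __post_init__(self) -> None:
        for sex in ("male", "female"):
            if self.case_threshold[sex] < self.control_ceiling[sex]:
                raise ConfigError(
                    f"{self.name}: case threshold below control ceiling for {sex}")
        if self.min_gap_days > self.window_days:
            raise ConfigError(f"{self.name}: min_gap_days exceeds window_days")
        if self.factor_mode not in ("any", "all"):
            raise ConfigError(f"{self.name}: factor_mode must be 'any' or 'all'")


METABOLIC_FACTORS = frozenset({"obesity", "dyslipidemia", "t2d", "prediabetes"})

#: Built-in definitions: the primary phenotype, the secondary metabolic one,
#: the lower-cutoff ABALT, and single-factor sensitivity phenotypes.
DEFINITIONS: dict[str, PhenotypeDefinition] = {
    "alt_threshold": PhenotypeDefinition(
        "alt_threshold", ALT_CASE_THRESHOLD, ALT_CONTROL_CEILING),
    "alt_metabolic": PhenotypeDefinition(
        "alt_metabolic", ALT_CASE_THRESHOLD, ALT_CONTROL_CEILING,
        required_factors=METABOLIC_FACTORS, factor_mode="any"),
    "abalt": PhenotypeDefinition(
        "abalt", ABALT_CASE_THRESHOLD, ABALT_CONTROL_CEILING),
    "alt2dl": PhenotypeDefinition(
        "alt2dl", ALT_CASE_THRESHOLD, ALT_CONTROL_CEILING,
        required_factors=frozenset({"dyslipidemia"})),
    "alt2dm": PhenotypeDefinition(
        "alt2dm", ALT_CASE_THRESHOLD, ALT_CONTROL_CEILING,
        required_factors=frozenset({"t2d"})),
    "alt2obese": PhenotypeDefinition(
        "alt2obese", ALT_CASE_THRESHOLD, ALT_CONTROL_CEILING,
        required_factors=frozenset({"obesity"})),
}


@dataclass
class MetabolicProfile:
    obesity: bool = False
    dyslipidemia: bool = False
    hypertension: bool = False
    t2d: bool = False
    prediabetes: bool = False

    @property
    def any_metabolic(self) -> bool:
        # hypertension is a covariate, not an ALT-metabolic qualifying factor
        return self.obesity or self.dyslipidemia or self.t2d or self.prediabetes

    def as_dict(self) -> dict[str, bool]:
        return {
            "obesity": self.obesity,
            "dyslipidemia": self.dyslipidemia,
            "hypertension": self.hypertension,
            "t2d": self.t2d,
            "prediabetes": self.prediabetes,
            "any_metabolic": self.any_metabolic,
        }


@dataclass
class PhenotypeCall:
    id: object
    phenotype: str
    stratum: str                      # case | control | indeterminate | excluded
    reasons: list[str] = field(default_factory=list)
    alt_max: float | None = None

    def __post_init__(self) -> None:
        if self.stratum not in ("case", "control", "indeterminate", "excluded"):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.stratum == "excluded" and not self.reasons:
            raise ValueError("excluded call must carry a reason")


# ---------------------------------------------------------------------------
# Code matching
# ---------------------------------------------------------------------------

def normalize_code(code: str) -> str:
    """Dot-stripped, upper-cased ICD code."""
    return str(code).replace(".", "").strip().upper()


def _check_patterns(patterns: Iterable[str]) -> list[str]:
    out = []
    for pat in patterns:
        norm = normalize_code(pat)
        if not norm:
            raise ConfigError(f"malformed ICD pattern {pat!r}")
        out.append(norm)
    return out


def matches_any(code: str, patterns: Iterable[str],
                exceptions: Iterable[str] = ()) -> bool:
    """Prefix match of a dot-stripped code against pattern prefixes,
    unless an exception prefix also matches."""
    norm = normalize_code(code)
    if any(norm.startswith(e) for e in _check_patterns(exceptions)):
        return False
    return any(norm.startswith(p) for p in _check_patterns(patterns))


def has_exclusion(codes: Sequence[str] | pd.DataFrame,
                  exclusion_config: Mapping[str, Sequence[str]] | None = None,
                  ) -> tuple[bool, str | None]:
    """True plus the first matching category if any code matches an
    exclusionary liver-disease / alcohol-use-disorder pattern."""
    if exclusion_config is None:
        exclusion_config = EXCLUSION_CODES
    code_list = codes["code"].tolist() if isinstance(codes, pd.DataFrame) else list(codes)
    for category, patterns in exclusion_config.items():
        pats = _check_patterns(patterns)
        for code in code_list:
            norm = normalize_code(code)
            if any(norm.startswith(p) for p in pats):
                return True, category
    return False, None


# ---------------------------------------------------------------------------
# Longitudinal ALT rules
# ---------------------------------------------------------------------------

def qualifying_alt_pair(alts: Sequence[tuple[float, int]], threshold: float,
                        min_gap_days: int = MIN_GAP_DAYS,
                        window_days: int = WINDOW_DAYS) -> bool:
    """Two ALT values above ``threshold`` whose days differ by at least
    ``min_gap_days`` and at most ``window_days``.

    ``alts`` is a list of (value, day) with day ≤ 0 (before enrollment).
    """
    days = sorted(day for value, day in alts if value > threshold)
    for i in range(len(days)):
        for j in range(i + 1, len(days)):
            gap = days[j] - days[i]
            if min_gap_days <= gap <= window_days:
                return True
    return False


def alt_max(alts: Sequence[tuple[float, int]],
            window_days: int = WINDOW_DAYS) -> float | None:
    """Maximum ALT within the last ``window_days`` before enrollment
    (−window ≤ day ≤ 0); None if no measurement falls in the window."""
    in_window = [value for value, day in alts if -window_days <= day <= 0]
    return max(in_window) if in_window else None


# ---------------------------------------------------------------------------
# Metabolic risk factors
# ---------------------------------------------------------------------------

def _most_recent(labs: pd.DataFrame, analyte: str):
    """(value, day, time_of_day) of the most recent pre-enrollment
    observation of ``analyte``, or None."""
    sub = labs[(labs["analyte"] == analyte) & (labs["day"] <= 0)]
    if sub.empty:
        return None
    row = sub.loc[sub["day"].idxmax()]
    tod = row.get("time_of_day")
    return float(row["value"]), int(row["day"]), tod


def _parse_hour(time_of_day) -> float | None:
    if time_of_day is None or (isinstance(time_of_day, float) and math.isnan(time_of_day)):
        return None
    if isinstance(time_of_day, (int, float)):
        return float(time_of_day)
    text = str(time_of_day).strip()
    if not text:
        return None
    parts = text.split(":")
    try:
        hour = float(parts[0])
        if len(parts) > 1:
            hour += float(parts[1]) / 60.0
        return hour
    except ValueError:
        return None


def _count_code_matches(codes: pd.DataFrame, patterns, exceptions=()) -> int:
    return sum(matches_any(c, patterns, exceptions) for c in codes["code"])


def metabolic_flags(labs: pd.DataFrame, codes: pd.DataFrame,
                    meds: pd.DataFrame, sex: str,
                    age_at_enrollment: float | None = None) -> MetabolicProfile:
    """Derive the metabolic risk-factor profile from the most recent
    pre-enrollment observation per analyte plus codes and prescriptions.

    Missing analytes yield False flags, never errors.
    """
    prof = MetabolicProfile()
    pre_codes = codes[codes["day"] <= 0] if "day" in codes else codes
    pre_meds = meds[meds["day"] <= 0] if "day" in meds else meds

    # obesity: BMI >= 30 at the most recent measurement
    bmi_obs = _most_recent(labs, "bmi")
    bmi = bmi_obs[0] if bmi_obs else None
    prof.obesity = bmi is not None and bmi >= BMI_OBESE

    # hypertension: any qualifying code
    prof.hypertension = _count_code_matches(pre_codes, HTN_CODES) >= 1

    # dyslipidemia: fasting-morning TG, or low HDL with >=2 codes, or a
    # fibrate prescription; statins alone never qualify
    tg_obs = _most_recent(labs, "tg")
    tg_route = False
    if tg_obs is not None:
        hour = _parse_hour(tg_obs[2])
        tg_route = tg_obs[0] >= TG_DL and hour is not None and hour < TG_CUTOFF_HOUR
    hdl_obs = _most_recent(labs, "hdl")
    hdl_route = (hdl_obs is not None and hdl_obs[0] < HDL_DL[sex]
                 and _count_code_matches(pre_codes, DL_CODES) >= 2)
    fibrate_route = bool(pre_meds["drug_class"].isin(FIBRATE_CLASSES).any())
    prof.dyslipidemia = tg_route or hdl_route or fibrate_route

    # T2D: (i) codes absent a type-1 pattern, (ii) HbA1c/glucose, or
    # (iii) >=2 diabetic-medication days
    hba1c_obs = _most_recent(labs, "hba1c")
    glucose_obs = _most_recent(labs, "glucose")
    lab_route = ((hba1c_obs is not None and hba1c_obs[0] >= HBA1C_T2D)
                 or (glucose_obs is not None and glucose_obs[0] >= GLUCOSE_T2D))

    dm_meds = pre_meds[pre_meds["drug_class"].isin(DIABETES_MED_CLASSES)]
    med_route = dm_meds["day"].nunique() >= 2

    dm_code_days = [int(r["day"]) for _, r in pre_codes.iterrows()
                    if matches_any(r["code"], T2D_CODES)]
    code_route = False
    if dm_code_days:
        insulin_only = (bool((pre_meds["drug_class"] == "insulin").any())
                        and not bool((pre_meds["drug_class"] == "diabetes_oral").any()))
        dka = _count_code_matches(pre_codes, DKA_CODES) >= 1
        low_bmi = bmi is not None and bmi < T1D_BMI
        young_onset = False
        if age_at_enrollment is not None:
            onset_days = list(dm_code_days)
            if hba1c_obs is not None and hba1c_obs[0] >= HBA1C_T2D:
                onset_days.append(hba1c_obs[1])
            if glucose_obs is not None and glucose_obs[0] >= GLUCOSE_T2D:
                onset_days.append(glucose_obs[1])
            onset_age = age_at_enrollment + min(onset_days) / 365.25
            young_onset = onset_age < T1D_ONSET_AGE
        t1d_pattern = insulin_only or dka or low_bmi or young_onset
        code_route = not t1d_pattern
    prof.t2d = code_route or lab_route or med_route

    # prediabetes: qualifying code or HbA1c 5.7–6.49, absent diabetes
    if not prof.t2d:
        lo, hi = HBA1C_PREDIABETES
        pre_lab = hba1c_obs is not None and lo <= hba1c_obs[0] <= hi
        pre_code = _count_code_matches(
            pre_codes, PREDIABETES_CODES["include"],
            PREDIABETES_CODES["exclude"]) >= 1
        prof.prediabetes = pre_lab or pre_code
    return prof


def audit_c_misuse(score: int, sex: str) -> bool:
    """Possible alcohol misuse by AUDIT-C: score ≥4 for men, ≥3 for women."""
    if not 0 <= score <= 12:
        raise ValueError(f"AUDIT-C score {score} outside [0, 12]")
    return score >= AUDIT_C_MISUSE_CUTOFF[sex]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_EMPTY_CODES = pd.DataFrame(columns=["id", "system", "code", "day"])
_EMPTY_MEDS = pd.DataFrame(columns=["id", "drug_class", "day"])


def classify(participant: Mapping, labs: pd.DataFrame,
             codes: pd.DataFrame | None = None,
             meds: pd.DataFrame | None = None,
             definition: PhenotypeDefinition | str = "alt_threshold",
             exclusion_config: Mapping[str, Sequence[str]] | None = None,
             profile: MetabolicProfile | None = None) -> PhenotypeCall:
    """Classify one participant as case / control / indeterminate / excluded.

    ``participant`` needs ``id`` and ``sex`` (and ``age_at_enrollment`` for
    the T1D onset-age rule); ``labs``/``codes``/``meds`` are that
    participant's records. A precomputed ``profile`` skips re-deriving
    metabolic flags.
    """
    if isinstance(definition, str):
        definition = DEFINITIONS[definition]
    codes = _EMPTY_CODES if codes is None else codes
    meds = _EMPTY_MEDS if meds is None else meds

    sex = participant.get("sex")
    if sex not in ("male", "female"):
        raise PhenotypeError(f"participant {participant.get('id')}: missing sex")
    pid = participant["id"]

    alts = [(float(v), int(d)) for v, d in
            labs.loc[(labs["analyte"] == "alt") & (labs["day"] <= 0),
                     ["value", "day"]].itertuples(index=False)]
    amax = alt_max(alts, definition.window_days)

    excluded, category = has_exclusion(codes[codes["day"] <= 0], exclusion_config)
    if excluded:
        return PhenotypeCall(pid, definition.name, "excluded",
                             [f"exclusionary code: {category}"], amax)

    if not alts:
        return PhenotypeCall(pid, definition.name, "indeterminate",
                             ["no ALT"], amax)

    if qualifying_alt_pair(alts, definition.case_threshold[sex],
                           definition.min_gap_days, definition.window_days):
        if definition.required_factors:
            if profile is None:
                profile = metabolic_flags(labs, codes, meds, sex,
                                          participant.get("age_at_enrollment"))
            flags = profile.as_dict()
            hits = [f for f in definition.required_factors if flags[f]]
            ok = (len(hits) > 0 if definition.factor_mode == "any"
                  else len(hits) == len(definition.required_factors))
            if not ok:
                return PhenotypeCall(pid, definition.name, "indeterminate",
                                     ["metabolic criteria unmet"], amax)
        return PhenotypeCall(pid, definition.name, "case", [], amax)

    if max(v for v, _ in alts) <= definition.control_ceiling[sex]:
        return PhenotypeCall(pid, definition.name, "control", [], amax)

    return PhenotypeCall(pid, definition.name, "indeterminate",
                         ["intermediate ALT"], amax)


def classify_cohort(participants: pd.DataFrame, labs: pd.DataFrame,
                    codes: pd.DataFrame, meds: pd.DataFrame,
                    definition: PhenotypeDefinition | str = "alt_threshold",
                    exclusion_config=None,
                    with_flags: bool = True) -> pd.DataFrame:
    """Vectorised wrapper: one :func:`classify` call per participant.

    Returns a calls table (id, phenotype, stratum, reasons, alt_max) joined,
    when ``with_flags``, with the metabolic profile and alcohol-misuse flag
    used as downstream model covariates.
    """
    if isinstance(definition, str):
        definition = DEFINITIONS[definition]
    if participants["id"].duplicated().any():
        raise ValueError("duplicate participant ids")

    lab_groups = dict(tuple(labs.groupby("id")))
    code_groups = dict(tuple(codes.groupby("id")))
    med_groups = dict(tuple(meds.groupby("id")))

    rows = []
    for rec in participants.to_dict("records"):
        pid = rec["id"]
        p_labs = lab_groups.get(pid, labs.iloc[0:0])
        p_codes = code_groups.get(pid, _EMPTY_CODES)
        p_meds = med_groups.get(pid, _EMPTY_MEDS)
        profile = metabolic_flags(p_labs, p_codes, p_meds, rec["sex"],
                                  rec.get("age_at_enrollment")) if with_flags else None
        call = classify(rec, p_labs, p_codes, p_meds, definition,
                        exclusion_config, profile)
        row = {"id": pid, "phenotype": call.phenotype, "stratum": call.stratum,
               "reasons": ";".join(call.reasons), "alt_max": call.alt_max}
        if with_flags:
            row.update(profile.as_dict())
            row["t2d_or_prediabetes"] = profile.t2d or profile.prediabetes
            if "audit_c" in rec and rec["audit_c"] is not None:
                row["alcohol_misuse"] = audit_c_misuse(int(rec["audit_c"]), rec["sex"])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-flow accounting
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up, matching how reported percentages are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_accounting(calls: pd.DataFrame) -> dict[str, float]:
    """Cohort-flow table from a calls table: eligible → excluded →
    indeterminate → analytic, with case/control splits and percentages."""
    if calls["id"].duplicated().any():
        raise ValueError("duplicate participant ids in calls")
    n = len(calls)
    counts = calls["stratum"].value_counts()
    n_case = int(counts.get("case", 0))
    n_control = int(counts.get("control", 0))
    n_excluded = int(counts.get("excluded", 0))
    n_indet = int(counts.get("indeterminate", 0))
    analytic = n_case + n_control
    out = {
        "eligible": n,
        "excluded": n_excluded,
        "indeterminate": n_indet,
        "analytic": analytic,
        "cases": n_case,
        "controls": n_control,
    }
    if n:
        out["pct_case_of_eligible"] = round_half_up(100 * n_case / n, 0)
    if analytic:
        out["pct_case_of_analytic"] = round_half_up(100 * n_case / analytic, 0)
    return out


def cohort_flow_from_counts(ancestry_eligible: Mapping[str, int],
                            exclusion_components: Mapping[str, int],
                            n_intermediate: int,
                            n_cases: int, n_controls: int,
                            n_cases_metabolic: int | None = None
                            ) -> dict[str, float]:
    """Reproduce printed cohort-flow arithmetic from given counts.

    The inputs are the published stage counts (per-ancestry eligible totals,
    exclusion components, the intermediate-ALT band, and the case/control
    split); outputs are the derived totals and rounded percentages.
    """
    eligible = int(sum(ancestry_eligible.values()))
    excluded = int(sum(exclusion_components.values()))
    analytic = eligible - excluded - int(n_intermediate)
    out = {
        "eligible": eligible,
        "excluded": excluded,
        "intermediate": int(n_intermediate),
        "analytic": analytic,
        "cases": int(n_cases),
        "controls": int(n_controls),
        "pct_case_of_eligible": round_half_up(100 * n_cases / eligible, 0),
        "pct_case_of_analytic": round_half_up(100 * n_cases / analytic, 0),
    }
    if analytic != n_cases + n_controls:
        out["flow_mismatch"] = analytic - (n_cases + n_controls)
    if n_cases_metabolic is not None:
        out["analytic_metabolic"] = int(n_cases_metabolic) + int(n_controls)
        out["pct_metabolic_of_cases"] = round_half_up(
            100 * n_cases_metabolic / n_cases, 1)
    return out
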