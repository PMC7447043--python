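"""Editable defaults: ALT thresholds, ICD code lists, the 16-variant panel,
and synthetic-cohort calibration.

Everything here is plain data so a study can override any piece from a YAML
config file (see :func:`load_config`) without touching code. ICD patterns are
matched case-insensitively by prefix on dot-stripped codes, so ``"272"``
covers 272.0–272.9 and ``"I10"`` covers I10 exactly plus any sub-codes.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for malformed configuration (bad pattern, missing EAF, ...)."""


# ---------------------------------------------------------------------------
# Temporal and clinical thresholds
# ---------------------------------------------------------------------------

MIN_GAP_DAYS = 183        # "at least 6 months apart"
WINDOW_DAYS = 730         # "within a two-year window period"

# case ALT threshold (exclusive lower bound) and control ceiling, U/L, by sex
ALT_CASE_THRESHOLD = {"male": 40.0, "female": 30.0}
ALT_CONTROL_CEILING = {"male": 30.0, "female": 20.0}
# ABALT alternative cutoffs
ABALT_CASE_THRESHOLD = {"male": 30.0, "female": 20.0}
ABALT_CONTROL_CEILING = {"male": 20.0, "female": 15.0}

FIB4_ADVANCED_CUTOFF = 2.670          # strict >
NFS_ADVANCED_CUTOFF = 0.676           # >= by default (strictness switchable)
LOW_PLATELET_CUTOFF = 150.0           # 10^9/L, strict <

AUDIT_C_MISUSE_CUTOFF = {"male": 4, "female": 3}   # standard VA cutoffs

HBA1C_T2D = 6.5          # %
GLUCOSE_T2D = 200.0      # mg/dL
HBA1C_PREDIABETES = (5.7, 6.49)
TG_DL = 150.0            # mg/dL, drawn before 9 AM
TG_CUTOFF_HOUR = 9.0
HDL_DL = {"male": 40.0, "female": 50.0}
BMI_OBESE = 30.0
T1D_ONSET_AGE = 40.0
T1D_BMI = 25.0

GENOME_WIDE_P = 5e-8
EXPERIMENT_WIDE_P = 1e-5
REPLICATION_P = 0.00625   # Bonferroni over 8 independent loci

# ---------------------------------------------------------------------------
# ICD-9-CM / ICD-10-CM prefix lists (dot-stripped). Supplementary code lists
# are not public; these defaults cover the categories named in the cohort
# definition and are meant to be replaced with site-specific lists.
# ---------------------------------------------------------------------------

EXCLUSION_CODES: dict[str, list[str]] = {
    # alcoholic liver disease and/or alcohol use disorder
    "alcohol_related": ["5710", "5711", "5712", "5713", "303", "3050",
                        "K70", "F10"],
    # chronic viral hepatitis
    "viral_hepatitis": ["070", "B15", "B16", "B17", "B18", "B19"],
    # metabolic / cholestatic liver disease and liver metastases
    "other_liver_disease": ["2750", "2751", "2734", "5714", "5715", "5716",
                            "1977", "K74", "K754", "E831", "E830", "C787"],
}

HTN_CODES = ["401", "402", "403", "404", "405",
             "I10", "I11", "I12", "I13", "I14", "I15", "I16"]
DL_CODES = ["272", "E780", "E781", "E782", "E783", "E784", "E785"]
T2D_CODES = ["250", "E11"]
DKA_CODES = ["2501", "E101", "E111"]
PREDIABETES_CODES = {"include": ["7902", "R73"],
                     "exclude": ["79029", "R7303"]}

DIABETES_MED_CLASSES = {"diabetes_oral", "insulin"}
FIBRATE_CLASSES = {"fibrate"}

# ---------------------------------------------------------------------------
# 16-variant replication panel: 8 NAFLD-risk loci tagged by 16 SNPs.
# eaf is the European effect-allele frequency (used for all ancestries unless
# overridden); planted_beta is the per-allele log-odds effect the synthetic
# generator plants on case status (0 for the ALT-level-only variants).
# ---------------------------------------------------------------------------

DEFAULT_VARIANT_TABLE: list[dict[str, Any]] = [
    {"rsid": "rs12137855", "gene": "LYPLAL1",  "chrom": "1",  "pos": 219448378, "effect_allele": "C", "eaf": 0.80, "planted_or": 1.00},
    {"rsid": "rs3001032",  "gene": "LYPLAL1",  "chrom": "1",  "pos": 219727779, "effect_allele": "T", "eaf": 0.69, "planted_or": 1.04},
    {"rsid": "rs780094",   "gene": "GCKR",     "chrom": "2",  "pos": 27741237,  "effect_allele": "T", "eaf": 0.40, "planted_or": 1.02},
    {"rsid": "rs6834314",  "gene": "HSD17B13", "chrom": "4",  "pos": 88213808,  "effect_allele": "A", "eaf": 0.72, "planted_or": 1.00},
    {"rsid": "rs72613567", "gene": "HSD17B13", "chrom": "4",  "pos": 88231392,  "effect_allele": "T", "eaf": 0.73, "planted_or": 1.09},
    {"rsid": "rs2954021",  "gene": "TRIB1",    "chrom": "8",  "pos": 126482077, "effect_allele": "A", "eaf": 0.50, "planted_or": 1.00},
    {"rsid": "rs4240624",  "gene": "PPP1R3B",  "chrom": "8",  "pos": 9184231,   "effect_allele": "G", "eaf": 0.09, "planted_or": 1.12},
    {"rsid": "rs10883437", "gene": "ERLIN1",   "chrom": "10", "pos": 101795361, "effect_allele": "T", "eaf": 0.61, "planted_or": 1.00},
    {"rsid": "rs11597390", "gene": "ERLIN1",   "chrom": "10", "pos": 101861435, "effect_allele": "G", "eaf": 0.64, "planted_or": 1.00},
    {"rsid": "rs11597086", "gene": "ERLIN1",   "chrom": "10", "pos": 101953705, "effect_allele": "A", "eaf": 0.58, "planted_or": 1.00},
    {"rsid": "rs11591741", "gene": "ERLIN1",   "chrom": "10", "pos": 101976501, "effect_allele": "G", "eaf": 0.58, "planted_or": 1.00},
    {"rsid": "rs2228603",  "gene": "TM6SF2",   "chrom": "19", "pos": 19329924,  "effect_allele": "T", "eaf": 0.08, "planted_or": 1.19},
    {"rsid": "rs58542926", "gene": "TM6SF2",   "chrom": "19", "pos": 19379549,  "effect_allele": "T", "eaf": 0.07, "planted_or": 1.23},
    {"rsid": "rs738409",   "gene": "PNPLA3",   "chrom": "22", "pos": 44324727,  "effect_allele": "G", "eaf": 0.23, "planted_or": 1.31},
    {"rsid": "rs2281135",  "gene": "PNPLA3",   "chrom": "22", "pos": 44332570,  "effect_allele": "A", "eaf": 0.17, "planted_or": 1.00},
    {"rsid": "rs2143571",  "gene": "PNPLA3",   "chrom": "22", "pos": 44391686,  "effect_allele": "A", "eaf": 0.18, "planted_or": 1.00},
]

# ---------------------------------------------------------------------------
# Synthetic-cohort calibration (cohort marginals of the study population)
# ---------------------------------------------------------------------------

ANCESTRY_PROPORTIONS = {"EU": 0.728, "AA": 0.202, "LA": 0.070}
TARGET_PREVALENCE = 0.31          # case share of the analytic cohort
FRACTION_FEMALE = 0.084
AGE_MEAN, AGE_SD = 64.5, 13.1

# P(factor | case), P(factor | control) — status-conditional base rates
METABOLIC_RATES = {
    "obesity":      (0.573, 0.408),
    "hypertension": (0.816, 0.662),
    "t2d":          (0.350, 0.218),
    "prediabetes":  (0.334, 0.396),
    "dyslipidemia": (0.677, 0.430),
}

DEFAULTS: dict[str, Any] = {
    "min_gap_days": MIN_GAP_DAYS,
    "window_days": WINDOW_DAYS,
    "alt_case_threshold": ALT_CASE_THRESHOLD,
    "alt_control_ceiling": ALT_CONTROL_CEILING,
    "fib4_advanced_cutoff": FIB4_ADVANCED_CUTOFF,
    "nfs_advanced_cutoff": NFS_ADVANCED_CUTOFF,
    "nfs_cutoff_inclusive": True,
    "low_platelet_cutoff": LOW_PLATELET_CUTOFF,
    "genome_wide_p": GENOME_WIDE_P,
    "experiment_wide_p": EXPERIMENT_WIDE_P,
    "replication_p": REPLICATION_P,
    "exclusion_codes": EXCLUSION_CODES,
    "htn_codes": HTN_CODES,
    "dl_codes": DL_CODES,
    "t2d_codes": T2D_CODES,
    "dka_codes": DKA_CODES,
    "prediabetes_codes": PREDIABETES_CODES,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default configuration, optionally overlaid with a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as handle:
        override = yaml.safe_load(handle) or {}
    if not isinstance(override, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return _merge(DEFAULTS, override)
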