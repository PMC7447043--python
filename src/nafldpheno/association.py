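"""Additive-genotype association models and fixed-effects meta-analysis.

Per ancestry stratum, each variant's dosage (0–2 copies of the effect allele)
enters a logistic (binary phenotype) or linear (continuous trait) regression
alongside the model's covariates:

* Model 1 — age, sex, 10 genetic principal components;
* Model 2 — Model 1 + alcohol consumption (AUDIT-C score);
* Model 3 — Model 2 + metabolic risk factors (T2D/prediabetes, hypertension,
  dyslipidemia, obesity).

Strata are combined by inverse-variance fixed-effects meta-analysis
(weights wᵢ = 1/seᵢ²) with Cochran's Q for heterogeneity, and p-values are
graded against genome-wide (5×10⁻⁸), experiment-wide (1×10⁻⁵) and
replication (6.25×10⁻³) significance tiers. Wald inference throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import EXPERIMENT_WIDE_P, GENOME_WIDE_P, REPLICATION_P

MODEL_COVARIATES: dict[int, list[str]] = {
    1: ["age", "sex_male", *[f"pc{i}" for i in range(1, 11)]],
    2: ["age", "sex_male", *[f"pc{i}" for i in range(1, 11)], "audit_c"],
    3: ["age", "sex_male", *[f"pc{i}" for i in range(1, 11)], "audit_c",
        "t2d_or_prediabetes", "hypertension", "dyslipidemia", "obesity"],
}


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    outcome: str
    covariates: tuple[str, ...]

    @classmethod
    def standard(cls, model_id: int, outcome: str) -> "ModelSpec":
        return cls(model_id, outcome, tuple(MODEL_COVARIATES[model_id]))


@dataclass
class AssociationResult:
    rsid: str
    stratum: str
    beta: float
    se: float
    p: float
    n: int
    binary: bool
    or_: float | None = None
    ci95: tuple[float, float] | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    estimable: bool = True
    note: str = ""


@dataclass
class MetaResult:
    rsid: str
    beta: float
    se: float
    z: float
    p: float
    k: int
    weights: list[float] = field(default_factory=list)
    q_stat: float | None = None
    q_df: int | None = None
    het_p: float | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))


def _not_estimable(rsid: str, stratum: str, n: int, binary: bool,
                   note: str) -> AssociationResult:
    return AssociationResult(rsid, stratum, np.nan, np.nan, np.nan, n,
                             binary, estimable=False, note=note)


def fit_snp_model(dosage: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series,
                  covariates: pd.DataFrame | None = None,
                  binary: bool | None = None,
                  rsid: str = "", stratum: str = "") -> AssociationResult:
    """Wald estimate of the additive per-allele effect.

    Logistic regression for binary outcomes (beta is a log-odds ratio),
    ordinary least squares for continuous traits. Degenerate designs
    (constant dosage, perfect separation, singular covariates) are returned
    flagged non-estimable rather than raising.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    if np.ptp(dosage) == 0:
        return _not_estimable(rsid, stratum, n, binary, "constant dosage")
    if binary and (y.sum() == 0 or y.sum() == n):
        return _not_estimable(rsid, stratum, n, binary, "single outcome class")

    if covariates is not None and len(covariates.columns):
        X = np.column_stack([dosage, covariates.to_numpy(dtype=float)])
    else:
        X = dosage[:, None]
    X = sm.add_constant(X, prepend=False)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if binary:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            else:
                fit = sm.OLS(y, X).fit()
    except Exception as exc:  # separation, singular matrix, no convergence
        return _not_estimable(rsid, stratum, n, binary, f"fit failed: {exc}")

    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not (np.isfinite(beta) and np.isfinite(se)) or se <= 0 or se > 1e3:
        return _not_estimable(rsid, stratum, n, binary, "unstable estimate")

    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    res = AssociationResult(rsid, stratum, beta, se, p, n, binary)
    if binary:
        res.or_ = float(np.exp(beta))
        res.ci95 = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        res.n_cases = int(y.sum())
        res.n_controls = n - res.n_cases
    else:
        res.ci95 = (beta - 1.96 * se, beta + 1.96 * se)
    return res


def meta_fixed_effects(results: list[AssociationResult]) -> MetaResult:
    """Inverse-variance fixed-effects combination of per-stratum estimates.

    beta = Σwᵢbᵢ/Σwᵢ with wᵢ = 1/seᵢ²; se = (Σwᵢ)^(−1/2); two-sided normal p.
    Non-estimable strata are dropped; at least one estimable stratum required.
    """
    usable = [r for r in results if r.estimable]
    if not usable:
        raise ValueError("no estimable strata to combine")
    if any(r.se <= 0 for r in usable):
        raise ValueError("non-positive standard error")
    rsids = {r.rsid for r in usable}
    if len(rsids) > 1:
        raise ValueError(f"mixed variants in meta-analysis: {sorted(rsids)}")

    b = np.array([r.beta for r in usable])
    w = np.array([r.se for r in usable]) ** -2.0
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    meta = MetaResult(usable[0].rsid, beta, se, z, p, k=len(usable),
                      weights=w.tolist())
    if len(usable) >= 2:
        meta.q_stat, meta.q_df, meta.het_p = cochran_q(usable, beta)
    return meta


def cochran_q(results: list[AssociationResult], combined_beta: float
              ) -> tuple[float | None, int | None, float | None]:
    """Cochran's Q heterogeneity statistic, Q = Σwᵢ(bᵢ − β̂)², df = k−1,
    with an upper-tail chi-square p-value. Missing for k < 2."""
    usable = [r for r in results if r.estimable]
    k = len(usable)
    if k < 2:
        return None, None, None
    b = np.array([r.beta for r in usable])
    w = np.array([r.se for r in usable]) ** -2.0
    q = float(np.sum(w * (b - combined_beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def classify_significance(p: float) -> str:
    """Strongest satisfied significance tier for a two-sided p-value."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p < GENOME_WIDE_P:
        return "genome_wide"
    if p < EXPERIMENT_WIDE_P:
        return "experiment_wide"
    if p < REPLICATION_P:
        return "replication"
    return "none"


# ---------------------------------------------------------------------------
# Panel-level convenience wrappers
# ---------------------------------------------------------------------------

def build_covariates(participants: pd.DataFrame,
                     calls: pd.DataFrame | None = None,
                     model_id: int = 1) -> pd.DataFrame:
    """Assemble the model's covariate frame, indexed like ``participants``.

    ``sex_male`` is coded 1/0; metabolic flags (Model 3) are taken from the
    calls table produced by :func:`nafldpheno.phenotyping.classify_cohort`.
    """
    cov = pd.DataFrame(index=participants.index)
    cov["age"] = participants["age_at_enrollment"].astype(float)
    cov["sex_male"] = (participants["sex"] == "male").astype(float)
    for i in range(1, 11):
        cov[f"pc{i}"] = participants[f"pc{i}"].astype(float)
    if model_id >= 2:
        cov["audit_c"] = participants["audit_c"].astype(float)
    if model_id >= 3:
        if calls is None:
            raise ValueError("Model 3 requires metabolic flags from a calls table")
        flags = calls.set_index("id").loc[participants["id"]]
        for col in ("t2d_or_prediabetes", "hypertension", "dyslipidemia", "obesity"):
            cov[col] = flags[col].astype(float).to_numpy()
    return cov


def associate_panel(dosages: pd.DataFrame, outcome: pd.Series,
                    participants: pd.DataFrame,
                    calls: pd.DataFrame | None = None,
                    model_id: int = 1,
                    strata: pd.Series | None = None,
                    binary: bool | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every variant per stratum and meta-analyse across strata.

    Returns (per-stratum table, meta table). ``dosages`` is participants ×
    rsids aligned by position with ``participants``/``outcome``; ``strata``
    defaults to the participants' ancestry labels.
    """
    if strata is None:
        strata = participants["ancestry"]
    strata = pd.Series(np.asarray(strata), index=participants.index)
    cov = build_covariates(participants, calls, model_id)

    rows, meta_rows = [], []
    for rsid in dosages.columns:
        per_stratum: list[AssociationResult] = []
        for label in sorted(strata.unique()):
            mask = (strata == label).to_numpy()
            res = fit_snp_model(dosages[rsid].to_numpy()[mask],
                                outcome.to_numpy()[mask],
                                cov[mask].reset_index(drop=True),
                                binary=binary, rsid=rsid, stratum=str(label))
            per_stratum.append(res)
            rows.append({
                "rsid": rsid, "stratum": res.stratum, "beta": res.beta,
                "se": res.se, "or": res.or_, "p": res.p, "n": res.n,
                "n_cases": res.n_cases, "n_controls": res.n_controls,
                "estimable": res.estimable, "note": res.note,
            })
        if any(r.estimable for r in per_stratum):
            meta = meta_fixed_effects(per_stratum)
            meta_rows.append({
                "rsid": rsid, "beta": meta.beta, "se": meta.se,
                "or": meta.or_, "z": meta.z, "p": meta.p, "k": meta.k,
                "q_stat": meta.q_stat, "q_df": meta.q_df, "het_p": meta.het_p,
                "tier": classify_significance(meta.p) if meta.p > 0 else "genome_wide",
            })
    per_stratum = pd.DataFrame(rows)
    for col in ("n_cases", "n_controls", "or"):
        per_stratum[col] = pd.to_numeric(per_stratum[col])
    return per_stratum, pd.DataFrame(meta_rows)
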