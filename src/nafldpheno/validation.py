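"""Chart-review validation statistics: PPV and Cohen's kappa.

The phenotype's performance against an adjudicated gold standard is
summarised by the positive predictive value PPV = TP/(TP+FP) (the sampling
design of a case-enriched chart review supports PPV only), and inter-rater
reliability by unweighted Cohen's kappa κ = (p_o − p_e)/(1 − p_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ValidationResult:
    kappa: float
    p_observed: float
    p_expected: float
    n: int
    ppv: float | None = None


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP/(TP+FP); undefined when no positives."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("PPV undefined: no positive calls")
    return tp / (tp + fp)


def cohens_kappa(table: np.ndarray | pd.DataFrame) -> ValidationResult:
    """Unweighted Cohen's kappa from a square k×k cross-tabulation.

    κ = (p_o − p_e)/(1 − p_e) with p_o the diagonal share and
    p_e = Σᵢ rowᵢ·colᵢ/N². Perfect agreement with degenerate margins
    (p_o = p_e = 1) is defined as κ = 1; p_e = 1 with imperfect agreement
    is undefined and returned as NaN.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"cross-tabulation must be square, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("negative cell count")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty cross-tabulation")
    p_o = float(np.trace(counts) / n)
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else float("nan")
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return ValidationResult(kappa, p_o, p_e, int(n))


def crosstab(a, b, labels=(False, True)) -> np.ndarray:
    """k×k count matrix of paired categorical calls (rows: a, cols: b)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    k = len(labels)
    out = np.zeros((k, k), dtype=int)
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            out[i, j] = int(np.sum((a == la) & (b == lb)))
    return out


def validate_calls(calls: pd.DataFrame, gold: pd.DataFrame) -> ValidationResult:
    """PPV of case calls against a gold standard plus κ of the two tables.

    ``calls`` has (id, stratum); ``gold`` has (id, nafld) with boolean truth.
    Only ids present in both and called case/control are evaluated.
    """
    merged = calls.merge(gold, on="id")
    merged = merged[merged["stratum"].isin(["case", "control"])]
    pred = (merged["stratum"] == "case").to_numpy()
    truth = merged["nafld"].astype(bool).to_numpy()
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    result = cohens_kappa(crosstab(pred, truth))
    result.ppv = ppv(tp, fp) if tp + fp else None
    return result
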