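"""FIB-4 and NAFLD fibrosis score (NFS) with advanced-fibrosis flags.

FIB-4 = age·AST / (platelets·√ALT), with platelets in 10⁹/L.
NFS   = −1.675 + 0.037·age + 0.094·BMI + 1.13·dysglycemia + 0.99·AST/ALT
        − 0.013·platelets − 0.66·albumin,
where dysglycemia is diabetes OR prediabetes (this cohort's variant of the
original score).

Advanced fibrosis is flagged at FIB-4 > 2.670 and NFS ≥ 0.676 (the published
results convention; a strict > is selectable), and platelets < 150·10⁹/L is
the low-platelet portal-hypertension surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    FIB4_ADVANCED_CUTOFF,
    LOW_PLATELET_CUTOFF,
    NFS_ADVANCED_CUTOFF,
)

NFS_INTERCEPT = -1.675
NFS_AGE, NFS_BMI, NFS_DYSGLYCEMIA = 0.037, 0.094, 1.13
NFS_AST_ALT, NFS_PLATELETS, NFS_ALBUMIN = 0.99, -0.013, -0.66


@dataclass(frozen=True)
class FibrosisInput:
    age: float                       # years
    ast: float                       # U/L
    alt: float                       # U/L
    platelets: float                 # 10^9/L
    bmi: float = float("nan")        # kg/m^2 (NFS only)
    diabetes_or_prediabetes: bool = False
    albumin: float = float("nan")    # g/dL (NFS only)


@dataclass(frozen=True)
class FibrosisResult:
    fib4: float
    nfs: float
    fib4_advanced: bool
    nfs_advanced: bool
    low_platelets: bool


def fib4(inp: FibrosisInput) -> float:
    """Evaluate FIB-4; ALT and platelets must be positive."""
    if not inp.alt > 0:
        raise ValueError(f"FIB-4 requires ALT > 0, got {inp.alt}")
    if not inp.platelets > 0:
        raise ValueError(f"FIB-4 requires platelets > 0, got {inp.platelets}")
    return inp.age * inp.ast / (inp.platelets * np.sqrt(inp.alt))


def nfs(inp: FibrosisInput) -> float:
    """Evaluate the NAFLD fibrosis score; ALT must be positive."""
    if not inp.alt > 0:
        raise ValueError(f"NFS requires ALT > 0, got {inp.alt}")
    return (NFS_INTERCEPT
            + NFS_AGE * inp.age
            + NFS_BMI * inp.bmi
            + NFS_DYSGLYCEMIA * float(inp.diabetes_or_prediabetes)
            + NFS_AST_ALT * (inp.ast / inp.alt)
            + NFS_PLATELETS * inp.platelets
            + NFS_ALBUMIN * inp.albumin)


def advanced_flags(fib4_score: float, nfs_score: float, platelets: float,
                   nfs_inclusive: bool = True) -> tuple[bool, bool, bool]:
    """(fib4_advanced, nfs_advanced, low_platelets) at the published cutoffs.

    ``nfs_inclusive`` selects NFS ≥ 0.676 (default, results convention)
    versus the strict > of the methods text.
    """
    fib4_adv = fib4_score > FIB4_ADVANCED_CUTOFF
    nfs_adv = (nfs_score >= NFS_ADVANCED_CUTOFF if nfs_inclusive
               else nfs_score > NFS_ADVANCED_CUTOFF)
    low_plt = platelets < LOW_PLATELET_CUTOFF
    return fib4_adv, nfs_adv, low_plt


def score(inp: FibrosisInput, nfs_inclusive: bool = True) -> FibrosisResult:
    """Both scores plus flags for one participant."""
    f = fib4(inp)
    n = nfs(inp)
    fa, na, lp = advanced_flags(f, n, inp.platelets, nfs_inclusive)
    return FibrosisResult(f, n, fa, na, lp)
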