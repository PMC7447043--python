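import numpy as np
import pandas as pd
import pytest

from nafldpheno import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-participant cohort with planted noise fractions."""
    return generate_cohort(SimulationConfig.with_total(600, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with no planted indeterminate or excluded participants,
    so phenotyping should recover truth exactly."""
    return generate_cohort(SimulationConfig.with_total(
        600, seed=7, indeterminate_fraction=0.0, exclusion_fraction=0.0))


def make_labs(pid, alt_pairs=(), **analytes):
    """Small labs table: alt_pairs is [(value, day), ...]; other analytes are
    value or (value, day) or (value, day, time_of_day)."""
    rows = [(pid, "alt", v, "U/L", d, None) for v, d in alt_pairs]
    for analyte, spec in analytes.items():
        if not isinstance(spec, tuple):
            spec = (spec, -10)
        value, day, *rest = spec
        tod = rest[0] if rest else None
        rows.append((pid, analyte, value, "", day, tod))
    return pd.DataFrame(rows, columns=["id", "analyte", "value", "unit",
                                       "day", "time_of_day"])


def make_codes(pid, *codes):
    """codes: (system, code) or (system, code, day) tuples."""
    rows = [(pid, c[0], c[1], c[2] if len(c) > 2 else -30) for c in codes]
    return pd.DataFrame(rows, columns=["id", "system", "code", "day"])


def make_meds(pid, *meds):
    """meds: (drug_class, day) tuples."""
    return pd.DataFrame([(pid, m[0], m[1]) for m in meds],
                        columns=["id", "drug_class", "day"])
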