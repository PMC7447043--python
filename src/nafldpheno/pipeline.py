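"""End-to-end orchestration: simulate → phenotype → score → associate →
validate, as one reproducible run from a single config and seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_panel
from .fibrosis import FibrosisInput, score as fibrosis_score
from .phenotyping import classify_cohort, cohort_accounting
from .synthetic_cohort import (
    Cohort,
    SimulationConfig,
    generate_cohort,
    simulate_adjudication,
)
from .validation import cohens_kappa, ppv as ppv_of

log = logging.getLogger("nafldpheno")


@dataclass
class RunConfig:
    """One reproducible run: cohort size, phenotype, models, rater behaviour."""

    n_total: int = 5000
    seed: int = 0
    phenotype: str = "alt_threshold"
    model_ids: tuple[int, ...] = (1, 2, 3)
    indeterminate_fraction: float = 0.15
    exclusion_fraction: float = 0.05
    review_sample: int = 457
    rater_sensitivity: float = 0.95
    rater_specificity: float = 0.95
    include_alt_max: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "model_ids" in raw:
            raw["model_ids"] = tuple(raw["model_ids"])
        return cls(**raw)


def enrollment_scores(cohort_labs: pd.DataFrame, participants: pd.DataFrame,
                      calls: pd.DataFrame,
                      nfs_inclusive: bool = True) -> pd.DataFrame:
    """Fibrosis scores from each participant's most recent pre-enrollment
    labs, with the diabetes-or-prediabetes flag taken from the calls table."""
    labs = cohort_labs[cohort_labs["day"] <= 0]
    latest = (labs.sort_values("day")
                  .groupby(["id", "analyte"])["value"].last()
                  .unstack())
    flags = calls.set_index("id")["t2d_or_prediabetes"]
    ages = participants.set_index("id")["age_at_enrollment"]
    rows = []
    for pid, row in latest.iterrows():
        needed = ("alt", "ast", "platelets", "bmi", "albumin")
        if any(pd.isna(row.get(a)) for a in needed) or row["alt"] <= 0:
            continue
        inp = FibrosisInput(
            age=float(ages[pid]), ast=float(row["ast"]), alt=float(row["alt"]),
            platelets=float(row["platelets"]), bmi=float(row["bmi"]),
            diabetes_or_prediabetes=bool(flags.get(pid, False)),
            albumin=float(row["albumin"]))
        res = fibrosis_score(inp, nfs_inclusive)
        rows.append({"id": pid, "fib4": res.fib4, "nfs": res.nfs,
                     "fib4_advanced": res.fib4_advanced,
                     "nfs_advanced": res.nfs_advanced,
                     "low_platelets": res.low_platelets})
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write calls, scores, association and meta tables,
    validation table, accounting table and a manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = SimulationConfig.with_total(
        config.n_total, seed=config.seed,
        indeterminate_fraction=config.indeterminate_fraction,
        exclusion_fraction=config.exclusion_fraction)
    cohort = generate_cohort(sim)
    cohort.write_tables(outdir / "cohort")
    log.info("simulated %d participants", len(cohort.participants))

    calls = classify_cohort(cohort.participants, cohort.labs, cohort.codes,
                            cohort.meds, config.phenotype)
    calls.to_csv(outdir / "calls.csv", index=False)
    accounting = cohort_accounting(calls)
    pd.DataFrame([accounting]).to_csv(outdir / "accounting.csv", index=False)
    log.info("cohort flow: %s", accounting)

    scores = enrollment_scores(cohort.labs, cohort.participants, calls)
    scores.to_csv(outdir / "scores.csv", index=False)

    analytic = calls[calls["stratum"].isin(["case", "control"])]
    idx = cohort.participants["id"].isin(analytic["id"]).to_numpy()
    part = cohort.participants[idx].reset_index(drop=True)
    sub_calls = analytic.set_index("id").loc[part["id"]].reset_index()
    outcome = pd.Series((sub_calls["stratum"] == "case").to_numpy(dtype=float))
    dosages = cohort.dosages.dosages.loc[part["id"]].reset_index(drop=True)

    assoc_frames, meta_frames = [], []
    for model_id in config.model_ids:
        per_stratum, meta = associate_panel(
            dosages, outcome, part, calls=sub_calls,
            model_id=model_id, binary=True)
        per_stratum["model"] = model_id
        meta["model"] = model_id
        meta["outcome"] = config.phenotype
        assoc_frames.append(per_stratum)
        meta_frames.append(meta)
    if config.include_alt_max:
        alt_max = sub_calls["alt_max"].astype(float)
        keep = alt_max.notna().to_numpy()
        per_stratum, meta = associate_panel(
            dosages[keep].reset_index(drop=True),
            alt_max[keep].reset_index(drop=True),
            part[keep].reset_index(drop=True),
            model_id=1, binary=False)
        per_stratum["model"] = 1
        meta["model"] = 1
        meta["outcome"] = "alt_max"
        assoc_frames.append(per_stratum)
        meta_frames.append(meta)
    assoc = pd.concat(assoc_frames, ignore_index=True)
    meta = pd.concat(meta_frames, ignore_index=True)
    assoc.to_csv(outdir / "association.csv", index=False)
    meta.to_csv(outdir / "meta.csv", index=False)

    # simulated chart review on a case-enriched analytic subsample
    truth = cohort.truth.set_index("id").loc[sub_calls["id"], "case"]
    k = min(config.review_sample, len(truth))
    rng = np.random.default_rng(config.seed + 1)
    pick = rng.choice(len(truth), size=k, replace=False)
    adjud = simulate_adjudication(truth.iloc[pick],
                                  config.rater_sensitivity,
                                  config.rater_specificity,
                                  seed=rng)
    kap = cohens_kappa(adjud.rater_table())
    gold = adjud.calls.set_index("id")["rater1"]
    pheno_case = (sub_calls.set_index("id").loc[gold.index, "stratum"] == "case")
    tp = int((pheno_case & gold).sum())
    fp = int((pheno_case & ~gold).sum())
    validation = pd.DataFrame([{
        "n_reviewed": k,
        "kappa_raters": kap.kappa,
        "ppv_vs_adjudication": ppv_of(tp, fp) if tp + fp else np.nan,
    }])
    validation.to_csv(outdir / "validation.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "intercept": cohort.intercept,
        "accounting": accounting,
        "artifacts": sorted(str(p.relative_to(outdir))
                            for p in outdir.rglob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
    return manifest
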