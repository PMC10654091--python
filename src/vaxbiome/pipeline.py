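"""One-command end-to-end pipeline over a cohort's tables.

Stage order: titer outcomes -> exposure statistics (grouped double-FDR)
-> community metrics -> association screen -> KEGG-module enrichment.
All randomness (rarefaction subsampling) flows from a single root seed
via named substreams, so re-running with identical inputs and config
reproduces byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .associations import (
    CONTINUOUS_OUTCOMES,
    DEFAULT_WINDOWS,
    make_windows,
    run_association_screen,
    select_window_samples,
)
from .diversity import alpha_diversity, bray_curtis, rarefy
from .enrichment import load_module_map, module_enrichment, select_nominal
from .exposure import (
    build_exposure_variables,
    cumulative_oral_days,
    current_use,
    fisher_exact_2x2,
    summarize_courses,
    use_in_window,
    zip_omnibus_lrt,
)
from .multiplicity import double_fdr
from .synthetic import SyntheticCohort
from .titers import compute_outcomes

logger = logging.getLogger(__name__)

#: Days used when a hypothesis references a nominal time point.
TIMEPOINT_DAYS = {"2mo": 61, "4mo": 122, "6mo": 183, "1yr": 365}


class PipelineConfig(BaseModel):
    """Analysis configuration (every documented default is a knob)."""

    out_dir: str = "results"
    outcome_timepoint: str = "1yr"
    windows: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    screen_timepoints: list[str] = Field(default_factory=lambda: ["2mo"])
    nominal_alpha: float = Field(default=0.05, gt=0, lt=1)
    double_fdr_q: float = Field(default=0.1, gt=0, lt=1)
    enrichment_q: float = Field(default=0.05, gt=0, lt=1)
    birth_window_days: int = 7
    recent_window_days: int = 7
    rarefaction_depths: dict[str, int] = Field(
        default_factory=lambda: {"stool_ko": 5000, "stool_genus": 5000,
                                 "nasal_otu": 5000}
    )
    min_module_size: int = 5
    seed: int = 0


def exposure_hypotheses(
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """The default 10-hypothesis grouped exposure screen.

    Groups: cumulative oral days at 2mo/4mo/6mo/1yr (ZIP omnibus LRT of
    LVR vs NVR), recent oral use within 7 days of 2mo/4mo/6mo (Fisher),
    current oral use at 2mo/4mo (Fisher), systemic use at birth
    (Fisher); double-FDR adjusted at ``config.double_fdr_q``.
    """
    out = outcomes.set_index("subject_id")
    known = out[out["category"].isin(["LVR", "NVR"])]
    is_lvr = known["category"] == "LVR"
    subjects = known.index

    groups: dict[str, list[tuple[str, float]]] = {
        "cumulative": [], "recent": [], "current": [], "birth": []
    }

    for label in ("2mo", "4mo", "6mo", "1yr"):
        cum = cumulative_oral_days(exposures, cutoff_day=TIMEPOINT_DAYS[label])
        cum = cum.reindex(subjects, fill_value=0)
        _, p, degenerate = zip_omnibus_lrt(cum[is_lvr].to_numpy(),
                                           cum[~is_lvr].to_numpy())
        if degenerate:
            logger.warning("ZIP fit degenerate for cumulative use at %s", label)
        groups["cumulative"].append((f"cumulative_use_{label}", p))

    def binary_fisher(flags: pd.Series) -> float:
        f = flags.reindex(subjects, fill_value=False).astype(bool)
        table = [[int((f & is_lvr).sum()), int((~f & is_lvr).sum())],
                 [int((f & ~is_lvr).sum()), int((~f & ~is_lvr).sum())]]
        return fisher_exact_2x2(table)

    for label in ("2mo", "4mo", "6mo"):
        flags = use_in_window(exposures, TIMEPOINT_DAYS[label],
                              config.recent_window_days)
        groups["recent"].append((f"recent_use_{label}", binary_fisher(flags)))
    for label in ("2mo", "4mo"):
        flags = current_use(exposures, TIMEPOINT_DAYS[label])
        groups["current"].append((f"current_use_{label}", binary_fisher(flags)))

    vars_ = build_exposure_variables(exposures, subjects,
                                     birth_window_days=config.birth_window_days)
    groups["birth"].append(("use_at_birth", binary_fisher(vars_["used_at_birth"])))

    return double_fdr(groups, q=config.double_fdr_q)


def run_pipeline(cohort: SyntheticCohort, config: PipelineConfig) -> dict:
    """Run every stage on an in-memory cohort; write result tables.

    Returns a manifest dict with output paths, per-stage row counts and
    the SHA-256 of each result table.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = make_windows(config.windows)
    manifest: dict = {"outputs": {}, "stages": {}, "seed": config.seed,
                      "version": __version__}

    def emit(name: str, df: pd.DataFrame, index: bool = False):
        path = out_dir / name
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"][name] = {
            "rows": len(df),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    # Stage 1: titer outcomes.
    outcomes, outlier_log = compute_outcomes(cohort.titers,
                                             timepoint=config.outcome_timepoint)
    emit("outcomes.tsv", outcomes)
    emit("outlier_log.tsv", outlier_log)
    n_cat = outcomes["category"].value_counts().to_dict()
    manifest["stages"]["titer_outcomes"] = {
        "subjects": len(outcomes), "categories": n_cat,
        "outliers_removed": int((outlier_log["reason"] == "outlier").sum()),
    }
    logger.info("titer outcomes: %d subjects, categories %s", len(outcomes), n_cat)

    # Stage 2: exposure statistics.
    if cohort.exposures.empty:
        logger.warning("exposure log empty: exposure stage skipped")
        manifest["stages"]["exposure"] = {"skipped": "empty exposure log"}
    else:
        tests = exposure_hypotheses(cohort.exposures, outcomes, config)
        emit("exposure_tests.tsv", tests)
        emit("course_summary.tsv", summarize_courses(cohort.exposures))
        manifest["stages"]["exposure"] = {
            "hypotheses": len(tests),
            "rejected": int(tests["reject"].sum()),
        }

    # Stage 3: community metrics (per assay, seeded substreams).
    seed_seq = np.random.SeedSequence(config.seed)
    assay_seeds = dict(zip(sorted(cohort.features),
                           (int(s.generate_state(1)[0] % (2**31))
                            for s in seed_seq.spawn(len(cohort.features)))))
    rarefied: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    diversity_frames = []
    for assay in sorted(cohort.features):
        table = cohort.features[assay]
        depth = config.rarefaction_depths.get(assay, 5000)
        rare, dropped = rarefy(table, depth, seed=assay_seeds[assay])
        meta = cohort.feature_meta(assay).loc[rare.index]
        rarefied[assay] = (rare, meta)
        if not rare.empty:
            alpha = alpha_diversity(rare).reset_index()
            alpha.insert(0, "assay", assay)
            diversity_frames.append(alpha)
            bc = bray_curtis(rare) if len(rare) > 1 else None
            if bc is not None:
                bc.to_csv(out_dir / f"distances_{assay}.tsv", sep="\t")
        manifest["stages"].setdefault("community", {})[assay] = {
            "samples": len(rare), "dropped": len(dropped), "depth": depth,
        }
    diversity = (pd.concat(diversity_frames, ignore_index=True)
                 if diversity_frames else pd.DataFrame(
                     columns=["assay", "sample_id", "richness", "shannon", "evenness"]))
    emit("diversity.tsv", diversity)

    # Stage 4: association screen (features, diversity, metabolites).
    feature_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = dict(rarefied)
    for assay in sorted(cohort.features):
        rare, meta = rarefied[assay]
        if rare.empty:
            continue
        alpha = alpha_diversity(rare)
        feature_tables[f"diversity_{assay}"] = (alpha, meta)
    if not cohort.metabolites.empty:
        met_meta = cohort.feature_meta("stool_metabolite").loc[
            cohort.metabolites.index.intersection(
                cohort.feature_meta("stool_metabolite").index)]
        feature_tables["stool_metabolite"] = (
            cohort.metabolites.loc[met_meta.index], met_meta)
    associations = run_association_screen(
        feature_tables, outcomes, windows=windows,
        timepoints=config.screen_timepoints,
    )
    emit("associations.tsv", associations)
    manifest["stages"]["associations"] = {
        "tests": len(associations),
        "nominal": int((associations["raw_p"] < config.nominal_alpha).sum()),
    }

    # Stage 5: KEGG-module enrichment from the stool KO screen.
    modules = load_module_map(cohort.module_map)
    ko_rare, _ = rarefied.get("stool_ko", (pd.DataFrame(), None))
    detected = set(ko_rare.columns[(ko_rare > 0).any()]) if not ko_rare.empty else set()
    enrich_frames = []
    ko_assoc = associations[associations["assay"] == "stool_ko"]
    for (timepoint, outcome), fam in ko_assoc.groupby(["timepoint", "outcome"]):
        sig = select_nominal(fam, alpha=config.nominal_alpha)
        res = module_enrichment(sig, detected, modules,
                                min_module_size=config.min_module_size)
        res.insert(0, "outcome", outcome)
        res.insert(0, "timepoint", timepoint)
        enrich_frames.append(res)
    enrichment = (pd.concat(enrich_frames, ignore_index=True)
                  if enrich_frames else pd.DataFrame())
    emit("enrichment.tsv", enrichment)
    if not enrichment.empty:
        manifest["stages"]["enrichment"] = {
            "modules_tested": int(enrichment.groupby(["timepoint", "outcome"]).size().max()),
            "significant": int((enrichment["adjusted_p"] < config.enrichment_q).sum()),
        }

    (out_dir / "run_log.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
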