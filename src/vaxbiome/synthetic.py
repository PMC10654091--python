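"""Synthetic infant-cohort generator with known ground truth.

Emulates the data structure of a longitudinal birth cohort followed to
two years: 19 correlated antigen titers (a 6-member DTaP/Hib block and a
13-member PCV block, with stronger correlation inside the PCV block),
threshold-defined low vaccine responders (LVR) at fixed rates,
zero-inflated-Poisson cumulative oral antibiotic exposure with
responder-group-specific parameters, irregular well-visit sampling with
dropout, Dirichlet-multinomial microbiome feature tables (stool KO,
stool genus, nasal OTU), and a continuous stool metabolite table.

Known effects can be planted: a designated set of KOs (grouped into one
KEGG module) whose abundance tracks the subject's vaccine-response
level with a configurable Spearman-scale effect size, and one
metabolite with a signed effect. Everything downstream of the generator
can therefore be tested for parameter and signal recovery.

Titers are drawn log-normally per antigen around configurable marginal
parameters; the marginals make no claim of matching any real cohort.
Responder labels are assigned exactly (a fixed number of subjects per
label) and the titer draws are then shifted through a closed loop with
the threshold classifier until each subject's DTaP/Hib titers produce
exactly the intended label — so label counts are exact by construction
and no label information leaks into any feature except the planted
ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import titers as titer_mod
from .panel import (
    ANTIGEN_PANEL,
    ANTIGEN_UNITS,
    DTAP_HIB_ANTIGENS,
    PCV_ANTIGENS,
    PROTECTIVE_THRESHOLDS,
    threshold_table,
)

#: Nominal well-visit schedule (days of life).
VISIT_SCHEDULE = (7, 14, 21, 30, 61, 122, 183, 274, 365, 456, 548, 730)

#: Default log-scale titer means per antigen (natural log of the
#: concentration in the antigen's own units); protective antigens sit
#: comfortably above threshold for a typical responder.
_DEFAULT_LOG_MEANS = {
    "DT": 0.0, "TT": 0.2, "PT": 3.7, "FHA": 4.0, "PRN": 3.8, "PRP": 0.8,
    **{a: 0.0 for a in PCV_ANTIGENS},
}

# Log-abundance shift per unit of configured Spearman-scale effect and
# unit of standardized response score. Calibrated once so that the
# realized Spearman correlation between a planted KO's counts and the
# cross-vaccine composite approximately equals the configured effect
# (accurate near |effect| = 0.5 under the default
# Dirichlet-multinomial noise; large effects saturate below 1 because
# the composite is itself a noisy readout of the latent response).
_PLANTED_LOG_SCALE = 1.1


class CohortConfig(BaseModel):
    """Ground-truth parameters of a synthetic cohort."""

    n_subjects: int = 101
    #: Fraction of year-1-assessed subjects labelled LVR (assigned exactly).
    lvr_rate: float = Field(default=12 / 72, ge=0, le=1)
    lvr_rate_2yr: float = Field(default=2 / 56, ge=0, le=1)
    #: Fractions of subjects with titer assessments at each year.
    assessed_1yr_rate: float = Field(default=72 / 101, ge=0, le=1)
    assessed_2yr_rate: float = Field(default=56 / 101, ge=0, le=1)
    #: Fraction of assessed subjects with only the DTaP/Hib panel measured.
    pcv_missing_rate: float = Field(default=0.05, ge=0, le=1)

    antigen_panel: tuple[str, ...] = ANTIGEN_PANEL
    titer_log_means: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_LOG_MEANS))
    titer_log_sds: dict[str, float] = Field(default_factory=lambda: {a: 1.0 for a in ANTIGEN_PANEL})
    intra_pcv_correlation: float = Field(default=0.75, ge=-1, le=1)
    intra_dtap_correlation: float = Field(default=0.45, ge=-1, le=1)
    cross_panel_correlation: float = Field(default=0.25, ge=-1, le=1)

    #: Zero-inflation probability and Poisson mean of first-year
    #: cumulative oral antibiotic days, per responder group (NVR, LVR).
    zip_pi: tuple[float, float] = (0.47, 0.50)
    zip_lambda: tuple[float, float] = (10.0, 28.0)
    #: Probability of a systemic course in the first week of life (NVR, LVR).
    birth_use_prob: tuple[float, float] = (2 / 60, 3 / 12)
    #: Mean number of topical / IM / IV courses per subject over follow-up.
    nonoral_course_rates: tuple[float, float, float] = (0.55, 0.07, 0.07)

    planted_ko_effect: float = 0.5
    n_planted_kos: int = 8
    planted_module: str = "M00042"
    planted_metabolite_effect: float = -0.5

    dropout_rate: float = Field(default=0.15, ge=0, le=1)
    assay_capture_rate: float = Field(default=0.85, ge=0, le=1)

    n_kos: int = 120
    n_genera: int = 40
    n_otus: int = 60
    n_metabolites: int = 30
    stool_depth: int = 20_000
    nasal_depth: int = 10_000
    genus_depth: int = 10_000
    #: Dirichlet-multinomial concentration (smaller = more overdispersed).
    dm_concentration: float = 200.0

    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        dtap = [a for a in self.antigen_panel if a in DTAP_HIB_ANTIGENS]
        pcv = [a for a in self.antigen_panel if a in PCV_ANTIGENS]
        if len(dtap) != 6 or len(pcv) != 13 or len(self.antigen_panel) != 19:
            raise ValueError(
                "antigen_panel must partition into 6 DTaP/Hib antigens and "
                "13 PCV serotypes"
            )
        for t in (self.zip_pi,):
            if not all(0 <= v <= 1 for v in t):
                raise ValueError("zip_pi entries must lie in [0, 1]")
        if not all(v > 0 for v in self.zip_lambda):
            raise ValueError("zip_lambda entries must be positive")
        if not all(0 <= v <= 1 for v in self.birth_use_prob):
            raise ValueError("birth_use_prob entries must lie in [0, 1]")
        corr = self.correlation_matrix()
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                "titer correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g}) for intra_pcv_correlation="
                f"{self.intra_pcv_correlation}, intra_dtap_correlation="
                f"{self.intra_dtap_correlation}, cross_panel_correlation="
                f"{self.cross_panel_correlation}"
            )
        return self

    def correlation_matrix(self) -> np.ndarray:
        """Block correlation matrix of log titers in panel order."""
        panel = list(self.antigen_panel)
        is_pcv = np.array([a in PCV_ANTIGENS for a in panel])
        corr = np.full((19, 19), self.cross_panel_correlation)
        for i in range(19):
            for j in range(19):
                if is_pcv[i] and is_pcv[j]:
                    corr[i, j] = self.intra_pcv_correlation
                elif not is_pcv[i] and not is_pcv[j]:
                    corr[i, j] = self.intra_dtap_correlation
        np.fill_diagonal(corr, 1.0)
        return corr


@dataclass
class GroundTruth:
    """Planted parameters of a generated cohort."""

    responder_1yr: dict[str, str]
    responder_2yr: dict[str, str]
    zip_pi: dict[str, float]
    zip_lambda: dict[str, float]
    planted_kos: list[str]
    planted_module: str
    planted_ko_effect: float
    planted_metabolite: str
    planted_metabolite_effect: float
    response_score: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class SyntheticCohort:
    """All tables of one generated cohort."""

    config: CohortConfig
    titers: pd.DataFrame
    exposures: pd.DataFrame
    samples: pd.DataFrame
    features: dict[str, pd.DataFrame]  # assay -> samples x features counts
    metabolites: pd.DataFrame
    module_map: pd.DataFrame
    ground_truth: GroundTruth

    def feature_meta(self, assay: str) -> pd.DataFrame:
        meta = self.samples[self.samples["sample_type"] == assay]
        return meta.set_index("sample_id")[["subject_id", "age_days"]]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["labels", "titers", "exposures", "visits",
             "stool_ko", "stool_genus", "nasal_otu", "metabolites", "modules"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _enforce_label(
    values: dict[str, float], target: str, rng: np.random.Generator
) -> dict[str, float]:
    """Shift DTaP/Hib titers multiplicatively until the threshold
    classifier emits the target label (closed loop)."""
    values = dict(values)
    step = np.exp(0.5)
    for _ in range(100):
        label = titer_mod.classify_responder(values)
        if label == target:
            return values
        factor = 1 / step if target == "LVR" else step
        values = {a: v * factor for a, v in values.items()}
    raise RuntimeError(f"could not reach label {target}")  # pragma: no cover


def _draw_titers(config, subjects, assessed_1yr, assessed_2yr, labels1, labels2,
                 pcv_missing, rng) -> pd.DataFrame:
    panel = list(config.antigen_panel)
    mu = np.array([config.titer_log_means[a] for a in panel])
    sd = np.array([config.titer_log_sds[a] for a in panel])
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(panel)))
    dtap_idx = [i for i, a in enumerate(panel) if a in DTAP_HIB_ANTIGENS]

    rows = []
    for timepoint, cohort in (("2mo", assessed_1yr), ("1yr", assessed_1yr),
                              ("2yr", assessed_2yr)):
        target = {"1yr": labels1, "2yr": labels2}.get(timepoint)
        for subject in subjects:
            if subject not in cohort:
                continue
            z = chol @ rng.standard_normal(len(panel))
            vals = np.exp(mu + sd * z)
            if target is not None:
                dtap_vals = {panel[i]: vals[i] for i in dtap_idx}
                dtap_vals = _enforce_label(dtap_vals, target[subject], rng)
                for i in dtap_idx:
                    vals[i] = dtap_vals[panel[i]]
            for i, antigen in enumerate(panel):
                if subject in pcv_missing and antigen in PCV_ANTIGENS:
                    continue
                rows.append(dict(subject_id=subject, antigen=antigen,
                                 timepoint=timepoint, value=float(vals[i]),
                                 units=ANTIGEN_UNITS[antigen]))
    return pd.DataFrame(rows, columns=["subject_id", "antigen", "timepoint",
                                       "value", "units"])


def _place_courses(total_days: int, rng: np.random.Generator,
                   lo: int = 8, hi: int = 356) -> list[tuple[int, int]]:
    """Partition ``total_days`` into non-overlapping (start, duration)
    oral courses inside [lo, hi); disjointness keeps the union of
    exposed days equal to the drawn ZIP total."""
    courses: list[tuple[int, int]] = []
    used: list[tuple[int, int]] = []
    remaining = total_days
    while remaining > 0:
        dur = int(min(remaining, rng.integers(3, 11)))
        for _ in range(200):
            start = int(rng.integers(lo, hi - dur))
            if all(start + dur + 1 < s or start > s + d + 1 for s, d in used):
                used.append((start, dur))
                courses.append((start, dur))
                break
        else:  # pragma: no cover - essentially impossible at these loads
            break
        remaining -= dur
    return courses


def _draw_exposures(config, subjects, labels1, rng) -> pd.DataFrame:
    rows = []
    rate_topical, rate_im, rate_iv = config.nonoral_course_rates
    for subject in subjects:
        group = 1 if labels1.get(subject) == "LVR" else 0
        pi, lam = config.zip_pi[group], config.zip_lambda[group]
        total = 0 if rng.random() < pi else int(rng.poisson(lam))
        for start, dur in _place_courses(total, rng):
            rows.append(dict(subject_id=subject, route="oral",
                             start_day=start, duration_days=dur))
        if rng.random() < config.birth_use_prob[group]:
            rows.append(dict(subject_id=subject, route="oral",
                             start_day=int(rng.integers(0, 4)),
                             duration_days=int(rng.integers(3, 8))))
        for route, rate in (("topical", rate_topical), ("IM", rate_im),
                            ("IV", rate_iv)):
            for _ in range(rng.poisson(rate)):
                rows.append(dict(subject_id=subject, route=route,
                                 start_day=int(rng.integers(8, 720)),
                                 duration_days=int(rng.integers(3, 11))))
    return pd.DataFrame(rows, columns=["subject_id", "route", "start_day",
                                       "duration_days"])


def _draw_visits(config, subjects, rng) -> pd.DataFrame:
    rows = []
    for subject in subjects:
        for v, nominal in enumerate(VISIT_SCHEDULE):
            if rng.random() < config.dropout_rate:
                continue
            age = max(1, nominal + int(rng.integers(-10, 11)))
            for assay in ("stool_ko", "stool_genus", "nasal_otu", "stool_metabolite"):
                if rng.random() < config.assay_capture_rate:
                    rows.append(dict(
                        sample_id=f"{subject}_v{v:02d}_{assay}",
                        subject_id=subject, age_days=age, sample_type=assay,
                    ))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "age_days",
                                       "sample_type"])


def _response_score(titer_table: pd.DataFrame) -> dict[str, float]:
    """Latent per-subject vaccine-response score: mean per-antigen
    z-score of log titer at 1 year, standardized across subjects."""
    t = titer_table[titer_table["timepoint"] == "1yr"].copy()
    if t.empty:
        return {}
    t["logv"] = np.log(t["value"].clip(lower=1e-12))
    z = t.groupby("antigen")["logv"].transform(
        lambda s: (s - s.mean()) / (s.std(ddof=0) or 1.0)
    )
    u = z.groupby(t["subject_id"]).mean()
    u = (u - u.mean()) / (u.std(ddof=0) or 1.0)
    return {s: float(v) for s, v in u.items()}


def _feature_counts(
    sample_meta: pd.DataFrame, feature_ids: list[str], depth: int,
    concentration: float, rng: np.random.Generator,
    planted: dict[str, float] | None = None,
    score: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Dirichlet-multinomial counts; planted features get a log-abundance
    shift proportional to the subject's response score."""
    base = rng.normal(0.0, 1.2, size=len(feature_ids))
    planted_idx = {feature_ids.index(f): eff for f, eff in (planted or {}).items()}
    counts = np.zeros((len(sample_meta), len(feature_ids)), dtype=np.int64)
    for i, (_, row) in enumerate(sample_meta.iterrows()):
        logp = base.copy()
        if planted_idx and score:
            u = score.get(row["subject_id"], 0.0)
            for j, eff in planted_idx.items():
                logp[j] += _PLANTED_LOG_SCALE * eff * u
        p = np.exp(logp - logp.max())
        p /= p.sum()
        w = rng.dirichlet(concentration * p)
        counts[i] = rng.multinomial(depth, w)
    return pd.DataFrame(
        counts,
        index=pd.Index(sample_meta["sample_id"].to_numpy(), name="sample_id"),
        columns=feature_ids,
    )


def _module_map(config, ko_ids: list[str], planted: list[str],
                rng: np.random.Generator) -> pd.DataFrame:
    rows = [(config.planted_module, k) for k in planted]
    rest = [k for k in ko_ids if k not in planted]
    rng.shuffle(rest)
    m = 101
    i = 0
    while len(rest) - i >= 5:
        size = int(rng.integers(5, 13))
        size = min(size, len(rest) - i)
        if size < 5:
            break
        for k in rest[i:i + size]:
            rows.append((f"M{m:05d}", k))
        i += size
        m += 1
    # Two deliberately undersized modules (exercise the K<5 filter).
    for size in (3, 4):
        for k in rng.choice(rest, size=min(size, len(rest)), replace=False):
            rows.append((f"M{m:05d}", k))
        m += 1
    return pd.DataFrame(rows, columns=["module_id", "ko_id"])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from ground-truth parameters.

    Deterministic: the same config (including seed) yields identical
    tables. Named RNG substreams per stage keep each table reproducible
    independently of the others.
    """
    rngs = _rngs(config.seed)
    n = config.n_subjects
    subjects = [f"S{i + 1:03d}" for i in range(n)]

    # Assessment subsets and exact responder labels.
    r = rngs["labels"]
    n1 = round(n * config.assessed_1yr_rate)
    assessed_1yr = set(sorted(r.choice(subjects, size=n1, replace=False))) if n else set()
    n2 = round(n * config.assessed_2yr_rate)
    pool2 = sorted(assessed_1yr) + [s for s in subjects if s not in assessed_1yr]
    assessed_2yr = set(pool2[:n2])

    n_lvr1 = round(len(assessed_1yr) * config.lvr_rate)
    lvr1 = set(sorted(r.choice(sorted(assessed_1yr), size=n_lvr1, replace=False))) if n_lvr1 else set()
    labels1 = {s: ("LVR" if s in lvr1 else "NVR") for s in assessed_1yr}
    n_lvr2 = round(len(assessed_2yr) * config.lvr_rate_2yr)
    pool_lvr2 = sorted(lvr1 & assessed_2yr) + sorted(assessed_2yr - lvr1)
    lvr2 = set(pool_lvr2[:n_lvr2])
    labels2 = {s: ("LVR" if s in lvr2 else "NVR") for s in assessed_2yr}

    n_miss = round(len(assessed_1yr) * config.pcv_missing_rate)
    pcv_missing = set(sorted(r.choice(sorted(assessed_1yr), size=n_miss, replace=False))) if n_miss else set()

    titers = _draw_titers(config, subjects, assessed_1yr, assessed_2yr,
                          labels1, labels2, pcv_missing, rngs["titers"])
    exposures = _draw_exposures(config, subjects, labels1, rngs["exposures"])
    samples = _draw_visits(config, subjects, rngs["visits"])
    score = _response_score(titers)

    ko_ids = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    planted_kos = ko_ids[: config.n_planted_kos]
    genus_ids = [f"g__Genus{i + 1:03d}" for i in range(config.n_genera)]
    otu_ids = [f"OTU{i + 1:04d}" for i in range(config.n_otus)]
    met_ids = [f"met{i + 1:03d}" for i in range(config.n_metabolites)]
    planted_met = met_ids[0] if met_ids else ""

    def meta(assay):
        return samples[samples["sample_type"] == assay]

    features = {
        "stool_ko": _feature_counts(
            meta("stool_ko"), ko_ids, config.stool_depth,
            config.dm_concentration, rngs["stool_ko"],
            planted={k: config.planted_ko_effect for k in planted_kos},
            score=score,
        ),
        "stool_genus": _feature_counts(
            meta("stool_genus"), genus_ids, config.genus_depth,
            config.dm_concentration, rngs["stool_genus"],
        ),
        "nasal_otu": _feature_counts(
            meta("nasal_otu"), otu_ids, config.nasal_depth,
            config.dm_concentration, rngs["nasal_otu"],
        ),
    }

    met_meta = meta("stool_metabolite")
    r_m = rngs["metabolites"]
    base_m = r_m.normal(3.0, 0.8, size=len(met_ids))
    vals = np.exp(
        base_m[None, :] + r_m.normal(0.0, 1.0, size=(len(met_meta), len(met_ids)))
    )
    if len(met_ids) and len(met_meta):
        u = met_meta["subject_id"].map(lambda s: score.get(s, 0.0)).to_numpy()
        vals[:, 0] *= np.exp(
            _PLANTED_LOG_SCALE * config.planted_metabolite_effect * u
        )
    metabolites = pd.DataFrame(
        vals,
        index=pd.Index(met_meta["sample_id"].to_numpy(), name="sample_id"),
        columns=met_ids,
    )

    module_map = _module_map(config, ko_ids, planted_kos, rngs["modules"])

    ground_truth = GroundTruth(
        responder_1yr=labels1,
        responder_2yr=labels2,
        zip_pi={"NVR": config.zip_pi[0], "LVR": config.zip_pi[1]},
        zip_lambda={"NVR": config.zip_lambda[0], "LVR": config.zip_lambda[1]},
        planted_kos=planted_kos,
        planted_module=config.planted_module,
        planted_ko_effect=config.planted_ko_effect,
        planted_metabolite=planted_met,
        planted_metabolite_effect=config.planted_metabolite_effect,
        response_score=score,
    )
    return SyntheticCohort(
        config=config, titers=titers, exposures=exposures, samples=samples,
        features=features, metabolites=metabolites, module_map=module_map,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# IO


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> pd.DataFrame:
    """Write all cohort tables as TSV (+ ground_truth.json); returns a
    manifest of files and row counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    def write(name: str, df: pd.DataFrame, index: bool = False, index_label=None):
        path = out / name
        df.to_csv(path, sep="\t", index=index, index_label=index_label)
        manifest.append(dict(file=name, rows=len(df)))

    write("titers.tsv", cohort.titers)
    write("exposures.tsv", cohort.exposures)
    write("samples.tsv", cohort.samples)
    for assay, table in cohort.features.items():
        write(f"features_{assay}.tsv", table, index=True, index_label="sample_id")
    write("metabolites.tsv", cohort.metabolites, index=True, index_label="sample_id")
    write("module_map.tsv", cohort.module_map)
    write("thresholds.tsv", threshold_table())
    (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    manifest.append(dict(file="ground_truth.json", rows=len(cohort.ground_truth.responder_1yr)))
    mdf = pd.DataFrame(manifest)
    mdf.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return mdf


def read_cohort(in_dir: str | Path, config: CohortConfig | None = None) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    d = Path(in_dir)
    gt = json.loads((d / "ground_truth.json").read_text())
    features = {
        assay: pd.read_csv(d / f"features_{assay}.tsv", sep="\t", index_col="sample_id")
        for assay in ("stool_ko", "stool_genus", "nasal_otu")
    }
    return SyntheticCohort(
        config=config if config is not None else CohortConfig(),
        titers=pd.read_csv(d / "titers.tsv", sep="\t"),
        exposures=pd.read_csv(d / "exposures.tsv", sep="\t"),
        samples=pd.read_csv(d / "samples.tsv", sep="\t"),
        features=features,
        metabolites=pd.read_csv(d / "metabolites.tsv", sep="\t", index_col="sample_id"),
        module_map=pd.read_csv(d / "module_map.tsv", sep="\t"),
        ground_truth=GroundTruth(**gt),
    )
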