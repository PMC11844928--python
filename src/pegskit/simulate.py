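"""Seed-reproducible synthetic study generator.

Emulates the data structure of a population methylation study of older US
adults: EWAS weight catalogs in both orientations, a beta-value methylation
matrix with plate/row/column batch shifts and cell-composition covariation,
and a sample table whose phenotypes are built from known score effects,
covariate effects, interaction terms and noise — so that every pipeline stage
can be exercised and its estimates compared against recorded truth.

Generation model
----------------
Methylation: each CpG k has a latent normal value
``l_ik = mu_k + batch shifts + cell loadings·(c_i − c̄) + e_ik`` mapped to a
beta value through the inverse logit; missingness is injected completely at
random.  The *true score* for a trait is the weighted sum of the clean beta
values (no batch shifts), with the known batch/cell design projected out —
i.e. the technical-artifact-free methylation signal the preprocessing step
estimates — then standardized.

Phenotypes: trait (on its analysis scale) = intercept + β_true·(true score)
+ covariate effects + Σ interaction·(true score × modifier) + normal noise.
Log-scale traits are exponentiated into the raw input columns; blood pressure
is emitted as reading pairs (with rare artifact readings, so censoring is
exercised); BMI is back-constructed through height and weight; LDL-C through
the lipid panel so the Friedewald rule is exercised.

Covariate marginals default to a realistic older-US-adult profile (mean age
69.5 y, 58.7% female, two-thirds non-Hispanic White, ~11% current smokers,
~61% nondrinkers).  Effect sizes default to values giving comfortable power
at n ≈ 2,000–4,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from .phenotypes import TRAITS, classify_drinker
from .preprocess import CELL_TYPES, MethylationMatrix, _design_matrix
from .weights import EWASWeightRecord, compute_r2

DEFAULT_BETA_TRUE = {
    "sbp": 1.2, "dbp": 0.9, "bmi": 2.4, "crp": 0.32,
    "hdl": 0.08, "ldl": 4.2, "tg": 0.17, "glucose": 0.03,
}
DEFAULT_NOISE_SD = {
    "sbp": 16.0, "dbp": 10.0, "bmi": 6.0, "crp": 1.0,
    "hdl": 0.28, "ldl": 34.0, "tg": 0.48, "glucose": 0.28,
}
DEFAULT_INTERCEPT = {
    "sbp": 128.0, "dbp": 76.5, "bmi": 30.0, "crp": 1.0,
    "hdl": 4.0, "ldl": 102.0, "tg": 4.85, "glucose": 4.68,
}
# per-trait covariate effects: (age−mean) slope, female offset, med offset,
# current-smoker offset
DEFAULT_COV_EFFECTS = {
    "sbp": (0.30, -2.0, -5.0, 1.0),
    "dbp": (-0.10, -1.0, -3.0, 0.5),
    "bmi": (-0.15, 0.5, 0.0, -0.8),
    "crp": (0.005, 0.20, 0.0, 0.25),
    "hdl": (0.003, 0.20, -0.02, -0.06),
    "ldl": (-0.30, 2.0, -15.0, 1.0),
    "tg": (-0.005, -0.05, -0.06, 0.05),
    "glucose": (0.002, -0.01, 0.10, 0.01),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; outputs are pure functions of it."""

    seed: int = 0
    n_samples: int = 4000
    n_cpgs_per_trait: int = 20
    traits: tuple[str, ...] = tuple(TRAITS)
    # methylation structure
    missing_rate: float = 0.01
    n_plates: int = 8
    n_plate_rows: int = 8
    n_plate_columns: int = 12
    batch_sd: float = 0.05        # latent (logit) scale
    cell_loading_sd: float = 0.5  # latent units per unit cell proportion
    cpg_sd: float = 0.4           # idiosyncratic latent SD per CpG
    orientation_mix: float = 0.5  # fraction of catalog CpGs meth_dependent
    n_nonsignificant: int = 2     # extra non-Bonferroni rows per catalog
    n_off_array: int = 2          # significant rows absent from the array
    # covariate marginals
    age_mean: float = 69.5
    age_sd: float = 9.6
    age_range: tuple[float, float] = (55.0, 100.0)
    p_female: float = 0.587
    race_probs: dict[str, float] = field(default_factory=lambda: {
        "nh_white": 0.665, "nh_black": 0.163, "hispanic": 0.141, "other": 0.031,
    })
    smoking_probs: dict[str, float] = field(default_factory=lambda: {
        "never": 0.445, "former": 0.441, "current": 0.114,
    })
    education_probs: dict[str, float] = field(default_factory=lambda: {
        "lt_hs": 0.167, "hs": 0.592, "college": 0.241,
    })
    p_active: float = 0.472
    p_nondrinker: float = 0.608
    drinks_meanlog: float = 1.25   # weekly units among drinkers
    drinks_sdlog: float = 0.9
    med_base: dict[str, float] = field(default_factory=lambda: {
        "htn_med": 0.493, "lipid_med": 0.480, "diab_med": 0.217,
    })
    med_age_slope: float = 0.04    # logit units per year of age
    p_fasting: float = 0.66
    # phenotype model
    beta_true: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TRUE))
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    intercepts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPT))
    #: (trait, modifier) -> interaction coefficient on the analysis scale
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    bp_reading_sd: float = 3.0
    bp_artifact_rate: float = 0.005

    def __post_init__(self) -> None:
        for name in ("race_probs", "smoking_probs", "education_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        for rate in (self.missing_rate, self.p_female, self.p_active,
                     self.p_nondrinker, self.p_fasting):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0,1], got {rate}")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Everything needed to score recovery exactly."""

    true_scores: pd.DataFrame          # standardized score per trait
    beta_true: dict[str, float]
    interactions: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    intercepts: dict[str, float]
    age_center: float
    true_weights: dict[str, dict[str, float]]   # trait -> cpg -> weight


@dataclass
class SimulatedStudy:
    """One complete synthetic dataset plus its generating truth."""

    config: GeneratorConfig
    covariates: pd.DataFrame
    methylation: MethylationMatrix
    clean_betas: pd.DataFrame          # no batch shifts, no missingness
    catalogs: dict[str, list[EWASWeightRecord]]
    samples: pd.DataFrame              # raw measurement table
    truth: TruthRecord


def _trait_cpgs(cfg: GeneratorConfig, trait: str) -> list[str]:
    return [f"cg_{trait}_{k:03d}" for k in range(cfg.n_cpgs_per_trait)]


def generate_covariates(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Demographics, behaviors, medication, fasting and sample weights."""
    n = cfg.n_samples
    lo, hi = cfg.age_range
    a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
    age = truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                        size=n, random_state=rng)

    def pick(probs: Mapping[str, float]) -> np.ndarray:
        levels = list(probs)
        return rng.choice(levels, size=n, p=[probs[k] for k in levels])

    sex = np.where(rng.random(n) < cfg.p_female, "female", "male")
    drinks = np.where(
        rng.random(n) < cfg.p_nondrinker,
        0.0,
        rng.lognormal(cfg.drinks_meanlog, cfg.drinks_sdlog, size=n),
    )
    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": pick(cfg.race_probs),
            "education3": pick(cfg.education_probs),
            "smoking3": pick(cfg.smoking_probs),
            "physically_active": rng.random(n) < cfg.p_active,
            "drinks_per_week": drinks,
            "fasting": rng.random(n) < cfg.p_fasting,
            "sample_weight": rng.lognormal(0.0, 0.5, size=n),
        },
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
    )
    for med, base in cfg.med_base.items():
        logit = np.log(base / (1 - base)) + cfg.med_age_slope * (age - cfg.age_mean)
        df[med] = rng.random(n) < expit(logit)
    df["sample_weight"] *= n / df["sample_weight"].sum()
    return df


@dataclass
class _MethTruth:
    clean_betas: pd.DataFrame


def generate_methylation(
    cfg: GeneratorConfig, covariates: pd.DataFrame, rng: np.random.Generator
) -> tuple[MethylationMatrix, _MethTruth]:
    """Beta matrix with batch shifts, cell covariation and MCAR missingness."""
    n = len(covariates)
    cpgs = [c for t in cfg.traits for c in _trait_cpgs(cfg, t)]
    k = len(cpgs)

    mu = rng.normal(0.0, 0.8, size=k)
    plate = rng.integers(cfg.n_plates, size=n)
    row = rng.integers(cfg.n_plate_rows, size=n)
    col = rng.integers(cfg.n_plate_columns, size=n)
    plate_eff = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_plates, k))
    row_eff = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_plate_rows, k))
    col_eff = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_plate_columns, k))

    # NK, B, CD4, CD8, MO plus an unmeasured granulocyte remainder
    alpha = np.array([1.5, 1.5, 4.5, 2.4, 2.4, 16.5])
    simplex = rng.dirichlet(alpha, size=n)
    cells = pd.DataFrame(simplex[:, :5], columns=list(CELL_TYPES),
                         index=covariates.index)
    loadings = rng.normal(0.0, cfg.cell_loading_sd, size=(5, k))
    cells_c = simplex[:, :5] - simplex[:, :5].mean(axis=0, keepdims=True)

    e = rng.normal(0.0, cfg.cpg_sd, size=(n, k))
    clean_latent = mu[None, :] + e
    latent = (
        clean_latent
        + plate_eff[plate] + row_eff[row] + col_eff[col]
        + cells_c @ loadings
    )
    betas = expit(latent)
    clean = pd.DataFrame(expit(clean_latent), index=covariates.index, columns=cpgs)
    values = pd.DataFrame(betas, index=covariates.index, columns=cpgs)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = values.mask(mask)
    batch = pd.DataFrame(
        {
            "plate": [f"P{p}" for p in plate],
            "plate_row": [f"R{r}" for r in row],
            "plate_column": [f"C{c}" for c in col],
        },
        index=covariates.index,
    )
    matrix = MethylationMatrix(values=values, batch=batch, cell_props=cells)
    return matrix, _MethTruth(clean_betas=clean)


def generate_ewas_catalog(
    cfg: GeneratorConfig, trait: str, rng: np.random.Generator
) -> tuple[list[EWASWeightRecord], dict[str, float]]:
    """Catalog records whose finalized weights equal the generating weights.

    ``meth_independent`` rows report the generating weight directly;
    ``meth_dependent`` rows report (β, SE, Z, N) constructed so that the
    orientation transformation reproduces the generating weight exactly.
    Extra non-significant and off-array rows exercise CpG selection.
    """
    cpgs = _trait_cpgs(cfg, trait)
    true_w = {c: float(w) for c, w in zip(cpgs, rng.normal(0.0, 1.0, len(cpgs)))}
    records = []
    for cpg, w in true_w.items():
        n_src = int(rng.integers(10_000, 30_000))
        z = float(np.sign(w) if w else 1.0) * rng.uniform(6.0, 30.0)
        if rng.random() < cfg.orientation_mix:
            se = rng.uniform(1e-3, 1e-2)
            r2 = compute_r2(z, n_src)
            beta = w * (n_src - 1) * se**2 / (1.0 - r2)
            records.append(EWASWeightRecord(
                cpg_id=cpg, beta=beta, se=se, n=n_src, z=z,
                orientation="meth_dependent", bonferroni_significant=True,
            ))
        else:
            se = abs(w) / abs(z) if w else 1e-3
            records.append(EWASWeightRecord(
                cpg_id=cpg, beta=w, se=se, n=n_src, z=z if w else 0.0,
                orientation="meth_independent", bonferroni_significant=True,
            ))
    for j in range(cfg.n_nonsignificant):
        records.append(EWASWeightRecord(
            cpg_id=f"cg_{trait}_ns{j:02d}", beta=rng.normal(0, 0.1),
            se=0.05, n=12_000, orientation="meth_independent",
            bonferroni_significant=False,
        ))
    for j in range(cfg.n_off_array):
        records.append(EWASWeightRecord(
            cpg_id=f"cg_{trait}_off{j:02d}", beta=rng.normal(0, 0.5),
            se=0.05, n=12_000, orientation="meth_independent",
            bonferroni_significant=True,
        ))
    return records, true_w


def _true_score(
    clean: pd.DataFrame,
    matrix: MethylationMatrix,
    weights: Mapping[str, float],
) -> np.ndarray:
    """Standardized technical-artifact-free score.

    Weighted sum of the clean beta values with the known batch/cell design
    projected out (projection is linear, so it is applied to the score
    vector directly).
    """
    cpgs = list(weights)
    s = clean[cpgs].to_numpy() @ np.array([weights[c] for c in cpgs])
    X, _ = _design_matrix(matrix)
    coef, *_ = np.linalg.lstsq(X, s, rcond=None)
    resid = s - X @ coef
    return (resid - resid.mean()) / resid.std(ddof=1)


def _modifier_values(cov: pd.DataFrame, modifier: str, age_center: float) -> np.ndarray:
    if modifier == "age_centered":
        return cov["age"].to_numpy() - age_center
    if modifier == "sex":
        return (cov["sex"] == "female").to_numpy(float)
    if modifier == "education2":
        return cov["education3"].isin(["hs", "college"]).to_numpy(float)
    if modifier == "current_smoker":
        return (cov["smoking3"] == "current").to_numpy(float)
    if modifier == "ever_smoker":
        return cov["smoking3"].isin(["former", "current"]).to_numpy(float)
    if modifier == "heavy_drinker":
        drinker = [
            classify_drinker(w, a, s)
            for w, a, s in zip(cov["drinks_per_week"], cov["age"], cov["sex"])
        ]
        return (np.asarray(drinker) == "heavy").astype(float)
    if modifier == "physically_active":
        return cov["physically_active"].to_numpy(float)
    raise ValueError(f"unknown modifier {modifier!r}")


def generate_phenotypes(
    cfg: GeneratorConfig,
    covariates: pd.DataFrame,
    clean_betas: pd.DataFrame,
    matrix: MethylationMatrix,
    true_weights: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Raw measurement table with known score, covariate and interaction effects."""
    missing_catalog = set(cfg.traits) - set(true_weights)
    if missing_catalog:
        raise ValueError(f"traits without catalogs: {sorted(missing_catalog)}")
    cov = covariates
    n = len(cov)
    age_center = float(cov["age"].mean())
    age_c = cov["age"].to_numpy() - age_center
    female = (cov["sex"] == "female").to_numpy(float)
    current = (cov["smoking3"] == "current").to_numpy(float)

    scores = {}
    analysis = {}
    for trait in cfg.traits:
        z = _true_score(clean_betas, matrix, true_weights[trait])
        scores[trait] = z
        a_eff, f_eff, m_eff, s_eff = DEFAULT_COV_EFFECTS[trait]
        med = TRAITS[trait].medication
        med_flag = cov[med].to_numpy(float) if med else np.zeros(n)
        y = (
            cfg.intercepts[trait]
            + cfg.beta_true[trait] * z
            + a_eff * age_c + f_eff * female + m_eff * med_flag + s_eff * current
        )
        for (t, modifier), coef in cfg.interactions.items():
            if t == trait:
                y = y + coef * z * _modifier_values(cov, modifier, age_center)
        y = y + rng.normal(0.0, cfg.noise_sd[trait], size=n)
        analysis[trait] = y

    out = cov.copy()
    # blood pressure as reading pairs with rare artifact readings
    for chan, artifact in (("sbp", 262.0), ("dbp", 31.0)):
        base = analysis.get(chan)
        if base is None:
            continue
        for r in (1, 2):
            reading = base + rng.normal(0.0, cfg.bp_reading_sd, size=n)
            bad = rng.random(n) < cfg.bp_artifact_rate
            reading = np.where(bad, artifact + rng.normal(0, 2, size=n), reading)
            out[f"{chan}{r}"] = reading
    for col in ("sbp1", "sbp2", "dbp1", "dbp2"):
        if col not in out:
            out[col] = np.nan

    if "bmi" in analysis:
        height = np.where(
            female > 0,
            rng.normal(1.62, 0.07, size=n),
            rng.normal(1.76, 0.07, size=n),
        )
        out["height_m"] = height
        out["weight_kg"] = analysis["bmi"] * height**2
    else:
        out["height_m"] = np.nan
        out["weight_kg"] = np.nan

    out["crp"] = np.exp(analysis["crp"]) if "crp" in analysis else np.nan
    out["hdl"] = np.exp(analysis["hdl"]) if "hdl" in analysis else 55.0
    out["tg"] = np.exp(analysis["tg"]) if "tg" in analysis else 130.0
    out["glucose"] = np.exp(analysis["glucose"]) if "glucose" in analysis else np.nan
    if "ldl" in analysis:
        out["tc"] = analysis["ldl"] + out["hdl"] + out["tg"] / 5.0
    else:
        out["tc"] = np.nan

    truth = TruthRecord(
        true_scores=pd.DataFrame(scores, index=cov.index),
        beta_true={t: cfg.beta_true[t] for t in cfg.traits},
        interactions=dict(cfg.interactions),
        noise_sd={t: cfg.noise_sd[t] for t in cfg.traits},
        intercepts={t: cfg.intercepts[t] for t in cfg.traits},
        age_center=age_center,
        true_weights={t: dict(true_weights[t]) for t in cfg.traits},
    )
    return out, truth


def simulate_study(cfg: GeneratorConfig) -> SimulatedStudy:
    """Generate one complete, seed-reproducible synthetic study."""
    rng = np.random.default_rng(cfg.seed)
    covariates = generate_covariates(cfg, rng)
    matrix, mtruth = generate_methylation(cfg, covariates, rng)
    catalogs, true_weights = {}, {}
    for trait in cfg.traits:
        catalogs[trait], true_weights[trait] = generate_ewas_catalog(cfg, trait, rng)
    samples, truth = generate_phenotypes(
        cfg, covariates, mtruth.clean_betas, matrix, true_weights, rng
    )
    return SimulatedStudy(
        config=cfg,
        covariates=covariates,
        methylation=matrix,
        clean_betas=mtruth.clean_betas,
        catalogs=catalogs,
        samples=samples,
        truth=truth,
    )


def write_dataset(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write catalogs, manifest, beta matrix, sample metadata and truth as text.

    Produces the delimited inputs the pipeline consumes from disk: one TSV
    catalog per trait plus a YAML manifest, the beta matrix (samples × CpGs),
    a sample-metadata table (batch factors and cell proportions), the raw
    sample table and the true standardized scores.
    """
    outdir = Path(outdir)
    (outdir / "catalogs").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest: dict[str, dict] = {}
    for trait, records in study.catalogs.items():
        p = outdir / "catalogs" / f"{trait}.tsv"
        pd.DataFrame(
            [
                {
                    "cpg": r.cpg_id, "beta": r.beta, "se": r.se, "z": r.z,
                    "n": r.n, "orientation": r.orientation,
                    "significant": r.bonferroni_significant,
                }
                for r in records
            ]
        ).to_csv(p, sep="\t", index=False)
        manifest[trait] = {"catalog": f"catalogs/{trait}.tsv",
                           "units": "analysis scale"}
        paths[f"catalog_{trait}"] = p
    mpath = outdir / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh)
    paths["manifest"] = mpath
    for name, df in (
        ("beta_matrix", study.methylation.values),
        ("sample_meta", pd.concat(
            [study.methylation.batch, study.methylation.cell_props], axis=1)),
        ("samples", study.samples),
        ("truth_scores", study.truth.true_scores),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p
    return paths


def with_options(cfg: GeneratorConfig, **kwargs) -> GeneratorConfig:
    """Copy of a config with selected fields replaced."""
    return replace(cfg, **kwargs)
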