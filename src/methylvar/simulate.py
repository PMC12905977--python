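"""Synthetic cohorts with known epigenetic/genetic architecture.

Generates aligned genotype, methylation, phenotype and covariate data in
which fixed fractions of the phenotypic variance are attributable to
standardized CpG-probe effects and to SNP effects, with optional mQTL
coupling between the two marker sets.  Every downstream stage of the
pipeline (residualization, relationship matrices, Bayesian mixture
regression, REML, scoring, PheWAS) can therefore be tested against known
truth without any cohort download.

Model
-----
Per individual ``i``::

    height_i = b0 + b_sex * sex_i + b_age * (age_i - mean_age)
               + u_m,i + u_g,i + e_i

where ``u_m = Z_m beta_m`` and ``u_g = Z_g beta_g`` are linear predictors
over column-standardized probe signals and allele dosages.  Probe effects
act on the confounder-free biological signal of each probe; batch, slide
and cell-composition structure perturbs only the measured beta values, so
covariate adjustment downstream recovers exactly the signal the trait
responds to.  Marker
effects are drawn from a four-class mixture {null, small, medium, large}
with class variances in ratio 1 : 10 : 100 and then rescaled by a single
constant per set so the realized sample variances of ``u_m`` and ``u_g``
hit ``var_frac_dnam`` and ``var_frac_snp`` of the (fixed-effect-adjusted)
phenotypic variance exactly.

Methylation is simulated additively on the logit scale and squashed to
(0, 1) by the logistic function: a designated fraction of probes carries a
cis-driver SNP explaining ``mqtl_r2`` of the probe's latent variance, plus
batch offsets and a neutrophil-proportion loading so that the covariate
residualization stage has real confounding to remove.

A single ``numpy.random.Generator`` keyed by ``seed`` drives every draw;
the draw order is fixed (genotypes, covariates, methylation, effects,
residuals), so the same config and seed reproduce the cohort bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "CohortData", "simulate_cohort", "write_cohort"]

CELL_TYPES = ("neu", "cd4t", "cd8t", "bcell", "mono")

#: variance of small : medium : large effect classes before rescaling
CLASS_VARIANCE_RATIO = (1.0, 10.0, 100.0)


@dataclass
class SimConfig:
    """Generator settings; defaults emulate a desk-scale population cohort.

    Fractions are of the phenotypic variance that remains after age/sex
    fixed effects; ``resid_pheno_sd_cm`` sets that scale (within-sex SD of
    adult height is roughly 6.5-7 cm).
    """

    n_individuals: int = 1000
    n_probes: int = 1000
    n_snps: int = 1500
    var_frac_dnam: float = 0.25
    var_frac_snp: float = 0.55
    # class mixes chosen so the per-class variance shares mirror a
    # medium-dominated probe architecture and a small-dominated SNP
    # architecture (weights p_k * v_k with v = 1:10:100)
    class_probs_dnam: tuple = (0.85, 0.11, 0.039, 0.001)
    class_probs_snp: tuple = (0.90, 0.0955, 0.0044, 0.0001)
    mqtl_frac: float = 0.3
    mqtl_r2: float = 0.2
    maf_range: tuple = (0.05, 0.5)
    n_batches: int = 4
    n_slides: int = 8
    cell_dirichlet: tuple = (12.0, 4.0, 3.0, 2.0, 1.0)
    age_range: tuple = (18.0, 93.0)
    sex_effect_cm: float = 14.0
    age_effect_cm_per_year: float = -0.05
    intercept_cm: float = 162.0
    resid_pheno_sd_cm: float = 6.5
    pgs_r2: float = 0.6
    cross_sex_corr: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_probes < 1 or self.n_snps < 1:
            raise ValueError("n_individuals, n_probes and n_snps must be positive")
        if not (0.0 <= self.var_frac_dnam and 0.0 <= self.var_frac_snp):
            raise ValueError("variance fractions must be nonnegative")
        if self.var_frac_dnam + self.var_frac_snp >= 1.0:
            raise ValueError(
                "var_frac_dnam + var_frac_snp must be < 1 (residual variance strictly positive)"
            )
        for name in ("class_probs_dnam", "class_probs_snp"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be 4 nonnegative probabilities summing to 1")
        if not (0.0 <= self.mqtl_frac <= 1.0):
            raise ValueError("mqtl_frac must lie in [0, 1]")
        if not (0.0 <= self.mqtl_r2 < 1.0):
            raise ValueError("mqtl_r2 must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a subset of (0, 0.5]")
        if self.var_frac_dnam > 0 and self.class_probs_dnam[0] >= 1.0:
            raise ValueError("var_frac_dnam > 0 unattainable with all-null probe classes")
        if self.var_frac_snp > 0 and self.class_probs_snp[0] >= 1.0:
            raise ValueError("var_frac_snp > 0 unattainable with all-null SNP classes")
        if self.cross_sex_corr is not None and not (-1.0 <= self.cross_sex_corr <= 1.0):
            raise ValueError("cross_sex_corr must lie in [-1, 1]")


@dataclass
class CohortData:
    """Row-aligned cohort matrices plus (synthetic-only) ground truth."""

    individual_ids: np.ndarray
    genotypes: np.ndarray  # n x p_g dosages in [0, 2]
    snp_ids: np.ndarray
    methylation: np.ndarray  # n x p_m betas in (0, 1)
    probe_ids: np.ndarray
    phenotype: np.ndarray  # height, cm
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.individual_ids)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_class_effects(rng, p, class_probs):
    """Class labels (0..3) and unscaled effects with variances 1:10:100."""
    labels = rng.choice(4, size=p, p=np.asarray(class_probs, dtype=float))
    sd = np.zeros(p)
    for k in (1, 2, 3):
        sd[labels == k] = np.sqrt(CLASS_VARIANCE_RATIO[k - 1])
    beta = rng.standard_normal(p) * sd
    return labels, beta


def _scale_to_target(Z, beta, target_var):
    """One multiplicative constant so Var(Z beta) == target_var exactly."""
    if target_var == 0.0:
        return np.zeros_like(beta), np.zeros(Z.shape[0])
    u = Z @ beta
    v = u.var()
    if v <= 0.0:
        raise ValueError("requested variance fraction unattainable: no non-null effects drawn")
    c = np.sqrt(target_var / v)
    return beta * c, u * c


def simulate_cohort(config: SimConfig) -> CohortData:
    """Simulate one cohort under ``config``.

    Returns a :class:`CohortData` whose ``truth`` block records the effect
    vectors, class labels, linear predictors and the realized (not target)
    variance fractions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p_m, p_g = config.n_individuals, config.n_probes, config.n_snps

    # --- genotypes -------------------------------------------------------
    maf = rng.uniform(*config.maf_range, size=p_g)
    G = rng.binomial(2, maf, size=(n, p_g)).astype(float)

    # --- covariates ------------------------------------------------------
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = male
    batch = rng.integers(0, config.n_batches, size=n)
    slide = rng.integers(0, config.n_slides, size=n)
    cells = rng.dirichlet(np.asarray(config.cell_dirichlet, dtype=float), size=n)
    smoking = rng.standard_normal(n)

    # --- methylation on the logit scale ----------------------------------
    mu = rng.uniform(-1.5, 1.5, size=p_m)
    eps_sd = 0.35
    n_mqtl = int(round(config.mqtl_frac * p_m))
    mqtl_probes = rng.choice(p_m, size=n_mqtl, replace=False)
    mqtl_driver = rng.integers(0, p_g, size=n_mqtl)
    batch_eff = rng.normal(0.0, 0.08, size=(config.n_batches, p_m))
    cell_load = rng.normal(0.0, 0.15, size=p_m)  # loads on neutrophil fraction
    eps = rng.normal(0.0, eps_sd, size=(n, p_m))

    X_sig = mu + eps
    if n_mqtl:
        g = G[:, mqtl_driver]
        gsd = g.std(axis=0)
        gsd[gsd == 0] = 1.0
        gz = (g - g.mean(axis=0)) / gsd
        # driver explains mqtl_r2 of the probe's latent (pre-squash) noise+driver variance
        a = np.sqrt(config.mqtl_r2 / (1.0 - config.mqtl_r2)) * eps_sd
        X_sig[:, mqtl_probes] += a * gz
    # batch/slide/cell structure confounds the MEASURED probe values only;
    # trait effects act on the biological signal, which is what downstream
    # covariate adjustment of the probes recovers
    neu_z = (cells[:, 0] - cells[:, 0].mean()) / cells[:, 0].std()
    X_obs = X_sig + batch_eff[batch] + np.outer(neu_z, cell_load)
    M = _sigmoid(X_obs)
    M_sig = _sigmoid(X_sig)

    # --- marker effects and phenotype ------------------------------------
    def _standardize(A):
        sd = A.std(axis=0)
        sd[sd == 0] = 1.0
        return (A - A.mean(axis=0)) / sd

    Zm, Zg = _standardize(M_sig), _standardize(G)
    sigma2_p = config.resid_pheno_sd_cm**2

    class_m, beta_m0 = _draw_class_effects(rng, p_m, config.class_probs_dnam)
    class_g, beta_g0 = _draw_class_effects(rng, p_g, config.class_probs_snp)

    truth: dict = {"class_m": class_m, "class_g": class_g}

    if config.cross_sex_corr is None:
        beta_m, u_m = _scale_to_target(Zm, beta_m0, config.var_frac_dnam * sigma2_p)
        indep = rng.standard_normal(p_m)  # draw-order stability across configs
    else:
        # sex-specific probe effects with correlation r, same class labels
        r = config.cross_sex_corr
        indep = rng.standard_normal(p_m)
        sd0 = np.where(class_m > 0, np.sqrt(np.where(class_m > 0,
                       np.asarray((1.0,) + CLASS_VARIANCE_RATIO)[class_m], 1.0)), 0.0)
        beta_f0 = r * beta_m0 + np.sqrt(max(0.0, 1.0 - r * r)) * indep * sd0
        male = sex == 1
        u_m = np.zeros(n)
        beta_m_male = beta_m_female = np.zeros(p_m)
        target = config.var_frac_dnam * sigma2_p
        if target > 0:
            um_male = Zm[male] @ beta_m0
            um_female = Zm[~male] @ beta_f0
            if um_male.var() <= 0 or um_female.var() <= 0:
                raise ValueError("requested variance fraction unattainable in one sex")
            beta_m_male = beta_m0 * np.sqrt(target / um_male.var())
            beta_m_female = beta_f0 * np.sqrt(target / um_female.var())
            u_m[male] = Zm[male] @ beta_m_male
            u_m[~male] = Zm[~male] @ beta_m_female
        beta_m = beta_m_male  # reported per-sex below
        truth["beta_m_male"] = beta_m_male
        truth["beta_m_female"] = beta_m_female
    beta_g, u_g = _scale_to_target(Zg, beta_g0, config.var_frac_snp * sigma2_p)

    resid_var = (1.0 - config.var_frac_dnam - config.var_frac_snp) * sigma2_p
    e = rng.normal(0.0, np.sqrt(resid_var), size=n)

    mean_age = np.mean(config.age_range)
    height = (
        config.intercept_cm
        + config.sex_effect_cm * sex
        + config.age_effect_cm_per_year * (age - mean_age)
        + u_m
        + u_g
        + e
    )

    # noisy polygenic-score proxy anchored to the true genetic value
    if u_g.std() > 0 and config.pgs_r2 > 0:
        ugz = (u_g - u_g.mean()) / u_g.std()
        pgs = np.sqrt(config.pgs_r2) * ugz + rng.normal(
            0.0, np.sqrt(1.0 - config.pgs_r2), size=n
        )
    else:
        pgs = rng.standard_normal(n)

    denom = u_m.var() + u_g.var() + e.var()
    truth.update(
        beta_m=beta_m,
        beta_g=beta_g,
        u_m=u_m,
        u_g=u_g,
        residual=e,
        realized_var_frac_dnam=float(u_m.var() / denom),
        realized_var_frac_snp=float(u_g.var() / denom),
        realized_var_frac_resid=float(e.var() / denom),
        mqtl_probes=np.sort(mqtl_probes),
        mqtl_driver=mqtl_driver[np.argsort(mqtl_probes)],
        config=asdict(config),
    )

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "batch": batch,
            "slide": slide,
            **{f"cell_{c}": cells[:, i] for i, c in enumerate(CELL_TYPES)},
            "smoking_score": smoking,
            "pgs": pgs,
        }
    )
    ids = np.array([f"id_{i:06d}" for i in range(n)])
    covariates.index = pd.Index(ids, name="iid")

    return CohortData(
        individual_ids=ids,
        genotypes=G,
        snp_ids=np.array([f"rs{j:06d}" for j in range(p_g)]),
        methylation=M,
        probe_ids=np.array([f"cg{j:06d}" for j in range(p_m)]),
        phenotype=height,
        covariates=covariates,
        truth=truth,
    )


def _matrix_frame(values, ids, cols) -> pd.DataFrame:
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "iid", ids)
    return df


def write_cohort(data: CohortData, dir: str | Path, overwrite: bool = False) -> dict:
    """Write a cohort as TSV matrices + covariate table + truth JSON.

    Returns the mapping of logical names to paths.  Refuses to overwrite
    existing files unless ``overwrite`` is set.
    """
    if data.n == 0:
        raise ValueError("refusing to write an empty cohort (n = 0)")
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylation": out / "methylation.tsv",
        "genotypes": out / "genotypes.tsv",
        "phenotype": out / "phenotype.tsv",
        "truth": out / "truth.json",
    }
    if not overwrite:
        for p in paths.values():
            if p.exists():
                raise FileExistsError(f"{p} exists; pass overwrite=True to replace")

    _matrix_frame(data.methylation, data.individual_ids, data.probe_ids).to_csv(
        paths["methylation"], sep="\t", index=False, float_format="%.10g"
    )
    _matrix_frame(data.genotypes, data.individual_ids, data.snp_ids).to_csv(
        paths["genotypes"], sep="\t", index=False, float_format="%.10g"
    )
    pheno = data.covariates.reset_index()
    pheno.insert(1, "height_cm", data.phenotype)
    pheno.to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.10g")

    def _jsonable(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    with open(paths["truth"], "w") as fh:
        json.dump({k: _jsonable(v) for k, v in data.truth.items()}, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
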