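"""Phenome-wide association of a profile score, with Bonferroni control.

For each phenotype in a panel the (cm-scale) profile score is regressed
on the standardized phenotype with age and sex adjustment — the score is
the outcome, matching the discovery analysis — and the same machinery is
run with measured height as the outcome for side-by-side comparison.
Effect sizes are per SD of the phenotype because every predictor is
mean-centred and scaled to unit variance before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import IncrementalR2, incremental_r2

__all__ = ["PhewasTable", "run_phewas", "joint_adjustment_fit"]


@dataclass
class PhewasTable:
    table: pd.DataFrame  # one row per phenotype
    alpha: float
    n_phenotypes: int
    bonferroni_threshold: float
    skipped: list

    def summary(self) -> str:
        lines = [
            f"PheWAS: {self.n_phenotypes} phenotypes, alpha = {self.alpha}, "
            f"Bonferroni threshold = {self.bonferroni_threshold:.4g}",
        ]
        sig = self.table[self.table["bonferroni_significant"]]
        lines.append(f"significant associations with the score: {len(sig)}")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['phenotype']}: beta = {row['effect']:.3f} "
                f"(SE {row['se']:.3f}), p = {row['p']:.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "n_phenotypes": int(self.n_phenotypes),
            "bonferroni_threshold": float(self.bonferroni_threshold),
            "skipped": list(self.skipped),
            "table": self.table.to_dict(orient="records"),
        }


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _fit_one(outcome, pheno, age, sex):
    X = np.column_stack([np.ones(len(pheno)), pheno, age, sex])
    fit = sm.OLS(outcome, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def run_phewas(score, phenotypes: pd.DataFrame, covariates: pd.DataFrame,
               alpha: float = 0.05, height=None) -> PhewasTable:
    """One age/sex-adjusted OLS per phenotype: ``score ~ phenotype + age + sex``.

    Phenotypes (binary ones supplied as 0/1) and the age/sex covariates
    are mean-centred and scaled to unit variance per complete-case
    subsample; phenotypes with fewer than 3 distinct values after
    standardization are skipped and recorded.  When ``height`` is given,
    a parallel column block reports the same regressions with measured
    height as the outcome.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    score = np.asarray(score, dtype=float)
    n_ph = phenotypes.shape[1]
    threshold = alpha / n_ph
    rows, skipped = [], []
    for col in phenotypes.columns:
        v = phenotypes[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if len(np.unique(v[ok])) < 3:
            skipped.append(str(col))
            continue
        pheno = _standardize(v[ok])
        age = _standardize(covariates["age"].to_numpy(float)[ok])
        sex = _standardize(covariates["sex"].to_numpy(float)[ok])
        beta, se, p = _fit_one(score[ok], pheno, age, sex)
        row = {
            "phenotype": str(col), "effect": beta, "se": se, "p": p,
            "bonferroni_significant": bool(p < threshold), "n_used": int(ok.sum()),
        }
        if height is not None:
            h = np.asarray(height, dtype=float)[ok]
            hb, hse, hp = _fit_one(h, pheno, age, sex)
            row.update(height_effect=hb, height_se=hse, height_p=hp,
                       height_bonferroni_significant=bool(hp < threshold))
        rows.append(row)
    return PhewasTable(
        table=pd.DataFrame(rows), alpha=alpha, n_phenotypes=n_ph,
        bonferroni_threshold=threshold, skipped=skipped,
    )


def joint_adjustment_fit(y, factors: pd.DataFrame | None, score,
                         covariates: pd.DataFrame | None = None,
                         pgs=None) -> IncrementalR2:
    """Does the score predict height beyond a joint health/lifestyle block?

    Base model: age + sex (+ every factor column, + optional PGS); the
    return value is the incremental adjusted R² and p-value of the score
    on top of that base.
    """
    parts = []
    if covariates is not None:
        parts.append(covariates[["age", "sex"]].to_numpy(float))
    if factors is not None and factors.shape[1] > 0:
        parts.append(factors.to_numpy(float))
    if pgs is not None:
        parts.append(np.asarray(pgs, dtype=float)[:, None])
    base = np.column_stack(parts) if parts else None
    return incremental_r2(y, base, score)
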