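"""Methylation profile scores (MPS) and their out-of-sample evaluation.

A profile score is a weighted sum of an individual's residualized,
standardized probe values, with weights taken from the posterior mean
effects of a training-cohort fit.  Evaluation covers: Pearson correlation
with the measured phenotype, rescaling of the score to phenotype units
(cm) using training-cohort anchors, incremental adjusted R² under nested
covariate models, and the top-vs-bottom-decile phenotype contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import ResidualizedMatrix

__all__ = [
    "WeightSet",
    "ScoreReport",
    "IncrementalR2",
    "weights_from_results",
    "compute_mps",
    "rescale_to_cm",
    "incremental_r2",
    "decile_contrast",
    "evaluate_score",
]

logger = logging.getLogger(__name__)


@dataclass
class WeightSet:
    """Posterior-mean marker weights plus cm-scale training anchors."""

    marker_ids: np.ndarray
    weights: np.ndarray
    source: str = ""
    train_pheno_mean: float | None = None
    train_pheno_sd: float | None = None

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.marker_ids) != len(self.weights):
            raise ValueError("marker_ids and weights differ in length")
        if len(np.unique(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids in weight set")
        if np.any(~np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def weights_from_results(results, set_name: str, train_phenotype=None,
                         source: str = "") -> WeightSet:
    """Extract a :class:`WeightSet` from a fitted BayesRResults set."""
    mean = sd = None
    if train_phenotype is not None:
        y = np.asarray(train_phenotype, dtype=float)
        mean, sd = float(y.mean()), float(y.std(ddof=1))
    return WeightSet(
        marker_ids=results.marker_ids[set_name],
        weights=np.asarray(results.beta_mean[set_name], dtype=float),
        source=source or f"bayesr:{set_name}",
        train_pheno_mean=mean,
        train_pheno_sd=sd,
    )


@dataclass
class IncrementalR2:
    incremental_adj_r2: float
    p_value: float
    adj_r2_base: float
    adj_r2_full: float
    score_coef: float
    collinear: bool = False


@dataclass
class ScoreReport:
    score_raw: np.ndarray
    score_cm: np.ndarray
    pearson_r: float
    r_pvalue: float
    incremental_adj_r2: dict  # model label -> IncrementalR2
    decile_diff_cm: float
    decile_pvalue: float
    n_markers_used: int = 0
    n_markers_missing: int = 0

    def summary(self) -> str:
        lines = [
            "Profile-score evaluation",
            f"  markers used / missing: {self.n_markers_used} / {self.n_markers_missing}",
            f"  Pearson r with phenotype: {self.pearson_r:.3f} (p = {self.r_pvalue:.3g})",
            f"  top-vs-bottom decile contrast: {self.decile_diff_cm:.2f} cm "
            f"(p = {self.decile_pvalue:.3g})",
        ]
        for label, inc in self.incremental_adj_r2.items():
            lines.append(
                f"  incremental adj. R2 [{label}]: {inc.incremental_adj_r2:.4f} "
                f"(p = {inc.p_value:.3g})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "score_raw": np.asarray(self.score_raw).tolist(),
            "score_cm": np.asarray(self.score_cm).tolist(),
            "pearson_r": float(self.pearson_r),
            "r_pvalue": float(self.r_pvalue),
            "incremental_adj_r2": {
                k: {
                    "incremental_adj_r2": float(v.incremental_adj_r2),
                    "p_value": float(v.p_value),
                    "adj_r2_base": float(v.adj_r2_base),
                    "adj_r2_full": float(v.adj_r2_full),
                    "score_coef": float(v.score_coef),
                    "collinear": bool(v.collinear),
                }
                for k, v in self.incremental_adj_r2.items()
            },
            "decile_diff_cm": float(self.decile_diff_cm),
            "decile_pvalue": float(self.decile_pvalue),
            "n_markers_used": int(self.n_markers_used),
            "n_markers_missing": int(self.n_markers_missing),
        }


def compute_mps(weights: WeightSet, markers: ResidualizedMatrix,
                return_overlap: bool = False):
    """Raw profile score: Σ_j w_j·z_ij over markers present in the target.

    Markers absent from the target matrix are skipped and counted; zero
    overlap raises with the first missing ids named.
    """
    target = pd.Index(markers.marker_ids)
    pos = target.get_indexer(weights.marker_ids)
    present = pos >= 0
    if not present.any():
        missing = list(map(str, weights.marker_ids[:10]))
        raise ValueError(f"no weight markers found in target matrix; first missing: {missing}")
    n_missing = int((~present).sum())
    if n_missing:
        logger.warning("%d of %d weight markers missing from target", n_missing,
                       len(weights.marker_ids))
    score = markers.values[:, pos[present]] @ weights.weights[present]
    if return_overlap:
        return score, int(present.sum()), n_missing
    return score


def rescale_to_cm(raw: np.ndarray, weights: WeightSet, anchors: str = "train",
                  target_phenotype=None) -> np.ndarray:
    """Anchor the score to phenotype units.

    The raw score is z-scored within the target sample and re-anchored to
    the training phenotype's mean/SD (``anchors='train'``, the default) or
    to the target sample's own phenotype (``anchors='target'``).
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std(ddof=1)
    if sd <= 0:
        raise ValueError("raw score has zero variance; cannot rescale")
    z = (raw - raw.mean()) / sd
    if anchors == "train":
        if weights.train_pheno_mean is None or weights.train_pheno_sd is None:
            raise ValueError("weight set carries no training anchors; cannot rescale to cm")
        return z * weights.train_pheno_sd + weights.train_pheno_mean
    if anchors == "target":
        if target_phenotype is None:
            raise ValueError("anchors='target' requires target_phenotype")
        t = np.asarray(target_phenotype, dtype=float)
        return z * t.std(ddof=1) + t.mean()
    raise ValueError("anchors must be 'train' or 'target'")


def _design(base: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if base is None:
        return np.ones((n, 1))
    B = np.asarray(base, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    return np.column_stack([np.ones(n), B])


def incremental_r2(y, base_covariates, score) -> IncrementalR2:
    """Adjusted-R² gain from adding the score to a base OLS model.

    Returns the adjusted-R² difference between ``y ~ base + score`` and
    ``y ~ base``, with the Wald p-value of the score coefficient.  A score
    collinear with the base is flagged and the increment set to 0.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(score, dtype=float)
    Xb = _design(base_covariates, len(y))
    resid_s = s - Xb @ np.linalg.lstsq(Xb, s, rcond=None)[0]
    fit_b = sm.OLS(y, Xb).fit()
    if resid_s.var() < 1e-12 * max(s.var(), 1e-300):
        return IncrementalR2(0.0, 1.0, fit_b.rsquared_adj, fit_b.rsquared_adj,
                             0.0, collinear=True)
    Xf = np.column_stack([Xb, s])
    fit_f = sm.OLS(y, Xf).fit()
    return IncrementalR2(
        incremental_adj_r2=float(fit_f.rsquared_adj - fit_b.rsquared_adj),
        p_value=float(fit_f.pvalues[-1]),
        adj_r2_base=float(fit_b.rsquared_adj),
        adj_r2_full=float(fit_f.rsquared_adj),
        score_coef=float(fit_f.params[-1]),
    )


def decile_contrast(score, y) -> tuple[float, float]:
    """Mean phenotype difference, top minus bottom score decile (Welch test).

    Deciles are formed from the empirical quantile rank of the score with
    ties broken by stable index order; each tail holds ``n // 10``
    individuals.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(score)
    if n < 20:
        raise ValueError("need n >= 20 for a decile contrast")
    m = n // 10
    order = np.argsort(score, kind="stable")
    bottom, top = y[order[:m]], y[order[-m:]]
    diff = float(top.mean() - bottom.mean())
    t = stats.ttest_ind(top, bottom, equal_var=False)
    return diff, float(t.pvalue)


def evaluate_score(weights: WeightSet, markers: ResidualizedMatrix, phenotype,
                   base_models: dict | None = None,
                   anchors: str = "train") -> ScoreReport:
    """Full out-of-sample evaluation of a weight set on a target cohort.

    ``base_models`` maps a label to a covariate table (or None for the
    intercept-only base); each yields one incremental adjusted-R² entry.
    """
    y = np.asarray(phenotype, dtype=float)
    raw, n_used, n_missing = compute_mps(weights, markers, return_overlap=True)
    cm = rescale_to_cm(raw, weights, anchors=anchors, target_phenotype=y)
    r, p = stats.pearsonr(raw, y)
    inc = {
        label: incremental_r2(y, base, raw)
        for label, base in (base_models or {"intercept_only": None}).items()
    }
    diff, dp = decile_contrast(raw, y)
    return ScoreReport(
        score_raw=raw, score_cm=cm, pearson_r=float(r), r_pvalue=float(p),
        incremental_adj_r2=inc, decile_diff_cm=diff, decile_pvalue=dp,
        n_markers_used=n_used, n_markers_missing=n_missing,
    )
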