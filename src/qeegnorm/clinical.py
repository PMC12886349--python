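"""Ordinal clinical severity: the additive EEG-abnormality rubric and
the rank-based PCA of clinical scales.

The rubric summarizes a clinician's qualitative EEG reading into a
single ordinal rank: no abnormalities -> rank 1; otherwise the rank is
the sum of the weights of all distinct abnormality types present
(focal transient spectral alterations weigh 2, focal-global epileptiform
discharges 3, focal-global diffuse beta 4, and global abnormalities —
slow posterior dominant rhythm, disrupted anterior-posterior gradient,
burst suppression — 5 each).

The clinical PCA rank-transforms five ordinal scales (Vineland ABC,
GMFCS, MACS, CFCS, EEG-abnormality rank), eigendecomposes their Spearman
correlation matrix, and projects the z-scored ranks onto the
eigenvectors.  Sampling-adequacy diagnostics (Kaiser-Meyer-Olkin,
Bartlett's sphericity) are computed on the Pearson correlation matrix of
the raw scores.  Overall displacement in the (PC1, PC2) plane is the
variance-standardized distance sqrt(sum_k score_k^2 / lambda_k).
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

#: Abnormality type -> severity weight.  The three weight-5 entries are
#: the "global" abnormality types; each distinct type present contributes
#: its weight once.
CATEGORY_WEIGHTS = {
    "focal_transient": 2,
    "epileptiform_discharge": 3,
    "diffuse_beta": 4,
    "slow_pdr": 5,
    "ap_gradient_disruption": 5,
    "burst_suppression": 5,
}

NORMAL_RANK = 1

#: The five clinical scale columns, in fixed order.
SCALE_COLUMNS = ("vineland_abc", "gmfcs", "macs", "cfcs", "eeg_severity_rank")


def severity_rank(abnormalities: Iterable[str]) -> int:
    """Ordinal severity rank of a set of abnormality types.

    Empty set -> 1 (normal); otherwise the sum of weights of the
    distinct types present (duplicates count once).
    """
    kinds = set(abnormalities)
    unknown = kinds - set(CATEGORY_WEIGHTS)
    if unknown:
        raise ValueError(
            f"unknown abnormality categories {sorted(unknown)}; "
            f"expected a subset of {sorted(CATEGORY_WEIGHTS)}"
        )
    if not kinds:
        return NORMAL_RANK
    return sum(CATEGORY_WEIGHTS[k] for k in kinds)


def load_table2() -> pd.DataFrame:
    """Packaged clinical severity table of the 15-patient cohort."""
    with resources.files("qeegnorm.data").joinpath("table2.csv").open() as f:
        return pd.read_csv(f)


def kmo(corr: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    Computed from the squared off-diagonal correlations versus squared
    partial correlations (anti-image).
    """
    corr = np.asarray(corr, dtype=float)
    inv = np.linalg.inv(corr)  # raises LinAlgError if singular
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    off = corr - np.diag(np.diag(corr))
    r2 = np.sum(off**2)
    a2 = np.sum(partial**2)
    return float(r2 / (r2 + a2))


def bartlett_sphericity(corr: np.ndarray, n: int) -> tuple[float, float]:
    """Bartlett's test of sphericity: chi2 and p against identity.

    ``chi2 = -(n - 1 - (2p + 5)/6) * ln det(R)`` with p(p-1)/2 df.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    det = np.linalg.det(corr)
    if det <= 0:
        raise ValueError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) / 2
    return float(chi2), float(stats.chi2.sf(chi2, df))


class ClinicalSeverityPCA(BaseEstimator):
    """Rank-based PCA of ordinal clinical scales.

    Each scale is rank-transformed (average ranks for ties), the 5x5
    Spearman correlation matrix eigendecomposed, and patient scores
    obtained by projecting z-scored ranks onto the eigenvectors.
    Explained variance per component is ``100 * lambda_k / p``.

    Sign conventions make the axes clinically interpretable: PC1 is
    flipped so GMFCS loads positively (higher = more severe), PC2 so the
    EEG-abnormality rank loads negatively.  When the anchor columns are
    absent the largest-magnitude loading is made positive instead.

    Attributes (after ``fit``)
    --------------------------
    spearman_ : (p, p) Spearman correlation matrix of the ranks
    raw_corr_ : (p, p) Pearson matrix of the raw scores (diagnostics)
    eigenvalues_ : (p,) descending; sums to p
    components_ : (p, p) eigenvectors as rows, sign-fixed
    explained_variance_pct_ : (p,) percentages, sums to 100
    scores_ : (n, p) patient scores
    kmo_, bartlett_chi2_, bartlett_p_ : adequacy diagnostics on raw_corr_
    """

    def __init__(self, anchor_positive_pc1: str = "gmfcs",
                 anchor_negative_pc2: str = "eeg_severity_rank"):
        self.anchor_positive_pc1 = anchor_positive_pc1
        self.anchor_negative_pc2 = anchor_negative_pc2

    def fit(self, table: pd.DataFrame, y=None):
        cols = [c for c in SCALE_COLUMNS if c in table.columns]
        if len(cols) < len(SCALE_COLUMNS):
            # generic numeric table (synthetic cohorts)
            cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
        X = table[cols].to_numpy(dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 patients for the clinical PCA")
        if np.isnan(X).any():
            raise ValueError("missing values are not allowed (listwise requirement)")
        for j, c in enumerate(cols):
            if np.all(X[:, j] == X[0, j]):
                raise ValueError(f"scale {c!r} is constant across patients")
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        spearman = np.corrcoef(ranks, rowvar=False)
        evals, evecs = np.linalg.eigh(spearman)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        V = evecs.T  # rows are components
        z = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0, ddof=1)
        V = self._fix_signs(V, cols)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.ranks_ = ranks
        self.spearman_ = spearman
        self.raw_corr_ = np.corrcoef(X, rowvar=False)
        self.eigenvalues_ = evals
        self.components_ = V
        self.explained_variance_pct_ = 100.0 * evals / p
        self.scores_ = z @ V.T
        self.kmo_ = kmo(self.raw_corr_)
        self.bartlett_chi2_, self.bartlett_p_ = bartlett_sphericity(self.raw_corr_, n)
        self.n_features_in_ = p
        return self

    def fit_transform(self, table: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(table).scores_

    def _fix_signs(self, V: np.ndarray, cols: list[str]) -> np.ndarray:
        V = V.copy()
        for k in range(V.shape[0]):
            flip = False
            if k == 0 and self.anchor_positive_pc1 in cols:
                flip = V[k, cols.index(self.anchor_positive_pc1)] < 0
            elif k == 1 and self.anchor_negative_pc2 in cols:
                flip = V[k, cols.index(self.anchor_negative_pc2)] > 0
            else:
                flip = V[k, np.argmax(np.abs(V[k]))] < 0
            if flip:
                V[k] *= -1
        return V

    def variance_standardized_md(self, n_components: int = 2) -> np.ndarray:
        """Per-patient displacement sqrt(sum_k score_k^2 / lambda_k)."""
        check_is_fitted(self, "scores_")
        return clinical_variance_standardized_md(
            self.scores_[:, :n_components], self.eigenvalues_[:n_components]
        )


def clinical_variance_standardized_md(scores: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """Distance from the cohort centroid with axes scaled by 1/lambda."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(eigenvalues <= 0):
        raise ValueError("eigenvalues must be strictly positive")
    return np.sqrt(np.sum(scores**2 / eigenvalues, axis=1))


def clinical_pca(table: pd.DataFrame) -> ClinicalSeverityPCA:
    """Thin functional wrapper over :class:`ClinicalSeverityPCA`."""
    return ClinicalSeverityPCA().fit(table)
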