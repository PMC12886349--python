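"""Inferential layer: paired state comparisons, block-wise FDR, and
Spearman correlations with permutation nulls and bootstrap intervals.

Deviance distributions are bounded below by zero and right-skewed, so
paired eyes-open/eyes-closed contrasts use Wilcoxon signed-rank tests
(normality of the differences is reported via Shapiro-Wilk alongside),
and deviance-clinical associations use Spearman rank correlations with
empirical permutation p-values and unstratified bootstrap percentile
confidence intervals.  Benjamini-Hochberg FDR is applied independently
within each family (block) of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 15_000
DEFAULT_N_BOOT = 15_000


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    effect_size_r: float
    shapiro_p: float
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p_perm: float
    n: int
    n_permutations: int
    n_bootstraps: int
    seed: int
    p_fdr: float = np.nan


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired vectors (zero diffs dropped).

    Effect size ``r = |Z| / sqrt(n)`` with the normal-approximation Z and
    n the number of pairs.  If every difference is zero the result is
    flagged degenerate with p = 1 and r = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(a)
    if n < 6:
        raise ValueError(f"need at least 6 pairs, got {n}")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(0.0, 1.0, 0.0, np.nan, n, degenerate=True)
    shapiro_p = float(stats.shapiro(d).pvalue) if np.ptp(d) > 0 else np.nan
    # exact p when scipy's default allows it (small n, no ties/zeros)
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    z = _signed_rank_z(d)
    return PairedTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_r=abs(z) / np.sqrt(n),
        shapiro_p=shapiro_p,
        n_pairs=n,
    )


def _signed_rank_z(d: np.ndarray) -> float:
    """Normal-approximation Z of the signed-rank statistic (ties corrected)."""
    d = d[d != 0]
    m = len(d)
    r = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(r[d > 0]))
    mu = m * (m + 1) / 4.0
    _, counts = np.unique(r, return_counts=True)
    tie_corr = np.sum(counts**3 - counts) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_corr
    return (w_plus - mu) / np.sqrt(var)


def bh_fdr(p_values: np.ndarray, blocks: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, independently per block."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value block")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if blocks is None:
        return multipletests(p, method="fdr_bh")[1]
    blocks = np.asarray(blocks)
    out = np.empty_like(p)
    for label in pd.unique(blocks):
        mask = blocks == label
        if not mask.any():
            raise ValueError(f"empty block {label!r}")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.sum(Xc * Yc, axis=1)
    den = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(Yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def spearman_perm_boot(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rho with a permutation p-value and bootstrap 95% CI.

    The two-tailed permutation p uses the add-one estimator
    ``(1 + #{|rho_perm| >= |rho|}) / (1 + n_perm)`` with y shuffled; the
    CI is the unstratified paired-bootstrap percentile interval.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rng = np.random.default_rng(seed)
    rx, ry = _rank(x), _rank(y)
    rho = float(_pearson_rows(rx[None, :], ry[None, :])[0])

    perm = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rho_perm = _pearson_rows(np.tile(rx, (n_perm, 1)), perm)
    p_perm = (1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (1 + n_perm)

    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    rbx = stats.rankdata(bx, axis=1)
    rby = stats.rankdata(by, axis=1)
    rho_boot = _pearson_rows(rbx, rby)
    rho_boot = rho_boot[np.isfinite(rho_boot)]  # drop constant resamples
    ci_low, ci_high = np.percentile(rho_boot, [2.5, 97.5])

    return CorrelationResult(
        rho=rho, ci_low=float(ci_low), ci_high=float(ci_high),
        p_perm=float(p_perm), n=n, n_permutations=n_perm,
        n_bootstraps=n_boot, seed=seed,
    )


def correlate_deviance_clinical(
    deviance: pd.DataFrame,
    clinical_scores: pd.DataFrame,
    axis: str,
    distance_kind: str,
    biomarker: str = "",
    n_perm: int = DEFAULT_N_PERM,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman MD-vs-clinical correlations per PC pair, FDR within the set.

    Parameters
    ----------
    deviance : DataFrame (subject, pc_pair, md_global, md_age, ...)
    clinical_scores : DataFrame indexed or keyed by ``subject`` with the
        clinical axis columns (e.g. ``pc1_clin``, ``pc2_clin``).
    axis : clinical axis column name.
    distance_kind : "global" or "age" (selects md_global / md_age).

    Returns one row per PC pair with rho, CI, permutation p, FDR p, and
    a significance flag at ``alpha``.
    """
    if distance_kind not in ("global", "age"):
        raise ValueError("distance_kind must be 'global' or 'age'")
    col = f"md_{distance_kind}"
    if axis not in clinical_scores.columns:
        raise ValueError(f"clinical scores lack axis column {axis!r}")
    clin = clinical_scores.set_index("subject") if "subject" in clinical_scores.columns \
        else clinical_scores
    missing = set(deviance["subject"]) - set(clin.index)
    if missing:
        raise ValueError(f"subjects without clinical scores: {sorted(missing)}")
    rows = []
    for k, (pair, grp) in enumerate(sorted(deviance.groupby("pc_pair"))):
        md = grp.set_index("subject")[col]
        yv = clin.loc[md.index, axis].to_numpy(dtype=float)
        res = spearman_perm_boot(
            md.to_numpy(dtype=float), yv,
            n_perm=n_perm, n_boot=n_boot, seed=seed + k,
        )
        rows.append({
            "biomarker": biomarker, "pc_pair": pair, "distance_kind": distance_kind,
            "clinical_axis": axis, "rho": res.rho, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p_perm": res.p_perm, "n": res.n,
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_perm"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out
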