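"""Robust deviance from the normative space.

Within each plane spanned by a pair of normative components, a robust
center and covariance are estimated with the Minimum Covariance
Determinant (MCD) estimator, and each subject's deviation is summarized
by the Mahalanobis distance

    MD = sqrt((x - u)^T  Sigma^-1  (x - u))

where u and Sigma come from the reference cohort.  Reference subjects'
own distances are computed leave-one-out (the subject is removed, the
center refitted, and the held-out point scored) to avoid optimism.  Two
centers are available: a global center over all reference subjects, and
an age-matched center over the reference subjects within +/-12 months of
the target subject's age.  Distances are reported in raw form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import MinCovDet

#: Default minimum number of reference subjects in an age window.
DEFAULT_MIN_AGE_SUPPORT = 10
#: Default age-matching half-window, in years (+/- 12 months).
DEFAULT_AGE_WINDOW_YEARS = 1.0


@dataclass(frozen=True)
class RobustCenter:
    """MCD location/scatter in a component-pair plane."""

    location: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2)
    support: np.ndarray  # indices of rows used to fit
    kind: str  # "global" | "age_matched"

    @property
    def n_support(self) -> int:
        return len(self.support)


def fit_mcd(
    scores: np.ndarray,
    kind: str = "global",
    random_state: int = 0,
    support_fraction: float | None = None,
) -> RobustCenter:
    """Robust center and covariance of n x 2 scores via MCD.

    The default support fraction is sklearn's ``(n + p + 1) / (2n)``
    (= ``(n + 3) / (2n)`` in a 2-D plane); the returned covariance is
    consistency-corrected and reweighted.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be an n x 2 matrix")
    n = scores.shape[0]
    if n < 5:
        raise ValueError(f"MCD needs at least 5 points, got {n}")
    mcd = MinCovDet(
        support_fraction=support_fraction, random_state=random_state
    ).fit(scores)
    cov = mcd.covariance_
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("singular robust covariance; points may be degenerate")
    return RobustCenter(
        location=mcd.location_,
        covariance=cov,
        support=np.arange(n),
        kind=kind,
    )


def mahalanobis(x: np.ndarray, center: RobustCenter) -> np.ndarray | float:
    """Mahalanobis distance (square-root form) of point(s) to a center."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x) - center.location
    det = np.linalg.det(center.covariance)
    if det <= 0 or not np.isfinite(det):
        raise ValueError("singular covariance matrix")
    sol = np.linalg.solve(center.covariance, pts.T)
    d = np.sqrt(np.einsum("ij,ji->i", pts, sol))
    return float(d[0]) if single else d


def jackknife_reference_md(
    scores: np.ndarray, random_state: int = 0, support_fraction: float | None = None
) -> np.ndarray:
    """Leave-one-out MD for every reference subject.

    Each subject is removed, the MCD refitted on the remaining n-1
    scores, and the held-out score's distance computed.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 6:
        raise ValueError(f"jackknife needs at least 6 subjects, got {n}")
    out = np.empty(n)
    for i in range(n):
        rest = np.delete(scores, i, axis=0)
        try:
            center = fit_mcd(
                rest, kind="global", random_state=random_state,
                support_fraction=support_fraction,
            )
        except ValueError as err:
            raise ValueError(f"jackknife refit failed for fold {i}: {err}") from err
        out[i] = mahalanobis(scores[i], center)
    return out


def age_matched_md(
    x: np.ndarray,
    age: float,
    reference_scores: np.ndarray,
    reference_ages: np.ndarray,
    window: float = DEFAULT_AGE_WINDOW_YEARS,
    min_n: int = DEFAULT_MIN_AGE_SUPPORT,
    random_state: int = 0,
) -> tuple[float, int]:
    """MD of one subject against the age-matched reference center.

    The center is the MCD of reference subjects with
    ``|reference_age - age| <= window`` (years).  If fewer than ``min_n``
    match, an error is raised — the window is never silently widened.

    Returns (distance, n_support).
    """
    reference_ages = np.asarray(reference_ages, dtype=float)
    reference_scores = np.asarray(reference_scores, dtype=float)
    mask = np.abs(reference_ages - age) <= window + 1e-12
    n_match = int(mask.sum())
    if n_match < min_n:
        raise ValueError(
            f"only {n_match} reference subjects within +/-{window:g} years of "
            f"age {age:g} (minimum {min_n}); supply a larger reference cohort"
        )
    center = fit_mcd(
        reference_scores[mask],
        kind="age_matched",
        random_state=random_state,
    )
    return float(mahalanobis(x, center)), n_match


def deviance_table(
    reference_scores: dict[tuple[int, int], np.ndarray],
    subject_scores: dict[tuple[int, int], np.ndarray],
    subject_ids: np.ndarray,
    cohort: str,
    reference_ages: np.ndarray | None = None,
    subject_ages: np.ndarray | None = None,
    window: float = DEFAULT_AGE_WINDOW_YEARS,
    min_n: int = DEFAULT_MIN_AGE_SUPPORT,
    random_state: int = 0,
) -> pd.DataFrame:
    """Global (and optionally age-matched) MD per subject per PC pair.

    ``reference_scores`` / ``subject_scores`` map a component pair
    ``(i, j)`` to n x 2 score matrices.  Age-matched distances are
    computed when both age vectors are given.

    Returns a DataFrame (subject, cohort, pc_pair, md_global, md_age,
    n_support_age); ``md_age`` is NaN when ages are not supplied.
    """
    with_age = reference_ages is not None and subject_ages is not None
    rows = []
    for pair, ref in reference_scores.items():
        center = fit_mcd(ref, kind="global", random_state=random_state)
        md_g = mahalanobis(subject_scores[pair], center)
        for s, sid in enumerate(subject_ids):
            md_a, n_sup = np.nan, 0
            if with_age:
                md_a, n_sup = age_matched_md(
                    subject_scores[pair][s], float(subject_ages[s]),
                    ref, reference_ages, window=window, min_n=min_n,
                    random_state=random_state,
                )
            rows.append(
                (sid, cohort, f"PC{pair[0] + 1}-PC{pair[1] + 1}",
                 float(np.atleast_1d(md_g)[s]), md_a, n_sup)
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "cohort", "pc_pair", "md_global", "md_age", "n_support_age"],
    )
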