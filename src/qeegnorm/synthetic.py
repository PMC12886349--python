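"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without external data:

- parcel time series: a band-limited 1/f background plus, per canonical
  band, a band-pass-filtered noise carrier modulated by a positive
  envelope derived from fractional Gaussian noise (FGN).  The Hurst
  parameter of FGN equals the DFA exponent of its fluctuations, so the
  planted long-range temporal correlation of each band envelope is known
  analytically; planted band powers are calibrated against the measured
  background spectrum so the *total* relative power per canonical band
  hits its target.
- cohort feature matrices: latent factor model with planted loadings,
  component variances, age trends, and isotropic noise.
- eyes-open / eyes-closed state pairs: relative-power cohorts where the
  closed-eyes state multiplies alpha and theta features by boost factors
  and renormalizes each network's band block to 100%.
- ordinal clinical cohorts: a Gaussian copula with a target latent
  correlation matrix, discretized at explicit thresholds.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .aggregate import NETWORKS, feature_names
from .bands import CANONICAL_BANDS, make_band_scheme, welch_psd, band_powers
from .lrtc import bandpass

_HIGHEST_EDGE = 44.8


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise by Davies-Harte circulant embedding.

    Returns n samples of a zero-mean, unit-variance stationary Gaussian
    process whose DFA exponent equals ``hurst``.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"Hurst parameter must be in (0, 1), got {hurst}")
    if hurst == 0.5:
        return rng.standard_normal(n)
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma[: n + 1], gamma[n - 1: 0: -1]])  # length 2n
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # clip tiny negative rounding errors
    m = 2 * n
    v = np.empty(m, dtype=complex)
    v[0] = np.sqrt(lam[0]) * rng.standard_normal()
    v[n] = np.sqrt(lam[n]) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    w = rng.standard_normal(n - 1)
    v[1:n] = np.sqrt(lam[1:n] / 2) * (u + 1j * w)
    v[n + 1:] = np.conj(v[1:n][::-1])
    x = np.fft.fft(v).real[:n] / np.sqrt(m)
    return x


@dataclass(frozen=True)
class SignalSpec:
    """Planted structure of synthetic parcel time series.

    band_relative_power maps canonical band name -> target fraction of
    total 1-45 Hz power; band_dfa maps band name -> target DFA exponent
    of that band's amplitude envelope.
    """

    n_parcels: int = 100
    fs: float = 250.0
    duration: float = 300.0
    band_relative_power: dict = field(default_factory=dict)
    band_dfa: dict = field(default_factory=dict)
    background_slope: float = 1.0
    envelope_strength: float = 0.8
    envelope_cutoff_hz: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 2 * _HIGHEST_EDGE:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge "
                f"({2 * _HIGHEST_EDGE} Hz)"
            )
        if self.n_parcels < 1 or self.duration <= 0:
            raise ValueError("n_parcels and duration must be positive")
        unknown = (set(self.band_relative_power) | set(self.band_dfa)) - set(CANONICAL_BANDS)
        if unknown:
            raise ValueError(f"unknown canonical bands {sorted(unknown)}")
        powers = np.array(list(self.band_relative_power.values()), dtype=float)
        if np.any(powers < 0) or powers.sum() > 1 + 1e-9:
            raise ValueError("band relative powers must be nonnegative and sum to <= 1")
        for band, h in self.band_dfa.items():
            if not 0.5 <= h <= 1.0:
                raise ValueError(f"DFA target for {band} must be in [0.5, 1.0]")


def _background_1f(n: int, fs: float, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^slope noise band-limited to 1-45 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    mask = (freqs >= 1.0) & (freqs <= 45.0)
    shape[mask] = freqs[mask] ** (-slope / 2.0)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def gen_parcel_timeseries(spec: SignalSpec) -> tuple[np.ndarray, dict]:
    """Generate n_parcels x (fs * duration) signals with planted structure.

    Returns (signals, ground_truth).  Ground truth records the planted
    band powers and DFA exponents, the achieved carrier variances, and
    any warnings (e.g. duration below the ~100 s DFA reliability limit).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    scheme = make_band_scheme()
    warnings_list = []
    if spec.band_dfa and spec.duration < 100:
        warnings_list.append(
            f"duration {spec.duration:g} s < 100 s: DFA targets are unreliable"
        )

    targets = dict(spec.band_relative_power)
    # bands with a DFA target but no power target still need a carrier
    for band in spec.band_dfa:
        targets.setdefault(band, min(0.3, max(0.0, 0.95 - sum(targets.values()))))

    def measured_rel(x: np.ndarray) -> dict[str, float]:
        freqs, psd = welch_psd(x, spec.fs)
        tbl = band_powers(freqs, psd, scheme)
        return {
            band: tbl.loc[tbl["bin"].isin(scheme.groups[band]), "relative_pct"].sum() / 100.0
            for band in CANONICAL_BANDS
        }

    b_lp, a_lp = sps.butter(4, spec.envelope_cutoff_hz / (spec.fs / 2))
    signals = np.empty((spec.n_parcels, n))
    carrier_var: dict[str, float] = {}
    for p in range(spec.n_parcels):
        bg = _background_1f(n, spec.fs, spec.background_slope, rng)
        if not targets:
            signals[p] = bg
            continue
        rel_bg = measured_rel(bg)
        S = sum(targets.values())
        B = sum(rel_bg[b] for b in targets)
        if S >= 1 - 1e-9:
            total_var, vb = 1.0, 0.0
        else:
            vb = 1.0
            total_var = vb * (1 - B) / (1 - S)
        carriers: dict[str, np.ndarray] = {}
        for band, r in targets.items():
            cv = r * total_var - rel_bg[band] * vb
            if cv <= 0:
                warnings_list.append(
                    f"band {band}: target {r:g} below background share; carrier skipped"
                )
                carrier_var[band] = 0.0
                continue
            carrier_var[band] = cv
            lo, hi = scheme.band_edges(band)
            carrier = bandpass(rng.standard_normal(n), (lo, hi), spec.fs)
            carrier /= np.std(carrier)
            h = spec.band_dfa.get(band, 0.5)
            # band-limited lognormal modulator: the FGN is low-passed well
            # below the DFA fit range so the planted Hurst exponent survives
            # in the envelope while spectral broadening stays small
            z = sps.filtfilt(b_lp, a_lp, fgn(n, h, rng))
            env = np.exp(spec.envelope_strength * z / np.std(z))
            mod = carrier * env
            carriers[band] = mod / np.std(mod) * np.sqrt(cv)
        x = bg * np.sqrt(vb) + sum(carriers.values())
        # two fixed-point corrections: rescale each carrier toward its
        # target total in-band share (filter roll-off and modulation
        # sidebands move a few percent of carrier power out of band)
        for _ in range(2):
            rel_now = measured_rel(x)
            for band in carriers:
                factor = targets[band] / max(rel_now[band], 1e-6)
                carriers[band] *= np.sqrt(np.clip(factor, 0.25, 4.0))
            x = bg * np.sqrt(vb) + sum(carriers.values())
        signals[p] = x

    ground_truth = {
        "seed": spec.seed,
        "fs": spec.fs,
        "duration": spec.duration,
        "target_relative_power": dict(spec.band_relative_power),
        "target_dfa": dict(spec.band_dfa),
        "carrier_variance": carrier_var,
        "warnings": warnings_list,
    }
    return signals, ground_truth


@dataclass(frozen=True)
class CohortSpec:
    """Latent factor model for cohort feature matrices."""

    n_subjects: int = 96
    n_features: int = 35
    loadings: np.ndarray | None = None  # (n_features, k)
    component_variances: np.ndarray | None = None  # (k,)
    noise_variance: float = 0.3
    age_range: tuple[float, float] = (4.3, 18.2)
    age_slope: np.ndarray | float = 0.0  # per-feature units/year
    age_sampling: str = "uniform"  # "uniform" | "stratified"
    seed: int = 0

    def resolved(self) -> tuple[np.ndarray, np.ndarray]:
        if self.loadings is None or self.component_variances is None:
            raise ValueError("loadings and component_variances must be set")
        L = np.asarray(self.loadings, dtype=float)
        v = np.asarray(self.component_variances, dtype=float)
        if L.shape[0] != self.n_features or L.shape[1] != len(v):
            raise ValueError("loading matrix shape inconsistent with spec")
        if L.shape[1] > self.n_features:
            raise ValueError("more components than features")
        if np.any(v <= 0):
            raise ValueError("component variances must be strictly positive")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        return L, v


def tdc_like_cohort_spec(seed: int = 0, n_subjects: int = 96) -> CohortSpec:
    """A reference-cohort spec mimicking the spectro-spatial structure of
    typically developing children: five components, each loading on one
    canonical band's seven network features."""
    L = np.zeros((35, 5))
    for k in range(5):
        L[k * len(NETWORKS): (k + 1) * len(NETWORKS), k] = 1.0
    return CohortSpec(
        n_subjects=n_subjects,
        loadings=L,
        component_variances=np.array([2.0, 1.5, 1.2, 1.0, 0.8]),
        noise_variance=0.3,
        age_slope=0.0,
        seed=seed,
    )


def gen_cohort_features(spec: CohortSpec, cohort: str = "TDC", state: str = "EOR"
                        ) -> tuple[pd.DataFrame, dict]:
    """Draw a feature matrix ``x = L z + slope (age - mean age) + noise``.

    Ages are uniform over the spec's range; latent scores z are Gaussian
    with the planted component variances.  Returns (FeatureMatrix,
    ground_truth with latent scores and ages).
    """
    L, v = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo_age, hi_age = spec.age_range
    if spec.age_sampling == "stratified":
        # one age per equal-width stratum (jittered): emulates age-matched
        # recruitment, guaranteeing near-constant density across the range
        ages = lo_age + (np.arange(n) + rng.uniform(0, 1, n)) * (hi_age - lo_age) / n
        rng.shuffle(ages)
    elif spec.age_sampling == "uniform":
        ages = rng.uniform(lo_age, hi_age, size=n)
    else:
        raise ValueError(f"unknown age_sampling {spec.age_sampling!r}")
    z = rng.standard_normal((n, len(v))) * np.sqrt(v)
    eps = rng.standard_normal((n, spec.n_features)) * np.sqrt(spec.noise_variance)
    slope = np.broadcast_to(np.asarray(spec.age_slope, dtype=float), (spec.n_features,))
    X = z @ L.T + np.outer(ages - np.mean(spec.age_range), slope) + eps
    names = feature_names() if spec.n_features == 35 else [f"f{j}" for j in range(spec.n_features)]
    df = pd.DataFrame(X, columns=names)
    meta = pd.DataFrame({
        "subject": [f"S{i:03d}" for i in range(n)],
        "cohort": cohort,
        "state": state,
        "age_years": ages,
        "sex": np.where(np.arange(n) % 2 == 0, "M", "F"),
    })
    out = pd.concat([meta, df], axis=1)
    return out, {"latent": z, "ages": ages, "seed": spec.seed}


_BASE_PROFILE = {"delta": 30.0, "theta": 25.0, "alpha": 20.0, "beta": 15.0,
                 "beta_gamma": 10.0}


def _renormalize_blocks(df: pd.DataFrame) -> pd.DataFrame:
    """Rescale each network's five band features to sum to 100%."""
    df = df.copy()
    for net in NETWORKS:
        cols = [f"{band}_{net}" for band in CANONICAL_BANDS]
        total = df[cols].sum(axis=1)
        df[cols] = df[cols].div(total, axis=0) * 100.0
    return df


def gen_state_pair(
    base: CohortSpec, alpha_boost: float = 1.5, theta_boost: float = 1.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired eyes-open / eyes-closed relative-power cohorts.

    The open-eyes state is a positive relative-power feature matrix
    (per-network band blocks summing to 100%); the closed-eyes state
    multiplies alpha- and theta-labelled features by the boosts and
    renormalizes, emulating the alpha enhancement of eye closure.
    Subject pairing is preserved.
    """
    if alpha_boost <= 0 or theta_boost <= 0:
        raise ValueError("boost factors must be strictly positive")
    if base.n_features != 35:
        raise ValueError("state pairs require the 35-feature layout")
    eor, truth = gen_cohort_features(base, cohort="TDC", state="EOR")
    names = feature_names()
    # impose a realistic positive band profile; latent variation rides on top
    for name in names:
        band = name.rsplit("_", 1)[0]
        eor[name] = np.clip(_BASE_PROFILE[band] + eor[name], 0.5, None)
    eor[names] = _renormalize_blocks(eor[names])
    ecr = eor.copy()
    ecr["state"] = "ECR"
    for name in names:
        band = name.rsplit("_", 1)[0]
        if band == "alpha":
            ecr[name] *= alpha_boost
        elif band == "theta":
            ecr[name] *= theta_boost
    ecr[names] = _renormalize_blocks(ecr[names])
    return eor, ecr


@dataclass(frozen=True)
class ClinicalCohortSpec:
    """Gaussian-copula model of ordinal clinical scales."""

    n_patients: int = 15
    correlation: np.ndarray | None = None  # (p, p) latent Spearman-like target
    levels: tuple = ((1, 2, 3, 4, 5),) * 5
    thresholds: tuple | None = None  # per scale, len(levels)-1 cut points
    names: tuple = ("scale_1", "scale_2", "scale_3", "scale_4", "scale_5")
    seed: int = 0

    def resolved_correlation(self) -> np.ndarray:
        C = np.asarray(self.correlation, dtype=float) if self.correlation is not None \
            else np.eye(len(self.levels))
        if C.shape[0] != C.shape[1] or not np.allclose(C, C.T):
            raise ValueError("correlation matrix must be square and symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        evals = np.linalg.eigvalsh(C)
        if evals.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semidefinite: "
                f"eigenvalue {evals.min():.3g} < 0"
            )
        return C

    def resolved_thresholds(self) -> list[np.ndarray]:
        if self.thresholds is not None:
            return [np.asarray(t, dtype=float) for t in self.thresholds]
        # equiprobable levels by default
        out = []
        from scipy.stats import norm
        for lv in self.levels:
            qs = np.linspace(0, 1, len(lv) + 1)[1:-1]
            out.append(norm.ppf(qs))
        return out


def gen_clinical_cohort(spec: ClinicalCohortSpec) -> pd.DataFrame:
    """Sample an ordinal clinical table from the Gaussian copula."""
    C = spec.resolved_correlation()
    thresholds = spec.resolved_thresholds()
    if len(thresholds) != len(spec.levels) or C.shape[0] != len(spec.levels):
        raise ValueError("levels, thresholds, and correlation sizes disagree")
    rng = np.random.default_rng(spec.seed)
    evals, evecs = np.linalg.eigh(C)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    latent = rng.standard_normal((spec.n_patients, C.shape[0])) @ root.T
    data = {}
    for j, (name, lv, th) in enumerate(zip(spec.names, spec.levels, thresholds)):
        idx = np.searchsorted(th, latent[:, j])
        data[name] = np.asarray(lv)[idx]
    df = pd.DataFrame(data)
    df.insert(0, "patient", np.arange(1, spec.n_patients + 1))
    return df


def save_timeseries(prefix, signals: np.ndarray, fs: float, seed: int) -> None:
    """Write signals as ``<prefix>.npy`` with a JSON sidecar."""
    np.save(f"{prefix}.npy", signals)
    sidecar = {
        "fs": fs,
        "n_parcels": int(signals.shape[0]),
        "n_samples": int(signals.shape[1]),
        "parcel_ids": list(range(1, signals.shape[0] + 1)),
        "seed": seed,
    }
    with open(f"{prefix}.json", "w") as f:
        json.dump(sidecar, f, indent=1)


def load_timeseries(prefix) -> tuple[np.ndarray, dict]:
    with open(f"{prefix}.json") as f:
        sidecar = json.load(f)
    return np.load(f"{prefix}.npy"), sidecar
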