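"""End-to-end orchestration: simulate -> features -> fit -> deviate ->
clinical -> correlate, with a run manifest for provenance.

The simulate stage generates cohort feature matrices directly from the
latent-factor generator by default ("features" mode); a "timeseries"
mode synthesizes parcel waveforms and pushes them through the spectral,
LRTC, and aggregation stages, and is intended for small demonstration
sizes.  All randomness flows from one master seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate, clinical, deviance, lrtc, normative, stats, synthetic
from .bands import make_band_scheme, power_table

BIOMARKERS = ("absolute_power", "relative_power", "lrtc")
CLINICAL_AXES = ("pc1_clin", "pc2_clin")
DISTANCE_KINDS = ("global", "age")


@dataclass
class RunConfig:
    """Configuration of a full synthetic run; defaults mirror the
    published analysis constants."""

    out_dir: str = "qeegnorm_run"
    simulate_mode: str = "features"  # "features" | "timeseries"
    stages: list = field(default_factory=lambda: [
        "simulate", "features", "clinical", "fit", "deviate", "correlate",
    ])
    n_reference: int = 96
    n_patients: int = 15
    n_components: int = 5
    sparsity: float = 1.5
    age_window_years: float = 1.0
    min_age_support: int = 10
    n_perm: int = 15_000
    n_boot: int = 15_000
    alpha: float = 0.05
    seed: int = 0
    # timeseries-mode sizes (kept small; the mode is demonstrative)
    ts_n_parcels: int = 100
    ts_duration_s: float = 120.0
    ts_fs: float = 250.0
    dfa_fit_range: list = field(default_factory=lambda: [2.0, 20.0])
    patient_shift: float = 3.0  # latent-space deviation magnitude of patients

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def substream(self, name: str) -> int:
        """Named 31-bit substream seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _simulate_features(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Reference + patient feature matrices per biomarker (features mode)."""
    out = {}
    for b, biomarker in enumerate(BIOMARKERS):
        spec = dataclasses.replace(
            synthetic.tdc_like_cohort_spec(
                seed=config.substream(f"ref-{biomarker}"),
                n_subjects=config.n_reference,
            ),
            age_sampling="stratified",
        )
        ref, _ = synthetic.gen_cohort_features(spec, cohort="TDC", state="EOR")
        pat_spec = dataclasses.replace(
            spec,
            n_subjects=config.n_patients,
            seed=config.substream(f"pat-{biomarker}"),
            age_range=(5.0, 12.8),
        )
        pat, truth = synthetic.gen_cohort_features(pat_spec, cohort="patient", state="EOR")
        # plant a deviation along the first latent direction so patient
        # deviance carries signal for the correlation stage
        rng = np.random.default_rng(config.substream(f"shift-{biomarker}"))
        severity = rng.uniform(0, 1, size=config.n_patients)
        L, _ = pat_spec.resolved()
        names = aggregate.feature_names()
        pat[names] = pat[names].to_numpy() + np.outer(
            severity * config.patient_shift, L[:, b % L.shape[1]]
        )
        pat["subject"] = [f"P{i:03d}" for i in range(config.n_patients)]
        out[biomarker] = pd.concat([ref, pat], ignore_index=True)
        out[f"_severity_{biomarker}"] = pd.DataFrame(
            {"subject": pat["subject"], "severity": severity}
        )
    return out


def _simulate_timeseries_features(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Small time-series cohort pushed through spectral/LRTC/aggregation."""
    scheme = make_band_scheme()
    pmap = aggregate.default_parcel_network_map()
    dfa_cfg = lrtc.DfaConfig(fit_range=tuple(config.dfa_fit_range))
    rows = {b: [] for b in BIOMARKERS}
    meta = []
    rng = np.random.default_rng(config.substream("ts-ages"))
    n_total = config.n_reference + config.n_patients
    for i in range(n_total):
        is_ref = i < config.n_reference
        spec = synthetic.SignalSpec(
            n_parcels=config.ts_n_parcels,
            fs=config.ts_fs,
            duration=config.ts_duration_s,
            band_relative_power={"alpha": 0.3 if is_ref else 0.15,
                                 "theta": 0.2 if is_ref else 0.35},
            band_dfa={"alpha": 0.7},
            seed=config.substream(f"ts-{i}"),
        )
        signals, _ = synthetic.gen_parcel_timeseries(spec)
        ptab = power_table(signals, config.ts_fs, scheme)
        dtab = lrtc.dfa_table(signals, config.ts_fs, scheme, dfa_cfg)
        for biomarker, tab in (
            ("absolute_power", ptab), ("relative_power", ptab), ("lrtc", dtab)
        ):
            rows[biomarker].append(
                aggregate.aggregate_biomarker(tab, biomarker, pmap, scheme)
            )
        meta.append({
            "subject": (f"S{i:03d}" if is_ref else f"P{i - config.n_reference:03d}"),
            "cohort": "TDC" if is_ref else "patient",
            "state": "EOR",
            "age_years": float(rng.uniform(4.3, 18.2)),
            "sex": "M" if i % 2 == 0 else "F",
        })
    meta_df = pd.DataFrame(meta)
    return {
        b: aggregate.build_feature_matrix(rows[b], meta_df) for b in BIOMARKERS
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the output bundle.

    Writes feature matrices, fitted spaces, deviance tables, clinical
    PCA results, the correlation table (3 biomarkers x 10 PC pairs x 2
    distance kinds x 2 clinical axes = 120 rows), and a manifest.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = []
    tables: dict[str, pd.DataFrame] = {}
    cpca = None
    clin_scores = None
    deviance_tables: dict[str, pd.DataFrame] = {}

    def requested(name: str) -> bool:
        return name in config.stages

    # --- simulate + features ---------------------------------------------
    if requested("simulate") or requested("features"):
        if config.simulate_mode == "features":
            tables = _simulate_features(config)
        elif config.simulate_mode == "timeseries":
            tables = _simulate_timeseries_features(config)
        else:
            raise ValueError(f"unknown simulate_mode {config.simulate_mode!r}")
        for biomarker in BIOMARKERS:
            tables[biomarker].to_csv(out_dir / f"features_{biomarker}.csv", index=False)
        stages += [s for s in ("simulate", "features") if requested(s)]

    # --- clinical ---------------------------------------------------------
    if requested("clinical"):
        table2 = clinical.load_table2()
        cpca = clinical.ClinicalSeverityPCA().fit(table2)
        clin_scores = pd.DataFrame({
            "subject": [f"P{i:03d}" for i in range(len(table2))],
            "pc1_clin": cpca.scores_[:, 0],
            "pc2_clin": cpca.scores_[:, 1],
        })
        clin_scores.to_csv(out_dir / "clinical_scores.csv", index=False)
        with open(out_dir / "clinical_pca.json", "w") as f:
            json.dump({
                "eigenvalues": cpca.eigenvalues_.tolist(),
                "explained_variance_pct": cpca.explained_variance_pct_.tolist(),
                "kmo": cpca.kmo_,
                "bartlett_chi2": cpca.bartlett_chi2_,
                "bartlett_p": cpca.bartlett_p_,
            }, f, indent=1)
        stages.append("clinical")

    # --- fit + deviate ----------------------------------------------------
    for biomarker in BIOMARKERS if (requested("fit") or requested("deviate")) else ():
        if not tables:
            raise RuntimeError("fit stage requires the simulate/features stages")
        fm = tables[biomarker]
        meta, X = aggregate.split_features(fm)
        ref_mask = (meta["cohort"] == "TDC").to_numpy()
        scaler, space = normative.fit_normative_space(
            X[ref_mask],
            n_components=config.n_components,
            sparsity=config.sparsity,
            random_state=config.substream(f"spca-{biomarker}"),
        )
        normative.save_space(out_dir / f"space_{biomarker}.json", scaler, space)
        Xs = scaler.transform(X)
        ref_scores = {p: space.project_pair(Xs[ref_mask], p)
                      for p in space.component_pairs()}
        pat_scores = {p: space.project_pair(Xs[~ref_mask], p)
                      for p in space.component_pairs()}
        dt = deviance.deviance_table(
            ref_scores, pat_scores,
            subject_ids=meta.loc[~ref_mask, "subject"].to_numpy(),
            cohort="patient",
            reference_ages=meta.loc[ref_mask, "age_years"].to_numpy(),
            subject_ages=meta.loc[~ref_mask, "age_years"].to_numpy(),
            window=config.age_window_years,
            min_n=config.min_age_support,
            random_state=config.substream(f"mcd-{biomarker}"),
        )
        dt.to_csv(out_dir / f"deviance_{biomarker}.csv", index=False)
        deviance_tables[biomarker] = dt
    stages += [s for s in ("fit", "deviate") if requested(s)]

    # --- correlate --------------------------------------------------------
    correlations = None
    if requested("correlate"):
        if not deviance_tables or clin_scores is None:
            raise RuntimeError(
                "correlate stage requires the deviate and clinical stages"
            )
        blocks = []
        for biomarker in BIOMARKERS:
            for kind in DISTANCE_KINDS:
                for axis in CLINICAL_AXES:
                    blocks.append(stats.correlate_deviance_clinical(
                        deviance_tables[biomarker], clin_scores, axis=axis,
                        distance_kind=kind, biomarker=biomarker,
                        n_perm=config.n_perm, n_boot=config.n_boot,
                        alpha=config.alpha,
                        seed=config.substream(f"corr-{biomarker}-{kind}-{axis}"),
                    ))
        correlations = pd.concat(blocks, ignore_index=True)
        correlations.to_csv(out_dir / "correlations.csv", index=False)
        stages.append("correlate")

    manifest = {
        "stages": stages,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_correlations": 0 if correlations is None else int(len(correlations)),
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return {
        "features": {b: tables[b] for b in BIOMARKERS} if tables else {},
        "clinical": cpca,
        "clinical_scores": clin_scores,
        "deviance": deviance_tables,
        "correlations": correlations,
        "manifest": manifest,
    }
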