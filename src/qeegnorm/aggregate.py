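"""Collapse parcel x bin biomarker values into the 35-feature
(canonical band x functional network) representation.

Bins are grouped into the five canonical bands (sum for power, median
for DFA exponents); parcels are collapsed to the seven functional
networks by taking the median across a network's parcels within each
hemisphere and then averaging the two hemispheres.  The result is
5 bands x 7 networks = 35 features per biomarker per subject.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, BandScheme, make_band_scheme

#: The seven functional networks, in fixed order.
NETWORKS = ("DEF", "SOM", "SVA", "DA", "VIS", "LIM", "CON")

HEMISPHERES = ("L", "R")

#: Metadata columns of a feature matrix, in order, before the 35 features.
META_COLUMNS = ("subject", "cohort", "state", "age_years", "sex")


def feature_names() -> list[str]:
    """The 35 feature labels, band-major (e.g. ``alpha_DEF``)."""
    return [f"{band}_{net}" for band in CANONICAL_BANDS for net in NETWORKS]


def default_parcel_network_map() -> pd.DataFrame:
    """Packaged synthetic 100-parcel map with balanced network sizes.

    This is a stand-in mapping for pipelines without an atlas table; a
    real parcel-to-network table can be supplied as a CSV with the same
    columns (parcel_id, network, hemisphere).
    """
    with resources.files("qeegnorm.data").joinpath("parcel_network_map.csv").open() as f:
        return pd.read_csv(f)


def validate_parcel_map(pmap: pd.DataFrame) -> pd.DataFrame:
    """Check a parcel-network map: unique parcels, all 14 groups present."""
    required = {"parcel_id", "network", "hemisphere"}
    if not required.issubset(pmap.columns):
        raise ValueError(f"parcel map must have columns {sorted(required)}")
    if pmap["parcel_id"].duplicated().any():
        dupes = pmap.loc[pmap["parcel_id"].duplicated(), "parcel_id"].tolist()
        raise ValueError(f"parcels mapped more than once: {dupes}")
    for hemi in HEMISPHERES:
        present = set(pmap.loc[pmap["hemisphere"] == hemi, "network"])
        missing = set(NETWORKS) - present
        if missing:
            raise ValueError(
                f"networks {sorted(missing)} have zero parcels in hemisphere {hemi}"
            )
    return pmap


def bins_to_bands(
    values: np.ndarray,
    scheme: BandScheme | None = None,
    method: str = "sum",
    db: bool = False,
) -> np.ndarray:
    """Aggregate parcel x 11-bin values into parcel x 5 canonical bands.

    Parameters
    ----------
    values : array (n_parcels, 11)
    method : {"sum", "median"}
        "sum" for power biomarkers, "median" for DFA exponents.
    db : bool
        If True, ``values`` are powers on a dB scale: they are converted
        to linear power, summed, and converted back (summing dB values
        directly is not meaningful).
    """
    scheme = scheme or make_band_scheme()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != scheme.n_bins:
        raise ValueError(f"expected {scheme.n_bins} bins, got {values.shape[1]}")
    if method not in ("sum", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    out = np.empty((values.shape[0], len(CANONICAL_BANDS)))
    for j, band in enumerate(CANONICAL_BANDS):
        bins = list(scheme.groups[band])
        block = values[:, bins]
        if method == "median":
            out[:, j] = np.median(block, axis=1)
        elif db:
            out[:, j] = 10.0 * np.log10(np.sum(10.0 ** (block / 10.0), axis=1))
        else:
            out[:, j] = np.sum(block, axis=1)
    return out


def parcels_to_networks(values: np.ndarray, pmap: pd.DataFrame) -> pd.Series:
    """Collapse parcel x 5-band values to the 35-feature row.

    Median across a network's parcels per hemisphere, then the mean of
    the left and right hemisphere medians.  Row i of ``values`` belongs
    to row i of the map.
    """
    validate_parcel_map(pmap)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    pmap = pmap.reset_index(drop=True)
    if values.shape[0] != len(pmap):
        raise ValueError(
            f"{values.shape[0]} parcel rows but map covers {len(pmap)} parcels"
        )
    if values.shape[1] != len(CANONICAL_BANDS):
        raise ValueError(f"expected {len(CANONICAL_BANDS)} band columns")
    out = {}
    for j, band in enumerate(CANONICAL_BANDS):
        for net in NETWORKS:
            hemi_medians = []
            for hemi in HEMISPHERES:
                idx = (pmap["network"] == net) & (pmap["hemisphere"] == hemi)
                hemi_medians.append(np.median(values[idx.to_numpy(), j]))
            out[f"{band}_{net}"] = float(np.mean(hemi_medians))
    return pd.Series(out)[feature_names()]


def aggregate_biomarker(
    table: pd.DataFrame,
    biomarker: str,
    pmap: pd.DataFrame | None = None,
    scheme: BandScheme | None = None,
) -> pd.Series:
    """One subject's parcel x bin table -> 35-feature row.

    ``table`` is a long table with columns (parcel, bin, <value>), as
    produced by :func:`qeegnorm.bands.power_table` or
    :func:`qeegnorm.lrtc.dfa_table`.  ``biomarker`` selects the value
    column and aggregation:

    - ``absolute_power``: column ``absolute_db``, linear-domain sum
    - ``relative_power``: column ``relative_pct``, direct sum
    - ``lrtc``: column ``dfa_exponent``, median
    """
    spec = {
        "absolute_power": ("absolute_db", "sum", True),
        "relative_power": ("relative_pct", "sum", False),
        "lrtc": ("dfa_exponent", "median", False),
    }
    if biomarker not in spec:
        raise ValueError(f"unknown biomarker {biomarker!r}; expected {sorted(spec)}")
    column, method, db = spec[biomarker]
    pmap = default_parcel_network_map() if pmap is None else pmap
    wide = table.pivot(index="parcel", columns="bin", values=column).sort_index()
    bands = bins_to_bands(wide.to_numpy(), scheme, method=method, db=db)
    return parcels_to_networks(bands, pmap)


def build_feature_matrix(rows: list[pd.Series], metadata: pd.DataFrame) -> pd.DataFrame:
    """Stack per-subject 35-feature rows with their metadata columns."""
    features = pd.DataFrame(rows).reset_index(drop=True)
    meta = metadata.reset_index(drop=True)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    return pd.concat([meta[list(META_COLUMNS)], features], axis=1)


def split_features(fm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature matrix into (metadata, 35-feature block)."""
    names = feature_names()
    missing = set(names) - set(fm.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns {sorted(missing)[:5]}...")
    meta_cols = [c for c in fm.columns if c not in names]
    return fm[meta_cols], fm[names]
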