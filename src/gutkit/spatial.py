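"""Spatial statistics: great-circle distances, neighborhood weights,
Moran's I with an MCMC permutation null, and a Mantel correlogram.

Distance-decay analyses ask whether geographically close participants
harbor more similar communities.  Per-feature spatial autocorrelation
is measured with Moran's I under binary, row-standardized neighborhood
weight matrices (distance bands in km); significance comes from chains
of random transpositions started at independent random permutations,
with Bonferroni control across features.  Community-level distance
decay is assessed with Mantel tests restricted to pairs within a
neighborhood radius, over a ladder of radii, with Benjamini-Hochberg
adjustment across radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .io import GeoCoords
from .effects import bh_adjust

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_matrix",
    "SpatialWeights",
    "neighborhood_weights",
    "morans_i",
    "morans_i_test",
    "mantel_correlogram",
]

EARTH_RADIUS_KM = 6371.0

#: Per-feature Moran neighborhood bands (km), and Mantel radius ladder (km).
DEFAULT_BANDS = ((0.0, 50.0), (50.0, 100.0), (100.0, 250.0))
DEFAULT_RADII = (100.0, 500.0, 1000.0, 2500.0, 4500.0)


def great_circle_matrix(geo: GeoCoords) -> skbio.DistanceMatrix:
    """Haversine great-circle distances in km (spherical Earth)."""
    lat = np.radians(geo.latitude)
    lon = np.radians(geo.longitude)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return skbio.DistanceMatrix(d, ids=geo.sample_ids)


@dataclass
class SpatialWeights:
    """Binary (optionally row-standardized) neighborhood weights."""

    sample_ids: list[str]
    weights: np.ndarray
    radius_lo: float
    radius_hi: float
    standardized: bool
    isolated: list[str]

    @property
    def n_connected(self) -> int:
        return len(self.sample_ids) - len(self.isolated)


def neighborhood_weights(
    dm_km: skbio.DistanceMatrix,
    radius_lo: float,
    radius_hi: float,
    standardize: bool = True,
) -> SpatialWeights:
    """w_ij = 1 iff radius_lo <= d_ij < radius_hi (i != j).

    Rows with any neighbor sum to 1 after standardization; samples with
    no neighbor in the band are flagged isolated and excluded from
    Moran's I.
    """
    if radius_lo >= radius_hi:
        raise ValueError("radius_lo must be below radius_hi")
    d = dm_km.data
    w = ((d >= radius_lo) & (d < radius_hi)).astype(float)
    np.fill_diagonal(w, 0.0)
    row_sums = w.sum(axis=1)
    isolated = [sid for sid, s in zip(dm_km.ids, row_sums) if s == 0]
    if standardize:
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(row_sums[:, None] > 0, w / row_sums[:, None], 0.0)
    return SpatialWeights(
        list(dm_km.ids), w, radius_lo, radius_hi, standardize, isolated
    )


def _connected(values: np.ndarray, w: SpatialWeights):
    mask = np.array([sid not in set(w.isolated) for sid in w.sample_ids])
    return values[mask], w.weights[np.ix_(mask, mask)]


def morans_i(values, w: SpatialWeights) -> float:
    """Moran's I = (n/S0) sum_ij w_ij z_i z_j / sum_i z_i^2.

    Isolated samples are excluded.  Zero variance -> NaN.
    """
    values = np.asarray(values, dtype=float)
    z, ww = _connected(values, w)
    n = len(z)
    if n < 3:
        raise ValueError("need >= 3 non-isolated samples")
    z = z - z.mean()
    denom = (z**2).sum()
    if denom == 0:
        return np.nan
    s0 = ww.sum()
    return float((n / s0) * (z @ ww @ z) / denom)


def morans_i_test(
    values,
    w: SpatialWeights,
    chains: int = 100,
    iterations: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
) -> dict:
    """Permutation p-value for Moran's I via transposition chains.

    ``chains`` independent chains each start from a random permutation
    of the values over locations and take ``iterations`` random
    transposition steps, recording I after each step.  The pooled draws
    form the null; p = (1 + #{null >= observed}) / (1 + draws) for the
    one-sided 'greater' alternative (two-sided compares |I - E[I]| with
    E[I] = -1/(n-1)).
    """
    values = np.asarray(values, dtype=float)
    z0, ww = _connected(values, w)
    n = len(z0)
    if n < 3:
        raise ValueError("need >= 3 non-isolated samples")
    obs = morans_i(values, w)
    if np.isnan(obs):
        return {"I": np.nan, "p_value": np.nan, "null_mean": np.nan}
    rng = np.random.default_rng(seed)
    z = z0 - z0.mean()
    denom = (z**2).sum()
    s0 = ww.sum()
    scale = n / (s0 * denom)

    null = np.empty(chains * iterations)
    k = 0
    for _ in range(chains):
        perm = rng.permutation(n)
        zp = z[perm]
        wz = ww @ zp
        for _ in range(iterations):
            i, j = rng.integers(n), rng.integers(n)
            if i != j:
                zp[i], zp[j] = zp[j], zp[i]
                wz = ww @ zp  # n is small enough to recompute
            null[k] = scale * (zp @ wz)
            k += 1
    e_i = -1.0 / (n - 1)
    if alternative == "greater":
        count = int((null >= obs).sum())
    elif alternative == "two-sided":
        count = int((np.abs(null - e_i) >= abs(obs - e_i)).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    p = (1 + count) / (1 + null.size)
    return {
        "I": obs,
        "p_value": float(p),
        "null_mean": float(null.mean()),
        "null_std": float(null.std(ddof=1)),
        "expected_i": e_i,
        "draws": int(null.size),
    }


def morans_i_features(
    table,
    w: SpatialWeights,
    min_prevalence: int = 10,
    chains: int = 100,
    iterations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-feature Moran's I with Bonferroni control across features.

    Features present in fewer than ``min_prevalence`` samples are
    filtered (insufficient power).  Relative abundances are tested.
    """
    rng = np.random.default_rng(seed)
    rel = table.relative_abundance()
    prevalence = (table.counts > 0).sum(axis=0)
    keep = [
        f for f, p in zip(table.feature_ids, prevalence)
        if p >= min_prevalence
    ]
    rows = []
    for f in keep:
        res = morans_i_test(
            rel[f].to_numpy(), w, chains=chains, iterations=iterations,
            seed=int(rng.integers(2**31)),
        )
        rows.append((f, res["I"], res["p_value"]))
    df = pd.DataFrame(rows, columns=["feature", "I", "p_value"])
    m = len(df)
    df["significant"] = df["p_value"] <= (alpha / m if m else np.nan)
    return df


def _mantel_r_masked(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    xs, ys = x[mask], y[mask]
    if xs.size < 3:
        return np.nan
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    den = np.sqrt((xs**2).sum() * (ys**2).sum())
    if den == 0:
        return np.nan
    return float((xs * ys).sum() / den)


def mantel_correlogram(
    dm_community: skbio.DistanceMatrix,
    dm_km: skbio.DistanceMatrix,
    radii=DEFAULT_RADII,
    permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel tests over a ladder of neighborhood radii, BH adjusted.

    For each radius, the Mantel r is the Pearson correlation between
    community and geographic distances over the pairs whose geographic
    distance is below the radius (pairs beyond the radius are masked,
    not truncated); the null co-permutes rows and columns of one matrix.
    Radii with fewer than 3 usable pairs are reported with NaN.
    """
    if list(dm_community.ids) != list(dm_km.ids):
        dm_km = dm_km.filter(dm_community.ids)
    rng = np.random.default_rng(seed)
    n = len(dm_community.ids)
    iu = np.triu_indices(n, k=1)
    comm = dm_community.data
    km = dm_km.data
    km_flat = km[iu]
    rows = []
    for radius in radii:
        mask = km_flat < radius
        r_obs = _mantel_r_masked(comm[iu], km_flat, mask)
        if np.isnan(r_obs) or mask.sum() < 3:
            rows.append((radius, np.nan, np.nan, int(mask.sum())))
            continue
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            comm_p = comm[np.ix_(perm, perm)]
            r_null = _mantel_r_masked(comm_p[iu], km_flat, mask)
            if not np.isnan(r_null) and abs(r_null) >= abs(r_obs):
                count += 1
        p = (1 + count) / (1 + permutations)
        rows.append((radius, r_obs, float(p), int(mask.sum())))
    df = pd.DataFrame(rows, columns=["radius_km", "mantel_r", "p_value", "n_pairs"])
    ok = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p_value"].to_numpy())
    df["adjusted_p"] = adj
    return df
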