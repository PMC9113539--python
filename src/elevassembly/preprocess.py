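"""Sample filtering, count normalization, alpha diversity and design summaries."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import OtuTable, ValidationError
from .io import geodesic_distance

__all__ = [
    "filter_low_depth_samples",
    "normalize",
    "observed_richness",
    "rarefaction_curve",
    "summarize_design",
    "collapse_to_sites",
]


def filter_low_depth_samples(table: OtuTable, threshold="q1") -> OtuTable:
    """Drop samples whose library size is strictly below a threshold.

    ``threshold="q1"`` resolves to the first quartile of library sizes
    (linear-interpolation / type-7 quantile). The comparison is strict
    (<), so a sample sitting exactly at the quartile is kept — e.g. with
    a quartile of 18 reads, 18-read samples survive.
    """
    table.require_raw("depth filtering")
    sizes = table.library_sizes
    if threshold == "q1":
        threshold = float(np.percentile(sizes.to_numpy(), 25))
    keep = sizes[sizes >= threshold].index
    if len(keep) == 0:
        raise ValidationError(
            f"depth filter at {threshold} would remove every sample"
        )
    return table.subset_samples(keep)


def normalize(
    table: OtuTable, method: str = "css", css_quantile: float = 0.5
) -> OtuTable:
    """Normalize raw counts by total-sum (TSS) or cumulative-sum scaling (CSS).

    TSS divides each sample by its library size. CSS divides each sample
    by the cumulative count of its OTUs at or below the sample's
    ``css_quantile``-th quantile of nonzero counts, then rescales by the
    median of those scaling factors across samples, damping the influence
    of a few dominant OTUs on the scaling.
    """
    table.require_raw("normalization")
    x = table.counts
    sizes = table.library_sizes
    if (sizes <= 0).any():
        empty = sizes[sizes <= 0].index.tolist()
        raise ValidationError(f"cannot normalize zero-depth samples: {empty}")
    if method == "tss":
        out = x.div(sizes, axis=0)
        params = {}
    elif method == "css":
        factors = {}
        for s in x.index:
            row = x.loc[s].to_numpy(dtype=float)
            nonzero = row[row > 0]
            q = np.quantile(nonzero, css_quantile)  # type-7 interpolation
            factors[s] = row[row <= q].sum()
        sf = pd.Series(factors)
        if (sf <= 0).any():
            raise ValidationError("CSS scaling factor of 0; raise css_quantile")
        scale = float(sf.median())
        out = x.div(sf, axis=0) * scale
        params = {"css_quantile": css_quantile, "median_scaling_factor": scale}
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return OtuTable(out, normalized=True, norm_method=method, norm_params=params)


def observed_richness(table: OtuTable) -> pd.Series:
    """Number of OTUs observed (count > 0) per sample. Raw counts only."""
    table.require_raw("richness")
    return (table.counts > 0).sum(axis=1).rename("observed_otus")


def _expected_richness_analytic(row: np.ndarray, depth: int) -> float:
    """E[# OTUs seen] in a without-replacement subsample of ``depth`` reads.

    Hypergeometric closed form: E[S_d] = Σ_i [1 − C(N−n_i, d) / C(N, d)].
    """
    N = int(row.sum())
    n = row[row > 0].astype(int)

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    miss = np.where(
        N - n >= depth,
        np.exp(logC(N - n, depth) - logC(N, depth)),
        0.0,
    )
    return float(len(n) - miss.sum())


def rarefaction_curve(
    table: OtuTable,
    depths,
    n_reps: int = 50,
    seed=None,
    method: str = "analytic",
) -> pd.DataFrame:
    """Expected OTU richness at each rarefaction depth, per sample.

    ``method="analytic"`` uses the exact hypergeometric expectation;
    ``"montecarlo"`` averages over ``n_reps`` subsamples drawn without
    replacement. Depths exceeding a sample's library size yield NaN.
    Returns a samples × depths frame.
    """
    table.require_raw("rarefaction")
    rng = np.random.default_rng(seed)
    depths = [int(d) for d in depths]
    out = pd.DataFrame(index=table.sample_ids, columns=depths, dtype=float)
    for s in table.sample_ids:
        row = table.counts.loc[s].to_numpy()
        N = int(row.sum())
        reads = np.repeat(np.arange(len(row)), row.astype(int))
        for d in depths:
            if d > N:
                out.loc[s, d] = np.nan
            elif method == "analytic":
                out.loc[s, d] = _expected_richness_analytic(row, d)
            elif method == "montecarlo":
                vals = [
                    len(np.unique(rng.choice(reads, size=d, replace=False)))
                    for _ in range(n_reps)
                ]
                out.loc[s, d] = float(np.mean(vals))
            else:
                raise ValueError(f"unknown rarefaction method {method!r}")
    return out


def collapse_to_sites(metadata: pd.DataFrame, site_col: str = "site") -> pd.DataFrame:
    """Collapse per-sample metadata to one record per site.

    Uses the ``site`` column when present; otherwise the part of the
    sample id before a ``_R<digits>`` replicate suffix (samples without
    the suffix are their own sites).
    """
    meta = metadata.copy()
    if site_col not in meta.columns:
        meta[site_col] = meta.index.str.replace(r"_R\d+$", "", regex=True)
    keep = [
        c
        for c in ("elevation", "latitude", "longitude", "group")
        if c in meta.columns
    ]
    return meta.groupby(site_col)[keep].first()


def summarize_design(metadata: pd.DataFrame, site_col: str = "site") -> dict:
    """Mean/max pairwise elevation change and mean geodesic distance between sites.

    Replicates are collapsed to unique sites first; averages run over all
    unordered site pairs. Geodesic distance is reported only when both
    coordinates are present for every site.
    """
    sites = collapse_to_sites(metadata, site_col)
    if len(sites) < 2:
        raise ValidationError("design summary needs at least 2 sites")
    elev = sites["elevation"].to_numpy(dtype=float)
    pairs = list(itertools.combinations(range(len(sites)), 2))
    dz = [abs(elev[i] - elev[j]) for i, j in pairs]
    out = {
        "n_sites": len(sites),
        "mean_pairwise_elevation_difference_m": float(np.mean(dz)),
        "max_pairwise_elevation_difference_m": float(np.max(dz)),
    }
    if {"latitude", "longitude"} <= set(sites.columns):
        lat = sites["latitude"].to_numpy(dtype=float)
        lon = sites["longitude"].to_numpy(dtype=float)
        if np.isfinite(lat).all() and np.isfinite(lon).all():
            dg = [
                geodesic_distance(lat[i], lon[i], lat[j], lon[j])
                for i, j in pairs
            ]
            out["mean_pairwise_geodesic_distance_m"] = float(np.mean(dg))
    return out
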