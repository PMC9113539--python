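"""Beta diversity: pairwise dissimilarities, their decomposition, and
matrix-correlation inference (ANOSIM, Mantel family, distance-decay).

Dissimilarity metrics follow the presence/abundance conventions standard
in community ecology:

* Bray–Curtis on (raw or normalized) abundances;
* Sørensen dissimilarity partitioned into its turnover (Simpson, βsim)
  and nestedness (βsne) components, with βsor = βsim + βsne entrywise;
* unweighted UniFrac on a rooted phylogeny (fraction of branch length
  unique to either community).

Inference uses permutation tests with "add-one" p-value estimators,
(1 + #extreme) / (1 + n_permutations), so p is never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import mantel as _skbio_mantel
from statsmodels.stats.multitest import multipletests

from .datatypes import OtuTable, ValidationError, as_distance_matrix
from .io import geodesic_distance

__all__ = [
    "BetaPartition",
    "MantelResult",
    "bray_curtis",
    "sorensen_partition",
    "unweighted_unifrac",
    "anosim",
    "mantel",
    "partial_mantel",
    "mantel_correlogram",
    "env_distance_matrix",
    "geodesic_matrix",
]


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between all sample pairs.

    BC(j,k) = Σ|x_j − x_k| / Σ(x_j + x_k). Undefined (error) when two
    all-zero samples meet.
    """
    x = table.values
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValidationError(
            f"Bray–Curtis undefined between all-zero samples: {bad}"
        )
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        bc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return as_distance_matrix(bc, table.sample_ids, "braycurtis")


@dataclass
class BetaPartition:
    """Sørensen dissimilarity split into turnover and nestedness parts."""

    total: DistanceMatrix  # βsor
    turnover: DistanceMatrix  # βsim
    nestedness: DistanceMatrix  # βsne

    @property
    def turnover_percent(self) -> float:
        """mean(βsim) / mean(βsor) × 100 across all pairs."""
        return float(
            self.turnover.condensed_form().mean()
            / self.total.condensed_form().mean()
            * 100.0
        )

    @property
    def nestedness_percent(self) -> float:
        return 100.0 - self.turnover_percent


def sorensen_partition(table: OtuTable) -> BetaPartition:
    """Partition Sørensen dissimilarity into turnover and nestedness.

    With a shared species, b and c unique to either sample:
    βsor = (b+c)/(2a+b+c); βsim = min(b,c)/(a+min(b,c)); βsne = βsor − βsim.
    Turnover reflects species replacement; nestedness reflects richness
    differences between nested communities.
    """
    pres = table.presence().to_numpy()
    if (~pres.any(axis=1)).any():
        empty = [
            s for s, ok in zip(table.sample_ids, pres.any(axis=1)) if not ok
        ]
        raise ValidationError(f"empty samples have no Sørensen value: {empty}")
    a = (pres[:, None, :] & pres[None, :, :]).sum(axis=2).astype(float)
    only_j = (pres[:, None, :] & ~pres[None, :, :]).sum(axis=2).astype(float)
    b = only_j
    c = only_j.T
    minbc = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        bsor = (b + c) / (2 * a + b + c)
        bsim = np.where(a + minbc > 0, minbc / (a + minbc), 0.0)
    np.fill_diagonal(bsor, 0.0)
    np.fill_diagonal(bsim, 0.0)
    bsne = bsor - bsim
    ids = table.sample_ids
    return BetaPartition(
        total=as_distance_matrix(bsor, ids, "sorensen"),
        turnover=as_distance_matrix(bsim, ids, "simpson_turnover"),
        nestedness=as_distance_matrix(bsne, ids, "nestedness"),
    )


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac distance between all sample pairs.

    Fraction of the branch length (on paths leading to taxa present in
    either sample) that leads exclusively to taxa of one sample. Requires
    a rooted tree — midpoint-root unrooted input upstream.
    """
    if len(tree.children) > 2:
        raise ValidationError(
            "unweighted UniFrac needs a rooted tree (root has "
            f"{len(tree.children)} children); midpoint-root it first"
        )
    pres = table.presence().to_numpy().astype(int)
    return _skbio_beta(
        "unweighted_unifrac",
        pres,
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
    )


def anosim(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None) -> dict:
    """Analysis of similarities: R statistic and one-sided permutation p.

    R compares mean between- vs within-group midranks of all pairwise
    distances, scaled to [−1, 1]; p is the add-one fraction of label
    permutations with R at least as large.
    """
    groups = pd.Series(groups)
    if groups.nunique() < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if (groups.value_counts() < 1).any():
        raise ValidationError("every ANOSIM group needs at least 1 member")
    grouping = groups.loc[list(dm.ids)].to_numpy()
    res = _skbio_anosim(dm, grouping, permutations=n_perm, seed=seed)
    return {
        "R": float(res["test statistic"]),
        "p": float(res["p-value"]),
        "n_permutations": n_perm,
    }


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    tail: str
    method: str = "pearson"


def _check_conformable(*dms: DistanceMatrix) -> None:
    ids = dms[0].ids
    for dm in dms[1:]:
        if dm.ids != ids:
            raise ValidationError("distance matrices have different labels/order")


def mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    n_perm: int = 999,
    seed=None,
    method: str = "pearson",
    tail: str = "two-sided",
) -> MantelResult:
    """Mantel test: correlation of two distance matrices with permutation p.

    Permutations jointly shuffle rows and columns of the second matrix.
    Two-sided by default since distance–environment correlations can run
    either way.
    """
    _check_conformable(dmA, dmB)
    r, p, _ = _skbio_mantel(
        dmA, dmB, method=method, permutations=n_perm, alternative=tail, seed=seed
    )
    return MantelResult(float(r), float(p), n_perm, tail, method)


def _upper(dm: DistanceMatrix) -> np.ndarray:
    return dm.condensed_form()


def partial_mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    dmC: DistanceMatrix,
    n_perm: int = 999,
    seed=None,
    tail: str = "two-sided",
) -> MantelResult:
    """Partial Mantel test of A–B correlation controlling for C.

    The statistic is the partial correlation
    r_AB·C = (r_AB − r_AC·r_BC) / √((1−r_AC²)(1−r_BC²)) over the
    upper-triangle vectors; p comes from jointly permuting rows and
    columns of B and recomputing the partial correlation.
    """
    _check_conformable(dmA, dmB, dmC)
    a, b, c = _upper(dmA), _upper(dmB), _upper(dmC)
    if np.std(c) == 0:
        raise ValidationError(
            "control matrix is constant; use a plain Mantel test"
        )
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("constant distance matrix in partial Mantel")
    r_ac_check = np.corrcoef(a, c)[0, 1]
    if 1 - r_ac_check**2 < 1e-12:
        raise ValidationError(
            "control matrix is collinear with the first matrix; the "
            "partial correlation is undefined"
        )

    def _partial(bvec: np.ndarray) -> float:
        r_ab = np.corrcoef(a, bvec)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(bvec, c)[0, 1]
        den = math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        return (r_ab - r_ac * r_bc) / den if den > 0 else np.nan

    obs = _partial(b)
    rng = np.random.default_rng(seed)
    n = dmB.shape[0]
    B = dmB.data
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        rp = _partial(bp)
        if tail == "two-sided":
            exceed += abs(rp) >= abs(obs) - 1e-12
        elif tail == "greater":
            exceed += rp >= obs - 1e-12
        else:
            exceed += rp <= obs + 1e-12
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(float(obs), float(p), n_perm, tail)


def sturges_classes(n_pairs: int) -> int:
    """Sturges' rule for the number of distance classes: ⌈log2(n)+1⌉."""
    return int(math.ceil(math.log2(n_pairs) + 1))


def mantel_correlogram(
    dm_community: DistanceMatrix,
    dm_space: DistanceMatrix,
    n_classes="sturges",
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Multivariate Mantel correlogram (distance-decay by distance class).

    Spatial distances are binned into equal-width classes; per class, the
    statistic is the negated Pearson correlation between the community
    distances and the class-membership indicator, so positive values at
    short range mean nearby communities are more similar. Two-sided
    permutation p-values (joint row/column shuffles of the community
    matrix) are Holm-corrected across classes. Classes holding fewer than
    two pairs are reported with missing statistics.
    """
    _check_conformable(dm_community, dm_space)
    comm = _upper(dm_community)
    space = _upper(dm_space)
    n_pairs = len(space)
    if n_classes == "sturges":
        n_classes = sturges_classes(n_pairs)
    edges = np.linspace(space.min(), space.max(), n_classes + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    which = np.digitize(space, edges) - 1
    n = dm_community.shape[0]
    iu = np.triu_indices(n, k=1)
    C = dm_community.data
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    rows = []
    comm_sd = np.std(comm)
    for cls in range(n_classes):
        member = (which == cls).astype(float)
        mid = (edges[cls] + min(edges[cls + 1], space.max())) / 2.0
        n_in = int(member.sum())
        if n_in < 2 or member.std() == 0:
            rows.append({"class": cls, "midpoint": mid, "n_pairs": n_in,
                         "r": np.nan, "p": np.nan})
            continue
        if comm_sd == 0:
            # no community variation at all: zero correlation by definition
            rows.append({"class": cls, "midpoint": mid, "n_pairs": n_in,
                         "r": 0.0, "p": 1.0})
            continue
        obs = -np.corrcoef(comm, member)[0, 1]
        exceed = 0
        for perm in perms:
            cp = C[np.ix_(perm, perm)][iu]
            if np.std(cp) == 0:
                rp = 0.0
            else:
                rp = -np.corrcoef(cp, member)[0, 1]
            exceed += abs(rp) >= abs(obs) - 1e-12
        p = (1 + exceed) / (1 + n_perm)
        rows.append({"class": cls, "midpoint": mid, "n_pairs": n_in,
                     "r": float(obs), "p": float(p)})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "p_holm"] = multipletests(
            out.loc[tested, "p"], method="holm"
        )[1]
    else:
        out["p_holm"] = np.nan
    return out


def env_distance_matrix(values: pd.Series, name: str = "env") -> DistanceMatrix:
    """Absolute-difference distance matrix for one environmental variable.

    Samples with missing values are dropped (e.g. pH recorded as NA), so
    the matrix may cover a subset of samples. Replicates at one station
    legitimately sit at distance 0 and are kept.
    """
    v = pd.to_numeric(values).dropna()
    if len(v) < 2:
        raise ValidationError(f"need >= 2 samples with {name} values")
    arr = v.to_numpy(dtype=float)
    return as_distance_matrix(
        np.abs(arr[:, None] - arr[None, :]), v.index, name
    )


def geodesic_matrix(metadata: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (m) between sample coordinates."""
    sub = metadata[["latitude", "longitude"]].dropna()
    if len(sub) < 2:
        raise ValidationError("need >= 2 samples with coordinates")
    n = len(sub)
    out = np.zeros((n, n))
    lat = sub["latitude"].to_numpy(dtype=float)
    lon = sub["longitude"].to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_distance(lat[i], lon[i], lat[j], lon[j])
            out[i, j] = out[j, i] = d
    return as_distance_matrix(out, sub.index, "geodesic")
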