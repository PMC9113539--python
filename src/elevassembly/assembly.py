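"""Null-model partitioning of community assembly processes.

Implements the two-stage null-model framework used to apportion pairwise
community turnover among ecological processes:

1. **βNTI** — the standardized effect size of between-community mean
   nearest-taxon distance (βMNTD) against a null built by shuffling tip
   labels across the whole phylogeny. |βNTI| > 2 indicates selection
   (phylogenetic turnover more (+) or less (−) than chance).
2. **RC-Bray** — a Raup–Crick test on Bray–Curtis dissimilarity under a
   null that preserves each sample's richness and library size while
   drawing species with probability proportional to occupancy and
   allocating individuals proportionally to regional relative abundance.
   RC is rescaled to [−1, 1]; |RC| > 0.95 indicates dispersal effects.

Pairs are then classified as variable selection (βNTI > +2), homogeneous
selection (βNTI < −2), dispersal limitation acting with drift
(|βNTI| ≤ 2, RC > +0.95), homogenizing dispersal (|βNTI| ≤ 2,
RC < −0.95), or drift alone (neither signal extreme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .datatypes import OtuTable, ValidationError, as_distance_matrix

__all__ = [
    "PROCESSES",
    "assign_zones",
    "pairwise_bmntd",
    "bnti",
    "null_communities",
    "raup_crick_bray",
    "rc_score",
    "classify_processes",
    "zone_summary",
    "AssemblyResult",
    "assembly_analysis",
]

#: canonical process labels, in reporting order
PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation_drift",
    "homogenizing_dispersal",
    "drift",
)


def assign_zones(
    elevations: pd.Series, high: float = 1000.0, low: float = 500.0
) -> pd.Series:
    """Map sample elevations to High / Middle / Low zones.

    High means strictly above ``high`` (default 1,000 m), Low strictly
    below ``low`` (default 500 m); boundary values fall in Middle.
    """
    elev = pd.to_numeric(elevations)
    zone = pd.Series("Middle", index=elev.index, dtype=object)
    zone[elev > high] = "High"
    zone[elev < low] = "Low"
    return zone


def _relative_abundance(table: OtuTable, weighted: bool) -> tuple[np.ndarray, list]:
    x = table.values
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValidationError(f"samples with zero total abundance: {empty}")
    if weighted:
        f = x / totals[:, None]
    else:
        pres = (x > 0).astype(float)
        f = pres / pres.sum(axis=1)[:, None]
    masks = [np.flatnonzero(x[k] > 0) for k in range(x.shape[0])]
    return f, masks


def _patristic(tree: TreeNode, otu_ids) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    order = [dm.index(o) for o in otu_ids]
    return dm.data[np.ix_(order, order)]


def _bmntd_from(D: np.ndarray, f: np.ndarray, masks) -> np.ndarray:
    """βMNTD for all sample pairs given a patristic matrix and weights."""
    n = f.shape[0]
    m = np.empty((n, D.shape[0]))
    for k in range(n):
        m[k] = D[:, masks[k]].min(axis=1)
    term = f @ m.T  # term[j, k] = sum_i f[j, i] * min-dist of i into sample k
    out = 0.5 * (term + term.T)
    np.fill_diagonal(out, 0.0)
    return out


def pairwise_bmntd(
    table: OtuTable,
    tree: TreeNode,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Between-community mean nearest-taxon distance (βMNTD).

    βMNTD(j, k) averages, over the taxa of each community (weighted by
    relative abundance, or equally when unweighted), the patristic
    distance to the nearest taxon of the other community.
    """
    f, masks = _relative_abundance(table, abundance_weighted)
    D = _patristic(tree, table.otu_ids)
    return as_distance_matrix(_bmntd_from(D, f, masks), table.sample_ids, "bMNTD")


def bnti(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed=None,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """β-nearest-taxon index: standardized βMNTD against a tip-shuffle null.

    The null shuffles taxon labels across the entire phylogeny (the
    standard choice in this framework), recomputing βMNTD for every pair
    per randomization; βNTI = (observed − null mean) / null s.d.
    Degenerate pairs (null s.d. 0) are reported as NaN with a warning.

    Notes
    -----
    A tip-label shuffle is equivalent to jointly permuting the rows and
    columns of the patristic matrix, so the tree is only traversed once.
    """
    if len(table.otu_ids) < 3:
        raise ValidationError("βNTI needs at least 3 taxa to shuffle")
    rng = np.random.default_rng(seed)
    f, masks = _relative_abundance(table, abundance_weighted)
    D = _patristic(tree, table.otu_ids)
    obs = _bmntd_from(D, f, masks)
    n_otus = D.shape[0]
    s1 = np.zeros_like(obs)
    s2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_otus)
        null = _bmntd_from(D[np.ix_(perm, perm)], f, masks)
        s1 += null
        s2 += null**2
    mean = s1 / n_null
    var = (s2 - n_null * mean**2) / (n_null - 1)
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    degenerate = (sd <= 0) & ~np.eye(len(z), dtype=bool)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum() // 2)} sample pairs have a degenerate "
            "βMNTD null (s.d. = 0); βNTI reported as NaN"
        )
        z[degenerate] = np.nan
    # NaNs break DistanceMatrix validation; keep a raw frame instead
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def rc_score(n_less: int, n_ties: int, n_null: int) -> float:
    """Rescaled Raup–Crick score from null comparison counts.

    ((#null < obs) + ½·(#null = obs)) / n_null, mapped onto [−1, 1]:
    +1 when every null dissimilarity falls below the observed one, −1
    when every null exceeds it.
    """
    frac = (n_less + 0.5 * n_ties) / n_null
    return (frac - 0.5) * 2.0


def null_communities(
    table: OtuTable,
    n_null: int = 999,
    seed=None,
) -> np.ndarray:
    """Draw Raup–Crick null realizations of every sample.

    Each realization preserves the sample's observed richness and total
    count: species are selected without replacement with probability
    proportional to their occupancy across samples, receive one
    individual each, and the remaining individuals are allocated
    multinomially in proportion to regional relative abundance.
    Returns an array of shape (n_null, n_samples, n_otus).
    """
    table.require_raw("Raup–Crick null draws")
    x = table.values
    n_samples, n_otus = x.shape
    counts_int = np.rint(x).astype(np.int64)
    if not np.allclose(x, counts_int):
        raise ValidationError("Raup–Crick requires integer counts")
    rng = np.random.default_rng(seed)

    occupancy = (counts_int > 0).sum(axis=0).astype(float)
    pool = counts_int.sum(axis=0).astype(float)
    occurring = occupancy > 0
    richness = (counts_int > 0).sum(axis=1)
    depth = counts_int.sum(axis=1)
    if (depth <= 0).any():
        raise ValidationError("samples with zero total abundance")
    if (richness > occurring.sum()).any():
        raise ValidationError("a sample is richer than the regional pool")
    q = pool / pool.sum()
    idx_all = np.flatnonzero(occurring)
    p_sub = occupancy[idx_all] / occupancy[idx_all].sum()

    nulls = np.zeros((n_null, n_samples, n_otus), dtype=np.float64)
    for s in range(n_samples):
        S, N = int(richness[s]), int(depth[s])
        for r in range(n_null):
            chosen = idx_all[
                rng.choice(len(idx_all), size=S, replace=False, p=p_sub)
            ]
            qc = q[chosen]
            alloc = np.ones(S, dtype=np.int64)
            if N > S:
                if qc.sum() <= 0:
                    qc = np.ones(S)
                alloc += rng.multinomial(N - S, qc / qc.sum())
            nulls[r, s, chosen] = alloc
    return nulls


def raup_crick_bray(
    table: OtuTable,
    n_null: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Raup–Crick metric on Bray–Curtis, rescaled to [−1, 1].

    For each pair, null communities preserve each sample's observed
    richness and total count: species are drawn without replacement with
    probability proportional to their occupancy across samples, receive
    one individual each, and the remaining individuals are allocated
    multinomially in proportion to regional relative abundance. RC is the
    fraction of null Bray–Curtis values below the observed one (ties at
    half weight), rescaled as (RC − 0.5)·2. RC → +1 means communities are
    more different than the null expects (dispersal limitation), −1 less
    different (homogenizing dispersal).
    """
    x = table.values
    n_samples, n_otus = x.shape
    if n_samples < 2:
        raise ValidationError("Raup–Crick needs at least 2 samples")
    counts_int = np.rint(x).astype(np.int64)
    depth = counts_int.sum(axis=1)

    # one set of null realizations per sample, paired up across pairs
    nulls = null_communities(table, n_null=n_null, seed=seed)

    obs_bc = np.zeros((n_samples, n_samples))
    rc = np.zeros((n_samples, n_samples))
    eps = 1e-12
    for j in range(n_samples):
        for k in range(j + 1, n_samples):
            denom = depth[j] + depth[k]
            obs = np.abs(counts_int[j] - counts_int[k]).sum() / denom
            null_bc = np.abs(nulls[:, j, :] - nulls[:, k, :]).sum(axis=1) / denom
            less = int((null_bc < obs - eps).sum())
            ties = int((np.abs(null_bc - obs) <= eps).sum())
            val = rc_score(less, ties, n_null)
            obs_bc[j, k] = obs_bc[k, j] = obs
            rc[j, k] = rc[k, j] = val
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


def classify_processes(
    bnti_dm,
    rc_dm,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Label every sample pair with its inferred assembly process.

    Returns a long-format frame with one row per unordered pair:
    columns ``sample_a``, ``sample_b``, ``bnti``, ``rc``, ``process``.
    Pairs with missing βNTI get process ``"missing"`` and are excluded
    from downstream fractions.
    """
    b = _as_frame(bnti_dm)
    r = _as_frame(rc_dm)
    if list(b.index) != list(r.index):
        raise ValidationError("βNTI and RC matrices have different samples")
    ids = list(b.index)
    rows = []
    n_missing = 0
    for j in range(len(ids)):
        for k in range(j + 1, len(ids)):
            bv = b.iat[j, k]
            rv = r.iat[j, k]
            if np.isnan(bv):
                proc = "missing"
                n_missing += 1
            elif bv > bnti_threshold:
                proc = "variable_selection"
            elif bv < -bnti_threshold:
                proc = "homogeneous_selection"
            elif not np.isnan(rv) and rv > rc_threshold:
                proc = "dispersal_limitation_drift"
            elif not np.isnan(rv) and rv < -rc_threshold:
                proc = "homogenizing_dispersal"
            else:
                proc = "drift"
            rows.append((ids[j], ids[k], bv, rv, proc))
    if n_missing:
        warnings.warn(f"{n_missing} pairs lacked βNTI and were labeled missing")
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bnti", "rc", "process"]
    )


def zone_summary(classification: pd.DataFrame, zones: pd.Series) -> pd.DataFrame:
    """Per zone-pair fractions of sample pairs assigned to each process.

    ``zones`` maps sample id → zone label. Rows are unordered zone pairs
    (within-zone included); columns are the five process labels plus
    ``n_pairs``; each fraction row sums to 1 over the processes.
    """
    cls = classification[classification["process"] != "missing"]
    counted = {}
    for _, row in cls.iterrows():
        za, zb = zones.get(row["sample_a"]), zones.get(row["sample_b"])
        if za is None or zb is None:
            continue
        key = tuple(sorted((za, zb)))
        counted.setdefault(key, []).append(row["process"])
    out = []
    for key in sorted(counted):
        procs = counted[key]
        n = len(procs)
        fracs = {p: procs.count(p) / n for p in PROCESSES}
        out.append({"zone_a": key[0], "zone_b": key[1], "n_pairs": n, **fracs})
    return pd.DataFrame(out)


@dataclass
class AssemblyResult:
    """Bundle of the full assembly-process analysis for one dataset."""

    bnti: pd.DataFrame
    rc: pd.DataFrame
    classification: pd.DataFrame
    fractions: pd.DataFrame
    zones: pd.Series


def assembly_analysis(
    table_raw: OtuTable,
    tree: TreeNode,
    elevations: pd.Series,
    table_for_bnti: OtuTable | None = None,
    n_null: int = 999,
    seed=None,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
    zone_high: float = 1000.0,
    zone_low: float = 500.0,
) -> AssemblyResult:
    """Run βNTI + RC-Bray, classify pairs, and summarize by elevation zone.

    βMNTD/βNTI use ``table_for_bnti`` when given (e.g. a CSS-normalized
    table); the Raup–Crick null always runs on the raw counts.
    """
    seeds = np.random.SeedSequence(seed).spawn(2)
    b = bnti(table_for_bnti or table_raw, tree, n_null=n_null, seed=seeds[0])
    r = raup_crick_bray(table_raw, n_null=n_null, seed=seeds[1])
    cls = classify_processes(b, r, bnti_threshold, rc_threshold)
    zones = assign_zones(elevations.loc[table_raw.sample_ids], zone_high, zone_low)
    frac = zone_summary(cls, zones)
    return AssemblyResult(b, r, cls, frac, zones)


def _as_frame(dm) -> pd.DataFrame:
    if isinstance(dm, DistanceMatrix):
        return dm.to_data_frame()
    return pd.DataFrame(dm)
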