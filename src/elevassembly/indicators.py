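"""Indicator species analysis and phylogenetic signal of habitat preference.

Covers the question "which OTUs mark an elevation zone, and is that
preference phylogenetically conserved?":

* IndVal indicator analysis (specificity × fidelity with a label-
  permutation test) per elevation zone;
* preferred elevation — the abundance-weighted mean elevation of the
  sites where an OTU is detected;
* patristic distances, bootstrap tests of whether indicator sets are
  phylogenetically clustered, clade-divergence permutation tests, and
  root-to-tip contrasts between preference groups;
* a shared-OTU abundance test (are regionally shared OTUs the abundant
  ones?) and Cohen's d effect sizes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .datatypes import OtuTable, ValidationError

__all__ = [
    "indval",
    "preferred_elevation",
    "patristic_matrix",
    "BootstrapNull",
    "bootstrap_pd_null",
    "clade_divergence_test",
    "root_to_tip",
    "shared_otu_abundance_test",
    "cohens_d",
]


def indval(
    table: OtuTable,
    groups,
    n_perm: int = 999,
    seed=None,
    alpha: float = 0.05,
    allow_raw: bool = False,
) -> pd.DataFrame:
    """IndVal indicator analysis of each OTU against sample groups.

    Per OTU and group: specificity A = mean abundance in the group over
    the sum of group mean abundances; fidelity B = fraction of the
    group's samples containing the OTU; IndVal = √(A·B). Each OTU is
    assigned its best (argmax) group; significance comes from permuting
    sample group labels and comparing the permuted maximum IndVal to the
    observed one (add-one estimator).

    IndVal is *not* invariant to per-sample rescaling (A depends on
    relative library sizes), so a normalized table is required unless
    ``allow_raw=True``.
    """
    if not table.normalized and not allow_raw:
        raise ValidationError(
            "IndVal specificity is sensitive to library size; normalize "
            "first (or pass allow_raw=True)"
        )
    groups = pd.Series(groups).loc[table.sample_ids]
    counts_by_group = groups.value_counts()
    if len(counts_by_group) < 2:
        raise ValidationError("IndVal needs at least 2 groups")
    x = table.values
    labels = groups.to_numpy()
    uniq = np.array(sorted(set(labels)))

    def stat(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        means = np.vstack([x[lab == g].mean(axis=0) for g in uniq])
        pres = np.vstack([(x[lab == g] > 0).mean(axis=0) for g in uniq])
        tot = means.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
        iv = np.sqrt(A * pres)
        return iv, A

    iv_obs, A_obs = stat(labels)
    best = iv_obs.argmax(axis=0)
    obs_max = iv_obs.max(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    for _ in range(n_perm):
        perm_iv, _ = stat(rng.permutation(labels))
        exceed += perm_iv.max(axis=0) >= obs_max - 1e-12
    p = (1 + exceed) / (1 + n_perm)

    j = np.arange(x.shape[1])
    B_obs = np.vstack(
        [(x[labels == g] > 0).mean(axis=0) for g in uniq]
    )
    out = pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "group": uniq[best],
            "A": A_obs[best, j],
            "B": B_obs[best, j],
            "indval": obs_max,
            "p": p,
        }
    )
    out["significant"] = out["p"] <= alpha
    return out.set_index("otu_id")


def preferred_elevation(table: OtuTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean elevation of samples where each OTU occurs.

    PE_i = Σ_s n_is·e_s / Σ_s n_is over the samples with n_is > 0 — so PE
    always lies between the lowest and highest elevation of detection.
    OTUs absent everywhere get a missing PE with a warning.
    """
    elev = pd.to_numeric(metadata.loc[table.sample_ids, "elevation"]).to_numpy()
    x = table.values
    totals = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pe = (x * elev[:, None]).sum(axis=0) / totals
    absent = totals == 0
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} OTUs detected nowhere; PE reported missing"
        )
        pe = np.where(absent, np.nan, pe)
    n_detect = (x > 0).sum(axis=0)
    return pd.DataFrame(
        {
            "preferred_elevation": pe,
            "n_samples_detected": n_detect,
            "total_abundance": totals,
        },
        index=pd.Index(table.otu_ids, name="otu_id"),
    )


def patristic_matrix(tree: TreeNode, otu_ids=None) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths on the path)."""
    if otu_ids is None:
        return tree.tip_tip_distances()
    return tree.tip_tip_distances(endpoints=list(otu_ids))


@dataclass
class BootstrapNull:
    """Observed statistic vs a bootstrap null of random distance draws."""

    observed: float
    null: np.ndarray = field(repr=False)
    ci_low: float = 0.0
    ci_high: float = 0.0
    p_lower: float = 1.0  # P(null <= observed): small => clustered
    t_statistic: float = np.nan
    t_p: float = np.nan
    statistic: str = "mean"


def bootstrap_pd_null(
    indicator_ids,
    community_ids,
    tree: TreeNode,
    n_boot: int = 1000,
    seed=None,
    statistic: str = "mean",
) -> BootstrapNull:
    """Are the indicator OTUs phylogenetically clustered within the community?

    The observed statistic (mean by default) summarizes all pairwise
    patristic distances among the indicators. Each bootstrap draw samples,
    with replacement, the same number of distances from the community-wide
    pairwise-distance pool and records the statistic, giving a sampling
    distribution of set-level means; the 95% interval is its 2.5/97.5
    percentiles and ``p_lower`` is the add-one fraction of draws at or
    below the observed value ("more similar than chance"). A plain
    two-sample t comparison of indicator vs pool distances is also
    reported.
    """
    indicator_ids = list(indicator_ids)
    community_ids = list(community_ids)
    if len(indicator_ids) < 2:
        raise ValidationError("need at least 2 indicator OTUs")
    if not set(indicator_ids) <= set(community_ids):
        raise ValidationError("indicator ids must be a subset of community ids")
    stat_fn = {"mean": np.mean, "median": np.median}[statistic]
    dm = patristic_matrix(tree, community_ids)
    pool = dm.condensed_form()
    sub = dm.filter(indicator_ids)
    obs_dists = sub.condensed_form()
    observed = float(stat_fn(obs_dists))
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_boot, len(obs_dists)), replace=True)
    null = np.apply_along_axis(stat_fn, 1, draws)
    lo, hi = np.percentile(null, [2.5, 97.5])
    p_lower = (1 + (null <= observed + 1e-12).sum()) / (1 + n_boot)
    t_stat, t_p = stats.ttest_ind(obs_dists, pool, equal_var=False)
    return BootstrapNull(
        observed=observed,
        null=null,
        ci_low=float(lo),
        ci_high=float(hi),
        p_lower=float(p_lower),
        t_statistic=float(t_stat),
        t_p=float(t_p),
        statistic=statistic,
    )


def _maximal_labeled_clades(tree: TreeNode, labeled: set) -> list[list[str]]:
    """Maximal monophyletic tip sets containing only labeled tips."""
    clades = []

    def collect(node):
        if node.is_tip():
            if node.name in labeled:
                clades.append([node.name])
            return
        if all_labeled[id(node)]:
            clades.append([t.name for t in node.tips()])
            return
        for c in node.children:
            collect(c)

    all_labeled = {}
    for node in tree.postorder():
        if node.is_tip():
            all_labeled[id(node)] = node.name in labeled
        else:
            all_labeled[id(node)] = all(
                all_labeled[id(c)] for c in node.children
            )
    collect(tree)
    return clades


def clade_divergence_test(
    tree: TreeNode,
    elevation_labels: dict,
    clades: list[list[str]] | None = None,
    n_perm: int = 1000,
    seed=None,
    correction: str = "bonferroni",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare within-clade divergence between clade preference types.

    Clades default to the maximal monophyletic groups whose tips are all
    labeled (high/low); user-supplied disjoint tip sets are accepted.
    Each clade is typed ``high_only`` / ``low_only`` / ``mixed`` from its
    member labels, and summarized by its mean within-clade pairwise
    patristic distance and mean root-to-tip distance. For every pair of
    types, a permutation t-test (shuffling type labels across clades)
    compares mean divergences, Bonferroni-corrected across comparisons.

    Returns ``(clade_report, comparisons)``.
    """
    labeled = set(elevation_labels)
    if clades is None:
        clades = _maximal_labeled_clades(tree, labeled)
    seen: set = set()
    for cl in clades:
        if seen & set(cl):
            raise ValidationError("clades must be disjoint tip sets")
        seen |= set(cl)

    r2t = root_to_tip(tree)["distance"]
    report = []
    for i, members in enumerate(clades):
        if len(members) < 2:
            warnings.warn(
                f"clade {i} has a single member; divergence undefined, skipped"
            )
            continue
        kinds = {elevation_labels[m] for m in members}
        ctype = f"{next(iter(kinds))}_only" if len(kinds) == 1 else "mixed"
        sub = patristic_matrix(tree, members)
        report.append(
            {
                "clade": i,
                "members": ",".join(members),
                "n": len(members),
                "type": ctype,
                "mean_pairwise_distance": float(sub.condensed_form().mean()),
                "mean_root_to_tip": float(r2t.loc[members].mean()),
            }
        )
    report = pd.DataFrame(report)
    comparisons = []
    if len(report):
        types = sorted(report["type"].unique())
        pairs = [
            (ta, tb)
            for ta, tb in itertools.combinations(types, 2)
        ]
        rng = np.random.default_rng(seed)
        vals = report["mean_pairwise_distance"].to_numpy()
        tvec = report["type"].to_numpy()
        for ta, tb in pairs:
            xa = vals[tvec == ta]
            xb = vals[tvec == tb]
            if len(xa) < 1 or len(xb) < 1:
                continue
            obs = xa.mean() - xb.mean()
            mask = (tvec == ta) | (tvec == tb)
            sub_vals = vals[mask]
            sub_lab = tvec[mask]
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_lab)
                d = sub_vals[perm == ta].mean() - sub_vals[perm == tb].mean()
                exceed += abs(d) >= abs(obs) - 1e-12
            p = (1 + exceed) / (1 + n_perm)
            comparisons.append(
                {"type_a": ta, "type_b": tb,
                 "mean_diff": float(obs), "p": float(p)}
            )
    comparisons = pd.DataFrame(comparisons)
    if len(comparisons):
        if correction == "bonferroni":
            comparisons["p_corrected"] = np.minimum(
                comparisons["p"] * len(comparisons), 1.0
            )
        else:
            raise ValueError(f"unknown correction {correction!r}")
    return report, comparisons


def root_to_tip(
    tree: TreeNode, tip_ids=None, groups: pd.Series | dict | None = None
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame, float]:
    """Root-to-tip path lengths, optionally contrasted between groups.

    Without ``groups``, returns a frame with one ``distance`` per tip.
    With ``groups`` (tip → label), additionally returns a per-group
    mean ± s.d. summary and a Kruskal–Wallis p-value across groups
    (p = 1 when every distance is identical, e.g. an ultrametric tree).
    """
    dist = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        dist[tip.name] = d
    df = pd.DataFrame({"distance": pd.Series(dist)})
    df.index.name = "otu_id"
    if tip_ids is not None:
        unknown = [t for t in tip_ids if t not in df.index]
        if unknown:
            raise ValidationError(f"unknown tip ids: {unknown}")
        df = df.loc[list(tip_ids)]
    if groups is None:
        return df
    g = pd.Series(groups)
    df = df.loc[df.index.intersection(g.index)]
    df["group"] = g.loc[df.index]
    summary = df.groupby("group")["distance"].agg(["mean", "std", "count"])
    samples = [sub["distance"].to_numpy() for _, sub in df.groupby("group")]
    if len(samples) < 2:
        raise ValidationError("root-to-tip contrast needs >= 2 groups")
    if np.ptp(df["distance"].to_numpy()) == 0:
        p = 1.0
    else:
        p = float(stats.kruskal(*samples).pvalue)
    return df, summary, p


def shared_otu_abundance_test(
    tableA: OtuTable, tableB: OtuTable, n_perm: int = 1000, seed=None
) -> dict:
    """Do OTUs shared between two regions have unusually high abundance?

    The observed statistic is the mean regional relative abundance
    (pooled over both tables) of the OTUs present in both; the null draws
    the same number of OTUs at random from the pooled list 1,000 times.
    p is the add-one fraction of draws with mean at or above the observed.
    """
    presA = tableA.counts.columns[(tableA.counts > 0).any(axis=0)]
    presB = tableB.counts.columns[(tableB.counts > 0).any(axis=0)]
    shared = sorted(set(presA) & set(presB))
    union = sorted(set(presA) | set(presB))
    n_shared = len(shared)
    if n_shared == 0:
        return {"n_shared": 0, "p": None, "observed_mean": None}
    pooled = (
        tableA.counts.sum(axis=0).reindex(union, fill_value=0)
        + tableB.counts.sum(axis=0).reindex(union, fill_value=0)
    )
    rel = pooled / pooled.sum()
    observed = float(rel.loc[shared].mean())
    rng = np.random.default_rng(seed)
    rel_arr = rel.to_numpy()
    null = np.array(
        [
            rel_arr[rng.choice(len(rel_arr), n_shared, replace=False)].mean()
            for _ in range(n_perm)
        ]
    )
    p = (1 + (null >= observed - 1e-15).sum()) / (1 + n_perm)
    return {"n_shared": n_shared, "p": float(p), "observed_mean": observed}


def cohens_d(valuesA, valuesB) -> dict:
    """Cohen's d (pooled s.d.) with a Welch's t-test alongside.

    d > 0 means group A has the larger mean. Errors on zero pooled
    variance, where the effect size is undefined.
    """
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Cohen's d needs n >= 2 per group")
    na, nb = len(a), len(b)
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 <= 0:
        raise ValidationError("zero pooled variance; Cohen's d undefined")
    d = (a.mean() - b.mean()) / np.sqrt(s2)
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    return {"d": float(d), "welch_t": float(t_stat), "welch_p": float(t_p)}
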