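"""End-to-end orchestration: one config, one output directory, one report.

Stage order: validate → depth filter → normalize → alpha/rarefaction →
beta diversity (Bray–Curtis, Sørensen partition, UniFrac) → ANOSIM /
Mantel family / correlogram → βNTI + RC-Bray → process classification and
zone fractions → IndVal → preferred elevation, bootstrap phylogenetic
nulls, clade divergence, root-to-tip → report (TSVs + JSON + log).

A single root seed deterministically spawns per-stage substreams, so a
re-run with the same config is byte-identical, and individual stages run
standalone reproduce the full-run numbers.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import assembly_analysis, assign_zones
from .beta import (
    anosim,
    bray_curtis,
    env_distance_matrix,
    geodesic_matrix,
    mantel,
    mantel_correlogram,
    partial_mantel,
    sorensen_partition,
    unweighted_unifrac,
)
from .datatypes import OtuTable, ValidationError, validate_dataset
from .indicators import (
    bootstrap_pd_null,
    clade_divergence_test,
    indval,
    preferred_elevation,
    root_to_tip,
)
from .io import read_metadata, read_otu_table, read_tree
from .preprocess import (
    filter_low_depth_samples,
    normalize,
    observed_richness,
    rarefaction_curve,
    summarize_design,
)
from .synthetic import simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "run_pipeline", "validate_report"]

#: structural schema of report.json: key -> (required, type)
REPORT_SCHEMA: dict = {
    "version": (True, str),
    "seed": (True, int),
    "config": (True, dict),
    "stages": (True, list),
    "alpha": (True, dict),
    "beta": (True, dict),
    "design_summary": (True, dict),
    "normalization": (True, dict),
    "n_samples_after_filter": (True, int),
    "anosim_zone": (False, dict),
    "mantel_elevation": (False, dict),
    "partial_mantel_elevation_given_space": (False, dict),
    "partial_mantel_space_given_elevation": (False, dict),
    "assembly": (False, dict),
    "indicators": (False, dict),
    "phylosignal": (False, dict),
    "root_to_tip": (False, dict),
}


def validate_report(report: dict) -> None:
    """Check a pipeline report against the shipped structural schema.

    Raises ``ValidationError`` on a missing required section or a
    mis-typed value; unknown keys are rejected so the schema stays the
    single source of truth for the report layout.
    """
    for key, (required, typ) in REPORT_SCHEMA.items():
        if key not in report:
            if required:
                raise ValidationError(f"report missing required key {key!r}")
            continue
        if not isinstance(report[key], typ):
            raise ValidationError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    unknown = set(report) - set(REPORT_SCHEMA)
    if unknown:
        raise ValidationError(f"unknown report keys: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """All pipeline knobs with their default (framework-standard) values."""

    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    synthetic_design: str | None = None
    synthetic_regime: str | None = None
    norm_method: str = "css"
    filter_threshold: object = "q1"
    n_perm_anosim: int = 9999
    n_perm_mantel: int = 999
    n_null: int = 999
    n_boot: int = 1000
    n_perm_indval: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    zone_high: float = 1000.0
    zone_low: float = 500.0
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "elevassembly_out"
    extra_synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage_seeds(root_seed: int, n: int = 10) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(root_seed).spawn(n)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the JSON-ready report.

    Raises with the failing stage's name; outputs produced up to that
    point remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp}\t{msg}")

    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "stages": [],
    }
    stage = "setup"
    try:
        # --- inputs -------------------------------------------------------
        stage = "inputs"
        real = config.table_path or config.metadata_path or config.tree_path
        synth = config.synthetic_design or config.synthetic_regime
        if real and synth:
            raise ValidationError(
                "real input paths and a synthetic regime are mutually exclusive"
            )
        if synth:
            ds = simulate_dataset(
                design=config.synthetic_design or "wm",
                regime=config.synthetic_regime or "selection",
                seed=int(seeds[0].generate_state(1)[0] % (2**31)),
                **config.extra_synthetic,
            )
            write_dataset(ds, out / "synthetic_input")
            table, metadata, tree = ds.table, ds.metadata, ds.tree
        else:
            if not (config.table_path and config.metadata_path):
                raise ValidationError(
                    "need table_path and metadata_path (or a synthetic regime)"
                )
            table = read_otu_table(config.table_path)
            metadata = read_metadata(config.metadata_path)
            tree = read_tree(config.tree_path) if config.tree_path else None
        log(f"inputs: {len(table.sample_ids)} samples, {len(table.otu_ids)} OTUs")

        stage = "validate"
        vd = validate_dataset(table, metadata, tree)
        table, metadata, tree = vd.table, vd.metadata, vd.tree
        report["stages"].append("validate")

        stage = "filter"
        table = filter_low_depth_samples(table, config.filter_threshold)
        metadata = metadata.loc[table.sample_ids]
        report["n_samples_after_filter"] = len(table.sample_ids)
        report["stages"].append("filter")
        log(f"filter: kept {len(table.sample_ids)} samples")

        stage = "normalize"
        table_norm = normalize(table, config.norm_method)
        report["normalization"] = {
            "method": config.norm_method,
            **table_norm.norm_params,
        }
        report["stages"].append("normalize")

        stage = "alpha"
        rich = observed_richness(table)
        rich.to_csv(out / "alpha_richness.tsv", sep="\t")
        report["alpha"] = {
            "mean_richness": float(rich.mean()),
            "sd_richness": float(rich.std(ddof=1)) if len(rich) > 1 else 0.0,
        }
        max_depth = int(table.library_sizes.max())
        depths = sorted({d for d in [1, 10, 50, 100, 500, max_depth] if d <= max_depth})
        rarefaction_curve(table, depths).to_csv(out / "rarefaction.tsv", sep="\t")
        report["design_summary"] = summarize_design(metadata)
        report["stages"].append("alpha")

        stage = "beta"
        bc = bray_curtis(table_norm)
        part = sorensen_partition(table)
        report["beta"] = {
            "turnover_percent": part.turnover_percent,
            "nestedness_percent": part.nestedness_percent,
            "mean_bray_curtis": float(bc.condensed_form().mean()),
        }
        bc.write(str(out / "bray_curtis.tsv"))
        part.total.write(str(out / "sorensen_total.tsv"))
        part.turnover.write(str(out / "sorensen_turnover.tsv"))
        part.nestedness.write(str(out / "sorensen_nestedness.tsv"))
        uf = None
        if tree is not None:
            uf = unweighted_unifrac(table, tree)
            uf.write(str(out / "unifrac.tsv"))
            report["beta"]["mean_unifrac"] = float(uf.condensed_form().mean())
            report["beta"]["sd_unifrac"] = float(
                uf.condensed_form().std(ddof=1)
            )
        report["stages"].append("beta")

        stage = "matrix_tests"
        comm = uf if uf is not None else bc
        zones = assign_zones(
            metadata["elevation"], config.zone_high, config.zone_low
        )
        seed_anosim = int(seeds[1].generate_state(1)[0] % (2**31))
        if zones.nunique() >= 2:
            report["anosim_zone"] = anosim(
                comm, zones, n_perm=config.n_perm_anosim, seed=seed_anosim
            )
        dm_elev = env_distance_matrix(metadata["elevation"], "elevation")
        seed_mantel = int(seeds[2].generate_state(1)[0] % (2**31))
        mt = mantel(comm, dm_elev, n_perm=config.n_perm_mantel, seed=seed_mantel)
        report["mantel_elevation"] = {
            "r": mt.statistic, "p": mt.p_value, "n_permutations": mt.n_permutations,
        }
        if {"latitude", "longitude"} <= set(metadata.columns):
            dm_geo = geodesic_matrix(metadata)
            pm = partial_mantel(
                comm, dm_elev, dm_geo,
                n_perm=config.n_perm_mantel, seed=seed_mantel,
            )
            report["partial_mantel_elevation_given_space"] = {
                "r": pm.statistic, "p": pm.p_value,
            }
            pm2 = partial_mantel(
                comm, dm_geo, dm_elev,
                n_perm=config.n_perm_mantel, seed=seed_mantel,
            )
            report["partial_mantel_space_given_elevation"] = {
                "r": pm2.statistic, "p": pm2.p_value,
            }
            cg = mantel_correlogram(
                comm, dm_geo, n_perm=config.n_perm_mantel, seed=seed_mantel
            )
            cg.to_csv(out / "mantel_correlogram.tsv", sep="\t", index=False)
        report["stages"].append("matrix_tests")

        stage = "assembly"
        if tree is not None:
            seed_asm = int(seeds[3].generate_state(1)[0] % (2**31))
            asm = assembly_analysis(
                table, tree, metadata["elevation"],
                table_for_bnti=table_norm,
                n_null=config.n_null, seed=seed_asm,
                bnti_threshold=config.bnti_threshold,
                rc_threshold=config.rc_threshold,
                zone_high=config.zone_high, zone_low=config.zone_low,
            )
            asm.classification.to_csv(
                out / "assembly_pairs.tsv", sep="\t", index=False
            )
            asm.fractions.to_csv(
                out / "assembly_zone_fractions.tsv", sep="\t", index=False
            )
            report["assembly"] = {
                "overall_fractions": asm.classification["process"]
                .value_counts(normalize=True)
                .to_dict(),
            }
            report["stages"].append("assembly")

        stage = "indicators"
        seed_iv = int(seeds[4].generate_state(1)[0] % (2**31))
        iv = None
        if zones.nunique() >= 2:
            iv = indval(
                table_norm, zones,
                n_perm=config.n_perm_indval, seed=seed_iv, alpha=config.alpha,
            )
            iv.to_csv(out / "indval.tsv", sep="\t")
            sig = iv[iv["significant"]]
            report["indicators"] = {
                z: int((sig["group"] == z).sum()) for z in zones.unique()
            }
            report["stages"].append("indicators")

        stage = "phylosignal"
        pe = preferred_elevation(table, metadata)
        pe.to_csv(out / "preferred_elevation.tsv", sep="\t")
        if tree is not None and iv is not None:
            sig = iv[iv["significant"]]
            labels = {}
            for z, lab in (("High", "high"), ("Low", "low")):
                for otu in sig.index[sig["group"] == z]:
                    labels[otu] = lab
            seed_boot = int(seeds[5].generate_state(1)[0] % (2**31))
            report["phylosignal"] = {}
            for lab in ("high", "low"):
                ids = [o for o, v in labels.items() if v == lab]
                if len(ids) >= 2:
                    bn = bootstrap_pd_null(
                        ids, table.otu_ids, tree,
                        n_boot=config.n_boot, seed=seed_boot,
                    )
                    report["phylosignal"][f"{lab}_indicators"] = {
                        "n": len(ids),
                        "observed_mean_pd": bn.observed,
                        "ci": [bn.ci_low, bn.ci_high],
                        "p_clustered": bn.p_lower,
                    }
            if len(set(labels.values())) == 2:
                rep, comp = clade_divergence_test(
                    tree, labels, n_perm=config.n_boot,
                    seed=seed_boot,
                )
                if len(rep):
                    rep.to_csv(out / "clade_report.tsv", sep="\t", index=False)
                if len(comp):
                    comp.to_csv(
                        out / "clade_comparisons.tsv", sep="\t", index=False
                    )
                _, r2t_summary, r2t_p = root_to_tip(
                    tree, groups=pd.Series(labels)
                )
                report["root_to_tip"] = {
                    "by_group": {
                        g: {
                            "mean": float(row["mean"]),
                            "sd": float(row["std"]) if row["count"] > 1 else 0.0,
                        }
                        for g, row in r2t_summary.iterrows()
                    },
                    "kruskal_p": r2t_p,
                }
            report["stages"].append("phylosignal")

        stage = "report"
        validate_report(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        log("pipeline complete")
        return report
    except Exception as exc:
        log(f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log_path.write_text("\n".join(log_lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
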