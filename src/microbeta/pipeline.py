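"""End-to-end orchestration: simulate or load data, curate, compute
diversity, ordinate, test, and write a machine-readable report.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is individually reproducible; every intermediate artifact (distance
matrices, FitE table, alpha table) is written to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, diversity, io_formats, ordination, stats
from .io_formats import DistanceMatrix, OtuTable, SampleMetadata
from .synthetic_data import GeneratorConfig, generate_dataset, generate_replicates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "plot_ordination"]

# fixed per-stage seed offsets from the global seed
_SEED_SIMULATE = 0
_SEED_RAREFY = 1
_SEED_ORDINATION = 2
_SEED_ANOSIM = 3
_SEED_REPLICATES = 4


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: GeneratorConfig | None = None
    table_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    rarefaction_depth: int = 5000
    min_otu_total: int = 10
    metrics: tuple = ("emd", "wunifrac")
    n_bins: int | None = None
    saturation_threshold: float = 0.9
    n_perm: int = 999
    constraint: str = "days_in_captivity"
    covariate: str = "species_code"
    anosim_group: str = "order_group"
    top_k: int = 10
    n_replicate_pairs: int = 2

    def __post_init__(self) -> None:
        unknown = [m for m in self.metrics if m not in ("emd", "wunifrac")]
        if unknown:
            raise ValueError(f"unknown metrics {unknown}")
        if self.simulate is None:
            for name in ("table_path", "taxonomy_path", "metadata_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"either simulate or {name} must be given")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: no such file {path!r}")
            if "wunifrac" in self.metrics:
                if self.tree_path is None or not Path(self.tree_path).exists():
                    raise ValueError("wunifrac metric requires an existing tree_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            if isinstance(sim.get("days_range"), list):
                sim["days_range"] = tuple(sim["days_range"])
            raw["simulate"] = GeneratorConfig(**sim)
        if isinstance(raw.get("metrics"), list):
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    parameters: dict
    alpha: list
    distance_summaries: dict
    pcoa_variance: list
    anosim: dict | None
    constrained: dict | None
    enrichment: dict | None
    group_comparison: dict | None
    metric_correlation: dict | None
    replicate_qc: dict | None
    dropped: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(name):
    logger.info("pipeline stage: %s", name)


def run_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis; returns the report and writes artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    _stage("acquire")
    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed + _SEED_SIMULATE)
        ds = generate_dataset(sim_cfg)
        table, taxonomy, tree, meta = ds.table, ds.taxonomy, ds.tree, ds.metadata
    else:
        table = io_formats.read_otu_table(cfg.table_path)
        taxonomy = io_formats.read_taxonomy(cfg.taxonomy_path)
        tree = io_formats.read_tree(cfg.tree_path) if cfg.tree_path else None
        meta = io_formats.read_metadata(cfg.metadata_path)

    _stage("rarefy")
    n_before = table.n_samples
    table = curation.rarefy(table, cfg.rarefaction_depth, seed=cfg.seed + _SEED_RAREFY)
    dropped_samples = n_before - table.n_samples

    _stage("filter")
    n_otus_before = table.n_otus
    table = curation.filter_rare_otus(table, cfg.min_otu_total)
    dropped_otus = n_otus_before - table.n_otus

    _stage("alpha")
    alpha = diversity.alpha_diversity(table)
    alpha_df = pd.DataFrame([dataclasses.asdict(a) for a in alpha])
    alpha_df.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)

    _stage("beta")
    dms: dict[str, DistanceMatrix] = {}
    summaries: dict[str, dict] = {}
    for metric in cfg.metrics:
        dm = diversity.distance_matrix(
            table, metric, tree=tree, taxonomy=taxonomy, n_bins=cfg.n_bins
        )
        dms[metric] = dm
        io_formats.write_distance_matrix(dm, outdir / f"dm_{metric}.tsv", "square-tsv")
        io_formats.write_distance_matrix(dm, outdir / f"dm_{metric}.phylip", "phylip-square")
        mean, sd, count_above, frac = diversity.saturation_summary(dm, cfg.saturation_threshold)
        summaries[metric] = {
            "n_pairs": len(dm.condensed()),
            "mean": mean,
            "sd": sd,
            "threshold": cfg.saturation_threshold,
            "count_above": count_above,
            "fraction_above": frac,
        }
    primary = dms.get("emd", next(iter(dms.values())))

    _stage("pcoa")
    pc = ordination.pcoa(primary)
    coords = pd.DataFrame(
        pc.coordinates,
        index=list(pc.sample_ids),
        columns=[f"axis{i + 1}" for i in range(pc.coordinates.shape[1])],
    )
    coords.index.name = "sample_id"
    coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")

    _stage("anosim")
    anosim_result = None
    groups = meta.column(cfg.anosim_group, table.sample_ids)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) >= 2 and counts.min() >= 2:
        r, p = stats.anosim(primary, groups, n_perm=cfg.n_perm, seed=cfg.seed + _SEED_ANOSIM)
        anosim_result = {"group": cfg.anosim_group, "R": r, "p": p, "n_perm": cfg.n_perm}
    else:
        logger.warning("skipping ANOSIM: group %r has a level with < 2 members", cfg.anosim_group)

    _stage("constrained ordination")
    constrained = None
    enrichment_block = None
    aligned = meta.aligned(table.sample_ids)
    survivors = [
        s for s, o in zip(table.sample_ids, aligned["outcome"]) if o == "survivor"
    ] if "outcome" in aligned.columns else list(table.sample_ids)
    if len(survivors) >= 8:
        sub = curation.subset_and_prune(table, survivors)
        days = meta.column(cfg.constraint, sub.sample_ids).astype(float)
        cov = ordination.species_dummies(meta, sub.sample_ids, cfg.covariate)
        res = ordination.partial_constrained_ordination(
            sub, days, cov, n_perm=cfg.n_perm, seed=cfg.seed + _SEED_ORDINATION
        )
        top = ordination.fite_ranking(res, min(cfg.top_k, len(res.fite)))
        fite_df = pd.DataFrame(
            sorted(res.fite.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["otu_id", "fite_percent"],
        )
        fite_df.to_csv(outdir / "fite.tsv", sep="\t", index=False)
        constrained = {
            "n_samples": sub.n_samples,
            "n_otus": sub.n_otus,
            "pseudo_f": res.pseudo_f,
            "p": res.p_value,
            "n_perm": res.n_permutations,
            "top_fite": list(top),
        }

        _stage("enrichment")
        enr = stats.phylum_enrichment(top, list(res.fite), taxonomy)
        enr.df.to_csv(outdir / "enrichment.tsv", sep="\t")
        bg = enr.df.drop(index="sum")["background"].to_numpy(float)
        obs = enr.df.drop(index="sum")["observed"].to_numpy(float)
        chi2, dof, chi_p = stats.chisq_gof(obs, bg / bg.sum())
        enrichment_block = {
            "table": {
                ph: {
                    "observed": int(row["observed"]),
                    "observed_pct": row["observed_pct"],
                    "background": int(row["background"]),
                    "background_pct": row["background_pct"],
                }
                for ph, row in enr.df.drop(index="sum").iterrows()
            },
            "chi2": chi2,
            "df": dof,
            "p": chi_p,
        }
        actino = enr.row("Actinobacteria")
        if actino["background"] > 0 and actino["background_pct_display"] > 0:
            fe = stats.fold_enrichment(enr, "Actinobacteria")
            enrichment_block["fold_enrichment_actinobacteria"] = {
                "rounded": fe.rounded,
                "exact": fe.exact,
            }
    else:
        logger.warning("skipping constrained ordination: only %d survivors", len(survivors))

    _stage("group comparison")
    group_cmp = None
    if "outcome" in aligned.columns and "emd" in dms:
        outcome = meta.column("outcome", table.sample_ids)
        died = [s for s, o in zip(table.sample_ids, outcome) if o != "survivor"]
        surv = [s for s, o in zip(table.sample_ids, outcome) if o == "survivor"]
        if len(died) >= 3 and len(surv) >= 3:
            d_died = dms["emd"].submatrix(died).condensed()
            d_surv = dms["emd"].submatrix(surv).condensed()
            u, p = stats.mann_whitney(d_died, d_surv)
            group_cmp = {
                "test": "mann_whitney_pairwise_emd",
                "n_died_pairs": len(d_died),
                "n_survivor_pairs": len(d_surv),
                "mean_died": float(d_died.mean()),
                "mean_survivor": float(d_surv.mean()),
                "U": u,
                "p": p,
                "caveat": "pairwise distances are not independent observations",
            }

    _stage("metric correlation")
    correlation = None
    if len(dms) == 2:
        rho, p = stats.spearman(dms["emd"].condensed(), dms["wunifrac"].condensed())
        correlation = {"rho": rho, "p": p, "n": len(dms["emd"].condensed())}

    _stage("replicate qc")
    replicate_qc = None
    if cfg.simulate is not None and cfg.n_replicate_pairs > 0 and "emd" in dms:
        qc_ids = list(table.sample_ids[: cfg.n_replicate_pairs])
        rep_a = generate_replicates(table, qc_ids, seed=cfg.seed + _SEED_REPLICATES, suffix="_a")
        rep_b = generate_replicates(table, qc_ids, seed=cfg.seed + _SEED_REPLICATES + 1, suffix="_b")
        enc = diversity.build_histogram_encoding(table, taxonomy, cfg.n_bins)
        gd = diversity.ground_distance(enc)
        rep_d = []
        for sid in qc_ids:
            ha = enc.bin_profile(rep_a.counts[rep_a.sample_index(f"{sid}_a")], rep_a.otu_ids)
            hb = enc.bin_profile(rep_b.counts[rep_b.sample_index(f"{sid}_b")], rep_b.otu_ids)
            rep_d.append(diversity.emd(ha, hb, gd))
        mean_rep = float(np.mean(rep_d))
        mean_inter = float(dms["emd"].condensed().mean())
        replicate_qc = {
            "n_pairs": len(rep_d),
            "mean_replicate_emd": mean_rep,
            "mean_inter_sample_emd": mean_inter,
            "ratio": mean_rep / mean_inter,
        }

    report = AnalysisReport(
        parameters={
            "seed": cfg.seed,
            "rarefaction_depth": cfg.rarefaction_depth,
            "min_otu_total": cfg.min_otu_total,
            "metrics": list(cfg.metrics),
            "n_perm": cfg.n_perm,
            "simulated": cfg.simulate is not None,
        },
        alpha=[dataclasses.asdict(a) for a in alpha],
        distance_summaries=summaries,
        pcoa_variance=[float(v) for v in pc.proportion_explained[:5]],
        anosim=anosim_result,
        constrained=constrained,
        enrichment=enrichment_block,
        group_comparison=group_cmp,
        metric_correlation=correlation,
        replicate_qc=replicate_qc,
        dropped={"samples_below_depth": dropped_samples, "rare_otus": dropped_otus},
    )
    (outdir / "report.json").write_text(report.to_json())
    return report


def plot_ordination(result, metadata: SampleMetadata, color_by: str, path) -> None:
    """Scatter of PCoA axes 1-2 colored by a metadata field.

    Categorical fields get a discrete palette with a legend entry per level;
    numeric fields get a continuous ramp with a colorbar.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.coordinates.shape[1] < 2:
        raise ValueError("need at least 2 ordination axes to plot")
    values = metadata.column(color_by, result.sample_ids)
    x, y = result.coordinates[:, 0], result.coordinates[:, 1]
    fig, ax = plt.subplots(figsize=(6, 5))
    if np.issubdtype(np.asarray(values).dtype, np.number):
        sc = ax.scatter(x, y, c=values, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=color_by)
    else:
        levels = sorted(set(values))
        cmap = plt.get_cmap("tab10")
        for i, level in enumerate(levels):
            mask = np.asarray(values) == level
            ax.scatter(x[mask], y[mask], color=cmap(i % 10), label=str(level))
        ax.legend(fontsize=8)
    pe = result.proportion_explained
    ax.set_xlabel(f"PCo1 ({pe[0] * 100:.1f}%)")
    ax.set_ylabel(f"PCo2 ({pe[1] * 100:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
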