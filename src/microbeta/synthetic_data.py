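"""Synthetic community generator with the statistical structure the analysis
assumes: Firmicutes-dominated, Bacteroidetes-poor communities with strong
inter-sample heterogeneity, a captivity covariate that expands a designated
subset of Actinobacteria OTUs, and multinomial technical replicates.

Model: per sample, phylum proportions ~ Dirichlet(theta * base shares);
within-phylum OTU proportions ~ Dirichlet(within_theta * base split), where
the base split comes from a heavy-tailed stick-breaking draw made once per
dataset.  The captivity effect multiplies the designated OTUs' latent
proportions by exp(beta * days) before renormalization (compositionally
coherent).  Counts are multinomial at fixed depth.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import (
    OtuTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
    UNCLASSIFIED,
    UNCLASSIFIED_PHYLUM,
    parse_newick,
)

import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_replicates",
    "tune_heterogeneity",
]

DEFAULT_SPECIES_COUNTS = {
    "AMKE": 1,
    "BAEA": 2,
    "BDOW": 8,
    "BWHA": 2,
    "COHA": 3,
    "GHOW": 1,
    "RTHA": 29,
}
# owls vs hawks/eagles/falcons
_OWL_SPECIES = {"BDOW", "GHOW"}

DEFAULT_PHYLUM_PROPS = {
    "Firmicutes": 0.600,
    "Proteobacteria": 0.248,
    "Actinobacteria": 0.069,
    "Bacteroidetes": 0.042,
    "Fusobacteria": 0.017,
    UNCLASSIFIED_PHYLUM: 0.024,
}

DEFAULT_OTUS_PER_PHYLUM = {
    "Firmicutes": 170,
    "Proteobacteria": 80,
    "Actinobacteria": 40,
    "Bacteroidetes": 25,
    "Fusobacteria": 12,
    UNCLASSIFIED_PHYLUM: 15,
}


def _scaled_roster(n_samples: int) -> dict[str, int]:
    """Largest-remainder scaling of the default species roster to n samples."""
    total = sum(DEFAULT_SPECIES_COUNTS.values())
    quotas = {sp: c * n_samples / total for sp, c in DEFAULT_SPECIES_COUNTS.items()}
    roster = {sp: int(q) for sp, q in quotas.items()}
    remainder = n_samples - sum(roster.values())
    for sp in sorted(quotas, key=lambda s: quotas[s] - roster[s], reverse=True)[:remainder]:
        roster[sp] += 1
    return {sp: c for sp, c in roster.items() if c > 0}


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 46
    species_counts: dict | None = None  # None -> default roster scaled to n_samples
    depth: int = 5000
    otus_per_phylum: dict = field(default_factory=lambda: dict(DEFAULT_OTUS_PER_PHYLUM))
    phylum_props: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_PROPS))
    theta: float = 2.2  # phylum-level Dirichlet concentration (heterogeneity knob)
    within_theta: float = 16.0  # within-phylum Dirichlet concentration
    stick_alpha: float = 100.0  # stick-breaking Beta(1, alpha): smaller -> heavier tail
    beta: float = 0.12  # per-day multiplicative log-abundance captivity effect
    n_affected_otus: int = 6  # Actinobacteria OTUs carrying the captivity effect
    days_range: tuple = (1, 83)
    days_distribution: str = "log-uniform"  # admission-skewed stays; "uniform" for gradient cohorts
    survivor_fraction: float = 22 / 46
    n_replicate_pairs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.theta <= 0 or self.within_theta <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        total = sum(self.phylum_props.values())
        if abs(total - 1) > 1e-9:
            raise ValueError(f"phylum proportions sum to {total!r}, not 1")
        if set(self.phylum_props) != set(self.otus_per_phylum):
            raise ValueError("phylum_props and otus_per_phylum must cover the same phyla")
        roster = self.species_counts
        if roster is not None and sum(roster.values()) != self.n_samples:
            raise ValueError(
                f"species roster sums to {sum(roster.values())}, not n_samples={self.n_samples}"
            )

    def roster(self) -> dict[str, int]:
        if self.species_counts is not None:
            return dict(self.species_counts)
        if self.n_samples == sum(DEFAULT_SPECIES_COUNTS.values()):
            return dict(DEFAULT_SPECIES_COUNTS)
        return _scaled_roster(self.n_samples)


@dataclass(frozen=True)
class SyntheticDataset:
    table: OtuTable
    taxonomy: TaxonomyMap
    tree: PhyloTree
    metadata: SampleMetadata
    affected_otus: tuple[str, ...]  # OTUs carrying the planted captivity effect

    def __iter__(self):  # allow 4-tuple unpacking
        return iter((self.table, self.taxonomy, self.tree, self.metadata))


def _stick_breaking(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    if n == 1:
        return np.ones(1)
    v = rng.beta(1.0, alpha, size=n)
    v[-1] = 1.0
    remaining = np.concatenate([[1.0], np.cumprod(1 - v[:-1])])
    w = v * remaining
    w = np.sort(w)[::-1]
    return w / w.sum()


def _random_clade(rng: np.random.Generator, leaves: list[str], scale: float) -> str:
    """Random bifurcating Newick subtree over the given leaves."""
    nodes = [f"{leaf}:{rng.exponential(scale):.6f}" for leaf in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(scale):.6f}")
    return nodes[0]


def _build_tree(rng: np.random.Generator, otus_by_phylum: dict) -> PhyloTree:
    """Random bifurcating topology in which same-phylum OTUs form clades."""
    clades = [
        _random_clade(rng, otus, scale=0.1)
        for phylum, otus in otus_by_phylum.items()
        if otus
    ]
    while len(clades) > 2:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        b = clades.pop(j)
        a = clades.pop(i)
        clades.append(f"({a},{b}):{rng.exponential(0.3):.6f}")
    if len(clades) == 1:
        newick = f"({clades[0]});"
    else:
        newick = f"({clades[0]},{clades[1]});"
    return parse_newick(newick)


_RANK_SUFFIXES = ("class", "order", "family", "genus")


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate (OtuTable, TaxonomyMap, PhyloTree, SampleMetadata).

    Row sums all equal ``cfg.depth``; output is bitwise-deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    phyla = list(cfg.phylum_props)
    base_props = np.array([cfg.phylum_props[p] for p in phyla])

    # OTU identities and taxonomy
    otus_by_phylum: dict[str, list[str]] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    counter = 1
    for phylum in phyla:
        members = []
        for _ in range(cfg.otus_per_phylum[phylum]):
            otu = f"Otu{counter:04d}"
            counter += 1
            members.append(otu)
            if phylum == UNCLASSIFIED_PHYLUM:
                lineages[otu] = ("Bacteria",) + (UNCLASSIFIED,) * 5
            else:
                lineages[otu] = ("Bacteria", phylum) + tuple(
                    f"{phylum}_{suffix}{counter % 7}" for suffix in _RANK_SUFFIXES
                )
        otus_by_phylum[phylum] = members
    taxonomy = TaxonomyMap(lineages)
    otu_ids = [o for p in phyla for o in otus_by_phylum[p]]
    otu_pos = {o: i for i, o in enumerate(otu_ids)}

    # base within-phylum splits (drawn once; heavy-tailed)
    base_split = {
        p: _stick_breaking(rng, len(otus_by_phylum[p]), cfg.stick_alpha) for p in phyla
    }

    # planted captivity effect on the most abundant Actinobacteria OTUs
    actino = otus_by_phylum.get("Actinobacteria", [])
    n_aff = min(cfg.n_affected_otus, len(actino))
    affected = tuple(actino[i] for i in range(n_aff))
    affected_idx = np.array([otu_pos[o] for o in affected], dtype=int)

    # metadata
    roster = cfg.roster()
    species = [sp for sp, c in roster.items() for _ in range(c)]
    rng.shuffle(species)
    lo, hi = cfg.days_range
    if cfg.days_distribution == "log-uniform":
        days = np.exp(rng.uniform(math.log(lo), math.log(hi + 1), size=cfg.n_samples))
        days = np.minimum(days.astype(int), hi)
    elif cfg.days_distribution == "uniform":
        days = rng.integers(lo, hi + 1, size=cfg.n_samples)
    else:
        raise ValueError(f"unknown days_distribution {cfg.days_distribution!r}")
    n_surv = round(cfg.survivor_fraction * cfg.n_samples)
    outcome = np.array(
        ["survivor"] * n_surv + ["died_or_euthanized"] * (cfg.n_samples - n_surv)
    )
    rng.shuffle(outcome)
    treated = rng.random(cfg.n_samples) < 0.08
    sample_ids = [f"s{i + 1:03d}" for i in range(cfg.n_samples)]

    # counts; the captivity effect multiplies the latent (mean) proportions of
    # the affected OTUs by exp(beta * days) before renormalization, at both
    # levels of the hierarchy, so the Dirichlet draws are centered on the
    # boosted composition rather than fighting an already-realized draw
    act_pos = phyla.index("Actinobacteria") if "Actinobacteria" in phyla else -1
    aff_local = np.array(
        [otus_by_phylum["Actinobacteria"].index(o) for o in affected], dtype=int
    ) if n_aff else np.array([], dtype=int)
    counts = np.zeros((cfg.n_samples, len(otu_ids)), dtype=np.int64)
    for i in range(cfg.n_samples):
        props_i = base_props.copy()
        split_act = base_split.get("Actinobacteria")
        if cfg.beta > 0 and len(aff_local) and act_pos >= 0:
            boost = np.ones(len(split_act))
            boost[aff_local] = np.exp(cfg.beta * days[i])
            boosted = split_act * boost
            props_i[act_pos] *= boosted.sum()
            props_i /= props_i.sum()
            split_act = boosted / boosted.sum()
        phylum_p = rng.dirichlet(cfg.theta * props_i)
        p = np.empty(len(otu_ids))
        start = 0
        for k, phylum in enumerate(phyla):
            size = len(otus_by_phylum[phylum])
            split = split_act if (k == act_pos and split_act is not None) else base_split[phylum]
            within = rng.dirichlet(cfg.within_theta * split)
            p[start : start + size] = phylum_p[k] * within
            start += size
        counts[i] = rng.multinomial(cfg.depth, p)

    table = OtuTable(tuple(sample_ids), tuple(otu_ids), counts)
    tree = _build_tree(rng, otus_by_phylum)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species_code": species,
                "order_group": [
                    "Strigiformes" if sp in _OWL_SPECIES else "Accipitriformes_Falconiformes"
                    for sp in species
                ],
                "days_in_captivity": days,
                "outcome": outcome,
                "treated_antibiotic": treated,
            }
        )
    )
    return SyntheticDataset(table, taxonomy, tree, meta, affected)


def generate_replicates(table: OtuTable, sample_ids, seed: int, suffix: str = "_rep") -> OtuTable:
    """Append technical replicates: multinomial resamples of each source
    sample's relative abundances at the same depth.

    A replicate *pair* (duplicate amplifications of one extract) is obtained
    by calling this twice with different suffixes and comparing the two
    resamples to each other.
    """
    rng = np.random.default_rng(seed)
    rel = table.relative_abundance()
    new_rows = []
    new_ids = []
    for sid in sample_ids:
        i = table.sample_index(sid)
        depth = int(table.counts[i].sum())
        new_rows.append(rng.multinomial(depth, rel[i]))
        new_ids.append(f"{sid}{suffix}")
    counts = np.vstack([table.counts] + [np.asarray(new_rows)])
    return OtuTable(table.sample_ids + tuple(new_ids), table.otu_ids, counts)


def _mean_pairwise_distance(cfg: GeneratorConfig, metric: str, seed: int) -> float:
    from . import diversity

    ds = generate_dataset(replace(cfg, seed=seed))
    if metric == "emd":
        dm = diversity.distance_matrix(ds.table, "emd", taxonomy=ds.taxonomy)
    elif metric == "wunifrac":
        dm = diversity.distance_matrix(ds.table, "wunifrac", tree=ds.tree)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return float(dm.condensed().mean())


def tune_heterogeneity(
    cfg: GeneratorConfig,
    target_mean_distance: float,
    metric: str = "emd",
    tol: float = 0.05,
    theta_bounds: tuple = (0.05, 200.0),
    n_seeds: int = 2,
    max_iter: int = 12,
) -> float:
    """Bisect the phylum-level concentration theta so the simulated mean
    pairwise distance hits the target within +/- tol.

    Mean distance decreases monotonically in theta (larger theta ->
    more homogeneous samples).
    """
    if target_mean_distance <= 0:
        raise ValueError("target must be positive")

    def mean_at(theta: float) -> float:
        c = replace(cfg, theta=theta)
        return float(
            np.mean([_mean_pairwise_distance(c, metric, cfg.seed + s) for s in range(n_seeds)])
        )

    lo, hi = theta_bounds
    d_lo, d_hi = mean_at(lo), mean_at(hi)
    if not (d_hi - tol <= target_mean_distance <= d_lo + tol):
        raise ValueError(
            f"target {target_mean_distance} unreachable for theta in {theta_bounds}: "
            f"mean distance spans [{d_hi:.3f}, {d_lo:.3f}]"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # bisection in log space
        d_mid = mean_at(mid)
        if abs(d_mid - target_mean_distance) <= tol:
            return mid
        if d_mid > target_mean_distance:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)
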