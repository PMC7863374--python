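"""Alpha diversity and the two beta-diversity metrics.

* Weighted, branch-length-normalized UniFrac over a rooted OTU phylogeny
  (range [0, 1]; 1 for communities sharing no sequences).
* Earth Mover's Distance over phylum-structured color histograms: each OTU
  maps to one of B bins (default 69), bins carry coordinates in the RGB unit
  cube with same-phylum bins deliberately closer than cross-phylum bins, and
  the distance is the exact optimal-transport cost between binned relative
  abundances.  The reserved white corner (1,1,1) never hosts a bin, so
  "background" carries no mass by construction.

The histogram construction replaces an image-rendering pipeline with the
equivalent direct computation: transport within a phylum is cheap, across
phyla expensive, and no rendering artifacts enter the distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix
from scipy.spatial.distance import cdist

from .io_formats import DistanceMatrix, OtuTable, PhyloTree, TaxonomyMap

__all__ = [
    "AlphaDiversityResult",
    "HistogramEncoding",
    "shannon",
    "berger_parker",
    "alpha_diversity",
    "weighted_unifrac",
    "build_histogram_encoding",
    "ground_distance",
    "emd",
    "distance_matrix",
    "saturation_summary",
]

DEFAULT_BINS = 69
_WHITE = np.array([1.0, 1.0, 1.0])

# the 7 unit-cube corners excluding white, in greedy farthest-first order so
# the most abundant phyla receive mutually remote anchors
_CUBE_ANCHORS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 1.0, 0.0],
        [1.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
    ]
)


# ---------------------------------------------------------------------------
# Alpha diversity


def shannon(profile) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats over nonzero abundances."""
    counts = np.asarray(profile, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("profile has no positive counts")
    if (counts < 0).any():
        raise ValueError("profile has negative counts")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def berger_parker(profile) -> float:
    """Proportion of the most abundant taxon."""
    counts = np.asarray(profile, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("profile has no positive counts")
    if (counts < 0).any():
        raise ValueError("profile has negative counts")
    return float(counts.max() / counts.sum())


@dataclass(frozen=True)
class AlphaDiversityResult:
    sample_id: str
    shannon: float
    berger_parker: float
    richness: int


def alpha_diversity(table: OtuTable) -> list[AlphaDiversityResult]:
    out = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        out.append(
            AlphaDiversityResult(
                sample_id=sid,
                shannon=shannon(row),
                berger_parker=berger_parker(row),
                richness=int((row > 0).sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Weighted UniFrac


def _branch_mass(table: OtuTable, tree: PhyloTree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-branch descending mass fractions for every sample.

    Returns (lengths, mass, leaf_depth_weighted) where ``mass[k, i]`` is the
    fraction of sample i's reads descending through branch k (root excluded)
    and ``leaf_depth_weighted[i]`` = sum_j depth_j * p_i(j).
    """
    tree.check_leaves([o for o, t in zip(table.otu_ids, table.otu_totals()) if t > 0])
    rel = table.relative_abundance()
    n_nodes = len(tree.parent)
    node_mass = np.zeros((n_nodes, table.n_samples))
    for j, otu in enumerate(table.otu_ids):
        idx = tree.leaf_index.get(otu)
        if idx is not None:
            node_mass[idx] += rel[:, j]
    for node in tree.postorder:
        p = tree.parent[node]
        if p >= 0:
            node_mass[p] += node_mass[node]
    non_root = np.flatnonzero(tree.parent >= 0)
    depths = tree.leaf_depths()
    leaf_rows = np.array([tree.leaf_index[o] for o in table.otu_ids if o in tree.leaf_index])
    leaf_depth = np.array([depths[tree.labels[i]] for i in leaf_rows])
    weighted_depth = leaf_depth @ node_mass[leaf_rows]
    return tree.length[non_root], node_mass[non_root], weighted_depth


def weighted_unifrac(table: OtuTable, tree: PhyloTree, sample_a: str, sample_b: str) -> float:
    """Normalized weighted UniFrac distance between two samples.

    raw = sum_b l_b |p_A(b) - p_B(b)| over branches; normalizer
    D = sum_leaves depth_j (p_A(j) + p_B(j)); returns raw / D in [0, 1].
    """
    if sample_a == sample_b:
        if table.counts[table.sample_index(sample_a)].sum() == 0:
            raise ValueError("both samples are empty; UniFrac undefined")
        return 0.0
    pair = table.select_samples([sample_a, sample_b])
    lengths, mass, wdepth = _branch_mass(pair, tree)
    raw = float(lengths @ np.abs(mass[:, 0] - mass[:, 1]))
    denom = float(wdepth[0] + wdepth[1])
    if denom == 0:
        raise ValueError("both samples are empty; UniFrac undefined")
    return raw / denom


def _unifrac_matrix(table: OtuTable, tree: PhyloTree) -> np.ndarray:
    lengths, mass, wdepth = _branch_mass(table, tree)
    n = table.n_samples
    out = np.zeros((n, n))
    weighted = mass * lengths[:, None]
    for i in range(n):
        diff = np.abs(weighted[:, i][:, None] - weighted[:, i + 1:])
        raw = diff.sum(axis=0)
        denom = wdepth[i] + wdepth[i + 1:]
        out[i, i + 1:] = raw / denom
    return out + out.T


# ---------------------------------------------------------------------------
# Histogram encoding & EMD


@dataclass(frozen=True)
class HistogramEncoding:
    """Assignment of OTUs to phylum-blocked color bins.

    ``bin_of_otu`` maps each nonzero OTU to a bin in [0, B); ``colors`` holds
    one RGB coordinate per bin; ``phylum_bins`` gives each phylum's
    contiguous bin block.
    """

    bin_of_otu: dict
    colors: np.ndarray
    phylum_bins: dict

    @property
    def n_bins(self) -> int:
        return len(self.colors)

    def bin_profile(self, profile, otu_ids) -> np.ndarray:
        """Aggregate a count/abundance vector into a normalized bin histogram."""
        profile = np.asarray(profile, dtype=float)
        total = profile.sum()
        if total <= 0:
            raise ValueError("profile has no mass to bin")
        hist = np.zeros(self.n_bins)
        for value, otu in zip(profile, otu_ids):
            if value == 0:
                continue
            b = self.bin_of_otu.get(otu)
            if b is None:
                raise KeyError(f"OTU {otu!r} has positive abundance but no bin assignment")
            hist[b] += value
        return hist / total


def _allocate_block_sizes(counts: np.ndarray, n_bins: int) -> np.ndarray:
    """Largest-remainder allocation of ``n_bins`` among blocks, each >= 1."""
    k = len(counts)
    if n_bins < k:
        raise ValueError(f"{n_bins} bins cannot cover {k} phyla (need >= 1 bin each)")
    quota = counts / counts.sum() * n_bins
    sizes = np.maximum(1, np.floor(quota).astype(int))
    sizes = np.minimum(sizes, counts)  # never more bins than OTUs in the block
    while sizes.sum() < n_bins:
        # grow the block with the largest unmet quota that can still absorb a bin
        gain = np.where(sizes < counts, quota - sizes, -np.inf)
        if np.all(np.isinf(gain) & (gain < 0)):
            break  # fewer OTUs than bins overall; leftover bins stay unused
        sizes[int(np.argmax(gain))] += 1
    while sizes.sum() > n_bins:
        loss = np.where(sizes > 1, quota - sizes, np.inf)
        sizes[int(np.argmin(loss))] -= 1
    return sizes


def _extra_anchors(n_needed: int, existing: np.ndarray, rng_grid: int = 5) -> np.ndarray:
    """Greedy farthest-point anchors on a cube grid, avoiding white."""
    axes = np.linspace(0, 1, rng_grid)
    grid = np.array(np.meshgrid(axes, axes, axes)).reshape(3, -1).T
    grid = grid[np.linalg.norm(grid - _WHITE, axis=1) > 0.3]
    chosen = list(existing)
    out = []
    for _ in range(n_needed):
        d = cdist(grid, np.asarray(chosen)).min(axis=1)
        pick = grid[int(np.argmax(d))]
        chosen.append(pick)
        out.append(pick)
    return np.array(out)


def build_histogram_encoding(
    table: OtuTable, taxonomy: TaxonomyMap, n_bins: int | None = None
) -> HistogramEncoding:
    """Assign nonzero OTUs to phylum-blocked color bins.

    Phyla are ordered by total abundance (descending, ties by label) and each
    receives a contiguous block of bins proportional to its OTU count (at
    least one).  Within a block, OTUs are ordered by total abundance and
    mapped round-robin when there are more OTUs than bins.  Block anchor
    colors sit at maximally separated cube points excluding the white corner;
    within-block colors are interpolated along a short segment toward the
    cube center, keeping intra-phylum color distances below inter-phylum
    ones.  All-zero OTUs are ignored, so adding one never changes the
    encoding.
    """
    totals = table.otu_totals()
    nonzero = [(o, int(t)) for o, t in zip(table.otu_ids, totals) if t > 0]
    if not nonzero:
        raise ValueError("table has no nonzero OTUs")
    if n_bins is None:
        n_bins = min(DEFAULT_BINS, len(nonzero))

    by_phylum: dict[str, list[tuple[str, int]]] = {}
    for otu, tot in nonzero:
        by_phylum.setdefault(taxonomy.phylum(otu), []).append((otu, tot))
    phyla = sorted(by_phylum, key=lambda p: (-sum(t for _, t in by_phylum[p]), p))
    if n_bins < len(phyla):
        raise ValueError(f"n_bins={n_bins} is below the number of phyla present ({len(phyla)})")

    otu_counts = np.array([len(by_phylum[p]) for p in phyla])
    sizes = _allocate_block_sizes(otu_counts, n_bins)

    if len(phyla) <= len(_CUBE_ANCHORS):
        anchors = _CUBE_ANCHORS[: len(phyla)]
    else:
        anchors = np.vstack(
            [_CUBE_ANCHORS, _extra_anchors(len(phyla) - len(_CUBE_ANCHORS), _CUBE_ANCHORS)]
        )
    pair_d = cdist(anchors, anchors)
    np.fill_diagonal(pair_d, np.inf)
    # within-block bins are scattered in a ball of radius r around the anchor
    # (pulled inward so the ball stays inside the cube); max intra-block
    # distance 2r stays below the guaranteed inter-block separation d_min - 2r
    radius = min(0.22, 0.24 * float(pair_d.min()))

    bin_of_otu: dict[str, int] = {}
    phylum_bins: dict[str, list[int]] = {}
    colors = np.zeros((n_bins, 3))
    center = np.array([0.5, 0.5, 0.5])
    scatter_rng = np.random.default_rng(1815)  # fixed: encoding is deterministic
    next_bin = 0
    for p_i, phylum in enumerate(phyla):
        size = int(sizes[p_i])
        block = list(range(next_bin, next_bin + size))
        next_bin += size
        phylum_bins[phylum] = block
        anchor = anchors[p_i]
        direction = center - anchor
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.zeros(3)
        ball_center = anchor + radius * direction
        colors[block[0]] = ball_center
        if size > 1:
            vecs = scatter_rng.normal(size=(size - 1, 3))
            vecs /= np.linalg.norm(vecs, axis=1)[:, None]
            radii = radius * scatter_rng.uniform(0.3, 1.0, size=size - 1) ** (1 / 3)
            colors[block[1:]] = np.clip(ball_center + radii[:, None] * vecs, 0.0, 1.0)
        members = sorted(by_phylum[phylum], key=lambda ot: (-ot[1], ot[0]))
        for k, (otu, _) in enumerate(members):
            bin_of_otu[otu] = block[k % size]

    used = sorted(set(bin_of_otu.values()))
    if len(used) < n_bins:  # fewer OTUs than bins: drop unused trailing bins
        remap = {b: i for i, b in enumerate(used)}
        bin_of_otu = {o: remap[b] for o, b in bin_of_otu.items()}
        phylum_bins = {p: [remap[b] for b in blk if b in remap] for p, blk in phylum_bins.items()}
        colors = colors[used]

    if np.any(np.linalg.norm(colors - _WHITE, axis=1) < 1e-9):
        raise AssertionError("a bin landed on the reserved white corner")
    return HistogramEncoding(bin_of_otu=bin_of_otu, colors=colors, phylum_bins=phylum_bins)


def ground_distance(encoding: HistogramEncoding, kind: str = "euclidean") -> np.ndarray:
    """Bin-to-bin transport cost matrix.

    ``euclidean``: distances between bin colors in the RGB cube (default).
    ``uniform``: 1 between distinct bins — degenerates EMD to total
    variation, useful as a sanity oracle.
    """
    if kind == "euclidean":
        return cdist(encoding.colors, encoding.colors)
    if kind == "uniform":
        gd = 1.0 - np.eye(encoding.n_bins)
        return gd
    raise ValueError(f"unknown ground distance kind {kind!r}")


def emd(hist_a, hist_b, gd: np.ndarray) -> float:
    """Exact Earth Mover's Distance between two normalized bin histograms.

    Solves the transportation LP min sum f_ij gd_ij subject to marginal
    constraints; no entropic approximation.
    """
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("histograms must be 1-D and of equal length")
    if abs(a.sum() - 1) > 1e-8 or abs(b.sum() - 1) > 1e-8:
        raise ValueError("histograms must each sum to 1")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("histograms must be non-negative")
    n = len(a)
    if gd.shape != (n, n):
        raise ValueError("ground distance shape does not match histograms")
    # restrict to bins with mass in either histogram
    support = (a > 0) | (b > 0)
    a, b, gd = a[support], b[support], gd[np.ix_(support, support)]
    m = len(a)
    if m == 1:
        return 0.0
    rows = []
    cols = []
    for i in range(m):  # row-sum constraints
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
    for j in range(m - 1):  # col-sum constraints (last one redundant)
        rows.extend([m + j] * m)
        cols.extend(range(j, m * m, m))
    data = np.ones(len(rows))
    a_eq = csr_matrix((data, (rows, cols)), shape=(2 * m - 1, m * m))
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(gd.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return max(float(res.fun), 0.0)


# ---------------------------------------------------------------------------
# Distance matrices


def distance_matrix(
    table: OtuTable,
    metric: str,
    tree: PhyloTree | None = None,
    taxonomy: TaxonomyMap | None = None,
    encoding: HistogramEncoding | None = None,
    n_bins: int | None = None,
    gd_kind: str = "euclidean",
) -> DistanceMatrix:
    """All-pairs beta-diversity matrix (n(n-1)/2 unordered pairs).

    ``metric`` is ``"wunifrac"`` (requires ``tree``) or ``"emd"`` (requires
    ``taxonomy`` or a prebuilt ``encoding``).
    """
    if metric == "wunifrac":
        if tree is None:
            raise ValueError("weighted UniFrac requires a tree")
        values = _unifrac_matrix(table, tree)
    elif metric == "emd":
        if encoding is None:
            if taxonomy is None:
                raise ValueError("EMD requires a taxonomy or a prebuilt encoding")
            encoding = build_histogram_encoding(table, taxonomy, n_bins)
        gd = ground_distance(encoding, gd_kind)
        hists = np.vstack(
            [encoding.bin_profile(table.counts[i], table.otu_ids) for i in range(table.n_samples)]
        )
        n = table.n_samples
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = emd(hists[i], hists[j], gd)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(table.sample_ids, values)


def saturation_summary(dm: DistanceMatrix, threshold: float):
    """(mean, sd, count_above, fraction_above) over the upper triangle.

    ``count_above`` counts values strictly greater than ``threshold``;
    the sd uses n-1 degrees of freedom.
    """
    if dm.n < 2:
        raise ValueError("need at least 2 samples")
    vals = dm.condensed()
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    count_above = int((vals > threshold).sum())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return (float(vals.mean()), sd, count_above, count_above / len(vals))
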