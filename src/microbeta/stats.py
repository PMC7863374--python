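"""Group-comparison and enrichment statistics.

ANOSIM, Mann-Whitney on pairwise distance values, phylum-level enrichment of
a top-ranked OTU set against its background, chi-square goodness-of-fit,
fold-enrichment and Spearman correlation.

Caveat (documented by design): feeding pairwise distance values to
Mann-Whitney violates its independence assumption; the operation mirrors a
common usage pattern and callers should treat the p-value as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import DistanceMatrix, TaxonomyMap, UNCLASSIFIED_PHYLUM

__all__ = [
    "anosim",
    "mann_whitney",
    "EnrichmentTable",
    "phylum_enrichment",
    "chisq_gof",
    "fold_enrichment",
    "FoldEnrichment",
    "spearman",
    "DEFAULT_DISPLAY_PHYLA",
]

DEFAULT_DISPLAY_PHYLA = (
    UNCLASSIFIED_PHYLUM,
    "Actinobacteria",
    "Firmicutes",
    "Proteobacteria",
    "Bacteroidetes",
)
OTHER = "other"


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None):
    """ANOSIM R and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and midranks over all pairwise distances; p is one-sided
    (R_perm >= R_obs) with the add-one estimator.
    """
    groups = np.asarray(list(groups))
    n = dm.n
    if len(groups) != n:
        raise ValueError("group labels do not match matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")
    ranks = sps.rankdata(dm.condensed())
    m = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(g):
        within = g[iu] == g[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    r_obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(groups[rng.permutation(n)]) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray):
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return u1, ranks


_EXACT_LIMIT = 20  # pooled size up to which the exact null is enumerated


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact enumeration of all C(n+m, n) rank assignments when n+m <= 20,
    otherwise a tie-corrected normal approximation with continuity
    correction.  Returns (U, p) with U the first sample's statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u1, ranks = _u_statistic(x, y)
    mu = n1 * n2 / 2
    if n1 + n2 <= _EXACT_LIMIT:
        dev = abs(u1 - mu)
        total = comb(n1 + n2, n1)
        hits = 0
        offset = n1 * (n1 + 1) / 2
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return float(u1), 1.0
        z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
        p = 2 * sps.norm.sf(max(z, 0.0))
    return float(u1), float(min(p, 1.0))


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-phylum counts and percentages for a top OTU set vs its background.

    ``df`` rows are the display phyla plus "other" and a "sum" row; integer
    display percentages are carried alongside full-precision ones.
    """

    df: pd.DataFrame
    k: int
    n_background: int

    def row(self, phylum: str) -> pd.Series:
        if phylum not in self.df.index:
            raise KeyError(f"phylum {phylum!r} not in enrichment table")
        return self.df.loc[phylum]


def phylum_enrichment(
    top_otus,
    all_otus,
    taxonomy: TaxonomyMap,
    display_phyla=DEFAULT_DISPLAY_PHYLA,
) -> EnrichmentTable:
    """Tally phylum membership of a top OTU set against the full background.

    Phyla outside ``display_phyla`` are collapsed into "other"; OTUs without
    a taxonomy entry count as "unclassified bacteria".
    """
    top = list(top_otus)
    background = list(all_otus)
    extra = set(top) - set(background)
    if extra:
        raise ValueError(f"top OTUs not present in background: {sorted(extra)[:5]}")

    def tally(otus):
        counts = dict.fromkeys(list(display_phyla) + [OTHER], 0)
        for otu in otus:
            ph = taxonomy.phylum(otu)
            counts[ph if ph in counts else OTHER] += 1
        return counts

    obs = tally(top)
    bg = tally(background)
    k, n_bg = len(top), len(background)
    rows = []
    for ph in list(display_phyla) + [OTHER]:
        rows.append(
            {
                "phylum": ph,
                "observed": obs[ph],
                "observed_pct": 100.0 * obs[ph] / k if k else 0.0,
                "observed_pct_display": round(100.0 * obs[ph] / k) if k else 0,
                "background": bg[ph],
                "background_pct": 100.0 * bg[ph] / n_bg,
                "background_pct_display": round(100.0 * bg[ph] / n_bg),
            }
        )
    df = pd.DataFrame(rows).set_index("phylum")
    total = df.sum()
    total.name = "sum"
    df = pd.concat([df, total.to_frame().T])
    return EnrichmentTable(df=df, k=k, n_background=n_bg)


def chisq_gof(observed, expected_proportions):
    """Chi-square goodness of fit: chi2 = sum (O-E)^2/E with E = N p.

    Categories with E = 0 and O = 0 are dropped; E = 0 with O > 0 is an
    error.  Returns (chi2, df, p).
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected proportions differ in length")
    if obs.sum() < 1:
        raise ValueError("observed counts must sum to at least 1")
    if abs(props.sum() - 1) > 1e-9:
        raise ValueError(f"expected proportions sum to {props.sum()!r}, not 1")
    if (props < 0).any():
        raise ValueError("expected proportions must be non-negative")
    expected = obs.sum() * props
    impossible = (expected == 0) & (obs > 0)
    if impossible.any():
        raise ValueError(
            f"categories {np.flatnonzero(impossible).tolist()} have zero expected "
            "count but positive observations"
        )
    keep = expected > 0
    obs, expected = obs[keep], expected[keep]
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass(frozen=True)
class FoldEnrichment:
    rounded: float  # ratio of integer-rounded display percentages
    exact: float  # ratio of full-precision percentages


def fold_enrichment(enrichment: EnrichmentTable, phylum: str) -> FoldEnrichment:
    """Observed / background percentage ratio for one phylum.

    Reported both on the integer-rounded display percentages (the printed-
    table convention) and at full precision.
    """
    row = enrichment.row(phylum)
    if row["background"] <= 0 or row["background_pct_display"] <= 0:
        raise ValueError(f"fold-enrichment undefined: background for {phylum!r} is zero")
    return FoldEnrichment(
        rounded=float(row["observed_pct_display"] / row["background_pct_display"]),
        exact=float(row["observed_pct"] / row["background_pct"]),
    )


def spearman(x, y):
    """Spearman rank correlation with midranks; two-sided p via the t
    approximation.  Returns (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho, p
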