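"""Unconstrained (PCoA) and partial constrained ordination.

The constrained analysis follows the literal data treatment of the study
design it supports: OTU abundances are Z-score normalized, a covariate block
(e.g. host-species dummies) is partialled out of both the response matrix
and the single quantitative constraint by least squares, the constrained
axis is the projection of the residualized responses on the residualized
constraint, and significance comes from a permutation pseudo-F with the
add-one estimator.  Despite the "CCA" label often attached to this design,
Z-scored responses make it a linear (redundancy-style) constrained
ordination; that is what is implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DistanceMatrix, OtuTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "PcoaResult",
    "ConstrainedOrdinationResult",
    "pcoa",
    "partial_constrained_ordination",
    "fite_ranking",
    "species_dummies",
]

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class PcoaResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal Coordinates Analysis by Gower double-centering.

    G = -1/2 J D^2 J is eigendecomposed; axes with non-positive eigenvalues
    are discarded (their count is logged) and coordinates are eigenvectors
    scaled by sqrt(eigenvalue).
    """
    n = dm.n
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    if n_axes is not None:
        if n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        if n_axes > n - 1:
            raise ValueError(f"n_axes={n_axes} exceeds the maximum of n-1={n - 1}")
    d2 = dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    positive = eigvals > _EIG_TOL * scale
    n_neg = int((eigvals < -_EIG_TOL * scale).sum())
    if n_neg:
        logger.info("pcoa: discarded %d negative-eigenvalue axes", n_neg)
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    prop = pos_vals / pos_vals.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pos_vals = pos_vals[:n_axes]
        prop = prop[:n_axes]
    return PcoaResult(
        sample_ids=dm.ids,
        coordinates=coords,
        eigenvalues=pos_vals,
        proportion_explained=prop,
        n_negative_eigenvalues=n_neg,
    )


@dataclass(frozen=True)
class ConstrainedOrdinationResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    constrained_axis: np.ndarray  # per-sample scores along the residualized constraint
    fite: dict  # otu_id -> percent variance explained, [0, 100]
    sample_ids: tuple[str, ...]
    dropped_otus: tuple[str, ...] = field(default=())


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_constrained_ordination(
    table: OtuTable,
    constraint,
    covariates: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> ConstrainedOrdinationResult:
    """Test a single quantitative constraint against an OTU table, partialling
    out a covariate block.

    Steps: Z-score each OTU column; residualize responses and constraint on
    [intercept | covariates]; fit the constrained axis; pseudo-F =
    (SS_constrained / 1) / (SS_residual / (n - 1 - c - 1)) with c covariate
    columns; p-value from ``n_perm`` permutations of the residualized
    constraint, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    Per-OTU FitE is the percent of that (residualized) OTU's variance
    explained by the constrained axis.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(constraint, dtype=float)
    n = table.n_samples
    if x.shape != (n,):
        raise ValueError(f"constraint length {x.shape} does not match {n} samples")

    counts = table.counts.astype(float)
    sd = counts.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(o for o, k in zip(table.otu_ids, keep) if not k)
    if dropped:
        logger.warning(
            "dropping %d constant OTU columns (no variance to explain)", len(dropped)
        )
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    z = (counts[:, keep] - counts[:, keep].mean(axis=0)) / sd[keep]

    design = np.ones((n, 1))
    c = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match samples")
        design = np.hstack([design, cov])
        c = np.linalg.matrix_rank(design) - 1

    y_res = _residualize(z, design)
    x_res = _residualize(x[:, None], design).ravel()
    x_norm2 = float(x_res @ x_res)
    if x_norm2 < 1e-12 * max(1.0, float(x @ x)):
        raise ValueError("constraint is constant after residualization; nothing to test")

    df_resid = n - 1 - c - 1
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")

    proj = x_res @ y_res  # 1 x p
    ss_fit = float((proj**2).sum() / x_norm2)
    ss_tot = float((y_res**2).sum())
    f_obs = (ss_fit / 1.0) / ((ss_tot - ss_fit) / df_resid)

    col_ss = (y_res**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fite_vals = 100.0 * (proj**2 / x_norm2) / col_ss
    fite_vals = np.nan_to_num(fite_vals, nan=0.0)
    fite = {o: float(v) for o, v in zip(otu_ids, fite_vals)}

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    xp = x_res[perm_idx]  # n_perm x n
    # Each permuted constraint must be re-residualized on the design.  Y_res
    # is orthogonal to the design already, so only the squared norm changes:
    # ||R xp||^2 = ||xp||^2 - ||Q^T xp||^2 with Q an orthonormal design basis.
    q, _ = np.linalg.qr(design)
    xp_norm2 = x_norm2 - ((xp @ q) ** 2).sum(axis=1)
    xp_norm2 = np.maximum(xp_norm2, 1e-30)
    ss_fit_perm = ((xp @ y_res) ** 2).sum(axis=1) / xp_norm2
    f_perm = ss_fit_perm / ((ss_tot - ss_fit_perm) / df_resid)
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)

    axis = (x_res - x_res.mean()) / x_res.std(ddof=1)
    return ConstrainedOrdinationResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        constrained_axis=axis,
        fite=fite,
        sample_ids=table.sample_ids,
        dropped_otus=dropped,
    )


def fite_ranking(result: ConstrainedOrdinationResult, k: int) -> list[str]:
    """Top-k OTU ids by FitE, descending; ties broken lexicographically."""
    if k > len(result.fite):
        raise ValueError(f"k={k} exceeds the {len(result.fite)} scored OTUs")
    ranked = sorted(result.fite.items(), key=lambda kv: (-kv[1], kv[0]))
    vals = [v for _, v in ranked]
    if k and vals.count(vals[k - 1]) > 1:
        logger.info("fite_ranking: tie at rank %d broken by OTU id", k)
    return [o for o, _ in ranked[:k]]


def species_dummies(meta: SampleMetadata, sample_ids, column: str = "species_code") -> np.ndarray:
    """Treatment-coded dummy matrix with the most frequent level as reference."""
    levels = pd.Series(meta.column(column, sample_ids))
    counts = levels.value_counts()
    reference = counts.index[0]
    others = [lv for lv in counts.index if lv != reference]
    return np.column_stack([(levels == lv).to_numpy(float) for lv in others]) if others else np.zeros((len(levels), 0))
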