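"""Signed weighted co-expression networks.

A network is built per condition from the Pearson correlation matrix of
gene expression profiles, soft-thresholded into a signed adjacency

    a_ij = ((1 + cor(i, j)) / 2) ** beta

so that anti-correlated genes receive near-zero connection strength.  The
power ``beta`` is the smallest integer for which the connectivity
distribution approximates scale-free topology (log-log regression R^2
above a cutoff, conventionally 0.8, with a negative slope).  The
topological overlap matrix (TOM) then augments direct adjacency with
shared-neighbour agreement; 1 - TOM is the clustering dissimilarity.

Matrices are dense numpy arrays; the intended scale is up to ~20,000
genes, and no operation holds more than a few n x n matrices at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoexpressionNetwork",
    "SoftThresholdScan",
    "correlation_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "tom_dissimilarity",
    "build_network",
]

logger = logging.getLogger(__name__)


@dataclass
class SoftThresholdScan:
    """Scale-free fit diagnostics over a ladder of candidate powers."""

    betas: list[int]
    r_squared: list[float]
    slopes: list[float]
    mean_connectivity: list[float]
    chosen: int
    criterion_met: bool  # False when no beta passed and the argmax fallback was used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas,
                "r_squared": self.r_squared,
                "slope": self.slopes,
                "mean_k": self.mean_connectivity,
            }
        )


@dataclass
class CoexpressionNetwork:
    """One condition's correlation, signed adjacency and TOM, plus the power used."""

    gene_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    beta: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes) -> np.ndarray:
        pos = getattr(self, "_pos", None)
        if pos is None:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_pos", pos)
        return np.array([pos[g] for g in genes], dtype=int)


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between gene expression profiles.

    Requires >= 3 samples and positive per-gene variance; the result is
    symmetrized by averaging with its transpose and has an exact unit
    diagonal.
    """
    x = expr.to_numpy(float)
    if x.shape[1] < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {x.shape[1]}")
    sd = x.std(axis=1)
    bad = np.where(sd == 0)[0]
    if len(bad):
        names = list(expr.index[bad[:10]])
        raise ValueError(f"zero-variance gene(s): {names}")
    c = np.corrcoef(x)
    c = (c + c.T) / 2.0
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def signed_adjacency(correlation: np.ndarray, beta: int) -> np.ndarray:
    """Elementwise ((1 + cor) / 2) ** beta."""
    if not float(beta).is_integer() or beta < 1:
        raise ValueError(f"beta must be a positive integer, got {beta}")
    a = ((1.0 + correlation) / 2.0) ** int(beta)
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit (R^2, slope) of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    frequency of each occupied bin is regressed on the log10 mean
    connectivity of that bin.
    """
    k = connectivity(adjacency)
    if np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity distribution (all k identical)")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    n = len(k)
    for b in range(n_bins):
        mask = which == b
        cnt = mask.sum()
        if cnt == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_f.append(np.log10(cnt / n))
    if len(log_k) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    res = stats.linregress(log_k, log_f)
    return float(res.rvalue**2), float(res.slope)


def pick_soft_threshold(
    correlation: np.ndarray,
    candidate_betas=tuple(range(1, 21)),
    r2_cut: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, SoftThresholdScan]:
    """Smallest power with scale-free fit R^2 > r2_cut and a negative slope.

    Falls back to the power maximizing R^2 (with a warning and
    ``criterion_met=False``) when no candidate qualifies.
    """
    betas = sorted(int(b) for b in candidate_betas)
    if not betas:
        raise ValueError("candidate_betas must be nonempty")
    r2s, slopes, mean_ks = [], [], []
    chosen = None
    for b in betas:
        a = signed_adjacency(correlation, b)
        try:
            r2, slope = scale_free_fit(a, n_bins=n_bins)
        except ValueError:
            r2, slope = np.nan, np.nan
        r2s.append(r2)
        slopes.append(slope)
        mean_ks.append(float(connectivity(a).mean()))
        if chosen is None and np.isfinite(r2) and r2 > r2_cut and slope < 0:
            chosen = b
    criterion_met = chosen is not None
    if chosen is None:
        finite = [(r, b) for r, b in zip(r2s, betas) if np.isfinite(r)]
        if not finite:
            raise ValueError("scale-free fit failed for every candidate beta")
        chosen = max(finite)[1]
        logger.warning(
            "WARN no candidate beta reached R^2 > %.2f; falling back to argmax beta=%d",
            r2_cut,
            chosen,
        )
    scan = SoftThresholdScan(betas, r2s, slopes, mean_ks, chosen, criterion_met)
    return chosen, scan


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a nonnegative symmetric adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), i != j, with
    L_ij = sum_{u != i,j} a_iu a_uj and k the connectivity; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    L = a0 @ a0  # L_ij includes no u==i or u==j terms since diag(a0)=0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a0) / denom
    tom = np.where(denom > 0, tom, 0.0)
    tom = (tom + tom.T) / 2.0
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_dissimilarity(tom: np.ndarray) -> np.ndarray:
    """1 - TOM, with an exact zero diagonal."""
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    return d


def build_network(
    expr: pd.DataFrame,
    beta: int | None = None,
    candidate_betas=tuple(range(1, 21)),
    r2_cut: float = 0.8,
) -> tuple[CoexpressionNetwork, SoftThresholdScan | None]:
    """Correlation -> soft threshold -> adjacency -> TOM for one condition.

    When ``beta`` is given the scale-free scan is skipped (used to share
    the reference condition's power with the test condition).
    """
    cor = correlation_matrix(expr)
    scan = None
    if beta is None:
        beta, scan = pick_soft_threshold(cor, candidate_betas, r2_cut)
    adj = signed_adjacency(cor, beta)
    tom = topological_overlap(adj)
    net = CoexpressionNetwork(
        gene_ids=list(expr.index), correlation=cor, adjacency=adj, tom=tom, beta=int(beta)
    )
    return net, scan
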