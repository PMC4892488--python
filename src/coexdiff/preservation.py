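"""Permutation-based module preservation between two co-expression networks.

For every module defined in the reference network, preservation in the
test network is quantified by two families of statistics:

* density — does the module stay densely connected in the test network?
  (mean within-module adjacency, mean within-module correlation,
  eigengene variance explained, all computed in the test condition)
* connectivity — does the wiring pattern persist?  (correlation between
  reference and test intramodular connectivity vectors, between
  vectorized within-module adjacencies, and between correlations)

Each observed statistic is standardized against its permutation null —
random gene sets of the same size drawn from the network's gene universe
— giving a Z score.  Z_density and Z_connectivity are the medians of
their families, and

    Z_summary = (Z_density + Z_connectivity) / 2.

Conventional calibration: Z_summary < 2 -> no evidence of preservation,
2..10 -> weak to moderate, > 10 -> strong.  Disease-module screening
selects *weakly* preserved modules (Z_summary below a cutoff, typically
5), excluding the artificial "grey" (unassigned) and "gold" (random
calibration sample) modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modules import ModulePartition, _first_pc, standardize
from .network import CoexpressionNetwork

__all__ = [
    "DENSITY_STATS",
    "CONNECTIVITY_STATS",
    "PreservationReport",
    "density_statistics",
    "connectivity_statistics",
    "permutation_null",
    "z_scores",
    "z_summary",
    "classify_preservation",
    "module_preservation",
    "select_weak_modules",
]

logger = logging.getLogger(__name__)

DENSITY_STATS = ("meanAdj", "meanCor", "propVarExplained")
CONNECTIVITY_STATS = ("cor_kIM", "cor_adj", "cor_cor")


def _offdiag_mean(sub: np.ndarray) -> float:
    m = sub.shape[0]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def density_statistics(
    module_genes, network: CoexpressionNetwork, expr: pd.DataFrame
) -> dict[str, float]:
    """Within-module density of a gene set inside one network/condition."""
    genes = list(module_genes)
    if len(genes) < 3:
        raise ValueError(f"module must have >= 3 genes, got {len(genes)}")
    idx = network.index_of(genes)
    adj = network.adjacency[np.ix_(idx, idx)]
    cor = network.correlation[np.ix_(idx, idx)]
    xs = standardize(expr.loc[genes]).to_numpy()
    _, var = _first_pc(xs)
    return {
        "meanAdj": _offdiag_mean(adj),
        "meanCor": _offdiag_mean(cor),
        "propVarExplained": var,
    }


def _safe_cor(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation; (0, degenerate=True) for constant vectors."""
    if x.std() == 0 or y.std() == 0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def connectivity_statistics(
    module_genes, reference: CoexpressionNetwork, test: CoexpressionNetwork
) -> dict[str, float]:
    """Cross-network agreement of within-module wiring for one gene set."""
    genes = list(module_genes)
    if len(genes) < 3:
        raise ValueError(f"module must have >= 3 genes, got {len(genes)}")
    ri = reference.index_of(genes)
    ti = test.index_of(genes)
    a_ref = reference.adjacency[np.ix_(ri, ri)]
    a_test = test.adjacency[np.ix_(ti, ti)]
    c_ref = reference.correlation[np.ix_(ri, ri)]
    c_test = test.correlation[np.ix_(ti, ti)]
    m = len(genes)
    k_ref = a_ref.sum(axis=1) - np.diag(a_ref)
    k_test = a_test.sum(axis=1) - np.diag(a_test)
    iu = np.triu_indices(m, k=1)
    out = {}
    for name, (x, y) in {
        "cor_kIM": (k_ref, k_test),
        "cor_adj": (a_ref[iu], a_test[iu]),
        "cor_cor": (c_ref[iu], c_test[iu]),
    }.items():
        val, _ = _safe_cor(x, y)
        out[name] = val
    return out


def permutation_null(
    module_size: int, network_genes, n_perm: int, seed: int
) -> list[list[str]]:
    """n_perm uniformly drawn gene sets of the given size, reproducibly."""
    universe = list(network_genes)
    if module_size > len(universe):
        raise ValueError(
            f"module_size {module_size} exceeds universe of {len(universe)} genes"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        [universe[i] for i in rng.choice(len(universe), size=module_size, replace=False)]
        for _ in range(n_perm)
    ]


def z_scores(
    observed: dict[str, float], null_values: dict[str, np.ndarray]
) -> tuple[dict[str, float], dict[str, bool]]:
    """Per-statistic Z = (observed - mean(null)) / sd(null).

    A constant null carries no calibration: the Z is a +/-inf sentinel
    when the observed value differs from the null, and NaN (undefined,
    excluded from downstream medians) when it coincides with it — e.g.
    cross-network wiring correlations when test == reference are 1 for
    every gene set.  Both cases are flagged degenerate.
    """
    zs, degenerate = {}, {}
    for name, obs in observed.items():
        null = np.asarray(null_values[name], dtype=float)
        if null.size == 0:
            raise ValueError(f"empty null for statistic {name!r}")
        mu = null.mean()
        sd = null.std(ddof=1) if null.size > 1 else 0.0
        if sd <= 1e-12:  # constant null up to floating-point noise
            degenerate[name] = True
            if abs(obs - mu) <= 1e-9:
                zs[name] = np.nan
            else:
                zs[name] = np.inf if obs > mu else -np.inf
        else:
            degenerate[name] = False
            zs[name] = float((obs - mu) / sd)
    return zs, degenerate


def z_summary(z_density_values, z_connectivity_values) -> tuple[float, float, float]:
    """Median-combine each family, then average the two medians."""
    zd = float(np.median(list(z_density_values)))
    zc = float(np.median(list(z_connectivity_values)))
    return zd, zc, (zd + zc) / 2.0


def classify_preservation(z: float) -> str:
    """Category per the conventional thresholds (boundaries fall low)."""
    if z <= 2:
        return "none"
    if z <= 10:
        return "weak-to-moderate"
    return "strong"


@dataclass
class ModulePreservation:
    module: int
    color: str
    size: int
    z_density: float
    z_connectivity: float
    z_summary: float
    category: str
    observed: dict[str, float] = field(default_factory=dict)
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    artificial: bool = False  # grey / gold calibration modules


@dataclass
class PreservationReport:
    """Per-module preservation summary (Table-1 style)."""

    rows: list[ModulePreservation]
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "module": r.module,
                    "color": r.color,
                    "size": r.size,
                    "z_density": r.z_density,
                    "z_connectivity": r.z_connectivity,
                    "z_summary": r.z_summary,
                    "category": r.category,
                    "artificial": r.artificial,
                }
                for r in self.rows
            ]
        ).sort_values("z_summary", ascending=False, kind="stable").reset_index(drop=True)


GOLD_LABEL = -1
GREY_LABEL = 0


def module_preservation(
    reference: CoexpressionNetwork,
    test: CoexpressionNetwork,
    test_expr: pd.DataFrame,
    partition: ModulePartition,
    n_perm: int = 200,
    seed: int = 0,
    include_gold: bool = True,
    include_grey: bool = True,
) -> PreservationReport:
    """Permutation Z preservation of every reference module in the test network.

    The null draws random gene sets of matching size from the shared gene
    universe and recomputes every statistic per draw.  A "gold" module (a
    random sample of min(1000, n/5) genes) is appended for calibration
    when ``include_gold``; grey collects the unassigned genes.  Both are
    marked artificial and never selected as disease modules.
    """
    if n_perm < 20:
        logger.warning("WARN preservation run with n_perm=%d (< 20); Z unstable", n_perm)
    test_genes = set(test.gene_ids)
    universe = [g for g in reference.gene_ids if g in test_genes]
    universe_set = set(universe)
    rng = np.random.default_rng(seed)

    jobs: list[tuple[int, list[str], bool]] = []
    for m in partition.module_ids:
        genes = [g for g in partition.genes_in(m) if g in universe_set]
        if len(genes) >= 3:
            jobs.append((m, genes, False))
    if include_grey:
        grey = [g for g in np.array(partition.gene_ids)[partition.labels == 0]]
        grey = [g for g in grey if g in universe_set]
        if len(grey) >= 3:
            jobs.append((GREY_LABEL, grey, True))
    if include_gold:
        gold_size = min(1000, max(3, len(universe) // 5))
        gold = [universe[i] for i in rng.choice(len(universe), gold_size, replace=False)]
        jobs.append((GOLD_LABEL, gold, True))

    # vectorized internals: one standardized test-expression array plus
    # integer gene indices per network (identical public statistics)
    x = test_expr.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        bad = list(test_expr.index[sd[:, 0] == 0][:10])
        raise ValueError(f"zero-variance gene(s) in test expression: {bad}")
    xs_test = (x - mu) / sd
    expr_row = {g: i for i, g in enumerate(test_expr.index)}
    uni_expr = np.array([expr_row[g] for g in universe])
    uni_ref = reference.index_of(universe)
    uni_test = test.index_of(universe)

    def stats_at(pos: np.ndarray) -> dict[str, float]:
        """All six statistics for universe positions ``pos``."""
        ti = uni_test[pos]
        ri = uni_ref[pos]
        a_test = test.adjacency[np.ix_(ti, ti)]
        c_test = test.correlation[np.ix_(ti, ti)]
        a_ref = reference.adjacency[np.ix_(ri, ri)]
        c_ref = reference.correlation[np.ix_(ri, ri)]
        _, var = _first_pc(xs_test[uni_expr[pos]])
        k_ref = a_ref.sum(axis=1) - np.diag(a_ref)
        k_test = a_test.sum(axis=1) - np.diag(a_test)
        iu = np.triu_indices(len(pos), k=1)
        out = {
            "meanAdj": _offdiag_mean(a_test),
            "meanCor": _offdiag_mean(c_test),
            "propVarExplained": var,
        }
        for name, (u, v) in {
            "cor_kIM": (k_ref, k_test),
            "cor_adj": (a_ref[iu], a_test[iu]),
            "cor_cor": (c_ref[iu], c_test[iu]),
        }.items():
            out[name], _ = _safe_cor(u, v)
        return out

    uni_pos = {g: i for i, g in enumerate(universe)}
    rows = []
    for m, genes, artificial in jobs:
        obs = stats_at(np.array([uni_pos[g] for g in genes]))
        null = {name: np.empty(n_perm) for name in obs}
        draw_rng = np.random.default_rng(int(rng.integers(2**31)))
        for p in range(n_perm):
            pos = draw_rng.choice(len(universe), size=len(genes), replace=False)
            for name, v in stats_at(pos).items():
                null[name][p] = v
        zs, degen = z_scores(obs, null)
        zd_vals = [zs[s] for s in DENSITY_STATS if not np.isnan(zs[s])]
        zc_vals = [zs[s] for s in CONNECTIVITY_STATS if not np.isnan(zs[s])]
        zd = float(np.median(zd_vals)) if zd_vals else np.nan
        zc = float(np.median(zc_vals)) if zc_vals else np.nan
        comps = [c for c in (zd, zc) if not np.isnan(c)]
        zsum = float(np.mean(comps)) if comps else np.nan
        if np.isfinite(zsum):
            category = classify_preservation(zsum)
        elif zsum == np.inf:
            category = "strong"
        else:
            category = "none"
        color = {GREY_LABEL: "grey", GOLD_LABEL: "gold"}.get(m, partition.color_of(m))
        rows.append(
            ModulePreservation(
                module=m,
                color=color,
                size=len(genes),
                z_density=zd,
                z_connectivity=zc,
                z_summary=zsum,
                category=category,
                observed=obs,
                null_mean={k: float(v.mean()) for k, v in null.items()},
                null_sd={k: float(v.std(ddof=1)) for k, v in null.items()},
                degenerate=any(degen.values()),
                artificial=artificial,
            )
        )
    return PreservationReport(rows=rows, n_perm=n_perm, seed=seed)


def select_weak_modules(report: PreservationReport, cutoff: float = 5.0) -> list[int]:
    """Modules with z_summary < cutoff, excluding grey/gold, ascending by z."""
    cand = [
        r for r in report.rows if not r.artificial and np.isfinite(r.z_summary)
        and r.z_summary < cutoff
    ]
    cand.sort(key=lambda r: r.z_summary)
    return [r.module for r in cand]
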