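"""Module partitions, color naming, eigengenes and module membership.

A module's *eigengene* is the first principal component of its
standardized (per gene: zero mean, unit variance, population
denominator) expression submatrix — a single per-sample vector
summarizing the module's behaviour.  *kME* (eigengene-based
connectivity, module membership) is the Pearson correlation of a gene's
profile with a module eigengene.  Modules are named by the conventional
color sequence ("turquoise", "blue", ...) in decreasing size order, with
"grey" reserved for unassigned genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_COLORS",
    "ModulePartition",
    "assign_colors",
    "module_eigengenes",
    "EigengeneSet",
    "kme",
    "merge_similar_modules",
]

#: conventional module color sequence, assigned by decreasing module size
STANDARD_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lavenderblush3",
    "honeydew1", "darkseagreen4", "coral1", "antiquewhite4",
]


@dataclass
class ModulePartition:
    """Gene -> module assignment (label 0 = unassigned = "grey")."""

    gene_ids: list[str]
    labels: np.ndarray  # int labels aligned to gene_ids; 0 = unassigned
    colors: dict[int, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.gene_ids):
            raise ValueError("labels and gene_ids length mismatch")

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in np.unique(self.labels) if m != 0)

    def module_sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def genes_in(self, module: int) -> list[str]:
        idx = np.where(self.labels == module)[0]
        return [self.gene_ids[i] for i in idx]

    def color_of(self, module: int) -> str:
        if module == 0:
            return "grey"
        return self.colors.get(module, f"module_{module}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "module": self.labels,
                "color": [self.color_of(m) for m in self.labels],
            }
        ).set_index("gene_id")


def assign_colors(partition: ModulePartition) -> ModulePartition:
    """Name modules by decreasing size from the standard color sequence.

    Ties in size break by module label; overflow past the color list
    falls back to "module_<k>".  Label 0 is always "grey".
    """
    sizes = partition.module_sizes()
    ordered = sorted(sizes, key=lambda m: (-sizes[m], m))
    colors = {}
    for i, m in enumerate(ordered):
        colors[m] = STANDARD_COLORS[i] if i < len(STANDARD_COLORS) else f"module_{m}"
    partition.colors = colors
    return partition


def standardize(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene zero mean, unit variance (population denominator)."""
    x = expr.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        bad = list(expr.index[(sd[:, 0] == 0)][:10])
        raise ValueError(f"zero-variance gene(s): {bad}")
    return pd.DataFrame((x - mu) / sd, index=expr.index, columns=expr.columns)


@dataclass
class EigengeneSet:
    """Per-module eigengene vectors (samples x modules) and variance explained."""

    eigengenes: pd.DataFrame        # index = sample ids, columns = module labels
    var_explained: dict[int, float]

    @property
    def module_ids(self) -> list[int]:
        return list(self.eigengenes.columns)


def _first_pc(xs: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm first right-singular vector over samples + variance fraction."""
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    v = vt[0]
    var = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return v, var


def module_eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> EigengeneSet:
    """First principal component per module over the standardized expression.

    The eigengene sign is aligned so that its correlation with the mean
    standardized module expression is nonnegative.
    """
    xs = standardize(expr)
    cols, vars_ = {}, {}
    gene_index = {g: i for i, g in enumerate(expr.index)}
    x = xs.to_numpy()
    for m in partition.module_ids:
        genes = partition.genes_in(m)
        rows = [gene_index[g] for g in genes if g in gene_index]
        if not rows:
            raise ValueError(f"module {m} has no genes present in the expression matrix")
        sub = x[rows]
        v, var = _first_pc(sub)
        mean_profile = sub.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        cols[m] = v
        vars_[m] = var
    eig = pd.DataFrame(cols, index=expr.columns)
    return EigengeneSet(eigengenes=eig, var_explained=vars_)


def kme(expr: pd.DataFrame, eigengenes: EigengeneSet) -> pd.DataFrame:
    """Gene x module matrix of correlations with each module eigengene."""
    xs = standardize(expr).to_numpy()
    out = {}
    n = xs.shape[1]
    for m in eigengenes.module_ids:
        e = eigengenes.eigengenes[m].to_numpy()
        ec = e - e.mean()
        denom = np.sqrt((ec**2).sum()) * np.sqrt(n)  # gene rows have unit population variance
        if denom == 0:
            raise ValueError(f"eigengene of module {m} has zero variance")
        out[m] = xs @ ec / denom
    return pd.DataFrame(out, index=expr.index).clip(-1.0, 1.0)


def merge_similar_modules(
    expr: pd.DataFrame,
    partition: ModulePartition,
    dissim_threshold: float = 0.0,
) -> ModulePartition:
    """Iteratively merge modules with similar eigengenes.

    Module pairs whose normalized eigengene dissimilarity
    ``(1 - cor) / 2`` is at or below the threshold merge closest-pair
    first, recomputing eigengenes after every merge.  ``threshold = 0``
    disables merging; ``threshold = 1`` collapses everything into one
    module.
    """
    if not (0.0 <= dissim_threshold <= 1.0):
        raise ValueError("dissim_threshold must be in [0, 1]")
    if dissim_threshold == 0.0 or len(partition.module_ids) < 2:
        return partition
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(partition.gene_ids, labels, params=partition.params)
        mods = part.module_ids
        if len(mods) < 2:
            break
        eig = module_eigengenes(expr, part)
        e = eig.eigengenes[mods].to_numpy()
        c = np.corrcoef(e.T)
        dis = (1.0 - c) / 2.0
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] > dissim_threshold:
            break
        keep, drop = sorted((mods[i], mods[j]))
        labels[labels == drop] = keep
    merged = ModulePartition(partition.gene_ids, labels, params=dict(partition.params))
    return assign_colors(merged)
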