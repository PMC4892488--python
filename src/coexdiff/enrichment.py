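"""Gene-set over-representation analysis for module gene lists.

One-sided hypergeometric tail test of the overlap between a module and
each gene set in a GMT collection, with Benjamini-Hochberg correction
across the sets tested for that module.  Reported hits are filtered to
overlap >= ``min_overlap`` (default 2) and q < ``q_cut`` (default 0.05).
The background universe defaults to the analysis gene set the modules
were drawn from, not the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "hypergeometric_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit background."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {k}: expected >= 3 fields, got {len(fields)}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}: line {k}: duplicate set name {name!r}")
            if len(set(genes)) != len(genes):
                logger.warning("WARN %s line %d: duplicate genes in set %r deduplicated", path, k, name)
            if not genes:
                raise ValueError(f"{path}: line {k}: set {name!r} has no genes")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


@dataclass
class EnrichmentResult:
    set_id: str
    description: str
    overlap: int
    set_size: int
    p_value: float
    q_value: float
    genes: list[str]


def hypergeometric_enrichment(
    module_genes,
    background,
    sets: GeneSetCollection,
    min_overlap: int = 2,
    q_cut: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of each set in the module, BH-corrected.

    p = P(overlap >= observed) under hypergeometric sampling of
    |module| genes from the background; sets are intersected with the
    background first.  Returns hits with overlap >= min_overlap and
    q < q_cut, sorted by p.
    """
    module = set(module_genes)
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    if not module <= bg:
        extra = sorted(module - bg)[:5]
        raise ValueError(f"module genes absent from background: {extra}")
    n_draw = len(module)
    n_bg = len(bg)
    records = []
    for name, members in sets.sets.items():
        inset = members & bg
        if not inset:
            continue
        hits = sorted(module & inset)
        k = len(hits)
        # P(X >= k), X ~ Hypergeom(N=n_bg, K=|inset|, n=n_draw)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(inset), n_draw))
        records.append((name, len(inset), k, min(p, 1.0), hits))
    if not records:
        return []
    pvals = [r[3] for r in records]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            set_id=name,
            description=sets.descriptions.get(name, ""),
            overlap=k,
            set_size=size,
            p_value=p,
            q_value=float(q),
            genes=hits,
        )
        for (name, size, k, p, hits), q in zip(records, qvals)
    ]
    results = [r for r in results if r.overlap >= min_overlap and r.q_value < q_cut]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Table-style frame: set id, name, count, p, q, semicolon-joined genes."""
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "description": r.description,
                "count": r.overlap,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "genes": ";".join(r.genes),
            }
            for r in results
        ]
    )
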