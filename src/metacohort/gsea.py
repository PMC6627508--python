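"""Preranked gene-set enrichment on summary statistics.

Weighted Kolmogorov-Smirnov-style running sum: genes are sorted by the
ranking statistic (a meta-analysis z-score or summary SMD), walking down
the list increments the sum by |stat|^w / sum_hits |stat|^w at set members
(weight w = 1) and decrements by 1/(N - N_hits) elsewhere; the enrichment
score ES is the signed maximal deviation from zero and the leading edge is
the set members up to (or, for negative ES, from) the extremum.
Significance comes from a gene-sampling permutation null with the plus-one
estimator, and NES normalizes ES by the mean magnitude of same-sign nulls.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "EnrichmentResult", "read_gmt", "write_gmt",
           "enrichment_score", "gsea_preranked", "enrichment_frame"]


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT content): name -> ordered unique gene list."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(genes))
            if any(not g for g in deduped):
                raise ValueError(f"gene set {name!r} has empty gene ids")
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclasses.dataclass
class EnrichmentResult:
    name: str
    size: int               # after intersection with the ranked universe
    ES: float
    NES: float
    p: float
    p_adjusted: float
    leading_edge: list[str]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Malformed lines (fewer than three fields) are logged and skipped;
    duplicate genes within a set are collapsed.  An empty file errors.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty GMT file: {path}")
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        fields = line.rstrip("\n").split("\t")
        genes = [g for g in fields[2:] if g]
        if len(fields) < 3 or not genes:
            logger.warning("%s:%d: malformed GMT line skipped (%r)",
                           path.name, ln, line[:40])
            continue
        sets[fields[0]] = genes
    if not sets:
        raise ValueError(f"no parseable gene sets in {path}")
    return GeneSetCollection(sets, source=path.name)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, "na", *genes])
        for name, genes in collection.sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


# ----------------------------------------------------------------------
# running sum
# ----------------------------------------------------------------------

def _rank_genes(ranked: pd.Series | dict, weight: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Sort descending by statistic, gene-id tiebreak; return (ids, |s|^w)."""
    s = pd.Series(ranked, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    s = s.iloc[np.lexsort((s.index.to_numpy(), -s.to_numpy()))]
    return s.index.to_numpy(), np.abs(s.to_numpy()) ** weight


def _es_at_positions(pos: np.ndarray, absw: np.ndarray, N: int
                     ) -> tuple[float, int]:
    """ES and extremum index given sorted hit positions in the ranking.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit (maxima candidates) or just before one (minima
    candidates); both families are scanned in O(set size).
    """
    m = len(pos)
    w = absw[pos]
    total = w.sum()
    w = w / total if total > 0 else np.full(m, 1.0 / m)
    cum = np.cumsum(w)
    dm = 1.0 / (N - m)
    i = np.arange(1, m + 1)
    after = cum - (pos + 1 - i) * dm          # value just after hit i
    before = np.r_[0.0, cum[:-1]] - (pos + 1 - i) * dm  # just before hit i
    hi, lo = after.max(), min(before.min(), 0.0)
    if hi >= -lo:
        return float(hi), int(pos[int(after.argmax())])
    return float(lo), int(pos[int(before.argmin())])


def enrichment_score(ranked: pd.Series | dict, gene_set: list[str],
                     weight: float = 1.0
                     ) -> tuple[float, np.ndarray, list[str]]:
    """ES, the full running sum, and the leading-edge genes for one set.

    ``weight=0`` makes the statistic rank-only (classic KS); the default
    ``weight=1`` weights hits by |statistic|.
    """
    ids, absw = _rank_genes(ranked, weight)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ids), bool, len(ids))
    m = int(hit.sum())
    N = len(ids)
    if m == 0 or m == N:
        raise ValueError("gene set must hit a strict subset of the universe")
    wsum = absw[hit].sum()
    inc = (absw / wsum if wsum > 0 else np.full(N, 1.0 / m))
    steps = np.where(hit, inc, -1.0 / (N - m))
    running = np.cumsum(steps)
    es, ext = _es_at_positions(np.flatnonzero(hit), absw, N)
    if es >= 0:
        leading = [g for g in ids[: ext + 1] if g in members]
    else:
        leading = [g for g in ids[ext:] if g in members]
    return es, running, leading


# ----------------------------------------------------------------------
# permutation significance
# ----------------------------------------------------------------------

def gsea_preranked(ranked: pd.Series | dict, collection: GeneSetCollection,
                   n_perm: int = 10_000, seed: int = 0, min_size: int = 5,
                   max_size: int = 500, weight: float = 1.0
                   ) -> list[EnrichmentResult]:
    """Enrichment of every eligible set, with gene-sampling permutation p.

    For each set the null is built from ``n_perm`` random same-size gene
    samples of the universe; p uses the plus-one estimator over same-sign
    nulls (so p >= 1/(n_perm+1)) and NES divides ES by the mean |null ES|
    of the same sign.  Deterministic for a fixed seed; Benjamini-Hochberg
    adjustment across the reported sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids, absw = _rank_genes(ranked, weight)
    N = len(ids)
    pos_of = {g: i for i, g in enumerate(ids)}
    rng = np.random.default_rng(seed)

    rows: list[tuple[str, int, float, list[str]]] = []
    sizes_needed: set[int] = set()
    for name, genes in collection.sets.items():
        pos = np.sort([pos_of[g] for g in genes if g in pos_of])
        if not (min_size <= len(pos) <= max_size) or len(pos) == N:
            logger.info("set %s skipped (size %d outside [%d, %d])",
                        name, len(pos), min_size, max_size)
            continue
        es, _run, leading = enrichment_score(
            pd.Series(ranked), [g for g in genes if g in pos_of], weight)
        rows.append((name, len(pos), es, leading))
        sizes_needed.add(len(pos))

    # one shared null per set size (sets of equal size share a null law);
    # when every same-size subset can be enumerated within the permutation
    # budget, the null is exhaustive rather than sampled
    nulls: dict[int, np.ndarray] = {}
    for m in sorted(sizes_needed):
        if math.comb(N, m) <= n_perm:
            combos = itertools.combinations(range(N), m)
            null = np.array([
                _es_at_positions(np.asarray(c), absw, N)[0] for c in combos
            ])
        else:
            null = np.empty(n_perm)
            for j in range(n_perm):
                p = np.sort(rng.choice(N, m, replace=False))
                null[j], _ = _es_at_positions(p, absw, N)
        nulls[m] = null

    results = []
    pvals = []
    for name, size, es, leading in rows:
        null = nulls[size]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = len(same)
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + n_same)
        denom = np.abs(same).mean() if n_same else np.nan
        nes = es / denom if n_same else np.nan
        pvals.append(p)
        results.append(EnrichmentResult(name, size, es, float(nes),
                                        float(p), np.nan, leading))
    if results:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Results as the TSV layout (leading edge comma-joined)."""
    return pd.DataFrame([
        {"set": r.name, "size": r.size, "ES": r.ES, "NES": r.NES,
         "p": r.p, "p_BH": r.p_adjusted,
         "leading_edge": ",".join(r.leading_edge)}
        for r in results
    ])
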