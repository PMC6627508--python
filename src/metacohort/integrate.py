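"""Cross-study comparisons and the gene-centric query layer.

Covers: pairwise cross-study reproducibility of per-study effect vectors,
scatter/correlation comparisons between meta-analysis result tables
(e.g. adenocarcinoma vs squamous SMDs, or SMD vs survival z), and targeted
queries — group-difference meta (mutant vs wild-type, histology vs
histology), gene-pair correlation meta, clinical-covariate survival meta,
and the global rank of a gene in a results table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import StudyBundle
from .effects import (DegenerateInputError, hedges_g, pearson_fisherz,
                      cox_association, estimates_to_frame, EffectEstimate,
                      CoxDivergenceError)
from .meta import MIN_GROUP_SIZE, MIN_STUDIES, MetaResult, random_effects_meta


# ----------------------------------------------------------------------
# reproducibility
# ----------------------------------------------------------------------

def reproducibility_matrix(estimates: pd.DataFrame, analysis: str,
                           min_shared_genes: int = 30
                           ) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlation of per-study effect vectors.

    For each study pair the per-gene estimates are correlated over their
    shared genes; pairs sharing fewer than ``min_shared_genes`` genes stay
    NaN and are excluded from the median.  Returns the symmetric matrix
    (unit diagonal) and the median of its upper triangle.
    """
    df = estimates[estimates["analysis"] == analysis]
    if df["study_id"].nunique() < 2:
        raise ValueError("reproducibility needs >= 2 studies")
    wide = df.pivot_table(index="gene_id", columns="study_id",
                          values="estimate", aggfunc="first")
    studies = list(wide.columns)
    mat = pd.DataFrame(np.eye(len(studies)), index=studies, columns=studies)
    vals = []
    for i, a in enumerate(studies):
        for j in range(i + 1, len(studies)):
            b = studies[j]
            pair = wide[[a, b]].dropna()
            if len(pair) < min_shared_genes:
                mat.loc[a, b] = mat.loc[b, a] = np.nan
                continue
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
            vals.append(r)
    median = float(np.median(vals)) if vals else float("nan")
    return mat, median


def compare_summaries(results_a: pd.DataFrame, results_b: pd.DataFrame,
                      field_a: str = "summary", field_b: str = "summary",
                      highlight: dict[str, list[str]] | None = None,
                      min_shared_genes: int = 30
                      ) -> tuple[pd.DataFrame, float]:
    """Inner-join two meta result tables on gene id and correlate.

    Supports SMD-vs-SMD, z-vs-z and SMD-vs-z comparisons by naming the
    columns to pair.  ``highlight`` optionally tags genes by set membership
    for plotting.  Returns the paired table and the Pearson r.
    """
    a = results_a.set_index("gene_id")[field_a].rename("value_a")
    b = results_b.set_index("gene_id")[field_b].rename("value_b")
    paired = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(paired) < min_shared_genes:
        raise ValueError(
            f"gene intersection too small ({len(paired)} < {min_shared_genes})")
    if highlight:
        tag = pd.Series("", index=paired.index, name="highlight")
        for name, genes in highlight.items():
            tag.loc[tag.index.intersection(genes)] = name
        paired = paired.join(tag)
    r = float(np.corrcoef(paired["value_a"], paired["value_b"])[0, 1])
    return paired.reset_index(), r


# ----------------------------------------------------------------------
# targeted queries
# ----------------------------------------------------------------------

def group_difference_meta(bundles: list[StudyBundle], gene: str,
                          group_column: str, group_a: str, group_b: str,
                          tumor_only: bool = True,
                          min_group: int = MIN_GROUP_SIZE) -> MetaResult:
    """Meta-analysis of a gene's expression difference between two groups.

    Per qualifying study (>= ``min_group`` samples in each group), Hedges'
    g of group A vs group B over tumor samples, pooled by random effects.
    Covers mutant-vs-wild-type and ADC-vs-SQCC style queries.  Refuses,
    listing per-study group counts, when fewer than three studies qualify.
    """
    estimates: list[EffectEstimate] = []
    tally = {}
    for b in bundles:
        if gene not in b.genes or group_column not in b.samples.columns:
            continue
        s = b.samples
        in_scope = s["tissue"] == "tumor" if tumor_only else pd.Series(
            True, index=s.index)
        ids_a = s.index[in_scope & (s[group_column] == group_a)]
        ids_b = s.index[in_scope & (s[group_column] == group_b)]
        tally[b.study_id] = (len(ids_a), len(ids_b))
        if len(ids_a) < min_group or len(ids_b) < min_group:
            continue
        estimates.append(hedges_g(
            b.expr.loc[gene, ids_a].to_numpy(),
            b.expr.loc[gene, ids_b].to_numpy(),
            study_id=b.study_id, gene_id=gene))
    if len(estimates) < MIN_STUDIES:
        raise ValueError(
            f"gene {gene!r}: only {len(estimates)} studies qualify for "
            f"{group_a} vs {group_b} (need {MIN_STUDIES}); per-study "
            f"({group_a}, {group_b}) counts: {tally}")
    return random_effects_meta(estimates)


def gene_pair_correlation_meta(bundles: list[StudyBundle], gene_a: str,
                               gene_b: str, tumor_only: bool = True,
                               min_samples: int = MIN_GROUP_SIZE
                               ) -> MetaResult:
    """Meta-analysis of the correlation between two genes' expression.

    Per-study Pearson r on tumor samples, pooled on the Fisher-z scale;
    the result's reporting scale (via :func:`metacohort.meta.forest_data`
    or ``tanh(summary)``) is the correlation itself.
    """
    estimates = []
    for b in bundles:
        if gene_a not in b.genes or gene_b not in b.genes:
            continue
        ids = b.tumor_ids() if tumor_only else b.samples.index
        if len(ids) < min_samples:
            continue
        try:
            est = pearson_fisherz(
                b.expr.loc[gene_a, ids].to_numpy(),
                b.expr.loc[gene_b, ids].to_numpy(),
                study_id=b.study_id, gene_id=f"{gene_a}~{gene_b}")
        except DegenerateInputError:
            continue
        estimates.append(est)
    if len(estimates) < MIN_STUDIES:
        raise ValueError(
            f"pair ({gene_a}, {gene_b}): only {len(estimates)} studies "
            f"qualify (need {MIN_STUDIES})")
    return random_effects_meta(estimates)


def rank_gene(results: pd.DataFrame, gene: str,
              direction: str = "positive") -> tuple[int, int]:
    """Global rank of a gene's summary effect in a results table.

    Rank 1 is the most extreme summary in the stated direction
    ('positive' or 'negative'); ties share the minimum rank.  An absent
    gene errors, naming the closest matching ids.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    s = results.set_index("gene_id")["summary"]
    if gene not in s.index:
        near = [g for g in s.index if gene.lower() in str(g).lower()][:5]
        raise KeyError(f"gene {gene!r} not in results; close matches: {near}")
    ranked = s.rank(ascending=(direction == "negative"), method="min")
    return int(ranked.loc[gene]), int(len(s))


def clinical_covariate_meta(bundles: list[StudyBundle], covariate: str,
                            encoding: str = "auto",
                            min_samples: int = MIN_GROUP_SIZE) -> MetaResult:
    """Survival meta-analysis of a clinical covariate across studies.

    Per-study univariate Cox on the encoded covariate over samples with
    survival data, pooled as log hazard ratios.  Encodings: ``decades``
    (age / 10, so the HR reads per 10 years), ``male_vs_female`` (1 for
    'M'), ``ordinal`` (numeric stages as given), ``identity``.  ``auto``
    picks decades for 'age', male_vs_female for 'gender', ordinal
    otherwise.  Studies where the covariate is constant, or where the fit
    degenerates, are excluded.
    """
    if encoding == "auto":
        encoding = {"age": "decades", "gender": "male_vs_female"}.get(
            covariate, "ordinal")
    estimates = []
    for b in bundles:
        if covariate not in b.samples.columns:
            continue
        ids = b.survival_ids()
        sub = b.samples.loc[ids]
        raw = sub[covariate]
        if encoding == "decades":
            x = pd.to_numeric(raw, errors="coerce") / 10.0
        elif encoding == "male_vs_female":
            x = raw.map({"M": 1.0, "F": 0.0})
        elif encoding in ("ordinal", "identity"):
            x = pd.to_numeric(raw, errors="coerce")
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        ok = x.notna()
        if ok.sum() < min_samples:
            continue
        x = x[ok]
        t = pd.to_numeric(sub.loc[ok.index[ok], "os_time"]).to_numpy()
        ev = pd.to_numeric(sub.loc[ok.index[ok], "os_event"]).to_numpy()
        try:
            est = cox_association(x.to_numpy(), t, ev,
                                  study_id=b.study_id, gene_id=covariate)
        except (DegenerateInputError, CoxDivergenceError):
            continue
        est = EffectEstimate(est.study_id, est.gene_id, "LOGHR",
                             est.estimate, est.variance, n=est.n,
                             events=est.events)
        estimates.append(est)
    if len(estimates) < MIN_STUDIES:
        raise ValueError(
            f"covariate {covariate!r}: only {len(estimates)} studies "
            f"qualify (need {MIN_STUDIES})")
    return random_effects_meta(estimates)
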