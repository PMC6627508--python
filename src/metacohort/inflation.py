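"""Pooled-sample vs meta-analysis calibration diagnostics.

Pooling samples from several studies and testing tumor vs normal directly
ignores study-level batch structure: after randomly permuting the tissue
labels, a pooled test should produce uniform p-values but instead produces
drastic inflation, because permuted groups end up unbalanced across
studies whose location differs.  The per-study + meta-analysis route is
immune: batch offsets cancel within each study.  This module runs that
contrast — label permutation, both analysis paths, QQ data, post-correction
significant fractions, and Kolmogorov-Smirnov uniformity statistics — plus
a per-study PCA tumor/normal separation check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .cohort import StudyBundle
from .effects import DegenerateInputError, smd_table
from .meta import meta_table

__all__ = ["pooled_differential", "permute_labels", "inflation_experiment",
           "pca_separation", "InflationReport"]


def pooled_differential(bundles: list[StudyBundle]) -> pd.DataFrame:
    """Welch t-test per gene, tumor vs normal, pooling all studies' samples.

    Studies are concatenated over their shared genes and study identity is
    deliberately ignored — this is the analysis the batch structure breaks.
    Returns gene_id, t, p; genes without variance in either group are
    masked.
    """
    if len(bundles) < 1:
        raise ValueError("pooled_differential needs at least one study")
    shared = bundles[0].genes
    for b in bundles[1:]:
        shared = shared.intersection(b.genes)
    if len(shared) == 0:
        raise ValueError("no genes shared by all studies")
    xt = np.hstack([b.expr.loc[shared, b.tumor_ids()].to_numpy()
                    for b in bundles])
    xn = np.hstack([b.expr.loc[shared, b.normal_ids()].to_numpy()
                    for b in bundles])
    if xt.shape[1] < 2 or xn.shape[1] < 2:
        raise ValueError("both tissue labels must be present in the pool")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    ok = np.isfinite(t)
    return pd.DataFrame({"gene_id": shared, "t": t, "p": p})[ok] \
        .reset_index(drop=True)


def permute_labels(bundles: list[StudyBundle], seed: int,
                   within_study: bool = True) -> list[StudyBundle]:
    """Shuffle tumor/normal labels; deterministic per seed.

    By default labels are permuted within each study, preserving per-study
    group sizes.  ``within_study=False`` permutes the pooled label vector
    across all samples instead.
    """
    rng = np.random.default_rng(seed)
    out = []
    if within_study:
        for b in bundles:
            s = b.samples.copy()
            s["tissue"] = rng.permutation(s["tissue"].to_numpy())
            out.append(StudyBundle(b.study_id, b.expr.copy(), s))
    else:
        labels = np.concatenate([b.samples["tissue"].to_numpy()
                                 for b in bundles])
        labels = rng.permutation(labels)
        pos = 0
        for b in bundles:
            s = b.samples.copy()
            s["tissue"] = labels[pos:pos + len(s)]
            pos += len(s)
            out.append(StudyBundle(b.study_id, b.expr.copy(), s))
    return out


@dataclasses.dataclass
class InflationReport:
    """Outcome of one label-permutation contrast between the two paths."""

    seed: int
    alpha: float
    correction: str
    pooled_p: pd.Series          # per-gene p, pooled Welch path
    meta_p: pd.Series            # per-gene p, per-study + meta path
    pooled_sig_frac: float       # fraction significant after correction
    meta_sig_frac: float
    pooled_ks: float             # KS statistic vs Uniform(0,1)
    meta_ks: float

    def qq_data(self) -> pd.DataFrame:
        """Long-format QQ table: -log10 expected vs observed per path."""
        frames = []
        for path, p in (("pooled", self.pooled_p), ("meta", self.meta_p)):
            obs = np.sort(p.to_numpy())
            n = len(obs)
            exp = (np.arange(1, n + 1) - 0.5) / n
            frames.append(pd.DataFrame({
                "path": path,
                "expected_neglog10": -np.log10(exp),
                "observed_neglog10": -np.log10(np.maximum(obs, 1e-300)),
            }))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> dict:
        return {
            "seed": self.seed, "alpha": self.alpha,
            "correction": self.correction,
            "n_genes_pooled": int(len(self.pooled_p)),
            "n_genes_meta": int(len(self.meta_p)),
            "pooled_sig_frac": self.pooled_sig_frac,
            "meta_sig_frac": self.meta_sig_frac,
            "pooled_ks": self.pooled_ks, "meta_ks": self.meta_ks,
        }


def _sig_fraction(p: np.ndarray, alpha: float, correction: str) -> float:
    if correction == "bonferroni":
        return float(np.mean(p * len(p) < alpha))
    if correction == "bh":
        return float(np.mean(multipletests(p, alpha=alpha,
                                           method="fdr_bh")[0]))
    if correction == "none":
        return float(np.mean(p < alpha))
    raise ValueError(f"unknown correction {correction!r}")


def inflation_experiment(bundles: list[StudyBundle], seed: int,
                         alpha: float = 0.05,
                         correction: str = "bonferroni",
                         within_study: bool = True) -> InflationReport:
    """Permute labels once, then run both analysis paths on the same data.

    The meta path runs per-study Hedges' g on the permuted labels followed
    by random-effects pooling under the usual inclusion rules; the pooled
    path runs the Welch test on the concatenated samples.  Under a correct
    null both p-vectors should be uniform; batch structure inflates only
    the pooled one.
    """
    if len(bundles) < 2:
        raise ValueError("inflation experiment needs >= 2 studies")
    permuted = permute_labels(bundles, seed, within_study=within_study)
    pooled = pooled_differential(permuted)
    frames = []
    for b in permuted:
        try:
            frames.append(smd_table(b))
        except DegenerateInputError:
            # e.g. a (nearly) tumor-only study: it cannot contribute a
            # per-study estimate, though the pooled path still ingests it
            continue
    est = pd.concat(frames, ignore_index=True)
    meta = meta_table(est, analysis="SMD")
    pooled_p = pd.Series(pooled["p"].to_numpy(), index=pooled["gene_id"],
                         name="p")
    meta_p = pd.Series(meta["p"].to_numpy(), index=meta["gene_id"], name="p")
    return InflationReport(
        seed=seed, alpha=alpha, correction=correction,
        pooled_p=pooled_p, meta_p=meta_p,
        pooled_sig_frac=_sig_fraction(pooled_p.to_numpy(), alpha, correction),
        meta_sig_frac=_sig_fraction(meta_p.to_numpy(), alpha, correction),
        pooled_ks=float(stats.kstest(pooled_p, "uniform").statistic),
        meta_ks=float(stats.kstest(meta_p, "uniform").statistic),
    )


def pca_separation(bundle: StudyBundle) -> tuple[pd.DataFrame, float]:
    """Tumor/normal separation of one study in PC1-PC2 space.

    Genes are centered, the first two principal components are computed
    over samples, and the separation score is the silhouette of the
    tumor/normal partition in that plane (1 = perfectly separated,
    ~0 = unseparated).
    """
    labels = bundle.samples["tissue"]
    if labels.nunique() < 2:
        raise DegenerateInputError(
            f"study {bundle.study_id!r}: only one tissue label, "
            "separation undefined")
    if bundle.n_samples < 3:
        raise DegenerateInputError("pca_separation needs >= 3 samples")
    X = bundle.expr.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
    pcs = pd.DataFrame(coords, index=bundle.samples.index,
                       columns=["PC1", "PC2"])
    pcs["tissue"] = labels
    score = float(silhouette_score(coords, labels.to_numpy()))
    return pcs, score
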