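"""Inverse-variance random-effects meta-analysis across studies, per gene.

The pooling model: each study i contributes an estimate y_i with known
sampling variance v_i; true effects vary across studies with between-study
variance tau^2.  Fixed-effect weights w_i = 1/v_i give Cochran's
Q = sum w_i (y_i - y_FE)^2; the DerSimonian-Laird moment estimator is
tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)), after which
random-effects weights w*_i = 1/(v_i + tau^2) yield the summary, its SE,
a Wald z and p, and I^2 = max(0, (Q - (k-1))/Q) * 100.

Inclusion rules applied before pooling: a study qualifies for the
tumor-vs-normal (SMD) analysis only with at least 10 samples in each
group, and for the survival (log HR) or correlation analysis only with at
least 10 informative samples; a gene is meta-analyzed only when at least
three qualifying studies contribute an estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .effects import ESTIMATE_COLUMNS, EffectEstimate, estimates_to_frame

MIN_STUDIES = 3
MIN_GROUP_SIZE = 10

RESULT_COLUMNS = ["gene_id", "analysis", "k", "summary", "se", "ci_low",
                  "ci_high", "z", "p", "p_bonf", "p_bh", "Q", "tau2", "I2"]


@dataclasses.dataclass
class MetaResult:
    """Cross-study summary for one gene, with its forest-plot backing rows."""

    gene_id: str
    analysis: str
    k: int
    summary: float
    se: float
    ci_low: float
    ci_high: float
    z_score: float
    p: float
    Q: float
    tau2: float
    I2: float
    per_study: pd.DataFrame  # ESTIMATE_COLUMNS + 'weight' (normalized)

    def __post_init__(self) -> None:
        assert self.ci_low <= self.summary <= self.ci_high
        assert self.tau2 >= 0 and 0 <= self.I2 <= 100
        assert abs(self.per_study["weight"].sum() - 1.0) < 1e-9


# ----------------------------------------------------------------------
# inclusion rules
# ----------------------------------------------------------------------

def qualify_studies(estimates: pd.DataFrame, analysis: str,
                    min_group: int = MIN_GROUP_SIZE,
                    min_studies: int = MIN_STUDIES
                    ) -> tuple[pd.DataFrame, dict]:
    """Apply the study- and gene-level inclusion rules for one analysis.

    Returns the surviving estimate rows and a counts dict for the run
    manifest: rows dropped by the study-size rule and genes dropped by the
    minimum-studies rule.
    """
    df = estimates[estimates["analysis"] == analysis]
    if analysis == "SMD":
        study_ok = (df["n1"] >= min_group) & (df["n2"] >= min_group)
    else:  # LOGHR, FISHERZ: informative-sample count
        study_ok = df["n"] >= min_group
    kept = df[study_ok]
    genes_in = df["gene_id"].nunique()
    counts = kept.groupby("gene_id").size()
    good_genes = counts.index[counts >= min_studies]
    out = kept[kept["gene_id"].isin(good_genes)].reset_index(drop=True)
    info = {
        "analysis": analysis,
        "rows_in": int(len(df)),
        "rows_dropped_study_rule": int((~study_ok).sum()),
        "genes_in": int(genes_in),
        "genes_dropped_min_studies": int(genes_in - len(good_genes)),
        "genes_out": int(len(good_genes)),
    }
    return out, info


# ----------------------------------------------------------------------
# core pooling (vectorized over genes)
# ----------------------------------------------------------------------

def _dl_tau2(y: np.ndarray, v: np.ndarray, mask: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DerSimonian-Laird tau^2 plus Q and k; NaN-aware over genes x studies."""
    w = np.where(mask, 1.0 / v, 0.0)
    k = mask.sum(axis=1)
    sw = w.sum(axis=1)
    y0 = np.where(mask, y, 0.0)
    y_fe = (w * y0).sum(axis=1) / sw
    Q = (w * (y0 - y_fe[:, None]) ** 2 * mask).sum(axis=1)
    c = sw - (w ** 2).sum(axis=1) / sw
    tau2 = np.maximum(0.0, (Q - (k - 1)) / c)
    return tau2, Q, k


def _reml_tau2(y: np.ndarray, v: np.ndarray, mask: np.ndarray,
               tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Iterative REML tau^2 (fixed point), started from DerSimonian-Laird."""
    tau2, _, _ = _dl_tau2(y, v, mask)
    y0 = np.where(mask, y, 0.0)
    for _ in range(max_iter):
        w = np.where(mask, 1.0 / (v + tau2[:, None]), 0.0)
        sw = w.sum(axis=1)
        mu = (w * y0).sum(axis=1) / sw
        resid2 = (y0 - mu[:, None]) ** 2
        num = (w ** 2 * (resid2 - np.where(mask, v, 0.0))).sum(axis=1)
        new = np.maximum(0.0, num / (w ** 2).sum(axis=1) + 1.0 / sw)
        if np.max(np.abs(new - tau2), initial=0.0) < tol:
            tau2 = new
            break
        tau2 = new
    return tau2


def _pool(y: np.ndarray, v: np.ndarray, mask: np.ndarray,
          method: str = "DL", knapp_hartung: bool = False) -> dict:
    """Pool genes x studies arrays; returns dict of per-gene vectors."""
    if method == "DL":
        tau2, Q, k = _dl_tau2(y, v, mask)
    elif method == "REML":
        _, Q, k = _dl_tau2(y, v, mask)
        tau2 = _reml_tau2(y, v, mask)
    else:
        raise ValueError(f"unknown tau^2 method {method!r}")
    wstar = np.where(mask, 1.0 / (v + tau2[:, None]), 0.0)
    sws = wstar.sum(axis=1)
    y0 = np.where(mask, y, 0.0)
    summary = (wstar * y0).sum(axis=1) / sws
    se = 1.0 / np.sqrt(sws)
    if knapp_hartung:
        q = (wstar * (y0 - summary[:, None]) ** 2).sum(axis=1) / (k - 1)
        se = np.sqrt(np.maximum(q, np.finfo(float).tiny)) * se
        crit = stats.t.ppf(0.975, k - 1)
        z = summary / se
        p = 2.0 * stats.t.sf(np.abs(z), k - 1)
    else:
        crit = 1.96
        z = summary / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(divide="ignore", invalid="ignore"):
        I2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / Q) * 100.0, 0.0)
    return {
        "k": k, "summary": summary, "se": se,
        "ci_low": summary - crit * se, "ci_high": summary + crit * se,
        "z": z, "p": np.clip(p, np.finfo(float).tiny, 1.0),
        "Q": Q, "tau2": tau2, "I2": I2,
        "weights": wstar / sws[:, None],
    }


def random_effects_meta(estimates: list[EffectEstimate] | pd.DataFrame,
                        method: str = "DL",
                        knapp_hartung: bool = False) -> MetaResult:
    """Random-effects meta-analysis of >= 3 estimates for one gene."""
    df = (estimates_to_frame(estimates)
          if not isinstance(estimates, pd.DataFrame) else estimates.copy())
    if df["gene_id"].nunique() != 1 or df["analysis"].nunique() != 1:
        raise ValueError("all estimates must share one gene and one analysis")
    if len(df) < MIN_STUDIES:
        raise ValueError(
            f"meta-analysis needs >= {MIN_STUDIES} studies, got {len(df)}")
    if (df["variance"] <= 0).any():
        raise ValueError("all variances must be > 0")
    y = df["estimate"].to_numpy()[None, :]
    v = df["variance"].to_numpy()[None, :]
    mask = np.ones_like(y, bool)
    r = _pool(y, v, mask, method=method, knapp_hartung=knapp_hartung)
    per_study = df.reindex(columns=ESTIMATE_COLUMNS).copy()
    per_study["weight"] = r["weights"][0]
    return MetaResult(
        gene_id=str(df["gene_id"].iloc[0]),
        analysis=str(df["analysis"].iloc[0]),
        k=int(r["k"][0]), summary=float(r["summary"][0]),
        se=float(r["se"][0]), ci_low=float(r["ci_low"][0]),
        ci_high=float(r["ci_high"][0]), z_score=float(r["z"][0]),
        p=float(r["p"][0]), Q=float(r["Q"][0]), tau2=float(r["tau2"][0]),
        I2=float(r["I2"][0]), per_study=per_study,
    )


def meta_table(estimates: pd.DataFrame, analysis: str | None = None,
               method: str = "DL", knapp_hartung: bool = False,
               apply_filters: bool = True) -> pd.DataFrame:
    """Genome-wide meta-analysis: one result row per gene.

    Applies the inclusion rules (unless ``apply_filters=False``), pools
    every gene at once, and appends Bonferroni and Benjamini-Hochberg
    adjusted p-values.  This table is the systematic-results artifact.
    """
    df = estimates
    if analysis is None:
        kinds = df["analysis"].unique()
        if len(kinds) != 1:
            raise ValueError("mixed analyses: pass `analysis` explicitly")
        analysis = str(kinds[0])
    if apply_filters:
        df, _info = qualify_studies(df, analysis)
    else:
        df = df[df["analysis"] == analysis]
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    ymat = df.pivot_table(index="gene_id", columns="study_id",
                          values="estimate", aggfunc="first")
    vmat = df.pivot_table(index="gene_id", columns="study_id",
                          values="variance", aggfunc="first")
    y = ymat.to_numpy()
    v = vmat.to_numpy()
    mask = ~np.isnan(y)
    r = _pool(np.nan_to_num(y), np.where(mask, v, 1.0), mask,
              method=method, knapp_hartung=knapp_hartung)
    out = pd.DataFrame({
        "gene_id": ymat.index, "analysis": analysis, "k": r["k"],
        "summary": r["summary"], "se": r["se"], "ci_low": r["ci_low"],
        "ci_high": r["ci_high"], "z": r["z"], "p": r["p"],
        "p_bonf": np.minimum(1.0, r["p"] * len(ymat)),
        "p_bh": multipletests(r["p"], method="fdr_bh")[1],
        "Q": r["Q"], "tau2": r["tau2"], "I2": r["I2"],
    }).reset_index(drop=True)
    return out[RESULT_COLUMNS]


# ----------------------------------------------------------------------
# forest-plot export
# ----------------------------------------------------------------------

def _to_reporting_scale(analysis: str, x: np.ndarray) -> np.ndarray:
    if analysis == "LOGHR":
        return np.exp(x)
    if analysis == "FISHERZ":
        return np.tanh(x)
    return np.asarray(x, float)


def forest_data(result: MetaResult) -> pd.DataFrame:
    """Per-study rows plus a summary row, on the natural reporting scale.

    Log hazard ratios are reported as HRs, Fisher-z values as correlations;
    SMDs stay as they are.  Weights are random-effects weights in percent.
    """
    ps = result.per_study
    se = np.sqrt(ps["variance"].to_numpy())
    est = ps["estimate"].to_numpy()
    rows = pd.DataFrame({
        "row": ps["study_id"],
        "estimate": _to_reporting_scale(result.analysis, est),
        "ci_low": _to_reporting_scale(result.analysis, est - 1.96 * se),
        "ci_high": _to_reporting_scale(result.analysis, est + 1.96 * se),
        "weight_pct": ps["weight"].to_numpy() * 100.0,
    })
    summary = pd.DataFrame({
        "row": ["summary"],
        "estimate": _to_reporting_scale(result.analysis,
                                        np.array([result.summary])),
        "ci_low": _to_reporting_scale(result.analysis,
                                      np.array([result.ci_low])),
        "ci_high": _to_reporting_scale(result.analysis,
                                       np.array([result.ci_high])),
        "weight_pct": [100.0],
    })
    return pd.concat([rows, summary], ignore_index=True)
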