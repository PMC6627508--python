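"""Per-study effect estimators.

Three estimator families, each yielding an estimate with a variance so the
meta-analysis layer can pool them by inverse variance:

* :func:`hedges_g` — tumor-vs-normal standardized mean difference with the
  small-sample bias correction J = 1 - 3/(4(n1+n2-2)-1);
* :func:`cox_association` — univariate Cox proportional-hazards log hazard
  ratio per 1 SD of expression, maximized by Newton-Raphson with the Efron
  tie correction;
* :func:`pearson_fisherz` — Pearson correlation on the Fisher z scale with
  variance 1/(n-3).

Matrix-level wrappers (:func:`smd_table`, :func:`cox_table`) run an
estimator over every gene of a study at once; genes with zero within-study
variance are masked and contribute no estimate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .cohort import StudyBundle

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["study_id", "gene_id", "analysis", "estimate", "variance",
                    "n1", "n2", "n", "events"]

R_CLAMP = 1.0 - 1e-12  # |r| bound before atanh


class DegenerateInputError(ValueError):
    """Input carries no information for the requested estimator."""


class CoxDivergenceError(RuntimeError):
    """Cox partial likelihood has no finite maximizer (separation)."""

    def __init__(self, message: str, last_beta: float):
        super().__init__(message)
        self.last_beta = last_beta


@dataclasses.dataclass
class EffectEstimate:
    """One gene x one study estimate for one analysis type."""

    study_id: str
    gene_id: str
    analysis: str               # SMD | LOGHR | FISHERZ
    estimate: float
    variance: float
    n: int
    n1: int | None = None       # SMD only: tumor (group A) size
    n2: int | None = None       # SMD only: normal (group B) size
    events: int | None = None   # LOGHR only

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate) or not self.variance > 0:
            raise ValueError(
                f"{self.analysis} estimate for {self.gene_id!r} in "
                f"{self.study_id!r}: estimate must be finite, variance > 0"
            )

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy table of estimates (the TSV serialization layout)."""
    return pd.DataFrame(
        [dataclasses.asdict(e) for e in estimates]
    ).reindex(columns=ESTIMATE_COLUMNS)


# ----------------------------------------------------------------------
# standardized mean difference
# ----------------------------------------------------------------------

def hedges_g(x_tumor: np.ndarray, x_normal: np.ndarray, *,
             study_id: str = "", gene_id: str = "") -> EffectEstimate:
    """Hedges' g for two groups, with its large-sample variance.

    g = J * (mean_t - mean_n) / s_pooled, where s_pooled pools the two
    group variances with n1+n2-2 degrees of freedom and J corrects the
    small-sample bias of Cohen's d.  Variance is
    (n1+n2)/(n1*n2) + g^2 / (2(n1+n2)).
    """
    x1 = np.asarray(x_tumor, float)
    x2 = np.asarray(x_normal, float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(
            f"hedges_g needs >= 2 samples per group, got {n1} and {n2}")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("hedges_g requires finite values")
    s2p = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2p <= 0:
        raise DegenerateInputError(
            f"gene {gene_id!r}: zero pooled SD, SMD undefined")
    d = (x1.mean() - x2.mean()) / np.sqrt(s2p)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = J * d
    var = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return EffectEstimate(study_id, gene_id, "SMD", float(g), float(var),
                          n=n1 + n2, n1=n1, n2=n2)


def smd_table(bundle: StudyBundle) -> pd.DataFrame:
    """Hedges' g for every gene of a study (tumor vs normal), vectorized.

    Genes with zero pooled SD are masked (dropped with a log line); the
    result is a tidy estimate table.
    """
    xt = bundle.expr.loc[:, bundle.tumor_ids()].to_numpy()
    xn = bundle.expr.loc[:, bundle.normal_ids()].to_numpy()
    n1, n2 = xt.shape[1], xn.shape[1]
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(
            f"study {bundle.study_id!r}: needs >= 2 tumor and >= 2 normal "
            f"samples, got {n1}/{n2}")
    s2p = ((n1 - 1) * xt.var(axis=1, ddof=1)
           + (n2 - 1) * xn.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    ok = s2p > 0
    if not ok.all():
        logger.warning("study %s: masked %d zero-variance genes in SMD",
                       bundle.study_id, int((~ok).sum()))
    J = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = J * (xt.mean(axis=1) - xn.mean(axis=1)) / np.sqrt(s2p)
    var = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    out = pd.DataFrame({
        "study_id": bundle.study_id,
        "gene_id": bundle.genes,
        "analysis": "SMD",
        "estimate": g,
        "variance": var,
        "n1": n1, "n2": n2, "n": n1 + n2, "events": np.nan,
    })
    return out[ok].reset_index(drop=True)


# ----------------------------------------------------------------------
# expression standardization
# ----------------------------------------------------------------------

def standardize_expression(bundle: StudyBundle,
                           scope: str = "tumor_only") -> StudyBundle:
    """Center and scale every gene to mean 0, SD 1 over the scoped samples.

    ``scope='tumor_only'`` uses the study's cancer samples (the convention
    for survival association, so the Cox coefficient reads per-1-SD of
    tumor expression); ``scope='all'`` uses every sample.  Genes constant
    over the scope are masked (dropped, warning logged) rather than
    erroring the run.  Idempotent to 1e-12.
    """
    if scope == "tumor_only":
        ids = bundle.tumor_ids()
    elif scope == "all":
        ids = bundle.samples.index
    else:
        raise ValueError(f"scope must be 'tumor_only' or 'all', got {scope!r}")
    if len(ids) < 2:
        raise DegenerateInputError(
            f"study {bundle.study_id!r}: scope {scope!r} has < 2 samples")
    sub = bundle.expr.loc[:, ids]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("study %s: masked %d constant genes in standardization",
                       bundle.study_id, int((~ok).sum()))
    expr = bundle.expr[ok].sub(mean[ok], axis=0).div(sd[ok], axis=0)
    return StudyBundle(bundle.study_id, expr, bundle.samples.copy())


# ----------------------------------------------------------------------
# univariate Cox proportional hazards
# ----------------------------------------------------------------------

def _cox_ll_grad_info(beta: np.ndarray, Z: np.ndarray, zsum: np.ndarray,
                      grp_end: np.ndarray, ev_grp: np.ndarray,
                      ev_pos: np.ndarray, frac: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, score and information for G genes.

    ``Z`` is genes x samples with columns sorted by time descending;
    ``grp_end`` indexes the last column of each tie group, ``ev_pos`` the
    event columns, ``ev_grp`` their tie-group ids, and ``frac`` the Efron
    fractions l/d for each event within its group.
    """
    w = np.exp(beta[:, None] * Z)
    wz = w * Z
    wzz = wz * Z
    R0 = np.cumsum(w, axis=1)[:, grp_end]
    R1 = np.cumsum(wz, axis=1)[:, grp_end]
    R2 = np.cumsum(wzz, axis=1)[:, grp_end]
    # within-tie-group event sums, per group
    n_grp = len(grp_end)
    D0 = np.zeros((w.shape[0], n_grp))
    D1 = np.zeros_like(D0)
    D2 = np.zeros_like(D0)
    np.add.at(D0, (slice(None), ev_grp), w[:, ev_pos])
    np.add.at(D1, (slice(None), ev_grp), wz[:, ev_pos])
    np.add.at(D2, (slice(None), ev_grp), wzz[:, ev_pos])
    phi = R0[:, ev_grp] - frac * D0[:, ev_grp]
    a1 = (R1[:, ev_grp] - frac * D1[:, ev_grp]) / phi
    a2 = (R2[:, ev_grp] - frac * D2[:, ev_grp]) / phi
    ll = beta * zsum - np.log(phi).sum(axis=1)
    U = zsum - a1.sum(axis=1)
    info = (a2 - a1 * a1).sum(axis=1)
    return ll, U, info


def _cox_fit_matrix(Z: np.ndarray, time: np.ndarray, event: np.ndarray,
                    max_iter: int = 50, tol: float = 1e-9
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one univariate Cox model per row of Z.  Returns (beta, var, ok).

    Newton-Raphson from beta = 0 with step-halving whenever a step lowers
    the partial likelihood; convergence on |delta ll| < tol.  ``ok`` is
    False for genes with no information (constant expression) or without a
    finite maximizer (separation).
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    order = np.argsort(-time, kind="stable")
    Zs = Z[:, order]
    t = time[order]
    e = event[order] > 0
    new_grp = np.r_[True, t[1:] != t[:-1]]
    gid = np.cumsum(new_grp) - 1
    n_grp = gid[-1] + 1
    grp_end = np.r_[np.flatnonzero(new_grp)[1:] - 1, len(t) - 1]
    ev_pos = np.flatnonzero(e)
    ev_grp = gid[ev_pos]
    # Efron fraction l/d for each event within its tie group
    d_per_grp = np.bincount(ev_grp, minlength=n_grp)
    frac = np.concatenate([np.arange(d) / d for d in d_per_grp if d > 0])
    # keep only groups containing events
    keep = d_per_grp > 0
    remap = np.cumsum(keep) - 1
    grp_end = grp_end[keep]
    ev_grp = remap[ev_grp]

    zsum = Zs[:, ev_pos].sum(axis=1)
    G = Z.shape[0]
    beta = np.zeros(G)
    ll, U, info = _cox_ll_grad_info(beta, Zs, zsum, grp_end, ev_grp,
                                    ev_pos, frac)
    dead = info <= 1e-12          # no information at beta=0: constant gene
    active = ~dead
    for _ in range(max_iter):
        if not active.any():
            break
        step = np.zeros(G)
        step[active] = U[active] / np.maximum(info[active], 1e-300)
        np.clip(step, -5.0, 5.0, out=step)
        new_beta = beta + step
        new_ll, new_U, new_info = _cox_ll_grad_info(
            new_beta, Zs, zsum, grp_end, ev_grp, ev_pos, frac)
        # halve steps that decreased the likelihood
        for _h in range(30):
            worse = active & (new_ll < ll - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta = beta + step
            new_ll, new_U, new_info = _cox_ll_grad_info(
                new_beta, Zs, zsum, grp_end, ev_grp, ev_pos, frac)
        converged = active & (np.abs(new_ll - ll) < tol)
        beta, ll, U, info = new_beta, new_ll, new_U, new_info
        active = active & ~converged
    diverged = active | (np.abs(beta) > 15)
    ok = ~(dead | diverged)
    with np.errstate(divide="ignore"):
        var = np.where(info > 0, 1.0 / info, np.inf)
    return beta, var, ok


def cox_association(z_expr: np.ndarray, os_time: np.ndarray,
                    os_event: np.ndarray, *, study_id: str = "",
                    gene_id: str = "") -> EffectEstimate:
    """Univariate Cox log hazard ratio for one standardized expression vector.

    ``z_expr`` should already be standardized (see
    :func:`standardize_expression`) so the coefficient is per 1 SD.
    Raises :class:`DegenerateInputError` for constant expression or < 2
    events and :class:`CoxDivergenceError` on monotone-likelihood
    separation.
    """
    z = np.asarray(z_expr, float)
    t = np.asarray(os_time, float)
    ev = np.asarray(os_event, float)
    if not (len(z) == len(t) == len(ev)):
        raise ValueError("cox_association: length mismatch")
    if (t <= 0).any():
        raise ValueError("cox_association: os_time must be > 0")
    n_events = int(ev.sum())
    if n_events < 2:
        raise DegenerateInputError(
            f"gene {gene_id!r}: needs >= 2 events, got {n_events}")
    if np.ptp(z) == 0:
        raise DegenerateInputError(
            f"gene {gene_id!r}: constant expression, zero information")
    beta, var, ok = _cox_fit_matrix(z[None, :], t, ev)
    if not ok[0]:
        raise CoxDivergenceError(
            f"gene {gene_id!r} in study {study_id!r}: Cox partial likelihood "
            f"diverged (monotone likelihood / separation)", float(beta[0]))
    return EffectEstimate(study_id, gene_id, "LOGHR", float(beta[0]),
                          float(var[0]), n=len(z), events=n_events)


def cox_table(bundle: StudyBundle, scope: str = "tumor_only") -> pd.DataFrame:
    """Per-gene univariate Cox association for a study, vectorized.

    Standardizes expression over the survival-informative samples of the
    requested scope, fits every gene, and masks constant or diverged genes.
    """
    surv_ids = bundle.survival_ids()
    if scope == "all":
        # include normal samples carrying survival data, if any
        s = bundle.samples
        ok = (pd.to_numeric(s["os_time"], errors="coerce").notna()
              & pd.to_numeric(s["os_event"], errors="coerce").notna())
        surv_ids = s.index[ok]
    if len(surv_ids) == 0:
        raise DegenerateInputError(
            f"study {bundle.study_id!r}: no samples with survival data")
    sub = bundle.subset_samples(surv_ids)
    time = pd.to_numeric(sub.samples["os_time"]).to_numpy()
    event = pd.to_numeric(sub.samples["os_event"]).to_numpy()
    n_events = int(event.sum())
    if n_events < 2:
        raise DegenerateInputError(
            f"study {bundle.study_id!r}: needs >= 2 events, got {n_events}")
    X = sub.expr.to_numpy()
    sd = X.std(axis=1, ddof=1)
    nonconst = sd > 0
    if not nonconst.all():
        logger.warning("study %s: masked %d constant genes in Cox",
                       bundle.study_id, int((~nonconst).sum()))
    Z = (X[nonconst] - X[nonconst].mean(axis=1, keepdims=True)) \
        / sd[nonconst, None]
    beta, var, ok = _cox_fit_matrix(Z, time, event)
    genes = sub.genes[nonconst]
    if not ok.all():
        logger.warning("study %s: masked %d diverged Cox fits",
                       bundle.study_id, int((~ok).sum()))
    out = pd.DataFrame({
        "study_id": bundle.study_id,
        "gene_id": genes,
        "analysis": "LOGHR",
        "estimate": beta,
        "variance": var,
        "n1": np.nan, "n2": np.nan, "n": len(surv_ids), "events": n_events,
    })
    return out[ok].reset_index(drop=True)


# ----------------------------------------------------------------------
# correlation on the Fisher z scale
# ----------------------------------------------------------------------

def pearson_fisherz(x: np.ndarray, y: np.ndarray, *, study_id: str = "",
                    gene_id: str = "") -> EffectEstimate:
    """Pearson correlation as a Fisher-z estimate with variance 1/(n-3).

    Perfect correlations are clamped to |r| <= 1 - 1e-12 before atanh so a
    duplicated gene still yields a (huge but finite) z.  The correlation is
    recoverable as tanh(estimate).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("pearson_fisherz: length mismatch")
    if n < 4:
        raise DegenerateInputError(
            f"pair {gene_id!r}: needs n >= 4 for Fisher-z variance, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            f"pair {gene_id!r}: constant vector, correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return EffectEstimate(study_id, gene_id, "FISHERZ", float(np.arctanh(r)),
                          1.0 / (n - 3), n=n)
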