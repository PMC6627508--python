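"""End-to-end pipeline: cohort -> effects -> meta -> enrichment -> reports.

The run mirrors the systematic-analysis workflow: per-study effect
estimates, inclusion filtering, random-effects pooling per gene, optional
preranked enrichment on the summary statistics, cross-study
reproducibility, and cross-analysis comparison — executed separately per
histology and written to a results directory::

    out/
      manifest.json            run configuration, versions, stage counts
      {ANALYSIS}/{HISTOLOGY}/results.tsv
      {ANALYSIS}/{HISTOLOGY}/enrichment.tsv      (if a GMT was given)
      {ANALYSIS}/{HISTOLOGY}/reproducibility.tsv
      comparisons.tsv          paired summary correlations across tables
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import StudyBundle, read_cohort
from .effects import DegenerateInputError, smd_table, cox_table
from .gsea import enrichment_frame, gsea_preranked, read_gmt
from .integrate import compare_summaries, reproducibility_matrix
from .meta import meta_table, qualify_studies

logger = logging.getLogger(__name__)

ANALYSES = ("SMD", "LOGHR")


@dataclasses.dataclass
class PipelineConfig:
    cohort_dir: str
    out_dir: str
    analyses: tuple[str, ...] = ANALYSES
    gmt: str | None = None
    seed: int = 0
    survival_scope: str = "tumor_only"
    gsea_rank_field: dict | None = None   # analysis -> results column
    n_perm: int = 1000
    min_set_size: int = 5
    max_set_size: int = 500
    tau2_method: str = "DL"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def rank_field(self, analysis: str) -> str:
        # survival analyses rank genes by the meta z-score, tumor-vs-normal
        # by the summary SMD
        default = {"SMD": "summary", "LOGHR": "z"}
        if self.gsea_rank_field and analysis in self.gsea_rank_field:
            return self.gsea_rank_field[analysis]
        return default.get(analysis, "z")


def _split_histology(bundles: list[StudyBundle]) -> dict[str, list[StudyBundle]]:
    out: dict[str, list[StudyBundle]] = {}
    for b in bundles:
        for h in sorted(b.samples["histology"].unique()):
            sub_ids = b.samples.index[b.samples["histology"] == h]
            sub = b.subset_samples(sub_ids)
            out.setdefault(str(h), []).append(sub)
    return out


def _estimates_for(bundles: list[StudyBundle], analysis: str,
                   scope: str) -> pd.DataFrame:
    frames = []
    for b in bundles:
        try:
            if analysis == "SMD":
                frames.append(smd_table(b))
            elif analysis == "LOGHR":
                frames.append(cox_table(b, scope=scope))
            else:
                raise ValueError(f"unknown analysis {analysis!r}")
        except DegenerateInputError as exc:
            logger.warning("study %s skipped for %s: %s",
                           b.study_id, analysis, exc)
    if not frames:
        return pd.DataFrame(columns=["study_id", "gene_id", "analysis",
                                     "estimate", "variance", "n1", "n2",
                                     "n", "events"])
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured analyses and write the results directory.

    Deterministic for a fixed config + seed: rerunning yields bit-identical
    tables.  The manifest records, per analysis and histology, how many
    genes were masked by per-study estimators, removed by the inclusion
    rules, and reported.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger("metacohort").addHandler(handler)

    bundles = read_cohort(config.cohort_dir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "n_studies": len(bundles),
        "stages": {},
        "warnings": [],
    }
    if len(bundles) < 3:
        msg = (f"cohort has only {len(bundles)} studies: the minimum-three-"
               "studies rule will leave every meta-analysis empty")
        logger.warning(msg)
        manifest["warnings"].append(msg)

    collection = read_gmt(config.gmt) if config.gmt else None
    result_tables: dict[tuple[str, str], pd.DataFrame] = {}

    for analysis in config.analyses:
        for hist, hb in _split_histology(bundles).items():
            d = out / analysis / hist
            d.mkdir(parents=True, exist_ok=True)
            est = _estimates_for(hb, analysis, config.survival_scope)
            genes_total = len(set().union(*[set(b.genes) for b in hb]))
            genes_with_est = est["gene_id"].nunique() if len(est) else 0
            filtered, qinfo = qualify_studies(est, analysis)
            results = meta_table(filtered, analysis=analysis,
                                 method=config.tau2_method,
                                 apply_filters=False)
            result_tables[(analysis, hist)] = results
            results.to_csv(d / "results.tsv", sep="\t", index=False,
                           float_format="%.10g")
            stage = {
                "genes_total": genes_total,
                "genes_masked": genes_total - genes_with_est,
                "genes_filtered": genes_with_est - len(results),
                "genes_in_results": len(results),
                "qualify": qinfo,
            }
            if results.empty:
                msg = f"{analysis}/{hist}: no genes passed the inclusion rules"
                logger.warning(msg)
                manifest["warnings"].append(msg)
            # reproducibility of per-study estimate vectors
            if est["study_id"].nunique() >= 2:
                mat, med = reproducibility_matrix(est, analysis)
                mat.to_csv(d / "reproducibility.tsv", sep="\t",
                           float_format="%.10g")
                stage["reproducibility_median"] = None if pd.isna(med) else med
            if collection is not None and not results.empty:
                ranked = results.set_index("gene_id")[
                    config.rank_field(analysis)]
                enr = gsea_preranked(ranked, collection,
                                     n_perm=config.n_perm, seed=config.seed,
                                     min_size=config.min_set_size,
                                     max_size=config.max_set_size)
                enrichment_frame(enr).to_csv(d / "enrichment.tsv", sep="\t",
                                             index=False,
                                             float_format="%.10g")
                stage["n_enriched_sets"] = len(enr)
            manifest["stages"][f"{analysis}/{hist}"] = stage

    # cross-table comparisons: histology pairs within an analysis, then
    # SMD-vs-survival-z within each histology
    comparisons = []
    for analysis in config.analyses:
        hists = sorted(h for (a, h) in result_tables if a == analysis
                       and not result_tables[(a, h)].empty)
        for i, ha in enumerate(hists):
            for hb_ in hists[i + 1:]:
                field = "z" if analysis == "LOGHR" else "summary"
                try:
                    _, r = compare_summaries(result_tables[(analysis, ha)],
                                             result_tables[(analysis, hb_)],
                                             field, field)
                except ValueError:
                    continue
                comparisons.append({"comparison": f"{analysis}:{ha}_vs_{hb_}",
                                    "r": r})
    if all(a in config.analyses for a in ("SMD", "LOGHR")):
        for (a, h), tab in result_tables.items():
            if a != "SMD" or tab.empty:
                continue
            surv = result_tables.get(("LOGHR", h))
            if surv is None or surv.empty:
                continue
            try:
                _, r = compare_summaries(tab, surv, "summary", "z")
            except ValueError:
                continue
            comparisons.append({"comparison": f"SMD_vs_survival_z:{h}",
                                "r": r})
    if comparisons:
        pd.DataFrame(comparisons).to_csv(out / "comparisons.tsv", sep="\t",
                                         index=False, float_format="%.10g")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    logging.getLogger("metacohort").removeHandler(handler)
    handler.close()
    return out
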