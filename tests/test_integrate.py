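import numpy as np
import pandas as pd
import pytest

from metacohort import (SyntheticConfig, generate_cohort, smd_table,
                        cox_table, meta_table, reproducibility_matrix,
                        compare_summaries, group_difference_meta,
                        gene_pair_correlation_meta, rank_gene,
                        clinical_covariate_meta)


# ------------------------------------------------------- reproducibility

def test_reproducible_studies_correlate_highly(signal_cohort):
    _, bundles, _ = signal_cohort
    est = pd.concat([smd_table(b) for b in bundles], ignore_index=True)
    mat, median = reproducibility_matrix(est, "SMD")
    assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)
    assert np.allclose(np.diag(mat), 1.0)
    assert median > 0.6  # shared true SMDs with SD 0.5 dominate noise


def test_noise_estimates_have_zero_median():
    rng = np.random.default_rng(0)
    rows = [{"study_id": f"s{i}", "gene_id": f"g{j}", "analysis": "SMD",
             "estimate": float(rng.normal()), "variance": 0.05,
             "n1": 30, "n2": 30, "n": 60, "events": np.nan}
            for i in range(6) for j in range(400)]
    _, median = reproducibility_matrix(pd.DataFrame(rows), "SMD")
    assert abs(median) < 0.05


def test_pair_below_shared_gene_floor_is_missing():
    rng = np.random.default_rng(1)
    rows = []
    for i, genes in enumerate([range(40), range(40), range(35, 45)]):
        for j in genes:
            rows.append({"study_id": f"s{i}", "gene_id": f"g{j}",
                         "analysis": "SMD", "estimate": float(rng.normal()),
                         "variance": 0.05, "n1": 30, "n2": 30, "n": 60,
                         "events": np.nan})
    mat, _ = reproducibility_matrix(pd.DataFrame(rows), "SMD",
                                    min_shared_genes=30)
    assert np.isnan(mat.loc["s0", "s2"])  # only 5 shared genes
    assert not np.isnan(mat.loc["s0", "s1"])


def test_smd_more_reproducible_than_survival(signal_cohort):
    # tumor/normal effects carry far more information per study than
    # event-limited survival associations
    _, bundles, _ = signal_cohort
    smd = pd.concat([smd_table(b) for b in bundles], ignore_index=True)
    cox = pd.concat([cox_table(b) for b in bundles], ignore_index=True)
    _, med_smd = reproducibility_matrix(smd, "SMD")
    _, med_cox = reproducibility_matrix(cox, "LOGHR")
    assert med_smd > med_cox


# ----------------------------------------------------------- comparisons

def _results_from(bundles):
    est = pd.concat([smd_table(b) for b in bundles], ignore_index=True)
    return meta_table(est, "SMD")


def test_compare_with_self_gives_unit_r(signal_cohort):
    _, bundles, _ = signal_cohort
    res = _results_from(bundles)
    paired, r = compare_summaries(res, res)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert len(paired) == len(res)


def test_independent_nulls_uncorrelated():
    outs = []
    for seed in (51, 52):
        cfg = SyntheticConfig(n_studies=5, genes=400, true_smd=0.0,
                              tau2_smd=0.0, seed=seed)
        bundles, _ = generate_cohort(cfg)
        outs.append(_results_from(bundles))
    _, r = compare_summaries(*outs)
    assert abs(r) < 0.12


def test_shared_signal_concordance_matches_truth_oracle():
    # two histology-like cohorts share 80% of the true-SMD vector; the
    # expected concordance of their summaries follows from attenuating the
    # truth-level correlation by each cohort's estimation noise
    rng = np.random.default_rng(9)
    genes = 600
    shared = rng.normal(0, 0.5, genes)
    a_true = shared.copy()
    b_true = shared.copy()
    idx = rng.choice(genes, int(0.2 * genes), replace=False)
    b_true[idx] = rng.normal(0, 0.5, len(idx))
    res = []
    for true, seed, hist in ((a_true, 61, "ADC"), (b_true, 62, "SQCC")):
        cfg = SyntheticConfig(n_studies=8, genes=genes, true_smd=true,
                              histology=hist, seed=seed)
        bundles, _ = generate_cohort(cfg)
        res.append(_results_from(bundles))
    _, r = compare_summaries(*res)
    truth_r = float(np.corrcoef(a_true, b_true)[0, 1])
    # attenuation: var(summary) = var(true) + meta noise (tau2/k + v/k)
    noise = 0.05 / 8 + 0.035 / 8
    expect = truth_r * 0.25 / (0.25 + noise)
    assert r == pytest.approx(expect, abs=0.1)


def test_highlight_column_tags_gene_sets(signal_cohort):
    _, bundles, _ = signal_cohort
    res = _results_from(bundles)
    paired, _ = compare_summaries(res, res,
                                  highlight={"mySet": ["G000", "G001"]})
    tags = paired.set_index("gene_id")["highlight"]
    assert tags["G000"] == "mySet"
    assert (tags == "").sum() == len(paired) - 2


# -------------------------------------------------------------- queries

def test_group_difference_antisymmetric(signal_cohort):
    _, bundles, _ = signal_cohort
    a = group_difference_meta(bundles, "G000", "EGFR_status", "mutant", "WT")
    b = group_difference_meta(bundles, "G000", "EGFR_status", "WT", "mutant")
    assert a.summary == pytest.approx(-b.summary, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


def test_group_difference_skips_missing_gene(signal_cohort):
    _, bundles, _ = signal_cohort
    full = group_difference_meta(bundles, "G000", "EGFR_status",
                                 "mutant", "WT")
    drop_study = full.per_study["study_id"].iloc[0]
    trimmed = [b.copy() for b in bundles]
    for b in trimmed:
        if b.study_id == drop_study:
            b.expr = b.expr.drop(index="G000")
    part = group_difference_meta(trimmed, "G000", "EGFR_status",
                                 "mutant", "WT")
    assert part.k == full.k - 1


def test_group_difference_refusal_lists_counts():
    cfg = SyntheticConfig(n_studies=3, genes=2, samples_per_study=(30, 30),
                          mutation_genes=[("RARE", 0.05, 0.5)], seed=71)
    bundles, _ = generate_cohort(cfg)
    with pytest.raises(ValueError, match="counts"):
        group_difference_meta(bundles, "G0", "RARE_status", "mutant", "WT")


def test_gene_pair_meta_recovers_rho(signal_cohort):
    _, bundles, _ = signal_cohort  # pair (G000, G001) at rho = 0.8
    res = gene_pair_correlation_meta(bundles, "G000", "G001")
    assert 0.7 < np.tanh(res.summary) < 0.9


def test_identical_genes_give_unit_summary(signal_cohort):
    _, bundles, _ = signal_cohort
    res = gene_pair_correlation_meta(bundles, "G002", "G002")
    assert np.tanh(res.summary) > 0.999


def test_rank_gene_basics_and_oracle():
    rng = np.random.default_rng(2)
    res = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                        "summary": rng.normal(0, 1, 100)})
    top = res.loc[res["summary"].idxmax(), "gene_id"]
    assert rank_gene(res, top, "positive") == (1, 100)
    # independent sort-and-search oracle
    gene = "g17"
    order = sorted(res["summary"], reverse=True)
    expect = order.index(float(res.set_index("gene_id")
                               .loc[gene, "summary"])) + 1
    assert rank_gene(res, gene, "positive")[0] == expect
    ties = pd.DataFrame({"gene_id": ["a", "b", "c"], "summary": [1.0] * 3})
    assert rank_gene(ties, "b") == (1, 3)
    with pytest.raises(KeyError, match="close matches"):
        rank_gene(res, "g17x")


def test_clinical_covariate_scaling():
    cfg = SyntheticConfig(n_studies=4, genes=3, samples_per_study=(150, 150),
                          age_loghr_per_decade=0.3, seed=81)
    bundles, _ = generate_cohort(cfg)
    dec = clinical_covariate_meta(bundles, "age", encoding="decades")
    yrs = clinical_covariate_meta(bundles, "age", encoding="identity")
    assert dec.summary == pytest.approx(10 * yrs.summary, rel=1e-6)
    assert dec.ci_low < 0.3 < dec.ci_high or abs(dec.summary - 0.3) < 0.2


def test_clinical_covariate_excludes_constant_study(signal_cohort):
    _, bundles, _ = signal_cohort
    mod = [b.copy() for b in bundles]
    mod[0].samples["gender"] = "M"
    res = clinical_covariate_meta(mod, "gender")
    assert res.k == len(bundles) - 1
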