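"""Study bundles: the per-study data unit and its on-disk layout.

A cohort is a list of :class:`StudyBundle`, one per study.  Each bundle
carries a genes x samples expression matrix (continuous, log-scale) and a
per-sample clinical table.  On disk a cohort is a directory with one
subdirectory per study containing ``expr.tsv`` and ``clinical.tsv``; the
same layout serves user-supplied real data and generator output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TISSUE_VALUES = ("tumor", "normal")
HISTOLOGY_VALUES = ("ADC", "SQCC")

#: clinical.tsv columns that are always present
CORE_CLINICAL_COLUMNS = ("tissue", "histology", "os_time", "os_event")


@dataclasses.dataclass
class StudyBundle:
    """One study: expression matrix plus sample annotations.

    Parameters
    ----------
    study_id
        Unique study label.
    expr
        Genes x samples DataFrame; index = gene ids, columns = sample ids.
    samples
        One row per sample, indexed by sample id.  Required columns:
        ``tissue`` ('tumor'/'normal'), ``histology`` ('ADC'/'SQCC'),
        ``os_time`` (months, NaN if missing), ``os_event`` (0/1, NaN if
        missing).  Optional: ``age`` (years), ``gender`` ('M'/'F'),
        ``stage`` (ordinal), and per-driver mutation columns taking values
        'mutant'/'WT'/'missing'.
    """

    study_id: str
    expr: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        if self.samples.index.has_duplicates:
            dupes = self.samples.index[self.samples.index.duplicated()].unique()
            raise ValueError(
                f"study {self.study_id!r}: duplicate sample ids {list(dupes)[:5]}"
            )
        if list(self.expr.columns) != list(self.samples.index):
            missing = set(self.samples.index) ^ set(self.expr.columns)
            raise ValueError(
                f"study {self.study_id!r}: expression columns and clinical rows "
                f"disagree (offenders: {sorted(missing)[:5] or 'order mismatch'})"
            )
        for col in CORE_CLINICAL_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"study {self.study_id!r}: missing column {col!r}")
        bad_tissue = set(self.samples["tissue"]) - set(TISSUE_VALUES)
        if bad_tissue:
            raise ValueError(
                f"study {self.study_id!r}: unknown tissue labels {sorted(bad_tissue)}"
            )
        os_time = pd.to_numeric(self.samples["os_time"], errors="coerce")
        if (os_time.dropna() <= 0).any():
            raise ValueError(f"study {self.study_id!r}: os_time must be > 0")
        os_event = pd.to_numeric(self.samples["os_event"], errors="coerce").dropna()
        if not os_event.isin([0, 1]).all():
            raise ValueError(f"study {self.study_id!r}: os_event must be 0/1")

    # -- convenience selectors ------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return (self.samples["tissue"] == tissue).to_numpy()

    def tumor_ids(self) -> pd.Index:
        return self.samples.index[self.tissue_mask("tumor")]

    def normal_ids(self) -> pd.Index:
        return self.samples.index[self.tissue_mask("normal")]

    def survival_ids(self) -> pd.Index:
        """Tumor samples with non-missing survival time and event."""
        s = self.samples
        ok = (
            (s["tissue"] == "tumor")
            & pd.to_numeric(s["os_time"], errors="coerce").notna()
            & pd.to_numeric(s["os_event"], errors="coerce").notna()
        )
        return s.index[ok]

    def subset_samples(self, sample_ids: Iterable[str]) -> "StudyBundle":
        ids = pd.Index(sample_ids)
        return StudyBundle(
            study_id=self.study_id,
            expr=self.expr.loc[:, ids],
            samples=self.samples.loc[ids],
        )

    def copy(self) -> "StudyBundle":
        return StudyBundle(self.study_id, self.expr.copy(), self.samples.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyBundle):
            return NotImplemented
        return (
            self.study_id == other.study_id
            and self.expr.equals(other.expr)
            and self.samples.equals(other.samples)
        )


# -- disk layout ---------------------------------------------------------

def write_cohort(bundles: list[StudyBundle], directory: str | Path,
                 truth=None) -> Path:
    """Write one subdirectory per study with expr.tsv + clinical.tsv.

    ``truth`` (a :class:`~metacohort.simulate.SyntheticTruth`) is stored as
    truth.json at the cohort root when given.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        d = root / b.study_id
        d.mkdir(exist_ok=True)
        expr = b.expr.copy()
        expr.index.name = "gene_id"
        expr.to_csv(d / "expr.tsv", sep="\t", float_format="%.10g")
        clin = b.samples.copy()
        clin.index.name = "sample_id"
        clin.to_csv(d / "clinical.tsv", sep="\t")
    if truth is not None:
        (root / "truth.json").write_text(json.dumps(truth.to_jsonable(), indent=1))
    return root


def read_cohort(directory: str | Path) -> list[StudyBundle]:
    """Load a cohort directory written by :func:`write_cohort`.

    Cross-checks sample-id agreement between the two files of each study;
    non-numeric expression cells and id mismatches raise with the offending
    study named.
    """
    root = Path(directory)
    study_dirs = sorted(d for d in root.iterdir()
                        if d.is_dir() and (d / "expr.tsv").exists())
    if not study_dirs:
        raise FileNotFoundError(f"no study subdirectories under {root}")
    bundles = []
    for d in study_dirs:
        expr = pd.read_csv(d / "expr.tsv", sep="\t", index_col=0)
        non_numeric = [c for c in expr.columns if not
                       pd.api.types.is_numeric_dtype(expr[c])]
        if non_numeric:
            col = non_numeric[0]
            bad = expr[col][pd.to_numeric(expr[col], errors="coerce").isna()]
            raise ValueError(
                f"study {d.name!r}: non-numeric expression value "
                f"{bad.iloc[0]!r} at gene {bad.index[0]!r}, sample {col!r}"
            )
        clin = pd.read_csv(d / "clinical.tsv", sep="\t", index_col=0)
        clin.index = clin.index.astype(str)
        expr.columns = expr.columns.astype(str)
        if set(expr.columns) != set(clin.index):
            off = sorted(set(expr.columns) ^ set(clin.index))
            raise ValueError(
                f"study {d.name!r}: sample ids disagree between expr.tsv and "
                f"clinical.tsv: {off[:10]}"
            )
        clin = clin.loc[expr.columns]
        bundles.append(StudyBundle(d.name, expr, clin))
    return bundles
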