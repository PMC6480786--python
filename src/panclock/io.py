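"""On-disk artefacts: copy-number, expression and clinical tables, gene lists.

All matrices are TSV with genes as rows (first column the gene identifier) and
samples as columns. Copy-number calls are GISTIC-style discrete indicators:
-2 deep deletion, -1 shallow deletion, 0 neutral, +1 shallow amplification,
+2 deep amplification. Expression is consumed already log2-transformed; no
pseudocount or transform is applied internally.

A cohort directory holds, per cancer type ``<ct>``::

    <ct>.cna.tsv           tumour copy-number calls (genes x samples)
    <ct>.tumour_expr.tsv   tumour log2 expression   (genes x samples)
    <ct>.normal_expr.tsv   normal log2 expression   (genes x samples)
    <ct>.clinical.tsv      clinical records, one row per sample

Readers never reorder: identifier order equals file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset((-2, -1, 0, 1, 2))

CLINICAL_COLUMNS = ["sample_id", "cancer_type", "os_time", "os_event",
                    "tnm_stage", "histology", "tissue"]


class FormatError(ValueError):
    """Raised for malformed input tables (bad codes, duplicate ids, ...)."""


def _check_unique(ids, what: str, source: str) -> None:
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what} in {source}: {sorted(set(dup))[:5]}")


@dataclass
class CNAMatrix:
    """Discrete gene-level copy-number calls, genes x samples."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, source: str = "<in-memory>") -> None:
        _check_unique(self.calls.index, "gene ids", source)
        _check_unique(self.calls.columns, "sample ids", source)
        values = self.calls.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if np.issubdtype(values.dtype, np.floating) and np.all(
                np.isfinite(values)) and np.all(values == np.round(values)):
                self.calls = self.calls.astype(int)
                values = self.calls.to_numpy()
            else:
                raise FormatError(
                    f"non-integer copy-number calls in {source}; discrete "
                    "GISTIC thresholded tables are required (real-valued "
                    "copy-ratio tables are rejected, not re-thresholded)")
        bad = ~np.isin(values, list(VALID_CALLS))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"copy-number call out of range in {source}: gene "
                f"{self.calls.index[g]!r}, sample {self.calls.columns[s]!r}, "
                f"value {values[g, s]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class ExprMatrix:
    """log2-scale expression values, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, source: str = "<in-memory>") -> None:
        _check_unique(self.values.index, "gene ids", source)
        _check_unique(self.values.columns, "sample ids", source)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"non-numeric expression values in {source}")
        if not np.all(np.isfinite(arr)):
            raise FormatError(f"non-finite expression values in {source}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-sample clinical records.

    Columns: sample_id, cancer_type, os_time (days), os_event (0/1),
    tnm_stage (ordinal 1-4, NaN if missing), histology (optional label),
    tissue ('tumour' or 'normal').
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, source: str = "<in-memory>") -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"clinical table {source} lacks columns: {missing}")
        _check_unique(self.table["sample_id"], "sample ids", source)
        if (self.table["os_time"] < 0).any():
            raise FormatError(f"negative os_time in {source}")
        if not self.table["os_event"].isin((0, 1)).all():
            raise FormatError(f"os_event must be 0/1 in {source}")
        stage = self.table["tnm_stage"].dropna()
        if not stage.isin((1, 2, 3, 4)).all():
            raise FormatError(f"tnm_stage must be 1-4 or missing in {source}")
        bad_tissue = set(self.table["tissue"]) - {"tumour", "normal"}
        if bad_tissue:
            raise FormatError(f"unknown tissue labels in {source}: {bad_tissue}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, sample_ids) -> "ClinicalTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return ClinicalTable(keep.reset_index(drop=True))


@dataclass
class Cohort:
    """One cancer type: tumour CNA calls, tumour/normal expression, clinical."""

    name: str
    cna: CNAMatrix
    expr_tumour: ExprMatrix
    expr_normal: ExprMatrix
    clinical: ClinicalTable

    def validate(self) -> None:
        clin = set(self.clinical.sample_ids)
        for label, ids in (("CNA", self.cna.sample_ids),
                           ("tumour expression", self.expr_tumour.sample_ids),
                           ("normal expression", self.expr_normal.sample_ids)):
            orphan = [s for s in ids if s not in clin]
            if orphan:
                raise FormatError(
                    f"cohort {self.name}: {label} samples absent from the "
                    f"clinical table: {orphan[:5]}")
        overlap = set(self.expr_tumour.sample_ids) & set(self.expr_normal.sample_ids)
        if overlap:
            raise FormatError(
                f"cohort {self.name}: samples in both tumour and normal "
                f"expression: {sorted(overlap)[:5]}")


@dataclass
class CohortBundle:
    """Multi-cancer container keyed by cancer type."""

    cohorts: dict[str, Cohort] = field(default_factory=dict)

    @property
    def cancer_types(self) -> list[str]:
        return list(self.cohorts)

    def __getitem__(self, name: str) -> Cohort:
        return self.cohorts[name]

    def __iter__(self):
        return iter(self.cohorts.values())

    def __len__(self) -> int:
        return len(self.cohorts)


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _drop_unknown_samples(df: pd.DataFrame, clinical_ids: set, label: str,
                          cohort: str) -> pd.DataFrame:
    unknown = [s for s in df.columns if s not in clinical_ids]
    if unknown:
        logger.warning("cohort %s: dropping %d %s sample(s) absent from the "
                       "clinical table: %s", cohort, len(unknown), label,
                       unknown[:5])
        df = df.drop(columns=unknown)
    return df


def read_cohort_bundle(directory: str | Path) -> CohortBundle:
    """Read a per-cancer directory of TSV tables into a :class:`CohortBundle`.

    Omics samples absent from the clinical table are dropped with a logged
    warning; malformed tables (out-of-range calls, duplicate ids) raise
    :class:`FormatError` naming the file and offending cell.
    """
    directory = Path(directory)
    clin_files = sorted(directory.glob("*.clinical.tsv"))
    if not clin_files:
        raise FormatError(f"no '*.clinical.tsv' files found in {directory}")
    bundle = CohortBundle()
    for clin_path in clin_files:
        ct = clin_path.name[: -len(".clinical.tsv")]
        clin_df = pd.read_csv(clin_path, sep="\t")
        clinical = ClinicalTable(clin_df)
        clinical.validate(str(clin_path))
        clin_ids = set(clinical.sample_ids)

        cna_path = directory / f"{ct}.cna.tsv"
        tum_path = directory / f"{ct}.tumour_expr.tsv"
        nor_path = directory / f"{ct}.normal_expr.tsv"
        for p in (cna_path, tum_path, nor_path):
            if not p.exists():
                raise FormatError(f"cohort {ct}: missing table {p.name}")

        cna_df = _drop_unknown_samples(_read_matrix(cna_path), clin_ids,
                                       "CNA", ct)
        cna = CNAMatrix.__new__(CNAMatrix)
        cna.calls = cna_df
        cna.validate(str(cna_path))

        tum_df = _drop_unknown_samples(_read_matrix(tum_path), clin_ids,
                                       "tumour expression", ct)
        nor_df = _drop_unknown_samples(_read_matrix(nor_path), clin_ids,
                                       "normal expression", ct)
        expr_t = ExprMatrix.__new__(ExprMatrix)
        expr_t.values = tum_df
        expr_t.validate(str(tum_path))
        expr_n = ExprMatrix.__new__(ExprMatrix)
        expr_n.values = nor_df
        expr_n.validate(str(nor_path))

        cohort = Cohort(ct, cna, expr_t, expr_n, clinical)
        cohort.validate()
        bundle.cohorts[ct] = cohort
    return bundle


def write_cohort_bundle(bundle: CohortBundle, directory: str | Path) -> None:
    """Write a bundle back to the per-cancer TSV layout (round-trip safe)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cohort in bundle:
        ct = cohort.name
        cohort.cna.calls.to_csv(directory / f"{ct}.cna.tsv", sep="\t")
        cohort.expr_tumour.values.to_csv(directory / f"{ct}.tumour_expr.tsv", sep="\t")
        cohort.expr_normal.values.to_csv(directory / f"{ct}.normal_expr.tsv", sep="\t")
        cohort.clinical.table.to_csv(directory / f"{ct}.clinical.tsv", sep="\t",
                                     index=False)


# ---------------------------------------------------------------------------
# gene lists


def _dedup(name: str, genes: list[str]) -> list[str]:
    seen, out, dups = set(), [], []
    for g in genes:
        if g in seen:
            dups.append(g)
        else:
            seen.add(g)
            out.append(g)
    if dups:
        logger.warning("gene set %s: removed duplicate members %s", name, dups[:5])
    if not out:
        raise FormatError(f"gene set {name} is empty")
    return out


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read named gene collections.

    ``.gmt`` files yield one set per line (``name<TAB>description<TAB>genes...``);
    any other file is a plain one-gene-per-line list named after the file stem.
    Lines starting with ``#`` and blank lines are ignored. Duplicate members are
    removed with a warning; an empty set is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(
                        f"GMT line in {path} needs name, description and at "
                        f"least one gene: {line[:60]!r}")
                sets[parts[0]] = _dedup(parts[0], [g for g in parts[2:] if g])
    else:
        with open(path) as fh:
            genes = [ln.strip() for ln in fh
                     if ln.strip() and not ln.startswith("#")]
        sets[path.stem] = _dedup(path.stem, genes)
    if not sets:
        raise FormatError(f"no gene sets found in {path}")
    return sets


def _packaged_list(filename: str) -> list[str]:
    text = (_ilres.files("panclock.resources") / filename).read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def clock_genes() -> list[str]:
    """The packaged 32 core circadian clock genes."""
    return _packaged_list("clock_genes.txt")


def hypoxia_signature() -> list[str]:
    """The packaged 52-gene tumour hypoxia signature."""
    return _packaged_list("hypoxia_signature_52.txt")
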