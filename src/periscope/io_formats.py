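"""Readers, writers and validated containers for every external format the pipeline touches.

The pipeline's root inputs are a gene × sample raw count matrix (TSV or
MatrixMarket triplet), gene-set collections (GMT), per-sample clonotype
tables (MiXCR-export-like or AIRR-style TSV) and a clinical sample
metadata table (CSV).  Each container validates its invariants on
construction, so downstream stages can assume well-formed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ValidationError",
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ClonotypeTable",
    "SampleTable",
    "TIMEPOINTS",
    "ARMS",
    "SUBTYPES",
    "RESPONSES",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_clonotypes",
    "write_clonotypes",
    "read_sample_table",
    "write_sample_table",
    "summarize_response_rates",
    "validate_files",
]

#: Longitudinal sampling schedule: baseline (T0), after one treatment cycle
#: (T1), between study treatment and anthracycline (T2), and surgery (T3).
TIMEPOINTS = ("Baseline", "EarlyTreatment", "InterReg", "Endpoint")
#: Treatment arms: paclitaxel control, paclitaxel + pembrolizumab, and the
#: oral-paclitaxel + dostarlimab validation arm.
ARMS = ("Chemo", "ChemoPembro", "Dostar")
SUBTYPES = ("HRpos", "TNBC")
RESPONSES = ("pCR", "RD", "unknown")


class ValidationError(ValueError):
    """An input file or container violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CountMatrix:
    """Raw gene × sample integer counts.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers.  Gene identifiers are treated as
        opaque strings (no symbol/Ensembl mapping is attempted).
    counts
        Non-negative integer matrix of shape ``(n_genes, n_samples)``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {arr.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.issubdtype(arr.dtype, np.integer):
            frac = np.asarray(arr, dtype=float)
            bad = np.argwhere(frac != np.round(frac))
            if bad.size:
                g, s = bad[0]
                raise ValidationError(
                    "non-integer count at "
                    f"(gene={self.gene_ids[g]}, sample={self.sample_ids[s]}): {frac[g, s]}"
                )
            arr = np.round(frac).astype(np.int64)
        neg = np.argwhere(arr < 0)
        if neg.size:
            g, s = neg[0]
            raise ValidationError(
                f"negative count at (gene={self.gene_ids[g]}, sample={self.sample_ids[s]})"
            )
        self.counts = arr.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return CountMatrix(list(self.gene_ids), list(samples), self.counts[:, cols])


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"genes in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection(Mapping[str, GeneSet]):
    """Ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValidationError(f"duplicate gene-set name {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection([self._sets[n] for n in names])


@dataclass
class ClonotypeTable:
    """Per-sample CDR3 clone abundances; identical CDR3 rows are merged."""

    sample_id: str
    clones: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["cdr3", "count"]))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.clones)
        if df.empty:
            self.clones = pd.DataFrame({"cdr3": pd.Series(dtype=str), "count": pd.Series(dtype=np.int64)})
            return
        if not {"cdr3", "count"}.issubset(df.columns):
            raise ValidationError("clonotype table needs 'cdr3' and 'count' columns")
        df = df[["cdr3", "count"]].copy()
        df["cdr3"] = df["cdr3"].astype(str)
        if (df["cdr3"].str.len() == 0).any():
            raise ValidationError(f"empty CDR3 string in sample {self.sample_id}")
        counts = pd.to_numeric(df["count"])
        if (counts <= 0).any():
            bad = df.loc[counts <= 0, "cdr3"].tolist()[:5]
            raise ValidationError(f"non-positive clone count in sample {self.sample_id} for {bad}")
        df["count"] = counts.astype(np.int64)
        merged = df.groupby("cdr3", sort=True, as_index=False)["count"].sum()
        self.clones = merged

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def total_reads(self) -> int:
        return int(self.clones["count"].sum()) if len(self.clones) else 0


_REQUIRED_SAMPLE_COLUMNS = [
    "sample_id",
    "patient_id",
    "timepoint",
    "arm",
    "clinical_subtype",
    "response",
]
_OPTIONAL_SAMPLE_COLUMNS = ["drfs_time", "drfs_event", "batch"]


@dataclass
class SampleTable:
    """Per-sample clinical and longitudinal annotations.

    Wraps a DataFrame with one row per sequenced blood sample.  The
    vocabulary of ``timepoint``, ``arm``, ``clinical_subtype`` and
    ``response`` is closed; survival columns (``drfs_time`` in consistent
    time units, ``drfs_event`` 0/1) and ``batch`` are optional.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.frame).copy()
        missing = [c for c in _REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        for col, vocab in [
            ("timepoint", TIMEPOINTS),
            ("arm", ARMS),
            ("clinical_subtype", SUBTYPES),
            ("response", RESPONSES),
        ]:
            vals = df[col].astype(str)
            bad = ~vals.isin(vocab)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"unknown {col} token {vals.iloc[row]!r} in row {row} "
                    f"(allowed: {list(vocab)})"
                )
            df[col] = vals
        _check_unique(list(df["sample_id"].astype(str)), "sample ids")
        pairs = list(zip(df["patient_id"].astype(str), df["timepoint"]))
        _check_unique([f"{p}:{t}" for p, t in pairs], "(patient, timepoint) pairs")
        per_patient = df.groupby("patient_id")["response"].nunique()
        inconsistent = per_patient[per_patient > 1]
        if len(inconsistent):
            raise ValidationError(
                f"response label not constant within patient(s): {list(inconsistent.index)}"
            )
        if "drfs_time" in df.columns:
            t = pd.to_numeric(df["drfs_time"], errors="coerce")
            if (t.dropna() < 0).any():
                raise ValidationError("negative drfs_time")
            df["drfs_time"] = t
        if "drfs_event" in df.columns:
            e = pd.to_numeric(df["drfs_event"], errors="coerce")
            if not e.dropna().isin([0, 1]).all():
                raise ValidationError("drfs_event must be 0/1")
            df["drfs_event"] = e
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def select(self, **conditions) -> pd.DataFrame:
        df = self.frame
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set)):
                df = df[df[col].isin(list(val))]
            else:
                df = df[df[col] == val]
        return df

    def patients(self) -> pd.DataFrame:
        """One row per patient with the sample-constant annotations."""
        cols = ["patient_id", "arm", "clinical_subtype", "response"]
        cols += [c for c in ("drfs_time", "drfs_event") if c in self.frame.columns]
        return self.frame[cols].drop_duplicates("patient_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Count matrix I/O


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a gene × sample count matrix.

    ``tsv``: gene rows × sample columns with a header line.
    ``mtx_triplet``: MatrixMarket coordinate file ``<path>`` with companion
    name files ``<path>.rows`` (genes) and ``<path>.cols`` (samples).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())
    if format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        return CountMatrix(genes, samples, np.asarray(mat))
    raise ValueError(f"unknown count-matrix format {format!r}")


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.counts), field="integer")
        Path(str(path) + ".rows").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within one line are de-duplicated with a warning.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} de-duplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, desc, uniq))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection.values():
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Clonotype tables

#: Column-name lookup table for clonotype dialects; first match wins.
CLONOTYPE_DIALECTS: dict[str, tuple[str, str]] = {
    "mixcr": ("aaSeqCDR3", "cloneCount"),
    "airr": ("junction_aa", "duplicate_count"),
    "plain": ("cdr3", "count"),
}


def read_clonotypes(
    path: str | Path,
    sample_id: str | None = None,
    cdr3_column: str | None = None,
    count_column: str | None = None,
) -> ClonotypeTable:
    """Read a tab-delimited clonotype export.

    Column names are auto-detected against :data:`CLONOTYPE_DIALECTS`
    (MiXCR export, AIRR, plain) unless given explicitly.  Rows sharing a
    CDR3 sequence are merged by summing counts.  An empty file yields an
    empty table (the diversity stage will exclude it).
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return ClonotypeTable(sid)
    if df.empty:
        return ClonotypeTable(sid)
    if cdr3_column is None or count_column is None:
        for c3, cc in CLONOTYPE_DIALECTS.values():
            if c3 in df.columns and cc in df.columns:
                cdr3_column, count_column = c3, cc
                break
        else:
            raise ValidationError(
                f"{path}: could not detect clonotype columns among {list(df.columns)}"
            )
    frame = df[[cdr3_column, count_column]].rename(
        columns={cdr3_column: "cdr3", count_column: "count"}
    )
    return ClonotypeTable(sid, frame)


def write_clonotypes(table: ClonotypeTable, path: str | Path, dialect: str = "airr") -> None:
    c3, cc = CLONOTYPE_DIALECTS[dialect]
    table.clones.rename(columns={"cdr3": c3, "count": cc}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample metadata


def read_sample_table(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path))


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def summarize_response_rates(table: SampleTable) -> pd.DataFrame:
    """Per (clinical subtype × arm) patient counts and pCR rate in percent.

    Patients with unknown response are excluded from the denominator.
    """
    pats = table.patients()
    pats = pats[pats["response"].isin(["pCR", "RD"])]
    rows = []
    for (subtype, arm), grp in pats.groupby(["clinical_subtype", "arm"], sort=True):
        n = len(grp)
        n_pcr = int((grp["response"] == "pCR").sum())
        rows.append(
            {
                "clinical_subtype": subtype,
                "arm": arm,
                "n_patients": n,
                "n_pcr": n_pcr,
                "pcr_rate_percent": round(100.0 * n_pcr / n, 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Validation report (CLI support)


def validate_files(specs: Iterable[tuple[str, str]]) -> list[dict]:
    """Validate ``(kind, path)`` pairs; kinds: counts_tsv, counts_mtx, gmt,
    clonotypes, samples.  Returns one report dict per file."""
    readers = {
        "counts_tsv": lambda p: read_count_matrix(p, "tsv"),
        "counts_mtx": lambda p: read_count_matrix(p, "mtx_triplet"),
        "gmt": read_gmt,
        "clonotypes": read_clonotypes,
        "samples": read_sample_table,
    }
    reports = []
    for kind, path in specs:
        rep = {"kind": kind, "path": str(path), "ok": True, "detail": ""}
        try:
            obj = readers[kind](path)
        except Exception as exc:  # noqa: BLE001 - report, do not crash
            rep["ok"] = False
            rep["detail"] = f"{type(exc).__name__}: {exc}"
        else:
            if isinstance(obj, CountMatrix):
                rep["detail"] = f"{obj.shape[0]} genes x {obj.shape[1]} samples"
            elif isinstance(obj, GeneSetCollection):
                rep["detail"] = f"{len(obj)} gene sets"
            elif isinstance(obj, ClonotypeTable):
                rep["detail"] = f"{obj.n_clones} clones, {obj.total_reads} reads"
            elif isinstance(obj, SampleTable):
                rep["detail"] = f"{len(obj)} samples"
        reports.append(rep)
    return reports
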