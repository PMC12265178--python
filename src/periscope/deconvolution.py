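"""Reference-based immune-cell fraction estimation by non-negative least squares.

Given a signature matrix of cell-type expression profiles over marker
genes, each bulk sample's linear-scale expression is decomposed as a
non-negative combination of the profiles (``min ||R^T x - b||, x >= 0``).
``absolute`` mode reports the raw coefficients as abundance scores;
``relative`` mode renormalizes them to fractions summing to one.  A
derived combined-monocyte row (classical + non-classical) is exposed for
monocyte-abundance contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import CountMatrix, GeneSetCollection, ValidationError
from .preprocess import TransformedMatrix

__all__ = [
    "DeconvReference",
    "CellFractionMatrix",
    "build_reference",
    "reference_from_marker_sets",
    "estimate_fractions",
    "add_monocyte_aggregate",
]

MONOCYTE_TYPES = ("Monocyte_nonclassical", "Monocyte_classical")


@dataclass
class DeconvReference:
    """Cell-type × signature-gene profile matrix (non-negative, linear scale)."""

    cell_types: list[str]
    signature_genes: list[str]
    profiles: np.ndarray
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.profiles, dtype=float)
        if arr.shape != (len(self.cell_types), len(self.signature_genes)):
            raise ValidationError("profile shape inconsistent with labels")
        if (arr < 0).any():
            raise ValidationError("negative reference profile entries")
        if len(self.cell_types) < 2:
            raise ValidationError("need >= 2 cell types")
        self.profiles = arr
        self.condition_number = float(np.linalg.cond(arr @ arr.T))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.cell_types, columns=self.signature_genes)


@dataclass
class CellFractionMatrix:
    cell_types: list[str]
    sample_ids: list[str]
    fractions: np.ndarray
    mode: str = "absolute"

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.shape != (len(self.cell_types), len(self.sample_ids)):
            raise ValidationError("fraction shape inconsistent with labels")
        if (arr < -1e-12).any():
            raise ValidationError("negative cell fractions")
        self.fractions = np.maximum(arr, 0.0)
        if self.mode not in {"absolute", "relative"}:
            raise ValidationError(f"unknown mode {self.mode!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.cell_types, columns=self.sample_ids)


def build_reference(
    profiles: pd.DataFrame, marker_sets: GeneSetCollection | None = None
) -> DeconvReference:
    """Build a deconvolution reference from cell-type × gene profiles.

    Restricted to the union of marker genes when ``marker_sets`` is
    given (set names must match cell types to contribute), and scaled so
    every cell-type profile has equal total.  Collinear profile pairs
    raise an error naming the offending types.
    """
    df = pd.DataFrame(profiles).astype(float)
    if marker_sets is not None:
        union: list[str] = []
        for gs in marker_sets.values():
            union += [g for g in gs.genes if g in df.columns]
        union = list(dict.fromkeys(union))
        if not union:
            raise ValidationError("no marker genes present in profile matrix")
        df = df[union]
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals[totals <= 0].index)
        raise ValidationError(f"cell type(s) with all-zero profile: {bad}")
    df = df.div(totals, axis=0)
    arr = df.to_numpy()
    norms = np.linalg.norm(arr, axis=1)
    gram = (arr / norms[:, None]) @ (arr / norms[:, None]).T
    np.fill_diagonal(gram, 0.0)
    i, j = np.unravel_index(np.argmax(gram), gram.shape)
    if gram[i, j] > 1 - 1e-10:
        raise ValidationError(
            f"collinear cell-type profiles: {df.index[i]!r} and {df.index[j]!r}"
        )
    return DeconvReference(list(df.index), list(df.columns), arr)


def reference_from_marker_sets(
    marker_sets: GeneSetCollection,
    cell_types: "list[str] | None" = None,
    fold: float = 6.0,
    baseline: float = 1.0,
) -> DeconvReference:
    """Block-structured reference built from disjoint marker sets.

    Each cell type's profile equals ``baseline`` everywhere on the union
    of marker genes and ``fold`` on its own markers — the idealized
    counterpart of a marker-block expression design.
    """
    names = cell_types if cell_types is not None else [n for n in marker_sets]
    union: list[str] = []
    for name in names:
        union += [g for g in marker_sets[name].genes]
    union = list(dict.fromkeys(union))
    prof = pd.DataFrame(baseline, index=names, columns=union, dtype=float)
    for name in names:
        prof.loc[name, [g for g in marker_sets[name].genes]] = fold
    return build_reference(prof)


def _linear_expression(values: TransformedMatrix | CountMatrix) -> pd.DataFrame:
    if isinstance(values, CountMatrix):
        return values.to_frame().astype(float)
    # log2(x + 1)-scale input back to linear scale
    return pd.DataFrame(
        np.power(2.0, values.values) - 1.0, index=values.gene_ids, columns=values.sample_ids
    ).clip(lower=0.0)


def estimate_fractions(
    values: TransformedMatrix | CountMatrix,
    ref: DeconvReference,
    mode: str = "absolute",
) -> CellFractionMatrix:
    """Per-sample non-negative least-squares mixture coefficients.

    ``TransformedMatrix`` input is exponentiated back to the linear
    scale before solving.  Samples whose signature genes are all zero
    get all-zero fractions with a warning.
    """
    expr = _linear_expression(values)
    missing = [g for g in ref.signature_genes if g not in expr.index]
    if missing:
        raise ValidationError(f"signature genes absent from expression matrix: {missing[:5]}")
    b_mat = expr.loc[ref.signature_genes].to_numpy()
    # scale each sample's signature expression to unit total so the
    # coefficients are comparable across library sizes
    a = ref.profiles.T  # gene x cell type
    out = np.zeros((len(ref.cell_types), b_mat.shape[1]))
    for j in range(b_mat.shape[1]):
        b = b_mat[:, j]
        tot = b.sum()
        if tot <= 0:
            warnings.warn(
                f"sample {expr.columns[j]!r}: all signature genes zero; fractions set to 0",
                stacklevel=2,
            )
            continue
        coef, _ = nnls(a, b / tot)
        out[:, j] = coef
    if mode == "relative":
        sums = out.sum(axis=0)
        nonzero = sums > 0
        out[:, nonzero] = out[:, nonzero] / sums[nonzero]
    return CellFractionMatrix(list(ref.cell_types), list(expr.columns), out, mode=mode)


def add_monocyte_aggregate(
    fractions: CellFractionMatrix, monocyte_types: tuple[str, str] = MONOCYTE_TYPES
) -> pd.DataFrame:
    """Fraction table with a derived combined-monocyte row appended."""
    df = fractions.to_frame()
    present = [t for t in monocyte_types if t in df.index]
    if not present:
        raise ValidationError(f"no monocyte rows among {list(df.index)}")
    agg = df.loc[present].sum(axis=0)
    agg.name = "Monocyte_combined"
    return pd.concat([df, agg.to_frame().T])
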