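"""Relative gene expression from single-cell triplicate Ct tables (2^-ddCt).

Replicates above the limit of detection (Ct > 37 by default, strict — 37.0
itself survives) or missing are dropped before averaging; a cell x gene with
no surviving replicate is censored.  dCt is the target Ct minus the
arithmetic mean of the reference-gene Cts (equivalent to normalizing
expression by the geometric mean of the references).  ddCt subtracts a
calibrator dCt; the default calibrator is the cohort mean dCt of each
target, making reported values fold changes relative to the cohort average.
A designated calibrator cell (e.g. a positive-control cell) or no calibrator
at all (values are then expression relative to the references) can be
selected instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PreconditionError, ValidationError
from .synthetic_data import QpcrPlate

__all__ = [
    "RelativeAbundance",
    "collapse_replicates",
    "relative_abundance",
    "summarize_abundance",
    "read_plate",
    "write_plate",
]


@dataclass
class RelativeAbundance:
    """Per (cell, gene) 2^-ddCt values; NaN marks censored entries."""

    values: pd.DataFrame            # index cell_id, columns target genes
    reference_genes: list[str] = field(default_factory=list)
    calibrator: str = "cohort-mean"


def collapse_replicates(plate: QpcrPlate) -> pd.DataFrame:
    """Mean Ct per (cell, gene) after the limit-of-detection rule.

    Replicates with Ct above ``plate.lod_ct`` (strictly) or missing are
    dropped; (cell, gene) combinations with no surviving replicate are
    censored (NaN).  Returns a cell x gene table of mean Cts.
    """
    df = plate.data.copy()
    df.loc[df["ct"] > plate.lod_ct, "ct"] = np.nan
    table = df.pivot_table(
        index="cell_id", columns="gene", values="ct", aggfunc="mean", dropna=False
    )
    return table


def relative_abundance(
    cts: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str],
    calibrator: str | None = "cohort-mean",
) -> RelativeAbundance:
    """2^-ddCt relative expression of ``targets`` normalized to ``references``.

    Parameters
    ----------
    cts
        Collapsed cell x gene mean-Ct table (from :func:`collapse_replicates`).
    targets, references
        Gene names; references must be present and uncensored in a cell for
        that cell to contribute (cells with a censored reference are excluded
        with a warning).
    calibrator
        ``"cohort-mean"`` (default): ddCt = dCt - mean cohort dCt per target;
        a cell_id: that cell's dCt is the calibrator; ``None``: ddCt = dCt,
        so values are expression relative to the reference genes.

    Cells with a censored target Ct yield a censored (NaN) value for that
    gene only.
    """
    targets = list(targets)
    references = list(references)
    missing = [g for g in targets + references if g not in cts.columns]
    if missing:
        raise PreconditionError(f"genes absent from the Ct table: {missing}")

    ref_ct = cts[references].mean(axis=1, skipna=False)
    usable = ref_ct.notna()
    if (~usable).any():
        excluded = list(cts.index[~usable])
        warnings.warn(
            f"excluding cells with a censored reference gene: {excluded}"
        )
    cts = cts.loc[usable]
    ref_ct = ref_ct.loc[usable]
    if cts.empty:
        raise PreconditionError("no cell has uncensored reference genes")

    dct = cts[targets].sub(ref_ct, axis=0)
    if calibrator is None:
        ddct = dct
    elif calibrator == "cohort-mean":
        ddct = dct.sub(dct.mean(axis=0, skipna=True), axis=1)
    else:
        if calibrator not in dct.index:
            raise PreconditionError(f"calibrator cell {calibrator!r} not in table")
        cal = dct.loc[calibrator]
        if cal.isna().any():
            raise PreconditionError(
                f"calibrator cell {calibrator!r} has censored target genes"
            )
        ddct = dct.sub(cal, axis=1)
    values = np.power(2.0, -ddct)
    return RelativeAbundance(
        values=values,
        reference_genes=references,
        calibrator="none" if calibrator is None else str(calibrator),
    )


def summarize_abundance(ra: RelativeAbundance) -> pd.DataFrame:
    """Per-gene summary: n, mean, median, quartiles, s.e.m.

    ``n`` reflects censoring exclusions; genes with no uncensored value are
    omitted with a warning.  The s.e.m. of a single value is emitted as NaN.
    """
    rows = []
    for gene in ra.values.columns:
        vals = ra.values[gene].dropna()
        if vals.empty:
            warnings.warn(f"all values censored for {gene!r}; omitting from summary")
            continue
        n = int(vals.size)
        rows.append(
            {
                "gene": gene,
                "n": n,
                "mean": float(vals.mean()),
                "median": float(vals.median()),
                "q1": float(vals.quantile(0.25)),
                "q3": float(vals.quantile(0.75)),
                "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()


# ---------------------------------------------------------------------------
# table I/O (delimited text: cell_id, gene, replicate, ct; empty ct = missing)
# ---------------------------------------------------------------------------

def write_plate(plate: QpcrPlate, path: str | Path) -> None:
    plate.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_plate(path: str | Path, lod_ct: float = 37.0) -> QpcrPlate:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: not a readable Ct table: {exc}") from exc
    required = {"cell_id", "gene", "replicate", "ct"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: Ct table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    try:
        return QpcrPlate(data=df, lod_ct=lod_ct)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc
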