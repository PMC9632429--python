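"""Differential-expression calls from per-contrast DE tables.

A gene is called differentially expressed in a contrast when all three
criteria hold simultaneously: |log2FC| ≥ 2, adjusted p ≤ 0.01, and the larger
of the two group-mean abundances ≥ 2 TPM.  Calls are encoded 0 (not DE),
1 (up), 2 (down); the encoding feeds the DEFE pattern stage directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

NOT_DE, UP, DOWN = 0, 1, 2


@dataclass
class DegThresholds:
    """The three-part DEG criterion; all boundaries are inclusive."""

    lfc_min: float = 2.0
    padj_max: float = 0.01
    tpm_min: float = 2.0
    #: with "replicate", the abundance criterion uses the max over individual
    #: replicates instead of the max of the two group means
    tpm_mode: str = "group_mean"

    def __post_init__(self) -> None:
        if self.lfc_min <= 0 or self.padj_max <= 0 or self.tpm_min <= 0:
            raise ValueError("all DEG thresholds must be positive")
        if self.tpm_mode not in ("group_mean", "replicate"):
            raise ValueError(f"unknown tpm_mode {self.tpm_mode!r}")


@dataclass
class ContrastTable:
    """Per-gene (log2FC, adjusted p) for one named two-group comparison."""

    name: str
    table: pd.DataFrame  # index: gene id; columns: log2fc, padj
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("log2fc", "padj"):
            if col not in self.table.columns:
                raise ValueError(f"contrast {self.name!r} lacks column {col!r}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"contrast {self.name!r}: duplicate gene {dup!r}")
        padj = self.table["padj"].to_numpy()
        finite = np.isfinite(padj)
        if ((padj[finite] < 0) | (padj[finite] > 1)).any():
            raise ValueError(f"contrast {self.name!r}: padj outside [0, 1]")
        if self.group_a and self.group_b and set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name!r}: sample groups overlap")


def filter_degs(
    contrast: ContrastTable,
    expr: ExpressionMatrix,
    thresholds: DegThresholds | None = None,
) -> pd.Series:
    """Apply the three-part DEG criterion to one contrast.

    Returns a status series over the expression matrix's genes (0/1/2).
    Genes absent from the contrast table default to 0 and are logged.
    Raises if the contrast names a gene missing from the expression matrix or
    carries a non-finite fold change at a significant adjusted p.
    """
    th = thresholds or DegThresholds()

    missing_expr = contrast.table.index.difference(expr.genes)
    if len(missing_expr):
        raise KeyError(
            f"contrast {contrast.name!r}: gene {missing_expr[0]!r} absent "
            "from the expression matrix"
        )
    if not contrast.group_a or not contrast.group_b:
        raise ValueError(f"contrast {contrast.name!r} has no sample groups")

    tab = contrast.table.reindex(expr.genes)
    lfc = tab["log2fc"].to_numpy(float)
    padj = tab["padj"].to_numpy(float)

    bad = ~np.isfinite(lfc) & (padj <= th.padj_max)
    if bad.any():
        gene = expr.genes[bad][0]
        raise ValueError(
            f"contrast {contrast.name!r}: non-finite log2fc for significant "
            f"gene {gene!r}"
        )

    absent = tab["log2fc"].isna().sum()
    if absent:
        log.info(
            "contrast %s: %d genes absent from the table, status set to 0",
            contrast.name,
            absent,
        )

    if th.tpm_mode == "group_mean":
        abund_a = expr.group_mean_tpm(contrast.group_a).to_numpy(float)
        abund_b = expr.group_mean_tpm(contrast.group_b).to_numpy(float)
        abund = np.maximum(abund_a, abund_b)
    else:
        abund = (
            expr.values[contrast.group_a + contrast.group_b]
            .max(axis=1)
            .to_numpy(float)
        )

    with np.errstate(invalid="ignore"):
        passes = (padj <= th.padj_max) & (abund >= th.tpm_min)
        up = passes & (lfc >= th.lfc_min)
        down = passes & (lfc <= -th.lfc_min)

    status = np.zeros(len(expr.genes), dtype=np.int8)
    status[up] = UP
    status[down] = DOWN
    return pd.Series(status, index=expr.genes, name=contrast.name)


def call_table(
    contrasts: list[ContrastTable],
    expr: ExpressionMatrix,
    thresholds: DegThresholds | None = None,
) -> pd.DataFrame:
    """Gene × contrast status matrix over a list of contrasts."""
    if not contrasts:
        raise ValueError("no contrasts given")
    return pd.concat([filter_degs(c, expr, thresholds) for c in contrasts], axis=1)


def union_deg_set(calls: pd.DataFrame) -> set[str]:
    """Genes called DE (status ≠ 0) in at least one contrast."""
    if calls.empty or calls.shape[1] == 0:
        raise ValueError("empty DEG call table")
    mask = (calls != NOT_DE).any(axis=1)
    return set(calls.index[mask])
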