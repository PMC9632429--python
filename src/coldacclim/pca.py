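"""PCA over the DEG expression matrix and group-separation summaries.

A single SVD of the gene × sample matrix (genes as observations) supplies
both gene scores — used to ask how well gene groups such as the winter-habit
vs spring-habit genes separate in PC space — and sample loadings, which show
how experimental conditions distribute over components.  Separation between
two gene groups on a chosen component subset is quantified by the silhouette
score and the centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score


@dataclass
class PcaResult:
    scores: pd.DataFrame  # genes × components
    loadings: pd.DataFrame  # samples × components
    variance_explained: np.ndarray  # fraction per component

    @property
    def n_components(self) -> int:
        return len(self.variance_explained)

    def component_scores(self, components: list[int]) -> pd.DataFrame:
        """Scores restricted to 1-based component indices."""
        cols = [f"PC{c}" for c in components]
        return self.scores[cols]


def run_pca(expr_rows: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """SVD-based PCA of genes (rows) over sample dimensions.

    Rows are centered — and scaled to unit variance when ``standardize`` —
    across samples before decomposition.  Components are ordered by
    decreasing variance and sign-canonicalized so the largest-magnitude
    sample loading of each component is positive.
    """
    if expr_rows.shape[0] < 2 or expr_rows.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if expr_rows.isna().any().any():
        raise ValueError("missing values not allowed in PCA input")
    x = expr_rows.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    if standardize:
        sd = x.std(axis=1, keepdims=True)
        flat = sd[:, 0] == 0.0
        if flat.any():
            genes = list(expr_rows.index[flat][:10])
            raise ValueError(f"constant rows cannot be standardized: {genes}")
        x = x / sd

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # canonical sign: largest-magnitude sample loading positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]

    var = s**2
    frac = var / var.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=expr_rows.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=expr_rows.columns, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, variance_explained=frac)


@dataclass
class SeparationReport:
    group_a: str
    group_b: str
    components: tuple[int, ...]
    silhouette: float
    centroid_distance: float


def separation(
    pca: PcaResult,
    group_a: set[str],
    group_b: set[str],
    components: list[int] = (1, 2, 3),
    names: tuple[str, str] = ("A", "B"),
) -> SeparationReport:
    """Silhouette and centroid distance between two gene groups in PC space."""
    if group_a & group_b:
        raise ValueError("gene groups must be disjoint")
    idx = pca.scores.index
    a = sorted(group_a & set(idx))
    b = sorted(group_b & set(idx))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 members present in the PCA")
    comps = [c for c in components if c <= pca.n_components]
    sub = pca.component_scores(comps)
    xa, xb = sub.loc[a].to_numpy(), sub.loc[b].to_numpy()
    x = np.vstack([xa, xb])
    labels = np.array([0] * len(a) + [1] * len(b))
    sil = float(silhouette_score(x, labels))
    dist = float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    return SeparationReport(
        group_a=names[0],
        group_b=names[1],
        components=tuple(comps),
        silhouette=sil,
        centroid_distance=dist,
    )
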