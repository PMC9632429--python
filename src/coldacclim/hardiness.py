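"""Cold-hardiness index and hardy / anti-hardy gene classification.

The index scales freezing tolerance onto (0, 1):

    H = LT50 / (−25)

where −25 °C is the temperature below which most wheat genotypes perish, so
hardier genotypes (more negative LT50) map to larger H.  A gene is *cold
hardy* when both its per-genotype cold/control log2 fold changes and its
per-genotype cold-treatment expression means correlate positively and
significantly (p ≤ 0.05) with H, and it is cold-induced in every genotype.
A gene is *anti-hardy* when it is significantly down-regulated by cold in the
hardiest genotype and both correlations are negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import DOWN
from .design import COLD, CONTROL, StudyDesign
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

PERISH_TEMPERATURE = -25.0

HARDY, ANTI_HARDY, NONE = "hardy", "anti_hardy", "none"


def hardiness_index(lt50: float) -> float:
    """H = LT50 / (−25); raises for non-negative LT50, warns below −25 °C."""
    if lt50 >= 0:
        raise ValueError(f"LT50 must be negative, got {lt50}")
    if lt50 < PERISH_TEMPERATURE:
        warnings.warn(
            f"LT50 {lt50} °C below {PERISH_TEMPERATURE} °C gives H > 1",
            stacklevel=2,
        )
    return lt50 / PERISH_TEMPERATURE


@dataclass(frozen=True)
class HardinessProfile:
    """Genotype → (LT50, H) in a fixed genotype order."""

    genotypes: tuple[str, ...]
    lt50: tuple[float, ...]

    @classmethod
    def from_design(cls, design: StudyDesign) -> "HardinessProfile":
        return cls(
            genotypes=tuple(design.genotypes),
            lt50=tuple(design.lt50[g] for g in design.genotypes),
        )

    @property
    def h(self) -> np.ndarray:
        return np.array([hardiness_index(v) for v in self.lt50])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lt50": self.lt50, "H": self.h}, index=pd.Index(self.genotypes, name="genotype")
        )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-distribution p-value (n − 2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors with n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    r = float((xd * yd).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at two-sided level alpha for n pairs."""
    t = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))


@dataclass
class HardyCall:
    gene: str
    label: str
    r_lfc: float
    p_lfc: float
    r_expr: float
    p_expr: float
    up_in_all_cold: bool
    down_in_hardiest: bool


def classify_hardy(
    gene: str,
    lfc_by_genotype: pd.Series,
    cold_means: pd.Series,
    control_means: pd.Series,
    hardiest_status: int,
    profile: HardinessProfile,
    alpha: float = 0.05,
    require_anti_significance: bool = False,
) -> HardyCall:
    """Classify one gene as hardy / anti-hardy / none.

    Parameters
    ----------
    lfc_by_genotype
        Cold-vs-control log2FC, one value per genotype in profile order.
    cold_means, control_means
        Replicate-averaged log2(TPM+1) expression per genotype.
    hardiest_status
        The gene's DEG status (0/1/2) in the cold/control contrast of the
        genotype with the largest H.
    require_anti_significance
        Also require p ≤ alpha for the anti-hardy correlations (off by
        default; the anti-hardy definition only demands negative signs).
    """
    h = profile.h
    order = list(profile.genotypes)
    lfc = lfc_by_genotype.reindex(order).to_numpy(float)
    cold = cold_means.reindex(order).to_numpy(float)
    ctrl = control_means.reindex(order).to_numpy(float)
    if np.isnan(lfc).any() or np.isnan(cold).any() or np.isnan(ctrl).any():
        raise ValueError(f"gene {gene!r}: missing per-genotype value")

    try:
        r_lfc, p_lfc = pearson_with_p(h, lfc)
        r_expr, p_expr = pearson_with_p(h, cold)
    except ValueError:
        # degenerate (flat) profile: correlation undefined, classify as none
        log.info("gene %s: zero-variance profile, classified as none", gene)
        return HardyCall(gene, NONE, np.nan, np.nan, np.nan, np.nan, False, False)

    up_all = bool((cold > ctrl).all())
    down_hardiest = hardiest_status == DOWN

    label = NONE
    if p_lfc <= alpha and p_expr <= alpha and r_lfc > 0 and r_expr > 0 and up_all:
        label = HARDY
    elif down_hardiest and r_lfc < 0 and r_expr < 0:
        if not require_anti_significance or (p_lfc <= alpha and p_expr <= alpha):
            label = ANTI_HARDY
    return HardyCall(gene, label, r_lfc, p_lfc, r_expr, p_expr, up_all, down_hardiest)


def classify_all(
    expr: ExpressionMatrix,
    contrasts: dict[str, pd.DataFrame],
    calls: pd.DataFrame,
    design: StudyDesign,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    require_anti_significance: bool = False,
) -> pd.DataFrame:
    """Hardy classification over many genes.

    ``contrasts`` maps cold/control contrast names to their tables; ``calls``
    is the gene × contrast DEG status table (used for the down-in-hardiest
    criterion).  Returns a frame indexed by gene with label and statistics.
    """
    profile = HardinessProfile.from_design(design)
    hardiest = design.genotypes[int(np.argmax(profile.h))]
    hardiest_contrast = design.cold_control_contrast(hardiest)

    lfc = pd.DataFrame(
        {
            g: contrasts[design.cold_control_contrast(g)]["log2fc"]
            for g in design.genotypes
        }
    )
    cold_means = expr.genotype_treatment_means(design, COLD)
    ctrl_means = expr.genotype_treatment_means(design, CONTROL)

    if genes is None:
        genes = list(expr.genes)
    rows = []
    for gene in genes:
        call = classify_hardy(
            gene,
            lfc.loc[gene],
            cold_means.loc[gene],
            ctrl_means.loc[gene],
            int(calls.at[gene, hardiest_contrast]),
            profile,
            alpha=alpha,
            require_anti_significance=require_anti_significance,
        )
        rows.append(call.__dict__)
    return pd.DataFrame(rows).set_index("gene")


def hardy_enrichment(group: set[str], hardy: set[str], universe: set[str]) -> float:
    """Fold enrichment of hardy genes in a group relative to the universe."""
    if not universe or not hardy:
        raise ValueError("universe and hardy set must be non-empty")
    if not group:
        raise ValueError("group must be non-empty")
    if not group <= universe or not hardy <= universe:
        raise ValueError("group and hardy set must be subsets of the universe")
    return (len(group & hardy) / len(group)) / (len(hardy) / len(universe))
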