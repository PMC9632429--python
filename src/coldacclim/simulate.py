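"""Synthetic cold-acclimation study generator with planted ground truth.

The generator emulates the 4-genotype × {cold, control} × 3-replicate wheat
design: a log-normal expression model (log2(TPM+1) = planted cell mean +
Gaussian replicate noise), DESeq2-style per-contrast DE tables fabricated by
a variance-moderated two-sample t-test with Benjamini–Hochberg adjustment,
a lipid trait matrix tied to planted gene groups, and per-genotype LT50
values.

Planted groups
--------------
WHG          up under cold in both winter-habit genotypes (WM, N) only
SHG          up under cold in both spring-habit genotypes (M, SN) only
hardy        cold induction proportional to the hardiness index H, so cold
             log2FC and cold expression increase monotonically with H
anti_hardy   the mirror image: cold repression proportional to H, hence
             down-regulation strongest in the hardiest genotype
background   no planted signal

Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deg import ContrastTable
from .design import COLD, CONTROL, StudyDesign
from .hardiness import HardinessProfile
from .matrix import ExpressionMatrix

GROUPS = ("WHG", "SHG", "hardy", "anti_hardy")


class ConfigurationError(ValueError):
    pass


@dataclass
class PlantedTruth:
    """Sizes and magnitudes of the planted signal."""

    n_genes: int = 3000
    n_lipids: int = 224
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"WHG": 60, "SHG": 60, "hardy": 60, "anti_hardy": 40}
    )
    effect_size_log2: float = 4.0
    noise_sd_log2: float = 0.3
    #: baseline log2(TPM+1) means drawn uniformly from this range
    baseline_range: tuple[float, float] = (3.0, 8.0)
    #: lipids tied positively / negatively to each of the hardy and WHG
    #: group mean profiles (4 × this many designated traits in total)
    n_designated_lipids_per_sign: int = 10
    lipid_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size_log2 < 0:
            raise ConfigurationError("effect_size_log2 must be >= 0")
        if self.noise_sd_log2 <= 0:
            raise ConfigurationError("noise_sd_log2 must be > 0")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown planted groups {sorted(unknown)}")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ConfigurationError("planted group sizes exceed n_genes")
        if 4 * self.n_designated_lipids_per_sign > self.n_lipids:
            raise ConfigurationError("designated lipids exceed n_lipids")

    def gene_groups(self) -> pd.Series:
        """Gene id → group label, planted groups first then background."""
        labels = []
        for g in GROUPS:
            labels.extend([g] * self.group_sizes.get(g, 0))
        labels.extend(["background"] * (self.n_genes - len(labels)))
        width = len(str(self.n_genes))
        ids = [f"G{str(i + 1).zfill(width)}" for i in range(self.n_genes)]
        return pd.Series(labels, index=pd.Index(ids, name="gene"), name="group")


@dataclass
class StudyBundle:
    """Everything a downstream stage needs, with the ground truth attached."""

    design: StudyDesign
    truth: PlantedTruth
    expression: ExpressionMatrix
    contrasts: list[ContrastTable]
    lipids: pd.DataFrame  # traits × samples
    lipid_groups: pd.Series  # lipid id → designation label
    profile: HardinessProfile
    gene_groups: pd.Series  # gene id → planted group

    def contrast(self, name: str) -> ContrastTable:
        for c in self.contrasts:
            if c.name == name:
                return c
        raise KeyError(name)

    def planted(self, group: str) -> set[str]:
        return set(self.gene_groups.index[self.gene_groups == group])


def _cell_means(design: StudyDesign, truth: PlantedTruth, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    """Noise-free log2(TPM+1) mean per gene × (genotype, treatment) cell."""
    groups = truth.gene_groups()
    genes = groups.index
    base = rng.uniform(*truth.baseline_range, size=len(genes))

    profile = HardinessProfile.from_design(design)
    h = pd.Series(profile.h, index=list(design.genotypes))
    h_scale = h / h.max()  # planted magnitude reaches effect_size_log2 at max H

    winter = {w for w, _ in design.nil_pairs()}
    spring = set(design.genotypes) - winter

    cols = pd.MultiIndex.from_product(
        [design.genotypes, (COLD, CONTROL)], names=["genotype", "treatment"]
    )
    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(cols))), index=genes, columns=cols
    )

    e = truth.effect_size_log2
    for g in design.genotypes:
        cold_col = (g, COLD)
        is_whg = (groups == "WHG") & (g in winter)
        is_shg = (groups == "SHG") & (g in spring)
        means.loc[is_whg, cold_col] += e
        means.loc[is_shg, cold_col] += e
        means.loc[groups == "hardy", cold_col] += e * h_scale[g]
        means.loc[groups == "anti_hardy", cold_col] -= e * h_scale[g]
    return means, groups


#: prior degrees of freedom for the variance shrinkage of the synthetic DE
#: statistic; emulates the dispersion sharing of count-based DE tools, which
#: a plain two-sample t at n = 3 lacks
MODERATION_PRIOR_DF = 20.0


def _moderated_t_contrast(
    name: str, log_expr: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> ContrastTable:
    """DE table stand-in: moderated two-sample t on log2(TPM+1), BH across genes.

    Per-gene pooled variances are shrunk toward their across-gene mean with
    ``MODERATION_PRIOR_DF`` prior degrees of freedom (empirical-Bayes style),
    then a t-test with residual + prior df is applied.
    """
    a = log_expr[group_a].to_numpy(float)
    b = log_expr[group_b].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)

    df_resid = na + nb - 2
    pooled = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / df_resid
    d0 = MODERATION_PRIOR_DF
    s2_prior = pooled.mean() if pooled.mean() > 0 else 1e-12
    s2_mod = (d0 * s2_prior + df_resid * pooled) / (d0 + df_resid)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid + d0)
    p = np.where(np.isfinite(p), p, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"log2fc": lfc, "padj": padj}, index=log_expr.index)
    return ContrastTable(name=name, table=table, group_a=group_a, group_b=group_b)


def _lipid_traits(
    design: StudyDesign,
    truth: PlantedTruth,
    log_expr: pd.DataFrame,
    groups: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Traits as linear combinations of group mean profiles plus noise."""
    samples = list(log_expr.columns)

    def group_profile(name: str) -> np.ndarray:
        sub = log_expr.loc[groups == name]
        prof = sub.mean(axis=0).to_numpy(float)
        sd = prof.std()
        return (prof - prof.mean()) / (sd if sd > 0 else 1.0)

    k = truth.n_designated_lipids_per_sign
    designations = (
        [("hardy_pos", 1.0, "hardy")] * k
        + [("hardy_neg", -1.0, "hardy")] * k
        + [("WHG_pos", 1.0, "WHG")] * k
        + [("WHG_neg", -1.0, "WHG")] * k
    )
    profiles = {g: group_profile(g) for g in ("hardy", "WHG")}

    rows = np.empty((truth.n_lipids, len(samples)))
    labels = []
    for i in range(truth.n_lipids):
        if i < len(designations):
            label, sign, src = designations[i]
            rows[i] = sign * profiles[src] + rng.normal(
                0.0, truth.lipid_noise_sd, len(samples)
            )
        else:
            label = "noise"
            rows[i] = rng.normal(0.0, 1.0, len(samples))
        labels.append(label)

    width = len(str(truth.n_lipids))
    ids = pd.Index(
        [f"LIP{str(i + 1).zfill(width)}" for i in range(truth.n_lipids)], name="lipid"
    )
    lipids = pd.DataFrame(rows, index=ids, columns=samples)
    return lipids, pd.Series(labels, index=ids, name="designation")


def generate_study(
    design: StudyDesign | None = None,
    truth: PlantedTruth | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """Generate a self-consistent synthetic study.

    ``seed`` overrides ``truth.seed`` when given.  The returned bundle holds
    the TPM expression matrix, the eight standard contrast tables computed
    from the generated expression, the lipid trait matrix, the hardiness
    profile, and the planted gene groups.
    """
    design = design or StudyDesign()
    truth = truth or PlantedTruth()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    means, groups = _cell_means(design, truth, rng)

    samples = design.sample_table()
    log_vals = np.empty((truth.n_genes, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        cell = means[(row["genotype"], row["treatment"])].to_numpy(float)
        log_vals[:, j] = cell + rng.normal(0.0, truth.noise_sd_log2, truth.n_genes)

    tpm = np.maximum(np.exp2(log_vals) - 1.0, 0.0)
    values = pd.DataFrame(tpm, index=groups.index, columns=samples.index)
    expr = ExpressionMatrix(values=values, samples=samples)

    log_expr = expr.log2()
    contrasts = []
    for name in design.default_contrasts():
        ga, gb = design.contrast_groups(name)
        contrasts.append(_moderated_t_contrast(name, log_expr, ga, gb))

    lipids, lipid_groups = _lipid_traits(design, truth, log_expr, groups, rng)

    return StudyBundle(
        design=design,
        truth=truth,
        expression=expr,
        contrasts=contrasts,
        lipids=lipids,
        lipid_groups=lipid_groups,
        profile=HardinessProfile.from_design(design),
        gene_groups=groups,
    )
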