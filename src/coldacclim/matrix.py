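"""Expression container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import COLD, StudyDesign


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance matrix (TPM-like units) with sample metadata.

    ``values`` rows are gene ids, columns sample ids; ``samples`` is indexed by
    sample id with columns genotype / treatment / replicate.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        # canonical axis names so that disk round-trips compare equal
        # (rename_axis copies the axis: values.columns may share the Index
        # object with samples.index)
        self.values = self.values.rename_axis(index="gene", columns=None)
        self.samples = self.samples.rename_axis(index="sample")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def log2(self) -> pd.DataFrame:
        """log2(TPM + 1) transform, the pipeline's working scale."""
        return np.log2(self.values + 1.0)

    def group_mean_tpm(self, sample_ids: list[str]) -> pd.Series:
        return self.values[sample_ids].mean(axis=1)

    def genotype_treatment_means(
        self, design: StudyDesign, treatment: str = COLD, log_scale: bool = True
    ) -> pd.DataFrame:
        """Replicate-averaged per-genotype means for one treatment.

        Columns follow the design's genotype order.  With ``log_scale`` the
        mean is taken on log2(TPM+1); otherwise on raw TPM.
        """
        base = self.log2() if log_scale else self.values
        cols = {}
        for g in design.genotypes:
            cols[g] = base[design.samples_of(g, treatment)].mean(axis=1)
        return pd.DataFrame(cols)
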