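"""Study design: genotypes, treatments, replication, LT50s, and contrast layout.

The default design mirrors a 4-genotype wheat cold-acclimation experiment:
spring-habit Manitou (M), winter-habit Norstar (N), and their reciprocal
near-isogenic lines winter Manitou (WM) and spring Norstar (SN), each grown
under cold treatment (C) and control conditions (K) with three biological
replicates.  Freezing tolerance per genotype is summarised by LT50, the
temperature at which half of a population survives an artificial freeze test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import pandas as pd

COLD = "cold"
CONTROL = "control"

#: treatment → single-letter code used in sample ids and contrast names
TREATMENT_CODE = {COLD: "C", CONTROL: "K"}

DEFAULT_GENOTYPES: Tuple[str, ...] = ("M", "WM", "SN", "N")
DEFAULT_LT50: Mapping[str, float] = {
    "M": -8.3,
    "WM": -13.2,
    "SN": -13.0,
    "N": -21.7,
}


class DesignError(ValueError):
    """Raised when a study design violates its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """A two-treatment multi-genotype design with per-genotype LT50 values.

    Parameters
    ----------
    genotypes
        Ordered genotype labels; the order fixes the digit order of the
        cold-response (P) DEFE series.
    replicates
        Biological replicates per genotype × treatment cell (≥ 2).
    lt50
        Genotype → LT50 in °C, strictly between −25 and 0.
    """

    genotypes: Tuple[str, ...] = DEFAULT_GENOTYPES
    replicates: int = 3
    lt50: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LT50))

    def __post_init__(self) -> None:
        if len(set(self.genotypes)) != len(self.genotypes):
            raise DesignError("genotype labels must be unique")
        if self.replicates < 2:
            raise DesignError("replicate count must be >= 2")
        for g in self.genotypes:
            if g not in self.lt50:
                raise DesignError(f"missing LT50 for genotype {g!r}")
            v = self.lt50[g]
            if not (-25.0 < v < 0.0):
                raise DesignError(
                    f"LT50 of {g!r} must lie strictly between -25 and 0 °C, got {v}"
                )

    # ------------------------------------------------------------------ samples
    @property
    def treatments(self) -> Tuple[str, str]:
        return (COLD, CONTROL)

    def sample_id(self, genotype: str, treatment: str, replicate: int) -> str:
        return f"{genotype}_{treatment}_{replicate}"

    def sample_table(self) -> pd.DataFrame:
        """Sample metadata, one row per sample, indexed by sample id."""
        rows = []
        for g in self.genotypes:
            for t in self.treatments:
                for r in range(1, self.replicates + 1):
                    rows.append(
                        {
                            "sample": self.sample_id(g, t, r),
                            "genotype": g,
                            "treatment": t,
                            "replicate": r,
                        }
                    )
        return pd.DataFrame(rows).set_index("sample")

    def samples_of(self, genotype: str, treatment: str) -> list[str]:
        return [
            self.sample_id(genotype, treatment, r)
            for r in range(1, self.replicates + 1)
        ]

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * 2 * self.replicates

    # ---------------------------------------------------------------- contrasts
    def cold_control_contrast(self, genotype: str) -> str:
        """Name of the cold-vs-control contrast of one genotype, e.g. ``NC-NK``."""
        return f"{genotype}C-{genotype}K"

    def habit_contrast(self, winter: str, spring: str, treatment: str) -> str:
        c = TREATMENT_CODE[treatment]
        return f"{winter}{c}-{spring}{c}"

    def contrast_groups(self, name: str) -> tuple[list[str], list[str]]:
        """Resolve a contrast name ``A-B`` to its two sample groups.

        Each side is ``<genotype><C|K>``; the left group is the numerator of
        the fold change (``log2fc > 0`` means higher in the left group).
        """
        try:
            left, right = name.split("-")
        except ValueError as exc:
            raise DesignError(f"malformed contrast name {name!r}") from exc

        def side(tok: str) -> list[str]:
            code, geno = tok[-1], tok[:-1]
            if geno not in self.genotypes or code not in ("C", "K"):
                raise DesignError(f"unknown contrast side {tok!r} in {name!r}")
            treatment = COLD if code == "C" else CONTROL
            return self.samples_of(geno, treatment)

        return side(left), side(right)

    def default_contrasts(self) -> list[str]:
        """The eight standard contrasts: four cold/control, two cold-habit,
        two control-habit comparisons (winter-habit vs spring-habit NIL)."""
        per_geno = [self.cold_control_contrast(g) for g in self.genotypes]
        nil_pairs = self.nil_pairs()
        habit_cold = [self.habit_contrast(w, s, COLD) for w, s in nil_pairs]
        habit_ctrl = [self.habit_contrast(w, s, CONTROL) for w, s in nil_pairs]
        return per_geno + habit_cold + habit_ctrl

    def nil_pairs(self) -> list[tuple[str, str]]:
        """(winter-habit, spring-habit) near-isogenic pairs.

        For the default design these are (WM, M) and (N, SN); generally the
        pairing is positional: genotype 2 with 1, genotype 4 with 3.
        """
        gs = self.genotypes
        if len(gs) % 2:
            raise DesignError("NIL pairing requires an even number of genotypes")
        return [(gs[i + 1], gs[i]) for i in range(0, len(gs), 2)]
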