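"""Differential expression feature extraction (DEFE).

Each gene's up/down/no-change status across an ordered series of contrasts is
encoded as a prefixed digit string (digits 0/1/2), e.g. ``P0101`` for a gene
up-regulated by cold in the second and fourth genotypes only.  The default
series are:

* ``P`` — cold vs control per genotype, digit order M, WM, SN, N;
* ``C`` — winter-habit vs spring-habit NIL under cold (WM/M, N/SN);
* ``K`` — the same comparisons in control samples.

Patterns support single-digit ``*`` wildcards and plain set algebra, which is
how named groups such as the winter-habit genes (P0101∩C11∩K00) are built.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Sequence

import pandas as pd

from .design import COLD, CONTROL, StudyDesign

DIGITS = "012"


class DefeError(ValueError):
    pass


@dataclass(frozen=True)
class SeriesSpec:
    """One DEFE series: a single-character prefix and an ordered contrast list."""

    prefix: str
    contrasts: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.prefix) != 1:
            raise DefeError(f"series prefix must be one character, got {self.prefix!r}")
        if not self.contrasts:
            raise DefeError(f"series {self.prefix!r} has no contrasts")

    @property
    def length(self) -> int:
        return 1 + len(self.contrasts)


def default_series(design: StudyDesign | None = None) -> dict[str, SeriesSpec]:
    """The P/C/K series for a design (default 4-genotype wheat layout)."""
    d = design or StudyDesign()
    pairs = d.nil_pairs()
    return {
        "P": SeriesSpec(
            "P", tuple(d.cold_control_contrast(g) for g in d.genotypes)
        ),
        "C": SeriesSpec(
            "C", tuple(d.habit_contrast(w, s, COLD) for w, s in pairs)
        ),
        "K": SeriesSpec(
            "K", tuple(d.habit_contrast(w, s, CONTROL) for w, s in pairs)
        ),
    }


def encode(calls: pd.DataFrame, spec: SeriesSpec) -> pd.Series:
    """Per-gene pattern strings for one series from a gene × contrast call table."""
    missing = [c for c in spec.contrasts if c not in calls.columns]
    if missing:
        raise DefeError(f"series {spec.prefix!r}: missing contrasts {missing}")
    sub = calls[list(spec.contrasts)]
    if not sub.isin([0, 1, 2]).all().all():
        raise DefeError("DEG statuses must be in {0, 1, 2}")
    digits = sub.astype(int).astype(str)
    patterns = spec.prefix + reduce(lambda a, b: a + b, (digits[c] for c in spec.contrasts))
    return patterns.rename(spec.prefix)


def frequency_table(codes: pd.Series) -> pd.DataFrame:
    """(pattern, count) rows sorted by count descending, then pattern."""
    if codes.empty:
        raise DefeError("no DEFE codes to tabulate")
    counts = codes.value_counts()
    df = counts.rename_axis("pattern").reset_index(name="count")
    return df.sort_values(
        ["count", "pattern"], ascending=[False, True], ignore_index=True
    )


def _check_query(query: str, spec: SeriesSpec) -> None:
    if not query or query[0] != spec.prefix:
        raise DefeError(
            f"query {query!r} does not match series prefix {spec.prefix!r}"
        )
    if len(query) != spec.length:
        raise DefeError(
            f"query {query!r} has length {len(query)}, series expects {spec.length}"
        )
    bad = [ch for ch in query[1:] if ch not in DIGITS + "*"]
    if bad:
        raise DefeError(f"query {query!r}: invalid characters {bad}")


def match(codes: pd.Series, query: str, spec: SeriesSpec) -> set[str]:
    """Genes whose pattern matches the query; ``*`` matches any single digit."""
    _check_query(query, spec)
    mask = pd.Series(True, index=codes.index)
    for i, ch in enumerate(query):
        if ch == "*":
            continue
        mask &= codes.str[i] == ch
    return set(codes.index[mask])


def intersect(groups: Sequence[Iterable[str]]) -> set[str]:
    """Exact intersection of ≥ 2 gene sets."""
    sets = [set(g) for g in groups]
    if len(sets) < 2:
        raise DefeError("intersection needs at least two gene sets")
    return reduce(set.intersection, sets)


#: named group → one query per series; a gene belongs to the group when its
#: pattern matches in every series (intersection across series)
NAMED_GROUPS = {
    "WHG": {"P": "P0101", "C": "C11", "K": "K00"},
    "SHG": {"P": "P1010", "C": "C22", "K": "K00"},
    "WHG_down": {"P": "P0202", "C": "C22", "K": "K00"},
    "SHG_down": {"P": "P2020", "C": "C11", "K": "K00"},
}


def named_group(
    codes_by_series: dict[str, pd.Series],
    series: dict[str, SeriesSpec],
    group: str,
) -> set[str]:
    """Resolve one of the named DEFE groups (WHG, SHG, and their
    down-regulated companions) by cross-series intersection."""
    if group not in NAMED_GROUPS:
        raise DefeError(f"unknown named group {group!r}")
    queries = NAMED_GROUPS[group]
    sets = [
        match(codes_by_series[prefix], q, series[prefix])
        for prefix, q in queries.items()
    ]
    return intersect(sets)
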