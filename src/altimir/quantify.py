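"""miRNA x library expression matrix: raw counts, RPM, detection rules.

Normalisation is plain reads-per-million against a per-library denominator
(cleaned-read total by default).  Cells with zero raw count are set to an
RPM of exactly 0.01 after normalisation so that every fold change is
defined; this floor is applied to the normalised value, never to the raw
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .annotation import AnnotationIndex
from .preprocess import LABEL_MIRNA, ClassificationResult

ZERO_RPM = 0.01
DEFAULT_MIN_READS = 10


@dataclass
class ExpressionMatrix:
    raw: pd.DataFrame  # units x libraries, int
    rpm: pd.DataFrame | None = None
    library_totals: pd.Series | None = None
    ambiguous_units: set[str] = field(default_factory=set)

    @property
    def units(self) -> list[str]:
        return list(self.raw.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.raw.columns)


def count_matrix(
    classified: Iterable[ClassificationResult],
    libraries: list[str],
    index: AnnotationIndex,
) -> ExpressionMatrix:
    """Raw per-unit counts from miRNA-labeled tags.

    Ambiguous tags (matching several collapsed matures) contribute their
    count to every matched unit; those units are flagged so totals can be
    computed without double counting.
    """
    units = index.units
    raw = pd.DataFrame(0, index=units, columns=libraries, dtype=int)
    ambiguous: set[str] = set()
    for r in classified:
        if r.label != LABEL_MIRNA:
            continue
        for unit in r.assigned_units:
            for lib, n in r.counts.items():
                raw.loc[unit, lib] += n
        if r.ambiguous:
            ambiguous.update(r.assigned_units)
    return ExpressionMatrix(raw=raw, ambiguous_units=ambiguous)


def normalize_rpm(m: ExpressionMatrix, library_totals: Mapping[str, int]) -> ExpressionMatrix:
    """Fill RPM = raw / library_total * 1e6, with the 0.01 zero adjustment."""
    totals = pd.Series({lib: library_totals[lib] for lib in m.libraries}, dtype=float)
    for lib, t in totals.items():
        if t <= 0:
            raise ValueError(f"library {lib!r} has non-positive denominator {t}")
    rpm = m.raw.astype(float).div(totals, axis=1) * 1e6
    rpm = rpm.mask(m.raw == 0, ZERO_RPM)
    m.rpm = rpm
    m.library_totals = totals
    return m


def detected_set(
    m: ExpressionMatrix,
    scope: Iterable[str] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> set[str]:
    """Units whose raw counts summed over the scope reach *min_reads*."""
    libs = list(scope) if scope is not None else m.libraries
    sums = m.raw[libs].sum(axis=1)
    return set(sums.index[sums >= min_reads])


def membership_partition(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Venn partition: exact-membership combination -> unit count.

    Keys are sorted tuples of the groups a unit is present in (and absent
    from all others); singleton keys are the "uniquely expressed" counts.
    """
    if len(sets) < 2:
        raise ValueError("membership_partition needs at least two groups")
    groups = sorted(sets)
    partition: dict[tuple[str, ...], int] = {}
    for k in range(1, len(groups) + 1):
        for combo in combinations(groups, k):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(*(sets[g] for g in groups if g not in combo), set())
            partition[combo] = len(inside - outside)
    return partition


def unique_units(sets: Mapping[str, set[str]], group: str) -> set[str]:
    """Units present in *group* and absent from every other group."""
    others = set.union(*(s for g, s in sets.items() if g != group), set())
    return sets[group] - others


def common_units(sets: Mapping[str, set[str]]) -> set[str]:
    return set.intersection(*sets.values())


def expression_table(m: ExpressionMatrix, index: AnnotationIndex) -> pd.DataFrame:
    """Flat unit x library table with family labels, raw and RPM columns."""
    df = pd.DataFrame({"unit": m.units})
    df["family"] = [index.unit_family.get(u, "") for u in m.units]
    for lib in m.libraries:
        df[f"raw_{lib}"] = m.raw[lib].to_numpy()
    if m.rpm is not None:
        for lib in m.libraries:
            df[f"rpm_{lib}"] = m.rpm[lib].to_numpy()
    return df
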