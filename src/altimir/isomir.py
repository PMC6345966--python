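"""Seven-class isomiR taxonomy, diversity, 3' tailing and arm usage.

Every read assigned to a mature miRNA locus is placed in exactly one of
seven categories by comparing it with the canonical mature sequence in
hairpin coordinates:

* ``canonical``        exact annotated mature sequence
* ``shifted``          both ends moved by the same offset on the precursor
* ``substitution``     same ends, 1..max_sub internal mismatches
* ``both_end``         both ends vary (independently)
* ``template_3p``      5' end canonical, 3' end trimmed/extended along the
                       precursor template
* ``nontemplate_3p``   5' end canonical, 3' tail absent from the template
* ``start_site``       3' end canonical, 5' start moved

The decision tree gives exact-template explanations precedence over
non-template tails and tails precedence over substitutions, so a
length-preserving read whose final base disagrees with the template is a
3' non-template addition, not a substitution (matching the biology of
3' nucleotidyl transferases).  Offsets are bounded by a window (default
5 nt) so unrelated precursor fragments are never claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats

from ._seq import to_rna
from .annotation import ARM_3P, ARM_5P, AnnotationIndex, MatureAnnotation
from .preprocess import TagTable
from .quantify import ZERO_RPM, ExpressionMatrix

CANONICAL = "canonical"
SHIFTED = "shifted"
SUBSTITUTION = "substitution"
BOTH_END = "both_end"
TEMPLATE_3P = "template_3p"
NONTEMPLATE_3P = "nontemplate_3p"
START_SITE = "start_site"

CATEGORIES = (
    CANONICAL,
    SHIFTED,
    SUBSTITUTION,
    BOTH_END,
    TEMPLATE_3P,
    NONTEMPLATE_3P,
    START_SITE,
)

DEFAULT_WINDOW = 5
DEFAULT_MAX_SUB = 2
DEFAULT_MAX_TAIL = 5  # longest 3' non-template tail considered; fixed so that
# enlarging the offset window never re-categorises an assigned tag
MIN_TAG_LEN = 18
MAX_TAG_LEN = 28


@dataclass(frozen=True)
class IsomiRRecord:
    tag: str
    mature: str
    category: str
    offset5: int
    offset3: int
    tail: str = ""
    mismatch_positions: tuple[int, ...] = ()


def classify_isomir(
    tag: str,
    mature: MatureAnnotation,
    hairpin: str,
    window: int = DEFAULT_WINDOW,
    max_sub: int = DEFAULT_MAX_SUB,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> IsomiRRecord | None:
    """Classify one tag against one mature locus; None if unexplainable.

    Offsets are tag end minus canonical end in hairpin coordinates
    (offset5 = tag start - mature start; offset3 = tag end - mature end,
    where a non-template tail counts toward the tag end).
    """
    if not (MIN_TAG_LEN <= len(tag) <= MAX_TAG_LEN):
        raise ValueError(f"tag length {len(tag)} outside the size-filtered range")
    s, e = mature.start, mature.end
    canon = mature.sequence
    if tag == canon:
        return IsomiRRecord(tag, mature.name, CANONICAL, 0, 0)

    # (2) exact template occurrence within the window
    best = None
    i = hairpin.find(tag)
    while i != -1:
        o5, o3 = i - s, i + len(tag) - e
        if abs(o5) <= window and abs(o3) <= window:
            key = (abs(o5) + abs(o3), abs(o5), o5)
            if best is None or key < best[0]:
                best = (key, o5, o3)
        i = hairpin.find(tag, i + 1)
    if best is not None:
        _, o5, o3 = best
        if o5 == o3:
            cat = SHIFTED
        elif o5 == 0:
            cat = TEMPLATE_3P
        elif o3 == 0:
            cat = START_SITE
        else:
            cat = BOTH_END
        return IsomiRRecord(tag, mature.name, cat, o5, o3)

    # (3)/(4) longest template prefix + short non-template 3' suffix
    best_tail = None
    for p in range(max(s - window, 0), s + window + 1):
        k = 0
        limit = min(len(tag), len(hairpin) - p)
        while k < limit and tag[k] == hairpin[p + k]:
            k += 1
        tail = tag[k:]
        if k == 0 or not (1 <= len(tail) <= max_tail):
            continue
        o5 = p - s
        o3 = p + len(tag) - e
        if abs(o5) > window or abs(o3) > window:
            continue
        # by construction the first tail base differs from the template
        # continuation (or the template has ended)
        key = (-k, abs(o5), o5)
        if best_tail is None or key < best_tail[0]:
            best_tail = (key, o5, o3, tail)
    if best_tail is not None:
        _, o5, o3, tail = best_tail
        cat = NONTEMPLATE_3P if o5 == 0 else BOTH_END
        return IsomiRRecord(tag, mature.name, cat, o5, o3, tail=tail)

    # (5) length-preserving internal substitutions at the canonical position
    if len(tag) == len(canon):
        mism = tuple(i for i, (a, b) in enumerate(zip(tag, canon)) if a != b)
        if (
            1 <= len(mism) <= max_sub
            and 0 not in mism
            and (len(canon) - 1) not in mism
        ):
            return IsomiRRecord(tag, mature.name, SUBSTITUTION, 0, 0, mismatch_positions=mism)

    return None


def assign_isomirs(
    tags: TagTable,
    index: AnnotationIndex,
    window: int = DEFAULT_WINDOW,
    max_sub: int = DEFAULT_MAX_SUB,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> list[tuple[IsomiRRecord, dict[str, int]]]:
    """Assign each tag to at most one mature locus with an isomiR category.

    A tag explainable by several matures goes to the one with the smallest
    |offset5| + |offset3| (ties: the 5p arm, then lexicographic name).
    Matures sharing a collapsed sequence are tried once via their unit
    representative.  Returns (record, per-library counts) pairs.
    """
    rep_matures = [index.mature_by_name[u] for u in index.units]
    anchor = MIN_TAG_LEN - window  # shortest exact 5' anchor any template-rooted variant keeps

    def hamming_le(a: str, b: str, k: int) -> bool:
        mm = 0
        for x, y in zip(a, b):
            if x != y:
                mm += 1
                if mm > k:
                    return False
        return True

    out: list[tuple[IsomiRRecord, dict[str, int]]] = []
    for tag, counts in tags.counts.items():
        candidates: list[tuple[tuple, IsomiRRecord]] = []
        for m in rep_matures:
            hp = index.hairpins[m.hairpin_id]
            # cheap prescreens: template-rooted variants keep an exact 5'
            # anchor in the hairpin; substitution variants keep the length
            # and at most max_sub mismatches against the canonical sequence
            if not (
                tag[:anchor] in hp
                or tag in hp
                or (len(tag) == len(m.sequence) and hamming_le(tag, m.sequence, max_sub))
            ):
                continue
            rec = classify_isomir(tag, m, hp, window=window, max_sub=max_sub, max_tail=max_tail)
            if rec is not None:
                arm_rank = 0 if m.arm == ARM_5P else 1
                candidates.append(((abs(rec.offset5) + abs(rec.offset3), arm_rank, m.name), rec))
        if candidates:
            candidates.sort(key=lambda c: c[0])
            out.append((candidates[0][1], counts))
    return out


def isomir_table(assigned: list[tuple[IsomiRRecord, dict[str, int]]], libraries: list[str]) -> pd.DataFrame:
    rows = []
    for rec, counts in assigned:
        row = {
            "tag": to_rna(rec.tag),
            "mature": rec.mature,
            "category": rec.category,
            "offset5": rec.offset5,
            "offset3": rec.offset3,
            "tail": to_rna(rec.tail),
            "mismatch_positions": ",".join(map(str, rec.mismatch_positions)),
        }
        for lib in libraries:
            row[f"count_{lib}"] = counts.get(lib, 0)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class IsomiRSummary:
    mature: str
    library: str
    category_rpm: dict[str, float]
    n_distinct_isomirs: int
    dominance: float

    @property
    def total_rpm(self) -> float:
        return sum(self.category_rpm.values())


def isomir_summary(
    assigned: list[tuple[IsomiRRecord, dict[str, int]]],
    library: str,
    library_total: int,
) -> list[IsomiRSummary]:
    """Per-mature category RPM sums, distinct-isomiR counts and dominance.

    Dominance is the RPM of the single most abundant tag sequence assigned
    to the mature divided by the mature's total assigned RPM; it is
    scale-invariant and bounded below by 1/n_distinct.
    """
    per_mature: dict[str, list[tuple[IsomiRRecord, int]]] = {}
    for rec, counts in assigned:
        n = counts.get(library, 0)
        if n > 0:
            per_mature.setdefault(rec.mature, []).append((rec, n))
    out = []
    scale = 1e6 / library_total
    for mature in sorted(per_mature):
        entries = per_mature[mature]
        cat_rpm = {c: 0.0 for c in CATEGORIES}
        for rec, n in entries:
            cat_rpm[rec.category] += n * scale
        total = sum(n for _, n in entries)
        dominant = max(n for _, n in entries)
        out.append(
            IsomiRSummary(
                mature=mature,
                library=library,
                category_rpm=cat_rpm,
                n_distinct_isomirs=len(entries),
                dominance=dominant / total,
            )
        )
    return out


def summary_table(summaries: list[IsomiRSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"mature": s.mature, "library": s.library}
        total = s.total_rpm
        for c in CATEGORIES:
            row[f"rpm_{c}"] = s.category_rpm[c]
            row[f"prop_{c}"] = s.category_rpm[c] / total if total else 0.0
        row["n_distinct_isomirs"] = s.n_distinct_isomirs
        row["dominance"] = s.dominance
        rows.append(row)
    return pd.DataFrame(rows)


def nta_base_composition(
    assigned: list[tuple[IsomiRRecord, dict[str, int]]], library: str
) -> dict[str, float]:
    """Expression-weighted base proportions of the first non-template 3' base.

    Reported over the RNA alphabet {A, C, G, U}; proportions sum to 1.
    Returns an empty dict (with a warning) when the library has no 3' NTA
    reads.
    """
    weights = {"A": 0, "C": 0, "G": 0, "U": 0}
    total = 0
    for rec, counts in assigned:
        if rec.category != NONTEMPLATE_3P or not rec.tail:
            continue
        n = counts.get(library, 0)
        if n == 0:
            continue
        base = to_rna(rec.tail[0])
        weights[base] += n
        total += n
    if total == 0:
        import warnings

        warnings.warn(f"no 3' non-template addition reads in library {library!r}")
        return {}
    return {b: w / total for b, w in weights.items()}


def arm_usage(
    m: ExpressionMatrix,
    index: AnnotationIndex,
    hairpin_id: str,
    library: str,
) -> tuple[int, int, float, float]:
    """5p/3p arm balance of one hairpin in one library.

    Returns (count5p, count3p, log2 ratio, binomial p).  The ratio guards a
    zero count with the count equivalent of the 0.01-RPM floor; the p-value
    is a two-sided exact binomial test of the 5p count against an equal
    split of the arm total.
    """
    matures = index.by_hairpin.get(hairpin_id, [])
    by_arm = {ARM_5P: None, ARM_3P: None}
    for mat in matures:
        if mat.arm in by_arm and by_arm[mat.arm] is None:
            by_arm[mat.arm] = index.unit_of(mat.name)
    if by_arm[ARM_5P] is None or by_arm[ARM_3P] is None:
        raise ValueError(f"hairpin {hairpin_id!r} lacks a labeled 5p or 3p mature")
    c5 = int(m.raw.loc[by_arm[ARM_5P], library])
    c3 = int(m.raw.loc[by_arm[ARM_3P], library])
    if m.library_totals is not None:
        floor = ZERO_RPM * float(m.library_totals[library]) / 1e6
    else:
        floor = ZERO_RPM
    ratio = float(np.log2(max(c5, floor) / max(c3, floor)))
    n = c5 + c3
    p = float(scipy.stats.binomtest(c5, n, 0.5).pvalue) if n > 0 else 1.0
    return c5, c3, ratio, p


def arm_usage_table(
    m: ExpressionMatrix, index: AnnotationIndex, libraries: Iterable[str] | None = None
) -> pd.DataFrame:
    """Arm usage for every both-arm hairpin with any expression, per library."""
    from .annotation import BOTH_ARMS, arm_category

    libs = list(libraries) if libraries is not None else m.libraries
    rows = []
    for hid in sorted(index.hairpins):
        if arm_category(hid, index) != BOTH_ARMS:
            continue
        for lib in libs:
            c5, c3, ratio, p = arm_usage(m, index, hid, lib)
            if c5 == 0 and c3 == 0:
                continue
            rows.append(
                {"hairpin": hid, "library": lib, "count5p": c5, "count3p": c3,
                 "log2_ratio_5p_3p": ratio, "p": p}
            )
    return pd.DataFrame(rows)
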