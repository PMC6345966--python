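"""Independent brute-force oracles used by the test suite.

These are written directly from the category and rule definitions, by
exhaustive enumeration rather than the search structure of the package
implementation, and exist only to cross-check it.
"""

from __future__ import annotations


def brute_force_isomir(
    tag: str,
    mature_start: int,
    mature_end: int,
    hairpin: str,
    window: int = 5,
    max_sub: int = 2,
    max_tail: int = 5,
):
    """Classify a tag against a mature locus by exhaustive enumeration.

    Returns (category, offset5, offset3, tail) or None, mirroring the
    decision order: canonical; exact template placement within the window;
    template prefix + short non-template 3' suffix (anchored / unanchored
    5' end); internal substitutions; unassigned.
    """
    s, e = mature_start, mature_end
    canon = hairpin[s:e]
    L = len(tag)
    if tag == canon:
        return ("canonical", 0, 0, "")

    # every exact placement of the whole tag on the hairpin
    placements = []
    for i in range(len(hairpin) - L + 1):
        if hairpin[i : i + L] != tag:
            continue
        o5, o3 = i - s, i + L - e
        if abs(o5) <= window and abs(o3) <= window:
            placements.append((abs(o5) + abs(o3), abs(o5), o5, o3))
    if placements:
        placements.sort()
        _, _, o5, o3 = placements[0]
        if o5 == o3:
            return ("shifted", o5, o3, "")
        if o5 == 0:
            return ("template_3p", o5, o3, "")
        if o3 == 0:
            return ("start_site", o5, o3, "")
        return ("both_end", o5, o3, "")

    # maximal template prefix at every admissible 5' anchor, short suffix
    tails = []
    for p in range(len(hairpin)):
        o5 = p - s
        if abs(o5) > window:
            continue
        k = 0
        while k < L and p + k < len(hairpin) and tag[k] == hairpin[p + k]:
            k += 1
        tail = tag[k:]
        o3 = p + L - e
        if k >= 1 and 1 <= len(tail) <= max_tail and abs(o3) <= window:
            tails.append((-k, abs(o5), o5, o3, tail))
    if tails:
        tails.sort()
        _, _, o5, o3, tail = tails[0]
        cat = "nontemplate_3p" if o5 == 0 else "both_end"
        return (cat, o5, o3, tail)

    if L == len(canon):
        mismatches = [i for i in range(L) if tag[i] != canon[i]]
        if (
            1 <= len(mismatches) <= max_sub
            and 0 not in mismatches
            and L - 1 not in mismatches
        ):
            return ("substitution", 0, 0, "")
    return None


def enumerate_isomir_tags(
    mature_start: int,
    mature_end: int,
    hairpin: str,
    window: int = 5,
    min_len: int = 18,
    max_len: int = 28,
) -> set[str]:
    """All windowed substrings, their 1-base 3' extensions and the 1-base
    substitution variants of the canonical sequence."""
    s, e = mature_start, mature_end
    tags: set[str] = set()
    for i in range(max(0, s - window), s + window + 1):
        for j in range(e - window, min(len(hairpin), e + window) + 1):
            if not (min_len <= j - i <= max_len):
                continue
            sub = hairpin[i:j]
            tags.add(sub)
            if j - i < max_len:
                for b in "ACGT":
                    tags.add(sub + b)
    canon = hairpin[s:e]
    for pos in range(len(canon)):
        for b in "ACGT":
            if b != canon[pos]:
                tags.add(canon[:pos] + b + canon[pos + 1 :])
    return {t for t in tags if min_len <= len(t) <= max_len}


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Closed-form Pearson statistic N(ad-bc)^2/((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def balanced_two_way_anova(values, pops, tmts):
    """Textbook sums-of-squares two-way ANOVA for a balanced design.

    Returns dict with F statistics for the two factors and the interaction.
    """
    import numpy as np

    values = np.asarray(values, dtype=float)
    pops = np.asarray(pops)
    tmts = np.asarray(tmts)
    grand = values.mean()
    pop_levels, tmt_levels = sorted(set(pops)), sorted(set(tmts))
    n_rep = len(values) / (len(pop_levels) * len(tmt_levels))
    ss_pop = sum(
        (values[pops == p].mean() - grand) ** 2 * (values[pops == p]).size for p in pop_levels
    )
    ss_tmt = sum(
        (values[tmts == t].mean() - grand) ** 2 * (values[tmts == t]).size for t in tmt_levels
    )
    ss_cells = 0.0
    ss_err = 0.0
    for p in pop_levels:
        for t in tmt_levels:
            cell = values[(pops == p) & (tmts == t)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_int = ss_cells - ss_pop - ss_tmt
    df_pop = len(pop_levels) - 1
    df_tmt = len(tmt_levels) - 1
    df_int = df_pop * df_tmt
    df_err = len(values) - len(pop_levels) * len(tmt_levels)
    ms_err = ss_err / df_err
    return {
        "F_pop": (ss_pop / df_pop) / ms_err,
        "F_tmt": (ss_tmt / df_tmt) / ms_err,
        "F_interaction": (ss_int / df_int) / ms_err,
    }
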