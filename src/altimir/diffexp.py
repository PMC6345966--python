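"""Pairwise differential expression and between-library structure.

Differential expression between two count libraries uses a Pearson
chi-square test (no continuity correction) on the 2x2 table of a unit's
count against the rest of its library, with fold changes computed from RPM
values (the 0.01 zero floor guarantees finite log ratios).  A comparison
is only *tested* when the raw count exceeds 10 in at least one of the two
libraries.  Between-library structure is summarised by presence/absence
Jaccard similarity with a percentile-bootstrap CI, average-linkage
clustering on 1 - Pearson correlation of log2 RPM profiles, and a
population x growing-condition two-way ANOVA per unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_ALPHA = 0.05
DEFAULT_FC_GATE = 1.0
TEST_GATE_COUNT = 10


def log2_fold_change(rpm_a: float, rpm_b: float) -> float:
    """log2(b over a); inputs must be positive (run RPM normalisation first)."""
    if rpm_a <= 0 or rpm_b <= 0:
        raise ValueError("fold change requires positive RPM values; was the 0.01 floor applied?")
    return math.log2(rpm_b / rpm_a)


def chisq_de(
    count_a: int, total_a: int, count_b: int, total_b: int, correction: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-square on [[a, Ta-a], [b, Tb-b]]; returns (chi2, p, tested).

    *tested* is False when the count is <= 10 in both libraries; the
    statistic is still reported but flagged.  The closed-form Pearson
    statistic N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) is used, optionally with
    the Yates correction (off by default).
    """
    if count_a > total_a or count_b > total_b:
        raise ValueError("count exceeds library total")
    if count_a < 0 or count_b < 0 or total_a <= 0 or total_b <= 0:
        raise ValueError("counts must be non-negative and totals positive")
    a, b = float(count_a), float(total_a - count_a)
    c, d = float(count_b), float(total_b - count_b)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        chi2 = 0.0
    else:
        delta = abs(a * d - b * c)
        if correction:
            delta = max(delta - n / 2.0, 0.0)
        chi2 = n * delta * delta / denom
    p = float(scipy.stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    tested = not (count_a <= TEST_GATE_COUNT and count_b <= TEST_GATE_COUNT)
    return chi2, p, tested


def de_table(
    m,
    lib_a: str,
    lib_b: str,
    unit_family: Mapping[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    fc_gate: float = DEFAULT_FC_GATE,
    correction: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-unit DE table for one library pair (b over a).

    The "significant" gate is tested AND p < alpha AND |log2fc| >= fc_gate;
    an optional Benjamini-Hochberg column is provided but raw p-values are
    the default decision basis.
    """
    if m.rpm is None or m.library_totals is None:
        raise ValueError("expression matrix must be RPM-normalised first")
    ta, tb = int(m.library_totals[lib_a]), int(m.library_totals[lib_b])
    rows = []
    for unit in m.units:
        ca, cb = int(m.raw.loc[unit, lib_a]), int(m.raw.loc[unit, lib_b])
        chi2, p, tested = chisq_de(ca, ta, cb, tb, correction=correction)
        fc = log2_fold_change(float(m.rpm.loc[unit, lib_a]), float(m.rpm.loc[unit, lib_b]))
        rows.append(
            {
                "unit": unit,
                "family": (unit_family or {}).get(unit, ""),
                "count_a": ca,
                "count_b": cb,
                "log2fc": fc,
                "chi2": chi2,
                "p": p,
                "tested": tested,
            }
        )
    df = pd.DataFrame(rows)
    if bh:
        df["p_bh"] = sm.stats.multipletests(df["p"], method="fdr_bh")[1]
    p_col = "p_bh" if bh else "p"
    df["significant"] = df["tested"] & (df[p_col] < alpha) & (df["log2fc"].abs() >= fc_gate)
    return df


@dataclass
class JaccardResult:
    pair: tuple[str, str]
    point: float
    ci_low: float
    ci_high: float
    n_boot: int


def jaccard(
    pop_a_units: Iterable[str],
    pop_b_units: Iterable[str],
    n_boot: int = 1000,
    seed: int = 0,
    pair: tuple[str, str] = ("A", "B"),
) -> JaccardResult:
    """Presence/absence Jaccard index with a percentile bootstrap CI.

    Each bootstrap replicate resamples the union of detected units with
    replacement and recomputes |A&B|/|A|B| on the resampled universe, so
    identical sets collapse the interval to [1, 1] and the interval narrows
    as the detected lists grow.
    """
    a_set, b_set = set(pop_a_units), set(pop_b_units)
    if not a_set and not b_set:
        raise ValueError("Jaccard index undefined for two empty sets")
    universe = sorted(a_set | b_set)
    point = len(a_set & b_set) / len(universe)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        resampled = set(rng.choice(universe, size=len(universe), replace=True))
        ra, rb = resampled & a_set, resampled & b_set
        union = ra | rb
        reps[i] = len(ra & rb) / len(union) if union else 0.0
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return JaccardResult(pair=pair, point=point, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def cluster_libraries(
    m, units: Iterable[str] | None = None
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage clustering of libraries on 1 - Pearson r of log2 RPM.

    Returns (scipy linkage matrix, leaf labels in input order, newick text).
    Libraries are processed in sorted id order so tie-breaks are
    deterministic.
    """
    if m.rpm is None:
        raise ValueError("expression matrix must be RPM-normalised first")
    libs = sorted(m.libraries)
    if len(libs) < 3:
        raise ValueError("clustering needs at least three libraries")
    sub = m.rpm.loc[list(units), libs] if units is not None else m.rpm[libs]
    if len(sub) < 2:
        raise ValueError("clustering needs at least two units")
    prof = np.log2(sub.to_numpy(dtype=float))
    sd = prof.std(axis=0)
    for lib, s in zip(libs, sd):
        if s == 0:
            raise ValueError(f"library {lib!r} has a constant expression profile")
    corr = np.corrcoef(prof, rowvar=False)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(len(libs), k=1)]
    # numerical floor: correlations slightly above 1 give tiny negatives
    condensed = np.clip(condensed, 0.0, None)
    z = sch.linkage(condensed, method="average")
    newick = _to_newick(sch.to_tree(z), libs)
    return z, libs, newick


def _to_newick(node, labels: list[str]) -> str:
    def rec(n) -> str:
        if n.is_leaf():
            return labels[n.id]
        left, right = rec(n.get_left()), rec(n.get_right())
        dl = max(n.dist - n.get_left().dist, 0.0)
        dr = max(n.dist - n.get_right().dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(node) + ";"


def anova_pop_tmt(
    responses: pd.DataFrame,
    design: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Two-way ANOVA (population x growing condition) per unit.

    *responses* is a unit x library table of log2 RPM values; *design* maps
    each library to its (population, condition).  Type-II sums of squares
    are reported.  With a single replicate per cell the interaction is not
    estimable: it is dropped with a warning and its p-value reported as NaN.
    All-equal responses yield p = 1 by convention.
    """
    libs = [l for l in responses.columns if l in design]
    pops = [design[l][0] for l in libs]
    tmts = [design[l][1] for l in libs]
    if len(set(pops)) < 2 or len(set(tmts)) < 2:
        raise ValueError("design needs >=2 populations and >=2 conditions")
    cells = pd.Series(list(zip(pops, tmts)))
    full_grid = len(set(pops)) * len(set(tmts))
    has_reps = cells.value_counts().min() >= 2 and cells.nunique() == full_grid
    if cells.nunique() < full_grid:
        warnings.warn("empty design cell: interaction dropped from the ANOVA")
        formula = "resp ~ C(pop) + C(tmt)"
        with_inter = False
    elif not has_reps:
        warnings.warn("single replicate per cell: interaction not estimable, dropped")
        formula = "resp ~ C(pop) + C(tmt)"
        with_inter = False
    else:
        formula = "resp ~ C(pop) * C(tmt)"
        with_inter = True

    rows = []
    for unit in responses.index:
        vals = responses.loc[unit, libs].to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            rows.append(
                {
                    "unit": unit,
                    "F_pop": 0.0,
                    "p_pop": 1.0,
                    "F_tmt": 0.0,
                    "p_tmt": 1.0,
                    "F_interaction": np.nan,
                    "p_interaction": np.nan if not with_inter else 1.0,
                }
            )
            continue
        df = pd.DataFrame({"resp": vals, "pop": pops, "tmt": tmts})
        fit = smf.ols(formula, data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = sm.stats.anova_lm(fit, typ=2)
        row = {
            "unit": unit,
            "F_pop": float(tab.loc["C(pop)", "F"]),
            "p_pop": float(tab.loc["C(pop)", "PR(>F)"]),
            "F_tmt": float(tab.loc["C(tmt)", "F"]),
            "p_tmt": float(tab.loc["C(tmt)", "PR(>F)"]),
            "F_interaction": float(tab.loc["C(pop):C(tmt)", "F"]) if with_inter else np.nan,
            "p_interaction": float(tab.loc["C(pop):C(tmt)", "PR(>F)"]) if with_inter else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def altitude_monotone_units(
    de_low_mid: pd.DataFrame, de_mid_high: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Units changing monotonically along the altitude gradient.

    Increasing: significantly up (per the table's gate) in both the
    low->mid and mid->high comparisons; decreasing is the mirror image.
    """
    def split(df: pd.DataFrame) -> tuple[set[str], set[str]]:
        sig = df[df["significant"]]
        return (
            set(sig.loc[sig["log2fc"] > 0, "unit"]),
            set(sig.loc[sig["log2fc"] < 0, "unit"]),
        )

    up1, down1 = split(de_low_mid)
    up2, down2 = split(de_mid_high)
    return up1 & up2, down1 & down2
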