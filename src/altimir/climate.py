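"""Bioclimatic PCA and climate-expression association.

Sites (altitudes) are described by a small table of bioclimatic variables
(the 19 standard temperature/precipitation summaries plus growing-season
averages of temperature, precipitation and radiation).  Because the
variables mix units, the PCA standardises each variable to zero mean and
unit variance across sites (correlation-matrix PCA); with three sites at
most two components carry variance and together they explain all of it.
Per-unit expression is then correlated with component scores and with the
growing-season factors directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

DEFAULT_R_THRESHOLD = 0.98
DEFAULT_ALPHA = 0.05
SEASON_FACTORS = ("AT", "AP", "AR")


@dataclass
class ClimatePCA:
    scores: pd.DataFrame  # site x component
    loadings: pd.DataFrame  # variable x component
    var_explained: pd.Series  # component -> fraction, sums to 1


def climate_pca(table: pd.DataFrame) -> ClimatePCA:
    """Standardised PCA of a site x variable climate table.

    Constant variables are dropped with a warning (they carry no
    between-site information after standardisation).  Components with
    numerically zero variance are not retained, so the explained-variance
    fractions always sum to one; each loading vector's largest-magnitude
    entry is made positive for a reproducible sign convention.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least two sites")
    if table.isna().any().any():
        raise ValueError("climate table contains missing values")
    sd = table.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant) == len(table.columns):
        raise ValueError("all climate variables are constant across sites")
    if len(constant):
        warnings.warn(f"dropping constant climate variables: {list(constant)}")
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    x = (table - table.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(x.to_numpy(dtype=float), full_matrices=False)
    keep = s > s[0] * 1e-9 if s[0] > 0 else s > 0
    u, s, vt = u[:, keep], s[keep], vt[keep]
    scores = u * s
    loadings = vt.T
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(len(s))]
    return ClimatePCA(
        scores=pd.DataFrame(scores, index=table.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comps),
        var_explained=pd.Series(s**2 / np.sum(s**2), index=comps),
    )


def _site_expression(m, site_map: Mapping[str, str]) -> pd.DataFrame:
    """Average RPM within each site (libraries sharing a site are pooled)."""
    if m.rpm is None:
        raise ValueError("expression matrix must be RPM-normalised first")
    libs = [l for l in m.libraries if l in site_map]
    if not libs:
        raise ValueError("no library maps to a site")
    groups = pd.Series({l: site_map[l] for l in libs})
    return m.rpm[libs].T.groupby(groups).mean().T


def pc_expression_correlation(
    pca: ClimatePCA,
    m,
    site_map: Mapping[str, str],
    n_components: int = 2,
) -> pd.DataFrame:
    """Pearson correlation of per-site expression with PC scores.

    With only three sites the p-values carry almost no power; they are
    reported with a ``low_power`` flag rather than suppressed.  Units with
    zero variance across sites get missing correlations.
    """
    expr = _site_expression(m, site_map)
    comps = list(pca.scores.columns[:n_components])
    sites = [s for s in pca.scores.index if s in expr.columns]
    rows = []
    low_power = len(sites) <= 3
    for unit in expr.index:
        vals = expr.loc[unit, sites].to_numpy(dtype=float)
        row: dict = {"unit": unit, "low_power": low_power}
        for comp in comps:
            scores = pca.scores.loc[sites, comp].to_numpy(dtype=float)
            if np.std(vals) == 0 or np.std(scores) == 0:
                row[f"r_{comp.lower()}"] = np.nan
                row[f"p_{comp.lower()}"] = np.nan
            else:
                r, p = scipy.stats.pearsonr(vals, scores)
                row[f"r_{comp.lower()}"] = float(r)
                row[f"p_{comp.lower()}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def season_factor_correlation(
    m,
    factors: pd.DataFrame,
    site_map: Mapping[str, str],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    p_rule: str = "less",
) -> pd.DataFrame:
    """Per-unit correlation with growing-season factors (AT, AP, AR).

    A unit is flagged for a factor when |r| exceeds *r_threshold* and the
    p-value clears *alpha*.  ``p_rule='less'`` (default) requires p < alpha;
    the literal reading p > alpha is available as ``p_rule='greater'``.
    The flag records the sign of the correlation (e.g. ``AT-``).
    """
    if p_rule not in ("less", "greater"):
        raise ValueError("p_rule must be 'less' or 'greater'")
    expr = _site_expression(m, site_map)
    sites = [s for s in factors.index if s in expr.columns]
    rows = []
    for unit in expr.index:
        vals = expr.loc[unit, sites].to_numpy(dtype=float)
        row: dict = {"unit": unit}
        flags = []
        for fac in factors.columns:
            fvals = factors.loc[sites, fac].to_numpy(dtype=float)
            if np.std(vals) == 0 or np.std(fvals) == 0:
                row[f"r_{fac}"], row[f"p_{fac}"] = np.nan, np.nan
                continue
            r, p = scipy.stats.pearsonr(vals, fvals)
            row[f"r_{fac}"], row[f"p_{fac}"] = float(r), float(p)
            p_ok = p < alpha if p_rule == "less" else p > alpha
            if abs(r) > r_threshold and p_ok:
                flags.append(f"{fac}{'+' if r > 0 else '-'}")
        row["flags"] = ",".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
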