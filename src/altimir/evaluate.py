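"""Score a pipeline run against the synthetic ground-truth manifest.

Recovery is measured exactly where the generator planted structure:

* population fold changes (field-condition library pairs) against the
  expected RPM ratios implied by the fold-change plan;
* the isomiR category mixture against the planted multinomial;
* the monotone-with-altitude unit sets (recall and false positives);
* per-population 5p/3p arm ratios against the planted log2 ratios;
* the no-guanosine rule for 3' non-template tails.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import ARM_3P, ARM_5P
from .isomir import NONTEMPLATE_3P
from .pipeline import FD_PAIRS, PipelineResult
from .simulate import POPULATIONS, TruthManifest


def fc_recovery(
    result: PipelineResult, manifest: TruthManifest, min_expected: float = 100.0
) -> pd.DataFrame:
    """Observed vs planted log2 fold changes for the population pairs.

    Only units with an expected countable read total of at least
    *min_expected* in both libraries of a pair are scored (below that the
    band is dominated by sampling noise rather than method error).
    """
    m = result.matrix
    rows = []
    for a, b in FD_PAIRS:
        if a not in m.libraries or b not in m.libraries:
            continue
        for unit in m.units:
            ea = manifest.expected_labeled_count(unit, a)
            eb = manifest.expected_labeled_count(unit, b)
            if min(ea, eb) < min_expected:
                continue
            observed = float(np.log2(m.rpm.loc[unit, b] / m.rpm.loc[unit, a]))
            planted = manifest.expected_log2fc(unit, a, b)
            rows.append(
                {
                    "unit": unit,
                    "pair": f"{b}_vs_{a}",
                    "planted": planted,
                    "observed": observed,
                    "abs_error": abs(observed - planted),
                    "expected_count_min": min(ea, eb),
                }
            )
    return pd.DataFrame(rows)


def mixture_recovery(result: PipelineResult, manifest: TruthManifest) -> pd.DataFrame:
    """Observed isomiR category counts vs the planted mixture, with z-scores
    in units of the multinomial standard error."""
    libs = result.matrix.libraries
    totals = {c: 0 for c in manifest.isomir_mixture}
    for rec, counts in result.isomir_assigned:
        if rec.category in totals:
            totals[rec.category] += sum(counts.get(l, 0) for l in libs)
    n = sum(totals.values())
    rows = []
    for cat, p in manifest.isomir_mixture.items():
        obs = totals[cat]
        se = np.sqrt(n * p * (1 - p))
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "expected": n * p,
                "proportion": obs / n if n else np.nan,
                "planted": p,
                "z": (obs - n * p) / se if se > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def monotone_recovery(result: PipelineResult, manifest: TruthManifest) -> dict:
    up_true, down_true = set(manifest.monotone_up), set(manifest.monotone_down)
    up_found, down_found = set(result.monotone_up), set(result.monotone_down)
    n_units = len(result.matrix.units)
    fp = (up_found - up_true) | (down_found - down_true)
    n_neutral = n_units - len(up_true) - len(down_true)
    return {
        "up_recall": len(up_found & up_true) / len(up_true) if up_true else 1.0,
        "down_recall": len(down_found & down_true) / len(down_true) if down_true else 1.0,
        "false_positives": sorted(fp),
        "fp_rate": len(fp) / n_neutral if n_neutral else 0.0,
    }


def arm_recovery(result: PipelineResult, manifest: TruthManifest) -> pd.DataFrame:
    """Per-population pooled 5p/3p log2 ratios vs the planted ratios."""
    index = result.index
    m = result.matrix
    rows = []
    for hairpin, planted in manifest.arm_ratio_log2.items():
        matures = index.by_hairpin[hairpin]
        u5 = next(index.unit_of(x.name) for x in matures if x.arm == ARM_5P)
        u3 = next(index.unit_of(x.name) for x in matures if x.arm == ARM_3P)
        for pop in POPULATIONS:
            libs = [l for l in m.libraries if l.startswith(f"{pop}_")]
            if not libs:
                continue
            c5 = int(m.raw.loc[u5, libs].sum())
            c3 = int(m.raw.loc[u3, libs].sum())
            if c5 == 0 or c3 == 0:
                continue
            observed = float(np.log2(c5 / c3))
            rows.append(
                {
                    "hairpin": hairpin,
                    "population": pop,
                    "planted": planted,
                    "observed": observed,
                    "abs_error": abs(observed - planted),
                    "count5p": c5,
                    "count3p": c3,
                }
            )
    return pd.DataFrame(rows)


def g_tail_reads(result: PipelineResult) -> int:
    """Total reads whose 3' non-template tail starts with guanosine."""
    libs = result.matrix.libraries
    total = 0
    for rec, counts in result.isomir_assigned:
        if rec.category == NONTEMPLATE_3P and rec.tail[:1] in ("G", "g"):
            total += sum(counts.get(l, 0) for l in libs)
    return total
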