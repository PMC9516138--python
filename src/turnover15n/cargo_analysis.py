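"""Significance testing, quadrant cargo classification, compartment summaries.

Putative autophagy cargo are proteins that, in an autophagy-deficient mutant,
degrade slower AND accumulate — the direct signature of losing a degradation
route.  Plotting relative delta-K_D against relative delta-abundance splits the
significantly changed proteins into four quadrants:

* Group 1: slower degradation, greater abundance  -> putative cargo
* Group 2: faster degradation, lower abundance    -> compensatory degradation
* Group 3: faster degradation, greater abundance  -> enhanced synthesis
* Group 4: slower degradation, lower abundance    -> feedback-reduced synthesis

A protein enters a quadrant only if at least one of its two contrasts is
significant (Student's t, P < alpha); this "abundance and/or degradation"
gate is the default, with a stricter AND mode available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "QuadrantCall",
    "CompartmentSummary",
    "protein_ttest",
    "classify_quadrant",
    "classify_table",
    "compartment_summary",
    "ks_compare",
]


@dataclass(frozen=True)
class QuadrantCall:
    protein_id: str
    contrast: str
    group: int  # 1-4, or 0 for unclassified
    significant_kd: bool
    significant_abundance: bool


@dataclass(frozen=True)
class CompartmentSummary:
    compartment: str
    n: int
    N: int
    percent: int


def protein_ttest(group_a, group_b) -> float:
    """Two-tailed pooled-variance (equal-variance) Student's t-test p-value.

    Returns NaN when either group has fewer than 2 finite values — such
    proteins are excluded from significance-dependent outputs.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def classify_quadrant(
    delta_kd: float,
    delta_abundance: float,
    p_kd: float,
    p_abundance: float,
    alpha: float = 0.05,
    gate: str = "or",
) -> int:
    """Assign a protein to quadrant Group 1-4, or 0 (unclassified).

    Group is determined solely by the signs of the two deltas; significance
    (min or both p < alpha, per ``gate``) decides whether the protein is
    classified at all.  Exact-zero deltas are boundary cases and stay
    unclassified.
    """
    if gate not in ("or", "and"):
        raise ValueError("gate must be 'or' or 'and'")
    if not (np.isfinite(delta_kd) and np.isfinite(delta_abundance)):
        return 0
    ps = [p for p in (p_kd, p_abundance) if np.isfinite(p)]
    if not ps:
        return 0
    if gate == "or":
        significant = min(ps) < alpha
    else:
        significant = len(ps) == 2 and max(ps) < alpha
    if not significant or delta_kd == 0.0 or delta_abundance == 0.0:
        return 0
    if delta_kd < 0 and delta_abundance > 0:
        return 1
    if delta_kd > 0 and delta_abundance < 0:
        return 2
    if delta_kd > 0 and delta_abundance > 0:
        return 3
    return 4


def classify_table(
    deltas: pd.DataFrame, alpha: float = 0.05, gate: str = "or"
) -> pd.DataFrame:
    """Vectorized quadrant calls for a delta table (one row per protein x contrast)."""
    out = deltas.copy()
    out["significant_kd"] = out["p_kd"] < alpha
    out["significant_abundance"] = out["p_abundance"] < alpha
    out["group"] = [
        classify_quadrant(r.delta_kd, r.delta_abundance, r.p_kd, r.p_abundance,
                          alpha=alpha, gate=gate)
        for r in out.itertuples()
    ]
    return out


def _percent_half_up(n: int, N: int) -> int:
    return int(math.floor(100.0 * n / N + 0.5))


def compartment_summary(
    selection: pd.Series | list,
    annotation: pd.DataFrame | dict,
    top: int | None = 3,
) -> pd.DataFrame:
    """Per-compartment counts and percentages for a protein selection.

    ``annotation`` maps protein_id -> compartment (DataFrame with those two
    columns, or a dict); unannotated proteins count as "other".  Compartments
    past the ``top`` most frequent are folded into "Others", mirroring how
    such tables are usually presented.  Percentages are half-up rounded
    integers of 100*n/N.
    """
    ids = list(selection)
    if not ids:
        raise ValueError("empty protein selection")
    if isinstance(annotation, pd.DataFrame):
        mapping = dict(zip(annotation["protein_id"], annotation["compartment"]))
    else:
        mapping = dict(annotation)
    comps = pd.Series([mapping.get(p, "other") for p in ids])
    counts = comps.value_counts()
    N = int(counts.sum())
    if top is not None and len(counts) > top:
        head = counts.iloc[:top]
        folded = pd.concat([head, pd.Series({"Others": int(counts.iloc[top:].sum())})])
    else:
        folded = counts
    rows = [
        {"compartment": c, "n": int(n), "N": N, "percent": _percent_half_up(int(n), N)}
        for c, n in folded.items()
    ]
    return pd.DataFrame(rows)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D statistic and asymptotic p-value.

    Used to contrast per-compartment distributions of relative deltas between
    conditions.  Returns (nan, nan) when either sample has fewer than 3
    values.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        return float("nan"), float("nan")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
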