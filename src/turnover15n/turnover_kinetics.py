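"""Degradation rates from labeled fractions, with growth-dilution correction.

In a growing tissue the pre-existing (unlabeled) protein pool is diluted both
by degradation and by growth.  With first-order degradation at rate K_D and
exponential tissue growth at rate g over the labeling window t, the unlabeled
fraction decays as exp(-K_D t) / FCP with FCP = exp(g t), so

    K_D = -(1/t) * ln((1 - LPF) * FCP)

A protein with LPF exactly at the growth-dilution floor has K_D = 0; values
below the floor give negative rates, which are retained with a qc flag rather
than truncated (truncation would bias downstream group contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KineticsConfig",
    "degradation_rate",
    "kd_table",
    "normalize_abundance",
    "relative_delta",
    "delta_table",
]

#: protein LPF above which the label is saturated and K_D is unreliable
SATURATION_LPF = 0.999

#: default growth/dilution rate per tissue (d^-1)
TISSUE_GROWTH = {"shoot": 0.1, "root": 0.5}


@dataclass(frozen=True)
class KineticsConfig:
    """Labeling window and growth-dilution correction.

    ``fcp`` (fold-change of the protein pool over the window) is derived as
    exp(g * t) from the tissue growth rate unless supplied directly; both are
    overridable because growth can be measured either way (rate or fold).
    """

    t: float = 3.0  # labeling duration, days
    tissue: str = "shoot"
    g: float | None = None  # d^-1
    fcp: float | None = None

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("labeling time t must be > 0")
        if self.fcp is not None and self.fcp < 1.0:
            raise ValueError("FCP must be >= 1")

    @property
    def growth_rate(self) -> float:
        if self.g is not None:
            return self.g
        return TISSUE_GROWTH[self.tissue]

    @property
    def fold_change_protein(self) -> float:
        if self.fcp is not None:
            return self.fcp
        return float(np.exp(self.growth_rate * self.t))


def degradation_rate(lpf, cfg: KineticsConfig = KineticsConfig()):
    """K_D (d^-1) from a labeled fraction; NaN where the label is saturated.

    Accepts scalars or arrays.  Returns ``(kd, qc)`` where qc is "" |
    "negative-rate" | "saturated-label".
    """
    lpf_arr = np.asarray(lpf, dtype=float)
    scalar = lpf_arr.ndim == 0
    lpf_arr = np.atleast_1d(lpf_arr)
    if np.any((lpf_arr < 0) & np.isfinite(lpf_arr)):
        raise ValueError("LPF must be >= 0")
    fcp = cfg.fold_change_protein
    saturated = lpf_arr > SATURATION_LPF
    with np.errstate(all="ignore"):
        kd = -np.log((1.0 - lpf_arr) * fcp) / cfg.t
    kd = np.where(saturated, np.nan, kd)
    qc = np.full(lpf_arr.shape, "", dtype=object)
    qc[saturated] = "saturated-label"
    qc[(~saturated) & (kd < 0)] = "negative-rate"
    if scalar:
        return float(kd[0]), str(qc[0])
    return kd, qc


def kd_table(protein_quant: pd.DataFrame, cfg: KineticsConfig = KineticsConfig()) -> pd.DataFrame:
    """Per protein x sample K_D from the protein-level LPF column."""
    out = protein_quant.dropna(subset=["lpf"]).copy()
    kd, qc = degradation_rate(out["lpf"].to_numpy(), cfg)
    out["kd"] = kd
    out["qc"] = qc
    return out[["protein_id", "genotype", "condition", "replicate", "kd", "qc"]]


def normalize_abundance(
    protein_quant: pd.DataFrame,
    value: str = "abundance_ratio",
    within: tuple[str, ...] = ("protein_id", "condition"),
) -> pd.DataFrame:
    """Divide each protein's spike-in ratios by its median across samples.

    The default normalizes within protein and condition, i.e. across the
    nine genotype x replicate samples of one condition, so each protein's
    normalized abundance is centred at 1 and comparable between proteins.
    All-missing proteins are dropped.
    """
    df = protein_quant.dropna(subset=[value]).copy()
    if df.empty:
        raise ValueError("no finite abundance ratios to normalize")
    med = df.groupby(list(within))[value].transform("median")
    df["abundance_norm"] = df[value] / med
    return df[["protein_id", "genotype", "condition", "replicate", value, "abundance_norm"]]


def relative_delta(group_a, group_b) -> float:
    """Relative difference (mean_a - mean_b) / mean(mean_a, mean_b).

    The scale-free change measure used for both K_D and abundance contrasts;
    bounded in (-2, 2) for nonnegative data and antisymmetric in its
    arguments.
    """
    a = float(np.mean(np.asarray(group_a, dtype=float)))
    b = float(np.mean(np.asarray(group_b, dtype=float)))
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("group means must be finite")
    pooled = 0.5 * (a + b)
    if pooled == 0.0:
        raise ValueError("pooled mean is zero; relative delta undefined")
    return (a - b) / pooled


def delta_table(
    kd: pd.DataFrame,
    abundance: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    condition: str | None = "control",
) -> pd.DataFrame:
    """Per-protein relative deltas and t-test p-values for genotype contrasts.

    ``contrasts`` lists (test, reference) genotype pairs, by default the two
    autophagy mutants against wild type.  K_D replicates enter the t-test
    unflagged or negative-rate flagged (saturated values are already missing);
    abundance uses the normalized values.
    """
    from .cargo_analysis import protein_ttest

    if contrasts is None:
        contrasts = [("atg5", "Wt"), ("atg11", "Wt")]
    kd_use = kd.dropna(subset=["kd"])
    ab_use = abundance.dropna(subset=["abundance_norm"])
    if condition is not None:
        kd_use = kd_use[kd_use["condition"] == condition]
        ab_use = ab_use[ab_use["condition"] == condition]

    rows = []
    for test, ref in contrasts:
        kd_piv = kd_use.pivot_table(index="protein_id", columns="genotype",
                                    values="kd", aggfunc=list)
        ab_piv = ab_use.pivot_table(index="protein_id", columns="genotype",
                                    values="abundance_norm", aggfunc=list)
        proteins = kd_piv.index.union(ab_piv.index)
        for pid in proteins:
            rec = {"protein_id": pid, "contrast": f"{test}_vs_{ref}",
                   "delta_kd": np.nan, "p_kd": np.nan,
                   "delta_abundance": np.nan, "p_abundance": np.nan}
            for piv, dcol, pcol in (
                (kd_piv, "delta_kd", "p_kd"),
                (ab_piv, "delta_abundance", "p_abundance"),
            ):
                if pid not in piv.index:
                    continue
                row = piv.loc[pid]
                va = row.get(test)
                vb = row.get(ref)
                if not isinstance(va, list) or not isinstance(vb, list):
                    continue
                va = [v for v in va if np.isfinite(v)]
                vb = [v for v in vb if np.isfinite(v)]
                if not va or not vb:
                    continue
                try:
                    rec[dcol] = relative_delta(va, vb)
                except ValueError:
                    continue
                rec[pcol] = protein_ttest(va, vb)
            rows.append(rec)
    return pd.DataFrame(rows)
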