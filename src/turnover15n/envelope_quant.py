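"""Per-peptide LPF and spike-in ratio estimation; peptide -> protein median polish.

The labeled peptide fraction (LPF) is identified purely by envelope shape, so
progressive-labeling observations are L1-normalized before fitting.  Because
the mixture envelope is linear in LPF, the bounded least-squares fit has a
closed form (projection onto the segment between the natural and labeled
envelopes, clamped to [0, 1]).  Spike-in observations keep their raw scale:
the light/heavy abundance ratio is read from a nonnegative least-squares
decomposition onto the natural and fully labeled basis envelopes.

Peptide-level values are summarized to proteins with Tukey median polish of
the peptide x sample matrix; the protein value in a sample is the overall
effect plus that sample's column effect, which is robust to outlier peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .isotope_model import EnrichmentModel, PeptideIon, peptide_envelopes

__all__ = [
    "LPFEstimate",
    "AbundanceRatio",
    "estimate_lpf",
    "spike_in_ratio",
    "median_polish",
    "quantify_peptides",
    "summarize_proteins",
]

SAMPLE_KEYS = ["genotype", "condition", "replicate"]


@dataclass(frozen=True)
class LPFEstimate:
    """Labeled-fraction estimate for one observation, with fit diagnostics."""

    lpf: float
    residual: float
    p_label: float
    converged: bool


@dataclass(frozen=True)
class AbundanceRatio:
    """Light (14N sample) / heavy (15N reference) abundance ratio."""

    ratio: float
    residual: float


def _common_length(*vecs: np.ndarray) -> list[np.ndarray]:
    k = max(len(v) for v in vecs)
    return [np.pad(v, (0, k - len(v))) for v in vecs]


def _fit_lpf_closed_form(
    obs: np.ndarray, nat: np.ndarray, lab: np.ndarray
) -> tuple[float, float]:
    """Least-squares LPF on the normalized envelope; exact for the linear model."""
    obs, nat, lab = _common_length(obs, nat, lab)
    obs = obs / obs.sum()
    d = lab - nat
    lpf = float(np.clip(np.dot(obs - nat, d) / np.dot(d, d), 0.0, 1.0))
    resid = float(np.linalg.norm(obs - (nat + lpf * d)))
    return lpf, resid


def estimate_lpf(
    intensities: np.ndarray,
    pep: PeptideIon,
    model: EnrichmentModel | None = None,
    fit_p_label: bool = False,
) -> LPFEstimate:
    """Estimate the labeled peptide fraction from a progressive-labeling envelope.

    Parameters
    ----------
    intensities
        Non-negative isotopologue intensities over k = 0..K.
    pep
        The peptide whose theoretical envelopes form the mixture basis.
    model
        Enrichment model; ``model.p_label`` is held fixed unless
        ``fit_p_label`` is set.
    fit_p_label
        Jointly fit the effective 15N enrichment of newly made protein.
        Opt-in: at low LPF the enrichment is weakly identified, so the
        default keeps it fixed at the configured value.
    """
    model = model or EnrichmentModel()
    intensities = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(intensities)) or np.any(intensities < 0):
        raise ValueError("intensities must be finite and non-negative")
    if np.count_nonzero(intensities) < 2:
        raise ValueError("need at least 2 nonzero channels to fit an envelope")

    if not fit_p_label:
        nat, lab = peptide_envelopes(pep, model)
        lpf, resid = _fit_lpf_closed_form(intensities, nat, lab)
        return LPFEstimate(lpf=lpf, residual=resid, p_label=model.p_label,
                           converged=True)

    from .isotope_model import composition_from_sequence, isotopologue_distribution

    comp = composition_from_sequence(pep)
    nat_env = isotopologue_distribution(comp, model.p_natural, model).probabilities

    def objective(p_label: float) -> tuple[float, float, float]:
        lab = isotopologue_distribution(comp, p_label, model).probabilities
        lpf, resid = _fit_lpf_closed_form(intensities, nat_env, lab)
        return resid, lpf, p_label

    res = scipy.optimize.minimize_scalar(
        lambda p: objective(p)[0],
        bounds=(model.p_natural + 1e-6, 1.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    resid, lpf, p_label = objective(float(res.x))
    return LPFEstimate(lpf=lpf, residual=resid, p_label=p_label,
                       converged=bool(res.success))


def spike_in_ratio(
    intensities: np.ndarray,
    pep: PeptideIon,
    model: EnrichmentModel | None = None,
) -> AbundanceRatio:
    """Light/heavy ratio from a spike-in envelope by nonnegative least squares.

    The observation is decomposed onto the natural envelope (the 14N sample)
    and the fully labeled envelope at ``p_label`` (the 15N reference pool);
    the ratio of the two coefficients is the relative abundance.
    """
    model = model or EnrichmentModel()
    intensities = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(intensities)) or np.any(intensities < 0):
        raise ValueError("intensities must be finite and non-negative")
    nat, lab = peptide_envelopes(pep, model)
    nat, lab, obs = _common_length(nat, lab, intensities)
    coef, rnorm = scipy.optimize.nnls(np.column_stack([nat, lab]), obs)
    light, heavy = float(coef[0]), float(coef[1])
    # NNLS returns denormal positives for an absent component; treat as zero
    if heavy <= 1e-12 * max(light, 1e-300):
        raise ValueError("no reference signal: heavy coefficient is zero")
    return AbundanceRatio(ratio=light / heavy, residual=float(rnorm))


def median_polish(
    matrix: np.ndarray | pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> dict:
    """Tukey median polish of a peptide x sample matrix (NaN cells allowed).

    Returns overall, row and column effects, residuals and convergence.
    The protein-level summary for sample j is ``overall + col[j]``.
    Medians are the standard mid-point median, which resolves ties.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("median polish needs a non-empty 2-D matrix")
    r = x.copy()
    nrow, ncol = r.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    converged = False
    with np.errstate(all="ignore"):
        for _ in range(max_iter):
            delta = 0.0
            rm = np.nanmedian(r, axis=1)
            rm = np.where(np.isnan(rm), 0.0, rm)
            r -= rm[:, None]
            row_eff += rm
            dc = np.nanmedian(col_eff)
            col_eff -= dc
            overall += dc
            delta = max(delta, float(np.max(np.abs(rm))), abs(float(dc)))

            cm = np.nanmedian(r, axis=0)
            cm = np.where(np.isnan(cm), 0.0, cm)
            r -= cm[None, :]
            col_eff += cm
            dr = np.nanmedian(row_eff)
            row_eff -= dr
            overall += dr
            delta = max(delta, float(np.max(np.abs(cm))), abs(float(dr)))
            if delta < tol:
                converged = True
                break
    return {
        "overall": float(overall),
        "row": row_eff,
        "col": col_eff,
        "residuals": r,
        "converged": converged,
    }


def quantify_peptides(
    observations: pd.DataFrame,
    model: EnrichmentModel | None = None,
    fit_p_label: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every observation in an envelope table; returns (lpf, ratio) tables.

    ``observations`` follows the simulator schema: identifier columns plus
    k0..kK intensity columns and an ``experiment`` column distinguishing
    progressive-labeling rows from spike-in rows.  Fits are vectorized per
    peptide (the theoretical basis envelopes are computed once each).
    """
    model = model or EnrichmentModel()
    kcols = [c for c in observations.columns if c.startswith("k") and c[1:].isdigit()]
    kcols = sorted(kcols, key=lambda c: int(c[1:]))
    lpf_rows, ratio_rows = [], []
    meta = ["protein_id", "peptide", "charge", "genotype", "condition", "replicate"]
    for (seq, charge), grp in observations.groupby(["peptide", "charge"], sort=False):
        pep = PeptideIon(str(seq), int(charge))
        nat, lab = peptide_envelopes(pep, model)
        intens = grp[kcols].to_numpy(dtype=float)
        k = max(intens.shape[1], len(nat))
        nat_p, lab_p = np.pad(nat, (0, k - len(nat))), np.pad(lab, (0, k - len(lab)))
        intens = np.pad(intens, ((0, 0), (0, k - intens.shape[1])))
        d = lab_p - nat_p
        dd = float(np.dot(d, d))

        is_prog = (grp["experiment"] == "progressive").to_numpy()
        if is_prog.any():
            sub = intens[is_prog]
            norm = sub / sub.sum(axis=1, keepdims=True)
            lpf = np.clip((norm - nat_p) @ d / dd, 0.0, 1.0)
            resid = np.linalg.norm(norm - (nat_p + lpf[:, None] * d), axis=1)
            sub_meta = grp.loc[is_prog, meta].reset_index(drop=True)
            sub_meta["lpf"] = lpf
            sub_meta["residual"] = resid
            sub_meta["p_label"] = model.p_label
            if fit_p_label:
                ests = [
                    estimate_lpf(row, pep, model, fit_p_label=True)
                    for row in intens[is_prog]
                ]
                sub_meta["lpf"] = [e.lpf for e in ests]
                sub_meta["residual"] = [e.residual for e in ests]
                sub_meta["p_label"] = [e.p_label for e in ests]
            lpf_rows.append(sub_meta)

        is_spike = (grp["experiment"] == "spikein").to_numpy()
        if is_spike.any():
            basis = np.column_stack([nat_p, lab_p])
            sub_meta = grp.loc[is_spike, meta].reset_index(drop=True)
            ratios, resids = [], []
            for row in intens[is_spike]:
                coef, rnorm = scipy.optimize.nnls(basis, row)
                ratios.append(coef[0] / coef[1] if coef[1] > 0 else np.nan)
                resids.append(rnorm)
            sub_meta["ratio"] = ratios
            sub_meta["residual"] = resids
            ratio_rows.append(sub_meta)

    lpf_df = pd.concat(lpf_rows, ignore_index=True) if lpf_rows else pd.DataFrame()
    ratio_df = pd.concat(ratio_rows, ignore_index=True) if ratio_rows else pd.DataFrame()
    return lpf_df, ratio_df


def _drop_shared_peptides(df: pd.DataFrame) -> pd.DataFrame:
    """Remove peptides mapping to more than one protein before aggregation."""
    n_prot = df.groupby("peptide")["protein_id"].transform("nunique")
    return df[n_prot == 1]


def summarize_proteins(
    lpf_df: pd.DataFrame, ratio_df: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate peptide LPFs and spike-in ratios to proteins by median polish.

    LPF is polished on its natural scale and clamped to [0, 1]; abundance
    ratios are polished on the log2 scale (multiplicative errors) and
    back-transformed.  Returns one row per protein x sample with columns
    lpf, abundance_ratio, n_peptides_lpf, n_peptides_ratio.
    """
    lpf_df = _drop_shared_peptides(lpf_df)
    ratio_df = _drop_shared_peptides(ratio_df)

    def polish_protein(grp: pd.DataFrame, value: str, log2: bool) -> pd.DataFrame:
        wide = grp.pivot_table(
            index="peptide", columns=SAMPLE_KEYS, values=value, aggfunc="mean"
        )
        vals = np.log2(wide.to_numpy()) if log2 else wide.to_numpy()
        fit = median_polish(vals)
        summary = fit["overall"] + fit["col"]
        if log2:
            summary = np.exp2(summary)
        out = pd.DataFrame(wide.columns.tolist(), columns=SAMPLE_KEYS)
        out[value if not log2 else "abundance_ratio"] = (
            np.clip(summary, 0.0, 1.0) if value == "lpf" else summary
        )
        out["n_peptides"] = wide.notna().any(axis=1).sum()
        return out

    lpf_sum = (
        lpf_df.groupby("protein_id")
        .apply(polish_protein, value="lpf", log2=False, include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
        .rename(columns={"n_peptides": "n_peptides_lpf"})
    )
    ratio_sum = (
        ratio_df.dropna(subset=["ratio"])
        .groupby("protein_id")
        .apply(polish_protein, value="ratio", log2=True, include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
        .rename(columns={"n_peptides": "n_peptides_ratio"})
    )
    merged = lpf_sum.merge(ratio_sum, on=["protein_id", *SAMPLE_KEYS], how="outer")
    return merged.sort_values(["protein_id", *SAMPLE_KEYS]).reset_index(drop=True)
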