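"""Ground-truth proteomes and simulated peptide-envelope observations.

The generator emulates the statistical design of a 15N progressive-labeling
turnover study in Arabidopsis: three genotypes (wild type and two autophagy
mutants) x two nutrient conditions x three biological replicates, a 3-day
label switch at high 15N enrichment, and a separate 1:1 spike-in of a fully
15N-labeled common reference pool for relative abundance.  A configurable
"cargo" subset of proteins degrades slower and accumulates in the mutants —
the signature the downstream quadrant classification must recover.

True per-peptide labeled fractions follow the first-order turnover model with
growth dilution::

    LPF = 1 - exp(-K_D * t) / FCP,      FCP = exp(g * t)

so the simulator and :func:`turnover15n.turnover_kinetics.degradation_rate`
are exact inverses by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope_model import EnrichmentModel, PeptideIon, peptide_envelopes

__all__ = ["SimulationConfig", "TruthTable", "generate_truth", "simulate_experiment"]

GENOTYPES = ("Wt", "atg5", "atg11")
CONDITIONS = ("control", "minusPi")

#: default growth/dilution rate g (d^-1) per tissue entering FCP = e^(g t)
TISSUE_GROWTH = {"shoot": 0.1, "root": 0.5}

# categorical compartment weights for a plant cell proteome
_COMPARTMENTS = {
    "cytosol": 0.35,
    "mitochondrion": 0.12,
    "plastid": 0.12,
    "ER": 0.06,
    "peroxisome": 0.04,
    "vacuole": 0.05,
    "nucleus": 0.08,
    "plasma membrane": 0.07,
    "extracellular": 0.04,
    "other": 0.07,
}

_AA = np.array(list("GASPVTCLINDQKEMHFRYW"))


@dataclass
class SimulationConfig:
    """Study design and noise model of the simulated experiment.

    Defaults mirror the labeling design the pipeline targets: 200 proteins,
    3 biological replicates x 3 genotypes x 2 conditions, 3-day labeling,
    5% multiplicative intensity noise, 10% cargo with halved degradation rate
    and +50% abundance in the autophagy mutants.
    """

    n_proteins: int = 200
    peptides_per_protein_mean: float = 5.0  # 1 + Poisson(mean - 1)
    kd_median: float = 0.2  # d^-1, lognormal median
    kd_sigma: float = 0.4  # ln-scale sd
    abundance_sigma: float = 0.5  # ln-scale sd of base abundance (median 1)
    cargo_fraction: float = 0.1
    cargo_kd_ratio: float = 0.5  # mutant K_D multiplier for cargo
    cargo_abundance_ratio: float = 1.5  # mutant abundance multiplier for cargo
    n_replicates: int = 3
    tissue: str = "shoot"
    growth_rate: float | None = None  # d^-1; default looked up from tissue
    t_label: float = 3.0  # days of progressive labeling
    noise_cv: float = 0.05  # multiplicative CV per isotopologue channel
    reference_scale: float = 1.0e6  # base intensity of unit abundance
    compartment_probs: dict[str, float] = field(
        default_factory=lambda: dict(_COMPARTMENTS)
    )
    seed: int = 0

    @property
    def g(self) -> float:
        if self.growth_rate is not None:
            return self.growth_rate
        return TISSUE_GROWTH[self.tissue]

    @property
    def fcp(self) -> float:
        """Fold-change of the tissue protein pool over the labeling window."""
        return float(np.exp(self.g * self.t_label))

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.kd_median <= 0 or self.g < 0 or self.t_label <= 0:
            raise ValueError("rates and labeling time must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates for any significance testing")
        if not 0.0 <= self.cargo_fraction <= 1.0:
            raise ValueError("cargo_fraction must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth: per-protein kinetics/abundance plus the peptide roster.

    ``proteins`` columns: protein_id, compartment, cargo, kd_<genotype>, and
    abundance_<genotype>_<condition>.  ``peptides`` columns: protein_id,
    peptide, charge.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame

    def to_tsv(self) -> str:
        buf = io.StringIO()
        merged = self.peptides.merge(self.proteins, on="protein_id")
        merged.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def _tryptic_like_sequences(rng: np.random.Generator, n: int) -> list[str]:
    """Random tryptic-like peptides: length 7-25, ending in K or R."""
    out = []
    for _ in range(n):
        length = int(rng.integers(7, 26))
        body = rng.choice(_AA, size=length - 1)
        out.append("".join(body) + str(rng.choice(["K", "R"])))
    return out


def true_lpf(kd: np.ndarray | float, g: float, t: float) -> np.ndarray | float:
    """Labeled fraction after time t for degradation rate kd and growth g."""
    lpf = 1.0 - np.exp(-np.asarray(kd, dtype=float) * t) / np.exp(g * t)
    if np.any(lpf < 0) or np.any(lpf >= 1):
        raise ValueError("true LPF outside [0, 1): inconsistent K_D, g, t")
    return lpf


def generate_truth(cfg: SimulationConfig) -> TruthTable:
    """Draw a ground-truth proteome; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    ids = [f"P{i:04d}" for i in range(n)]
    comps = list(cfg.compartment_probs)
    probs = np.array([cfg.compartment_probs[c] for c in comps], dtype=float)
    compartment = rng.choice(comps, size=n, p=probs / probs.sum())
    cargo = rng.random(n) < cfg.cargo_fraction
    kd_wt = np.exp(np.log(cfg.kd_median) + cfg.kd_sigma * rng.standard_normal(n))
    base_ab = np.exp(cfg.abundance_sigma * rng.standard_normal(n))

    proteins = pd.DataFrame({"protein_id": ids, "compartment": compartment, "cargo": cargo})
    for geno in GENOTYPES:
        mult = np.where(cargo & (geno != "Wt"), cfg.cargo_kd_ratio, 1.0)
        proteins[f"kd_{geno}"] = kd_wt * mult
    for geno in GENOTYPES:
        ab_mult = np.where(cargo & (geno != "Wt"), cfg.cargo_abundance_ratio, 1.0)
        for cond in CONDITIONS:
            proteins[f"abundance_{geno}_{cond}"] = base_ab * ab_mult

    n_pep = 1 + rng.poisson(max(cfg.peptides_per_protein_mean - 1.0, 0.0), size=n)
    rows = []
    for pid, k in zip(ids, n_pep):
        for seq in _tryptic_like_sequences(rng, int(k)):
            rows.append((pid, seq, int(rng.integers(2, 4))))
    peptides = pd.DataFrame(rows, columns=["protein_id", "peptide", "charge"])
    return TruthTable(proteins=proteins, peptides=peptides)


def simulate_experiment(
    truth: TruthTable,
    cfg: SimulationConfig,
    model: EnrichmentModel | None = None,
) -> pd.DataFrame:
    """Simulate envelope observations for every peptide/sample.

    Returns one table with both experiment kinds:

    * ``progressive`` — the 3-day labeled sample: mixture of natural and
      enriched envelopes at the protein's true LPF, scaled by abundance.
    * ``spikein`` — unlabeled sample plus the fully labeled common reference
      pool (at the protein's base abundance), summed into one envelope.

    Columns: protein_id, peptide, charge, experiment, genotype, condition,
    replicate, k0..kK.  Multiplicative lognormal noise (CV ``cfg.noise_cv``)
    is applied per isotopologue channel.
    """
    cfg.validate()
    model = model or EnrichmentModel()
    rng = np.random.default_rng(cfg.seed + 1)
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))

    prot = truth.proteins.set_index("protein_id")
    # reference pool = Wt-like base abundance, shared across all samples
    ref_abundance = prot["abundance_Wt_control"]

    records: list[tuple] = []
    envelopes: list[np.ndarray] = []
    for pep_row in truth.peptides.itertuples(index=False):
        pid, seq, charge = pep_row.protein_id, pep_row.peptide, pep_row.charge
        nat, lab = peptide_envelopes(PeptideIon(seq, charge), model)
        p = prot.loc[pid]
        for geno in GENOTYPES:
            lpf = float(true_lpf(p[f"kd_{geno}"], cfg.g, cfg.t_label))
            mix = (1.0 - lpf) * nat + lpf * lab
            for cond in CONDITIONS:
                ab = float(p[f"abundance_{geno}_{cond}"]) * cfg.reference_scale
                ref = float(ref_abundance.loc[pid]) * cfg.reference_scale
                spike = nat * ab + lab * ref
                for rep in range(1, cfg.n_replicates + 1):
                    for kind, clean in (("progressive", mix * ab), ("spikein", spike)):
                        noisy = clean
                        if cfg.noise_cv > 0:
                            noise = rng.lognormal(
                                -0.5 * sigma**2, sigma, size=clean.shape
                            )
                            noisy = clean * noise
                        records.append((pid, seq, charge, kind, geno, cond, rep))
                        envelopes.append(noisy)

    kmax = max(len(e) for e in envelopes)
    mat = np.zeros((len(envelopes), kmax))
    for i, e in enumerate(envelopes):
        mat[i, : len(e)] = e
    obs = pd.DataFrame(
        records,
        columns=["protein_id", "peptide", "charge", "experiment", "genotype",
                 "condition", "replicate"],
    )
    for k in range(kmax):
        obs[f"k{k}"] = mat[:, k]
    return obs


def annotation_table(truth: TruthTable) -> pd.DataFrame:
    """Protein -> compartment annotation table (classify-stage input)."""
    return truth.proteins[["protein_id", "compartment"]].copy()
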