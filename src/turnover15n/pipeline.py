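"""End-to-end orchestration: simulate -> quantify -> kinetics -> classify -> report.

Every output table is tab-separated UTF-8 with one '#'-prefixed provenance
header line carrying the package version, the seed and a hash of the run
configuration, so any table can be traced back to the exact run that wrote it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .isotope_model import EnrichmentModel
from .synthetic_data import SimulationConfig, annotation_table, generate_truth, simulate_experiment
from .envelope_quant import quantify_peptides, summarize_proteins
from .turnover_kinetics import KineticsConfig, delta_table, kd_table, normalize_abundance
from .cargo_analysis import classify_table, compartment_summary

log = logging.getLogger("turnover15n")

__all__ = ["PipelineConfig", "run_all", "write_table", "read_table"]


@dataclass
class PipelineConfig:
    """Run configuration: paths, simulation design, model and thresholds."""

    outdir: str = "turnover15n_out"
    seed: int = 0
    alpha: float = 0.05
    gate: str = "or"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    enrichment: EnrichmentModel = field(default_factory=EnrichmentModel)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        enr = EnrichmentModel(**raw.pop("enrichment", {}))
        kin = KineticsConfig(**raw.pop("kinetics", {}))
        cfg = cls(simulation=sim, enrichment=enr, kinetics=kin, **raw)
        cfg.simulation.seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # hash analytic parameters, not file layout
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, cfg: PipelineConfig) -> None:
    """Write a TSV with a single provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# turnover15n v{__version__} seed={cfg.seed} config={cfg.config_hash()}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a provenance-headed TSV, validating required columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    cfg.simulation.seed = cfg.seed
    truth = generate_truth(cfg.simulation)
    obs = simulate_experiment(truth, cfg.simulation, cfg.enrichment)
    merged_truth = truth.peptides.merge(truth.proteins, on="protein_id")
    write_table(merged_truth, out / "truth.tsv", cfg)
    write_table(obs, out / "envelopes.tsv", cfg)
    write_table(annotation_table(truth), out / "annotation.tsv", cfg)
    log.info("simulate: %d observations for %d proteins", len(obs), cfg.simulation.n_proteins)
    return {name: out / f"{name}.tsv" for name in ("truth", "envelopes", "annotation")}


def stage_quantify(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    obs = read_table(out / "envelopes.tsv",
                     required=["protein_id", "peptide", "charge", "experiment"])
    lpf_df, ratio_df = quantify_peptides(obs, cfg.enrichment)
    quant = summarize_proteins(lpf_df, ratio_df)
    write_table(lpf_df, out / "peptide_lpf.tsv", cfg)
    write_table(ratio_df, out / "peptide_ratio.tsv", cfg)
    write_table(quant, out / "protein_quant.tsv", cfg)
    log.info("quantify: %d peptide LPFs -> %d protein x sample rows", len(lpf_df), len(quant))
    return {n: out / f"{n}.tsv" for n in ("peptide_lpf", "peptide_ratio", "protein_quant")}


def stage_kinetics(cfg: PipelineConfig) -> dict[str, Path]:
    out = Path(cfg.outdir)
    quant = read_table(out / "protein_quant.tsv", required=["protein_id", "lpf"])
    kd = kd_table(quant, cfg.kinetics)
    ab = normalize_abundance(quant)
    deltas = delta_table(kd, ab)
    write_table(kd, out / "protein_kd.tsv", cfg)
    write_table(ab, out / "protein_abundance_norm.tsv", cfg)
    write_table(deltas, out / "delta.tsv", cfg)
    log.info("kinetics: K_D for %d protein x sample rows", len(kd))
    return {n: out / f"{n}.tsv" for n in ("protein_kd", "protein_abundance_norm", "delta")}


def stage_classify(cfg: PipelineConfig, annotation_path: str | Path | None = None) -> dict[str, Path]:
    out = Path(cfg.outdir)
    deltas = read_table(out / "delta.tsv",
                        required=["protein_id", "delta_kd", "delta_abundance"])
    ann = read_table(annotation_path or out / "annotation.tsv",
                     required=["protein_id", "compartment"])
    calls = classify_table(deltas, alpha=cfg.alpha, gate=cfg.gate)
    write_table(calls, out / "quadrants.tsv", cfg)

    summaries = []
    for contrast, grp in calls.groupby("contrast"):
        slower = grp[(grp["group"] != 0) & (grp["delta_kd"] < 0)]["protein_id"]
        if len(slower) == 0:
            continue
        summ = compartment_summary(slower, ann)
        summ.insert(0, "contrast", contrast)
        summaries.append(summ)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    write_table(summary, out / "compartment_summary.tsv", cfg)

    import numpy as np

    volcano = calls[["protein_id", "contrast", "delta_kd", "delta_abundance"]].copy()
    with pd.option_context("mode.chained_assignment", None):
        volcano["neglog10_p_kd"] = -np.log10(calls["p_kd"])
        volcano["neglog10_p_abundance"] = -np.log10(calls["p_abundance"])
    write_table(volcano, out / "volcano.tsv", cfg)
    log.info("classify: %d Group-1 calls", int((calls["group"] == 1).sum()))
    return {n: out / f"{n}.tsv" for n in ("quadrants", "compartment_summary", "volcano")}


_STAGE_OUTPUTS = {
    "stage_simulate": ("truth", "envelopes", "annotation"),
    "stage_quantify": ("peptide_lpf", "peptide_ratio", "protein_quant"),
    "stage_kinetics": ("protein_kd", "protein_abundance_norm", "delta"),
    "stage_classify": ("quadrants", "compartment_summary", "volcano"),
}


def run_all(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage in order; returns the map of all written tables.

    A failing stage removes its partial outputs before the error propagates.
    """
    paths = {}
    for stage in (stage_simulate, stage_quantify, stage_kinetics, stage_classify):
        try:
            paths.update(stage(cfg))
        except Exception:
            log.exception("stage %s failed; removing partial outputs", stage.__name__)
            for name in _STAGE_OUTPUTS[stage.__name__]:
                (Path(cfg.outdir) / f"{name}.tsv").unlink(missing_ok=True)
            raise
    return paths
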