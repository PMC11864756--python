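"""Synthetic paired transcriptome/proteome benchmark with planted influence.

The generator emulates the shape of the study design the pipeline targets —
4 timepoints (estrus, 0.5, 1.5, 2.5 dpc) x 2 oviduct regions (IA, IU) with a
few replicates per cell — without attempting to match any real dataset's
distributions.  Counts come from a negative-binomial model with additive
timepoint/region effects on the log mean.  Each protein's abundance is a
noisy monotone function of a small planted set of transcription-factor
expressions, so attention-based influence ranking has a known ground truth
to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ContractError
from .io import REGIONS, TIMEPOINTS, OmicsMatrix, SampleSheet, TFAnnotation


@dataclass
class GeneratorConfig:
    """Knobs of the planted-structure generator.

    The defaults are the desk-scale study conditions used throughout the test
    suite: 300 genes of which 30 are TFs, 50 proteins each driven by 3 planted
    TFs, 4 timepoints x 2 regions x 3 replicates = 24 samples.
    """

    n_genes: int = 300
    n_tfs: int = 30
    n_proteins: int = 50
    planted_tfs_per_protein: int = 3
    timepoints: tuple[str, ...] = TIMEPOINTS
    regions: tuple[str, ...] = REGIONS
    replicates: int = 3
    #: log-normal parameters of per-gene baseline expression
    base_log_mean: float = 4.0
    base_log_sd: float = 1.5
    #: negative-binomial dispersion (1/size); 0 degenerates to Poisson
    dispersion: float = 0.1
    #: SD of per-gene additive timepoint effects on the log mean (TF genes
    #: always receive effects; a fraction of non-TF genes do too)
    tf_effect_sd: float = 1.5
    gene_effect_sd: float = 0.8
    responsive_gene_fraction: float = 0.3
    region_effect_sd: float = 0.3
    #: per-sample biological variability of each gene's log mean (replicates
    #: within a timepoint/region cell are not identical animals)
    replicate_effect_sd: float = 1.0
    #: protein side: drive = log1p(sum w * cpm of planted TFs), standardized
    #: per protein against an independent reference pool of hypothetical
    #: replicates (never the realized samples, which would tie the held-out
    #: samples to the training ones), squashed to u = sigmoid(z) in (0, 1);
    #: abundance = abundance_scale ** (u + N(0, noise_sd)) — intensities span
    #: orders of magnitude, as proteomic measurements do, and noise_sd is the
    #: noise SD on the unit latent scale
    abundance_scale: float = 1000.0
    noise_sd: float = 0.05
    n_reference_samples: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_tfs <= self.n_genes):
            raise ConfigError("need 0 < n_tfs <= n_genes")
        if not (0 < self.planted_tfs_per_protein <= self.n_tfs):
            raise ConfigError("need 0 < planted_tfs_per_protein <= n_tfs")
        if min(self.dispersion, self.noise_sd, self.region_effect_sd,
               self.tf_effect_sd, self.gene_effect_sd) < 0:
            raise ConfigError("variance parameters must be >= 0")
        if self.replicates < 1 or self.n_proteins < 1:
            raise ConfigError("need at least one replicate and one protein")


def default_preset(seed: int = 0) -> GeneratorConfig:
    """Moderate-noise study conditions (3 planted TFs per protein)."""
    return GeneratorConfig(seed=seed)


def noiseless_preset(seed: int = 0, planted_tfs_per_protein: int = 1) -> GeneratorConfig:
    """Zero protein noise, near-Poisson counts and strong TF effects: labels
    are a deterministic function of the planted TF drive and that drive
    dominates the per-sample normalization wobble."""
    return GeneratorConfig(
        noise_sd=0.0,
        dispersion=0.02,
        tf_effect_sd=2.5,
        planted_tfs_per_protein=planted_tfs_per_protein,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator planted: which TFs drive each protein, and how."""

    influence: dict[str, list[tuple[str, float]]]  # protein -> [(tf_id, weight)]
    timepoint_effects: pd.DataFrame  # genes x timepoints, log-scale
    region_effects: pd.DataFrame  # genes x regions, log-scale
    latent_abundance: pd.DataFrame  # proteins x samples, pre-noise

    def planted_tfs(self, protein_id: str) -> set[str]:
        return {tf for tf, _ in self.influence[protein_id]}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "influence": {p: [[t, w] for t, w in tws] for p, tws in self.influence.items()},
            "timepoint_effects": self.timepoint_effects.to_dict(orient="split"),
            "region_effects": self.region_effects.to_dict(orient="split"),
            "latent_abundance": self.latent_abundance.to_dict(orient="split"),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        def df(key):
            d = payload[key]
            return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])
        return cls(
            influence={p: [(t, float(w)) for t, w in tws] for p, tws in payload["influence"].items()},
            timepoint_effects=df("timepoint_effects"),
            region_effects=df("region_effects"),
            latent_abundance=df("latent_abundance"),
        )


@dataclass
class SyntheticDataset:
    counts: OmicsMatrix
    proteins: OmicsMatrix
    sheet: SampleSheet
    tfs: TFAnnotation
    truth: GroundTruth


def _minmax(rows: np.ndarray) -> np.ndarray:
    lo = rows.min(axis=1, keepdims=True)
    hi = rows.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (rows - lo) / span


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one paired dataset, fully determined by ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    tf_idx = np.arange(config.n_tfs)  # first n_tfs genes are the TFs
    tf_ids = [gene_ids[i] for i in tf_idx]
    protein_ids = [f"prot{i:03d}" for i in range(config.n_proteins)]

    sample_rows = []
    for tp in config.timepoints:
        for rg in config.regions:
            for r in range(config.replicates):
                sample_rows.append((f"{tp}_{rg}_r{r + 1}", tp, rg))
    sheet = SampleSheet(pd.DataFrame(sample_rows, columns=["sample_id", "timepoint", "region"]))
    sample_ids = sheet.sample_ids

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=config.n_genes)

    tp_eff = np.zeros((config.n_genes, len(config.timepoints)))
    responsive = rng.random(config.n_genes) < config.responsive_gene_fraction
    responsive[tf_idx] = True
    sds = np.where(np.isin(np.arange(config.n_genes), tf_idx),
                   config.tf_effect_sd, config.gene_effect_sd)
    for j in range(len(config.timepoints)):
        tp_eff[:, j] = np.where(responsive, rng.normal(0, 1, config.n_genes) * sds, 0.0)
    rg_eff = np.zeros((config.n_genes, len(config.regions)))
    for j in range(len(config.regions)):
        rg_eff[:, j] = np.where(responsive, rng.normal(0, config.region_effect_sd, config.n_genes), 0.0)

    tp_index = {t: j for j, t in enumerate(config.timepoints)}
    rg_index = {r: j for j, r in enumerate(config.regions)}
    log_mu = np.empty((config.n_genes, len(sample_ids)))
    for s, (sid, tp, rg) in enumerate(sample_rows):
        rep = rng.normal(0.0, config.replicate_effect_sd, config.n_genes) \
            if config.replicate_effect_sd > 0 else 0.0
        log_mu[:, s] = base + tp_eff[:, tp_index[tp]] + rg_eff[:, rg_index[rg]] + rep
    mu = np.exp(log_mu)

    if config.dispersion > 0:
        size = 1.0 / config.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)

    cpm = counts / np.maximum(counts.sum(axis=0), 1.0) * 1e6

    # reference pool: hypothetical samples whose condition effects are fresh
    # draws from the effect prior (not the dataset's realized effects), used
    # only to center/scale each protein's drive.  Standardizing against the
    # realized timepoints would force a protein that is high at the training
    # stages to be low at the held-out stage — an artifact, not biology.
    n_ref = max(config.n_reference_samples, 8)
    ref_cpm_tf = np.empty((config.n_tfs, n_ref))
    for i in range(n_ref):
        eff = np.where(responsive, rng.normal(0, 1, config.n_genes) * sds, 0.0)
        reg = np.where(responsive, rng.normal(0, config.region_effect_sd, config.n_genes), 0.0)
        jit = rng.normal(0.0, config.replicate_effect_sd, config.n_genes) \
            if config.replicate_effect_sd > 0 else 0.0
        mu_ref = np.exp(base + eff + reg + jit)
        ref_cpm_tf[:, i] = mu_ref[tf_idx] / mu_ref.sum() * 1e6

    influence: dict[str, list[tuple[str, float]]] = {}
    latent = np.empty((config.n_proteins, len(sample_ids)))
    for p, pid in enumerate(protein_ids):
        chosen = rng.choice(config.n_tfs, size=config.planted_tfs_per_protein, replace=False)
        weights = rng.uniform(0.5, 1.5, size=config.planted_tfs_per_protein)
        influence[pid] = [(tf_ids[int(c)], float(w)) for c, w in zip(chosen, weights)]
        drive = np.log1p((weights[:, None] * cpm[tf_idx[chosen], :]).sum(axis=0))
        drive_ref = np.log1p((weights[:, None] * ref_cpm_tf[chosen, :]).sum(axis=0))
        mu_ref, sd_ref = drive_ref.mean(), max(drive_ref.std(), 1e-9)
        latent[p] = 1.0 / (1.0 + np.exp(-(drive - mu_ref) / sd_ref))

    noise = rng.normal(0.0, config.noise_sd, size=latent.shape)
    protein_values = config.abundance_scale ** np.clip(latent + noise, 0.0, None)
    latent = config.abundance_scale**latent  # recorded on the abundance scale

    truth = GroundTruth(
        influence=influence,
        timepoint_effects=pd.DataFrame(tp_eff, index=gene_ids, columns=list(config.timepoints)),
        region_effects=pd.DataFrame(rg_eff, index=gene_ids, columns=list(config.regions)),
        latent_abundance=pd.DataFrame(latent, index=protein_ids, columns=sample_ids),
    )
    return SyntheticDataset(
        counts=OmicsMatrix(gene_ids, list(sample_ids), counts, "transcript"),
        proteins=OmicsMatrix(protein_ids, list(sample_ids), protein_values, "protein"),
        sheet=sheet,
        tfs=TFAnnotation(set(tf_ids)),
        truth=truth,
    )


def null_proteome(config: GeneratorConfig) -> tuple[OmicsMatrix, SampleSheet]:
    """Proteome with zero group effects: per-protein constant latent mean plus
    i.i.d. Gaussian noise, for type-I-error studies of the DPA procedure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    protein_ids = [f"prot{i:04d}" for i in range(config.n_proteins)]
    sample_rows = []
    for tp in config.timepoints:
        for rg in config.regions:
            for r in range(config.replicates):
                sample_rows.append((f"{tp}_{rg}_r{r + 1}", tp, rg))
    sheet = SampleSheet(pd.DataFrame(sample_rows, columns=["sample_id", "timepoint", "region"]))
    latent = rng.uniform(0.2, 1.0, size=config.n_proteins)[:, None] * config.abundance_scale
    noise = rng.normal(0.0, config.noise_sd * config.abundance_scale,
                       size=(config.n_proteins, len(sample_rows)))
    values = np.maximum(latent + noise, 0.0)
    return OmicsMatrix(protein_ids, sheet.sample_ids, values, "protein"), sheet


def recovery_score(report, truth: GroundTruth, k: int) -> tuple[dict[str, float], float]:
    """Recall@k per protein against the planted sets, plus the mean.

    ``report`` is an :class:`~tfinfluence.influence.InfluencerReport`; recall
    is |top-k intersect planted| / |planted| for each protein in the report.
    """
    recalls: dict[str, float] = {}
    for pid, entries in report.per_protein.items():
        if pid not in truth.influence:
            raise ContractError(f"protein {pid!r} absent from ground truth")
        planted = truth.planted_tfs(pid)
        top = {tf for tf, _ in entries[:k]}
        recalls[pid] = len(top & planted) / len(planted)
    mean = float(np.mean(list(recalls.values()))) if recalls else 0.0
    return recalls, mean


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)
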