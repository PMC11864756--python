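"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate ->
influence -> dpa, with a manifest recording the fully resolved configuration,
input hashes, seeds and stage timings.

Stage outputs use fixed filenames inside the run directory and are written
atomically (temp file + rename), so a crashed stage never leaves a partial
table behind.  Re-running a stage with unchanged inputs and seed reproduces
its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dpa import SdSpec, dpa_test, expand_gaussian, significant_proteins, volcano_table
from .exceptions import ConfigError, DomainError
from .influence import (
    extract_influence,
    intersect_significant,
    restrict_to_tfs,
    topk_influencers,
    write_influencer_report,
)
from .io import (
    SignificanceLists,
    read_matrix,
    read_sample_sheet,
    read_significance_lists,
    read_tf_list,
    write_matrix,
    write_sample_sheet,
    write_tf_list,
)
from .model import (
    HELDOUT_TIMEPOINT,
    TRAIN_TIMEPOINTS,
    Dataset,
    ModelConfig,
    build_model,
    evaluate_heldout,
    load_checkpoint,
    save_checkpoint,
    train,
)
from .preprocess import cap_to_top_variance, make_model_input, make_protein_labels
from .synthetic import GeneratorConfig, generate

STAGES = ("simulate", "preprocess", "train", "evaluate", "influence", "dpa")

FILES = {
    "counts": "counts.tsv",
    "proteins": "proteins.tsv",
    "samples": "samples.tsv",
    "tfs": "tfs.txt",
    "truth": "truth.json",
    "checkpoint": "model.ckpt",
    "metrics": "training_metrics.tsv",
    "evaluation": "evaluation.json",
    "influence_matrix": "influence_matrix.tsv",
    "report": "influencers.tsv",
    "dpa": "dpa_{label}.tsv",
    "volcano": "volcano_{label}.tsv",
    "manifest": "manifest.json",
}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    tau: float = 0.6
    k: int = 25
    alpha: float = 0.05
    influence_method: str = "saliency"
    #: optional externally supplied inputs; when unset the simulate stage
    #: provides them
    counts_path: str | None = None
    proteins_path: str | None = None
    samples_path: str | None = None
    tfs_path: str | None = None
    significance_path: str | None = None
    significance_label: str = "none"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        gen = GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("generator", {}).items()
        })
        model = ModelConfig(**raw.pop("model", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(generator=gen, model=model, **raw)
        # one global seed drives every stochastic stage unless overridden
        cfg.generator = dataclasses.replace(cfg.generator, seed=cfg.generator.seed or cfg.seed)
        cfg.model = dataclasses.replace(cfg.model, seed=cfg.model.seed or cfg.seed,
                                        tau=cfg.tau)
        return cfg

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Stateful driver executing stages into one output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "config": config.resolved(),
            "stages": {},
            "inputs": {},
        }

    def path(self, key: str, **fmt) -> Path:
        return self.outdir / FILES[key].format(**fmt)

    def _record(self, stage: str, started: float, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "seconds": round(time.time() - started, 3),
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }

    # -- individual stages -------------------------------------------------

    def simulate(self) -> None:
        t0 = time.time()
        data = generate(self.config.generator)
        outs = [self.path(k) for k in ("counts", "proteins", "samples", "tfs", "truth")]
        _atomic_write(outs[0], lambda p: write_matrix(data.counts, p))
        _atomic_write(outs[1], lambda p: write_matrix(data.proteins, p))
        _atomic_write(outs[2], lambda p: write_sample_sheet(data.sheet, p))
        _atomic_write(outs[3], lambda p: write_tf_list(data.tfs, p))
        _atomic_write(outs[4], lambda p: data.truth.to_json(p))
        self._record("simulate", t0, outs)

    def _input(self, key: str, override: str | None):
        path = Path(override) if override else self.path(key)
        if not path.exists():
            raise DomainError(
                f"stage input {path} is missing; run the providing stage first"
            )
        self.manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        return path

    def _load_inputs(self):
        counts = read_matrix(self._input("counts", self.config.counts_path), "transcript")
        proteins = read_matrix(self._input("proteins", self.config.proteins_path), "protein")
        sheet = read_sample_sheet(self._input("samples", self.config.samples_path))
        tfs = read_tf_list(self._input("tfs", self.config.tfs_path))
        return counts, proteins, sheet, tfs

    def _datasets(self):
        counts, proteins, sheet, tfs = self._load_inputs()
        tensor = make_model_input(counts, tfs)
        if self.config.model.top_variance_genes:
            tensor = cap_to_top_variance(tensor, self.config.model.top_variance_genes)
        labels = make_protein_labels(proteins, tau=self.config.tau)
        timepoints = sheet.timepoints_for(tensor.sample_ids)
        full = Dataset(tensor, labels, timepoints)
        train_idx = [i for i, t in enumerate(timepoints) if t in TRAIN_TIMEPOINTS]
        held_idx = [i for i, t in enumerate(timepoints) if t == HELDOUT_TIMEPOINT]
        return full, np.array(train_idx), np.array(held_idx), tfs

    def preprocess(self) -> None:
        t0 = time.time()
        full, _, _, _ = self._datasets()
        expr_path = self.outdir / "expression_normalized.tsv"
        label_path = self.outdir / "protein_labels.tsv"
        import pandas as pd

        _atomic_write(expr_path, lambda p: pd.DataFrame(
            full.tensor.expression, index=full.tensor.gene_ids,
            columns=full.tensor.sample_ids,
        ).to_csv(p, sep="\t", index_label="gene_id"))
        _atomic_write(label_path, lambda p: pd.DataFrame(
            full.labels.labels, index=full.labels.protein_ids,
            columns=full.labels.sample_ids,
        ).to_csv(p, sep="\t", index_label="protein_id"))
        self._record("preprocess", t0, [expr_path, label_path])

    def train(self) -> None:
        t0 = time.time()
        full, train_idx, _, _ = self._datasets()
        if train_idx.size == 0:
            raise DomainError("no training-timepoint samples present")
        dataset = full.subset(train_idx)
        mc = self.config.model
        model = build_model(mc, dataset.tensor.gene_ids, dataset.labels.protein_ids,
                            dataset.tensor.tf_flag)
        model = train(model, dataset)
        ckpt = self.path("checkpoint")
        _atomic_write(ckpt, lambda p: save_checkpoint(model, p))
        metrics = self.path("metrics")
        import pandas as pd

        _atomic_write(metrics, lambda p: pd.DataFrame(model.history).to_csv(p, sep="\t", index=False))
        self._record("train", t0, [ckpt, metrics])

    def evaluate(self) -> None:
        t0 = time.time()
        ckpt = self.path("checkpoint")
        if not ckpt.exists():
            raise DomainError("evaluate requires a trained checkpoint; run train first")
        model = load_checkpoint(ckpt)
        full, _, held_idx, _ = self._datasets()
        if held_idx.size == 0:
            raise DomainError(f"no {HELDOUT_TIMEPOINT} samples to evaluate on")
        report = evaluate_heldout(model, full.subset(held_idx))
        out = self.path("evaluation")
        payload = {
            "split": report.split_description,
            "micro": report.micro,
            "macro": report.macro,
            "confusion": report.confusion,
            "per_protein": report.per_protein,
        }
        _atomic_write(out, lambda p: p.write_text(json.dumps(payload, indent=2)))
        self._record("evaluate", t0, [out])

    def influence(self) -> None:
        t0 = time.time()
        ckpt = self.path("checkpoint")
        if not ckpt.exists():
            raise DomainError("influence requires a trained checkpoint; run train first")
        model = load_checkpoint(ckpt)
        full, train_idx, _, tfs = self._datasets()
        infl = extract_influence(model, full.subset(train_idx).tensor,
                                 method=self.config.influence_method)
        mat_path = self.path("influence_matrix")
        _atomic_write(mat_path, lambda p: infl.to_frame().to_csv(p, sep="\t", index_label="gene_id"))
        report = topk_influencers(restrict_to_tfs(infl, tfs), k=self.config.k)
        if self.config.significance_path:
            lists = read_significance_lists(self.config.significance_path,
                                            self.config.significance_label)
            report = intersect_significant(report, lists)
        rep_path = self.path("report")
        _atomic_write(rep_path, lambda p: write_influencer_report(report, p))
        self._record("influence", t0, [mat_path, rep_path])

    def dpa(self) -> None:
        t0 = time.time()
        _, proteins, sheet, _ = self._load_inputs()
        expanded = expand_gaussian(proteins, SdSpec())
        outs = []
        baseline = "estrus"
        for tp in (t for t in set(sheet.table["timepoint"]) if t != baseline):
            group_a = sheet.samples_at([tp])
            group_b = sheet.samples_at([baseline])
            if not group_a or not group_b:
                continue
            table = dpa_test(expanded, group_a, group_b, tail="two")
            label = f"{tp}_vs_{baseline}"
            sig = significant_proteins(table, self.config.alpha)
            table.attrs["n_significant"] = len(sig)
            dpa_path = self.path("dpa", label=label)
            vol_path = self.path("volcano", label=label)
            _atomic_write(dpa_path, lambda p, t=table: t.to_csv(p, sep="\t", index=False))
            _atomic_write(vol_path, lambda p, t=table: volcano_table(t).to_csv(p, sep="\t", index=False))
            outs += [dpa_path, vol_path]
        self._record("dpa", t0, outs)

    # -- composite ---------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        for stage in STAGES:  # canonical order regardless of listing order
            if stage in stages:
                getattr(self, stage)()
        manifest_path = self.path("manifest")
        _atomic_write(manifest_path, lambda p: p.write_text(json.dumps(self.manifest, indent=2)))
        return self.manifest


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    return PipelineRun(config).run(stages)
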