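"""Normalization chain turning raw tables into model-ready tensors.

Genes: drop never-observed rows, scale each library to counts-per-million,
then map each sample's CPM values to within-sample percentile ranks so every
model input lies in [0, 1].  Proteins: log-min-max within each sample, then
binarize at a threshold tau into high/low abundance labels — the targets the
classifier is trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import DomainError
from .io import OmicsMatrix, TFAnnotation

#: Labeling thresholds exposed as named presets.
TAU_PRESETS = (0.6, 0.8)


@dataclass
class ModelInputTensor:
    """Per-sample gene token values: normalized expression plus a TF flag.

    ``expression`` is genes x samples with every entry in [0, 1];
    ``tf_flag[g]`` is 1 iff gene g is an annotated transcription factor.
    Gene order is canonical and identical across samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    expression: np.ndarray  # (n_genes, n_samples) in [0, 1]
    tf_flag: np.ndarray  # (n_genes,) binary

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.tf_flag = np.asarray(self.tf_flag, dtype=float)
        if self.expression.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DomainError("expression shape does not match ids")
        if self.expression.size and (self.expression.min() < 0 or self.expression.max() > 1):
            raise DomainError("expression values must lie in [0, 1]")
        if not np.all(np.isin(self.tf_flag, (0.0, 1.0))):
            raise DomainError("tf_flag must be binary")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ProteinLabelMatrix:
    """Binary high/low abundance labels at threshold tau.

    ``labels[p, s] = 1`` iff the normalized abundance of protein p in sample s
    is >= tau (inclusive boundary).
    """

    protein_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray  # (n_proteins, n_samples) binary
    tau: float
    normalized_values: np.ndarray  # (n_proteins, n_samples) in [0, 1]

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


def filter_unobserved(matrix: OmicsMatrix) -> OmicsMatrix:
    """Remove features with no recorded signal in any sample (all-zero rows)."""
    keep = (matrix.values > 0).any(axis=1)
    if not keep.any():
        raise DomainError("every feature is unobserved; nothing left to model")
    if keep.all():
        return matrix
    return matrix.select_features(keep)


def cpm_normalize(counts: OmicsMatrix) -> OmicsMatrix:
    """Counts-per-million: value[g, s] = count[g, s] / libsize[s] * 1e6."""
    if counts.modality != "transcript":
        raise DomainError("CPM normalization applies to transcript counts")
    libsize = counts.values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = [counts.sample_ids[i] for i in zero]
        raise DomainError(f"zero library size for sample(s) {names}")
    values = counts.values / libsize * 1e6
    return OmicsMatrix(list(counts.feature_ids), list(counts.sample_ids), values, "transcript")


def percentile_normalize(values: np.ndarray) -> np.ndarray:
    """Within-sample percentile ranks p = (rank - 1) / (n - 1), in [0, 1].

    Ties get the average rank; a length-1 or all-tied vector maps to 0.5.
    Applied column-wise when given a 2-D (features x samples) array.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("cannot percentile-normalize an empty vector")
    if not np.all(np.isfinite(values)):
        raise DomainError("non-finite values in percentile normalization")
    if values.ndim == 2:
        return np.column_stack([percentile_normalize(values[:, j]) for j in range(values.shape[1])])
    n = values.shape[0]
    if n == 1 or np.all(values == values[0]):
        return np.full(n, 0.5)
    ranks = rankdata(values, method="average")
    return (ranks - 1.0) / (n - 1.0)


def log_minmax_normalize(
    abundance: OmicsMatrix, *, eps: float = 1.0, base: float | None = None
) -> OmicsMatrix:
    """Per-sample log then min-max: y = log(x + eps); (y - min) / (max - min).

    Natural log by default; ``base`` selects another base (the min-max output
    is base-invariant).  A constant column maps to all 0.5 by convention.
    """
    if abundance.modality != "protein":
        raise DomainError("log-min-max normalization applies to protein abundances")
    if eps < 0:
        raise DomainError("pseudocount eps must be >= 0")
    y = np.log(abundance.values + eps)
    if base is not None:
        y = y / np.log(base)
    lo = y.min(axis=0)
    hi = y.max(axis=0)
    span = hi - lo
    out = np.empty_like(y)
    const = span == 0
    out[:, const] = 0.5
    if (~const).any():
        out[:, ~const] = (y[:, ~const] - lo[~const]) / span[~const]
    return OmicsMatrix(list(abundance.feature_ids), list(abundance.sample_ids), out, "protein")


def label_abundance(normalized: OmicsMatrix, tau: float = 0.6) -> ProteinLabelMatrix:
    """Binarize normalized abundances: high (1) iff value >= tau."""
    if not 0.0 < tau < 1.0:
        raise DomainError(f"tau must lie in (0, 1); got {tau}")
    if tau not in TAU_PRESETS:
        warnings.warn(
            f"tau={tau} is outside the standard presets {TAU_PRESETS}", stacklevel=2
        )
    vals = normalized.values
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise DomainError("label_abundance expects values already normalized to [0, 1]")
    labels = (vals >= tau).astype(float)
    return ProteinLabelMatrix(
        protein_ids=list(normalized.feature_ids),
        sample_ids=list(normalized.sample_ids),
        labels=labels,
        tau=tau,
        normalized_values=vals.copy(),
    )


def make_model_input(counts: OmicsMatrix, tfs: TFAnnotation) -> ModelInputTensor:
    """Full gene-side chain: filter -> CPM -> within-sample percentile + TF flag."""
    filtered = filter_unobserved(counts)
    cpm = cpm_normalize(filtered)
    expr = percentile_normalize(cpm.values)
    tf_flag = np.array([1.0 if g in tfs else 0.0 for g in cpm.feature_ids])
    return ModelInputTensor(list(cpm.feature_ids), list(cpm.sample_ids), expr, tf_flag)


def cap_to_top_variance(tensor: ModelInputTensor, n_genes: int) -> ModelInputTensor:
    """Keep the ``n_genes`` highest-variance genes (canonical order preserved).

    A desk-scale cap on the token sequence length; 0 or a cap at or above the
    gene count returns the tensor unchanged.  Ties resolve to the earlier gene
    in the canonical order.
    """
    if n_genes < 0:
        raise DomainError("gene cap must be >= 0")
    if n_genes == 0 or n_genes >= tensor.n_genes:
        return tensor
    var = tensor.expression.var(axis=1)
    keep = np.sort(np.argsort(-var, kind="stable")[:n_genes])
    return ModelInputTensor(
        [tensor.gene_ids[i] for i in keep], list(tensor.sample_ids),
        tensor.expression[keep], tensor.tf_flag[keep],
    )


def make_protein_labels(
    abundance: OmicsMatrix, *, tau: float = 0.6, eps: float = 1.0, base: float | None = None
) -> ProteinLabelMatrix:
    """Full protein-side chain: filter -> per-sample log-min-max -> threshold."""
    filtered = filter_unobserved(abundance)
    normed = log_minmax_normalize(filtered, eps=eps, base=base)
    return label_abundance(normed, tau=tau)


@dataclass
class AugmentedDataset:
    """Original plus resampled-and-jittered samples with copied labels."""

    tensor: ModelInputTensor
    labels: ProteinLabelMatrix
    source_sample: list[str]  # for each sample, the original it derives from


def augment(
    tensor: ModelInputTensor,
    labels: ProteinLabelMatrix,
    n_aug: int,
    seed: int,
    *,
    jitter_sd: float = 0.01,
) -> AugmentedDataset:
    """Append ``n_aug`` synthetic samples, each a uniformly resampled original
    with i.i.d. Gaussian jitter on its expression vector, clipped to [0, 1];
    labels are copied unchanged from the source sample."""
    if n_aug < 0:
        raise DomainError("n_aug must be >= 0")
    if tensor.sample_ids != labels.sample_ids:
        raise DomainError("expression and label sample ids differ")
    rng = np.random.default_rng(seed)
    n = tensor.n_samples
    expr_cols = [tensor.expression]
    label_cols = [labels.labels]
    norm_cols = [labels.normalized_values]
    new_ids = list(tensor.sample_ids)
    sources = list(tensor.sample_ids)
    picks = rng.integers(0, n, size=n_aug)
    for i, src in enumerate(picks):
        jit = rng.normal(0.0, jitter_sd, size=tensor.n_genes) if jitter_sd > 0 else 0.0
        col = np.clip(tensor.expression[:, src] + jit, 0.0, 1.0)
        expr_cols.append(col[:, None])
        label_cols.append(labels.labels[:, src][:, None])
        norm_cols.append(labels.normalized_values[:, src][:, None])
        new_ids.append(f"{tensor.sample_ids[src]}_aug{i}")
        sources.append(tensor.sample_ids[src])
    aug_tensor = ModelInputTensor(
        list(tensor.gene_ids), new_ids, np.hstack(expr_cols), tensor.tf_flag.copy()
    )
    aug_labels = ProteinLabelMatrix(
        list(labels.protein_ids), new_ids, np.hstack(label_cols), labels.tau, np.hstack(norm_cols)
    )
    return AugmentedDataset(aug_tensor, aug_labels, sources)
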