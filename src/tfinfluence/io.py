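"""Core data containers and tabular I/O.

The pipeline moves three kinds of tables around: feature-by-sample numeric
matrices (gene counts or protein abundances), a sample sheet mapping each
sample to its mating timepoint and oviduct region, and small id lists
(transcription factors, significance calls).  Everything is plain TSV/CSV so
that inputs can come from any upstream quantification tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError

#: The four estrous/pregnancy stages profiled in the study design this
#: package targets: estrus plus 0.5, 1.5 and 2.5 days post-coitus.
TIMEPOINTS = ("estrus", "dpc0.5", "dpc1.5", "dpc2.5")

#: Oviduct regions: infundibulum+ampulla (distal) and isthmus+UTJ (proximal).
REGIONS = ("IA", "IU")

MODALITIES = ("transcript", "protein")


@dataclass
class OmicsMatrix:
    """A features x samples numeric matrix with a declared modality.

    Values are raw, nonnegative measurements: read counts for
    ``modality="transcript"``, abundance intensities for ``modality="protein"``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise DomainError(f"unknown modality {self.modality!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.feature_ids)}, {len(self.sample_ids)}) ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError("matrix contains non-finite values")
        if np.any(self.values < 0):
            raise DomainError("matrix contains negative values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def select_features(self, keep: np.ndarray) -> "OmicsMatrix":
        ids = [f for f, k in zip(self.feature_ids, keep) if k]
        return OmicsMatrix(ids, list(self.sample_ids), self.values[np.asarray(keep, bool)], self.modality)

    def select_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        sample_ids = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DomainError(f"unknown sample ids: {missing}")
        cols = [idx[s] for s in sample_ids]
        return OmicsMatrix(list(self.feature_ids), sample_ids, self.values[:, cols], self.modality)


@dataclass
class SampleSheet:
    """Per-sample metadata: timepoint and oviduct region."""

    table: pd.DataFrame  # columns: sample_id, timepoint, region

    def __post_init__(self) -> None:
        required = {"sample_id", "timepoint", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in sample sheet: {dup}")
        bad_tp = set(self.table["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DomainError(f"unknown timepoints {sorted(bad_tp)}; expected one of {TIMEPOINTS}")
        bad_rg = set(self.table["region"]) - set(REGIONS)
        if bad_rg:
            raise DomainError(f"unknown regions {sorted(bad_rg)}; expected one of {REGIONS}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def timepoint_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise DomainError(f"sample {sample_id!r} not in sample sheet")
        return row["timepoint"].iloc[0]

    def timepoints_for(self, sample_ids: Iterable[str]) -> list[str]:
        lut = dict(zip(self.table["sample_id"], self.table["timepoint"]))
        try:
            return [lut[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - message clarity
            raise DomainError(f"sample {exc.args[0]!r} not in sample sheet") from None

    def samples_at(self, timepoints: Iterable[str]) -> list[str]:
        tps = set(timepoints)
        return self.table.loc[self.table["timepoint"].isin(tps), "sample_id"].tolist()


@dataclass
class TFAnnotation:
    """The set of gene ids annotated as transcription factors."""

    tf_ids: set[str] = field(default_factory=set)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.tf_ids

    def __len__(self) -> int:
        return len(self.tf_ids)


@dataclass
class SignificanceLists:
    """Significant genes/proteins for one comparison (e.g. dpc0.5 vs estrus).

    These are consumed as external inputs, typically the output of a
    differential-expression tool on the gene side and a differential-abundance
    tool on the protein side.
    """

    comparison_label: str
    sig_genes: set[str] = field(default_factory=set)
    sig_proteins: set[str] = field(default_factory=set)


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(path: str | Path, modality: str) -> OmicsMatrix:
    """Read a delimited features x samples table (first column = feature id).

    Tab or comma delimiters are auto-detected from the header line.  Feature
    and sample id matching downstream is exact, case-sensitive string match.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate feature ids: {dup[:5]}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise FormatError(f"{path}: non-numeric values in columns {list(non_numeric)[:5]}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values are not supported")
    if (df.values < 0).any():
        raise DomainError(f"{path}: negative values are not valid {modality} measurements")
    return OmicsMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.values.astype(float),
        modality=modality,
    )


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_tf_list(path: str | Path) -> TFAnnotation:
    """Read a plain-text TF list, one gene id per line; trimmed, deduplicated."""
    ids = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.strip()
        if token:
            ids.add(token)
    if not ids:
        warnings.warn(f"{path}: transcription-factor list is empty", stacklevel=2)
    return TFAnnotation(ids)


def write_tf_list(tfs: TFAnnotation, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tfs.tf_ids)) + "\n", encoding="utf-8")


def read_significance_lists(path: str | Path, comparison_label: str) -> SignificanceLists:
    """Read a two-column table (id, set) with set in {gene, protein}."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    missing = {"id", "set"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["set"]) - {"gene", "protein"}
    if bad:
        raise DomainError(f"{path}: unknown set labels {sorted(bad)}")
    return SignificanceLists(
        comparison_label=comparison_label,
        sig_genes=set(df.loc[df["set"] == "gene", "id"]),
        sig_proteins=set(df.loc[df["set"] == "protein", "id"]),
    )


def write_significance_lists(lists: SignificanceLists, path: str | Path) -> None:
    rows = [{"id": g, "set": "gene"} for g in sorted(lists.sig_genes)]
    rows += [{"id": p, "set": "protein"} for p in sorted(lists.sig_proteins)]
    pd.DataFrame(rows, columns=["id", "set"]).to_csv(path, sep="\t", index=False)
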