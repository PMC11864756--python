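"""Differential protein abundance via Gaussian-replicate expansion.

Pooled proteomic samples carry one measurement per protein per condition, so
no within-group variance exists for a t-test.  The procedure implemented here
treats each measurement x as the mean of a Gaussian and materializes the
+/- 1 SD values around it, turning x into the triplet {x - s, x, x + s}
whose sample mean is exactly x and whose sample standard deviation is
exactly s.  Two-sample Student t-tests between condition groups then run on
the expanded columns, with Benjamini-Hochberg control of the false discovery
rate.

Statistical caveat, stated plainly: the artificial triplet values are not
independent replicates, so p-values from this construction are anticonservative
relative to true biological replication.  The module reproduces the procedure
and exposes its null behavior for measurement (see ``tfinfluence.synthetic.
null_proteome``); it does not claim the resulting tests are calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, DomainError
from .io import OmicsMatrix

TAILS = ("two", "one_greater", "one_less")


@dataclass
class SdSpec:
    """How the expansion SD ``s`` is resolved per protein.

    ``per_protein_sd`` (default): sample SD of that protein's empirical values
    across the samples being expanded.  ``global_sd``: one SD pooled over the
    whole matrix.  ``cv``: s = cv_fraction * x per measurement... resolved per
    protein as cv_fraction * mean(x).  ``user``: caller-supplied per-protein s.
    """

    method: str = "per_protein_sd"
    cv_fraction: float = 0.1
    user_s: dict[str, float] | None = None

    def resolve(self, matrix: OmicsMatrix) -> np.ndarray:
        if self.method == "per_protein_sd":
            if matrix.n_samples < 2:
                raise DomainError("per_protein_sd needs >= 2 samples")
            s = matrix.values.std(axis=1, ddof=1)
        elif self.method == "global_sd":
            s = np.full(matrix.n_features, matrix.values.std(ddof=1))
        elif self.method == "cv":
            s = self.cv_fraction * matrix.values.mean(axis=1)
        elif self.method == "user":
            if self.user_s is None:
                raise ConfigError("user SD spec requires user_s")
            try:
                s = np.array([self.user_s[p] for p in matrix.feature_ids], float)
            except KeyError as exc:
                raise DomainError(f"no SD supplied for protein {exc.args[0]!r}") from None
        else:
            raise ConfigError(f"unknown SD method {self.method!r}")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise DomainError("resolved SD must be finite and >= 0")
        return s


@dataclass
class GaussianExpandedMatrix:
    """Each original column split into _lo/_mid/_hi triplet columns."""

    protein_ids: list[str]
    sample_ids: list[str]  # expanded: 3 per original sample
    values: np.ndarray
    original_sample_ids: list[str]
    s: np.ndarray  # per-protein expansion SD
    sd_source: str

    def columns_for(self, original_ids: Iterable[str]) -> list[int]:
        wanted = set(original_ids)
        return [
            i for i, sid in enumerate(self.sample_ids)
            if sid.rsplit("_", 1)[0] in wanted
        ]


def expand_gaussian(abundance: OmicsMatrix, sd_spec: SdSpec | None = None) -> GaussianExpandedMatrix:
    """Expand every measurement x into {x - s, x, x + s} with per-protein s."""
    if abundance.modality != "protein":
        raise DomainError("Gaussian expansion applies to protein abundances")
    sd_spec = sd_spec or SdSpec()
    s = sd_spec.resolve(abundance)
    n_p, n_s = abundance.values.shape
    expanded = np.empty((n_p, 3 * n_s))
    ids = []
    for j, sid in enumerate(abundance.sample_ids):
        x = abundance.values[:, j]
        expanded[:, 3 * j] = x - s
        expanded[:, 3 * j + 1] = x
        expanded[:, 3 * j + 2] = x + s
        ids.extend([f"{sid}_lo", f"{sid}_mid", f"{sid}_hi"])
    return GaussianExpandedMatrix(
        protein_ids=list(abundance.feature_ids),
        sample_ids=ids,
        values=expanded,
        original_sample_ids=list(abundance.sample_ids),
        s=s,
        sd_source=sd_spec.method,
    )


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t statistic and degrees of freedom."""
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return (a.mean() - b.mean()) / se, float(df)


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, float(df)


def dpa_test(
    expanded: GaussianExpandedMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    tail: str = "two",
    *,
    welch: bool = False,
    log2fc_eps: float = 1.0,
) -> pd.DataFrame:
    """Per-protein t-test (group A vs group B) on the expanded values.

    ``tail='one_greater'`` tests A > B, ``'one_less'`` tests A < B.  Proteins
    with zero pooled variance are flagged ``testable=False`` with NaN
    statistics — never reported significant.  Fold changes come from the
    empirical (un-expanded, ``_mid``) means with a pseudocount.
    """
    if tail not in TAILS:
        raise DomainError(f"tail must be one of {TAILS}")
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise DomainError(f"groups overlap on samples {sorted(overlap)}")
    cols_a = expanded.columns_for(group_a)
    cols_b = expanded.columns_for(group_b)
    if not cols_a or not cols_b:
        raise DomainError("both groups must match at least one expanded sample")
    mid_a = [i for i in cols_a if expanded.sample_ids[i].endswith("_mid")]
    mid_b = [i for i in cols_b if expanded.sample_ids[i].endswith("_mid")]

    rows = []
    for i, pid in enumerate(expanded.protein_ids):
        a = expanded.values[i, cols_a]
        b = expanded.values[i, cols_b]
        emp_a = expanded.values[i, mid_a].mean()
        emp_b = expanded.values[i, mid_b].mean()
        log2fc = np.log2((emp_a + log2fc_eps) / (emp_b + log2fc_eps))
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            rows.append((pid, emp_a, emp_b, log2fc, np.nan, np.nan, np.nan, False))
            continue
        t, df = _welch_t(a, b) if welch else _student_t(a, b)
        if tail == "two":
            p = 2.0 * stats.t.sf(abs(t), df)
        elif tail == "one_greater":
            p = stats.t.sf(t, df)
        else:
            p = stats.t.cdf(t, df)
        rows.append((pid, emp_a, emp_b, log2fc, t, df, p, True))
    table = pd.DataFrame(
        rows, columns=["protein_id", "mean_a", "mean_b", "log2fc", "t", "df", "p", "testable"]
    )
    table.attrs["tail"] = tail
    table.attrs["sd_source"] = expanded.sd_source
    tested = table["testable"]
    q = np.full(len(table), np.nan)
    if tested.any():
        q[tested.values] = adjust_fdr(table.loc[tested, "p"].values)
    table["q"] = q
    return table


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    if p.size and (p.min() < 0 or p.max() > 1 or not np.all(np.isfinite(p))):
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def significant_proteins(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Proteins with q strictly below alpha (FDR < alpha)."""
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    mask = table["testable"] & (table["q"] < alpha)
    return table.loc[mask, "protein_id"].tolist()


def volcano_table(table: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change against -log10 p, ready for plotting."""
    out = table.loc[table["testable"], ["protein_id", "log2fc", "p", "q"]].copy()
    out["neg_log10_p"] = -np.log10(np.maximum(out.pop("p"), 1e-300))
    return out
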