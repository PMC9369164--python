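"""Validation of a predicted association matrix against a reference.

The predicted co-citation matrix is compared with an independently
derived comorbidity/association matrix (e.g. one based on genetic
evidence) by correlating the matched off-diagonal values. The diagonal is
excluded: self-association is a convention, not an observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationMatrix


class InsufficientOverlapError(ValueError):
    """Fewer than 3 shared labels after alias resolution."""


class UndefinedCorrelationError(ValueError):
    """A correlation was requested on a zero-variance vector."""


@dataclass
class ReferenceMatrix:
    """A square labeled matrix of externally reported association values."""

    labels: list[str]
    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("reference matrix is not square over its labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference matrix contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("reference matrix contains negative values")


def read_reference(path: str | Path, sep: str = "\t", source: str = "") -> ReferenceMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ReferenceMatrix(
        labels=[str(l) for l in df.index],
        values=df.to_numpy(dtype=float),
        source=source or str(path),
    )


@dataclass
class AlignedVectors:
    """Matched off-diagonal value vectors over the shared label set."""

    labels: list[str]
    pairs: list[tuple[str, str]]
    pred: np.ndarray
    ref: np.ndarray
    unmatched_pred: list[str]
    unmatched_ref: list[str]


def align_matrices(
    pred: AssociationMatrix,
    ref: ReferenceMatrix,
    aliases: Mapping[str, str] | None = None,
) -> AlignedVectors:
    """Extract identically ordered upper-triangle vectors from both
    matrices over the shared label set.

    ``aliases`` maps reference labels onto predicted-matrix ids (e.g.
    "SLE" -> "systemic lupus erythematosus"). Shared labels are taken in
    the predicted matrix's order, so the result does not depend on how the
    reference file happens to be sorted.
    """
    aliases = dict(aliases or {})
    ref_to_pred = {r: aliases.get(r, r) for r in ref.labels}
    pred_ids = set(pred.labels)
    shared = [p for p in pred.labels if p in {v for v in ref_to_pred.values()}]
    shared = [p for p in shared if p in pred_ids]
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared label(s) after alias resolution"
        )
    pred_to_ref = {v: k for k, v in ref_to_pred.items() if v in set(shared)}

    pred_vec, ref_vec, pairs = [], [], []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            a, b = shared[i], shared[j]
            pred_vec.append(pred.value(a, b))
            ia = ref.labels.index(pred_to_ref[a])
            ib = ref.labels.index(pred_to_ref[b])
            ref_vec.append(float(ref.values[ia, ib]))
            pairs.append((a, b))
    return AlignedVectors(
        labels=shared,
        pairs=pairs,
        pred=np.asarray(pred_vec),
        ref=np.asarray(ref_vec),
        unmatched_pred=[p for p in pred.labels if p not in set(shared)],
        unmatched_ref=[r for r in ref.labels if ref_to_pred[r] not in set(shared)],
    )


def matrix_correlation(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Correlation between two matched value vectors (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    if np.array_equal(x, y):
        # identical vectors correlate at exactly 1; avoid rounding to 1-eps
        return 1.0
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ValidationReport:
    """Correlation-based agreement between prediction and reference."""

    r: float
    n_pairs: int
    method: str
    labels: list[str]
    table: pd.DataFrame = field(repr=False)
    reference_source: str = ""

    def summary(self) -> dict:
        return {
            "r": self.r,
            "n_pairs": self.n_pairs,
            "method": self.method,
            "labels": self.labels,
            "reference_source": self.reference_source,
        }

    def write(self, pairs_path: str | Path, summary_path: str | Path | None = None):
        self.table.to_csv(pairs_path, sep="\t", index=False)
        if summary_path is not None:
            Path(summary_path).write_text(json.dumps(self.summary(), indent=2))


def validate(
    pred: AssociationMatrix,
    ref: ReferenceMatrix,
    aliases: Mapping[str, str] | None = None,
    method: str = "pearson",
) -> ValidationReport:
    """Align the matrices and correlate their off-diagonal values."""
    aligned = align_matrices(pred, ref, aliases)
    r = matrix_correlation(aligned.pred, aligned.ref, method)
    table = pd.DataFrame({
        "term_a": [a for a, _ in aligned.pairs],
        "term_b": [b for _, b in aligned.pairs],
        "predicted": aligned.pred,
        "reference": aligned.ref,
    })
    return ValidationReport(
        r=r,
        n_pairs=len(aligned.pairs),
        method=method,
        labels=aligned.labels,
        table=table,
        reference_source=ref.source,
    )
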