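"""The normalized co-citation association statistic and its matrix.

The association between two diseases is the Jaccard index over their
PubMed document sets,

    association = count(A AND B) / count(A OR B),

which counters the citation-volume bias of the raw co-citation count:
dividing by the union shrinks the association of heavily cited diseases
and lifts that of rarely cited ones. Multiplied by 100 the value reads as
an approximate percent comorbidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .counts import (
    CountBackend,
    CountCache,
    CountsResult,
    DiseaseTerm,
    IncompleteInputError,
    InconsistentCountsError,
    PairCounts,
    FIELDS_TIAB_OT,
    fetch_all_pairs,
    pair_key,
)

MASK_KEPT = "kept"
MASK_FLOORED = "floored"

#: Association values below this are treated as noise and floored to zero.
DEFAULT_ASSOCIATION_FLOOR = 1e-5
#: Diseases with fewer singleton citations than this are dropped as
#: indistinct / under-studied.
DEFAULT_MIN_CITATIONS = 100


def association_value(counts: PairCounts) -> float:
    """Jaccard association ``n_and / n_or`` for one pair; 0 when both
    diseases have no literature at all."""
    if counts.n_and > counts.n_or:
        raise InconsistentCountsError(
            f"n_and={counts.n_and} > n_or={counts.n_or} for "
            f"({counts.term_a}, {counts.term_b})"
        )
    if counts.n_or == 0:
        return 0.0
    return counts.n_and / counts.n_or


def to_percent_comorbidity(assoc: float) -> float:
    """Association value on the approximate percent-comorbidity scale."""
    if not 0.0 <= assoc <= 1.0:
        raise ValueError(f"association value {assoc} outside [0, 1]")
    return assoc * 100.0


@dataclass
class AssociationMatrix:
    """Symmetric labeled matrix of pairwise association values.

    The diagonal is 1 by convention (a disease trivially co-cites itself)
    and is ignored by clustering and validation. ``mask`` records, per
    cell, whether the value was kept or floored by filtering.
    """

    labels: list[str]
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if self.mask is None:
            self.mask = np.full((n, n), MASK_KEPT, dtype="<U8")
        kept = self.values[self.mask == MASK_KEPT]
        if kept.size and (kept.min() < 0 or kept.max() > 1):
            raise ValueError("kept association values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, order: list[str]) -> "AssociationMatrix":
        if sorted(order) != sorted(self.labels):
            raise ValueError("order is not a permutation of the labels")
        idx = [self.index(l) for l in order]
        return AssociationMatrix(
            labels=list(order),
            values=self.values[np.ix_(idx, idx)],
            mask=self.mask[np.ix_(idx, idx)],
        )


@dataclass
class FilterPolicy:
    """Filtering rules applied before classification.

    Associations below ``association_floor`` are considered unrealistic
    noise and floored to zero; diseases below ``min_citations`` singleton
    citations, or explicitly listed in ``exclusion_ids``, are dropped.
    """

    association_floor: float = DEFAULT_ASSOCIATION_FLOOR
    min_citations: int = DEFAULT_MIN_CITATIONS
    exclusion_ids: frozenset = frozenset()
    reasons: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.association_floor < 0:
            raise ValueError("association_floor must be >= 0")
        if self.min_citations < 0:
            raise ValueError("min_citations must be >= 0")
        self.exclusion_ids = frozenset(self.exclusion_ids)


def build_matrix(pairs: Iterable[PairCounts], labels: list[str]) -> AssociationMatrix:
    """Assemble the symmetric association matrix from pair counts.

    Every unordered label pair must be covered; the diagonal is set to 1.
    """
    labels = list(labels)
    by_key = {pc.key: pc for pc in pairs}
    n = len(labels)
    values = np.eye(n)
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            key = pair_key(labels[i], labels[j])
            pc = by_key.get(key)
            if pc is None:
                missing.append(key)
                continue
            values[i, j] = values[j, i] = association_value(pc)
    if missing:
        raise IncompleteInputError(missing)
    return AssociationMatrix(labels=labels, values=values)


def matrix_from_backend(
    terms: Iterable[DiseaseTerm],
    backend: CountBackend,
    cache: CountCache | None = None,
    fields: str = FIELDS_TIAB_OT,
) -> tuple[AssociationMatrix, CountsResult]:
    """Fetch all counts from a backend and build the association matrix."""
    terms = list(terms)
    result = fetch_all_pairs(terms, backend, cache, fields)
    matrix = build_matrix(result.pairs, [t.id for t in terms])
    return matrix, result


def apply_filters(
    m: AssociationMatrix,
    policy: FilterPolicy,
    singletons: Mapping[str, int],
) -> tuple[AssociationMatrix, pd.DataFrame]:
    """Apply exclusion and flooring rules; return the new matrix + report.

    Rows/columns of excluded diseases (curated exclusions and those under
    the citation minimum) are removed; surviving cells under the floor are
    set to 0 (mask ``floored``) so the matrix shape stays stable for
    clustering. The report has one row per excluded disease and one per
    floored unordered pair, with columns (item, reason, value).
    """
    missing = [l for l in m.labels if l not in singletons]
    if missing:
        raise ValueError(f"no singleton count for labels {missing}")

    report_rows = []
    kept_labels = []
    for label in m.labels:
        if label in policy.exclusion_ids:
            reason = policy.reasons.get(label, "curated exclusion")
            report_rows.append((label, reason, float(singletons[label])))
        elif singletons[label] < policy.min_citations:
            report_rows.append(
                (label, f"fewer than {policy.min_citations} citations",
                 float(singletons[label]))
            )
        else:
            kept_labels.append(label)

    idx = [m.index(l) for l in kept_labels]
    values = m.values[np.ix_(idx, idx)].copy()
    mask = m.mask[np.ix_(idx, idx)].copy()

    k = len(kept_labels)
    for i in range(k):
        for j in range(i + 1, k):
            if mask[i, j] == MASK_KEPT and values[i, j] < policy.association_floor:
                report_rows.append(
                    (f"{kept_labels[i]}|{kept_labels[j]}", "below association floor",
                     float(values[i, j]))
                )
                values[i, j] = values[j, i] = 0.0
                mask[i, j] = mask[j, i] = MASK_FLOORED

    report = pd.DataFrame(report_rows, columns=["item", "reason", "value"])
    return AssociationMatrix(kept_labels, values, mask), report


# ---------------------------------------------------------------------------
# Matrix I/O: labeled square delimited table, first row/column = ids.

def write_matrix(m: AssociationMatrix, path: str | Path, sep: str = "\t"):
    """Write a labeled square matrix; floats use repr-exact precision so a
    write/read round trip is lossless."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join(["", *m.labels]) + "\n")
        for label, row in zip(m.labels, m.values):
            cells = [np.format_float_positional(v, trim="0", unique=True) for v in row]
            fh.write(sep.join([label, *cells]) + "\n")


def read_matrix(path: str | Path, sep: str = "\t") -> AssociationMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValueError(f"row and column labels differ in {path}")
    return AssociationMatrix(labels=labels, values=df.to_numpy(dtype=float))
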