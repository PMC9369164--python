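"""Simulated literature corpora with planted disease-community structure.

The generator emulates the count structure of a bibliographic corpus:
heavy-tailed per-disease citation totals (log-normal marginal mention
probabilities) and excess co-mention among diseases of the same affected
"system", induced by a per-document block topic — each document activates
one block and mentions that block's diseases with boosted probability.
Block-level gender skew is generated as metadata only (it shapes
annotations, not counts). Every corpus carries its ground-truth block
assignment, so cluster recovery and validation correlation can be scored
exactly, offline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .counts import DiseaseTerm, QueryParseError, Phrase, BoolOp, fold_diacritics, parse_query
from .validation import ReferenceMatrix


@dataclass
class SyntheticCorpusSpec:
    """Parameters of one simulated corpus.

    ``base_mention_prob`` may be given explicitly (one probability per
    disease); when None it is drawn log-normally with the given log-scale
    parameters, producing citation totals spanning orders of magnitude as
    real literatures do. Diseases are assigned to blocks round-robin
    unless ``block_assignment`` is supplied. Boosted probabilities are
    clipped to 1 with a warning.
    """

    n_diseases: int = 50
    n_blocks: int = 5
    n_documents: int = 20_000
    base_mention_prob: np.ndarray | None = None
    log_prob_mean: float = np.log(0.01)
    log_prob_sigma: float = 1.0
    within_block_boost: float = 10.0
    between_block_boost: float = 1.0
    #: probability that a document carries a block topic at all
    block_topic_prob: float = 1.0
    gender_skew: np.ndarray | None = None
    block_assignment: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks > self.n_diseases:
            raise ValueError("n_blocks exceeds n_diseases")
        if self.n_diseases < 1 or self.n_documents < 1:
            raise ValueError("n_diseases and n_documents must be positive")
        if self.between_block_boost > self.within_block_boost:
            raise ValueError("between_block_boost must be <= within_block_boost")
        if not 0.0 <= self.block_topic_prob <= 1.0:
            raise ValueError("block_topic_prob outside [0, 1]")
        if self.base_mention_prob is not None:
            p = np.asarray(self.base_mention_prob, dtype=float)
            if p.shape != (self.n_diseases,):
                raise ValueError("base_mention_prob length != n_diseases")
            if (p < 0).any() or (p > 1).any():
                raise ValueError("base_mention_prob outside [0, 1]")
            self.base_mention_prob = p
        if self.gender_skew is not None:
            g = np.asarray(self.gender_skew, dtype=float)
            if g.shape != (self.n_blocks,):
                raise ValueError("gender_skew length != n_blocks")
            if (g < 0).any() or (g > 1).any():
                raise ValueError("gender_skew outside [0, 1]")
            self.gender_skew = g

    @property
    def disease_ids(self) -> list[str]:
        width = len(str(self.n_diseases - 1))
        return [f"d{i:0{width}d}" for i in range(self.n_diseases)]

    def blocks(self) -> dict[str, int]:
        if self.block_assignment is not None:
            return dict(self.block_assignment)
        return {d: i % self.n_blocks for i, d in enumerate(self.disease_ids)}

    def to_json(self, path: str | Path):
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCorpusSpec":
        payload = json.loads(Path(path).read_text())
        for key in ("base_mention_prob", "gender_skew"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=float)
        if payload.get("block_assignment") is not None:
            payload["block_assignment"] = {
                k: int(v) for k, v in payload["block_assignment"].items()
            }
        return cls(**payload)


@dataclass
class SyntheticCorpus:
    """Simulated documents (per-document disease-mention sets) plus truth."""

    documents: list[frozenset[str]]
    truth: dict[str, int]
    spec: SyntheticCorpusSpec
    #: realized per-disease marginal probabilities (after any draw)
    base_prob: np.ndarray = field(repr=False, default=None)  # type: ignore

    def __post_init__(self):
        known = set(self.spec.disease_ids)
        for doc in self.documents:
            if not doc <= known:
                raise ValueError(f"document mentions unknown disease(s): {doc - known}")
        if len(self.documents) != self.spec.n_documents:
            raise ValueError("document count != n_documents")

    @property
    def disease_ids(self) -> list[str]:
        return self.spec.disease_ids

    def mention_matrix(self) -> np.ndarray:
        """Documents x diseases boolean occurrence matrix (cached)."""
        cached = getattr(self, "_mention_matrix", None)
        if cached is not None:
            return cached
        ids = {d: i for i, d in enumerate(self.disease_ids)}
        mat = np.zeros((len(self.documents), len(ids)), dtype=bool)
        for r, doc in enumerate(self.documents):
            for d in doc:
                mat[r, ids[d]] = True
        object.__setattr__(self, "_mention_matrix", mat)
        return mat

    def terms(self, gender_noise_sd: float = 0.05) -> list[DiseaseTerm]:
        """Disease terms with block-derived metadata for annotation.

        Gender fraction is the block skew plus small per-disease noise;
        system label is the block name. Deterministic given the spec seed.
        """
        rng = np.random.default_rng(self.spec.seed + 1)
        skew = self.spec.gender_skew
        if skew is None:
            skew = rng.uniform(0.15, 0.85, size=self.spec.n_blocks)
        out = []
        for d in self.disease_ids:
            b = self.truth[d]
            g = float(np.clip(skew[b] + rng.normal(0, gender_noise_sd), 0, 1))
            out.append(
                DiseaseTerm(
                    id=d,
                    name=d,
                    gender_female_fraction=g,
                    onset_age=float(rng.uniform(10, 70)),
                    prevalence=float(10 ** rng.uniform(-5, -2)),
                    system_label=f"block{b}",
                )
            )
        return out


def generate_corpus(spec: SyntheticCorpusSpec) -> SyntheticCorpus:
    """Draw one corpus from the block-topic document model.

    Per document: with probability ``block_topic_prob`` one block is
    activated uniformly at random; each disease is then mentioned
    independently with its base probability times the within-block boost
    (if its block is active) or the between-block boost (otherwise; also
    used when no block is active so equal boosts reduce exactly to
    independence). Bit-for-bit reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ids = spec.disease_ids
    blocks = spec.blocks()
    block_idx = np.array([blocks[d] for d in ids])

    if spec.base_mention_prob is not None:
        base = spec.base_mention_prob.copy()
    else:
        base = np.exp(rng.normal(spec.log_prob_mean, spec.log_prob_sigma, spec.n_diseases))
        base = np.clip(base, 0.0, 1.0)

    has_topic = rng.random(spec.n_documents) < spec.block_topic_prob
    active = rng.integers(0, spec.n_blocks, size=spec.n_documents)

    probs = np.tile(base * spec.between_block_boost, (spec.n_documents, 1))
    boosted_rows = has_topic[:, None] & (block_idx[None, :] == active[:, None])
    boosted = np.tile(base * spec.within_block_boost, (spec.n_documents, 1))
    probs = np.where(boosted_rows, boosted, probs)
    if (probs > 1.0).any():
        warnings.warn("boosted mention probabilities clipped to 1", stacklevel=2)
        np.clip(probs, 0.0, 1.0, out=probs)

    mentions = rng.random((spec.n_documents, spec.n_diseases)) < probs
    id_arr = np.asarray(ids, dtype=object)
    documents = [frozenset(id_arr[row]) for row in mentions]
    return SyntheticCorpus(documents=documents, truth=blocks, spec=spec, base_prob=base)


class SimulatedCorpusBackend:
    """Snapshot-consistent count backend over a synthetic corpus.

    ``count(query)`` parses the Boolean query and evaluates it against the
    per-document mention sets (vectorized over a boolean occurrence
    matrix). Phrases resolve to disease ids directly, or through the
    name/synonym table when ``terms`` is given; an unknown phrase simply
    matches no documents, like a term absent from the literature.
    """

    snapshot_consistent = True

    def __init__(self, corpus: SyntheticCorpus, terms: list[DiseaseTerm] | None = None):
        self.corpus = corpus
        self.backend_id = f"simulated-seed{corpus.spec.seed}"
        self._matrix = corpus.mention_matrix()
        self._col = {d: i for i, d in enumerate(corpus.disease_ids)}
        self._phrase_to_id: dict[str, str] = {}
        for d in corpus.disease_ids:
            self._phrase_to_id[self._norm(d)] = d
        for t in terms or ():
            for phrase in t.phrases:
                self._phrase_to_id[self._norm(phrase)] = t.id

    @staticmethod
    def _norm(phrase: str) -> str:
        return fold_diacritics(phrase).casefold()

    def _eval(self, node) -> np.ndarray:
        if isinstance(node, Phrase):
            disease = self._phrase_to_id.get(self._norm(node.text))
            if disease is None or disease not in self._col:
                return np.zeros(self._matrix.shape[0], dtype=bool)
            return self._matrix[:, self._col[disease]]
        if isinstance(node, BoolOp):
            parts = [self._eval(c) for c in node.operands]
            combined = parts[0].copy()
            for p in parts[1:]:
                combined = (combined & p) if node.op == "AND" else (combined | p)
            return combined
        raise QueryParseError(f"unsupported query node {node!r}")

    def count(self, query: str) -> int:
        return int(self._eval(parse_query(query)).sum())


def corpus_backend(
    corpus: SyntheticCorpus, terms: list[DiseaseTerm] | None = None
) -> SimulatedCorpusBackend:
    """Wrap a synthetic corpus as a snapshot-consistent count backend."""
    return SimulatedCorpusBackend(corpus, terms)


def empirical_association_matrix(corpus: SyntheticCorpus) -> tuple[list[str], np.ndarray]:
    """True Jaccard association matrix of the corpus, by direct set
    arithmetic on the occurrence matrix (independent of the query path)."""
    mat = corpus.mention_matrix()
    counts = mat.sum(axis=0).astype(np.int64)
    # float matmul runs through BLAS and is exact for counts << 2**53
    matf = mat.astype(np.float64)
    inter = np.rint(matf.T @ matf).astype(np.int64)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        assoc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(assoc, 1.0)
    return corpus.disease_ids, assoc


def reference_from_truth(
    corpus: SyntheticCorpus, noise_sd: float, seed: int | None = None
) -> ReferenceMatrix:
    """Synthetic stand-in for an independent comorbidity reference.

    The reference is the corpus's true empirical association matrix plus
    independent symmetric Gaussian noise (sd ``noise_sd``), clipped at 0 —
    an idealized external study measuring the same quantity with error.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    labels, assoc = empirical_association_matrix(corpus)
    values = assoc.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(corpus.spec.seed + 7919 if seed is None else seed)
        n = len(labels)
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        upper = np.triu(noise, k=1)
        values = values + upper + upper.T
        np.clip(values, 0.0, None, out=values)
    return ReferenceMatrix(
        labels=labels, values=values, source=f"synthetic(noise_sd={noise_sd})"
    )


# ---------------------------------------------------------------------------
# Serialization: one document per line, tab-separated disease ids.

def save_corpus(corpus: SyntheticCorpus, path: str | Path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in corpus.documents:
            fh.write("\t".join(sorted(doc)) + "\n")


def load_documents(path: str | Path) -> list[frozenset[str]]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            docs.append(frozenset(line.split("\t")) if line else frozenset())
    return docs


def save_truth(corpus: SyntheticCorpus, path: str | Path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tblock\n")
        for d in corpus.disease_ids:
            fh.write(f"{d}\t{corpus.truth[d]}\n")
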