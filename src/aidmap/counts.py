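"""Document-count acquisition for disease terms and term pairs.

A disease association is computed from four PubMed-style document counts:
the two singleton counts, the ``AND`` count and the ``OR`` count. This
module builds the Boolean queries, talks to a pluggable count backend
(live NCBI E-utilities, a cached query table, or a simulated corpus) and
caches pair-level results on disk so a long run over all C(n, 2) pairs is
resumable.
"""

from __future__ import annotations

import csv
import logging
import time
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Protocol, runtime_checkable

logger = logging.getLogger(__name__)

#: Restrict queries to title, abstract and other-terms fields.
FIELDS_TIAB_OT = "title-abstract-otherterms"
#: No field restriction (PubMed "All Fields").
FIELDS_ALL = "all"

_VALID_FIELDS = (FIELDS_TIAB_OT, FIELDS_ALL)


class InvalidTermError(ValueError):
    """A disease term is malformed (empty name or synonym)."""


class SelfPairError(ValueError):
    """A pair query was requested for a term against itself."""


class QueryParseError(ValueError):
    """A query string contains a construct the parser does not support."""


class InconsistentCountsError(ValueError):
    """Counts violate a set identity they must satisfy."""


class FetchError(RuntimeError):
    """A backend request failed; the failing query is attached."""

    def __init__(self, message: str, query: str | None = None):
        super().__init__(message)
        self.query = query


class IncompleteInputError(ValueError):
    """Pair records do not cover all requested label pairs."""

    def __init__(self, missing: list[tuple[str, str]]):
        super().__init__(f"missing counts for {len(missing)} pair(s): {missing[:5]}")
        self.missing = missing


@dataclass(frozen=True)
class DiseaseTerm:
    """One queryable disease with optional epidemiological metadata.

    Parameters
    ----------
    id : str
        Short stable token, unique within a term list.
    name : str
        Canonical display name; also the default query phrase.
    synonyms : tuple of str
        Additional query phrases OR-ed with the name.
    gender_female_fraction : float or None
        Fraction of patients who are female, in [0, 1].
    onset_age : float or None
        Average age of onset in years.
    prevalence : float or None
        Fraction of the population affected.
    system_label : str or None
        Affected-system category (e.g. "endocrine").
    """

    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    gender_female_fraction: float | None = None
    onset_age: float | None = None
    prevalence: float | None = None
    system_label: str | None = None

    def __post_init__(self):
        if not self.id:
            raise InvalidTermError("term id must be non-empty")
        if not self.name:
            raise InvalidTermError(f"term {self.id!r} has an empty name")
        if any(not s for s in self.synonyms):
            raise InvalidTermError(f"term {self.id!r} has an empty synonym")
        if self.gender_female_fraction is not None and not (
            0.0 <= self.gender_female_fraction <= 1.0
        ):
            raise InvalidTermError(
                f"term {self.id!r}: gender_female_fraction outside [0, 1]"
            )

    @property
    def phrases(self) -> tuple[str, ...]:
        """Name plus synonyms, in query order."""
        return (self.name, *self.synonyms)


@dataclass(frozen=True)
class PairCounts:
    """The four document counts underlying one association value."""

    term_a: str
    term_b: str
    n_a: int
    n_b: int
    n_and: int
    n_or: int
    retrieved_at: str = "simulated"

    def __post_init__(self):
        for name in ("n_a", "n_b", "n_and", "n_or"):
            v = getattr(self, name)
            if v < 0:
                raise InconsistentCountsError(f"{name} = {v} is negative")
        if self.n_and > min(self.n_a, self.n_b):
            raise InconsistentCountsError(
                f"n_and = {self.n_and} exceeds min(n_a, n_b) = "
                f"{min(self.n_a, self.n_b)} for pair "
                f"({self.term_a}, {self.term_b})"
            )
        if self.n_or < max(self.n_a, self.n_b):
            raise InconsistentCountsError(
                f"n_or = {self.n_or} below max(n_a, n_b) for pair "
                f"({self.term_a}, {self.term_b})"
            )

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.term_a, self.term_b)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) unordered pair key, so (a, b) == (b, a)."""
    if a == b:
        raise SelfPairError(f"pair key requested for identical ids {a!r}")
    return (a, b) if a < b else (b, a)


def fold_diacritics(text: str) -> str:
    """ASCII-fold a phrase (e.g. 'Sjögren' -> 'Sjogren')."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def _phrase_clauses(phrase: str, fields: str, diacritic_fold: bool) -> list[str]:
    variants = [phrase]
    if diacritic_fold:
        folded = fold_diacritics(phrase)
        if folded != phrase:
            variants.append(folded)
    clauses = []
    for v in variants:
        if fields == FIELDS_TIAB_OT:
            clauses.append(f'"{v}"[tiab]')
            clauses.append(f'"{v}"[ot]')
        else:
            clauses.append(f'"{v}"[All Fields]')
    return clauses


def build_term_query(
    term: DiseaseTerm,
    fields: str = FIELDS_TIAB_OT,
    diacritic_fold: bool = True,
) -> str:
    """Build the Boolean query for a single disease.

    Every phrase (name and synonyms) becomes a quoted string restricted to
    the configured fields; phrases and field variants are OR-ed. Quoting
    suppresses PubMed automatic term mapping, so the count reflects literal
    phrase occurrence.

    Examples
    --------
    >>> build_term_query(DiseaseTerm("lupus", "lupus"))
    '("lupus"[tiab] OR "lupus"[ot])'
    """
    if fields not in _VALID_FIELDS:
        raise ValueError(f"fields must be one of {_VALID_FIELDS}, got {fields!r}")
    clauses: list[str] = []
    for phrase in term.phrases:
        clauses.extend(_phrase_clauses(phrase, fields, diacritic_fold))
    return "(" + " OR ".join(clauses) + ")"


def build_pair_query(
    a: DiseaseTerm,
    b: DiseaseTerm,
    op: str = "AND",
    fields: str = FIELDS_TIAB_OT,
    diacritic_fold: bool = True,
) -> str:
    """Build the Boolean query for a disease pair.

    Operands are ordered canonically (lexicographic by id) so the query
    string — and hence any cache key derived from it — is the same for
    (a, b) and (b, a).
    """
    if op not in ("AND", "OR"):
        raise ValueError(f"op must be 'AND' or 'OR', got {op!r}")
    if a.id == b.id:
        raise SelfPairError(f"pair query requested for identical term {a.id!r}")
    first, second = (a, b) if a.id < b.id else (b, a)
    qa = build_term_query(first, fields, diacritic_fold)
    qb = build_term_query(second, fields, diacritic_fold)
    return f"({qa}) {op} ({qb})"


# ---------------------------------------------------------------------------
# Query parsing (used by simulated backends to evaluate the Boolean queries
# the builders above emit).

@dataclass(frozen=True)
class Phrase:
    text: str
    field: str | None


@dataclass(frozen=True)
class BoolOp:
    op: str  # "AND" | "OR"
    operands: tuple


def _tokenize(query: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(query)
    while i < n:
        c = query[i]
        if c.isspace():
            i += 1
        elif c in "()":
            tokens.append(c)
            i += 1
        elif c == '"':
            j = query.find('"', i + 1)
            if j < 0:
                raise QueryParseError(f"unterminated quote in query: {query!r}")
            tokens.append(query[i : j + 1])
            i = j + 1
        elif c == "[":
            j = query.find("]", i + 1)
            if j < 0:
                raise QueryParseError(f"unterminated field tag in query: {query!r}")
            tokens.append(query[i : j + 1])
            i = j + 1
        else:
            j = i
            while j < n and not query[j].isspace() and query[j] not in '()"[':
                j += 1
            tokens.append(query[i:j])
            i = j
    return tokens


def parse_query(query: str):
    """Parse a builder-emitted query into a Phrase/BoolOp tree.

    Grammar: ``expr := and_expr (OR and_expr)*``;
    ``and_expr := atom (AND atom)*``;
    ``atom := '(' expr ')' | '"phrase"' ['[field]']``.
    """
    tokens = _tokenize(query)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_atom():
        tok = peek()
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise QueryParseError(f"expected ')' in query: {query!r}")
            advance()
            return node
        if tok is not None and tok.startswith('"'):
            advance()
            fld = None
            if peek() is not None and peek().startswith("["):
                fld = advance()[1:-1]
            return Phrase(tok[1:-1], fld)
        raise QueryParseError(f"unsupported construct {tok!r} in query: {query!r}")

    def parse_and():
        operands = [parse_atom()]
        while peek() == "AND":
            advance()
            operands.append(parse_atom())
        return operands[0] if len(operands) == 1 else BoolOp("AND", tuple(operands))

    def parse_or():
        operands = [parse_and()]
        while peek() == "OR":
            advance()
            operands.append(parse_and())
        return operands[0] if len(operands) == 1 else BoolOp("OR", tuple(operands))

    tree = parse_or()
    if pos != len(tokens):
        raise QueryParseError(f"trailing tokens {tokens[pos:]} in query: {query!r}")
    return tree


# ---------------------------------------------------------------------------
# Backends

@runtime_checkable
class CountBackend(Protocol):
    """Provider of ``count(query) -> int`` over some document corpus."""

    backend_id: str
    #: True when all counts derive from one fixed corpus state, so
    #: inclusion-exclusion identities hold exactly.
    snapshot_consistent: bool

    def count(self, query: str) -> int: ...


class TableBackend:
    """Snapshot-consistent backend answering from a query -> count table.

    The table is a two-column tab-delimited file (query, count), typically
    a dump of previously retrieved esearch responses.
    """

    snapshot_consistent = True

    def __init__(self, counts: Mapping[str, int] | str | Path, backend_id: str = "table"):
        if isinstance(counts, (str, Path)):
            loaded: dict[str, int] = {}
            with open(counts, newline="", encoding="utf-8") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if not row or row[0] == "query":
                        continue
                    loaded[row[0]] = int(row[1])
            counts = loaded
        self._counts = dict(counts)
        self.backend_id = backend_id

    def count(self, query: str) -> int:
        try:
            return self._counts[query]
        except KeyError:
            raise FetchError(f"query not present in count table", query=query) from None


class EntrezBackend:
    """Live NCBI E-utilities esearch backend (count-only queries).

    Not snapshot-consistent: PubMed grows between requests, so the
    inclusion-exclusion identity is checked only as a warning downstream.
    Polite by default: at most 3 requests/second without an API key, 10/s
    with one, with exponential backoff on transient failures.
    """

    snapshot_consistent = False
    backend_id = "entrez"

    def __init__(
        self,
        email: str,
        api_key: str | None = None,
        max_retries: int = 3,
        backoff_base: float = 1.0,
    ):
        from Bio import Entrez  # deferred so offline use never touches it

        self._entrez = Entrez
        self._entrez.email = email
        if api_key:
            self._entrez.api_key = api_key
        self._min_interval = 0.1 if api_key else 1.0 / 3.0
        self._last_request = 0.0
        self.max_retries = max_retries
        self.backoff_base = backoff_base

    def _throttle(self):
        wait = self._min_interval - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        self._last_request = time.monotonic()

    def count(self, query: str) -> int:
        last_err: Exception | None = None
        for attempt in range(self.max_retries + 1):
            self._throttle()
            try:
                handle = self._entrez.esearch(db="pubmed", term=query, retmax=0)
                record = self._entrez.read(handle)
                handle.close()
                return int(record["Count"])
            except (OSError, RuntimeError, KeyError, ValueError) as err:
                last_err = err
                if attempt < self.max_retries:
                    time.sleep(self.backoff_base * 2**attempt)
        raise FetchError(f"esearch failed after retries: {last_err}", query=query)


# ---------------------------------------------------------------------------
# On-disk cache

_CACHE_COLUMNS = (
    "pair_key", "term_a", "term_b", "n_a", "n_b", "n_and", "n_or",
    "backend", "fields", "retrieved_at",
)


class CountCache:
    """Append-only tab-delimited cache of singleton and pair counts.

    Pair rows carry all four counts; singleton rows have an empty
    ``term_b`` and the count in ``n_a``. Keys include the backend id and
    the field restriction so counts from different sources never mix.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._pairs: dict[tuple, PairCounts] = {}
        self._terms: dict[tuple, int] = {}
        if self.path.exists():
            self._load()
        else:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            with open(self.path, "w", newline="", encoding="utf-8") as fh:
                csv.writer(fh, delimiter="\t").writerow(_CACHE_COLUMNS)

    def _load(self):
        with open(self.path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                if row["term_b"]:
                    pc = PairCounts(
                        term_a=row["term_a"],
                        term_b=row["term_b"],
                        n_a=int(row["n_a"]),
                        n_b=int(row["n_b"]),
                        n_and=int(row["n_and"]),
                        n_or=int(row["n_or"]),
                        retrieved_at=row["retrieved_at"],
                    )
                    self._pairs[(row["backend"], pc.key, row["fields"])] = pc
                else:
                    self._terms[(row["backend"], row["term_a"], row["fields"])] = int(
                        row["n_a"]
                    )

    def _append(self, row: dict):
        with open(self.path, "a", newline="", encoding="utf-8") as fh:
            csv.writer(fh, delimiter="\t").writerow(row[c] for c in _CACHE_COLUMNS)

    def get_pair(self, backend_id, key, fields) -> PairCounts | None:
        return self._pairs.get((backend_id, key, fields))

    def put_pair(self, backend_id: str, fields: str, pc: PairCounts):
        self._pairs[(backend_id, pc.key, fields)] = pc
        a, b = pc.key
        self._append({
            "pair_key": f"{a}|{b}", "term_a": pc.term_a, "term_b": pc.term_b,
            "n_a": pc.n_a, "n_b": pc.n_b, "n_and": pc.n_and, "n_or": pc.n_or,
            "backend": backend_id, "fields": fields,
            "retrieved_at": pc.retrieved_at,
        })

    def get_term(self, backend_id, term_id, fields) -> int | None:
        return self._terms.get((backend_id, term_id, fields))

    def put_term(self, backend_id, fields, term_id, count, retrieved_at):
        self._terms[(backend_id, term_id, fields)] = count
        self._append({
            "pair_key": term_id, "term_a": term_id, "term_b": "",
            "n_a": count, "n_b": "", "n_and": "", "n_or": "",
            "backend": backend_id, "fields": fields, "retrieved_at": retrieved_at,
        })


def _timestamp(backend: CountBackend) -> str:
    if backend.snapshot_consistent:
        return "simulated"
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


# ---------------------------------------------------------------------------
# Fetching

def fetch_term_count(
    term: DiseaseTerm,
    backend: CountBackend,
    cache: CountCache | None = None,
    fields: str = FIELDS_TIAB_OT,
) -> int:
    """Singleton document count for one disease, cache-aware."""
    if cache is not None:
        hit = cache.get_term(backend.backend_id, term.id, fields)
        if hit is not None:
            return hit
    query = build_term_query(term, fields)
    try:
        n = backend.count(query)
    except FetchError:
        raise
    except Exception as err:  # malformed response, etc.
        raise FetchError(f"backend failed on term {term.id!r}: {err}", query) from err
    if cache is not None:
        cache.put_term(backend.backend_id, fields, term.id, n, _timestamp(backend))
    return n


def fetch_pair_counts(
    a: DiseaseTerm,
    b: DiseaseTerm,
    backend: CountBackend,
    cache: CountCache | None = None,
    fields: str = FIELDS_TIAB_OT,
    _term_counts: dict[str, int] | None = None,
) -> PairCounts:
    """All four counts for one unordered pair, cache-aware.

    On snapshot-consistent backends the inclusion-exclusion identity
    ``n_or == n_a + n_b - n_and`` is enforced; on a live backend a
    violation (count drift between requests) is only logged.
    """
    key = pair_key(a.id, b.id)
    if cache is not None:
        hit = cache.get_pair(backend.backend_id, key, fields)
        if hit is not None:
            return hit

    def term_count(t: DiseaseTerm) -> int:
        if _term_counts is not None and t.id in _term_counts:
            return _term_counts[t.id]
        n = fetch_term_count(t, backend, cache, fields)
        if _term_counts is not None:
            _term_counts[t.id] = n
        return n

    n_a, n_b = term_count(a), term_count(b)
    if a.id > b.id:  # canonical orientation
        a, b = b, a
        n_a, n_b = n_b, n_a
    q_and = build_pair_query(a, b, "AND", fields)
    q_or = build_pair_query(a, b, "OR", fields)
    try:
        n_and = backend.count(q_and)
        n_or = backend.count(q_or)
    except FetchError:
        raise
    except Exception as err:
        raise FetchError(f"backend failed on pair {key}: {err}", q_and) from err

    if n_or != n_a + n_b - n_and:
        msg = (
            f"inclusion-exclusion violated for pair {key}: "
            f"n_or={n_or} != {n_a}+{n_b}-{n_and}"
        )
        if backend.snapshot_consistent:
            raise InconsistentCountsError(msg)
        logger.warning("%s (live backend drift)", msg)

    pc = PairCounts(a.id, b.id, n_a, n_b, n_and, n_or, _timestamp(backend))
    if cache is not None:
        cache.put_pair(backend.backend_id, fields, pc)
    return pc


@dataclass
class CountsResult:
    """Counts for every unordered pair plus per-disease singleton counts."""

    pairs: list[PairCounts]
    singletons: dict[str, int]

    def pair_map(self) -> dict[tuple[str, str], PairCounts]:
        return {pc.key: pc for pc in self.pairs}


def fetch_all_pairs(
    terms: Iterable[DiseaseTerm],
    backend: CountBackend,
    cache: CountCache | None = None,
    fields: str = FIELDS_TIAB_OT,
    progress: bool = False,
) -> CountsResult:
    """Counts for all C(n, 2) unordered pairs and the n singletons.

    Resumable: pairs already present in the cache are not re-fetched, so an
    interrupted run can simply be restarted.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    ids = [t.id for t in terms]
    if len(set(ids)) != len(ids):
        raise InvalidTermError("duplicate term ids in list")

    term_counts: dict[str, int] = {}
    singletons = {
        t.id: (
            term_counts.setdefault(t.id, fetch_term_count(t, backend, cache, fields))
        )
        for t in terms
    }
    pairs = []
    all_pairs = list(combinations(terms, 2))
    for i, (a, b) in enumerate(all_pairs):
        pairs.append(
            fetch_pair_counts(a, b, backend, cache, fields, _term_counts=term_counts)
        )
        if progress and (i + 1) % 500 == 0:
            logger.info("fetched %d / %d pairs", i + 1, len(all_pairs))
    return CountsResult(pairs=pairs, singletons=singletons)


# ---------------------------------------------------------------------------
# Term-list I/O

_TERM_COLUMNS = (
    "id", "name", "synonyms", "gender_female_fraction", "onset_age",
    "prevalence", "system_label",
)


def load_terms(path: str | Path) -> list[DiseaseTerm]:
    """Read a disease-term table (tab-delimited; synonyms pipe-separated)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                DiseaseTerm(
                    id=row["id"],
                    name=row["name"],
                    synonyms=tuple(s for s in row.get("synonyms", "").split("|") if s),
                    gender_female_fraction=_opt_float(row.get("gender_female_fraction")),
                    onset_age=_opt_float(row.get("onset_age")),
                    prevalence=_opt_float(row.get("prevalence")),
                    system_label=row.get("system_label") or None,
                )
            )
    ids = [t.id for t in out]
    if len(set(ids)) != len(ids):
        raise InvalidTermError(f"duplicate ids in term table {path}")
    return out


def save_terms(terms: Iterable[DiseaseTerm], path: str | Path):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TERM_COLUMNS)
        for t in terms:
            writer.writerow([
                t.id, t.name, "|".join(t.synonyms),
                "" if t.gender_female_fraction is None else t.gender_female_fraction,
                "" if t.onset_age is None else t.onset_age,
                "" if t.prevalence is None else t.prevalence,
                t.system_label or "",
            ])


def _opt_float(value: str | None) -> float | None:
    return float(value) if value else None


def training_terms() -> list[DiseaseTerm]:
    """The seven-disease validation set (SLE, Sjögren's, T1D, autoimmune
    thyroid disease, rheumatoid arthritis, multiple sclerosis, systemic
    sclerosis), shipped as an editable fixture."""
    path = resources.files("aidmap").joinpath("data/training_terms.tsv")
    with resources.as_file(path) as p:
        return load_terms(p)
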