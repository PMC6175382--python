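"""Reference collections: RIS input/output, tokenisation, vocabulary.

A screening task starts from a bibliographic *collection* exported by a
literature search (RIS format: tagged ``XX  - value`` lines, records closed
by ``ER  -``).  Each reference carries a title, an (optionally empty)
abstract and free-form metadata.  Downstream modules consume the collection
through two products built here:

* tokenised documents — (surface, lemma, pos) triples per field, produced by
  a pluggable lemmatiser (:mod:`screenprio.lemmatise`);
* the collection vocabulary — lemmas occurring at least ``min_count`` times
  in the whole collection (default 5) and absent from the stop list, with a
  deterministic lexicographic column order.

Screening decision traces (tab-separated ``reference_id  decision
[timestamp]`` rows) are also read and written here.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from .errors import ConfigurationError, EmptyCollectionError, FormatError
from .lemmatise import Lemmatiser, default_lemmatiser, default_stoplist

__all__ = [
    "Reference",
    "Collection",
    "TokenisedDocument",
    "Vocabulary",
    "read_ris",
    "write_ris",
    "tokenise",
    "tokenise_collection",
    "build_vocabulary",
    "read_trace",
    "write_trace",
]

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")
_TOKEN = re.compile(r"[A-Za-z0-9]+")
_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  -\s?(.*)$")

#: Field label type used throughout the package.
Field = Literal["title", "abstract"]


def _norm(text: str) -> str:
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class Reference:
    """One bibliographic record at the title/abstract screening level."""

    id: str
    title: str
    abstract: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def text(self, fld: Field) -> str:
        return self.title if fld == "title" else self.abstract


class Collection:
    """An ordered set of references with unique identifiers."""

    def __init__(self, references: Sequence[Reference], name: str = "collection"):
        refs = list(references)
        if not refs:
            raise EmptyCollectionError("a collection must contain at least one reference")
        ids = [r.id for r in refs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate reference ids: {dupes[:5]}")
        self.references: list[Reference] = refs
        self.name = name
        self._by_id = {r.id: r for r in refs}

    def __len__(self) -> int:
        return len(self.references)

    def __iter__(self) -> Iterator[Reference]:
        return iter(self.references)

    def __getitem__(self, ref_id: str) -> Reference:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.references]


@dataclass(frozen=True)
class TokenisedDocument:
    """(surface, lemma, pos) triples for one field of one reference."""

    tokens: tuple[tuple[str, str, str], ...]
    source_field: Field

    @property
    def lemmas(self) -> list[str]:
        return [lem for _, lem, _ in self.tokens]

    def countable_lemmas(self) -> list[str]:
        """Lemmas that participate in vocabulary counting.

        Pure-numeric and single-character tokens are excluded by design.
        """
        return [
            lem
            for surface, lem, _ in self.tokens
            if len(lem) > 1 and not surface.isdigit()
        ]


def tokenise(
    text: str, fld: Field, lemmatiser: Lemmatiser | None = None
) -> TokenisedDocument:
    """Split ``text`` on non-alphanumeric boundaries and lemmatise.

    Hyphenated words are split; lemmas are lowercased.  Empty text yields an
    empty token list (legitimate for missing abstracts).
    """
    lem = lemmatiser if lemmatiser is not None else default_lemmatiser()
    tokens = tuple(
        (m.group(0), *lem(m.group(0))) for m in _TOKEN.finditer(text)
    )
    return TokenisedDocument(tokens=tokens, source_field=fld)


def tokenise_collection(
    collection: Collection, lemmatiser: Lemmatiser | None = None
) -> dict[str, tuple[TokenisedDocument, TokenisedDocument]]:
    """Tokenise every reference; returns id -> (title doc, abstract doc)."""
    lem = lemmatiser if lemmatiser is not None else default_lemmatiser()
    return {
        r.id: (tokenise(r.title, "title", lem), tokenise(r.abstract, "abstract", lem))
        for r in collection
    }


@dataclass(frozen=True)
class Vocabulary:
    """Collection vocabulary with contiguous lexicographic column indices."""

    entries: dict[str, int]
    doc_frequency: dict[str, int]
    total_frequency: dict[str, int]
    stoplist: frozenset[str]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    @property
    def index_to_lemma(self) -> list[str]:
        out = [""] * len(self.entries)
        for lemma, idx in self.entries.items():
            out[idx] = lemma
        return out


def build_vocabulary(
    collection: Collection,
    min_count: int = 5,
    stoplist: frozenset[str] | None = None,
    lemmatiser: Lemmatiser | None = None,
    tokenised: dict[str, tuple[TokenisedDocument, TokenisedDocument]] | None = None,
) -> Vocabulary:
    """Lemmas with total collection frequency >= ``min_count``, minus stops.

    The threshold applies to the total count over all titles and abstracts
    (not the document frequency).  Index assignment is lexicographic, so the
    result is invariant to reference order.
    """
    stops = default_stoplist() if stoplist is None else stoplist
    docs = tokenised if tokenised is not None else tokenise_collection(collection, lemmatiser)
    total: Counter[str] = Counter()
    doc_freq: Counter[str] = Counter()
    for ref_id in collection.ids:
        title_doc, abstract_doc = docs[ref_id]
        lemmas = title_doc.countable_lemmas() + abstract_doc.countable_lemmas()
        total.update(lemmas)
        doc_freq.update(set(lemmas))
    kept = sorted(
        lemma for lemma, n in total.items() if n >= min_count and lemma not in stops
    )
    if not kept:
        raise ConfigurationError(
            f"vocabulary is empty at min_count={min_count}; "
            "lower min_count or check the stop list"
        )
    return Vocabulary(
        entries={lemma: i for i, lemma in enumerate(kept)},
        doc_frequency={lemma: doc_freq[lemma] for lemma in kept},
        total_frequency={lemma: total[lemma] for lemma in kept},
        stoplist=frozenset(stops),
    )


# ---------------------------------------------------------------------------
# RIS input/output
# ---------------------------------------------------------------------------

_TITLE_TAGS = ("TI", "T1")
_ABSTRACT_TAGS = ("AB", "N2")
_RESERVED_TAGS = {"TY", "ER", "ID", *_TITLE_TAGS, *_ABSTRACT_TAGS}


def read_ris(path: str | Path, name: str | None = None) -> Collection:
    """Parse a RIS file into a :class:`Collection`.

    ``TI``/``T1`` map to the title, ``AB``/``N2`` to the abstract, ``ID`` to
    the stable identifier (generated sequentially when absent).  Records
    lacking both title and abstract are dropped with a logged warning;
    ingestion order is preserved.  Repeated tags (e.g. multiple ``AU``) are
    joined with ``"; "``.
    """
    path = Path(path)
    lines = path.read_text("utf-8-sig").splitlines()
    references: list[Reference] = []
    fields: dict[str, list[str]] | None = None
    current_tag: str | None = None
    dropped = 0

    def close_record(record: dict[str, list[str]]) -> None:
        nonlocal dropped
        title = next((_norm(" ".join(record[t])) for t in _TITLE_TAGS if t in record), "")
        abstract = next(
            (_norm(" ".join(record[t])) for t in _ABSTRACT_TAGS if t in record), ""
        )
        if not title and not abstract:
            dropped += 1
            logger.warning("dropping RIS record %d: no title and no abstract",
                           len(references) + dropped)
            return
        ref_id = _norm(" ".join(record.get("ID", []))) or f"ref-{len(references) + 1:05d}"
        metadata = {
            tag: "; ".join(_norm(v) for v in values)
            for tag, values in record.items()
            if tag not in _RESERVED_TAGS or tag == "TY"
        }
        if "TY" in record:
            metadata["TY"] = "; ".join(record["TY"])
        references.append(Reference(ref_id, title, abstract, metadata))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n\r")
        if not line.strip():
            continue
        m = _RIS_TAG.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            if tag == "TY" or fields is None:
                if fields is not None:
                    # unterminated record: close it leniently
                    close_record(fields)
                fields = {}
            if tag == "ER":
                close_record(fields)
                fields, current_tag = None, None
                continue
            fields.setdefault(tag, []).append(value)
            current_tag = tag
        elif fields is not None and current_tag is not None:
            fields[current_tag][-1] += " " + line.strip()
        else:
            raise FormatError(f"{path}: not RIS-formatted at line {lineno}: {line[:60]!r}")
    if fields:
        close_record(fields)
    if not references:
        raise EmptyCollectionError(f"{path}: no usable records (dropped {dropped})")
    return Collection(references, name=name or path.stem)


def write_ris(collection: Collection, path: str | Path) -> Path:
    """Serialise a collection to RIS, losslessly for title/abstract/metadata.

    Emits ``TI`` and ``AB`` regardless of the tags seen at read time, so a
    write/read round trip is the identity on titles, abstracts, ids and
    stored metadata values.
    """
    path = Path(path)
    out: list[str] = []
    for ref in collection:
        if not _norm(ref.title):
            raise FormatError(f"reference {ref.id!r}: empty title cannot be serialised")
        out.append(f"TY  - {ref.metadata.get('TY', 'JOUR')}")
        out.append(f"ID  - {ref.id}")
        out.append(f"TI  - {_norm(ref.title)}")
        if _norm(ref.abstract):
            out.append(f"AB  - {_norm(ref.abstract)}")
        for tag in sorted(ref.metadata):
            if tag == "TY":
                continue
            for part in ref.metadata[tag].split("; "):
                out.append(f"{tag}  - {part}")
        out.append("ER  - ")
    path.write_text("\n".join(out) + "\n", "utf-8")
    return path


# ---------------------------------------------------------------------------
# Screening-trace files
# ---------------------------------------------------------------------------

_DECISIONS = {"include", "exclude"}


def read_trace(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read a TSV decision trace: reference_id, decision, [ISO timestamp]."""
    rows: list[tuple[str, str, str | None]] = []
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or parts[1] not in _DECISIONS:
            raise FormatError(f"{path}: bad trace row at line {lineno}: {line[:60]!r}")
        rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 and parts[2] else None))
    return rows


def write_trace(
    rows: Iterable[tuple[str, str, str | None]], path: str | Path
) -> Path:
    path = Path(path)
    lines = []
    for ref_id, decision, ts in rows:
        if decision not in _DECISIONS:
            raise FormatError(f"bad decision {decision!r} for {ref_id!r}")
        lines.append(f"{ref_id}\t{decision}" + (f"\t{ts}" if ts else ""))
    path.write_text("\n".join(lines) + "\n", "utf-8")
    return path
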