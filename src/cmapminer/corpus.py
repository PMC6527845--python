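"""Abstract corpora, term lexicons and dictionary-based annotation.

This module turns free-text abstracts into the per-abstract sentence
statistics that the association scores consume: for every abstract it
records which sentences mention the disease, which mention genes or
drugs, and which mention both (the co-occurrence signal).

Matching is deterministic dictionary lookup — case-insensitive,
word-boundary delimited, longest-match-wins — which is the standard
recall-oriented strategy when the output feeds manual curation rather
than a downstream classifier.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Abstract",
    "Lexicon",
    "TermHit",
    "AbstractAnnotation",
    "segment_sentences",
    "match_terms",
    "annotate_abstract",
    "read_corpus",
    "read_lexicons",
]

CATEGORIES = ("disease", "gene", "drug", "event")

#: Categories that participate in scoring; "event" terms are display-only.
SCORED_CATEGORIES = ("disease", "gene", "drug")


def _load_default_abbreviations() -> frozenset[str]:
    text = resources.files("cmapminer.data").joinpath("abbreviations.txt").read_text()
    abbrevs = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            abbrevs.add(line.lower())
    return frozenset(abbrevs)


_DEFAULT_ABBREVIATIONS = _load_default_abbreviations()

# Candidate sentence boundary: terminal punctuation, whitespace, then an
# uppercase letter or digit opening the next sentence.
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")
_WORD_RE = re.compile(r"\S+$")


def segment_sentences(
    text: str, extra_abbreviations: Iterable[str] = ()
) -> list[str]:
    """Split plain text into sentences.

    A sentence boundary is sentence-terminal punctuation (``.``, ``!``,
    ``?``) followed by whitespace and an uppercase letter or digit.
    Tokens in the packaged abbreviation list (e.g. ``vs.``, ``et al.``)
    and single-initial tokens (``J.``) never end a sentence.

    Empty or whitespace-only input yields an empty list.
    """
    if not text or not text.strip():
        return []
    abbrevs = _DEFAULT_ABBREVIATIONS | {a.lower() for a in extra_abbreviations}
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        token_match = _WORD_RE.search(text, start, end)
        token = token_match.group(0) if token_match else ""
        if token.lower() in abbrevs:
            continue
        # Single-initial tokens like "J." are abbreviations, not boundaries.
        if re.fullmatch(r"[A-Z]\.", token):
            continue
        sentence = text[start:end].strip()
        if sentence:
            sentences.append(sentence)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass(frozen=True)
class Abstract:
    """A literature abstract; the optional title becomes sentence 0."""

    abstract_id: str
    text: str
    title: str | None = None

    @property
    def sentences(self) -> list[str]:
        body = segment_sentences(self.text)
        if self.title and self.title.strip():
            return [self.title.strip()] + body
        return body


class Lexicon:
    """Canonical entities of one category with their synonym sets.

    A synonym may map to several canonical ids; the ambiguity is kept
    (one hit per canonical id) rather than silently resolved.
    """

    def __init__(self, category: str, entries: Mapping[str, Iterable[str]]):
        if category not in CATEGORIES:
            raise ValueError(f"unknown lexicon category: {category!r}")
        self.category = category
        self.entries: dict[str, frozenset[str]] = {}
        for canonical_id, synonyms in entries.items():
            syns = frozenset(synonyms)
            if not syns or any(not s for s in syns):
                raise ValueError(
                    f"entry {canonical_id!r}: synonym set must be non-empty "
                    "strings"
                )
            self.entries[canonical_id] = syns
        # synonym (lowercased) -> sorted canonical ids
        self._by_synonym: dict[str, tuple[str, ...]] = {}
        for cid, syns in self.entries.items():
            for s in syns:
                key = s.lower()
                ids = set(self._by_synonym.get(key, ())) | {cid}
                self._by_synonym[key] = tuple(sorted(ids))
        self._pattern = self._compile()

    def _compile(self) -> re.Pattern[str] | None:
        if not self._by_synonym:
            return None
        # Longest-first alternation => the regex engine yields the longest
        # match at each position; finditer then skips overlapped shorter ones.
        alts = sorted(self._by_synonym, key=len, reverse=True)
        body = "|".join(re.escape(a) for a in alts)
        return re.compile(
            rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", re.IGNORECASE
        )

    def canonical_ids_for(self, synonym: str) -> tuple[str, ...]:
        return self._by_synonym.get(synonym.lower(), ())

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Lexicon({self.category!r}, {len(self)} entries)"


@dataclass(frozen=True)
class TermHit:
    """One dictionary match inside one sentence."""

    sentence_index: int
    canonical_id: str
    category: str
    char_span: tuple[int, int]
    matched_text: str


@dataclass
class AbstractAnnotation:
    """Sentence-level term statistics for one abstract.

    ``n_c`` counts sentences with a disease term and a gene-or-drug term
    (the co-occurrence evidence); ``n_hnc`` counts disease-only
    sentences; ``n_gene``/``n_drug`` count sentences with a gene/drug
    term and no disease term. The flags record whether any term of the
    category occurs anywhere in the abstract.
    """

    abstract_id: str
    n_sentences: int
    hits: list[TermHit] = field(default_factory=list)
    n_c: int = 0
    n_hnc: int = 0
    n_gene: int = 0
    n_drug: int = 0
    flag_gene: int = 0
    flag_drug: int = 0
    flag_hnc: int = 0

    def entity_ids(self, category: str) -> set[str]:
        """Canonical ids of the given category mentioned in the abstract."""
        return {h.canonical_id for h in self.hits if h.category == category}


def match_terms(sentence: str, lexicon: Lexicon) -> list[TermHit]:
    """Find lexicon terms in a sentence.

    Case-insensitive, bounded by non-alphanumeric characters (so hyphens
    delimit: ``EGFR-positive`` matches ``EGFR``). At each position the
    longest synonym wins and shorter overlapping matches are suppressed.
    An ambiguous synonym yields one hit per canonical id.
    """
    pattern = lexicon._pattern
    if pattern is None:
        return []
    return [
        TermHit(0, cid, lexicon.category, (m.start(), m.end()), m.group(0))
        for m in pattern.finditer(sentence)
        for cid in lexicon.canonical_ids_for(m.group(0))
    ]


def annotate_abstract(
    abstract: Abstract,
    disease: Lexicon,
    genes: Lexicon,
    drugs: Lexicon,
    events: Lexicon | None = None,
    flag_hnc_from_any_disease: bool = True,
) -> AbstractAnnotation:
    """Scan all sentences of an abstract and tally the score inputs.

    Sentence classification: a sentence with a disease term and a
    gene-or-drug term counts in ``n_c``; a sentence with a disease term
    and no gene/drug term counts in ``n_hnc``; ``n_gene`` (``n_drug``)
    counts sentences with a gene (drug) term and no disease term, other
    non-disease terms notwithstanding. Event terms are recorded as hits
    for display but never counted.

    ``flag_hnc_from_any_disease`` controls the disease presence flag
    (the formula uses it as a gate but its definition is a convention):
    if True, any disease term anywhere in the abstract sets it.
    """
    lexicons = [disease, genes, drugs] + ([events] if events else [])
    ann = AbstractAnnotation(abstract.abstract_id, 0)
    sentences = abstract.sentences
    ann.n_sentences = len(sentences)
    for idx, sentence in enumerate(sentences):
        cats_here: set[str] = set()
        for lex in lexicons:
            for hit in match_terms(sentence, lex):
                ann.hits.append(
                    TermHit(idx, hit.canonical_id, hit.category,
                            hit.char_span, hit.matched_text)
                )
                cats_here.add(lex.category)
        has_disease = "disease" in cats_here
        has_gene = "gene" in cats_here
        has_drug = "drug" in cats_here
        if has_disease and (has_gene or has_drug):
            ann.n_c += 1
        elif has_disease:
            ann.n_hnc += 1
        if has_gene and not has_disease:
            ann.n_gene += 1
        if has_drug and not has_disease:
            ann.n_drug += 1
    ann.flag_gene = int(any(h.category == "gene" for h in ann.hits))
    ann.flag_drug = int(any(h.category == "drug" for h in ann.hits))
    if flag_hnc_from_any_disease:
        ann.flag_hnc = int(any(h.category == "disease" for h in ann.hits))
    else:
        ann.flag_hnc = int(ann.n_c + ann.n_hnc > 0)
    return ann


def read_corpus(path: str | Path) -> list[Abstract]:
    """Read abstracts from TSV (abstract_id, text[, title]) or JSON lines."""
    path = Path(path)
    abstracts: list[Abstract] = []
    if path.suffix in {".jsonl", ".json"}:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                abstracts.append(
                    Abstract(str(rec["abstract_id"]), rec["text"],
                             rec.get("title"))
                )
        return abstracts
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"abstract_id", "text"} <= set(df.columns):
        raise ValueError("corpus TSV needs columns: abstract_id, text")
    for _, row in df.iterrows():
        title = row["title"] if "title" in df.columns and row["title"] else None
        abstracts.append(Abstract(row["abstract_id"], row["text"], title))
    return abstracts


def read_lexicons(path: str | Path) -> dict[str, Lexicon]:
    """Read lexicons from a TSV with columns canonical_id, category, synonym.

    Returns one :class:`Lexicon` per category present in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"canonical_id", "category", "synonym"}
    if not required <= set(df.columns):
        raise ValueError(f"lexicon TSV needs columns: {sorted(required)}")
    out: dict[str, Lexicon] = {}
    for category, sub in df.groupby("category"):
        entries: dict[str, set[str]] = {}
        for _, row in sub.iterrows():
            entries.setdefault(row["canonical_id"], set()).add(row["synonym"])
        out[str(category)] = Lexicon(str(category), entries)
    return out


def annotate_corpus(
    abstracts: Sequence[Abstract],
    disease: Lexicon,
    genes: Lexicon,
    drugs: Lexicon,
    events: Lexicon | None = None,
    flag_hnc_from_any_disease: bool = True,
) -> list[AbstractAnnotation]:
    """Annotate every abstract of a corpus (convenience wrapper)."""
    return [
        annotate_abstract(a, disease, genes, drugs, events,
                          flag_hnc_from_any_disease)
        for a in abstracts
    ]
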