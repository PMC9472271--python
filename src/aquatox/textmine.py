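"""Literature sentence mining for toxicity trend discovery.

The miner turns a plain-text article body into the small set of sentences
worth reading: it strips front matter and the reference list, segments the
body into sentences, ranks candidate key phrases, and keeps only sentences
that simultaneously mention a *main term* (the endpoint vocabulary, e.g.
"toxicity", "LC50") and a *connection word* (a relational stem such as
"increas" or "correlate").  A sentence passing both filters plausibly states
a structure-toxicity relationship and is forwarded to a human reader.

Input is pre-extracted UTF-8 text, one file per article; PDF handling is out
of scope.  All matching is case-insensitive.  Main terms match whole tokens;
connection words match by token prefix, because the curated stem list
contains truncated lemmas ("decreas", "relat") that are meant to cover every
inflection.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import EmptyDocumentError

__all__ = [
    "Document",
    "MiningConfig",
    "RelevantSentence",
    "clean_text",
    "split_sentences",
    "extract_keyphrases",
    "extract_relevant",
    "mine_document",
    "mine_corpus",
    "write_sentences_csv",
    "write_sentences_jsonl",
    "DEFAULT_MAIN_TERMS",
    "DEFAULT_CONNECTION_STEMS",
    "DEFAULT_STOPWORDS",
]

DEFAULT_MAIN_TERMS: tuple[str, ...] = ("toxicity", "acute", "lc50", "ec50")

DEFAULT_CONNECTION_STEMS: tuple[str, ...] = (
    "increase", "decreas", "relat", "correlate", "structure", "fragment",
    "class", "significant", "high", "affect", "low", "link", "reason",
    "determin", "predict", "influence", "severe", "depend",
)

# Compact builtin English stopword list (standard closed-class words) used by
# the RAKE-style key-phrase scorer to delimit candidate phrases.
DEFAULT_STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all also am an and any are as at be because
been before being below between both but by can cannot could did do does doing
down during each few for from further had has have having he her here hers
him his how i if in into is it its itself just me more most my no nor not of
off on once only or other our ours out over own same she should so some such
than that the their theirs them then there these they this those through to
too under until up very was we were what when where which while who whom why
will with would you your yours
""".split())

_PROTECTED_TOKENS: tuple[str, ...] = (
    "fig.", "figs.", "et al.", "e.g.", "i.e.", "vs.", "ref.", "refs.",
    "no.", "eq.", "eqs.", "ca.", "cf.", "dr.", "prof.", "approx.",
)

_SENTINEL = "\x00"


@dataclass(frozen=True)
class Document:
    """One article: an identifier plus its raw extracted text."""

    doc_id: str
    raw_text: str


@dataclass(frozen=True)
class RelevantSentence:
    """A sentence selected by the relevance filter, with its match evidence."""

    doc_id: str
    sentence_index: int
    text: str
    matched_main_terms: tuple[str, ...]
    matched_connection_stems: tuple[str, ...]


@dataclass
class MiningConfig:
    """Reader-provided vocabulary steering the relevance filter.

    Parameters
    ----------
    main_terms : sequence of str
        Endpoint words; a sentence must contain at least one as a whole
        token (case-insensitive).
    connection_stems : sequence of str
        Relational stems; a sentence must contain at least one token whose
        prefix matches a stem (``match_mode="prefix"``, the default) or that
        equals a stem exactly (``match_mode="exact"``).
    """

    main_terms: tuple[str, ...] = DEFAULT_MAIN_TERMS
    connection_stems: tuple[str, ...] = DEFAULT_CONNECTION_STEMS
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        self.main_terms = tuple(self.main_terms)
        self.connection_stems = tuple(self.connection_stems)
        for name in ("main_terms", "connection_stems"):
            terms = getattr(self, name)
            if not terms:
                raise ValueError(f"{name} must be non-empty")
            if any(t != t.lower() for t in terms):
                raise ValueError(f"{name} entries must be lowercase")
            if len(set(terms)) != len(terms):
                raise ValueError(f"{name} contains duplicates")
        if self.match_mode not in ("prefix", "exact"):
            raise ValueError("match_mode must be 'prefix' or 'exact'")


def _as_document(doc: Document | str, doc_id: str = "doc") -> Document:
    if isinstance(doc, Document):
        return doc
    return Document(doc_id=doc_id, raw_text=doc)


def clean_text(
    doc: Document | str,
    *,
    body_start_markers: Sequence[str] = ("introduction",),
    references_markers: Sequence[str] = ("references", "bibliography", "literature cited"),
) -> str:
    """Strip front matter and the reference list; normalise whitespace.

    Content up to and including the first *body start* heading (default
    "Introduction", i.e. the end of title/abstract) is removed, as is
    everything from the last *references* heading onward.  Markers are
    matched case-insensitively as headings at the start of a line, with an
    optional leading section number.  Absent markers leave that side of the
    text untouched.  Runs of whitespace collapse to single spaces.
    """
    doc = _as_document(doc)
    text = doc.raw_text
    if not text or not text.strip():
        raise EmptyDocumentError(f"document {doc.doc_id!r} has no text")

    def _heading_pattern(marker: str) -> re.Pattern[str]:
        return re.compile(
            r"^[ \t]*(?:\d+[.)]?\s*)?" + re.escape(marker) + r"\b.*$",
            re.IGNORECASE | re.MULTILINE,
        )

    start = 0
    for marker in body_start_markers:
        m = _heading_pattern(marker).search(text)
        if m:
            start = max(start, m.end())
            break
    end = len(text)
    for marker in references_markers:
        matches = list(_heading_pattern(marker).finditer(text, start))
        if matches:
            end = min(end, matches[-1].start())
            break
    body = text[start:end]
    return re.sub(r"\s+", " ", body).strip()


def split_sentences(
    body_text: str,
    *,
    protected_tokens: Sequence[str] = _PROTECTED_TOKENS,
) -> list[str]:
    """Segment cleaned text into sentences on ``.!?`` boundaries.

    Periods inside protected abbreviations ("Fig.", "et al.", ...) and
    decimal numbers do not end a sentence.  Concatenating the result (modulo
    whitespace) reconstructs the input.
    """
    if not body_text or not body_text.strip():
        return []
    shielded = body_text
    # Shield decimals like "0.5" and abbreviation periods with a sentinel.
    shielded = re.sub(r"(?<=\d)\.(?=\d)", _SENTINEL, shielded)
    for token in sorted(protected_tokens, key=len, reverse=True):
        pattern = re.compile(re.escape(token[:-1]) + r"\.", re.IGNORECASE)
        shielded = pattern.sub(lambda m: m.group(0)[:-1] + _SENTINEL, shielded)
    parts = re.split(r"(?<=[.!?])\s+", shielded)
    sentences = []
    for part in parts:
        restored = part.replace(_SENTINEL, ".").strip()
        if restored:
            sentences.append(restored)
    return sentences


def _phrase_candidates(text: str, stopwords: frozenset[str]) -> list[tuple[str, ...]]:
    phrases: list[tuple[str, ...]] = []
    for chunk in re.split(r"[.!?,;:()\[\]{}\"“”]+", text.lower()):
        current: list[str] = []
        for token in re.findall(r"[a-z0-9][a-z0-9'’-]*", chunk):
            if token in stopwords or not re.search(r"[a-z]", token):
                if current:
                    phrases.append(tuple(current))
                    current = []
            else:
                current.append(token)
        if current:
            phrases.append(tuple(current))
    return phrases


def extract_keyphrases(
    body_text: str,
    top_n: int = 10,
    *,
    stopwords: Iterable[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank candidate key phrases by the RAKE degree/frequency score.

    Candidate phrases are maximal stopword-free token runs.  Each word gets
    the score deg(w)/freq(w), where deg(w) counts co-occurring words (phrase
    length summed over occurrences) and freq(w) counts occurrences; a phrase
    scores the sum of its word scores.  Ties break lexicographically so the
    ranking is fully deterministic.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    stops = frozenset(w.lower() for w in stopwords) if stopwords is not None else DEFAULT_STOPWORDS
    phrases = _phrase_candidates(body_text, stops)
    if not phrases:
        return []
    freq: dict[str, int] = {}
    degree: dict[str, int] = {}
    for phrase in phrases:
        for word in phrase:
            freq[word] = freq.get(word, 0) + 1
            degree[word] = degree.get(word, 0) + len(phrase)
    word_score = {w: degree[w] / freq[w] for w in freq}
    scored: dict[tuple[str, ...], float] = {}
    for phrase in phrases:
        scored.setdefault(phrase, sum(word_score[w] for w in phrase))
    ranked = sorted(scored.items(), key=lambda kv: (-kv[1], " ".join(kv[0])))
    return [(" ".join(p), s) for p, s in ranked[:top_n]]


def _tokenize(sentence: str) -> list[str]:
    return re.findall(r"[a-z0-9]+", sentence.lower())


def _match_sentence(
    sentence: str, cfg: MiningConfig
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    tokens = _tokenize(sentence)
    token_set = set(tokens)
    mains = tuple(t for t in cfg.main_terms if t in token_set)
    if cfg.match_mode == "exact":
        stems = tuple(s for s in cfg.connection_stems if s in token_set)
    else:
        stems = tuple(
            s for s in cfg.connection_stems if any(tok.startswith(s) for tok in token_set)
        )
    return mains, stems


def extract_relevant(
    sentences: Sequence[str],
    cfg: MiningConfig | None = None,
    *,
    doc_id: str = "doc",
) -> list[RelevantSentence]:
    """Keep sentences containing >=1 main term and >=1 connection stem.

    Order is preserved and every returned sentence carries the matched
    vocabulary, so the selection is self-certifying: replaying the predicate
    on ``text`` reproduces the recorded matches.
    """
    cfg = cfg or MiningConfig()
    out: list[RelevantSentence] = []
    for i, sentence in enumerate(sentences):
        mains, stems = _match_sentence(sentence, cfg)
        if mains and stems:
            out.append(
                RelevantSentence(
                    doc_id=doc_id,
                    sentence_index=i,
                    text=sentence,
                    matched_main_terms=mains,
                    matched_connection_stems=stems,
                )
            )
    return out


@dataclass
class MiningReport:
    """Per-document sentence counts supporting a text-reduction summary."""

    doc_id: str
    n_sentences: int
    n_relevant: int

    @property
    def reduction(self) -> float:
        """Fraction of sentences the reader no longer has to scan."""
        if self.n_sentences == 0:
            return 0.0
        return 1.0 - self.n_relevant / self.n_sentences


def mine_document(
    doc: Document,
    cfg: MiningConfig | None = None,
    **clean_kwargs,
) -> tuple[list[RelevantSentence], MiningReport]:
    """Full per-article pipeline: clean, segment, filter."""
    body = clean_text(doc, **clean_kwargs)
    sentences = split_sentences(body)
    relevant = extract_relevant(sentences, cfg, doc_id=doc.doc_id)
    return relevant, MiningReport(doc.doc_id, len(sentences), len(relevant))


def mine_corpus(
    docs: Iterable[Document],
    cfg: MiningConfig | None = None,
    **clean_kwargs,
) -> tuple[list[RelevantSentence], list[MiningReport]]:
    """Mine a corpus; returns all relevant sentences plus per-doc reports."""
    all_relevant: list[RelevantSentence] = []
    reports: list[MiningReport] = []
    for doc in docs:
        rel, rep = mine_document(doc, cfg, **clean_kwargs)
        all_relevant.extend(rel)
        reports.append(rep)
    return all_relevant, reports


def read_corpus_dir(path: str | Path, pattern: str = "*.txt") -> list[Document]:
    """Load a directory of UTF-8 text files, one document per file."""
    docs = []
    for file in sorted(Path(path).glob(pattern)):
        docs.append(Document(doc_id=file.stem, raw_text=file.read_text(encoding="utf-8")))
    return docs


def write_sentences_csv(sentences: Sequence[RelevantSentence], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["doc_id", "sentence_index", "text", "matched_main_terms", "matched_connection_stems"]
        )
        for s in sentences:
            writer.writerow(
                [s.doc_id, s.sentence_index, s.text,
                 ";".join(s.matched_main_terms), ";".join(s.matched_connection_stems)]
            )


def write_sentences_jsonl(sentences: Sequence[RelevantSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps({
                "doc_id": s.doc_id,
                "sentence_index": s.sentence_index,
                "text": s.text,
                "matched_main_terms": list(s.matched_main_terms),
                "matched_connection_stems": list(s.matched_connection_stems),
            }) + "\n")
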