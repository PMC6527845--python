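"""Gene-disease (SGD) and drug-disease (SDD) association scores.

Per abstract, the score is a weighted sentence tally::

    SGD = N_c * w_c + FLAG_gene * N_hnc * w_hnc + FLAG_hnc * N_gene * w_gene
    SDD = N_c * w_c + FLAG_drug * N_hnc * w_hnc + FLAG_hnc * N_drug * w_drug

where N_c counts sentences co-mentioning the disease and a gene/drug,
N_hnc counts disease-only sentences, N_gene / N_drug count gene- or
drug-only sentences, and the FLAG terms gate the context counts on the
entity class actually being present in the abstract. Candidate entities
are ranked by the sum of scores over the abstracts mentioning them and
exported as curation sheets with highlighted evidence.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Abstract, AbstractAnnotation

__all__ = [
    "ScoreWeights",
    "AssociationScore",
    "CurationRecord",
    "score_gene_association",
    "score_drug_association",
    "rank_candidates",
    "export_curation_sheet",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the sentence-count terms; all must be finite and >= 0.

    Defaults make one co-occurrence sentence worth ten context
    sentences: the co-mention is the strongest literature signal, and
    only relative order matters for ranking.
    """

    w_c: float = 10.0
    w_hnc: float = 1.0
    w_gene: float = 1.0
    w_drug: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_c", "w_hnc", "w_gene", "w_drug"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class AssociationScore:
    entity_id: str
    abstract_id: str
    score: float
    kind: str  # "gene" or "drug"


@dataclass(frozen=True)
class CurationRecord:
    """One (abstract, entity) row of a curation sheet with its evidence."""

    abstract_id: str
    entity_id: str
    kind: str
    score: float
    # (sentence_index, (start, end), category)
    highlighted_spans: tuple[tuple[int, tuple[int, int], str], ...]


def score_gene_association(ann: AbstractAnnotation, w: ScoreWeights) -> float:
    """SGD of one abstract."""
    return (
        ann.n_c * w.w_c
        + ann.flag_gene * ann.n_hnc * w.w_hnc
        + ann.flag_hnc * ann.n_gene * w.w_gene
    )


def score_drug_association(ann: AbstractAnnotation, w: ScoreWeights) -> float:
    """SDD of one abstract."""
    return (
        ann.n_c * w.w_c
        + ann.flag_drug * ann.n_hnc * w.w_hnc
        + ann.flag_hnc * ann.n_drug * w.w_drug
    )


def rank_candidates(
    annotations: Sequence[AbstractAnnotation],
    kind: str,
    weights: ScoreWeights = ScoreWeights(),
    min_score: float = 1.0,
    threshold_level: str = "entity",
) -> list[tuple[str, float, int]]:
    """Rank candidate genes or drugs across a corpus.

    Each entity's total score is the sum, over the abstracts that
    mention it, of that abstract's SGD (``kind="gene"``) or SDD
    (``kind="drug"``). ``threshold_level`` selects where ``min_score``
    applies: ``"entity"`` filters on the total, ``"abstract"`` drops
    per-abstract contributions below the threshold before summing.

    Returns ``(entity_id, total_score, n_abstracts)`` sorted by
    descending score, ties broken by abstract count then id.
    """
    if kind not in ("gene", "drug"):
        raise ValueError("kind must be 'gene' or 'drug'")
    if threshold_level not in ("entity", "abstract"):
        raise ValueError("threshold_level must be 'entity' or 'abstract'")
    scorer = score_gene_association if kind == "gene" else score_drug_association
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ann in annotations:
        s = scorer(ann, weights)
        if threshold_level == "abstract" and s < min_score:
            continue
        for entity in ann.entity_ids(kind):
            totals[entity] = totals.get(entity, 0.0) + s
            counts[entity] = counts.get(entity, 0) + 1
    ranked = [
        (e, totals[e], counts[e])
        for e in totals
        if threshold_level == "abstract" or totals[e] >= min_score
    ]
    ranked.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return ranked


def make_curation_records(
    abstracts: Sequence[Abstract],
    annotations: Sequence[AbstractAnnotation],
    kind: str,
    weights: ScoreWeights = ScoreWeights(),
    min_score: float = 1.0,
) -> list[CurationRecord]:
    """Build curation records for every (abstract, entity) pair at or above
    ``min_score`` (per-abstract score)."""
    scorer = score_gene_association if kind == "gene" else score_drug_association
    records = []
    for abstract, ann in zip(abstracts, annotations):
        s = scorer(ann, weights)
        if s < min_score:
            continue
        spans = tuple(
            (h.sentence_index, h.char_span, h.category) for h in ann.hits
        )
        for entity in sorted(ann.entity_ids(kind)):
            records.append(
                CurationRecord(abstract.abstract_id, entity, kind, s, spans)
            )
    return records


_HIGHLIGHT_COLORS = {
    "disease": "#f8c8c8",
    "gene": "#c8e6c8",
    "drug": "#c8d8f8",
    "event": "#f8e8b8",
}


def _render_sentence(sentence: str, spans: list[tuple[tuple[int, int], str]]) -> str:
    """HTML for one sentence with non-overlapping spans highlighted."""
    spans = sorted(spans, key=lambda s: s[0])
    out: list[str] = []
    pos = 0
    for (start, end), category in spans:
        if start < pos:
            continue  # overlapping display span; keep the first
        out.append(_html.escape(sentence[pos:start]))
        color = _HIGHLIGHT_COLORS.get(category, "#e0e0e0")
        out.append(
            f'<span class="hit {category}" style="background:{color}">'
            f"{_html.escape(sentence[start:end])}</span>"
        )
        pos = end
    out.append(_html.escape(sentence[pos:]))
    return "".join(out)


def export_curation_sheet(
    records: Sequence[CurationRecord],
    abstracts: Mapping[str, Abstract],
    tsv_path: str | Path,
    html_path: str | Path | None = None,
) -> None:
    """Write a curation sheet as TSV and, optionally, highlighted HTML.

    The TSV has one row per (abstract, entity) record. The HTML shows
    each abstract's sentences with every matched span color-coded by
    category, the format used for manual review.
    """
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        fh.write("abstract_id\tentity_id\tkind\tscore\tn_highlighted_spans\n")
        for r in records:
            fh.write(
                f"{r.abstract_id}\t{r.entity_id}\t{r.kind}\t{r.score:g}\t"
                f"{len(r.highlighted_spans)}\n"
            )
    if html_path is None:
        return
    parts = [
        "<html><head><meta charset='utf-8'><title>Curation sheet</title>"
        "</head><body>"
    ]
    seen: set[str] = set()
    for r in records:
        entities = [x.entity_id for x in records if x.abstract_id == r.abstract_id]
        if r.abstract_id in seen:
            continue
        seen.add(r.abstract_id)
        abstract = abstracts[r.abstract_id]
        sentences = abstract.sentences
        by_sentence: dict[int, list[tuple[tuple[int, int], str]]] = {}
        for idx, span, category in r.highlighted_spans:
            by_sentence.setdefault(idx, []).append((span, category))
        parts.append(f"<h3>{_html.escape(r.abstract_id)}</h3>")
        parts.append(
            "<p class='candidates'>candidates: "
            f"{_html.escape(', '.join(sorted(set(entities))))}</p>"
        )
        for idx, sentence in enumerate(sentences):
            parts.append(
                "<p>" + _render_sentence(sentence, by_sentence.get(idx, []))
                + "</p>"
            )
    parts.append("</body></html>")
    Path(html_path).write_text("\n".join(parts))
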