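"""Document filtering and paragraph segmentation.

Reproduces the corpus-construction funnel — documents are retained when
they are long (character length strictly above the corpus median by
default), mention at least one symptom keyword, and contain more than
five temporal expressions — and the paragraph retention rules: at least
five words, not header-like, and at least one temporal expression.

Documents are divided into paragraphs on block-level HTML tags (``p``,
``br``, ``div``, ``li``, ``tr``, headings, ...) and, in untagged text, on
blank lines.  Paragraph spans are 0-based half-open intervals into the
raw document text, so standoff annotation offsets remain valid; inline
tags are stripped from the paragraph *text* only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import temporal
from .corpus import Document

logger = logging.getLogger("onsetnlp")


@dataclass
class Paragraph:
    doc_id: str
    index: int
    span: tuple  # (start, end) into raw document text
    text: str  # tags stripped
    word_count: int = 0
    expressions: list = field(default_factory=list)
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.word_count:
            self.word_count = len(self.text.split())


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the document and paragraph filters.

    ``min_doc_expressions`` defaults to 6, i.e. strictly more than five
    expressions per document.  ``header_max_words_per_line`` and
    ``header_colon_max_words`` operationalise "header-like" paragraphs:
    every physical line has at most 3 words, or the paragraph ends with a
    colon and has at most 6 words.
    """

    length_percentile: float = 0.5
    min_symptom_keywords: int = 1
    min_doc_expressions: int = 6
    min_paragraph_words: int = 5
    min_paragraph_expressions: int = 1
    header_max_words_per_line: int = 3
    header_colon_max_words: int = 6
    absolute_length_threshold: Optional[float] = None  # overrides the percentile

    def __post_init__(self) -> None:
        if not 0 < self.length_percentile < 1:
            raise ValueError("length_percentile must be in (0, 1)")


_BLOCK_TAG = re.compile(
    r"</?(?:p|br|div|li|ul|ol|tr|td|th|table|tbody|thead|h[1-6])\b[^>]*/?>|\n{2,}",
    re.IGNORECASE,
)
_INLINE_TAG = re.compile(r"<[^>]+>")


def strip_tags(text: str) -> str:
    return _INLINE_TAG.sub(" ", text)


def split_paragraphs(document: Document) -> List[Paragraph]:
    """Split a document into paragraphs on block tags and blank lines.

    Returns paragraphs in document order with disjoint, ordered spans into
    the raw text.  Segments that contain no visible text are skipped.
    """
    text = document.text
    breaks = [(m.start(), m.end()) for m in _BLOCK_TAG.finditer(text)]
    bounds = [0] + [pos for pair in breaks for pos in pair] + [len(text)]
    paragraphs: List[Paragraph] = []
    for seg_start, seg_end in zip(bounds[0::2], bounds[1::2]):
        raw = text[seg_start:seg_end]
        stripped = strip_tags(raw)
        if not stripped.strip():
            continue
        lead = len(raw) - len(raw.lstrip())
        trail = len(raw) - len(raw.rstrip())
        span = (seg_start + lead, seg_end - trail)
        paragraphs.append(
            Paragraph(
                doc_id=document.doc_id,
                index=len(paragraphs),
                span=span,
                text=stripped.strip(),
            )
        )
    return paragraphs


def count_keywords(text: str, lexicon: Sequence[str]) -> int:
    """Case-insensitive word-boundary keyword match count (no stemming)."""
    visible = strip_tags(text)
    total = 0
    for kw in lexicon:
        total += len(re.findall(rf"\b{re.escape(kw)}\b", visible, re.IGNORECASE))
    return total


@dataclass
class FunnelReport:
    """Per-stage document and patient counts (corpus-construction funnel)."""

    stages: list = field(default_factory=list)  # (stage, n_documents, n_patients)

    def add(self, stage: str, documents: Sequence[Document]) -> None:
        self.stages.append((stage, len(documents), len({d.patient_id for d in documents})))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "documents", "patients"])


def filter_documents(
    corpus: Sequence[Document],
    lexicon: Sequence[str],
    config: FilterConfig = FilterConfig(),
    tagger_config: temporal.TaggerConfig = temporal.DEFAULT_CONFIG,
) -> Tuple[List[Document], FunnelReport]:
    """Apply the three document filters and report the funnel.

    A document is retained iff its character length strictly exceeds the
    corpus length quantile (or an absolute override), it contains at least
    ``min_symptom_keywords`` lexicon matches, and it has at least
    ``min_doc_expressions`` temporal expressions.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if not lexicon:
        raise ValueError("empty symptom lexicon")
    report = FunnelReport()
    report.add("initial", corpus)

    if config.absolute_length_threshold is not None:
        threshold = config.absolute_length_threshold
    else:
        threshold = float(
            np.quantile([len(d.text) for d in corpus], config.length_percentile)
        )
    stage1 = [d for d in corpus if len(d.text) > threshold]
    report.add("length", stage1)

    stage2 = [d for d in stage1 if count_keywords(d.text, lexicon) >= config.min_symptom_keywords]
    report.add("keywords", stage2)

    stage3 = [
        d
        for d in stage2
        if temporal.count_expressions(strip_tags(d.text), d.document_date, tagger_config)
        >= config.min_doc_expressions
    ]
    report.add("expressions", stage3)
    logger.info(
        "document funnel: %s",
        " -> ".join(f"{s}={n}" for s, n, _ in report.stages),
    )
    return stage3, report


def attach_expressions(
    paragraphs: Iterable[Paragraph],
    anchor,
    config: temporal.TaggerConfig = temporal.DEFAULT_CONFIG,
) -> None:
    """Run the temporal tagger over each paragraph's stripped text in place."""
    for p in paragraphs:
        p.expressions = temporal.tag(p.text, anchor, config)


def is_header_like(paragraph: Paragraph, config: FilterConfig = FilterConfig()) -> bool:
    lines = [ln for ln in paragraph.text.splitlines() if ln.strip()]
    if lines and all(len(ln.split()) <= config.header_max_words_per_line for ln in lines):
        return True
    return (
        paragraph.text.rstrip().endswith(":")
        and paragraph.word_count <= config.header_colon_max_words
    )


def filter_paragraphs(
    paragraphs: Iterable[Paragraph], config: FilterConfig = FilterConfig()
) -> List[Paragraph]:
    """Retain paragraphs with >=5 words, not header-like, and >=1 expression."""
    return [
        p
        for p in paragraphs
        if p.word_count >= config.min_paragraph_words
        and not is_header_like(p, config)
        and len(p.expressions) >= config.min_paragraph_expressions
    ]
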