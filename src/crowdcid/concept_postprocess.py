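"""Post-process concept recognition output.

Upstream NER tools leave some mentions unmapped (concept ID ``-1``) and
map others to non-MeSH ontologies.  This module resolves unmapped
acronym mentions against mapped mentions in the same document, and
filters out annotations that carry no usable MeSH ID before candidate
generation.

The acronym resolver is a deliberately simple two-clause rule:

(a) *same-text propagation* — an unmapped mention whose surface exactly
    equals a mapped same-class mention's surface in the same document
    inherits that mention's IDs;

(b) *parenthetical definition* — when an unmapped acronym appears
    wrapped in parentheses immediately (within 2 characters) after a
    mapped same-class mention, every same-surface unmapped mention in
    the document inherits the defining mention's IDs.

A surface qualifies as an acronym candidate when it is short
(``max_acronym_length`` characters or fewer), contains an uppercase
letter (configurable) and no whitespace.  When several resolvers with
different IDs compete, the nearest mapped mention preceding the acronym
wins, for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from crowdcid.corpus_io import ConceptAnnotation, Document

__all__ = ["AcronymRuleConfig", "resolve_acronyms", "exclude_non_mesh"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcronymRuleConfig:
    """Parameters of the acronym-resolution rule."""

    max_acronym_length: int = 10
    require_uppercase: bool = True
    parenthetical_slack: int = 2  # max chars between long form and "("

    def __post_init__(self) -> None:
        if self.max_acronym_length < 1:
            raise ValueError("max_acronym_length must be >= 1")
        if self.parenthetical_slack < 0:
            raise ValueError("parenthetical_slack must be >= 0")

    def is_acronym_candidate(self, surface: str) -> bool:
        if len(surface) > self.max_acronym_length or not surface:
            return False
        if any(ch.isspace() for ch in surface):
            return False
        if self.require_uppercase and not any(ch.isupper() for ch in surface):
            return False
        return True


def _pick_resolver(
    acronym: ConceptAnnotation, resolvers: Sequence[ConceptAnnotation]
) -> ConceptAnnotation:
    """Nearest mapped mention preceding the acronym; else nearest following."""
    preceding = [r for r in resolvers if r.start <= acronym.start]
    if preceding:
        return max(preceding, key=lambda r: r.start)
    return min(resolvers, key=lambda r: r.start)


def resolve_acronyms(
    document: Document,
    annotations: Sequence[ConceptAnnotation],
    config: AcronymRuleConfig | None = None,
) -> list[ConceptAnnotation]:
    """Copy IDs from mapped mentions onto qualifying unmapped acronyms.

    Spans, surfaces, classes and annotation count are never changed; the
    only modification is replacing an all-``-1`` ID list.  Applying the
    function twice yields the same result (idempotence): a resolved
    mention is simply another mapped mention on the second pass.
    """
    if config is None:
        config = AcronymRuleConfig()
    text = document.combined_text
    mapped = [a for a in annotations if not a.is_unmapped]

    # surface -> inherited IDs, per concept class
    inherited: dict[tuple[str, str], tuple[str, ...]] = {}

    unmapped = [
        a
        for a in annotations
        if a.is_unmapped and config.is_acronym_candidate(a.surface)
    ]
    for acro in unmapped:
        key = (acro.concept_class, acro.surface)
        if key in inherited:
            continue
        same_class = [m for m in mapped if m.concept_class == acro.concept_class]
        # (a) exact same surface as a mapped mention
        same_text = [m for m in same_class if m.surface == acro.surface]
        if same_text:
            resolver = _pick_resolver(acro, same_text)
            if len({m.concept_ids for m in same_text}) > 1:
                logger.warning(
                    "conflicting resolvers for %r in %s; using mention at %d",
                    acro.surface,
                    document.doc_id,
                    resolver.start,
                )
            inherited[key] = resolver.concept_ids
            continue
        # (b) parenthetical definition right after a mapped mention
        defining = []
        for m in same_class:
            window = text[m.end : m.end + config.parenthetical_slack + 1]
            open_idx = window.find("(")
            if open_idx < 0:
                continue
            defn_start = m.end + open_idx + 1
            defn_end = defn_start + len(acro.surface)
            if (
                text[defn_start:defn_end] == acro.surface
                and text[defn_end : defn_end + 1] == ")"
            ):
                defining.append(m)
        if defining:
            resolver = _pick_resolver(acro, defining)
            if len({m.concept_ids for m in defining}) > 1:
                logger.warning(
                    "conflicting parenthetical definitions for %r in %s; "
                    "using mention at %d",
                    acro.surface,
                    document.doc_id,
                    resolver.start,
                )
            inherited[key] = resolver.concept_ids

    out: list[ConceptAnnotation] = []
    for ann in annotations:
        key = (ann.concept_class, ann.surface)
        if ann.is_unmapped and key in inherited:
            out.append(
                ConceptAnnotation(
                    doc_id=ann.doc_id,
                    start=ann.start,
                    end=ann.end,
                    surface=ann.surface,
                    concept_class=ann.concept_class,
                    concept_ids=inherited[key],
                )
            )
        else:
            out.append(ann)
    return out


def exclude_non_mesh(
    annotations: Sequence[ConceptAnnotation],
) -> list[ConceptAnnotation]:
    """Keep only annotations carrying at least one MeSH ID.

    Mentions mapped solely to the ``-1`` sentinel or to foreign
    ontologies (e.g. CHEBI) are dropped; composite ID lists survive as
    long as one component is a MeSH ID.
    """
    return [a for a in annotations if a.mesh_ids]
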