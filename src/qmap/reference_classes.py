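"""Ternary reference interaction matrices from curated edge lists.

Curated genetic-interaction databases (BioGRID) report unordered gene
pairs with an experimental-system category. For evaluation against a
screen's (query, array) universe these are turned into ternary label
matrices per interaction class: each addressable pair is *interacting*,
*non-interacting*, or *excluded*. Exclusions cover (i) ambiguous pairs
annotated in both the positive and the negative class, (ii) self pairs
(the matrix diagonal measures a single mutant, not an interaction), and
(iii) pairs from an explicit exclusion list, e.g. interactions that were
themselves extracted from the screens under evaluation. Pairs are treated
as unordered throughout: an edge A-B also labels B-A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fitness_io import EdgeRecord

logger = logging.getLogger(__name__)

INTERACTING = 1
NON_INTERACTING = 0
EXCLUDED = -1

#: Default BioGRID category-to-class assignment. Matching is
#: case-insensitive after trimming; both the 'Synthetic Lethality' and
#: 'Synthetic Lethal' spellings are accepted.
DEFAULT_CATEGORY_MAP = {
    "positive genetic": "positive",
    "phenotypic suppression": "positive",
    "negative genetic": "negative",
    "synthetic growth defect": "negative",
    "synthetic lethality": "negative",
    "synthetic lethal": "negative",
    "phenotypic enhancement": "negative",
}


@dataclass
class InteractionClassMatrix:
    """Ternary reference labels for one interaction class over a pair grid.

    ``labels[a, b]`` is 1 (interacting), 0 (non-interacting) or -1
    (excluded) for the pair (query_ids[a], array_ids[b]).
    """

    query_ids: list[str]
    array_ids: list[str]
    labels: np.ndarray
    class_name: str
    categories_used: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.query_ids), len(self.array_ids)):
            raise ValidationError("label grid does not match id lists")
        if self.class_name not in ("positive", "negative"):
            raise ValidationError(
                f"class_name must be 'positive' or 'negative', got {self.class_name!r}"
            )

    def counts(self) -> dict[str, int]:
        """Counts of each label; they sum to the universe size m*n."""
        return {
            "interacting": int(np.sum(self.labels == INTERACTING)),
            "non_interacting": int(np.sum(self.labels == NON_INTERACTING)),
            "excluded": int(np.sum(self.labels == EXCLUDED)),
        }


def _unordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _classify_edges(edges: list[EdgeRecord], category_map: dict[str, str],
                    strict: bool) -> dict[str, set[tuple[str, str]]]:
    by_class: dict[str, set[tuple[str, str]]] = {"positive": set(), "negative": set()}
    for e in edges:
        cls = category_map.get(e.category.strip().lower())
        if cls is None:
            if strict:
                raise ValidationError(f"unknown interaction category {e.category!r}")
            logger.warning("ignoring edge with unknown category %r", e.category)
            continue
        by_class[cls].add(_unordered(e.gene_a, e.gene_b))
    return by_class


def build_class_matrix(edges: list[EdgeRecord], class_name: str,
                       query_ids: list[str], array_ids: list[str],
                       category_map: dict[str, str] | None = None,
                       exclude_edges: list[EdgeRecord] | None = None,
                       strict: bool = False) -> InteractionClassMatrix:
    """Build the ternary reference matrix for one class over an id universe.

    A pair is *interacting* if its unordered gene pair carries a category of
    ``class_name``; pairs annotated in both classes are ambiguous and
    *excluded* (in both sibling matrices), as are self pairs and unordered
    pairs in ``exclude_edges``; all other pairs are *non-interacting*.
    Unknown category terms raise in ``strict`` mode, otherwise they are
    skipped with a warning.
    """
    if category_map is None:
        category_map = DEFAULT_CATEGORY_MAP
    else:
        category_map = {k.strip().lower(): v for k, v in category_map.items()}
    if class_name not in ("positive", "negative"):
        raise ValidationError(
            f"class_name must be 'positive' or 'negative', got {class_name!r}"
        )
    by_class = _classify_edges(edges, category_map, strict)
    ambiguous = by_class["positive"] & by_class["negative"]
    own = by_class[class_name]
    excluded_pairs: set[tuple[str, str]] = set(ambiguous)
    if exclude_edges:
        excluded_pairs |= {_unordered(e.gene_a, e.gene_b) for e in exclude_edges}

    labels = np.zeros((len(query_ids), len(array_ids)), dtype=np.int8)
    for a, qa in enumerate(query_ids):
        for b, ab in enumerate(array_ids):
            if qa == ab:
                labels[a, b] = EXCLUDED
                continue
            key = _unordered(qa, ab)
            if key in excluded_pairs:
                labels[a, b] = EXCLUDED
            elif key in own:
                labels[a, b] = INTERACTING
    categories = sorted(k for k, v in category_map.items() if v == class_name)
    return InteractionClassMatrix(
        query_ids=list(query_ids), array_ids=list(array_ids), labels=labels,
        class_name=class_name, categories_used=categories,
    )


def restrict_labels(cm: InteractionClassMatrix,
                    pairs: list[tuple[str, str]],
                    ) -> tuple[np.ndarray, list[int]]:
    """Label vector for a list of (query, array) pairs, in request order.

    Excluded pairs are dropped; the second return value maps each kept label
    back to its index in ``pairs``. Raises for pairs outside the universe.
    """
    qidx = {g: i for i, g in enumerate(cm.query_ids)}
    aidx = {g: i for i, g in enumerate(cm.array_ids)}
    labels: list[int] = []
    index_map: list[int] = []
    for i, (qa, ab) in enumerate(pairs):
        if qa not in qidx or ab not in aidx:
            raise ValidationError(f"pair ({qa!r}, {ab!r}) outside the label universe")
        lab = cm.labels[qidx[qa], aidx[ab]]
        if lab == EXCLUDED:
            continue
        labels.append(int(lab))
        index_map.append(i)
    return np.asarray(labels, dtype=np.int8), index_map
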