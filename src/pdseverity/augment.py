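"""Bag-level augmentation on symbolic documents.

Similar same-class bag pairs are found by a positionwise Hamming distance
over chronologically ordered word sequences; new bags are synthesized by
positionwise parent crossover (mixing) and by shuffling instance order
within each activity block.  Labels are conserved by construction and every
synthetic bag records its parentage for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from pdseverity.bags import Document, Word

logger = logging.getLogger(__name__)


class IncomparablePairError(ValueError):
    """Raised when two documents share no activity with a common prefix."""


@dataclass(frozen=True)
class BagPair:
    """A same-class document pair with its Hamming distance."""

    subject_a: str
    subject_b: str
    label: int
    distance: int
    common_length: int

    def __post_init__(self) -> None:
        if self.subject_a == self.subject_b:
            raise ValueError("a pair must join two distinct subjects")
        if not 0 <= self.distance <= self.common_length:
            raise ValueError("distance must lie in [0, common_length]")


def sequence_hamming(seq_a: Sequence[int], seq_b: Sequence[int]) -> int:
    """Positionwise mismatch count over the common prefix of two sequences."""
    n = min(len(seq_a), len(seq_b))
    return int(sum(1 for i in range(n) if seq_a[i] != seq_b[i]))


def _common_blocks(
    doc_a: Document, doc_b: Document
) -> List[Tuple[int, List[Word], List[Word]]]:
    blocks_a = doc_a.activity_blocks()
    blocks_b = doc_b.activity_blocks()
    shared = sorted(set(blocks_a) & set(blocks_b))
    return [(a, blocks_a[a], blocks_b[a]) for a in shared]


def hamming_distance(doc_a: Document, doc_b: Document) -> Tuple[int, int]:
    """(distance, common_length) between two documents.

    Sequences are compared per activity over the chronological common
    prefix (unequal lengths truncated), then summed across activities.
    """
    shared = _common_blocks(doc_a, doc_b)
    common_length = sum(min(len(wa), len(wb)) for _, wa, wb in shared)
    if common_length == 0:
        raise IncomparablePairError(
            f"documents {doc_a.subject_id!r} and {doc_b.subject_id!r} share no "
            "activity with a non-empty common prefix"
        )
    distance = sum(
        sequence_hamming(
            [w.global_word_id for w in wa], [w.global_word_id for w in wb]
        )
        for _, wa, wb in shared
    )
    return distance, common_length


def select_similar_pairs(
    documents: Sequence[Document],
    neighbors_per_subject: int = 1,
) -> List[BagPair]:
    """Nearest same-class neighbors per subject, deduplicated.

    Ties in distance are broken by subject-id order; classes with a single
    subject yield no pairs.
    """
    by_class: Dict[int, List[Document]] = {}
    for doc in documents:
        if doc.label is None:
            raise ValueError(f"document {doc.subject_id!r} has no label")
        by_class.setdefault(doc.label, []).append(doc)

    pairs: Dict[Tuple[str, str], BagPair] = {}
    for label, docs in sorted(by_class.items()):
        docs = sorted(docs, key=lambda d: d.subject_id)
        if len(docs) < 2:
            logger.warning("class %d has a single subject; no pairs formed", label)
            continue
        for doc in docs:
            candidates = []
            for other in docs:
                if other.subject_id == doc.subject_id:
                    continue
                try:
                    distance, common = hamming_distance(doc, other)
                except IncomparablePairError:
                    continue
                candidates.append((distance, other.subject_id, common))
            candidates.sort()
            for distance, other_id, common in candidates[:neighbors_per_subject]:
                key = tuple(sorted((doc.subject_id, other_id)))
                if key not in pairs:
                    pairs[key] = BagPair(
                        subject_a=key[0],
                        subject_b=key[1],
                        label=label,
                        distance=distance,
                        common_length=common,
                    )
    return [pairs[k] for k in sorted(pairs)]


def mix_pair(
    pair: BagPair,
    documents: Mapping[str, Document],
    seed: int,
    child_id: Optional[str] = None,
) -> Document:
    """Positionwise 1/2-1/2 crossover of a similar same-class pair.

    Within each shared activity the child copies, at each chronological
    position of the common prefix, the word of one parent chosen uniformly;
    positions beyond the common prefix — and activities present in only one
    parent — are copied through from the longer parent.  The label is the
    parents' shared class.
    """
    doc_a = documents[pair.subject_a]
    doc_b = documents[pair.subject_b]
    if doc_a.label != doc_b.label:
        raise ValueError("parents of a mixed bag must share a label")
    rng = np.random.default_rng(seed)
    blocks_a = doc_a.activity_blocks()
    blocks_b = doc_b.activity_blocks()
    shared = set(blocks_a) & set(blocks_b)
    if not any(min(len(blocks_a[a]), len(blocks_b[a])) > 0 for a in shared):
        raise IncomparablePairError(
            f"pair ({pair.subject_a}, {pair.subject_b}) is incomparable"
        )

    words: List[Word] = []
    for activity in sorted(set(blocks_a) | set(blocks_b)):
        wa = blocks_a.get(activity, [])
        wb = blocks_b.get(activity, [])
        common = min(len(wa), len(wb))
        longer = wa if len(wa) >= len(wb) else wb
        for i in range(common):
            words.append(wa[i] if rng.random() < 0.5 else wb[i])
        words.extend(longer[common:])
    child_id = child_id or f"syn-mix-{pair.subject_a}+{pair.subject_b}"
    return Document(
        subject_id=child_id,
        words=words,
        label=doc_a.label,
        parents=(pair.subject_a, pair.subject_b),
    )


def shuffle_bag(
    document: Document, seed: int, child_id: Optional[str] = None
) -> Document:
    """Uniformly permute instance order within each activity block.

    The word multiset (and therefore the count histogram) is unchanged;
    only chronology within activities is destroyed.
    """
    if len(document) == 0:
        raise ValueError(f"document {document.subject_id!r} is empty")
    rng = np.random.default_rng(seed)
    words: List[Word] = []
    for activity in sorted(document.activity_blocks()):
        block = document.activity_blocks()[activity]
        order = rng.permutation(len(block))
        words.extend(block[i] for i in order)
    child_id = child_id or f"syn-shuffle-{document.subject_id}"
    return Document(
        subject_id=child_id,
        words=words,
        label=document.label,
        parents=(document.subject_id,),
    )


def augment_training_set(
    documents: Sequence[Document],
    seed: int,
    policy: str = "balance",
    methods: Sequence[str] = ("mix", "shuffle"),
    neighbors_per_subject: int = 1,
) -> Tuple[List[Document], List[dict]]:
    """Grow the training set with synthetic same-class bags.

    ``policy='balance'`` tops every minority class up to the majority-class
    count; ``policy='factor:<f>'`` adds round(f * class size) synthetic bags
    per class.  Originals are always retained.  Returns (documents, audit),
    where each audit entry records the child id, method, parents, and seed.
    """
    methods = tuple(methods)
    if not methods or not set(methods) <= {"mix", "shuffle"}:
        raise ValueError(f"methods must be a non-empty subset of {{mix, shuffle}}")
    by_class: Dict[int, List[Document]] = {}
    for doc in documents:
        by_class.setdefault(doc.label, []).append(doc)
    counts = {label: len(docs) for label, docs in by_class.items()}

    if policy == "balance":
        target_extra = {
            label: max(counts.values()) - n for label, n in counts.items()
        }
    elif policy.startswith("factor:"):
        factor = float(policy.split(":", 1)[1])
        if factor < 0:
            raise ValueError("augmentation factor must be non-negative")
        target_extra = {label: int(round(factor * n)) for label, n in counts.items()}
    else:
        raise ValueError(f"unknown augmentation policy {policy!r}")

    rng = np.random.default_rng(seed)
    doc_index = {d.subject_id: d for d in documents}
    augmented: List[Document] = list(documents)
    audit: List[dict] = []

    all_pairs = select_similar_pairs(documents, neighbors_per_subject)
    pairs_by_class: Dict[int, List[BagPair]] = {}
    for pair in all_pairs:
        pairs_by_class.setdefault(pair.label, []).append(pair)

    for label in sorted(by_class):
        need = target_extra[label]
        if need <= 0:
            continue
        originals = sorted(by_class[label], key=lambda d: d.subject_id)
        pairs = pairs_by_class.get(label, [])
        class_methods = list(methods)
        if len(originals) < 2 or not pairs:
            if len(originals) < 2:
                logger.warning(
                    "class %d has a single subject; using shuffle only", label
                )
            class_methods = ["shuffle"]
        made = 0
        cursor = 0
        while made < need:
            method = class_methods[made % len(class_methods)]
            child_seed = int(rng.integers(0, 2**31 - 1))
            if method == "mix":
                pair = pairs[cursor % len(pairs)]
                child = mix_pair(
                    pair,
                    doc_index,
                    seed=child_seed,
                    child_id=f"syn-mix-{label}-{made:03d}",
                )
                cursor += 1
            else:
                parent = originals[made % len(originals)]
                child = shuffle_bag(
                    parent, seed=child_seed, child_id=f"syn-shuffle-{label}-{made:03d}"
                )
            augmented.append(child)
            audit.append(
                {
                    "child": child.subject_id,
                    "method": method,
                    "parents": list(child.parents),
                    "label": label,
                    "seed": child_seed,
                }
            )
            made += 1
    return augmented, audit
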