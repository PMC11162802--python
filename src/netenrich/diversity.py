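"""Genus-level Shannon diversity of gene cluster family models.

A BiG-FAM-style model groups BGCs from many public genomes; its genus
composition tells whether the family is concentrated in one genus
(specialised pathway) or spread broadly (universal pathway, or an
artefact of over-merged clustering). The Shannon index

    H = -sum_i p_i ln p_i   (nats)

over genus proportions p_i quantifies that spread: H = 0 for a single
genus, H = ln R for a uniform spread over R genera. Downstream, models
whose top genus holds a small share (and hence high H) are removed
before network enrichment, since their membership edges would bridge
unrelated families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io import GenusCount

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelDiversity:
    model_id: str
    shannon_h: float
    top_genus: str
    top_genus_share: float
    n_genera: int
    model_size: int


def shannon_index(counts: Iterable[float]) -> float:
    """Shannon index H = -sum p ln p (nats) of a count vector.

    Zero counts contribute nothing; an all-zero vector is an error.
    """
    counts = [float(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValidationError("negative genus count")
    total = sum(counts)
    if total <= 0:
        raise ValidationError("all genus counts are zero")
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def model_diversity(table: Sequence[GenusCount]) -> list[ModelDiversity]:
    """Per-model diversity summary from a genus count table.

    ``top_genus`` is the argmax genus; ties resolve to the
    lexicographically smallest name with a warning. Models appear in the
    output sorted by model_id.
    """
    by_model: dict[str, dict[str, int]] = {}
    for row in table:
        genus_counts = by_model.setdefault(row.model_id, {})
        genus_counts[row.genus] = genus_counts.get(row.genus, 0) + row.count
    out: list[ModelDiversity] = []
    for model_id in sorted(by_model):
        genus_counts = {g: c for g, c in by_model[model_id].items() if c > 0}
        if not genus_counts:
            raise ValidationError(f"{model_id}: all genus counts are zero")
        size = sum(genus_counts.values())
        top_count = max(genus_counts.values())
        top_candidates = sorted(g for g, c in genus_counts.items() if c == top_count)
        if len(top_candidates) > 1:
            logger.warning(
                "%s: top-genus tie between %s; keeping %s",
                model_id,
                ", ".join(top_candidates),
                top_candidates[0],
            )
        out.append(
            ModelDiversity(
                model_id=model_id,
                shannon_h=shannon_index(genus_counts.values()),
                top_genus=top_candidates[0],
                top_genus_share=top_count / size,
                n_genera=len(genus_counts),
                model_size=size,
            )
        )
    return out
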