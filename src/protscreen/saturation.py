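"""In-silico single-point saturation mutagenesis with redundancy removal.

Each specified position is substituted with all 20 amino acids (wild type
included), then candidates identical to the base or to any previously
characterized sequence are removed.  Identity is full-sequence identity, not
id or mutation-string identity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .library_io import (
    AMINO_ACIDS,
    BaseConstruct,
    MutationRangeError,
    MutationSpec,
    VariantLibrary,
    VariantRecord,
    apply_mutations,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaturationSpec:
    base: BaseConstruct
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("saturation positions must be unique")
        for p in self.positions:
            self.base.residue_at(p)  # raises MutationRangeError if out of range


@dataclass
class NovelLibrary:
    """Saturation candidates surviving redundancy removal."""

    variants: list[VariantRecord]
    removed_base_identical: int
    removed_previously_characterized: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)


def generate_saturation(spec: SaturationSpec) -> list[VariantRecord]:
    """All |positions| x 20 single-substitution candidates, wild type included.

    Ids follow the ``<RefAA><Pos><AltAA>`` grammar (wild-type candidates get
    ref == alt, e.g. ``L317L``).
    """
    candidates: list[VariantRecord] = []
    for pos in spec.positions:
        ref = spec.base.residue_at(pos)
        for alt in AMINO_ACIDS:
            if alt == ref:
                seq = spec.base.sequence
                muts: tuple[MutationSpec, ...] = ()
            else:
                mut = MutationSpec(position=pos, ref_aa=ref, alt_aa=alt)
                seq = apply_mutations(spec.base, [mut])
                muts = (mut,)
            candidates.append(
                VariantRecord(id=f"{ref}{pos}{alt}", mutations=muts, sequence=seq)
            )
    return candidates


def remove_redundant(
    candidates: Sequence[VariantRecord],
    characterized: VariantLibrary | None,
    base: BaseConstruct,
) -> NovelLibrary:
    """Drop base-identical candidates and any matching characterized sequences."""
    known = (
        {r.sequence for r in characterized.records} if characterized is not None else set()
    )
    variants: list[VariantRecord] = []
    seen: set[str] = set()
    n_base = 0
    removed_known: list[str] = []
    for cand in candidates:
        if cand.sequence == base.sequence:
            n_base += 1
            continue
        if cand.sequence in known:
            removed_known.append(cand.id)
            continue
        if cand.sequence in seen:
            continue
        seen.add(cand.sequence)
        variants.append(cand)
    logger.info(
        "saturation redundancy removal: %d base-identical, %d previously "
        "characterized, %d novel variants retained",
        n_base, len(removed_known), len(variants),
    )
    return NovelLibrary(
        variants=variants,
        removed_base_identical=n_base,
        removed_previously_characterized=removed_known,
    )


def saturate(
    base: BaseConstruct,
    positions: Sequence[int],
    characterized: VariantLibrary | None = None,
) -> NovelLibrary:
    """Generate + deduplicate in one call."""
    spec = SaturationSpec(base=base, positions=tuple(positions))
    return remove_redundant(generate_saturation(spec), characterized, base)


def novel_library_as_variant_library(
    novel: NovelLibrary, base: BaseConstruct, target_attribute: str = "prediction"
) -> VariantLibrary:
    return VariantLibrary(base=base, records=list(novel.variants), target_attribute=target_attribute)


def write_removal_report(novel: NovelLibrary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_novel": len(novel.variants),
                "removed_base_identical": novel.removed_base_identical,
                "removed_previously_characterized": novel.removed_previously_characterized,
            },
            indent=2,
        )
    )
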