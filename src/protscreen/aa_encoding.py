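"""Numeric encodings of residue-letter sequence tables.

Three encodings are supported: amino-acid property scales (AAINDEX-style
per-residue indices), seed-deterministic random integer labels, and one-hot
indicators.  Property scales are read from AAINDEX-1 flat files; only scales
with a finite value for all 20 amino acids are retained for sweeps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .library_io import AMINO_ACIDS, VariantLibrary

logger = logging.getLogger(__name__)

# Column order of the two value rows following an AAINDEX-1 "I" line.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


class AAIndexParseError(ValueError):
    """Raised when an AAINDEX-1 record cannot be parsed."""


@dataclass(frozen=True)
class PropertyScale:
    """A named amino-acid -> float map (one AAINDEX index)."""

    scale_id: str
    description: str
    values: Mapping[str, float]

    @property
    def is_complete(self) -> bool:
        return all(
            aa in self.values and np.isfinite(self.values[aa]) for aa in AMINO_ACIDS
        )

    def as_array(self) -> np.ndarray:
        """Values in alphabetical amino-acid order."""
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)


@dataclass
class PropertyDictionary:
    """An ordered collection of complete property scales."""

    scales: list[PropertyScale]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.scale_id for s in self.scales]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate scale_ids in property dictionary")

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def get(self, scale_id: str) -> PropertyScale:
        for s in self.scales:
            if s.scale_id == scale_id:
                return s
        raise KeyError(f"no scale {scale_id!r} in dictionary")

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "scales": [
                    {
                        "scale_id": s.scale_id,
                        "description": s.description,
                        "values": dict(s.values),
                    }
                    for s in self.scales
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PropertyDictionary":
        d = json.loads(text)
        return cls(
            scales=[
                PropertyScale(s["scale_id"], s["description"], s["values"])
                for s in d["scales"]
            ],
            provenance=d.get("provenance", ""),
        )


@dataclass
class EncodedMatrix:
    """A numeric n x d design matrix aligned with an ordered id list."""

    variant_ids: list[str]
    matrix: np.ndarray
    encoding_kind: str  # "property" | "label" | "onehot"
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.variant_ids):
            raise ValueError("row count does not match variant_ids")


def parse_aaindex(text: str) -> tuple[list[PropertyScale], int]:
    """Parse AAINDEX-1 flat-file text.

    Returns all scales (complete or not) plus the total record count.
    Values of ``NA`` (or ``-``) become NaN, marking a scale incomplete.
    """
    scales: list[PropertyScale] = []
    current_id: str | None = None
    description = ""
    lines = iter(text.splitlines())
    for line in lines:
        if line.startswith("H "):
            current_id = line[2:].strip()
            description = ""
        elif line.startswith("D ") and current_id is not None:
            description = line[2:].strip()
        elif line.startswith("I ") and current_id is not None:
            try:
                row1 = next(lines).split()
                row2 = next(lines).split()
            except StopIteration as exc:
                raise AAIndexParseError(
                    f"truncated value rows in scale {current_id!r}"
                ) from exc
            if len(row1) != 10 or len(row2) != 10:
                raise AAIndexParseError(
                    f"scale {current_id!r}: expected 2 rows of 10 values, "
                    f"got {len(row1)} and {len(row2)}"
                )
            values: dict[str, float] = {}
            for aa_order, row in ((_AAINDEX_ROW1, row1), (_AAINDEX_ROW2, row2)):
                for aa, tok in zip(aa_order, row):
                    if tok in ("NA", "-", "NA.") or tok.startswith("NA"):
                        values[aa] = float("nan")
                    else:
                        try:
                            values[aa] = float(tok)
                        except ValueError as exc:
                            raise AAIndexParseError(
                                f"scale {current_id!r}: bad value {tok!r} for {aa}"
                            ) from exc
            scales.append(PropertyScale(current_id, description, values))
            current_id = None
    return scales, len(scales)


def load_property_dictionary(source: str | Path | None = None) -> PropertyDictionary:
    """Load an AAINDEX-1 file into a dictionary of complete scales.

    With no ``source`` the packaged curated fixture is used, so no download
    is ever required.  Incomplete scales are excluded (logged), not fatal.
    """
    if source is None:
        text = (
            resources.files("protscreen.data")
            .joinpath("aaindex_subset.txt")
            .read_text()
        )
        provenance = "packaged fixture aaindex_subset.txt"
    else:
        text = Path(source).read_text()
        provenance = str(source)
    all_scales, n_parsed = parse_aaindex(text)
    complete = [s for s in all_scales if s.is_complete]
    n_excluded = n_parsed - len(complete)
    logger.info(
        "parsed %d scales from %s; retained %d complete, excluded %d incomplete",
        n_parsed, provenance, len(complete), n_excluded,
    )
    return PropertyDictionary(scales=complete, provenance=provenance)


def _sequences(library: VariantLibrary) -> list[str]:
    return [r.sequence for r in library.records]


def encode_property(library: VariantLibrary, scale: PropertyScale) -> EncodedMatrix:
    """Elementwise scale lookup; d = L."""
    if not scale.is_complete:
        raise ValueError(f"scale {scale.scale_id!r} is incomplete; cannot encode")
    lookup = np.full(128, np.nan)
    for aa, v in scale.values.items():
        lookup[ord(aa)] = v
    seqs = _sequences(library)
    codes = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = lookup[codes].reshape(len(seqs), -1) if seqs else np.empty((0, len(library.base)))
    off = library.base.numbering_offset
    names = [f"pos{j + off}" for j in range(len(library.base))]
    return EncodedMatrix(library.ids(), mat, "property", names)


def encode_label(library: VariantLibrary, seed: int) -> EncodedMatrix:
    """Seed-deterministic random bijection of the 20 amino acids onto 0..19."""
    rng = np.random.default_rng(seed)
    codes = rng.permutation(20)
    mapping = {aa: int(c) for aa, c in zip(AMINO_ACIDS, codes)}
    scale = PropertyScale(f"label_seed{seed}", "random integer labels", mapping)
    enc = encode_property(library, scale)
    return EncodedMatrix(enc.variant_ids, enc.matrix, "label", enc.feature_names)


def encode_onehot(library: VariantLibrary) -> EncodedMatrix:
    """Position-major one-hot indicators; d = 20 * L, alphabetical AA order."""
    seqs = _sequences(library)
    L = len(library.base)
    n = len(seqs)
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    mat = np.zeros((n, 20 * L))
    for i, seq in enumerate(seqs):
        for j, aa in enumerate(seq):
            mat[i, j * 20 + aa_index[aa]] = 1.0
    off = library.base.numbering_offset
    names = [f"pos{j + off}_{aa}" for j in range(L) for aa in AMINO_ACIDS]
    return EncodedMatrix(library.ids(), mat, "onehot", names)


def write_encoded_csv(encoded: EncodedMatrix, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(encoded.matrix, columns=encoded.feature_names)
    df.insert(0, "id", encoded.variant_ids)
    df.to_csv(path, index=False)


def random_scales(
    n: int, seed: int, *, prefix: str = "RAND", low: float = -2.0, high: float = 2.0
) -> list[PropertyScale]:
    """Seeded uniform-random decoy scales (complete by construction)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        vals = {aa: float(v) for aa, v in zip(AMINO_ACIDS, rng.uniform(low, high, 20))}
        out.append(PropertyScale(f"{prefix}{i:03d}", "random decoy scale", vals))
    return out
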