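"""Variant library parsing, validation, deduplication, normalization and splitting.

A variant library is a set of mutants defined relative to a single base
construct by mutation strings such as ``"L317H;Q305D"``.  Sequences are
lifted to full length before any downstream use, so the full amino-acid
sequence (not the mutation string) is the identity of a variant.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
_AA_SET = frozenset(AMINO_ACIDS)

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class LibraryError(ValueError):
    """Base error for variant-library violations."""


class MutationFormatError(LibraryError):
    """Raised when a mutation token does not parse."""


class MutationRangeError(LibraryError):
    """Raised when a mutation position falls outside the construct."""


class MutationConsistencyError(LibraryError):
    """Raised when a mutation's reference residue disagrees with the base."""


@dataclass(frozen=True)
class BaseConstruct:
    """A named base amino-acid sequence with a numbering offset."""

    name: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise LibraryError("base construct sequence must be non-empty")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise LibraryError(
                f"non-canonical letters in base construct {self.name!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a position expressed in construct numbering."""
        idx = position - self.numbering_offset
        if not 0 <= idx < len(self.sequence):
            raise MutationRangeError(
                f"position {position} outside construct "
                f"[{self.numbering_offset}, {self.numbering_offset + len(self.sequence) - 1}]"
            )
        return self.sequence[idx]


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single substitution in construct numbering, e.g. L317H."""

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in _AA_SET:
                raise MutationFormatError(f"non-canonical amino acid {aa!r}")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @classmethod
    def parse(cls, token: str) -> "MutationSpec":
        m = _MUTATION_RE.match(token.strip())
        if m is None:
            raise MutationFormatError(f"unparseable mutation token {token!r}")
        ref, pos, alt = m.groups()
        return cls(position=int(pos), ref_aa=ref.upper(), alt_aa=alt.upper())


@dataclass(frozen=True)
class VariantRecord:
    """One variant: id, mutations, lifted full sequence, measured phenotypes."""

    id: str
    mutations: tuple[MutationSpec, ...]
    sequence: str
    phenotypes: Mapping[str, float] = field(default_factory=dict)


@dataclass
class VariantLibrary:
    base: BaseConstruct
    records: list[VariantRecord]
    target_attribute: str

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, variant_id: str) -> VariantRecord:
        for r in self.records:
            if r.id == variant_id:
                return r
        raise KeyError(f"no variant with id {variant_id!r}")

    def target_values(self) -> np.ndarray:
        return np.array(
            [r.phenotypes[self.target_attribute] for r in self.records], dtype=float
        )

    def subset(self, ids: Sequence[str]) -> "VariantLibrary":
        wanted = set(ids)
        return VariantLibrary(
            base=self.base,
            records=[r for r in self.records if r.id in wanted],
            target_attribute=self.target_attribute,
        )


@dataclass(frozen=True)
class SplitLibrary:
    """A reproducible train/test partition of a library's ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "ratio": self.ratio,
                "seed": self.seed,
                "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitLibrary":
        d = json.loads(text)
        return cls(
            train_ids=tuple(d["train_ids"]),
            test_ids=tuple(d["test_ids"]),
            ratio=d["ratio"],
            seed=d["seed"],
        )


def apply_mutations(base: BaseConstruct, mutations: Iterable[MutationSpec]) -> str:
    """Lift a mutation list to a full-length sequence.

    Raises
    ------
    MutationRangeError
        If any position is outside the construct.
    MutationConsistencyError
        If a mutation's ``ref_aa`` does not match the base sequence.
    """
    seq = list(base.sequence)
    for mut in mutations:
        actual = base.residue_at(mut.position)
        if actual != mut.ref_aa:
            raise MutationConsistencyError(
                f"mutation {mut} inconsistent: base {base.name!r} has "
                f"{actual!r} at position {mut.position}"
            )
        seq[mut.position - base.numbering_offset] = mut.alt_aa
    return "".join(seq)


def diff_against_base(base: BaseConstruct, sequence: str) -> tuple[MutationSpec, ...]:
    """Recover the mutation list of a full sequence relative to the base."""
    if len(sequence) != len(base):
        raise LibraryError(
            f"sequence length {len(sequence)} != base length {len(base)}"
        )
    muts = []
    for i, (ref, alt) in enumerate(zip(base.sequence, sequence)):
        if ref != alt:
            muts.append(
                MutationSpec(position=i + base.numbering_offset, ref_aa=ref, alt_aa=alt)
            )
    return tuple(muts)


def parse_mutation_string(text: str, delimiter: str = ";") -> tuple[MutationSpec, ...]:
    """Parse ``"L317H;Q305D"`` style mutation lists; empty string means wild type."""
    text = text.strip()
    if not text:
        return ()
    return tuple(MutationSpec.parse(tok) for tok in text.split(delimiter) if tok.strip())


def parse_variant_table(
    rows: pd.DataFrame,
    base: BaseConstruct,
    target: str,
    *,
    delimiter: str = ";",
    id_column: str = "id",
    mutations_column: str = "mutations",
) -> VariantLibrary:
    """Build a :class:`VariantLibrary` from a tabular mutation list.

    Rows missing the target phenotype are dropped with a logged warning.
    Phenotype columns are every column other than the id and mutation columns.
    """
    phenotype_cols = [c for c in rows.columns if c not in (id_column, mutations_column)]
    if target not in phenotype_cols:
        raise LibraryError(f"target attribute {target!r} not among columns {phenotype_cols}")
    records: list[VariantRecord] = []
    n_dropped = 0
    for _, row in rows.iterrows():
        rid = str(row[id_column])
        try:
            muts = parse_mutation_string(str(row[mutations_column]), delimiter=delimiter)
        except MutationFormatError as exc:
            raise MutationFormatError(f"row {rid!r}: {exc}") from exc
        seq = apply_mutations(base, muts)
        phen = {}
        for col in phenotype_cols:
            val = row[col]
            if pd.notna(val):
                phen[col] = float(val)
        if target not in phen:
            n_dropped += 1
            logger.warning("variant %r has no %r value; excluded", rid, target)
            continue
        records.append(VariantRecord(id=rid, mutations=muts, sequence=seq, phenotypes=phen))
    if n_dropped:
        logger.info("dropped %d records missing target %r", n_dropped, target)
    return VariantLibrary(base=base, records=records, target_attribute=target)


def sequence_table(library: VariantLibrary) -> pd.DataFrame:
    """The flat model-training table: 1 id column + L residue columns + 1 target.

    For a base of length 451 this is the canonical 453-column layout.
    """
    L = len(library.base)
    off = library.base.numbering_offset
    cols = {"id": library.ids()}
    seq_array = np.array([list(r.sequence) for r in library.records])
    for j in range(L):
        cols[f"pos{j + off}"] = seq_array[:, j] if len(library.records) else []
    cols[library.target_attribute] = library.target_values()
    return pd.DataFrame(cols)


def deduplicate_average(library: VariantLibrary) -> VariantLibrary:
    """Collapse records with identical full sequences, averaging phenotypes.

    The surviving record keeps the lexicographically smallest member id.
    Idempotent.
    """
    groups: dict[str, list[VariantRecord]] = {}
    order: list[str] = []
    for r in library.records:
        if r.sequence not in groups:
            order.append(r.sequence)
        groups.setdefault(r.sequence, []).append(r)
    merged = []
    for seq in order:
        members = groups[seq]
        if len(members) == 1:
            merged.append(members[0])
            continue
        keeper = min(members, key=lambda r: r.id)
        keys = set().union(*(m.phenotypes.keys() for m in members))
        phen = {
            k: float(np.mean([m.phenotypes[k] for m in members if k in m.phenotypes]))
            for k in keys
        }
        merged.append(replace(keeper, phenotypes=phen))
    n_collapsed = len(library.records) - len(merged)
    if n_collapsed:
        logger.info("deduplication collapsed %d duplicate records", n_collapsed)
    return VariantLibrary(base=library.base, records=merged, target_attribute=library.target_attribute)


def normalize_to_reference(library: VariantLibrary, reference_id: str) -> VariantLibrary:
    """Divide every phenotype by the reference variant's value, per attribute.

    The reference ends up at exactly 1.0 for every attribute it carries.
    """
    ref = library.record(reference_id)  # KeyError if absent
    ref_vals = dict(ref.phenotypes)
    for attr, v in ref_vals.items():
        if v == 0:
            raise ZeroDivisionError(
                f"reference {reference_id!r} has zero value for {attr!r}"
            )
    records = []
    for r in library.records:
        phen = {
            k: (v / ref_vals[k] if k in ref_vals else v) for k, v in r.phenotypes.items()
        }
        records.append(replace(r, phenotypes=phen))
    return VariantLibrary(base=library.base, records=records, target_attribute=library.target_attribute)


def split_train_test(library: VariantLibrary, ratio: float = 0.8, seed: int = 42) -> SplitLibrary:
    """Deterministic shuffled partition; train size = floor(ratio * n)."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(library.records)
    if n < 2:
        raise LibraryError(f"need at least 2 records to split, have {n}")
    ids = np.array(library.ids())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    train = tuple(ids[perm[:n_train]])
    test = tuple(ids[perm[n_train:]])
    return SplitLibrary(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# File I/O

def read_base_construct(path: str | Path, numbering_offset: int = 1) -> BaseConstruct:
    """Read a single-record FASTA file as the base construct."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise LibraryError(f"expected exactly 1 FASTA record in {path}, found {len(records)}")
    rec = records[0]
    return BaseConstruct(name=rec.id, sequence=str(rec.seq).upper(), numbering_offset=numbering_offset)


def write_base_construct(base: BaseConstruct, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{base.name}\n")
        for i in range(0, len(base.sequence), 60):
            fh.write(base.sequence[i : i + 60] + "\n")


def read_variant_table(
    path: str | Path,
    base: BaseConstruct,
    target: str,
    *,
    delimiter: str = ";",
    source_name: str | None = None,
) -> VariantLibrary:
    """Read a ``id,mutations,<phenotypes>`` CSV/TSV into a library.

    ``source_name`` optionally namespaces ids (``source:id``) so records from
    different source tables can never collide.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    rows = pd.read_csv(path, sep=sep, dtype={"id": str, "mutations": str})
    rows["mutations"] = rows["mutations"].fillna("")
    if source_name:
        rows["id"] = [f"{source_name}:{i}" for i in rows["id"]]
    return parse_variant_table(rows, base, target, delimiter=delimiter)


def write_variant_table(library: VariantLibrary, path: str | Path, *, delimiter: str = ";") -> None:
    attrs: list[str] = []
    for r in library.records:
        for k in r.phenotypes:
            if k not in attrs:
                attrs.append(k)
    rows = []
    for r in library.records:
        row = {"id": r.id, "mutations": delimiter.join(str(m) for m in r.mutations)}
        for a in attrs:
            row[a] = r.phenotypes.get(a, np.nan)
        rows.append(row)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def merge_libraries(libraries: Sequence[VariantLibrary], base: BaseConstruct, target: str) -> VariantLibrary:
    """Merge libraries (possibly lifted from different bases) on full sequence.

    Sequences must all have the base's length; dedup-average afterwards to
    collapse cross-library duplicates.
    """
    records: list[VariantRecord] = []
    for lib in libraries:
        for r in lib.records:
            if len(r.sequence) != len(base):
                raise LibraryError(
                    f"record {r.id!r} length {len(r.sequence)} != merge base length {len(base)}"
                )
            records.append(
                replace(r, mutations=diff_against_base(base, r.sequence))
            )
    return deduplicate_average(
        VariantLibrary(base=base, records=records, target_attribute=target)
    )
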