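"""Synthetic genotype-phenotype libraries and fluorescence traces.

Libraries are point mutants of a (random or supplied) base construct whose
phenotype is an additive function of a chosen true property scale evaluated
at the mutated positions, plus Gaussian noise.  Every generator is fully
determined by its config's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aa_encoding import PropertyDictionary, PropertyScale
from .library_io import (
    AMINO_ACIDS,
    BaseConstruct,
    MutationSpec,
    VariantLibrary,
    VariantRecord,
    apply_mutations,
)
from .traces import DEFAULT_BASELINE_WINDOW, FluorescenceTrace

logger = logging.getLogger(__name__)


@dataclass
class SyntheticLibraryConfig:
    true_scale_id: str
    n_variants: int = 600
    base_length: int = 451
    n_mutable_positions: int = 75
    mutable_positions: tuple[int, ...] | None = None  # overrides the count
    effect_size: float = 0.5
    intercept: float = 1.0
    noise_sd: float = 0.1
    multi_mutation_rate: float = 0.0
    target_attribute: str = "phenotype"
    seed: int = 0


@dataclass
class SyntheticTraceConfig:
    baseline_level: float = 100.0
    peak_dff_percent: float = 200.0
    lambda_: float = 0.5
    sampling_rate_hz: float = 20.0
    duration_s: float = 30.0
    baseline_s: float | None = None  # default: baseline window worth of samples
    noise_sd: float = 0.0
    baseline_window: int = DEFAULT_BASELINE_WINDOW
    seed: int = 0


def random_base_construct(length: int, seed: int, name: str = "synthetic_base") -> BaseConstruct:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return BaseConstruct(name=name, sequence=seq)


def _phenotype(
    base: BaseConstruct, mutations: Sequence[MutationSpec], scale: PropertyScale,
    effect_size: float, intercept: float,
) -> float:
    delta = sum(scale.values[m.alt_aa] - scale.values[m.ref_aa] for m in mutations)
    return intercept + effect_size * delta


def simulate_library(
    config: SyntheticLibraryConfig,
    dictionary: PropertyDictionary,
    base: BaseConstruct | None = None,
) -> VariantLibrary:
    """Random point mutants with additive property-driven phenotypes.

    The base construct is included as a record ("base") with its noiseless
    phenotype.  Distinct mutants are sampled without replacement; a request
    exceeding the distinct-mutant count is capped with a warning.
    """
    scale = dictionary.get(config.true_scale_id)
    rng = np.random.default_rng(config.seed)
    if base is None:
        base = random_base_construct(config.base_length, config.seed)
    if config.mutable_positions is not None:
        positions = tuple(config.mutable_positions)
    else:
        off = base.numbering_offset
        n_pos = config.n_mutable_positions
        if n_pos > len(base):
            logger.warning(
                "n_mutable_positions %d exceeds base length %d; capped", n_pos, len(base)
            )
            n_pos = len(base)
        positions = tuple(
            sorted(
                rng.choice(
                    np.arange(off, off + len(base)), size=n_pos, replace=False
                )
            )
        )
    for p in positions:
        base.residue_at(p)  # range check

    # enumerate all single mutants at the mutable positions
    singles: list[MutationSpec] = []
    for pos in positions:
        ref = base.residue_at(pos)
        singles.extend(
            MutationSpec(position=pos, ref_aa=ref, alt_aa=alt)
            for alt in AMINO_ACIDS
            if alt != ref
        )
    n_singles = len(singles)
    n = config.n_variants
    if config.multi_mutation_rate == 0 and n > n_singles:
        logger.warning(
            "requested %d variants but only %d distinct single mutants; capped",
            n, n_singles,
        )
        n = n_singles

    records: list[VariantRecord] = []
    seen: set[str] = set()
    single_order = rng.permutation(n_singles)
    cursor = 0
    attempts = 0
    max_attempts = 50 * max(n, 1)
    while len(records) < n and attempts < max_attempts:
        attempts += 1
        if rng.uniform() < config.multi_mutation_rate:
            k = int(rng.integers(2, 4))
            pos_pick = rng.choice(len(positions), size=min(k, len(positions)), replace=False)
            muts = []
            for pi in sorted(pos_pick):
                pos = positions[pi]
                ref = base.residue_at(pos)
                alt = rng.choice([a for a in AMINO_ACIDS if a != ref])
                muts.append(MutationSpec(position=pos, ref_aa=ref, alt_aa=str(alt)))
            muts = tuple(muts)
        else:
            if cursor >= n_singles:
                break
            muts = (singles[single_order[cursor]],)
            cursor += 1
        seq = apply_mutations(base, muts)
        if seq in seen or seq == base.sequence:
            continue
        seen.add(seq)
        value = _phenotype(base, muts, scale, config.effect_size, config.intercept)
        value += float(rng.normal(0, config.noise_sd))
        records.append(
            VariantRecord(
                id=";".join(str(m) for m in muts),
                mutations=muts,
                sequence=seq,
                phenotypes={config.target_attribute: value},
            )
        )
    records.append(
        VariantRecord(
            id="base",
            mutations=(),
            sequence=base.sequence,
            phenotypes={config.target_attribute: config.intercept},
        )
    )
    return VariantLibrary(base=base, records=records, target_attribute=config.target_attribute)


def simulate_trace(config: SyntheticTraceConfig) -> FluorescenceTrace:
    """Baseline segment, instantaneous rise to the peak, exponential decay."""
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate_hz
    n_total = int(round(config.duration_s * config.sampling_rate_hz))
    if config.baseline_s is None:
        n_base = config.baseline_window
    else:
        n_base = int(round(config.baseline_s * config.sampling_rate_hz))
    if not 0 < n_base < n_total - 2:
        raise ValueError(
            f"baseline ({n_base} samples) must leave room for a response "
            f"within the {n_total}-sample trace"
        )
    times = np.arange(n_total) * dt
    f0 = config.baseline_level
    fmax = f0 * (1.0 + config.peak_dff_percent / 100.0)
    intensities = np.empty(n_total)
    intensities[:n_base] = f0
    t_decay = times[n_base:] - times[n_base]
    intensities[n_base:] = f0 + (fmax - f0) * np.exp(-config.lambda_ * t_decay)
    if config.noise_sd > 0:
        intensities = intensities + rng.normal(0, config.noise_sd, n_total)
    else:
        # a noiseless flat baseline has zero sd; add an infinitesimal,
        # deterministic ripple so SNR stays defined
        intensities[: n_base] += 1e-9 * np.cos(np.arange(n_base))
    return FluorescenceTrace(
        times=times, intensities=intensities, baseline_window=config.baseline_window
    )
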