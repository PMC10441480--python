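"""Statistics over ensemble predictions: deltas vs the base construct,
per-variant t-tests across contributor predictions, sigma bands on
-log10(p), and residue prevalence in the prediction extremes.

Caveat: the contributor predictions entering each t-test are not independent
samples — the resulting p-values are heuristic ranking scores for volcano
displays, not calibrated inference.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import PredictionRecord
from .library_io import VariantLibrary

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # avoids -log10 infinities


@dataclass(frozen=True)
class DeltaRecord:
    variant_id: str
    delta: float
    t_statistic: float
    p_value: float
    neg_log10_p: float


@dataclass(frozen=True)
class SigmaBand:
    mean: float
    sd: float
    k: float = 3.0

    @property
    def lower(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.k * self.sd

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass
class PrevalenceTable:
    """Counts of each residue position appearing in prediction extremes."""

    top_counts: dict[int, int]
    bottom_counts: dict[int, int]
    fraction: float
    n_contributors: int
    n_variants: int

    def total(self) -> int:
        return sum(self.top_counts.values()) + sum(self.bottom_counts.values())

    def to_frame(self) -> pd.DataFrame:
        positions = sorted(set(self.top_counts) | set(self.bottom_counts))
        total = self.total()
        rows = []
        for pos in positions:
            top = self.top_counts.get(pos, 0)
            bot = self.bottom_counts.get(pos, 0)
            rows.append(
                {
                    "position": pos,
                    "top_count": top,
                    "bottom_count": bot,
                    "share": (top + bot) / total if total else 0.0,
                }
            )
        return pd.DataFrame(rows)


def predicted_change(record: PredictionRecord, base_record: PredictionRecord) -> float:
    """Mean-prediction difference from the base construct."""
    return record.mean_prediction - base_record.mean_prediction


def test_vs_base(
    record: PredictionRecord,
    base_record: PredictionRecord,
    *,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided unpaired t-test between two contributor-prediction vectors.

    Student's pooled-variance test by default (df = n1 + n2 - 2); Welch via
    ``equal_var=False``.  Zero pooled variance: p = 1 if the means are equal,
    else the p-value floor (logged).
    """
    a = np.asarray(record.contributor_predictions, dtype=float)
    b = np.asarray(base_record.contributor_predictions, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each side needs >= 2 predictions")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means: p floored")
        return math.copysign(math.inf, a.mean() - b.mean()), P_FLOOR
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(max(p, P_FLOOR))


def delta_records(
    predictions: Sequence[PredictionRecord],
    base_record: PredictionRecord,
    *,
    equal_var: bool = True,
) -> list[DeltaRecord]:
    out = []
    for rec in predictions:
        t, p = test_vs_base(rec, base_record, equal_var=equal_var)
        out.append(
            DeltaRecord(
                variant_id=rec.variant_id,
                delta=predicted_change(rec, base_record),
                t_statistic=t,
                p_value=p,
                neg_log10_p=-math.log10(p),
            )
        )
    return out


def sigma_band(values: Sequence[float], k: float = 3.0) -> SigmaBand:
    """Sample mean +/- k * sample sd (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values for a sigma band")
    return SigmaBand(mean=float(v.mean()), sd=float(v.std(ddof=1)), k=k)


def prevalence_counts(
    predictions: Sequence[PredictionRecord],
    variant_positions: Mapping[str, Sequence[int]],
    fraction: float = 0.025,
    *,
    mode: str = "per_contributor",
) -> PrevalenceTable:
    """Count mutated-position appearances in the top/bottom prediction tails.

    For each contributor model independently (default), its predictions over
    the library are ranked and the ceil(fraction * n) highest and lowest
    variants are taken; each such variant's mutated positions are tallied.
    ``mode="ensemble_mean"`` ranks the mean predictions once instead.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    if mode not in ("per_contributor", "ensemble_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(predictions)
    ids = [r.variant_id for r in predictions]
    if mode == "per_contributor":
        mat = np.array([r.contributor_predictions for r in predictions], dtype=float).T
    else:
        mat = np.array([[r.mean_prediction for r in predictions]], dtype=float)
    m = math.ceil(fraction * n)
    top: dict[int, int] = {}
    bottom: dict[int, int] = {}
    for row in mat:
        order = np.argsort(row, kind="stable")
        for i in order[-m:]:
            for pos in variant_positions[ids[i]]:
                top[pos] = top.get(pos, 0) + 1
        for i in order[:m]:
            for pos in variant_positions[ids[i]]:
                bottom[pos] = bottom.get(pos, 0) + 1
    return PrevalenceTable(
        top_counts=top,
        bottom_counts=bottom,
        fraction=fraction,
        n_contributors=mat.shape[0],
        n_variants=n,
    )


def position_share(library: VariantLibrary, position: int) -> float:
    """Percent of library variants carrying a mutation at a position."""
    n = len(library.records)
    if n == 0:
        raise ValueError("empty library")
    count = sum(
        1 for r in library.records if any(m.position == position for m in r.mutations)
    )
    return 100.0 * count / n


def mutated_positions(library: VariantLibrary) -> dict[str, tuple[int, ...]]:
    return {r.id: tuple(m.position for m in r.mutations) for r in library.records}


def volcano_table(
    deltas: Sequence[DeltaRecord], band: SigmaBand | None = None
) -> pd.DataFrame:
    """Export rows for a volcano display, flagging points outside the band."""
    rows = []
    for d in deltas:
        row = {
            "id": d.variant_id,
            "delta": d.delta,
            "t": d.t_statistic,
            "p": d.p_value,
            "neg_log10_p": d.neg_log10_p,
        }
        if band is not None:
            row["outside_band"] = not band.contains(d.neg_log10_p)
        rows.append(row)
    return pd.DataFrame(rows)
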