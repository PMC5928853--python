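"""The filter-bank benchmark: grid evaluation, normalization, ranking.

For each filter configuration in the bank, every labeled record is filtered
zero-phase and scored with the windowed skewness index; the grid cell
(family, order, group) is the arithmetic mean of record scores over that
quality group.  Scores are then min–max normalized per group across the
configurations, and configurations are ranked by the sum of their three
normalized group scores (the height of a stacked per-group bar).  Ties
break toward the lower order (lower orders mean less computation on a
wearable device), then alphabetically by family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filters import BandSpec, DEFAULT_BAND, FilterSpec, apply_zero_phase, design_filter
from .records import PPGRecord, QUALITY_LABELS
from .sqi import windowed_sqi

__all__ = [
    "BenchmarkResult",
    "run_benchmark",
    "normalize_scores",
    "rank_configurations",
    "report",
]

_GRID_COLUMNS = ["family", "order_param", "group", "mean_sqi"]


@dataclass(frozen=True)
class BenchmarkResult:
    """Benchmark outputs.

    ``grid`` has one row per (family, order_param, group) with the group's
    mean record SQI after filtering; ``norm_grid`` adds a ``norm_sqi``
    column in [0, 1] (per-group min–max over configurations; populated by
    :func:`normalize_scores`).  ``ranking`` is the full configuration list
    ordered best-first with combined scores (populated by
    :func:`rank_configurations`).  ``raw_group_sqi`` holds the unfiltered
    per-group means for reference.
    """

    raw_group_sqi: Dict[str, float]
    grid: pd.DataFrame
    band: BandSpec
    fs: float
    window_len_s: float
    n_records: Dict[str, int]
    norm_grid: Optional[pd.DataFrame] = None
    ranking: Optional[List[Tuple[FilterSpec, float]]] = None


def run_benchmark(
    records: Sequence[PPGRecord],
    bank: Sequence[FilterSpec],
    fs: float,
    band: BandSpec = DEFAULT_BAND,
    window_len_s: float = 1.0,
) -> BenchmarkResult:
    """Evaluate every configuration of the bank on a labeled dataset.

    Raises
    ------
    ValueError
        If the bank is empty, any record is unlabeled (offending ids are
        listed), records disagree on sampling rate, or a group is empty
        (its mean would be undefined).
    """
    if len(bank) == 0:
        raise ValueError("filter bank is empty")
    if len(records) == 0:
        raise ValueError("no records to benchmark")
    unlabeled = [
        f"{r.subject_id}/{r.segment_id}" for r in records if r.label not in QUALITY_LABELS
    ]
    if unlabeled:
        raise ValueError(f"benchmark requires labeled records; unlabeled: {unlabeled}")
    if any(r.fs != fs for r in records):
        raise ValueError(f"all records must share fs={fs} Hz")

    groups: Dict[str, List[PPGRecord]] = {g: [] for g in QUALITY_LABELS}
    for r in records:
        groups[r.label].append(r)
    empty = [g for g, rs in groups.items() if not rs]
    if empty:
        raise ValueError(f"empty group(s) {empty}: group means undefined")

    raw_group_sqi = {
        g: float(np.mean([windowed_sqi(r, window_len_s).record_sqi for r in rs]))
        for g, rs in groups.items()
    }

    rows = []
    for spec in bank:
        designed = design_filter(spec, fs=fs, band=band)
        scores: Dict[str, float] = {}
        for g, rs in groups.items():
            vals = [
                windowed_sqi(apply_zero_phase(designed, r), window_len_s).record_sqi
                for r in rs
            ]
            scores[g] = float(np.mean(vals))
        for g in QUALITY_LABELS:
            rows.append(
                {
                    "family": spec.family,
                    "order_param": spec.order_param,
                    "group": g,
                    "mean_sqi": scores[g],
                }
            )
    grid = pd.DataFrame(rows, columns=_GRID_COLUMNS)
    return BenchmarkResult(
        raw_group_sqi=raw_group_sqi,
        grid=grid,
        band=band,
        fs=fs,
        window_len_s=window_len_s,
        n_records={g: len(rs) for g, rs in groups.items()},
    )


def normalize_scores(result: BenchmarkResult) -> BenchmarkResult:
    """Min–max normalize the grid per group across configurations.

    Within each group g, ``norm = (cell - min_g) / (max_g - min_g)`` over
    the configurations; a degenerate group (all cells equal) maps to 0.
    """
    grid = result.grid
    if grid.empty:
        raise ValueError("grid is empty; run the benchmark first")
    norm = grid.copy()

    def _mm(s: pd.Series) -> pd.Series:
        lo, hi = s.min(), s.max()
        if hi == lo:
            return pd.Series(np.zeros(len(s)), index=s.index)
        return (s - lo) / (hi - lo)

    norm["norm_sqi"] = norm.groupby("group")["mean_sqi"].transform(_mm)
    return replace(result, norm_grid=norm)


def rank_configurations(result: BenchmarkResult) -> List[Tuple[FilterSpec, float]]:
    """Order configurations by combined score, best first.

    The combined score of a configuration is the sum over the three groups
    of its normalized mean SQI — the total height of its stacked bar.  Ties
    break by lower order, then family name.
    """
    if result.norm_grid is None:
        raise ValueError("norm_grid not populated; call normalize_scores first")
    combined = (
        result.norm_grid.groupby(["family", "order_param"], sort=False)["norm_sqi"]
        .sum()
        .reset_index(name="combined")
    )
    combined = combined.sort_values(
        by=["combined", "order_param", "family"], ascending=[False, True, True]
    )
    return [
        (FilterSpec(family=row.family, order_param=row.order_param), float(row.combined))
        for row in combined.itertuples(index=False)
    ]


def report(result: BenchmarkResult, out_path) -> Path:
    """Write the benchmark report CSV plus a plain-text summary.

    The CSV has one row per (configuration, group) — 270 rows for the full
    bank — with columns family, order_param, group, mean_sqi, norm_sqi,
    combined_score, rank.  The summary (same stem, ``.txt``) names the
    top-ranked configuration.  Returns the CSV path.
    """
    if result.norm_grid is None or result.norm_grid.empty:
        raise ValueError("result incomplete: normalized grid missing")
    ranking = result.ranking if result.ranking is not None else rank_configurations(result)

    rank_of = {
        (spec.family, spec.order_param): (i + 1, score)
        for i, (spec, score) in enumerate(ranking)
    }
    table = result.norm_grid.copy()
    table["combined_score"] = [
        rank_of[(f, o)][1] for f, o in zip(table["family"], table["order_param"])
    ]
    table["rank"] = [rank_of[(f, o)][0] for f, o in zip(table["family"], table["order_param"])]

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False, float_format="%.17g")

    best_spec, best_score = ranking[0]
    summary = out_path.with_suffix(".txt")
    lines = [
        "PPG filter benchmark summary",
        f"band: {result.band.f_low}-{result.band.f_high} Hz at fs={result.fs} Hz; "
        f"window {result.window_len_s} s",
        "records per group: "
        + ", ".join(f"{g}={n}" for g, n in sorted(result.n_records.items())),
        "raw mean SQI per group: "
        + ", ".join(f"{g}={v:.4f}" for g, v in sorted(result.raw_group_sqi.items())),
        f"top configuration: {best_spec.family} order {best_spec.order_param} "
        f"(combined normalized score {best_score:.4f})",
    ]
    summary.write_text("\n".join(lines) + "\n")
    return out_path
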