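"""Design scoring and selection.

The library never runs external modelling or relax programs; it consumes
per-design score tables (TSV) produced outside — a comparative-modelling
statistical potential ("dope", arbitrary energy units) and an
energy-minimization total score ("fastrelax", Rosetta energy units).
Both metrics use lower values for higher predicted stability.  Two
selection strategies are supported: joint (rank all multi-loop designs
at once) and sequential grafting (fix the best-scoring single-loop
design, then enumerate and score the second loop on that background).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .grafting import DesignSet
from .pairing import Pairing

METRICS = ("dope", "fastrelax")


@dataclass(frozen=True)
class ScoreRecord:
    design_id: str
    dope: float | None = None
    fastrelax: float | None = None

    def __post_init__(self) -> None:
        if self.dope is None and self.fastrelax is None:
            raise ValueError(f"{self.design_id}: at least one score required")

    def get(self, metric: str) -> float:
        value = getattr(self, metric)
        if value is None:
            raise ValueError(f"{self.design_id}: no {metric} score")
        return value


@dataclass(frozen=True)
class SelectionStrategy:
    mode: str = "joint"        # "joint" or "sequential"
    metric: str = "dope"
    k: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("joint", "sequential"):
            raise ValueError("mode must be 'joint' or 'sequential'")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def ingest_scores(tsv_text: str,
                  designs: DesignSet | None = None) -> list[ScoreRecord]:
    """Parse a score table with a ``design_id`` column plus one or both
    metric columns; missing cells are allowed.  Duplicate ids, and ids
    unknown to a provided design set, raise."""
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype={"design_id": str})
    if "design_id" not in df.columns:
        raise ValueError("score table must have a 'design_id' column")
    if not any(m in df.columns for m in METRICS):
        raise ValueError(f"score table needs at least one of {METRICS}")
    dup = df["design_id"][df["design_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate design ids: {sorted(set(dup))}")
    if designs is not None:
        known = {d.design_id for d in designs.designs}
        unknown = sorted(set(df["design_id"]) - known)
        if unknown:
            raise KeyError(f"score table names unknown designs: {unknown}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ScoreRecord(
                design_id=row["design_id"],
                dope=None if "dope" not in df.columns or pd.isna(row.get("dope"))
                else float(row["dope"]),
                fastrelax=None if "fastrelax" not in df.columns
                or pd.isna(row.get("fastrelax"))
                else float(row["fastrelax"]),
            )
        )
    return records


def rank(records: list[ScoreRecord], metric: str) -> list[ScoreRecord]:
    """Ascending by score (lower = more stable); ties broken by id."""
    return sorted(records, key=lambda r: (r.get(metric), r.design_id))


def select_topk(records: list[ScoreRecord],
                strategy: SelectionStrategy) -> list[str]:
    """Ids of the first k designs under the strategy's metric."""
    if not records:
        raise ValueError("no score records to select from")
    ordered = rank(records, strategy.metric)
    if strategy.k > len(ordered):
        warnings.warn(
            f"k={strategy.k} exceeds {len(ordered)} scored designs; "
            "returning all", stacklevel=2,
        )
    return [r.design_id for r in ordered[:strategy.k]]


def sequential_select(base_scores: list[ScoreRecord], metric: str,
                      second_loop_enumerator: Callable[[str], DesignSet]
                      ) -> DesignSet:
    """Sequential grafting: pick the metric-best single-loop design, then
    enumerate the second loop on that fixed background.  The returned set
    is handed back for external scoring."""
    if not base_scores:
        raise ValueError("empty base design set")
    best = rank(base_scores, metric)[0]
    return second_loop_enumerator(best.design_id)


def flexibility_delta(chimera_normalized: np.ndarray,
                      template_normalized: np.ndarray,
                      pairing: Pairing) -> np.ndarray:
    """Per-chimera-residue difference of min-max-normalized flexibility
    profiles, chimera minus template at paired positions; unpaired
    chimera positions are NaN (reported as missing)."""
    chim = np.asarray(chimera_normalized, dtype=float)
    temp = np.asarray(template_normalized, dtype=float)
    delta = np.full(len(chim), np.nan)
    for p in pairing.pairs:
        delta[p.i] = chim[p.i] - temp[p.j]
    return delta


def selection_report(records: list[ScoreRecord],
                     designs: DesignSet) -> pd.DataFrame:
    """Score summary table: one row per scored design with its grafted
    loops and insert segments."""
    by_id = {d.design_id: d for d in designs.designs}
    rows = []
    for r in records:
        d = by_id.get(r.design_id)
        rows.append(
            {
                "design_id": r.design_id,
                "loops": "+".join(f"L{w.loop_id}" for w in d.windows)
                if d else "",
                "dope": r.dope,
                "fastrelax": r.fastrelax,
                "inserts": ";".join(d.insert_segments) if d else "",
            }
        )
    return pd.DataFrame(rows)
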