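"""Stage-trajectory analysis between two checkup years.

A CKD stage is treated as an integer coordinate on the 4 x 4
(G category, dipstick grade) grid with G1 P(-) at the origin, so the
change between two years is a vector whose components are stage-unit
differences; per-baseline-stage mean vectors summarise the direction of
drift, and the 16 x 16 transition matrix gives the full year-pair
cross-tabulation.  All analyses are complete-case per year pair: a subject
contributes iff it has a staged record in both years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .staging import (
    CKDStage,
    Dipstick,
    GCategory,
    PrognosticCategory,
    round_half_up_pct,
)

__all__ = ["StageVector", "TransitionMatrix", "stage_to_coord",
           "change_vector", "year_pair", "mean_vectors_by_stage",
           "transition_matrix", "category_counts_by_year", "ALL_STAGES"]

#: The 16 stage cells in row-major (G, dipstick) order.
ALL_STAGES = tuple(CKDStage(GCategory(g), Dipstick(p))
                   for g in range(4) for p in range(4))


@dataclass(frozen=True)
class StageVector:
    """Change on the stage grid: (G-axis delta, proteinuria-axis delta)."""

    dg: float
    dp: float

    def __neg__(self) -> "StageVector":
        return StageVector(-self.dg, -self.dp)


@dataclass(frozen=True)
class TransitionMatrix:
    """Complete-case 16 x 16 stage cross-tabulation between two years."""

    baseline_year: int
    final_year: int
    counts: np.ndarray  # (16, 16) ints, row = from-cell, col = to-cell

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalised percentages; empty rows are all-NaN."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    def to_frame(self) -> pd.DataFrame:
        labels = [str(s) for s in ALL_STAGES]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def stage_to_coord(stage: CKDStage) -> tuple[int, int]:
    """Grid coordinate of a stage cell; G1 P(-) is (0, 0)."""
    return stage.coord()


def change_vector(from_stage: CKDStage, to_stage: CKDStage) -> StageVector:
    """Componentwise coordinate difference between two stage cells."""
    g0, p0 = from_stage.coord()
    g1, p1 = to_stage.coord()
    return StageVector(float(g1 - g0), float(p1 - p0))


def year_pair(staged: pd.DataFrame, baseline_year: int,
              final_year: int) -> pd.DataFrame:
    """Complete-case inner join of a staged cohort on two years.

    Returns one row per subject present in both years, with suffixed
    ``g0,p0,cat0`` / ``g1,p1,cat1`` coordinate columns.
    """
    for y in (baseline_year, final_year):
        if not (staged["year"] == y).any():
            raise ValueError(f"year {y} not present in staged cohort")
    a = staged.loc[staged["year"] == baseline_year,
                   ["subject_id", "g", "p", "category"]]
    b = staged.loc[staged["year"] == final_year,
                   ["subject_id", "g", "p", "category"]]
    merged = a.merge(b, on="subject_id", suffixes=("_0", "_1"))
    return merged.rename(columns={
        "g_0": "g0", "p_0": "p0", "category_0": "cat0",
        "g_1": "g1", "p_1": "p1", "category_1": "cat1"})


def mean_vectors_by_stage(staged: pd.DataFrame, baseline_year: int,
                          final_year: int) -> dict[CKDStage, StageVector]:
    """Mean change vector of the subjects at each baseline stage.

    Stages with no complete-case subject are absent from the map; an empty
    complete-case set raises.
    """
    pairs = year_pair(staged, baseline_year, final_year)
    if pairs.empty:
        raise ValueError(
            f"no complete cases between {baseline_year} and {final_year}")
    out: dict[CKDStage, StageVector] = {}
    grouped = pairs.groupby(["g0", "p0"], sort=True)
    for (g, p), grp in grouped:
        out[CKDStage(GCategory(int(g)), Dipstick(int(p)))] = StageVector(
            float((grp["g1"] - grp["g0"]).mean()),
            float((grp["p1"] - grp["p0"]).mean()))
    return out


def transition_matrix(staged: pd.DataFrame, baseline_year: int,
                      final_year: int) -> TransitionMatrix:
    """16 x 16 complete-case stage transition counts between two years."""
    pairs = year_pair(staged, baseline_year, final_year)
    frm = pairs["g0"].to_numpy() * 4 + pairs["p0"].to_numpy()
    to = pairs["g1"].to_numpy() * 4 + pairs["p1"].to_numpy()
    counts = np.zeros((16, 16), dtype=int)
    np.add.at(counts, (frm, to), 1)
    return TransitionMatrix(baseline_year, final_year, counts)


def mean_vectors_from_matrix(tm: TransitionMatrix) -> dict[CKDStage, StageVector]:
    """Mean vectors recomputed from a transition matrix (consistency aid)."""
    coords = np.array([s.coord() for s in ALL_STAGES])  # (16, 2)
    out: dict[CKDStage, StageVector] = {}
    for i, stage in enumerate(ALL_STAGES):
        row = tm.counts[i]
        n = row.sum()
        if n == 0:
            continue
        dg = float((row * (coords[:, 0] - coords[i, 0])).sum() / n)
        dp = float((row * (coords[:, 1] - coords[i, 1])).sum() / n)
        out[stage] = StageVector(dg, dp)
    return out


def category_counts_by_year(staged: pd.DataFrame) -> pd.DataFrame:
    """Counts and round-half-up percentages per prognostic category per year.

    Returns a tidy DataFrame with columns ``year, category, count, pct``;
    every (year, category) combination is present (count 0 allowed).
    """
    rows = []
    for year, grp in staged.groupby("year", sort=True):
        total = len(grp)
        counts = grp["category"].value_counts()
        for cat in PrognosticCategory:
            c = int(counts.get(int(cat), 0))
            rows.append({"year": int(year), "category": cat.name,
                         "count": c,
                         "pct": round_half_up_pct(c, total) if total else 0.0})
    return pd.DataFrame(rows, columns=["year", "category", "count", "pct"])
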