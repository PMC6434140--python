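"""Deterministic renal staging: eGFR, CKD stage grid, KDIGO prognostic
categories, comorbidity definitions and the study outcome.

The eGFR equation is the Japanese serum-creatinine equation

    eGFR = 194 * Cr^(-1.094) * age^(-0.287)   [* 0.739 if female]

in mL/min/1.73 m^2 with Cr in mg/dL and age in years.  G categories above
G3b (i.e. G4/G5) are collapsed into G3b, and dipstick proteinuria grades
above (2+) are truncated to (2+), so the stage grid is exactly 4 x 4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "GCategory",
    "Dipstick",
    "ACategory",
    "CKDStage",
    "PrognosticCategory",
    "ComorbidityProfile",
    "FEMALE_FACTOR",
    "compute_egfr",
    "inverse_creatinine",
    "g_category",
    "proteinuria_to_a",
    "prognostic_category",
    "classify_comorbidities",
    "outcome",
    "stage_cohort",
    "round_half_up_pct",
]

FEMALE_FACTOR = 0.739

#: eGFR band edges (mL/min/1.73 m^2); lower bound inclusive for the better
#: category, i.e. eGFR == 90 is G1 and eGFR == 60 is G2.
G_EDGES = (90.0, 60.0, 45.0)


class GCategory(enum.IntEnum):
    """GFR category; the integer value is the grid coordinate (G1 = 0)."""

    G1 = 0
    G2 = 1
    G3a = 2
    G3b = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class Dipstick(enum.IntEnum):
    """Ordinal dipstick proteinuria grade; integer value is the grid
    coordinate ((-) = 0)."""

    neg = 0
    trace = 1
    plus1 = 2
    plus2 = 3

    @property
    def label(self) -> str:
        return _DIPSTICK_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Dipstick":
        try:
            return _DIPSTICK_FROM_LABEL[label]
        except KeyError:
            raise ValueError(
                f"invalid dipstick label {label!r}; expected one of "
                f"{sorted(_DIPSTICK_FROM_LABEL)} (grades above 2+ must be "
                "truncated to 2+ before entry)"
            ) from None


_DIPSTICK_LABELS = {
    Dipstick.neg: "neg",
    Dipstick.trace: "trace",
    Dipstick.plus1: "1+",
    Dipstick.plus2: "2+",
}
_DIPSTICK_FROM_LABEL = {v: k for k, v in _DIPSTICK_LABELS.items()}


class ACategory(enum.IntEnum):
    """KDIGO albuminuria/proteinuria category (dipstick-based)."""

    A1 = 0
    A2 = 1
    A3 = 2


class PrognosticCategory(enum.IntEnum):
    """KDIGO prognostic risk category: low < moderate < high < very_high."""

    low = 0
    moderate = 1
    high = 2
    very_high = 3


@dataclass(frozen=True, order=True)
class CKDStage:
    """One of the 16 cells of the G x proteinuria stage grid."""

    g: GCategory
    p: Dipstick

    def coord(self) -> tuple[int, int]:
        """Grid coordinate with G1 P(-) at (0, 0)."""
        return (int(self.g), int(self.p))

    def __str__(self) -> str:
        return f"{self.g.name} P({['-', '+-', '+', '2+'][self.p]})"


@dataclass(frozen=True)
class ComorbidityProfile:
    hypertension: bool
    dm: bool
    dyslipidemia: bool


def compute_egfr(creatinine, age, sex):
    """Estimated GFR from serum creatinine, age and sex.

    Parameters
    ----------
    creatinine : float or array
        Serum creatinine, mg/dL; must be > 0.
    age : float or array
        Age in years; must be > 0.
    sex : str or array of str
        ``"male"`` or ``"female"``.

    Returns
    -------
    float or ndarray
        eGFR in mL/min/1.73 m^2.
    """
    cr = np.asarray(creatinine, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(cr <= 0):
        raise ValueError("creatinine must be > 0")
    if np.any(a <= 0):
        raise ValueError("age must be > 0")
    female = _is_female(sex)
    egfr = 194.0 * cr ** -1.094 * a ** -0.287
    egfr = np.where(female, egfr * FEMALE_FACTOR, egfr)
    return float(egfr) if egfr.ndim == 0 else egfr


def inverse_creatinine(egfr, age, sex):
    """Serum creatinine that yields a given eGFR (exact algebraic inverse)."""
    e = np.asarray(egfr, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(e <= 0):
        raise ValueError("egfr must be > 0")
    if np.any(a <= 0):
        raise ValueError("age must be > 0")
    female = _is_female(sex)
    factor = np.where(female, FEMALE_FACTOR, 1.0)
    cr = (194.0 * factor * a ** -0.287 / e) ** (1.0 / 1.094)
    return float(cr) if cr.ndim == 0 else cr


def _is_female(sex):
    sexes = np.asarray(sex)
    if sexes.dtype.kind == "O":
        sexes = sexes.astype(str)
    if sexes.dtype.kind not in "US":
        raise ValueError("sex must be 'male' or 'female'")
    valid = np.isin(sexes, ("male", "female"))
    if not np.all(valid):
        bad = np.unique(sexes[~valid])
        raise ValueError(f"invalid sex value(s): {bad.tolist()}")
    return sexes == "female"


def g_category(egfr) -> GCategory:
    """Map eGFR to GFR category; G4/G5 collapse into G3b."""
    e = np.asarray(egfr, dtype=float)
    if np.any(e <= 0):
        raise ValueError("egfr must be > 0")
    # negate so bin edges increase; right=True keeps 90/60/45 in the
    # better category (eGFR 90 -> G1, 60 -> G2, 45 -> G3a)
    idx = np.digitize(-e, [-x for x in G_EDGES], right=True)
    if e.ndim == 0:
        return GCategory(int(idx))
    return idx.astype(int)


def proteinuria_to_a(p: Dipstick) -> ACategory:
    """Dipstick grade -> KDIGO A category: (-)→A1, (±)→A2, (+)/(2+)→A3."""
    p = Dipstick(p)
    return ACategory(min(int(p), 2))


# Prognostic category by (G coord, A coord) on the KDIGO heat-map grid.
_PROGNOSIS_GRID = {
    (0, 0): PrognosticCategory.low,
    (1, 0): PrognosticCategory.low,
    (0, 1): PrognosticCategory.moderate,
    (1, 1): PrognosticCategory.moderate,
    (2, 0): PrognosticCategory.moderate,
    (0, 2): PrognosticCategory.high,
    (1, 2): PrognosticCategory.high,
    (2, 1): PrognosticCategory.high,
    (3, 0): PrognosticCategory.high,
    (2, 2): PrognosticCategory.very_high,
    (3, 1): PrognosticCategory.very_high,
    (3, 2): PrognosticCategory.very_high,
}


def prognostic_category(stage: CKDStage) -> PrognosticCategory:
    """KDIGO prognostic risk category of a stage cell."""
    a = proteinuria_to_a(stage.p)
    return _PROGNOSIS_GRID[(int(stage.g), int(a))]


def classify_comorbidities(record) -> ComorbidityProfile:
    """Hypertension / diabetes / dyslipidemia status of a checkup record.

    Hypertension: SBP >= 140 mmHg, or DBP >= 90 mmHg, or on BP medication.
    Diabetes: casual glucose >= 200 mg/dL, or HbA1c >= 6.5 %, or on
    antidiabetic medication.  Dyslipidemia: LDL >= 140 mg/dL or on
    lipid-lowering medication.  All thresholds inclusive.
    """
    fields = ("sbp", "dbp", "glucose", "hba1c", "ldl",
              "on_bp_med", "on_dm_med", "on_lipid_med")
    vals = {}
    for f in fields:
        v = getattr(record, f, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing field {f!r} in record")
        vals[f] = v
    return ComorbidityProfile(
        hypertension=vals["sbp"] >= 140 or vals["dbp"] >= 90
        or bool(vals["on_bp_med"]),
        dm=vals["glucose"] >= 200 or vals["hba1c"] >= 6.5
        or bool(vals["on_dm_med"]),
        dyslipidemia=vals["ldl"] >= 140 or bool(vals["on_lipid_med"]),
    )


def outcome(baseline: PrognosticCategory, final: PrognosticCategory,
            rule: str = "very_high_at_end") -> bool:
    """Study outcome: risk-category aggravation or bad end state.

    True iff the final prognostic category exceeds the baseline one, or the
    final category meets the end-state rule: ``"very_high_at_end"`` (final is
    very_high) or ``"high_at_end"`` (final is high or very_high).
    """
    baseline = PrognosticCategory(baseline)
    final = PrognosticCategory(final)
    if rule == "very_high_at_end":
        at_end = final == PrognosticCategory.very_high
    elif rule == "high_at_end":
        at_end = final >= PrognosticCategory.high
    else:
        raise ValueError(f"unknown outcome rule {rule!r}")
    return final > baseline or at_end


def stage_cohort(cohort_df):
    """Stage every subject-year of a cohort DataFrame.

    Parameters
    ----------
    cohort_df : DataFrame
        Cohort table in the cohort CSV schema (dipstick as label or as
        ordinal code 0-3).

    Returns
    -------
    DataFrame
        Columns ``subject_id, year, egfr, g, p, a, category`` with ``g``,
        ``p``, ``a`` and ``category`` as integer grid coordinates (G1=0,
        neg=0, A1=0, low=0).
    """
    import pandas as pd

    dip = cohort_df["dipstick"]
    if dip.dtype == object:
        p = dip.map(lambda s: int(Dipstick.from_label(s))).to_numpy()
    else:
        p = dip.to_numpy(dtype=int)
    egfr = compute_egfr(cohort_df["creatinine"].to_numpy(),
                        cohort_df["age"].to_numpy(),
                        cohort_df["sex"].to_numpy())
    g = g_category(egfr)
    a = np.minimum(p, 2)
    cat_lut = np.array([[int(_PROGNOSIS_GRID[(gi, ai)]) for ai in range(3)]
                        for gi in range(4)])
    category = cat_lut[g, a]
    return pd.DataFrame({
        "subject_id": cohort_df["subject_id"].to_numpy(),
        "year": cohort_df["year"].to_numpy(),
        "egfr": egfr, "g": g, "p": p, "a": a, "category": category,
    })


def round_half_up_pct(count, total, digits: int = 1) -> float:
    """Percentage with round-half-up at ``digits`` decimals (the convention
    that reproduces printed cohort percentages, e.g. 730/7465 -> 9.8)."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(q, ROUND_HALF_UP)
    )
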