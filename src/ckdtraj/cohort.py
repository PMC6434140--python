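"""Synthetic longitudinal checkup cohorts.

Two generators share the ``CheckupRecord`` schema:

``generate_cohort``
    A drift model: each subject carries a latent baseline eGFR and a linear
    per-year slope; annual measurements add Gaussian noise, so stages churn
    in both directions (apparent improvement as well as exacerbation), as
    seen in real repeated checkup data.  Serum creatinine is back-solved
    from the latent eGFR through the inverse of the staging equation, so
    the equation is exercised in both directions.

``generate_markov_cohort``
    Subjects walk on the 16-cell (G category x dipstick) stage grid under
    an explicit transition kernel; emitted creatinine values are drawn so
    the computed eGFR lands inside the assigned G band.  This gives
    downstream transition analyses a known ground truth.

Comorbidity status (hypertension / diabetes / dyslipidemia) is drawn first
as a Bernoulli indicator at the configured prevalence and the blood
pressure, glucose, HbA1c, LDL and medication flags are then drawn
consistently with it, so re-classifying the emitted record recovers the
drawn status exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .staging import (
    Dipstick,
    GCategory,
    compute_egfr,
    g_category,
    inverse_creatinine,
)

__all__ = ["CohortConfig", "CheckupRecord", "generate_cohort",
           "generate_markov_cohort", "DEFAULT_INITIAL_STAGE_PROBS"]

#: Baseline stage-cell proportions of a healthy middle-aged checkup
#: population (row-major over the 4x4 G x dipstick grid); used as the
#: default initial distribution of the Markov-mode generator.
DEFAULT_INITIAL_STAGE_PROBS = np.array(
    [1375, 53, 25, 10,
     5061, 355, 129, 36,
     322, 34, 18, 16,
     17, 3, 2, 9], dtype=float) / 7465.0


@dataclass(frozen=True)
class CheckupRecord:
    """One subject-year of raw checkup measurements."""

    subject_id: int
    year: int
    age: float
    sex: str                      # "male" | "female"
    sbp: float                    # mmHg
    dbp: float                    # mmHg
    glucose: float                # mg/dL, casual
    hba1c: float                  # % NGSP
    ldl: float                    # mg/dL
    creatinine: float             # mg/dL
    dipstick: Dipstick
    bmi: float                    # kg/m^2
    waist: float                  # cm
    on_bp_med: bool
    on_dm_med: bool
    on_lipid_med: bool

    def __post_init__(self):
        if self.creatinine <= 0:
            raise ValueError("creatinine must be > 0")
        if self.age <= 0:
            raise ValueError("age must be > 0")
        object.__setattr__(self, "dipstick", Dipstick(self.dipstick))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the first moments of a middle-aged Japanese worksite
    checkup population: age 50.1 +/- 6.3 y, 64.2 % male, eGFR 79 +/- 14.4
    mL/min/1.73 m^2, comorbidity prevalences 29.9 % hypertension, 5.6 %
    diabetes, 35.7 % dyslipidemia.  ``slope_mean``/``slope_sd`` set the
    subject-level linear eGFR drift (mL/min/1.73 m^2 per year) and
    ``noise_sd`` the within-subject measurement noise; ``missing_rate`` is
    the fraction of subject-years dropped completely at random.
    """

    n_subjects: int = 1000
    years: tuple[int, ...] = tuple(range(2009, 2017))
    seed: int = 0
    age_mean: float = 50.1
    age_sd: float = 6.3
    male_fraction: float = 0.642
    egfr_mean: float = 79.0
    egfr_sd: float = 14.4
    slope_mean: float = -0.3
    slope_sd: float = 0.6
    noise_sd: float = 4.0
    proteinuria_thresholds: tuple[float, float, float] = (1.33, 1.84, 2.35)
    comorbidity_prevalences: tuple[float, float, float] = (0.299, 0.056, 0.357)
    missing_rate: float = 0.25

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("invalid config field n_subjects: must be >= 1")
        yrs = tuple(self.years)
        if len(yrs) == 0 or any(b <= a for a, b in zip(yrs, yrs[1:])):
            raise ValueError(
                "invalid config field years: must be nonempty and strictly "
                "increasing")
        object.__setattr__(self, "years", yrs)
        for name in ("male_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid config field {name}: {v} not in [0,1]")
        prevs = tuple(self.comorbidity_prevalences)
        if len(prevs) != 3 or any(not 0.0 <= p <= 1.0 for p in prevs):
            raise ValueError(
                "invalid config field comorbidity_prevalences: need 3 "
                "proportions in [0,1]")
        object.__setattr__(self, "comorbidity_prevalences", prevs)
        thr = tuple(self.proteinuria_thresholds)
        if len(thr) != 3 or not (thr[0] < thr[1] < thr[2]):
            raise ValueError(
                "invalid config field proteinuria_thresholds: need 3 "
                "strictly increasing values")
        object.__setattr__(self, "proteinuria_thresholds", thr)
        for name in ("age_sd", "egfr_sd", "slope_sd", "noise_sd", "age_mean",
                     "egfr_mean"):
            if getattr(self, name) < 0 and name != "slope_mean":
                raise ValueError(f"invalid config field {name}: must be >= 0")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_comorbidity_block(rng, n):
    """Status-first draw of the comorbidity-defining measurements.

    Returns per-subject arrays: status flags, measurement values and
    medication flags, mutually consistent with the clinical definitions
    (thresholds 140/90 mmHg, 200 mg/dL, 6.5 %, 140 mg/dL, all inclusive).
    """
    out = {}
    # hypertension: positive by raised pressure (60 %) or by medication
    ht = out["ht"] = np.zeros(n, bool)
    out["sbp"] = _truncnorm(rng, 120.0, 13.0, hi=139.9, size=n)
    out["dbp"] = _truncnorm(rng, 76.0, 9.0, hi=89.9, size=n)
    out["on_bp_med"] = np.zeros(n, bool)
    # dm
    out["glucose"] = _truncnorm(rng, 93.0, 14.0, hi=199.0, size=n)
    out["hba1c"] = _truncnorm(rng, 5.55, 0.45, hi=6.49, size=n)
    out["on_dm_med"] = np.zeros(n, bool)
    # dyslipidemia
    out["ldl"] = _truncnorm(rng, 118.0, 22.0, hi=139.9, size=n)
    out["on_lipid_med"] = np.zeros(n, bool)
    return out


def _apply_comorbidity_status(rng, block, prevalences):
    """Flip a Bernoulli(prevalence) subset of subjects to positive status,
    redrawing their measurements/medication flags above threshold."""
    n = len(block["sbp"])
    p_ht, p_dm, p_dl = prevalences

    ht = rng.random(n) < p_ht
    by_med = ht & (rng.random(n) < 0.4)
    by_bp = ht & ~by_med
    m = int(by_bp.sum())
    if m:
        high_sbp = rng.random(m) < 0.7  # raised systolic vs raised diastolic
        sbp_hi = _truncnorm(rng, 148.0, 10.0, lo=140.0, size=m)
        dbp_hi = _truncnorm(rng, 94.0, 5.0, lo=90.0, size=m)
        block["sbp"][by_bp] = np.where(high_sbp, sbp_hi, block["sbp"][by_bp])
        block["dbp"][by_bp] = np.where(~high_sbp, dbp_hi, block["dbp"][by_bp])
    block["on_bp_med"][by_med] = True
    block["ht"] = ht

    dm = rng.random(n) < p_dm
    by_med = dm & (rng.random(n) < 0.5)
    by_lab = dm & ~by_med
    m = int(by_lab.sum())
    if m:
        block["hba1c"][by_lab] = _truncnorm(rng, 7.0, 0.8, lo=6.5, size=m)
        block["glucose"][by_lab] = _truncnorm(rng, 160.0, 40.0, lo=90.0, size=m)
    block["on_dm_med"][by_med] = True
    block["dm"] = dm

    dl = rng.random(n) < p_dl
    by_med = dl & (rng.random(n) < 0.3)
    by_ldl = dl & ~by_med
    m = int(by_ldl.sum())
    if m:
        block["ldl"][by_ldl] = _truncnorm(rng, 155.0, 15.0, lo=140.0, size=m)
    block["on_lipid_med"][by_med] = True
    block["dl"] = dl
    return block


def _subject_frame(rng, config):
    """Draw the per-subject (time-invariant) variables."""
    n = config.n_subjects
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, n), 20.0, 75.0)
    bmi = np.clip(rng.normal(23.3, 3.3, n), 14.0, 45.0)
    waist = np.clip(82.7 + 8.9 * (0.8 * (bmi - 23.3) / 3.3
                                  + 0.6 * rng.standard_normal(n)), 55.0, 140.0)
    block = _draw_comorbidity_block(rng, n)
    block = _apply_comorbidity_status(rng, block, config.comorbidity_prevalences)
    return sex, age0, bmi, waist, block


def _records_from_arrays(subject_ids, years_arr, ages, sexes, sbp, dbp,
                         glucose, hba1c, ldl, creat, dip, bmi, waist,
                         bp_med, dm_med, lipid_med, keep):
    records = []
    for i in np.flatnonzero(keep):
        records.append(CheckupRecord(
            subject_id=int(subject_ids[i]), year=int(years_arr[i]),
            age=float(ages[i]), sex=str(sexes[i]), sbp=float(sbp[i]),
            dbp=float(dbp[i]), glucose=float(glucose[i]),
            hba1c=float(hba1c[i]), ldl=float(ldl[i]),
            creatinine=float(creat[i]), dipstick=Dipstick(int(dip[i])),
            bmi=float(bmi[i]), waist=float(waist[i]),
            on_bp_med=bool(bp_med[i]), on_dm_med=bool(dm_med[i]),
            on_lipid_med=bool(lipid_med[i])))
    return records


def generate_cohort(config: CohortConfig) -> list[CheckupRecord]:
    """Generate a drift-model longitudinal cohort.

    Latent eGFR of subject *i* in calendar year *y* is
    ``base_i + slope_i * (y - y0) + eps_iy`` with ``eps`` iid Gaussian
    measurement noise; creatinine is the exact algebraic inverse of the
    staging equation at that eGFR.  Dipstick grade is obtained by
    thresholding a latent severity correlated with the negative eGFR slope
    (faster decliners spill protein more often), redrawn each year.

    Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    years = np.asarray(config.years)
    y0 = years[0]

    sex, age0, bmi, waist, block = _subject_frame(rng, config)
    # Baseline eGFR is right-skewed (healthy populations have a light low
    # tail): shifted lognormal with a fixed coefficient of variation of
    # the lognormal part, matching the configured mean and marginal SD
    # exactly.  egfr_sd is the measured cross-sectional SD, so the latent
    # between-subject SD is reduced by the measurement-noise variance.
    base_sd = np.sqrt(max(config.egfr_sd ** 2 - config.noise_sd ** 2,
                          (0.1 * config.egfr_sd) ** 2))
    cv = 0.35
    ln_mean = base_sd / cv
    shift = config.egfr_mean - ln_mean
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(ln_mean) - sigma2 / 2.0
    base = np.clip(shift + rng.lognormal(mu, np.sqrt(sigma2), n), 8.0, None)
    slope = rng.normal(config.slope_mean, config.slope_sd, n)

    # latent proteinuria propensity: a persistent subject effect plus a
    # coupling to the (negative) eGFR slope, so fast decliners spill
    # protein more often and positivity tracks within subject over years
    coupling, persistence = 0.5, 0.7
    z_subj = (-coupling * (slope - config.slope_mean)
              / max(config.slope_sd, 1e-12)
              + persistence * rng.standard_normal(n))

    nyr = len(years)
    sid = np.repeat(np.arange(n), nyr)
    yr = np.tile(years, n)
    dt = (yr - y0).astype(float)

    egfr_lat = np.clip(base[sid] + slope[sid] * dt
                       + rng.normal(0.0, config.noise_sd, n * nyr), 2.0, None)
    ages = age0[sid] + dt
    creat = inverse_creatinine(egfr_lat, ages, sex[sid])

    w = np.sqrt(max(1.0 - coupling ** 2 - persistence ** 2, 0.0))
    z = z_subj[sid] + w * rng.standard_normal(n * nyr)
    dip = np.digitize(z, config.proteinuria_thresholds)

    keep = rng.random(n * nyr) >= config.missing_rate

    return _records_from_arrays(
        sid, yr, ages, sex[sid], block["sbp"][sid], block["dbp"][sid],
        block["glucose"][sid], block["hba1c"][sid], block["ldl"][sid],
        creat, dip, bmi[sid], waist[sid], block["on_bp_med"][sid],
        block["on_dm_med"][sid], block["on_lipid_med"][sid], keep)


#: eGFR sampling band per G category for Markov-mode emission
#: (upper edge of G1 and lower edge of G3b are nominal).
_G_BANDS = {GCategory.G1: (90.0, 115.0), GCategory.G2: (60.0, 89.99),
            GCategory.G3a: (45.0, 59.99), GCategory.G3b: (15.0, 44.99)}


def generate_markov_cohort(config: CohortConfig,
                           transition_kernel) -> list[CheckupRecord]:
    """Generate a cohort whose stage dynamics follow a known Markov kernel.

    ``transition_kernel`` is a 16 x 16 row-stochastic matrix over stage
    cells in row-major (G, dipstick) order.  Initial stages are drawn from
    the default baseline stage distribution.  Emitted creatinine is drawn
    uniformly in eGFR within the assigned G band and back-solved, so
    staging the record recovers the assigned cell.
    """
    kernel = np.asarray(transition_kernel, dtype=float)
    if kernel.shape != (16, 16):
        raise ValueError("transition kernel must be 16x16")
    if np.any(kernel < 0) or np.any(np.abs(kernel.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each kernel row must be nonnegative and sum to 1 "
                         "within 1e-9")

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    years = np.asarray(config.years)
    nyr = len(years)

    sex, age0, bmi, waist, block = _subject_frame(rng, config)

    cum0 = np.cumsum(DEFAULT_INITIAL_STAGE_PROBS)
    cumk = np.cumsum(kernel, axis=1)
    states = np.empty((n, nyr), dtype=int)
    states[:, 0] = np.searchsorted(cum0, rng.random(n), side="right")
    for t in range(1, nyr):
        u = rng.random(n)
        prev = states[:, t - 1]
        states[:, t] = (cumk[prev] < u[:, None]).sum(axis=1)
    np.clip(states, 0, 15, out=states)

    sid = np.repeat(np.arange(n), nyr)
    yr = np.tile(years, n)
    dt = (yr - years[0]).astype(float)
    flat = states.reshape(-1)
    g_idx, dip = np.divmod(flat, 4)

    lo = np.array([_G_BANDS[GCategory(g)][0] for g in range(4)])[g_idx]
    hi = np.array([_G_BANDS[GCategory(g)][1] for g in range(4)])[g_idx]
    egfr = lo + (hi - lo) * rng.random(n * nyr)
    ages = age0[sid] + dt
    creat = inverse_creatinine(egfr, ages, sex[sid])

    keep = rng.random(n * nyr) >= config.missing_rate

    return _records_from_arrays(
        sid, yr, ages, sex[sid], block["sbp"][sid], block["dbp"][sid],
        block["glucose"][sid], block["hba1c"][sid], block["ldl"][sid],
        creat, dip, bmi[sid], waist[sid], block["on_bp_med"][sid],
        block["on_dm_med"][sid], block["on_lipid_med"][sid], keep)
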