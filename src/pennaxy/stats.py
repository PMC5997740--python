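"""Population readouts: defect-load ratios, sex ratios, locus profiles,
recombination trajectories and the Jukes-Cantor divergence correction.

Defect-load comparisons between chromosomes use per-copy mean defective
fractions rather than raw counts, so chromosomes of unequal configured length
stay comparable; for length-matched pairs (X vs the comparator autosome) the
two definitions coincide.  X pools copies from both sexes (two per female,
one per male), Y pools the paternal sex-pair copy of males only.  Undefined
ratios (empty cohort or zero denominator load) are reported as NaN, never as
zero.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InvariantViolation

__all__ = [
    "cohort_of", "cohort_masks", "mutation_ratios", "sex_ratio",
    "mean_norm_xy", "locus_profile", "yx_slope", "suppression_step",
    "jukes_cantor",
]

COHORTS = ("newborns", "youths", "adults")


def cohort_of(ind_or_age, repro_age: int) -> str:
    """Age-group label: newborns at age 0, adults from the reproductive age."""
    age = ind_or_age if isinstance(ind_or_age, (int, np.integer)) else ind_or_age.age
    if age == 0:
        return "newborns"
    return "youths" if age < repro_age else "adults"


def cohort_masks(state) -> dict[str, np.ndarray]:
    """Boolean cell masks for the three age cohorts of a run state."""
    R = state.config.repro_age
    alive = state.occ
    return {
        "newborns": alive & (state.age == 0),
        "youths": alive & (state.age > 0) & (state.age < R),
        "adults": alive & (state.age >= R),
    }


def _mean_fractions(state, mask):
    """Per-copy mean defective fraction of (X pool, Y pool, comparator pool)."""
    t = state.table
    len_sex = float(t.lengths[t.sex_index])
    len_cmp = float(t.lengths[t.index(state.config.comparator)])
    males = mask & (state.sex == 1)
    females = mask & (state.sex == 0)
    n = int(mask.sum())
    n_f = int(females.sum())
    n_m = int(males.sum())
    # X copies: everyone's maternal copy plus females' paternal copy
    n_x = n + n_f
    frac_x = (state.cnt_s0[mask].sum() + state.cnt_s1[females].sum()) / (n_x * len_sex) \
        if n_x else np.nan
    frac_y = state.cnt_s1[males].sum() / (n_m * len_sex) if n_m else np.nan
    n_c = 2 * n
    frac_c = (state.cnt_c0[mask].sum() + state.cnt_c1[mask].sum()) / (n_c * len_cmp) \
        if n_c else np.nan
    return frac_x, frac_y, frac_c


def mutation_ratios(state, mask) -> tuple[float, float]:
    """(X/comparator, Y/X) ratios of per-copy mean defective fractions.

    NaN when the cohort is empty or a denominator load is zero (an undefined
    ratio is never reported as 0).
    """
    frac_x, frac_y, frac_c = _mean_fractions(state, mask)
    x10 = frac_x / frac_c if frac_c and not np.isnan(frac_c) and frac_c > 0 else np.nan
    if np.isnan(frac_x):
        x10 = np.nan
    yx = frac_y / frac_x if frac_x and not np.isnan(frac_x) and frac_x > 0 else np.nan
    if np.isnan(frac_y):
        yx = np.nan
    return float(x10), float(yx)


def sex_ratio(state, mask) -> float:
    """Males per female within the cohort; NaN when there are no females."""
    males = int((mask & (state.sex == 1)).sum())
    females = int((mask & (state.sex == 0)).sum())
    return males / females if females else float("nan")


def mean_norm_xy(state) -> float:
    """Mean male X-Y recombination value over the initial (X-typical) rate."""
    males = state.occ & (state.sex == 1)
    if not males.any() or state.initial_xy_rate <= 0:
        return float("nan")
    return float(state.xymod[males].mean() / state.initial_xy_rate)


def locus_profile(state, spec_name: str, pool: str = "auto") -> np.ndarray:
    """Mean fraction of defective alleles per locus, ranked by activation time.

    For autosomes all copies in the population are pooled.  For the sex pair
    ``pool`` selects the chromosome type: "X" (both sexes' X copies, the
    default) or "Y" (males' paternal copy only).
    """
    t = state.table
    idx = t.index(spec_name)
    sl = t.slice_of(spec_name)
    alive = np.flatnonzero(state.occ)
    length = int(t.lengths[idx])
    if alive.size == 0:
        return np.zeros(length)
    bits = state.genome[alive][:, :, sl]
    is_male = state.sex[alive] == 1
    if idx != t.sex_index:
        if pool != "auto":
            raise ConfigurationError("pool selection only applies to the sex pair")
        return bits.reshape(-1, length).mean(axis=0)
    if pool in ("auto", "X"):
        copies = np.concatenate([bits[:, 0, :], bits[~is_male, 1, :]])
    elif pool == "Y":
        copies = bits[is_male, 1, :]
    else:
        raise ConfigurationError(f"pool must be 'X' or 'Y', got {pool!r}")
    if copies.shape[0] == 0:
        return np.full(length, np.nan)
    return copies.mean(axis=0)


def yx_slope(records: pd.DataFrame, cohort: str = "newborns") -> tuple[float, float]:
    """OLS slope of the Y/X load ratio against time, per 100,000 steps.

    Returns (slope, R^2) over the defined portion of the series.
    """
    if cohort not in COHORTS:
        raise ConfigurationError(f"cohort must be one of {COHORTS}")
    col = f"yx_{cohort}"
    sub = records[["step", col]].dropna()
    if len(sub) < 2:
        return float("nan"), float("nan")
    res = sps.linregress(sub["step"].to_numpy(float) / 1e5, sub[col].to_numpy(float))
    return float(res.slope), float(res.rvalue ** 2)


def suppression_step(records: pd.DataFrame) -> Optional[int]:
    """First step at which the mean normalized X-Y recombination equals 0.

    None if it never does.  If the series rises above 0 again afterwards
    (which the absorbing modifier should not allow), the first zero is still
    returned with a warning.
    """
    vals = records["norm_xy"].to_numpy(float)
    zero = np.flatnonzero(vals == 0.0)
    if zero.size == 0:
        return None
    first = int(zero[0])
    if np.any(vals[first:] > 0):
        warnings.warn("normalized X-Y recombination rose again after reaching 0; "
                      "the modifier state should be absorbing", RuntimeWarning,
                      stacklevel=2)
    return int(records["step"].iloc[first])


def jukes_cantor(p):
    """Jukes-Cantor correction K = -(3/4) ln(1 - (4/3) p).

    Converts an observed substitution fraction p in [0, 0.75) into an
    estimated divergence; vectorized over array input.
    """
    arr = np.asarray(p, float)
    if np.any(arr < 0) or np.any(arr >= 0.75):
        raise InvariantViolation("substitution fraction must lie in [0, 0.75)")
    k = -0.75 * np.log1p(-(4.0 / 3.0) * arr)
    return float(k) if np.isscalar(p) or np.ndim(p) == 0 else k
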