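"""Peak-area-ratio screening statistics.

The screen's decision rule: for every consensus compound, the per-pair
peak-area ratio PAR_i = sample_area_i / control_area_i is computed over
the n replicate pairs, and the compound is called a ligand when the
mean PAR exceeds 1 *and* a two-tailed two-sample t-test on the raw
areas gives p < 0.05.  Also provides the spectrophotometric enzyme
inhibition-% utility used by the activity assay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

logger = logging.getLogger(__name__)

DEFAULT_PAR_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05


@dataclass
class ScreeningResult:
    """Per-compound screening outcome."""

    compound_id: str
    par_values: np.ndarray
    par_mean: float
    par_sd: float
    p_value: float
    selected: bool = False
    imputed_control: bool = False
    neutral_mass: float = float("nan")
    rt: float = float("nan")
    annotation: str = ""


def compute_par(
    sample_areas: np.ndarray,
    control_areas: np.ndarray,
    control_floor: float | None = None,
) -> tuple[np.ndarray, float, float, bool]:
    """Per-pair PARs with mean and sample SD (n-1 denominator).

    Replicate i of the sample group is paired with replicate i of the
    control group.  A missing (NaN) control area is imputed at
    ``control_floor`` — the detection floor, so a binder stripped from
    the control entirely still yields a (conservative, flagged) ratio —
    while a missing sample area drops the pair.  Returns
    ``(par_values, par_mean, par_sd, imputed_control)``.

    Raises ``ValueError`` if fewer than 2 usable pairs remain.
    """
    sample = np.asarray(sample_areas, dtype=float)
    control = np.asarray(control_areas, dtype=float)
    if sample.shape != control.shape:
        raise ValueError("sample and control area vectors differ in length")
    imputed = False
    usable_s, usable_c = [], []
    for s, c in zip(sample, control):
        if np.isnan(s):
            continue
        if np.isnan(c):
            if control_floor is None or control_floor <= 0:
                continue
            c = control_floor
            imputed = True
        usable_s.append(s)
        usable_c.append(c)
    if len(usable_s) < 2:
        raise ValueError("fewer than 2 usable replicate pairs")
    par = np.array(usable_s) / np.array(usable_c)
    mean = float(np.mean(par))
    sd = float(np.std(par, ddof=1))
    return par, mean, sd, imputed


def t_test(
    sample_areas: np.ndarray,
    control_areas: np.ndarray,
    variant: str = "student",
) -> float:
    """Two-tailed two-sample t-test p-value on raw peak areas.

    ``variant``: ``"student"`` (pooled variance, the default) or
    ``"welch"``.  Degenerate zero-variance input is resolved by
    convention: identical constant groups give p = 1, different
    constant groups give p = 0 (with a warning) — the data admit no
    other answer.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(sample_areas, dtype=float)
    b = np.asarray(control_areas, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("areas must be finite")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 1.0
        logger.warning("zero variance in both groups with unequal means; p = 0")
        return 0.0
    res = scipy.stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


def screen_compound(
    compound_id: str,
    sample_areas: np.ndarray,
    control_areas: np.ndarray,
    control_floor: float | None = None,
    variant: str = "student",
    use_pairing: bool = True,
) -> ScreeningResult | None:
    """PAR + t-test for one compound; None if too few usable pairs.

    With ``use_pairing=False`` the PAR is the ratio of group means
    instead of the mean of per-pair ratios (sensitivity-analysis
    option); the t-test is unaffected.
    """
    try:
        par, mean, sd, imputed = compute_par(
            sample_areas, control_areas, control_floor
        )
    except ValueError as exc:
        logger.info("compound %s excluded from screening: %s", compound_id, exc)
        return None
    if not use_pairing:
        s = np.asarray(sample_areas, float)
        c = np.where(
            np.isnan(control_areas), control_floor or np.nan, control_areas
        )
        mean = float(np.nanmean(s) / np.nanmean(c))
    control_filled = np.where(
        np.isnan(control_areas),
        control_floor if control_floor else np.nan,
        control_areas,
    )
    p = t_test(sample_areas, control_filled, variant=variant)
    return ScreeningResult(
        compound_id=compound_id,
        par_values=par,
        par_mean=mean,
        par_sd=sd,
        p_value=p,
        imputed_control=imputed,
    )


def select_ligands(
    results: list[ScreeningResult],
    par_threshold: float = DEFAULT_PAR_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "none",
) -> list[ScreeningResult]:
    """Apply the selection rule: mean PAR > threshold (strict) and
    p < alpha (strict), optionally after Benjamini-Hochberg adjustment.

    Marks ``selected`` on every result and returns the selected subset
    sorted by mean PAR descending.
    """
    if not results:
        raise ValueError("no screening results to select from")
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    pvals = np.array([r.p_value for r in results])
    if correction == "BH":
        from statsmodels.stats.multitest import multipletests

        _, pvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, p in zip(results, pvals):
        r.selected = bool(r.par_mean > par_threshold and p < alpha)
    chosen = [r for r in results if r.selected]
    chosen.sort(key=lambda r: -r.par_mean)
    return chosen


@dataclass(frozen=True)
class AssayAbsorbance:
    """Control (A_a) and test-compound (A_b) absorbances of the enzyme
    activity assay, in absorbance units."""

    A_a: float
    A_b: float

    def __post_init__(self) -> None:
        if self.A_a <= 0:
            raise ValueError("control absorbance A_a must be > 0")
        if self.A_b < 0:
            raise ValueError("test absorbance A_b must be >= 0")


def inhibition_percent(a: AssayAbsorbance) -> float:
    """Enzyme inhibition (%) = (A_a - A_b) / A_a x 100."""
    return (a.A_a - a.A_b) / a.A_a * 100.0
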