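"""Difference test, equivalence limits, equivalence tests and outcomes.

The assessment of one analyte proceeds in two steps on the ln scale:

* step L - equivalence limits are set as outer confidence limits around the
  reference mean, ``m_R +/- lsd(GR;2;97.5)``, using the model-2 GMO-vs-
  reference contrast so that the spread between reference varieties widens
  the limits;
* step E - three equivalence tests against those limits:

  - E1 ("shared risk"): is the GMO mean inside the limits?  Equivalent to a
    two-sided 95% test of the GMO-vs-reference difference under model 2.
  - E2 (proof of equivalence): is the interval ``m_G +/- lsd(GR;1;95)``
    entirely inside the limits?
  - E3 (proof of non-equivalence): is that interval entirely outside?

together with the conventional difference test D of GMO against the
counterpart (two-sided 90%, model 1).  The joint outcome is one of seven
types, grouped into four categories: (i) equivalence proven {1,2};
(ii) equivalence more likely than not {3,4}; (iii) non-equivalence more
likely than not {5,6}; (iv) non-equivalence proven {7}.

All tests reduce to comparisons of (estimate, sed, df) triples, so the same
code drives both model fits and summary tables of previously published
results.  Tie policy: a point or interval endpoint exactly on a limit
counts as non-rejection of the relevant null (inside for E1, not proven
for E2/E3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .mixed_model import ContrastEstimate, ModelFit, fit_model
from .trial_data import AnalyteDataset

__all__ = [
    "AssessmentConfig",
    "EquivalenceLimits",
    "DifferenceResult",
    "EquivalenceTests",
    "EquivalenceAssessment",
    "estimate_equivalence_limits",
    "test_difference",
    "run_equivalence_tests",
    "classify_outcome",
    "assess_analyte",
    "assess_from_summary",
    "CATEGORY_OF_TYPE",
]

CATEGORY_OF_TYPE = {1: "i", 2: "i", 3: "ii", 4: "ii", 5: "iii", 6: "iii", 7: "iv"}


@dataclass(frozen=True)
class AssessmentConfig:
    """Confidence levels and conventions (risk-manager choices, not
    statistical ones).

    difference_level
        two-sided % level of the D confidence interval (default 90).
    limit_level
        one-sided % for the equivalence-limit half-width (default 97.5,
        i.e. 95% confidence limits around the reference mean).
    interval_level
        one-sided % for the E2/E3 interval (default 95, a 90% two-sided
        interval).
    limit_contrast / interval_contrast
        which contrast's lsd is used for the limits (model 2) and for the
        E2/E3 interval (model 1); ``GR`` reproduces the canonical
        procedure, ``GC`` is kept as a documented alternative reading.
    one_sided
        ``None`` for the usual two-sided tests, or ``"upper"``/``"lower"``
        to restrict attention to one direction.
    """

    difference_level: float = 90.0
    limit_level: float = 97.5
    interval_level: float = 95.0
    limit_contrast: Literal["GR", "GC"] = "GR"
    interval_contrast: Literal["GR", "GC"] = "GR"
    df_method: Literal["kenward_roger", "satterthwaite"] = "kenward_roger"
    one_sided: Literal[None, "upper", "lower"] = None


@dataclass(frozen=True)
class EquivalenceLimits:
    """Equivalence limits on the ln scale, symmetric around ``m_R``."""

    lower: float
    upper: float
    center: float
    half_width: float
    level: float  # one-sided %
    degenerate: bool = False

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def natural(self) -> tuple[float, float]:
        """Back-transform to the natural (geometric-mean) scale."""
        return (math.exp(self.lower), math.exp(self.upper))

    def ratio_to_reference(self, m_g: float) -> tuple[float, float]:
        """Equivalence interval on the GMO/reference ratio scale.

        The half-width is carried over to the estimated GMO-vs-reference
        ratio, ``exp(m_G - m_R -/+ half_width)``; the test E1 verdict reads
        off directly as whether this interval contains 1.
        """
        d = m_g - self.center
        return (math.exp(d - self.half_width), math.exp(d + self.half_width))


@dataclass(frozen=True)
class DifferenceResult:
    estimate: float  # m_G - m_C on the ln scale
    lower: float
    upper: float
    level: float  # two-sided %
    significant: bool

    def ratio(self) -> float:
        return math.exp(self.estimate)

    def ratio_interval(self) -> tuple[float, float]:
        return (math.exp(self.lower), math.exp(self.upper))


@dataclass(frozen=True)
class EquivalenceTests:
    e1: Literal["equiv_more_likely", "nonequiv_more_likely"]
    e2_proven: bool
    e3_proven: bool
    interval_lower: float  # m_G +/- lsd(GR;1;interval_level) on ln scale
    interval_upper: float
    usable: bool = True  # False when the limits are degenerate


@dataclass(frozen=True)
class EquivalenceAssessment:
    analyte: str
    difference: DifferenceResult
    equivalence: EquivalenceTests
    limits: EquivalenceLimits
    outcome_type: int | None
    category: str | None
    degenerate: bool
    counterpart_outside_limits: bool
    m_c: float = math.nan
    m_g: float = math.nan
    m_r: float = math.nan


def estimate_equivalence_limits(
    fit2: ModelFit | None = None,
    level: float = 97.5,
    *,
    m_r: float | None = None,
    contrast: ContrastEstimate | None = None,
    degenerate: bool | None = None,
) -> EquivalenceLimits:
    """Step L: limits ``m_R +/- t_{df;level} x sed_GR;2`` on the ln scale.

    Either pass a variant-2 :class:`ModelFit`, or the reference mean and the
    model-2 GMO-vs-reference contrast explicitly (the summary-table route).
    Refuses datasets with fewer than two reference genotypes.
    """
    if fit2 is not None:
        if fit2.variant != 2:
            raise ValueError("equivalence limits require a variant-2 fit")
        if fit2.design is not None and fit2.design.n_ref_genotypes < 2:
            raise ValueError(
                "equivalence limits require at least two reference genotypes"
            )
        m_r = fit2.m_r
        contrast = fit2.contrasts["GR"]
        degenerate = fit2.degenerate_vg
    if m_r is None or contrast is None:
        raise ValueError("provide either fit2 or (m_r, contrast)")
    half = contrast.lsd(level) if contrast.sed > 0 else 0.0
    return EquivalenceLimits(
        lower=m_r - half,
        upper=m_r + half,
        center=m_r,
        half_width=half,
        level=level,
        degenerate=bool(degenerate) if degenerate is not None else False,
    )


def test_difference(
    fit1: ModelFit | None = None,
    level: float = 90.0,
    *,
    contrast: ContrastEstimate | None = None,
) -> DifferenceResult:
    """Test D: two-sided `level`% confidence interval for ``m_G - m_C``.

    The difference is significant when the interval excludes zero
    (equivalently, when ``m_C`` falls outside ``m_G +/- lsd``).
    """
    if fit1 is not None:
        if fit1.variant != 1:
            raise ValueError("the difference test uses a variant-1 fit")
        contrast = fit1.contrasts["GC"]
    if contrast is None:
        raise ValueError("provide either fit1 or contrast")
    lo, hi = contrast.confidence_interval(level)
    return DifferenceResult(
        estimate=contrast.estimate,
        lower=lo,
        upper=hi,
        level=level,
        significant=not (lo <= 0.0 <= hi),
    )


def run_equivalence_tests(
    fit1: ModelFit | None,
    fit2: ModelFit | None,
    limits: EquivalenceLimits,
    interval_level: float = 95.0,
    *,
    m_g: float | None = None,
    interval_contrast: ContrastEstimate | None = None,
) -> EquivalenceTests:
    """Step E: tests E1, E2 and E3 against the given limits.

    E2/E3 use the interval ``m_G +/- lsd(GR;1;interval_level)`` built from
    the model-1 GMO-vs-reference contrast.  With degenerate limits the
    verdicts are still computed but flagged unusable.
    """
    if fit1 is not None:
        m_g = fit1.m_g
        interval_contrast = fit1.contrasts["GR"]
    if m_g is None or interval_contrast is None:
        raise ValueError("provide either fit1 or (m_g, interval_contrast)")
    lsd = (
        interval_contrast.lsd(interval_level)
        if interval_contrast.sed > 0
        else 0.0
    )
    lo = m_g - lsd
    hi = m_g + lsd
    inside = limits.contains(m_g)
    e2 = (lo > limits.lower) and (hi < limits.upper)
    e3 = (hi < limits.lower) or (lo > limits.upper)
    # ties sit exactly on a limit: non-rejection, so neither proof succeeds
    return EquivalenceTests(
        e1="equiv_more_likely" if inside else "nonequiv_more_likely",
        e2_proven=bool(e2),
        e3_proven=bool(e3),
        interval_lower=lo,
        interval_upper=hi,
        usable=not limits.degenerate,
    )


def classify_outcome(
    difference: DifferenceResult,
    equivalence: EquivalenceTests,
    limits: EquivalenceLimits,
    m_c: float,
) -> tuple[int | None, str | None, bool]:
    """Map the joint test verdicts to outcome type 1-7 and category i-iv.

    When the no-difference point (the counterpart mean) lies outside the
    equivalence limits the counterpart itself is not equivalent to the
    references; the classification is still returned, but the
    ``counterpart_outside_limits`` flag marks the case for the separate,
    non-statistical discussion it calls for.  Degenerate limits leave the
    type undefined.
    """
    counterpart_outside = not limits.contains(m_c)
    if limits.degenerate or not equivalence.usable:
        return None, None, counterpart_outside
    different = difference.significant
    if equivalence.e3_proven:
        otype = 7
    elif equivalence.e2_proven:
        otype = 2 if different else 1
    elif equivalence.e1 == "equiv_more_likely":
        otype = 4 if different else 3
    else:
        otype = 6 if different else 5
    return otype, CATEGORY_OF_TYPE[otype], counterpart_outside


def assess_analyte(
    data: AnalyteDataset,
    config: AssessmentConfig | None = None,
) -> EquivalenceAssessment:
    """Full assessment of one analyte: fit both model variants, set limits,
    run tests D/E1/E2/E3 and classify the outcome."""
    cfg = config or AssessmentConfig()
    fit1 = fit_model(data, 1, df_method=cfg.df_method)
    fit2 = fit_model(data, 2, df_method=cfg.df_method)
    limits = estimate_equivalence_limits(
        m_r=fit2.m_r,
        contrast=fit2.contrasts[cfg.limit_contrast],
        degenerate=fit2.degenerate_vg,
        level=cfg.limit_level,
    )
    diff = test_difference(fit1, level=cfg.difference_level)
    eq = run_equivalence_tests(
        None,
        None,
        limits,
        interval_level=cfg.interval_level,
        m_g=fit1.m_g,
        interval_contrast=fit1.contrasts[cfg.interval_contrast],
    )
    otype, cat, cp_out = classify_outcome(diff, eq, limits, fit1.m_c)
    return EquivalenceAssessment(
        analyte=data.analyte,
        difference=diff,
        equivalence=eq,
        limits=limits,
        outcome_type=otype,
        category=cat,
        degenerate=limits.degenerate,
        counterpart_outside_limits=cp_out,
        m_c=fit1.m_c,
        m_g=fit1.m_g,
        m_r=fit1.m_r,
    )


def assess_from_summary(
    analyte: str,
    ratio_gc: float,
    sed_gc1: float,
    df_gc1: float,
    ratio_gr: float,
    sed_gr2: float,
    df_gr2: float,
    var_genotype: float,
    gm_reference: float,
    config: AssessmentConfig | None = None,
    df_gr1: float | None = None,
    d_interval: tuple[float, float] | None = None,
    gr_interval: tuple[float, float] | None = None,
) -> EquivalenceAssessment:
    """Assessment reconstructed from published per-analyte summaries.

    Inputs are the natural-scale GMO/counterpart ratio with its model-1 sed
    and df, the GMO/reference-mean ratio with its model-2 sed and df, the
    genotype variance component and the reference geometric mean.  The
    model-1 GMO-vs-reference sed is recovered through the exact relation
    ``sed_GR;1^2 = sed_GR;2^2 - V_g``; since its df is usually not reported,
    ``df_gc1`` serves as a proxy unless ``df_gr1`` is given.

    When the published confidence intervals themselves are available
    (``d_interval`` for the GMO/counterpart ratio, ``gr_interval`` for the
    GMO/reference ratio, both on the natural scale) they take precedence
    over intervals recomputed from the rounded sed/df, so borderline
    verdicts match the published ones exactly.

    The ln-scale origin is placed at the reference mean (``m_R = ln`` of the
    reference geometric mean, ``m_G = m_R + ln(ratio_gr)``), which leaves
    every test verdict unchanged.
    """
    cfg = config or AssessmentConfig()
    m_r = math.log(gm_reference)
    m_g = m_r + math.log(ratio_gr)
    m_c = m_g - math.log(ratio_gc)
    degenerate = var_genotype <= 0.0
    var_gr1 = sed_gr2**2 - var_genotype
    if var_gr1 <= 0:
        raise ValueError(f"{analyte}: genotype variance exceeds sed_GR;2^2")
    c_gc1 = ContrastEstimate(math.log(ratio_gc), sed_gc1, df_gc1)
    c_gr2 = ContrastEstimate(math.log(ratio_gr), sed_gr2, df_gr2)
    c_gr1 = ContrastEstimate(
        math.log(ratio_gr),
        math.sqrt(var_gr1),
        df_gr1 if df_gr1 is not None else df_gc1,
    )
    limits = estimate_equivalence_limits(
        m_r=m_r, contrast=c_gr2, degenerate=degenerate, level=cfg.limit_level
    )
    diff = test_difference(contrast=c_gc1, level=cfg.difference_level)
    if d_interval is not None:
        lo, hi = math.log(d_interval[0]), math.log(d_interval[1])
        diff = DifferenceResult(
            estimate=diff.estimate, lower=lo, upper=hi,
            level=cfg.difference_level, significant=not (lo <= 0.0 <= hi),
        )
    eq = run_equivalence_tests(
        None, None, limits, interval_level=cfg.interval_level,
        m_g=m_g, interval_contrast=c_gr1,
    )
    if gr_interval is not None and not degenerate:
        inside = gr_interval[0] <= 1.0 <= gr_interval[1]
        eq = EquivalenceTests(
            e1="equiv_more_likely" if inside else "nonequiv_more_likely",
            e2_proven=eq.e2_proven,
            e3_proven=eq.e3_proven,
            interval_lower=eq.interval_lower,
            interval_upper=eq.interval_upper,
            usable=eq.usable,
        )
    otype, cat, cp_out = classify_outcome(diff, eq, limits, m_c)
    return EquivalenceAssessment(
        analyte=analyte,
        difference=diff,
        equivalence=eq,
        limits=limits,
        outcome_type=otype,
        category=cat,
        degenerate=degenerate,
        counterpart_outside_limits=cp_out,
        m_c=m_c,
        m_g=m_g,
        m_r=m_r,
    )
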