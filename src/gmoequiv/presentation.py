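"""Three-scale reporting, adjusted display limits and plots.

A single set of equivalence limits is reported on three scales:

1. the natural scale (geometric means, for food/feed experts);
2. the ratio-to-reference scale (GMO relative to the reference mean, the
   direct view of test E1);
3. the adjusted scale relative to the counterpart, on which one confidence
   bar (the difference-test CI) serves visually for both the difference
   and the equivalence tests.

The adjustment rescales the limits so the difference-test CI and the
E2/E3 interval have equal width and shifts them to the counterpart
baseline:

    (m_G - m_C) + [(m_R - m_G) +/- lsd(GR;2;97.5)] * lsd(GC;1;95)/lsd(GR;1;95)

Comparing the difference CI with the adjusted limits is algebraically
identical to the canonical E2/E3 comparison of ``m_G +/- lsd(GR;1;95)``
with the unadjusted limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .assessment import EquivalenceAssessment, EquivalenceLimits
from .mixed_model import ContrastEstimate, ModelFit
from .trial_data import AnalyteDataset, COUNTERPART, GMO, REFERENCE

__all__ = [
    "AdjustedLimits",
    "adjusted_limits",
    "adjusted_limits_from_components",
    "report_scales",
    "render_assessment_plot",
    "render_boxplot",
]

#: display colours by outcome group (types 3-4 share black with degenerate)
_OUTCOME_COLORS = {1: "green", 2: "blue", 3: "black", 4: "black",
                   5: "red", 6: "red", 7: "red", None: "black"}


@dataclass(frozen=True)
class AdjustedLimits:
    """Equivalence limits on the counterpart-baseline ln scale."""

    lower: float
    upper: float
    scaling: float  # lsd(GC;1;95) / lsd(GR;1;95)
    shift: float  # m_G - m_C

    def ratio(self) -> tuple[float, float]:
        """Back-transformed limits as ratios to the counterpart."""
        return (math.exp(self.lower), math.exp(self.upper))

    def contains_interval(self, lo: float, hi: float) -> bool:
        return self.lower < lo and hi < self.upper

    def excludes_interval(self, lo: float, hi: float) -> bool:
        return hi < self.lower or lo > self.upper


def adjusted_limits_from_components(
    m_g_minus_m_c: float,
    m_r_minus_m_g: float,
    lsd_gr2: float,
    lsd_gc1: float,
    lsd_gr1: float,
) -> AdjustedLimits:
    """Apply the adjustment formula to precomputed ln-scale quantities."""
    if lsd_gr1 <= 0:
        raise ValueError("lsd(GR;1) must be positive for the adjustment")
    scaling = lsd_gc1 / lsd_gr1
    lo = m_g_minus_m_c + (m_r_minus_m_g - lsd_gr2) * scaling
    hi = m_g_minus_m_c + (m_r_minus_m_g + lsd_gr2) * scaling
    return AdjustedLimits(lower=lo, upper=hi, scaling=scaling, shift=m_g_minus_m_c)


def adjusted_limits(
    fit1: ModelFit,
    fit2: ModelFit,
    limits: EquivalenceLimits,
    difference_level: float = 90.0,
    interval_level: float = 95.0,
) -> AdjustedLimits:
    """Adjusted display limits from the two model fits.

    Typically asymmetric around zero; with degenerate genotype variance the
    limits are computed but should be displayed flagged, as the assessment
    itself is inconclusive.
    """
    p_diff = 50.0 + difference_level / 2.0
    return adjusted_limits_from_components(
        m_g_minus_m_c=fit1.m_g - fit1.m_c,
        m_r_minus_m_g=fit1.m_r - fit1.m_g,
        lsd_gr2=limits.half_width,
        lsd_gc1=fit1.contrasts["GC"].lsd(p_diff),
        lsd_gr1=fit1.contrasts["GR"].lsd(interval_level),
    )


def report_scales(assessment: EquivalenceAssessment,
                  adjusted: AdjustedLimits | None = None) -> dict[str, dict]:
    """Per-scale report of means, the difference CI and the limits.

    The natural scale back-transforms ln means to geometric means; the
    ratio scale divides by the reference geometric mean; the adjusted scale
    is relative to the counterpart (supply ``adjusted`` to include the
    adjusted limits themselves).
    """
    a = assessment
    out = {
        "natural": {
            "gm_counterpart": math.exp(a.m_c),
            "gm_gmo": math.exp(a.m_g),
            "gm_reference": math.exp(a.m_r),
            "equivalence_limits": a.limits.natural(),
        },
        "ratio_to_reference": {
            "gmo": math.exp(a.m_g - a.m_r),
            "equivalence_limits": a.limits.ratio_to_reference(a.m_g),
        },
        "adjusted": {
            "ratio_gmo_counterpart": a.difference.ratio(),
            "difference_ci": a.difference.ratio_interval(),
        },
    }
    if adjusted is not None:
        out["adjusted"]["equivalence_limits"] = adjusted.ratio()
    return out


def _log2_axis(ax) -> None:
    """Multiplicative axis on which 2x and 1/2x are equally spaced."""
    ax.set_xscale("log", base=2)
    ticks = [0.25, 0.5, 0.7071, 1.0, 1.4142, 2.0, 4.0]
    ax.set_xticks(ticks)
    ax.set_xticklabels(["1/4", "1/2", "0.71", "1", "1.41", "2", "4"])


def render_assessment_plot(
    assessments: list[EquivalenceAssessment],
    path: str,
    adjusted: dict[str, AdjustedLimits] | None = None,
    title: str = "Comparative assessment",
) -> str:
    """Forest-style assessment graph on the adjusted ratio scale.

    One row per analyte: circle and bar for the GMO/counterpart ratio and
    its confidence interval, diamonds for the adjusted equivalence limits,
    a vertical line at ratio 1 (no difference).  Colours follow the outcome
    type: green 1, blue 2, black 3-4 and degenerate, red 5-7.
    """
    if not assessments:
        raise ValueError("no assessments to plot")
    n = len(assessments)
    fig, ax = plt.subplots(figsize=(7.0, 1.2 + 0.26 * n))
    for i, a in enumerate(reversed(assessments)):
        color = _OUTCOME_COLORS.get(a.outcome_type, "black")
        lo, hi = a.difference.ratio_interval()
        ax.plot([lo, hi], [i, i], color=color, lw=1.4)
        ax.plot([a.difference.ratio()], [i], "o", color=color, ms=4)
        adj = None
        if adjusted is not None:
            adj = adjusted.get(a.analyte)
        if adj is not None:
            rlo, rhi = adj.ratio()
            ax.plot([rlo, rhi], [i, i], "D", color=color, ms=5, mfc="none")
    ax.axvline(1.0, color="0.3", lw=1.6)
    ax.set_yticks(range(n))
    ax.set_yticklabels([a.analyte for a in reversed(assessments)], fontsize=7)
    _log2_axis(ax)
    ax.set_xlabel("ratio GMO / counterpart (adjusted scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def render_boxplot(
    data: AnalyteDataset,
    limits: EquivalenceLimits | None,
    path: str,
) -> str:
    """Tukey boxplots of the raw-scale data per group.

    Whiskers reach the extreme points unless these lie farther than 1.5
    box lengths from the quartiles, in which case they are drawn separately
    as crosses.  The reference panel is overlaid with the geometric mean
    and the equivalence limits back-transformed to the natural scale.
    """
    df = data.data
    values = {}
    for grp, label in ((COUNTERPART, "comp"), (GMO, "gmo"), (REFERENCE, "ref")):
        v = df.loc[df["group"] == grp, "y"].to_numpy(float)
        if data.transform == "ln":
            v = np.exp(v)
        if len(v) < 2:
            import warnings

            warnings.warn(f"group {grp!r} has <2 observations; box omitted")
            continue
        values[label] = v
    if not values:
        raise ValueError("no group with enough observations")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.boxplot(
        list(values.values()),
        tick_labels=list(values.keys()),
        whis=1.5,
        sym="x",
    )
    if limits is not None and "ref" in values:
        pos = list(values.keys()).index("ref") + 1
        lo, hi = limits.natural()
        gm = math.exp(limits.center)
        for yv in (lo, gm, hi):
            ax.hlines(yv, pos - 0.35, pos + 0.35, color="tab:blue", lw=2.5)
    ax.set_ylabel(f"{data.analyte} (natural scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
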