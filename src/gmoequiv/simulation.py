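"""Synthetic field trials and operating-characteristic studies.

The generator emulates a multi-site randomised complete block trial on the
ln scale: independent normal random effects for site, block-within-site,
reference genotype and plot residual, with configurable variances.  The
default scenario is 8 sites x 4 blocks x 8 genotypes (GMO, counterpart and
6 reference varieties) with variance components (0.0029, 0.0008, 0.0127,
0.0073) for site, block, genotype and residual - the average components
observed across the 53 analytes of the packaged maize example.

Three kinds of study are provided:

* ``run_power_study``: rejection rates of the difference test D and the
  equivalence tests E1/E2/E3 under a scenario (GMO exchangeable with the
  references, GMO fixed at the equivalence border, or a fixed ln-scale
  offset ``d``).
* ``power_curve``: the same over a grid of offsets.
* ``null_significance_study``: expected count of significant
  GMO-vs-counterpart tests across many analytes when every variety is
  exchangeable (difference driven purely by genotype variance).

Equivalence-test convention.  The operating characteristics of the
two-step procedure are defined conditionally on the equivalence limits, so
the simulator by default evaluates E1/E2/E3 against limits of theoretical
half-width z_{0.975} x sed_GR;2 computed from the *true* variance
components, centred on the estimated reference mean.  Estimated limits
(t-quantile times the estimated sed_GR;2, the rule used for data analysis)
are available via ``limit_rule="estimated"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import VarianceComponents, balanced_sed
from .trial_data import AnalyteDataset, DesignSummary, COUNTERPART, GMO, REFERENCE

__all__ = [
    "SimulationSpec",
    "SimulationSummary",
    "example_field_design",
    "generate_trial_from_design",
    "generate_trial",
    "theoretical_border",
    "run_power_study",
    "power_curve",
    "semi_analytic_power",
    "null_significance_study",
]

DEFAULT_VC = VarianceComponents(site=0.0029, block=0.0008,
                                genotype=0.0127, residual=0.0073)

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class SimulationSpec:
    """Scenario definition for the operating-characteristic studies."""

    n_sites: int = 8
    n_blocks: int = 4
    n_ref: int = 6
    vc: VarianceComponents = DEFAULT_VC
    gmo_rule: Literal["draw_from_reference", "fixed_offset", "at_border"] = (
        "draw_from_reference"
    )
    counterpart_rule: Literal[
        "draw_from_reference", "equal_reference_mean", "equal_gmo"
    ] = "draw_from_reference"
    d: float = 0.0  # ln-scale GMO offset under the fixed_offset rule
    reference_mean: float = 0.0
    n_iter: int = 10_000
    seed: int = 0
    limit_rule: Literal["theoretical", "estimated"] = "theoretical"
    difference_level: float = 90.0  # two-sided %
    equivalence_level: float = 95.0  # one-sided % for the limit quantile
    interval_level: float = 95.0  # one-sided % for the E2/E3 interval

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.n_ref < 2:
            raise ValueError("need at least two reference genotypes")

    @property
    def design(self) -> DesignSummary:
        return DesignSummary(
            n_sites=self.n_sites,
            n_blocks_per_site=self.n_blocks,
            n_ref_genotypes=self.n_ref,
            balanced=True,
            plots_per_site={},
        )


@dataclass(frozen=True)
class SimulationSummary:
    """Monte-Carlo rejection proportions with their standard errors."""

    spec: SimulationSpec
    rate_d: float
    rate_e1: float  # equivalence-more-likely rate (GMO inside limits)
    rate_e2: float  # proven-equivalence rate
    rate_e3: float  # proven-non-equivalence rate
    n_iter: int
    n_nonconverged: int = 0

    def mc_se(self, rate: float) -> float:
        return math.sqrt(rate * (1.0 - rate) / self.n_iter)

    def as_dict(self) -> dict[str, float]:
        return {
            "power_D": self.rate_d,
            "power_E1": self.rate_e1,
            "power_E2": self.rate_e2,
            "power_E3": self.rate_e3,
        }


def theoretical_border(
    vc: VarianceComponents,
    design: DesignSummary,
    quantile_rule: Literal["normal", "t"] = "normal",
) -> tuple[float, float]:
    """Equivalence border on the ln scale, and as a percent difference.

    The border is the half-width of the theoretical equivalence interval:
    the 97.5% quantile (standard normal by default, or t with n_g - 1 df)
    times the closed-form sed_GR;2 at the given variance components.
    Returns ``(b, dif)`` with ``dif = 100 (exp(b) - 1)``.
    """
    sed = balanced_sed(vc, design, "GR", 2)
    if quantile_rule == "normal":
        q = _Z975
    elif quantile_rule == "t":
        q = stats.t.ppf(0.975, design.n_g - 1)
    else:
        raise ValueError("quantile_rule must be 'normal' or 't'")
    b = q * sed
    return float(b), float(100.0 * math.expm1(b))


def _gmo_counterpart_means(spec: SimulationSpec, rng: np.random.Generator, n: int):
    sd_g = math.sqrt(spec.vc.genotype)
    if spec.gmo_rule == "draw_from_reference":
        mg = spec.reference_mean + rng.normal(0.0, sd_g, n)
    elif spec.gmo_rule == "at_border":
        b, _ = theoretical_border(spec.vc, spec.design)
        mg = np.full(n, spec.reference_mean + b)
    elif spec.gmo_rule == "fixed_offset":
        mg = np.full(n, spec.reference_mean + spec.d)
    else:
        raise ValueError(f"unknown gmo_rule {spec.gmo_rule!r}")
    if spec.counterpart_rule == "draw_from_reference":
        mc = spec.reference_mean + rng.normal(0.0, sd_g, n)
    elif spec.counterpart_rule == "equal_reference_mean":
        mc = np.full(n, spec.reference_mean)
    elif spec.counterpart_rule == "equal_gmo":
        mc = mg.copy()
    else:
        raise ValueError(f"unknown counterpart_rule {spec.counterpart_rule!r}")
    return mg, mc


def _simulate_responses(spec: SimulationSpec, rng: np.random.Generator, n: int):
    """Response array of shape (n, n_s, n_r, g); genotype 0 = counterpart,
    1 = GMO, 2.. = references."""
    ns, nr, ng = spec.n_sites, spec.n_blocks, spec.n_ref
    g = ng + 2
    vc = spec.vc
    mg, mc = _gmo_counterpart_means(spec, rng, n)
    site = rng.normal(0.0, math.sqrt(vc.site), (n, ns, 1, 1))
    block = rng.normal(0.0, math.sqrt(vc.block), (n, ns, nr, 1))
    geno = spec.reference_mean + rng.normal(0.0, math.sqrt(vc.genotype), (n, ng))
    y = rng.normal(0.0, math.sqrt(vc.residual), (n, ns, nr, g))
    y += site + block
    y[..., 0] += mc[:, None, None]
    y[..., 1] += mg[:, None, None]
    y[..., 2:] += geno[:, None, None, :]
    return y


def generate_trial(spec: SimulationSpec, iteration: int = 0) -> AnalyteDataset:
    """Generate one balanced synthetic trial as an :class:`AnalyteDataset`.

    Uses a counter-based (Philox) stream keyed by ``(seed, iteration)`` so
    individual trials are reproducible independently of generation order.
    """
    rng = np.random.Generator(np.random.Philox(key=[spec.seed, iteration]))
    y = _simulate_responses(spec, rng, 1)[0]
    ns, nr, ng = spec.n_sites, spec.n_blocks, spec.n_ref
    g = ng + 2
    geno_names = ["counterpart", "gmo"] + [f"ref{i + 1}" for i in range(ng)]
    groups = [COUNTERPART, GMO] + [REFERENCE] * ng
    rows = {
        "site": np.repeat([f"S{i + 1}" for i in range(ns)], nr * g),
        "block": np.tile(np.repeat([f"B{j + 1}" for j in range(nr)], g), ns),
        "genotype": np.tile(geno_names, ns * nr),
        "group": np.tile(groups, ns * nr),
        "y": y.reshape(-1),
    }
    data = pd.DataFrame(rows)
    return AnalyteDataset(
        analyte="simulated",
        data=data,
        exclusions=pd.DataFrame(
            columns=["analyte", "site", "block", "genotype", "action"]
        ),
        design=DesignSummary(ns, nr, ng, True,
                             {f"S{i + 1}": nr * g for i in range(ns)}),
        transform="ln",
    )


def example_field_design() -> pd.DataFrame:
    """Synthetic 67-plot layout emulating a four-site maize field study.

    One GM variety (3 replicates at each of 4 sites), one counterpart (3
    replicates at two sites, 2 at the others) and 13 reference varieties,
    three of which appear at two sites and ten at a single site, mostly in
    3 replicates - 14 to 18 plots per site, 67 plots in total.  Returns a
    frame of (site, block, genotype, group) rows; pair with
    :func:`generate_trial_from_design` to simulate responses.
    """
    layout: dict[str, list[tuple[str, int]]] = {
        "S1": [("gmo", 3), ("counterpart", 3), ("ref01", 3), ("ref04", 3),
               ("ref05", 2), ("ref10", 3)],
        "S2": [("gmo", 3), ("counterpart", 3), ("ref01", 3), ("ref02", 3),
               ("ref06", 3), ("ref07", 2)],
        "S3": [("gmo", 3), ("counterpart", 2), ("ref02", 3), ("ref03", 3),
               ("ref08", 3), ("ref09", 2)],
        "S4": [("gmo", 3), ("counterpart", 2), ("ref03", 3), ("ref11", 3),
               ("ref12", 3), ("ref13", 3)],
    }
    rows = []
    for site, entries in layout.items():
        for genotype, reps in entries:
            group = genotype if genotype in (GMO, COUNTERPART) else REFERENCE
            for j in range(reps):
                rows.append(
                    {"site": site, "block": f"B{j + 1}",
                     "genotype": genotype, "group": group}
                )
    return pd.DataFrame(rows)


def generate_trial_from_design(
    design: pd.DataFrame,
    vc: VarianceComponents = DEFAULT_VC,
    m_counterpart: float = 0.0,
    m_gmo: float = 0.0,
    m_reference: float = 0.0,
    seed: int = 0,
    analyte: str = "simulated",
) -> AnalyteDataset:
    """Simulate ln-scale responses on an arbitrary (site, block, genotype,
    group) layout, e.g. the one from :func:`example_field_design`."""
    rng = np.random.Generator(np.random.Philox(key=[seed, 1]))
    df = design.copy().reset_index(drop=True)
    means = {COUNTERPART: m_counterpart, GMO: m_gmo, REFERENCE: m_reference}
    sites = df["site"].unique()
    blocks = df[["site", "block"]].drop_duplicates()
    refs = df.loc[df["group"] == REFERENCE, "genotype"].unique()
    site_eff = dict(zip(sites, rng.normal(0, math.sqrt(vc.site), len(sites))))
    block_eff = {
        (s, b): e
        for (s, b), e in zip(
            blocks.itertuples(index=False),
            rng.normal(0, math.sqrt(vc.block), len(blocks)),
        )
    }
    ref_eff = dict(zip(refs, rng.normal(0, math.sqrt(vc.genotype), len(refs))))
    y = np.array(
        [
            means[r.group]
            + site_eff[r.site]
            + block_eff[(r.site, r.block)]
            + (ref_eff[r.genotype] if r.group == REFERENCE else 0.0)
            for r in df.itertuples(index=False)
        ]
    ) + rng.normal(0, math.sqrt(vc.residual), len(df))
    data = df.assign(y=y)
    from .trial_data import _design_summary  # shared design computation

    return AnalyteDataset(
        analyte=analyte,
        data=data,
        exclusions=pd.DataFrame(
            columns=["analyte", "site", "block", "genotype", "action"]
        ),
        design=_design_summary(data),
        transform="ln",
    )


def _batch_statistics(spec: SimulationSpec, y: np.ndarray):
    """Vectorised balanced-ANOVA summaries for a batch of trials.

    This is the closed-form EMS path: on a balanced layout it coincides
    with iterative REML (up to the non-negativity truncation, which only
    the variance components need - the mean squares feed the tests
    directly).
    """
    ns, nr, ng = spec.n_sites, spec.n_blocks, spec.n_ref
    g = ng + 2
    m_c = y[..., 0].mean(axis=(1, 2))
    m_g = y[..., 1].mean(axis=(1, 2))
    m_r = y[..., 2:].mean(axis=(1, 2, 3))
    ybar = y.mean(axis=(1, 2, 3))
    site_m = y.mean(axis=(2, 3))
    block_m = y.mean(axis=3)
    geno_m = y.mean(axis=(1, 2))
    ref_m = geno_m[:, 2:]
    ms_gen = ns * nr * ((ref_m - m_r[:, None]) ** 2).sum(1) / (ng - 1)
    pred = (
        site_m[:, :, None, None]
        + (block_m - site_m[:, :, None])[:, :, :, None]
        + (geno_m - ybar[:, None])[:, None, None, :]
    )
    df_res = ns * nr * g - 1 - (ns - 1) - ns * (nr - 1) - (g - 1)
    ss_res = ((y - ybar[:, None, None, None] - (pred - ybar[:, None, None, None])) ** 2
              ).sum(axis=(1, 2, 3))
    ms_res = ss_res / df_res
    return m_c, m_g, m_r, ms_gen, ms_res, df_res


def run_power_study(spec: SimulationSpec, chunk: int = 4096) -> SimulationSummary:
    """Monte-Carlo rejection rates of tests D, E1, E2 and E3.

    Per iteration a balanced trial is generated and summarised through the
    closed-form balanced fitting path; the four tests are then applied:

    * D rejects when |m_G - m_C| exceeds t_{df_res} x sed_GC;1 at the
      two-sided ``difference_level``;
    * the equivalence limits are m_R +/- half-width (theoretical by
      default, see module docstring);
    * E1 declares equivalence-more-likely when m_G lies inside the limits;
    * E2 (E3) is proven when m_G +/- t x sed_GR;1 lies entirely inside
      (outside) the limits, with a Satterthwaite t-quantile.
    """
    ns, nr, ng = spec.n_sites, spec.n_blocks, spec.n_ref
    rng = np.random.Generator(np.random.Philox(key=[spec.seed, 2**32]))
    p_diff = 0.5 + spec.difference_level / 200.0
    alpha_lim = (50.0 + spec.equivalence_level / 2.0) / 100.0
    p_int = spec.interval_level / 100.0
    b_true, _ = theoretical_border(spec.vc, spec.design)

    totals = np.zeros(4)
    done = 0
    while done < spec.n_iter:
        n = min(chunk, spec.n_iter - done)
        y = _simulate_responses(spec, rng, n)
        m_c, m_g, m_r, ms_gen, ms_res, df_res = _batch_statistics(spec, y)
        sed_gc1 = np.sqrt(2.0 * ms_res / (ns * nr))
        var_a = ms_res / (ns * nr)
        var_b = ms_gen / (ng * ns * nr)
        sed_gr1 = np.sqrt(var_a + var_b)
        df_gr1 = (var_a + var_b) ** 2 / (
            var_a**2 / df_res + var_b**2 / (ng - 1)
        )
        rej_d = np.abs(m_g - m_c) > stats.t.ppf(p_diff, df_res) * sed_gc1
        if spec.limit_rule == "theoretical":
            half = b_true
        else:
            sed_gr2 = np.sqrt((1.0 + 1.0 / ng) * ms_gen / (ns * nr))
            half = stats.t.ppf(alpha_lim, ng - 1) * sed_gr2
        lo = m_r - half
        hi = m_r + half
        e1 = (m_g >= lo) & (m_g <= hi)
        lsd1 = stats.t.ppf(p_int, df_gr1) * sed_gr1
        e2 = (m_g - lsd1 > lo) & (m_g + lsd1 < hi)
        e3 = (m_g + lsd1 < lo) | (m_g - lsd1 > hi)
        totals += np.array([rej_d.sum(), e1.sum(), e2.sum(), e3.sum()])
        done += n
    rates = totals / spec.n_iter
    return SimulationSummary(
        spec=spec,
        rate_d=float(rates[0]),
        rate_e1=float(rates[1]),
        rate_e2=float(rates[2]),
        rate_e3=float(rates[3]),
        n_iter=spec.n_iter,
    )


def power_curve(
    spec: SimulationSpec, d_grid: Sequence[float]
) -> pd.DataFrame:
    """Rejection rates over a grid of fixed ln-scale GMO offsets.

    The counterpart mean is held at the reference mean, the usual setting
    for a dose-response power curve.  Returns a tidy frame with one row
    per offset, including the percent difference ``dif = 100 (exp(d)-1)``.
    """
    rows = []
    for i, d in enumerate(d_grid):
        sp = replace(
            spec,
            gmo_rule="fixed_offset",
            counterpart_rule="equal_reference_mean",
            d=float(d),
            seed=spec.seed + i,
        )
        s = run_power_study(sp)
        rows.append(
            {
                "d": float(d),
                "dif_percent": 100.0 * math.expm1(d),
                "power_D": s.rate_d,
                "power_E1": s.rate_e1,
                "power_E2": s.rate_e2,
                "power_E3": s.rate_e3,
            }
        )
    return pd.DataFrame(rows)


def semi_analytic_power(spec: SimulationSpec) -> dict[str, float]:
    """Normal-approximation rejection probabilities (independent oracle).

    Treats all seds as known (plug-in true variance components) and uses
    only the closed-form variance algebra of the balanced design; the
    E2/E3 interval quantile is the t value at the Satterthwaite df implied
    by the true components.  Agreement with the Monte-Carlo rates is
    expected to within 3 percentage points at the default scenario.
    """
    ns, nr, ng = spec.n_sites, spec.n_blocks, spec.n_ref
    vc = spec.vc
    cell = vc.residual / (ns * nr)
    sed_gc1 = math.sqrt(2.0 * cell)
    sed_gr1 = math.sqrt(cell + vc.genotype / ng + vc.residual / (ng * ns * nr))
    b, _ = theoretical_border(spec.vc, spec.design)
    z_d = stats.norm.ppf(0.5 + spec.difference_level / 200.0)
    # Satterthwaite df of sed_GR;1 at the true components
    g = ng + 2
    df_res = ns * nr * g - 1 - (ns - 1) - ns * (nr - 1) - (g - 1)
    var_a = cell
    var_b = (ns * nr * vc.genotype + vc.residual) / (ng * ns * nr)
    df_gr1 = (var_a + var_b) ** 2 / (var_a**2 / df_res + var_b**2 / (ng - 1))
    z_e = stats.t.ppf(spec.interval_level / 100.0, df_gr1)

    # distribution of the true GMO - counterpart difference
    Vg = vc.genotype
    if spec.gmo_rule == "draw_from_reference":
        mu_gr, var_gr = 0.0, Vg
    elif spec.gmo_rule == "at_border":
        mu_gr, var_gr = b, 0.0
    else:
        mu_gr, var_gr = spec.d, 0.0
    if spec.counterpart_rule == "equal_gmo":
        mu_d, var_d = 0.0, 0.0
    elif spec.counterpart_rule == "equal_reference_mean":
        mu_d, var_d = mu_gr, var_gr
    else:
        mu_d, var_d = mu_gr, var_gr + Vg

    def two_sided(mu, sd, thr):
        return float(stats.norm.sf((thr - mu) / sd) + stats.norm.cdf((-thr - mu) / sd))

    sd_d = math.sqrt(var_d + sed_gc1**2)
    power_d = two_sided(mu_d, sd_d, z_d * sed_gc1)

    sd_gr = math.sqrt(var_gr + sed_gr1**2)
    e1 = 1.0 - two_sided(mu_gr, sd_gr, b)
    e2 = max(
        float(
            stats.norm.cdf((b - z_e * sed_gr1 - mu_gr) / sd_gr)
            - stats.norm.cdf((-b + z_e * sed_gr1 - mu_gr) / sd_gr)
        ),
        0.0,
    )
    e3 = two_sided(mu_gr, sd_gr, b + z_e * sed_gr1)
    return {"power_D": power_d, "power_E1": e1, "power_E2": e2, "power_E3": e3}


def null_significance_study(
    vg_per_analyte: Sequence[float],
    sed_per_analyte: Sequence[float],
    df_per_analyte: Sequence[float],
    n_iter: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Expected number of significant difference tests under exchangeability.

    For each analyte a true variety difference ``d ~ N(0, 2 V_g)`` is drawn
    and declared significant when ``|d| > t_{df;0.975} x sed``; the count of
    significant analytes is averaged over iterations.  The returned interval
    is a normal-approximation 95% range of the per-iteration count.
    """
    vg = np.asarray(vg_per_analyte, float)
    sed = np.asarray(sed_per_analyte, float)
    dfs = np.asarray(df_per_analyte, float)
    if not (len(vg) == len(sed) == len(dfs)):
        raise ValueError("per-analyte inputs must have equal length")
    rng = np.random.Generator(np.random.Philox(key=[seed, 0]))
    crit = stats.t.ppf(0.975, dfs) * sed
    d = rng.normal(0.0, 1.0, (n_iter, len(vg))) * np.sqrt(2.0 * vg)
    counts = (np.abs(d) > crit).sum(axis=1)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    return {
        "mean_count": mean,
        "lower95": mean - 1.96 * sd,
        "upper95": mean + 1.96 * sd,
        "sd_count": sd,
        "n_iter": n_iter,
    }
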