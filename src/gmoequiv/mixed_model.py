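"""REML estimation of the comparative-assessment mixed models.

Two model variants share the same fixed structure (one mean per genotype
group: counterpart, GMO, reference) and the same random site and
block-within-site terms; they differ in the random genotype term.

* Variant 1 gives the reference genotypes, and only them, independent
  random effects with variance ``V_g``.  Contrasts between group means are
  then judged against plot-level error only: this is the model for the
  difference test and for the proof-of-(non-)equivalence intervals.
* Variant 2 lets every genotype, including the GMO and the counterpart,
  carry a random effect.  The GMO's (and counterpart's) effect is aliased
  with its fixed group mean, so the restricted likelihood and all variance
  components are identical between the variants; only contrast standard
  errors and degrees of freedom change:

      sed_GC;2^2 = sed_GC;1^2 + 2 V_g,      sed_GR;2^2 = sed_GR;1^2 + V_g.

  Variant 2 is the model for estimating equivalence limits from the spread
  of the reference varieties.

The identity above holds for any layout (the extra random columns lie in
the fixed-effect column space), so a single REML optimisation serves both
variants; the variants differ only in the prediction variance of the group
means and in the degrees-of-freedom computation.

Denominator degrees of freedom use the Kenward-Roger small-sample method by
default, with Satterthwaite available as a configurable alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trial_data import AnalyteDataset, COUNTERPART, GMO, REFERENCE, DesignSummary

__all__ = [
    "VarianceComponents",
    "ContrastEstimate",
    "ModelFit",
    "fit_model",
    "balanced_sed",
    "balanced_anova_fit",
    "approximate_df",
    "wald_test_gxe",
    "ConvergenceError",
]

_GROUP_ORDER = (COUNTERPART, GMO, REFERENCE)

#: variance estimates below this fraction of the total variance count as zero
_BOUNDARY_REL_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components on the ln^2 scale (all >= 0)."""

    site: float
    block: float
    genotype: float
    residual: float

    def __post_init__(self) -> None:
        for name in ("site", "block", "genotype", "residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative variance component {name}")

    @property
    def V_s(self) -> float:
        return self.site

    @property
    def V_b(self) -> float:
        return self.block

    @property
    def V_g(self) -> float:
        return self.genotype

    @property
    def V_eps(self) -> float:
        return self.residual

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.site, self.block, self.genotype, self.residual)


@dataclass(frozen=True)
class ContrastEstimate:
    """A single-df contrast between group means on the ln scale."""

    estimate: float
    sed: float
    df: float

    def lsd(self, p: float) -> float:
        """Least significant difference t_{df;p} * sed for one-sided % p."""
        if not 50.0 < p < 100.0:
            raise ValueError("one-sided percentage must lie in (50, 100)")
        return float(stats.t.ppf(p / 100.0, self.df) * self.sed)

    def confidence_interval(self, level: float) -> tuple[float, float]:
        """Two-sided `level`% confidence interval for the contrast."""
        half = self.lsd(50.0 + level / 2.0)
        return (self.estimate - half, self.estimate + half)


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one model variant to one analyte."""

    variant: int
    m_c: float
    m_g: float
    m_r: float
    vc: VarianceComponents
    contrasts: dict[str, ContrastEstimate]
    degenerate_vg: bool
    converged: bool
    n_obs: int
    reml_loglik: float
    df_method: str
    design: DesignSummary | None = None

    @property
    def means(self) -> dict[str, float]:
        return {"counterpart": self.m_c, "gmo": self.m_g, "reference": self.m_r}


# ---------------------------------------------------------------------------
# design matrices


def _design_matrices(data: pd.DataFrame):
    """Fixed (cell-means by group) and random-effect incidence matrices."""
    n = len(data)
    X = np.zeros((n, 3))
    for j, grp in enumerate(_GROUP_ORDER):
        X[:, j] = (data["group"] == grp).to_numpy(float)
    if not (X.sum(axis=0) > 0).all():
        missing = [g for j, g in enumerate(_GROUP_ORDER) if X[:, j].sum() == 0]
        raise ValueError(f"group(s) missing from data: {missing}")

    def incidence(labels: pd.Series) -> np.ndarray:
        codes, _ = pd.factorize(labels)
        Z = np.zeros((n, codes.max() + 1))
        Z[np.arange(n), codes] = 1.0
        return Z

    Z_site = incidence(data["site"])
    Z_block = incidence(data["site"].astype(str) + "\x00" + data["block"].astype(str))
    ref_mask = (data["group"] == REFERENCE).to_numpy()
    geno_codes, _ = pd.factorize(data.loc[ref_mask, "genotype"])
    Z_ref = np.zeros((n, geno_codes.max() + 1 if ref_mask.any() else 0))
    Z_ref[np.flatnonzero(ref_mask), geno_codes] = 1.0
    return X, Z_site, Z_block, Z_ref


# ---------------------------------------------------------------------------
# REML engine


def _reml_neg2(theta, y, X, G_list):
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], G_list[:-1]):
        V += t * G
    from scipy.linalg import cho_factor, cho_solve

    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, None
    diag = np.diag(cf[0])
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return np.inf, None
    logdetV = 2.0 * np.log(diag).sum()
    Vi_X = cho_solve(cf, X, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, None
    Vi_y = cho_solve(cf, y, check_finite=False)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    yPy = float(r @ cho_solve(cf, r, check_finite=False))
    return logdetV + logdetXtViX + yPy, (V, Vi_X, XtViX, Vi_y, beta)


def _reml_gradient(theta, y, X, G_list):
    val, aux = _reml_neg2(theta, y, X, G_list)
    if aux is None:
        return val, np.zeros(len(theta))
    V, Vi_X, XtViX, Vi_y, beta = aux
    n = len(y)
    Vi = np.linalg.inv(V)
    P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    Py = P @ y
    grad = np.empty(len(theta))
    for i, G in enumerate(G_list):
        PG = P @ G
        grad[i] = np.trace(PG) - float(Py @ G @ Py)
    return val, grad


def _solve_reml(y, X, G_list, start, tol=1e-10, max_restarts=3):
    """Minimise -2 * restricted log-likelihood over variances >= 0."""
    scale = max(float(np.var(y)), 1e-12)
    # residual variance keeps a tiny positive floor so V stays invertible
    bounds = [(0.0, None)] * (len(start) - 1) + [(scale * 1e-10, None)]
    best = None
    starts = [np.asarray(start, float)]
    starts.append(np.full(len(start), scale / len(start)))
    starts.append(np.concatenate([np.full(len(start) - 1, scale * 0.05), [scale]]))
    for s0 in starts[: 1 + max_restarts]:
        res = optimize.minimize(
            lambda th: _reml_gradient(th, y, X, G_list),
            np.maximum(s0, scale * 1e-8),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("REML optimisation failed")
    theta = np.maximum(best.x, 0.0)
    # truncate tiny boundary-hugging estimates exactly to zero
    theta[theta < _BOUNDARY_REL_TOL * scale] = 0.0
    return theta, -0.5 * float(best.fun), bool(best.success)


# ---------------------------------------------------------------------------
# Kenward-Roger / Satterthwaite degrees of freedom


def _kr_quantities(V, X, G_list):
    n, p = X.shape
    Vi = np.linalg.inv(V)
    Vi_X = Vi @ X
    XtViX = X.T @ Vi_X
    Phi = np.linalg.inv(XtViX)
    P_full = Vi - Vi_X @ Phi @ Vi_X.T
    k = len(G_list)
    info = np.empty((k, k))
    PG = [P_full @ G for G in G_list]
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.trace(PG[i] @ PG[j])
    W = np.linalg.pinv(info)  # asymptotic covariance of the variance estimates
    P_i = [Vi_X.T @ G @ Vi_X for G in G_list]  # X' Vi G Vi X
    GViX = [G @ Vi_X for G in G_list]
    Q = {
        (i, j): GViX[i].T @ Vi @ GViX[j]  # X' Vi G_i Vi G_j Vi X
        for i in range(k)
        for j in range(k)
    }
    return Phi, W, P_i, Q


def _kr_df_and_vcov(V, X, G_list, c):
    """Kenward-Roger adjusted covariance and df for a 1-df contrast `c`.

    Follows the original small-sample formulation for covariance structures
    that are linear in the parameters (second derivatives of V vanish).
    """
    Phi, W, P_i, Q = _kr_quantities(V, X, G_list)
    k = len(G_list)
    M = np.zeros_like(Phi)
    for i in range(k):
        for j in range(k):
            M += W[i, j] * (Q[(i, j)] - P_i[i] @ Phi @ P_i[j])
    Phi_A = Phi + 2.0 * Phi @ M @ Phi

    l = 1
    denom = float(c @ Phi @ c)
    Theta = np.outer(c, c) / denom
    A1 = 0.0
    A2 = 0.0
    TP = [Theta @ Phi @ P_i[i] @ Phi for i in range(k)]
    for i in range(k):
        for j in range(k):
            A1 += W[i, j] * np.trace(TP[i]) * np.trace(TP[j])
            A2 += W[i, j] * np.trace(TP[i] @ TP[j])
    if A2 <= 0.0:
        return np.inf, Phi_A
    B = (A1 + 6.0 * A2) / (2.0 * l)
    g = ((l + 1.0) * A1 - (l + 4.0) * A2) / ((l + 2.0) * A2)
    den = 3.0 * l + 2.0 * (1.0 - g)
    c1 = g / den
    c2 = (l - g) / den
    c3 = (l + 2.0 - g) / den
    V0 = 1.0 + c1 * B
    V1 = 1.0 - c2 * B
    V2 = 1.0 - c3 * B
    if abs(V0) < 1e-10:
        V0 = 0.0
    if V1 == 0.0 or V2 == 0.0:
        return np.inf, Phi_A
    rho = (1.0 / l) * (1.0 - A2 / l) ** 2 * V0 / (V1**2 * V2)
    df = 4.0 + (l + 2.0) / (l * rho - 1.0) if l * rho > 1.0 else np.inf
    return float(df), Phi_A


def _satterthwaite_df(V, X, G_list, c):
    Phi, W, P_i, _ = _kr_quantities(V, X, G_list)
    var_c = float(c @ Phi @ c)
    grad = np.array([float(c @ Phi @ P_i[i] @ Phi @ c) for i in range(len(G_list))])
    denom = float(grad @ W @ grad)
    if denom <= 0:
        return np.inf
    return 2.0 * var_c**2 / denom


# ---------------------------------------------------------------------------
# public fitting API


def fit_model(
    data: AnalyteDataset,
    variant: int = 1,
    df_method: Literal["kenward_roger", "satterthwaite"] = "kenward_roger",
) -> ModelFit:
    """Fit one variant of the mixed model by REML.

    Requires at least two sites and both the GMO and the counterpart in the
    data.  Variance components are constrained non-negative; a genotype
    variance estimated at the zero boundary is flagged ``degenerate_vg``
    and, following the boundary policy, standard errors and degrees of
    freedom are then derived from the model that omits the random genotype
    term.
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    df = data.data
    if df["site"].nunique() < 2:
        raise ValueError("at least two sites are required")
    y = df["y"].to_numpy(float)
    X, Z_s, Z_b, Z_r = _design_matrices(df)
    if Z_r.shape[1] == 0:
        raise ValueError("no reference genotypes in data")

    if float(np.var(y)) == 0.0:
        # constant response: all components zero, means equal the constant
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0)
        m = float(y[0])
        zero = ContrastEstimate(0.0, 0.0, np.inf)
        return ModelFit(variant, m, m, m, vc, {"GC": zero, "GR": zero}, True, True,
                        len(y), 0.0, df_method, data.design)

    G_site = Z_s @ Z_s.T
    G_block = Z_b @ Z_b.T
    G_geno1 = Z_r @ Z_r.T
    I_n = np.eye(len(y))
    G_list1 = [G_site, G_block, G_geno1, I_n]

    v0 = float(np.var(y))
    theta, loglik, ok = _solve_reml(y, X, G_list1, [v0 / 8, v0 / 8, v0 / 4, v0 / 2])
    degenerate = theta[2] == 0.0
    vc = VarianceComponents(*theta)

    # variant-2 genotype incidence adds aliased columns for GMO & counterpart
    x_c, x_g = X[:, 0], X[:, 1]
    G_geno2 = G_geno1 + np.outer(x_c, x_c) + np.outer(x_g, x_g)

    if degenerate:
        # boundary policy: inference from the reduced model without genotypes
        G_eff = [G_site, G_block, I_n]
        th_eff = np.array([theta[0], theta[1], theta[3]])
        G_eff2 = G_eff
    else:
        G_eff = G_list1
        th_eff = theta
        G_eff2 = [G_site, G_block, G_geno2, I_n]

    def build_V(G_used, th):
        V = th[-1] * I_n
        for t, G in zip(th[:-1], G_used[:-1]):
            V += t * G
        return V

    V1 = build_V(G_eff, th_eff)
    V2 = build_V(G_eff2, th_eff)
    V = V1 if variant == 1 else V2
    G_used = G_eff if variant == 1 else G_eff2

    Vi_X = np.linalg.solve(V, X)
    Phi = np.linalg.inv(X.T @ Vi_X)
    beta = Phi @ (Vi_X.T @ y)
    m_c, m_g, m_r = (float(b) for b in beta)

    contrasts = {}
    for label, cvec in (("GC", np.array([-1.0, 1.0, 0.0])),
                        ("GR", np.array([0.0, 1.0, -1.0]))):
        sed = math.sqrt(float(cvec @ Phi @ cvec))
        if df_method == "kenward_roger":
            dof, Phi_A = _kr_df_and_vcov(V, X, G_used, cvec)
            sed = math.sqrt(max(float(cvec @ Phi_A @ cvec), 0.0))
        else:
            dof = _satterthwaite_df(V, X, G_used, cvec)
        est = float(cvec @ beta)
        contrasts[label] = ContrastEstimate(est, sed, float(dof))

    return ModelFit(
        variant=variant,
        m_c=m_c,
        m_g=m_g,
        m_r=m_r,
        vc=vc,
        contrasts=contrasts,
        degenerate_vg=bool(degenerate),
        converged=bool(ok),
        n_obs=len(y),
        reml_loglik=loglik,
        df_method=df_method,
        design=data.design,
    )


def approximate_df(fit: ModelFit, contrast: str) -> float:
    """Denominator df of a fitted contrast (``'GC'`` or ``'GR'``)."""
    return fit.contrasts[contrast].df


# ---------------------------------------------------------------------------
# balanced closed forms


def balanced_sed(
    vc: VarianceComponents,
    design: DesignSummary,
    contrast: Literal["GC", "GR"],
    variant: int,
) -> float:
    """Closed-form standard error of difference for a balanced design.

    For a layout with the GMO, the counterpart and ``n_g`` reference
    genotypes each grown once in every one of ``n_r`` blocks at ``n_s``
    sites:

        sed_GC;1 = sqrt(2 V_eps / (n_s n_r))
        sed_GC;2 = sqrt(2 (V_g + V_eps / (n_s n_r)))
        sed_GR;1 = sqrt(V_eps/(n_s n_r) + V_g/n_g + V_eps/(n_g n_s n_r))
        sed_GR;2 = sqrt(V_g + V_eps/(n_s n_r) + V_g/n_g + V_eps/(n_g n_s n_r))
    """
    if not design.balanced:
        raise ValueError("closed-form seds require a balanced design")
    ns, nr, ng = design.n_s, design.n_r, design.n_g
    Ve, Vg = vc.residual, vc.genotype
    cell = Ve / (ns * nr)
    if contrast == "GC":
        base = 2.0 * cell
        extra = 2.0 * Vg
    elif contrast == "GR":
        base = cell + Vg / ng + Ve / (ng * ns * nr)
        extra = Vg
    else:
        raise ValueError("contrast must be 'GC' or 'GR'")
    if variant == 1:
        return math.sqrt(base)
    if variant == 2:
        return math.sqrt(base + extra)
    raise ValueError("variant must be 1 or 2")


@dataclass(frozen=True)
class BalancedAnova:
    """Mean squares and ANOVA variance components for a balanced layout."""

    m_c: float
    m_g: float
    m_r: float
    ms_site: float
    ms_block: float
    ms_genotype: float
    ms_residual: float
    df_site: int
    df_block: int
    df_genotype: int
    df_residual: int
    vc: VarianceComponents
    degenerate_vg: bool
    design: DesignSummary


def balanced_anova_fit(data: AnalyteDataset) -> BalancedAnova:
    """Method-of-moments (EMS) fit for a balanced dataset.

    On balanced data the ANOVA estimators coincide with REML whenever the
    estimates are interior; with the non-negativity truncation applied they
    provide a fast exact path used heavily by the simulation engine.
    """
    if not data.design.balanced:
        raise ValueError("balanced_anova_fit requires a balanced design")
    df = data.data
    ns, nr, ng = data.design.n_s, data.design.n_r, data.design.n_g
    g = ng + 2
    y = df["y"].to_numpy(float)
    ybar = y.mean()
    site_means = df.groupby("site")["y"].mean()
    block_means = df.groupby(["site", "block"])["y"].mean()
    geno_means = df.groupby("genotype")["y"].mean()
    m_c = df.loc[df["group"] == COUNTERPART, "y"].mean()
    m_g = df.loc[df["group"] == GMO, "y"].mean()
    ref = df[df["group"] == REFERENCE]
    m_r = ref["y"].mean()
    ref_means = ref.groupby("genotype")["y"].mean()

    ss_site = g * nr * ((site_means - ybar) ** 2).sum()
    ss_block = g * ((block_means - site_means.reindex(
        block_means.index.get_level_values(0)).to_numpy()) ** 2).sum()
    ss_geno_all = ns * nr * ((geno_means - ybar) ** 2).sum()  # groups + within-ref
    ss_ref = ns * nr * ((ref_means - m_r) ** 2).sum()
    ss_tot = ((y - ybar) ** 2).sum()
    ss_res = ss_tot - ss_site - ss_block - ss_geno_all
    df_site, df_block = ns - 1, ns * (nr - 1)
    df_geno, df_res = ng - 1, ns * nr * g - 1 - (ns - 1) - ns * (nr - 1) - (g - 1)
    ms = dict(
        site=ss_site / df_site,
        block=ss_block / df_block,
        genotype=ss_ref / df_geno,
        residual=max(ss_res, 0.0) / df_res,
    )
    Ve = ms["residual"]
    Vg = max((ms["genotype"] - Ve) / (ns * nr), 0.0)
    Vb = max((ms["block"] - Ve) / g, 0.0)
    Vs = max((ms["site"] - ms["block"]) / (g * nr), 0.0)
    return BalancedAnova(
        m_c=float(m_c), m_g=float(m_g), m_r=float(m_r),
        ms_site=ms["site"], ms_block=ms["block"],
        ms_genotype=ms["genotype"], ms_residual=ms["residual"],
        df_site=df_site, df_block=df_block,
        df_genotype=df_geno, df_residual=df_res,
        vc=VarianceComponents(Vs, Vb, Vg, Ve),
        degenerate_vg=Vg == 0.0,
        design=data.design,
    )


def balanced_contrasts(anova: BalancedAnova, variant: int) -> dict[str, ContrastEstimate]:
    """Contrast estimates with classical/Satterthwaite dfs from mean squares.

    On a balanced layout the contrast variances are linear combinations of
    the independent genotype and residual mean squares, so exact chi-square
    mixing gives the dfs: sed_GC;1 rests on the residual mean square alone
    (classical residual df); sed_GC;2 and sed_GR;2 rest on the genotype mean
    square alone (df = n_g - 1); sed_GR;1 mixes both (Satterthwaite).
    """
    ns, nr, ng = anova.design.n_s, anova.design.n_r, anova.design.n_g
    cell = anova.ms_residual / (ns * nr)
    est_gc = anova.m_g - anova.m_c
    est_gr = anova.m_g - anova.m_r
    out: dict[str, ContrastEstimate] = {}
    if variant == 1:
        out["GC"] = ContrastEstimate(est_gc, math.sqrt(2 * cell), anova.df_residual)
        a = cell
        b = anova.ms_genotype / (ng * ns * nr)
        var = a + b
        dof = var**2 / (a**2 / anova.df_residual + b**2 / anova.df_genotype)
        out["GR"] = ContrastEstimate(est_gr, math.sqrt(var), dof)
    elif variant == 2:
        var_gc = 2 * anova.ms_genotype / (ns * nr)
        out["GC"] = ContrastEstimate(est_gc, math.sqrt(var_gc), anova.df_genotype)
        var_gr = (1 + 1 / ng) * anova.ms_genotype / (ns * nr)
        out["GR"] = ContrastEstimate(est_gr, math.sqrt(var_gr), anova.df_genotype)
    else:
        raise ValueError("variant must be 1 or 2")
    return out


# ---------------------------------------------------------------------------
# genotype-by-environment interaction


def wald_test_gxe(data: AnalyteDataset) -> float:
    """Wald test for a site-specific GMO-vs-counterpart difference.

    Adds fixed site interactions for the test-material pair (GMO and
    counterpart against the references, and GMO against counterpart within
    the pair) to model 1 and tests the latter block.  Returns the p-value
    of the chi-square Wald statistic.
    """
    df = data.data
    n_sites = df["site"].nunique()
    if n_sites < 2:
        raise ValueError("GxE test requires at least two sites")
    y = df["y"].to_numpy(float)
    if float(np.var(y)) == 0.0:
        return 1.0
    X, Z_s, Z_b, Z_r = _design_matrices(df)
    sites = pd.factorize(df["site"])[0]
    pair = (df["group"] != REFERENCE).to_numpy(float)  # GMO + counterpart
    gmo = (df["group"] == GMO).to_numpy(float)
    n = len(y)
    # pair x site (drop last site for identifiability)
    F1 = np.zeros((n, n_sites - 1))
    F2 = np.zeros((n, n_sites - 1))
    for s in range(n_sites - 1):
        F1[:, s] = pair * (sites == s)
        F2[:, s] = gmo * (sites == s)
    X_full = np.column_stack([X, F1, F2])

    G_list = [Z_s @ Z_s.T, Z_b @ Z_b.T, Z_r @ Z_r.T, np.eye(n)]
    v0 = float(np.var(y))
    theta, _, _ = _solve_reml(y, X_full, G_list, [v0 / 8, v0 / 8, v0 / 4, v0 / 2])
    V = theta[3] * np.eye(n)
    for t, G in zip(theta[:3], G_list[:3]):
        V += t * G
    Vi_X = np.linalg.solve(V, X_full)
    XtViX = X_full.T @ Vi_X
    Phi = np.linalg.pinv(XtViX)
    beta = Phi @ (Vi_X.T @ y)
    idx = np.arange(X.shape[1] + F1.shape[1], X_full.shape[1])
    b2 = beta[idx]
    C22 = Phi[np.ix_(idx, idx)]
    stat = float(b2 @ np.linalg.pinv(C22) @ b2)
    rank = int(np.linalg.matrix_rank(C22))
    if rank == 0:
        return 1.0
    return float(stats.chi2.sf(stat, rank))
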