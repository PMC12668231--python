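"""Biophysical length-dependence model of mRNA sedimentation.

Baseline (no condensation): the sedimented fraction of a transcript of
length L grows as a power law, giving

    pSup(L) = 1 - beta * L**x.

Under condensation, inter-mRNA interactions add a per-transcript term mu
and a per-nucleotide term nu, multiplying the sedimented fraction:

    pSup(L) = 1 - beta * L**x * exp(sign * (mu + nu * L))

where ``sign`` (+1 default) sets the convention in which positive mu, nu
mean more condensation.  Fits minimize squared error on the log-odds(pSup)
scale (residuals approximately normal there).  The contribution of the
length-independent term is assessed by a nested-model F-test: the reduced
model drops mu, and the F statistic compares residual sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logit

__all__ = [
    "SedModelParams",
    "SedModelFit",
    "FTestResult",
    "predict_psup",
    "fit_baseline",
    "fit_stress",
    "nested_f_test",
]

_EPS = 1e-6


@dataclass
class SedModelParams:
    """Parameters of the sedimentation length-dependence model."""

    beta: float
    x: float
    mu: float = 0.0
    nu: float = 0.0
    exponent_sign: int = 1

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.exponent_sign not in (1, -1):
            raise ValueError("exponent_sign must be +1 or -1")


@dataclass
class SedModelFit:
    """A fitted model: parameters, RSS, and bookkeeping for nesting."""

    params: SedModelParams
    rss: float
    n_obs: int
    n_free_params: int
    converged: bool = True


@dataclass
class FTestResult:
    F: float
    df_num: int
    df_den: int
    p_value: float
    rss_full: float
    rss_reduced: float


def predict_psup(L, params: SedModelParams, eps: float = _EPS):
    """pSup(L) = 1 - min(beta*L^x*exp(sign*(mu+nu*L)), 1-eps)."""
    L = np.asarray(L, dtype=float)
    f = params.beta * L**params.x * np.exp(
        params.exponent_sign * (params.mu + params.nu * L)
    )
    out = 1.0 - np.minimum(f, 1.0 - eps)
    return float(out) if out.ndim == 0 else out


def _prepare(psup_table: pd.DataFrame, annotation: pd.DataFrame):
    from .scores import average_replicates

    tab = average_replicates(psup_table)
    tab = tab.merge(annotation[["gene_id", "length_total"]], on="gene_id")
    tab = tab.dropna(subset=["psup"])
    tab = tab[(tab["psup"] > 0) & (tab["psup"] < 1)]
    tab = tab.sort_values("gene_id", kind="stable")
    L = tab["length_total"].to_numpy(dtype=float)
    y = logit(tab["psup"].to_numpy(dtype=float))
    return L, y


def fit_baseline(
    psup_table: pd.DataFrame,
    annotation: pd.DataFrame,
    exponent_sign: int = 1,
    n_starts: int = 8,
) -> SedModelFit:
    """Fit (beta, x) on log-odds(pSup) by multi-start trust-region NLS.

    Starts cover a log-spaced grid in beta and x; the best of all
    converged starts is returned.
    """
    L, y = _prepare(psup_table, annotation)
    if len(L) < 10:
        raise ValueError(f"need >= 10 usable genes, got {len(L)}")

    def resid(theta):
        beta, x = np.exp(theta)
        f = np.minimum(beta * L**x, 1.0 - _EPS)
        return logit(1.0 - f) - y

    # grid of starts: beta such that median gene starts at various pSup
    medL = np.median(L)
    best = None
    xs = np.geomspace(0.4, 2.5, max(n_starts // 2, 1))
    fracs = (0.1, 0.5)
    for x0 in xs:
        for f0 in fracs:
            theta0 = np.array([np.log(f0 / medL**x0), np.log(x0)])
            try:
                res = optimize.least_squares(
                    resid, theta0, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success:
        raise RuntimeError("baseline fit failed to converge from any start")
    beta, x = np.exp(best.x)
    rss = float(2.0 * best.cost)
    params = SedModelParams(beta=float(beta), x=float(x), exponent_sign=exponent_sign)
    return SedModelFit(params=params, rss=rss, n_obs=len(L), n_free_params=2)


def fit_stress(
    psup_table: pd.DataFrame,
    annotation: pd.DataFrame,
    baseline: SedModelParams,
    fit_mu: bool = True,
    fit_nu: bool = True,
) -> SedModelFit:
    """Fit the condensation terms (mu, nu) with (beta, x) held fixed.

    The enabled subset of {mu, nu} is optimized on the log-odds scale;
    disabling mu gives the reduced, length-only model used in the nested
    F-test.
    """
    if not (fit_mu or fit_nu):
        raise ValueError("at least one of fit_mu, fit_nu must be enabled")
    L, y = _prepare(psup_table, annotation)
    sign = baseline.exponent_sign
    f0 = baseline.beta * L**baseline.x

    # scale nu by mean length so both free parameters are O(1)
    Lbar = L.mean()

    def unpack(theta):
        i = 0
        mu = nu = 0.0
        if fit_mu:
            mu = theta[i]
            i += 1
        if fit_nu:
            nu = theta[i] / Lbar
        return mu, nu

    def resid(theta):
        mu, nu = unpack(theta)
        f = np.minimum(f0 * np.exp(sign * (mu + nu * L)), 1.0 - _EPS)
        return logit(1.0 - f) - y

    k = int(fit_mu) + int(fit_nu)
    starts = [np.zeros(k), np.full(k, 0.5), np.full(k, -0.5)]
    if k == 2:
        # seed with the optima of each single-parameter restriction so the
        # full fit provably dominates the nested fits (RSS_full <= RSS_red)
        for frozen in (0, 1):
            def resid1(t1, frozen=frozen):
                th = np.zeros(2)
                th[1 - frozen] = t1[0]
                return resid(th)

            r1 = optimize.least_squares(resid1, np.zeros(1), method="trf",
                                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
            th = np.zeros(2)
            th[1 - frozen] = r1.x[0]
            starts.append(th)
    best = None
    for start in starts:
        res = optimize.least_squares(
            resid, start, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        if best is None or res.cost < best.cost:
            best = res
    mu, nu = unpack(best.x)
    params = replace(baseline, mu=float(mu), nu=float(nu))
    return SedModelFit(
        params=params, rss=float(2.0 * best.cost), n_obs=len(L), n_free_params=k
    )


def nested_f_test(full: SedModelFit, reduced: SedModelFit) -> FTestResult:
    """F-test of a reduced model nested in a full model on the same data.

    F = ((RSS_r - RSS_f) / df_num) / (RSS_f / df_den), df_num the
    difference in free parameters, df_den = n_obs - p_full.
    """
    if reduced.n_free_params >= full.n_free_params:
        raise ValueError("reduced model must have fewer free parameters")
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on the same data (n_obs differ)")
    if reduced.rss < full.rss * (1.0 - 1e-9):
        raise ValueError(
            "reduced RSS < full RSS: models are not nested or the full "
            "optimization failed"
        )
    df_num = full.n_free_params - reduced.n_free_params
    df_den = full.n_obs - full.n_free_params
    rss_f, rss_r = full.rss, max(reduced.rss, full.rss)
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return FTestResult(
        F=float(F), df_num=df_num, df_den=df_den, p_value=p,
        rss_full=rss_f, rss_reduced=rss_r,
    )
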