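"""Mutant-vs-WT comparative interactome capture: shift coefficients.

Per protein, the RIC/WCE ratio of each genotype is summarized by its mean
and a propagated uncertainty (second-order Taylor expansion on the ratio of
means, or the exact difference formula in log2 space).  The mutant-minus-WT
shift is rescaled by a constant (mean-centering over crosslinked proteins,
i.e. a constant multiplicative factor in linear space), turned into n
pseudo-replicates with *exact* sample moments, and tested against zero
with the moderated t-test.  Because the pseudo-replicates have exact sample
mean and SD, the resulting statistics are invariant to the simulation seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import (
    VariancePrior,
    adjust_p,
    fit_variance_prior,
    moderated_t,
)
from .tables import IntensityTable

SHIFT_COLUMNS = [
    "protein_id",
    "shift",
    "se_shift",
    "t_mod",
    "df_total",
    "p",
    "q_fdr",
    "detected_in_mutant",
    "rescale_constant_applied",
]


@dataclass(frozen=True)
class RatioMoments:
    """Means and squared standard errors of the RIC and WCE signals.

    scale="log2_difference": mu are mean log2 intensities and the ratio is
    f = x - y (exact propagation).  scale="linear_ratio": mu are means on
    the linear intensity scale and the ratio is f = x / y (second-order
    Taylor propagation).  cov is the covariance of the two *means*.
    """

    mu_ric: float
    mu_wce: float
    var_ric: float
    var_wce: float
    cov: float = 0.0
    scale: str = "log2_difference"

    def __post_init__(self) -> None:
        if self.var_ric < 0 or self.var_wce < 0:
            raise ValueError("variances must be >= 0")
        bound = math.sqrt(self.var_ric * self.var_wce)
        if abs(self.cov) > bound + 1e-12:
            raise ValueError("|cov| must be <= sqrt(var_ric * var_wce)")
        if self.scale not in ("log2_difference", "linear_ratio"):
            raise ValueError("scale must be 'log2_difference' or 'linear_ratio'")


@dataclass(frozen=True)
class CompareConfig:
    propagation: str = "log2_difference"
    covariance: str = "paired"  # or "independent" (cov = 0)
    pseudo_n: int = 3
    pseudo_sd_scale: str = "sqrt_n"  # or "literal" (SD = propagated SE)
    min_detected: int = 1
    seed: int = 0


def taylor_propagate(moments: RatioMoments) -> tuple[float, float]:
    """Second-order Taylor propagation of the ratio statistic.

    For jointly Gaussian (x, y) with mean mu and covariance Sigma,
    E[f] ~ f(mu) + 1/2 tr(H Sigma) and
    Var[f] ~ g' Sigma g + 1/2 tr((H Sigma)^2), with gradient g and Hessian
    H at mu.  For f = x - y the Hessian vanishes and the result is exact;
    for f = x / y both corrections are nonzero.
    """
    mx, my = moments.mu_ric, moments.mu_wce
    sigma = np.array(
        [[moments.var_ric, moments.cov], [moments.cov, moments.var_wce]]
    )
    if moments.scale == "log2_difference":
        e = mx - my
        var = moments.var_ric + moments.var_wce - 2.0 * moments.cov
        return float(e), float(max(var, 0.0))
    if my == 0:
        raise ValueError("linear_ratio propagation requires mu_wce != 0")
    g = np.array([1.0 / my, -mx / my**2])
    h = np.array([[0.0, -1.0 / my**2], [-1.0 / my**2, 2.0 * mx / my**3]])
    hs = h @ sigma
    e = mx / my + 0.5 * np.trace(hs)
    var = g @ sigma @ g + 0.5 * np.trace(hs @ hs)
    return float(e), float(max(var, 0.0))


def empirical_mvn(
    n: int, mean: float, sd: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n values whose *sample* mean and SD (n-1 denominator) are exact.

    Standard normals are centered to sample mean zero, rescaled so that the
    sample SD equals ``sd`` exactly, and shifted by ``mean`` (the
    empirical=TRUE construction).  A degenerate all-equal draw is redrawn.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd == 0.0:
        return np.full(n, float(mean))
    for _ in range(100):
        z = rng.standard_normal(n)
        z = z - z.mean()
        s = z.std(ddof=1)
        if s > 0:
            return mean + sd * z / s
    raise RuntimeError("degenerate normal draws")  # pragma: no cover


def _empirical_mvn_matrix(
    n: int, means: np.ndarray, sds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized exact-moment draws: one row of n values per protein."""
    m = len(means)
    z = rng.standard_normal((m, n))
    z = z - z.mean(axis=1, keepdims=True)
    s = z.std(axis=1, ddof=1)
    bad = s == 0
    while bad.any():  # pragma: no cover - probability zero
        z[bad] = rng.standard_normal((int(bad.sum()), n))
        z[bad] -= z[bad].mean(axis=1, keepdims=True)
        s = z.std(axis=1, ddof=1)
        bad = s == 0
    return means[:, None] + sds[:, None] * z / s[:, None]


def rescale_shifts(raw_shifts, crosslinked_mask) -> tuple[float, np.ndarray]:
    """Mean-center shifts over the crosslinked set (constant log2 factor).

    Returns (c, raw + c) with c = -mean(raw over mask); after correction the
    crosslinked-set mean shift is zero, so the operation is idempotent.
    """
    raw = np.asarray(raw_shifts, dtype=float)
    mask = np.asarray(crosslinked_mask, dtype=bool)
    if mask.shape != raw.shape:
        raise ValueError("mask shape must match shifts")
    if not mask.any():
        raise ValueError("crosslinked mask is empty")
    c = -float(raw[mask].mean())
    return c, raw + c


def _paired_ratio_moments(
    table: IntensityTable, config: CompareConfig
) -> pd.DataFrame:
    """Per-protein RatioMoments fields for one genotype's table."""
    ric_ids = sorted(
        table.sample_ids_where(fraction="RIC"),
        key=lambda s: (table.meta(s).batch, table.meta(s).replicate),
    )
    wce_ids = sorted(
        table.sample_ids_where(fraction="WCE"),
        key=lambda s: (table.meta(s).batch, table.meta(s).replicate),
    )
    if len(ric_ids) != len(wce_ids) or len(ric_ids) < 2:
        raise ValueError("need matched RIC/WCE replicates (>= 2)")
    n = len(ric_ids)
    ric = table.values[ric_ids].to_numpy()
    wce = table.values[wce_ids].to_numpy()

    if config.propagation == "linear_ratio":
        ric = np.exp2(ric)
        wce = np.exp2(wce)

    mu_ric = ric.mean(axis=1)
    mu_wce = wce.mean(axis=1)
    var_ric = ric.var(axis=1, ddof=1) / n
    var_wce = wce.var(axis=1, ddof=1) / n
    if config.covariance == "paired":
        cov = (
            ((ric - mu_ric[:, None]) * (wce - mu_wce[:, None])).sum(axis=1)
            / (n - 1)
            / n
        )
        # numerical guard: keep |cov| within the Cauchy-Schwarz bound
        bound = np.sqrt(var_ric * var_wce)
        cov = np.clip(cov, -bound, bound)
    elif config.covariance == "independent":
        cov = np.zeros(len(mu_ric))
    else:
        raise ValueError("covariance must be 'paired' or 'independent'")
    return pd.DataFrame(
        {
            "mu_ric": mu_ric,
            "mu_wce": mu_wce,
            "var_ric": var_ric,
            "var_wce": var_wce,
            "cov": cov,
            "n": n,
        },
        index=table.values.index,
    )


def _propagate_frame(mom: pd.DataFrame, config: CompareConfig) -> tuple[np.ndarray, np.ndarray]:
    e = np.empty(len(mom))
    v = np.empty(len(mom))
    for i, row in enumerate(mom.itertuples()):
        ev, vv = taylor_propagate(
            RatioMoments(
                mu_ric=row.mu_ric,
                mu_wce=row.mu_wce,
                var_ric=row.var_ric,
                var_wce=row.var_wce,
                cov=row.cov,
                scale=config.propagation,
            )
        )
        if config.propagation == "linear_ratio":
            # the reported shift is a log2 fold change; delta-method transform
            if ev <= 0:
                raise ValueError("linear-ratio expectation is non-positive")
            vv = vv / (ev * math.log(2.0)) ** 2
            ev = math.log2(ev)
        e[i] = ev
        v[i] = vv
    return e, v


def compare(
    wt: IntensityTable,
    mut: IntensityTable,
    config: CompareConfig = CompareConfig(),
) -> tuple[pd.DataFrame, float]:
    """Comparative shift coefficients (mutant minus WT RIC/WCE ratios).

    Both tables must already be imputed and median-normalized and share the
    same protein universe (use :func:`ric_activity.pipeline.prepare_pair`).
    Returns the per-protein shift table (restricted to proteins detected in
    RIC of at least one genotype) and the applied rescale constant.
    """
    if list(wt.values.index) != list(mut.values.index):
        raise ValueError("WT and mutant tables must share the same protein universe")

    mom_wt = _paired_ratio_moments(wt, config)
    mom_mut = _paired_ratio_moments(mut, config)
    e_wt, v_wt = _propagate_frame(mom_wt, config)
    e_mut, v_mut = _propagate_frame(mom_mut, config)

    raw_shift = e_mut - e_wt
    se_shift = np.sqrt(v_mut + v_wt)

    obs_wt = wt.observed()
    obs_mut = mut.observed()
    ric_wt = obs_wt[wt.sample_ids_where(fraction="RIC")].sum(axis=1).to_numpy()
    ric_mut = obs_mut[mut.sample_ids_where(fraction="RIC")].sum(axis=1).to_numpy()
    detected_wt = ric_wt >= config.min_detected
    detected_mut = ric_mut >= config.min_detected
    crosslinked = detected_wt & detected_mut

    c, corrected = rescale_shifts(raw_shift, crosslinked)

    keep = detected_wt | detected_mut
    ids = wt.values.index.to_numpy()[keep]
    shift = corrected[keep]
    se = se_shift[keep]
    det_mut = detected_mut[keep]

    n = config.pseudo_n
    sd_scale = {"literal": 1.0, "sqrt_n": math.sqrt(n)}.get(config.pseudo_sd_scale)
    if sd_scale is None:
        raise ValueError("pseudo_sd_scale must be 'literal' or 'sqrt_n'")
    rng = np.random.default_rng(config.seed)
    pseudo = _empirical_mvn_matrix(n, shift, se * sd_scale, rng)
    s2 = pseudo.var(axis=1, ddof=1)

    # The pseudo-replicates carry the propagated SE *exactly*, so the
    # scatter of these variances across proteins is that of the underlying
    # replicate-based SE estimate; moment-matching therefore uses its
    # effective degrees of freedom, (n_wt - 1) + (n_mut - 1), not the
    # nominal pseudo-replicate count.
    df_eff = float(mom_wt["n"].iloc[0] - 1 + mom_mut["n"].iloc[0] - 1)
    positive = s2 > 0
    if positive.sum() >= 2:
        prior = fit_variance_prior(s2[positive], df_eff)
    else:
        # degenerate (noise-free) input: point prior at a tiny variance so
        # zero shifts give p = 1 and nonzero shifts give p ~ 0
        prior = VariancePrior(d0=math.inf, s0sq=1e-24)
    t, df_total, p = moderated_t(shift, s2, n, prior, df=df_eff)
    q = adjust_p(p, "fdr")

    out = pd.DataFrame(
        {
            "protein_id": ids,
            "shift": shift,
            "se_shift": se,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "q_fdr": q,
            "detected_in_mutant": det_mut,
            "rescale_constant_applied": c,
        }
    )
    out.attrs["prior"] = prior
    return out, c
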