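"""Single-condition enrichment statistics for interactome capture.

Pipeline: background imputation at a fixed log2 floor, per-column median
centering, paired (RIC vs WCE) or unpaired (CL vs noCL) log2 fold changes,
an empirical-Bayes moderated one-sample t-test (scaled inverse-chi-square
variance prior fitted by moment matching on log variances), and BH /
Bonferroni multiple-testing adjustment.  Population flags follow the full
circle / empty circle / cross convention (detected in both fractions, RIC
only, WCE only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .tables import (
    POPULATION_BOTH,
    POPULATION_RIC_ONLY,
    POPULATION_WCE_ONLY,
    IntensityTable,
)

# smallest reported P-value; keeps p in (0, 1] even for infinite t
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class VariancePrior:
    """Scaled inverse-chi-square prior on per-protein variances.

    d0 is the prior degrees of freedom (+inf collapses to a point prior;
    0 recovers the ordinary, unmoderated t-test), s0sq the prior variance
    (log2-units squared).
    """

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or math.isnan(self.d0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0sq > 0):
            raise ValueError("s0sq must be positive")


@dataclass(frozen=True)
class EnrichmentConfig:
    impute_value: float = 18.0
    min_detected: int = 1


ENRICHMENT_COLUMNS = [
    "protein_id",
    "population",
    "mean_log2fc",
    "ratio_sd",
    "n_pairs",
    "t_mod",
    "df_total",
    "p",
    "q_fdr",
    "q_bonf",
    "n_imputed_ric",
    "n_imputed_wce",
]


# ---------------------------------------------------------------------------
# normalization


def impute_background(
    table: IntensityTable, value: float = 18.0, scope: str = "batch"
) -> IntensityTable:
    """Fill every missing cell with the fixed background value (log2).

    The fill value is a constant, so per-batch and global scope give the
    same numbers; the parameter records that missingness is assessed at the
    level of the triplicate experiments, before batches are merged.
    """
    if scope not in ("batch", "global"):
        raise ValueError("scope must be 'batch' or 'global'")
    out = table.copy()
    missing = out.values.isna()
    out.values[missing] = float(value)
    out.imputed |= missing
    return out


def median_normalize(table: IntensityTable) -> IntensityTable:
    """Subtract each column's median so that every column has median zero."""
    out = table.copy()
    for col in out.values.columns:
        column = out.values[col]
        if column.isna().all():
            raise ValueError(f"column {col!r} is all-missing; cannot normalize")
        out.values[col] = column - column.median()
    return out


def mean_log2_fc(
    table: IntensityTable,
    group_a: list[str],
    group_b: list[str],
    paired: bool,
):
    """Per-protein mean log2 fold change of group A over group B.

    Paired mode matches samples by (batch, genotype-agnostic replicate
    label): both groups must have equal size and identical (batch,
    replicate) multisets; it returns ``(mean, diffs)`` with ``diffs`` the
    per-pair differences (proteins x pairs).  Unpaired mode returns
    ``(mean_a - mean_b, (mean_a, mean_b))``.
    """
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    va = table.values[group_a]
    vb = table.values[group_b]
    if not paired:
        mean_a = va.mean(axis=1)
        mean_b = vb.mean(axis=1)
        return mean_a - mean_b, (mean_a, mean_b)

    def pair_key(sid: str):
        m = table.meta(sid)
        return (m.batch, m.replicate)

    keys_a = sorted(group_a, key=pair_key)
    keys_b = sorted(group_b, key=pair_key)
    if len(keys_a) != len(keys_b) or [pair_key(s) for s in keys_a] != [
        pair_key(s) for s in keys_b
    ]:
        raise ValueError(
            "paired mode requires matched (batch, replicate) labels between groups"
        )
    diffs = pd.DataFrame(
        va[keys_a].to_numpy() - vb[keys_b].to_numpy(),
        index=table.values.index,
        columns=[f"pair_{table.meta(s).batch}_{table.meta(s).replicate}" for s in keys_a],
    )
    return diffs.mean(axis=1), diffs


# ---------------------------------------------------------------------------
# moderated t machinery


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration).

    trigamma is strictly decreasing; for large x, trigamma(x) ~ 1/x.
    """
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(variances, df) -> VariancePrior:
    """Moment-match the scaled inverse-chi-square prior on log variances.

    With s_g^2 ~ s0^2 * (d0/chi2_d0) * (chi2_d / d) marginally, the log
    variance e_g = ln s_g^2 - psi(d/2) + ln(d/2) has mean
    ln s0^2 + psi(d0/2) - ln(d0/2) and excess variance psi'(d0/2) above the
    sampling term psi'(d/2).  Solving the trigamma equation for d0 and
    back-substituting gives s0^2.  Zero/negative variances are excluded
    from the fit (but are still moderated downstream).
    """
    s2 = np.asarray(variances, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    usable = np.isfinite(s2) & (s2 > 0) & (d > 0)
    if usable.sum() < 2:
        raise ValueError("need at least 2 positive finite variances to fit the prior")
    s2 = s2[usable]
    d = d[usable]

    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(_trigamma(d / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = math.inf
        s0sq = float(np.exp(emean))
    return VariancePrior(d0=d0, s0sq=s0sq)


def posterior_variance(s2, df, prior: VariancePrior):
    """Shrink per-protein variances toward the prior: (d0 s0^2 + d s^2)/(d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(df, dtype=float)
    if math.isinf(prior.d0):
        return np.full_like(s2, prior.s0sq)
    return (prior.d0 * prior.s0sq + d * s2) / (prior.d0 + d)


def moderated_t(
    mean,
    s2,
    n,
    prior: VariancePrior,
    df=None,
    se_scale=None,
):
    """Moderated one-sample t-test of the mean against zero.

    With d = n - 1 (override via ``df`` for pooled two-group designs) the
    posterior variance is s~^2 = (d0 s0^2 + d s^2)/(d0 + d); the statistic
    is t = mean / (s~ * se_scale) with se_scale = 1/sqrt(n) by default, on
    d0 + d degrees of freedom (standard normal when d0 is infinite).
    Returns (t, df_total, p); p is two-sided and lies in (0, 1].
    """
    mean = np.asarray(mean, dtype=float)
    scalar = mean.ndim == 0
    mean = np.atleast_1d(mean)
    s2 = np.broadcast_to(np.asarray(s2, dtype=float), mean.shape)
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), mean.shape)
    if np.any(n_arr < 2):
        raise ValueError("need n >= 2")
    if np.any(s2 < 0):
        raise ValueError("variances must be >= 0")
    d = (
        n_arr - 1.0
        if df is None
        else np.broadcast_to(np.asarray(df, dtype=float), mean.shape)
    )
    scale = (
        1.0 / np.sqrt(n_arr)
        if se_scale is None
        else np.broadcast_to(np.asarray(se_scale, dtype=float), mean.shape)
    )

    s2_post = posterior_variance(s2, d, prior)
    if np.any(s2_post <= 0):
        raise ValueError("posterior variance is zero; cannot form t-statistic")
    t = mean / (np.sqrt(s2_post) * scale)
    df_total = prior.d0 + d if not math.isinf(prior.d0) else np.full_like(d, math.inf)
    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(t)),
            2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
        )
    p = np.clip(p, _P_FLOOR, 1.0)
    if scalar:
        return float(t[0]), float(df_total[0]), float(p[0])
    return t, df_total, p


def adjust_p(p_values, method: str):
    """Multiple-testing adjustment: 'fdr' (Benjamini-Hochberg) or 'bonferroni'."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method == "fdr":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise ValueError("method must be 'fdr' or 'bonferroni'")


# ---------------------------------------------------------------------------
# population flags and the full table


def population_flags(
    table: IntensityTable,
    ric_samples: list[str],
    wce_samples: list[str],
    min_detected: int = 1,
) -> pd.Series:
    """Per-protein detection flag from pre-imputation missingness.

    Proteins detected (observed in >= min_detected replicates) in both
    fractions map to "both", RIC only to "ric_only", WCE only to
    "wce_only"; proteins detected in neither are dropped.
    """
    obs = table.observed()
    ric_n = obs[ric_samples].sum(axis=1)
    wce_n = obs[wce_samples].sum(axis=1)
    in_ric = ric_n >= min_detected
    in_wce = wce_n >= min_detected
    flags = pd.Series(index=table.values.index, dtype=object)
    flags[in_ric & in_wce] = POPULATION_BOTH
    flags[in_ric & ~in_wce] = POPULATION_RIC_ONLY
    flags[~in_ric & in_wce] = POPULATION_WCE_ONLY
    return flags.dropna()


def enrichment_table(
    table: IntensityTable,
    mode: str,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Full enrichment statistics for one (imputed, normalized) table.

    mode="wce": paired per-replicate log2 RIC/WCE ratios (matched by batch
    and replicate), moderated one-sample t on the paired differences.
    mode="nocl": unpaired CL (RIC) vs noCL contrast on raw intensities with
    pooled variance and d = n1 + n2 - 2.
    """
    if mode not in ("wce", "nocl"):
        raise ValueError("mode must be 'wce' or 'nocl'")
    ric_ids = table.sample_ids_where(fraction="RIC")
    wce_ids = table.sample_ids_where(fraction="WCE")
    if not ric_ids or not wce_ids:
        raise ValueError("table needs both RIC and WCE samples")

    flags = population_flags(table, ric_ids, wce_ids, config.min_detected)

    if mode == "wce":
        mean_fc, diffs = mean_log2_fc(table, ric_ids, wce_ids, paired=True)
        n = diffs.shape[1]
        s2 = diffs.var(axis=1, ddof=1)
        sd = np.sqrt(s2)
        df = float(n - 1)
        se_scale = 1.0 / math.sqrt(n)
        n_pairs = n
    else:
        nocl_ids = table.sample_ids_where(fraction="noCL")
        if not nocl_ids:
            raise ValueError("mode='nocl' requires noCL samples")
        mean_fc, (_, _) = mean_log2_fc(table, ric_ids, nocl_ids, paired=False)
        n1, n2 = len(ric_ids), len(nocl_ids)
        s2 = (
            (n1 - 1) * table.values[ric_ids].var(axis=1, ddof=1)
            + (n2 - 1) * table.values[nocl_ids].var(axis=1, ddof=1)
        ) / (n1 + n2 - 2)
        sd = np.sqrt(s2)
        df = float(n1 + n2 - 2)
        se_scale = math.sqrt(1.0 / n1 + 1.0 / n2)
        n_pairs = n1

    keep = flags.index
    mean_fc = mean_fc.loc[keep]
    s2 = s2.loc[keep]
    sd = sd.loc[keep]

    positive = s2[s2 > 0].to_numpy()
    if len(positive) >= 2:
        prior = fit_variance_prior(positive, df)
    else:
        # degenerate (noise-free) input: point prior at a tiny variance so
        # zero contrasts give p = 1 and nonzero contrasts p ~ 0
        prior = VariancePrior(d0=math.inf, s0sq=1e-24)
    t, df_total, p = moderated_t(
        mean_fc.to_numpy(), s2.to_numpy(), n_pairs, prior, df=df, se_scale=se_scale
    )
    q_fdr = adjust_p(p, "fdr")
    q_bonf = adjust_p(p, "bonferroni")

    imput = table.imputed
    n_imp_ric = imput[ric_ids].sum(axis=1).loc[keep]
    n_imp_wce = imput[wce_ids].sum(axis=1).loc[keep]

    out = pd.DataFrame(
        {
            "protein_id": keep,
            "population": flags.to_numpy(),
            "mean_log2fc": mean_fc.to_numpy(),
            "ratio_sd": sd.to_numpy(),
            "n_pairs": n_pairs,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "q_fdr": q_fdr,
            "q_bonf": q_bonf,
            "n_imputed_ric": n_imp_ric.to_numpy(),
            "n_imputed_wce": n_imp_wce.to_numpy(),
        }
    )
    out.attrs["prior"] = prior
    return out


def prepare_table(
    table: IntensityTable,
    impute_value: float = 18.0,
    normalize: bool = True,
) -> IntensityTable:
    """Impute missing cells at the background floor, then median-center columns.

    Imputation happens at the raw log2 scale within each batch (the fill is
    a constant, so the batch scope is implicit); normalization is applied
    column-wise afterwards, so the batch merge order does not matter.
    """
    out = impute_background(table, value=impute_value, scope="batch")
    if normalize:
        out = median_normalize(out)
    return out
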