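"""Empirical-Bayes moderated t-statistics and multiple-testing control.

Per-feature sample variances s2_g with d_g residual degrees of freedom are
modeled as scaled chi-square draws around a prior variance s0^2 with d0
prior degrees of freedom. The prior is estimated by moment-matching the
distribution of log s2_g (a shifted log-chi-square): the excess variance of
log s2 beyond trigamma(d_g/2) identifies d0 through

    trigamma(d0/2) = var(log s2_g) - trigamma(d_g/2),

and the posterior variance s~2_g = (d0 s0^2 + d_g s2_g) / (d0 + d_g) gives
the moderated t with d0 + d_g degrees of freedom. When the observed
variances are no more dispersed than chi-square sampling alone explains,
d0 is +infinity and every feature shares the common variance s0^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .quantify import AbundanceMatrix

__all__ = [
    "EbPrior",
    "fit_eb_prior",
    "trigamma_inverse",
    "moderated_t_test",
    "bh_adjust",
    "consensus_matrix",
    "summarize_counts",
]

GROUPS = ("DS", "RS")


@dataclass(frozen=True)
class EbPrior:
    """Prior degrees of freedom (may be math.inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, decreasing and convex, so the iteration
    x <- x + (trigamma(x) - y) / |trigamma'(x)| scaled by trigamma(x)/y
    (working on 1/x as in the usual scheme) converges monotonically.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_eb_prior(s2: Sequence[float] | np.ndarray, d_g: float) -> EbPrior:
    """Estimate (d0, s0^2) from per-feature sample variances.

    Zero variances are excluded from the fit (they carry no log-scale
    information); at least 10 positive variances are required.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValueError("need >= 10 features with positive variance")
    if d_g <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    z = np.log(s2)
    e = z - float(special.digamma(d_g / 2)) + math.log(d_g / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    if e_var == 0.0:
        # exactly equal variances: the common value is the prior itself
        return EbPrior(d0=math.inf, s0_sq=float(s2.mean()))
    excess = e_var - float(_trigamma(d_g / 2))
    if excess <= 0:
        return EbPrior(d0=math.inf, s0_sq=float(math.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
    )
    return EbPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    matrix: AbundanceMatrix | pd.DataFrame,
    groups: Mapping[str, str],
    prior: EbPrior | None = None,
    alpha: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Two-group moderated t-test on a complete (imputed) log2 matrix.

    ``groups`` maps sample id -> 'DS' | 'RS'. log2FC is mean(RS) - mean(DS),
    so positive values mean higher abundance with resistant starch. When
    ``prior`` is None it is fitted from the data; ``prior=EbPrior(d0=eps)``
    recovers the ordinary pooled-variance t-test in the limit. The total
    degrees of freedom are capped at the pooled residual df (so the
    d0=infinity limit keeps a proper t reference distribution).

    Returns a DataFrame indexed by feature with columns log2fc, s2, t_mod,
    df_total, p, p_adj, significant_05, significant_01.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    unknown = set(groups) - set(values.columns)
    if unknown:
        raise ValueError(f"group labels for unknown sample(s) {sorted(unknown)}")
    ds = [s for s in values.columns if groups.get(s) == "DS"]
    rs = [s for s in values.columns if groups.get(s) == "RS"]
    if len(ds) < 2 or len(rs) < 2:
        raise ValueError("each group needs >= 2 samples")
    if values.isna().to_numpy().any():
        raise ValueError("matrix must be complete (impute first)")

    x_ds, x_rs = values[ds].to_numpy(), values[rs].to_numpy()
    n1, n2 = len(ds), len(rs)
    d_g = n1 + n2 - 2
    log2fc = x_rs.mean(axis=1) - x_ds.mean(axis=1)
    s2 = (x_ds.var(axis=1, ddof=1) * (n1 - 1) + x_rs.var(axis=1, ddof=1) * (n2 - 1)) / d_g

    if prior is None:
        prior = fit_eb_prior(s2, d_g)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    df_total = min(prior.d0 + d_g, d_g * len(values))  # cap at pooled residual df
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": p_adj,
            "significant_05": p_adj < alpha[0],
            "significant_01": p_adj < alpha[1],
        },
        index=values.index,
    )
    out.attrs["prior"] = prior
    return out


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, ties stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_matrix(
    matrices: Sequence[AbundanceMatrix | pd.DataFrame],
) -> AbundanceMatrix:
    """Average per-cell over methods after per-column standardization.

    Different label-free scales (log2 NSAF, log2 riBAQ, ...) live on
    different log scales, so each sample column of each method is z-scored
    before averaging. Only features present in every method are kept; the
    dropped features are recorded in ``attrs['dropped_features']``.
    """
    if not matrices:
        raise ValueError("no matrices given")
    frames = [m.values if isinstance(m, AbundanceMatrix) else m for m in matrices]
    common = frames[0].index
    all_feats = set(frames[0].index)
    for f in frames[1:]:
        common = common.intersection(f.index)
        all_feats |= set(f.index)
    if len(common) == 0:
        raise ValueError("no features shared by all methods")
    cols = frames[0].columns
    standardized = []
    for f in frames:
        sub = f.loc[common, cols]
        standardized.append((sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1))
    avg = sum(standardized) / len(standardized)
    out = AbundanceMatrix(values=avg, scale="log2")
    out.values.attrs["dropped_features"] = sorted(all_feats - set(common))
    return out


def summarize_counts(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-method counts of quantified / BH-significant features.

    One row per method with columns quantified, sig_05, sig_01 — the layout
    used to compare quantification platforms.
    """
    rows = {
        method: {
            "quantified": len(df),
            "sig_05": int(df["significant_05"].sum()),
            "sig_01": int(df["significant_01"].sum()),
        }
        for method, df in results.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "method"
    return out
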