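"""Per-study two-group differential expression with empirical-Bayes moderation.

For each probeset the injured-vs-control contrast is summarized by
log2FC = mean(injured) - mean(control) and a residual variance s^2 on
d = n1 + n2 - 2 degrees of freedom.  The per-probeset variances are shrunk
toward a prior (d0, s0^2) estimated from the whole ensemble by moment-matching
on log s^2 (the scaled-F / moderated-t model): the posterior variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t statistic t = log2FC / (s~ * sqrt(1/n1 + 1/n2)) is referred
to a Student t distribution with d0 + d degrees of freedom.  95% confidence
intervals use the same moderated standard error.  P-values are adjusted by the
Benjamini-Hochberg step-up procedure.

When several probesets map to one gene, the probeset with the highest average
expression across all samples represents that gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from xsci.io import ExpressionStudy

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene", "log2fc", "t_mod", "p", "p_adj", "ci_low", "ci_high", "mean_expr",
]


@dataclass(frozen=True)
class EBayesPrior:
    """Shrinkage hyperparameters of the moderated-t model.

    d0 is the prior degrees of freedom (may be ``inf``), s0_sq the prior
    variance in squared log2 units.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior degrees of freedom d0 must be > 0")
        if not (self.s0_sq > 0) or not math.isfinite(self.s0_sq):
            raise ValueError("prior variance s0_sq must be finite and > 0")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the Newton step is taken on 1/trigamma, which
    is nearly linear, so convergence is fast from x0 = 0.5 + 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    # asymptotic shortcuts: trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> EBayesPrior:
    """Moment-matching estimate of (d0, s0^2) from observed variances.

    Works on z = log(s^2): under the scaled-F model, z - digamma(d/2) +
    log(d/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) beyond the sampling term trigamma(d/2); inverting
    the trigamma recovers d0.  A non-positive excess variance means the
    variances are no more dispersed than sampling alone predicts, i.e.
    d0 = infinity.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all probesets have zero variance; degenerate input")
    if positive.size < s2.size:
        logger.info(
            "prior estimation: ignoring %d zero-variance probeset(s)",
            s2.size - positive.size,
        )
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return EBayesPrior(d0=math.inf, s0_sq=float(math.exp(emean)))
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, for ranks i = 1..m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def fit_moderated_t(
    study: ExpressionStudy,
    prior: EBayesPrior | None = None,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Moderated-t differential expression for one study (injured vs control).

    Parameters
    ----------
    study : ExpressionStudy
        Validated study; at least 2 samples per arm.
    prior : EBayesPrior, optional
        Pin the shrinkage hyperparameters instead of estimating them (used for
        testing and sensitivity analysis).
    ci_level : float
        Confidence level of the reported interval.

    Returns
    -------
    (results, prior) : per-probeset DataFrame (index probeset id, columns
        gene, log2fc, t_mod, p, p_adj, ci_low, ci_high, mean_expr) and the
        prior actually used.

    Notes
    -----
    If the estimated prior degrees of freedom are infinite (the observed
    variances show no excess dispersion), the fit falls back to a common
    pooled variance s0^2 for every probeset, with normal-reference p-values;
    the fallback is logged.
    """
    injured = study.samples("injured")
    control = study.samples("control")
    n1, n2 = len(injured), len(control)
    x1 = study.matrix[injured].to_numpy(dtype=float)
    x2 = study.matrix[control].to_numpy(dtype=float)

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    log2fc = m1 - m2
    mean_expr = study.matrix.to_numpy(dtype=float).mean(axis=1)

    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior is None:
        prior = estimate_prior(s2, df_resid)
        if math.isinf(prior.d0):
            logger.info(
                "study %s: infinite prior df estimate; falling back to the "
                "pooled variance s0^2 = %.4g for all probesets",
                study.study_id, prior.s0_sq,
            )

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = prior.d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
        crit = stats.norm.ppf(0.5 + ci_level / 2.0)
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
        crit = stats.t.ppf(0.5 + ci_level / 2.0, df=df_total)
    p = np.clip(p, 0.0, 1.0)

    genes = [study.probeset_to_gene.get(ps, "") for ps in study.matrix.index]
    results = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p": p,
            "p_adj": benjamini_hochberg(p),
            "ci_low": log2fc - crit * se,
            "ci_high": log2fc + crit * se,
            "mean_expr": mean_expr,
        },
        index=study.matrix.index.copy(),
    )
    results.index.name = "probeset_id"
    return results, prior


def collapse_probesets(
    results: pd.DataFrame, mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse a per-probeset table to one row per gene.

    The representative of each gene is the probeset with the highest
    ``mean_expr``; ties are broken by the lexicographically smallest probeset
    id.  Probesets that map to no gene are dropped first (logged with a count).
    The returned table is indexed by gene and keeps the winning probeset id in
    a ``probeset_id`` column.
    """
    df = results.copy()
    if mapping is not None:
        df["gene"] = [mapping.get(ps, "") for ps in df.index]
    unmapped = (df["gene"] == "") | df["gene"].isna()
    if unmapped.any():
        logger.info("collapse: dropped %d unmapped probeset(s)", int(unmapped.sum()))
        df = df[~unmapped]
    df = df.reset_index()
    probeset_col = df.columns[0]
    # highest mean_expr wins; ties -> smallest probeset id
    df = df.sort_values(
        ["gene", "mean_expr", probeset_col], ascending=[True, False, True],
        kind="mergesort",
    )
    collapsed = df.drop_duplicates("gene", keep="first").set_index("gene")
    collapsed = collapsed.rename(columns={probeset_col: "probeset_id"})
    return collapsed.sort_index()
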