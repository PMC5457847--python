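"""Differential expression: per-study two-sample tests, Fisher meta-analysis
and threshold-based DE calling.

The per-study default is the Welch (unequal-variance) t test, robust to the
unbalanced miRNA cohort (33 cases vs 58 controls).  An empirical-Bayes
moderated t is available as an alternative: per-feature pooled variances are
shrunk toward a prior (d0, s0^2) estimated by moment matching of the log
sample variances, the moderated statistic using the posterior variance

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d),   df = d + d0.

Evidence across studies is combined per feature with Fisher's method,
X^2 = -2 * sum(ln p) ~ chi^2 with 2k degrees of freedom.

DE calling follows two rule sets: the human rule (raw p strictly below the
threshold, no fold-change filter) and the rat rule (p <= .05 AND linear
|fold change| >= 2.0, i.e. |log2FC| >= 1), with the strictness of each
inequality preserved.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .enrich import bh_adjust
from .errors import ConfigError, DesignError
from .io import ExpressionStudy

logger = logging.getLogger(__name__)

#: smallest representable p, used for degenerate zero-variance contrasts
TINY_P = float(np.finfo(float).tiny)

DE_COLUMNS = ["log2fc", "t", "df", "p", "p_adj", "se", "direction", "degenerate"]


def _direction(log2fc: np.ndarray) -> np.ndarray:
    out = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat"))
    return out.astype(object)


def _group_stats(study: ExpressionStudy):
    case = study.case_values()
    ctrl = study.control_values()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise DesignError("need >=2 samples per group")
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1, v2 = case.var(axis=1, ddof=1), ctrl.var(axis=1, ddof=1)
    return m1, m2, v1, v2, n1, n2


def welch_t_table(study: ExpressionStudy) -> pd.DataFrame:
    """Two-sided Welch t per feature, log2FC = case mean - control mean.

    Zero variance in both groups yields t=0, p=1 when the means agree, and
    a degenerate record (p = smallest representable value) when they differ.
    """
    m1, m2, v1, v2, n1, n2 = _group_stats(study)
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2
    se = np.sqrt(se2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))

    degenerate = se == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(diff == 0, 1.0, TINY_P), p)
    p = np.clip(p, TINY_P, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "df": df,
            "p": p,
            "p_adj": bh_adjust(p),
            "se": se,
            "direction": _direction(diff),
            "degenerate": degenerate,
        },
        index=pd.Index(study.feature_ids, name="feature"),
    )
    return table


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse, as in
    moment-matched variance-prior estimation)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from per-feature pooled variances ``s2`` with
    ``d`` residual df each, via the spread of log sample variances.

    When the log variances show no excess spread beyond sampling noise the
    prior df is infinite and s0^2 is the (common) sample variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(np.maximum(s2, TINY_P)))))
    e = np.log(s2[ok])
    evar = np.var(e, ddof=1) - float(special.polygamma(1, d / 2))
    if evar <= 1e-10:
        # no detectable spread of true variances: complete shrinkage
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    log_s0 = (
        np.mean(e)
        - float(special.digamma(d / 2))
        + float(special.digamma(d0 / 2))
        + np.log(d / 2)
        - np.log(d0 / 2)
    )
    return float(d0), float(np.exp(log_s0))


def moderated_t_table(study: ExpressionStudy, d0: float | None = None, s0_sq: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t per feature.

    The pooled per-feature variance is shrunk toward the moment-matched
    prior; ``d0``/``s0_sq`` may be forced (e.g. ``d0=np.inf`` for complete
    shrinkage).  Falls back to :func:`welch_t_table` with a logged warning
    when fewer than 10 features are available for hyperparameter estimation.
    """
    if len(study.feature_ids) < 10 and d0 is None:
        logger.warning(
            "study %s has %d < 10 features; falling back to Welch t",
            study.study_id, len(study.feature_ids),
        )
        return welch_t_table(study)

    m1, m2, v1, v2, n1, n2 = _group_stats(study)
    diff = m1 - m2
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d

    if d0 is None:
        d0, s0_est = estimate_variance_prior(s2, d)
        if s0_sq is None:
            s0_sq = s0_est
    elif s0_sq is None:
        s0_sq = float(np.exp(np.mean(np.log(np.maximum(s2, TINY_P)))))

    if np.isinf(d0):
        s_post = np.full_like(s2, s0_sq)
        df_mod = np.inf
    else:
        s_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_mod = d + d0

    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), diff / np.where(se == 0, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df_mod)
    p = np.where(degenerate, np.where(diff == 0, 1.0, TINY_P), p)
    p = np.clip(p, TINY_P, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "df": np.full_like(diff, df_mod),
            "p": p,
            "p_adj": bh_adjust(p),
            "se": se,
            "direction": _direction(diff),
            "degenerate": degenerate,
        },
        index=pd.Index(study.feature_ids, name="feature"),
    )
    table.attrs["d0"] = d0
    table.attrs["s0_sq"] = s0_sq
    return table


def fisher_combine(tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-study DE tables with Fisher's method.

    Features are intersected across studies (features absent from any study
    are dropped and logged).  The consensus log2FC is the inverse-variance
    weighted mean of the per-study estimates; records whose per-study fold
    changes disagree in sign are flagged ``discordant``.
    """
    if isinstance(tables, Mapping):
        named = list(tables.items())
    else:
        named = [(f"study_{i + 1}", t) for i, t in enumerate(tables)]
    if not named:
        raise ConfigError("no studies to combine")

    common = named[0][1].index
    for _, t in named[1:]:
        common = common.intersection(t.index)
    n_union = len(set().union(*[set(t.index) for _, t in named]))
    if len(common) < n_union:
        logger.info("fisher_combine: dropped %d features missing from some study", n_union - len(common))
    if len(common) == 0:
        raise ConfigError("no features shared across studies")

    k = len(named)
    p_mat = np.column_stack([t.loc[common, "p"].to_numpy(dtype=float) for _, t in named])
    if np.any(p_mat <= 0):
        raise ConfigError("all p values must be > 0 for Fisher combination")
    fc_mat = np.column_stack([t.loc[common, "log2fc"].to_numpy(dtype=float) for _, t in named])
    se_mat = np.column_stack([t.loc[common, "se"].to_numpy(dtype=float) for _, t in named])

    x2 = -2.0 * np.log(p_mat).sum(axis=1)
    df = 2 * k
    p = stats.chi2.sf(x2, df)
    p = np.clip(p, TINY_P, 1.0)

    w = 1.0 / np.clip(se_mat, 1e-12, None) ** 2
    log2fc = (w * fc_mat).sum(axis=1) / w.sum(axis=1)
    signs = np.sign(fc_mat)
    discordant = (signs.max(axis=1) > 0) & (signs.min(axis=1) < 0)

    out = pd.DataFrame(
        {
            "x2": x2,
            "df": float(df),
            "p": p,
            "p_adj": bh_adjust(p),
            "log2fc": log2fc,
            "direction": _direction(log2fc),
            "discordant": discordant,
        },
        index=pd.Index(common, name="feature"),
    )
    for name, t in named:
        out[f"p_{name}"] = t.loc[common, "p"].to_numpy(dtype=float)
    return out


def call_de(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    """Select DE records from a per-study or meta table.

    Without a fold-change threshold the human rule applies: raw p strictly
    below ``p_threshold``.  With one, the rat rule applies: p <= threshold
    AND linear |fold change| >= ``fc_threshold`` (both inclusive).
    """
    if not (0 <= p_threshold <= 1):
        raise ConfigError("p_threshold must be in [0, 1]")
    if len(table) == 0:
        return table.copy()
    if fc_threshold is None:
        mask = table["p"].to_numpy() < p_threshold
    else:
        if fc_threshold <= 0:
            raise ConfigError("fc_threshold must be positive")
        mask = (table["p"].to_numpy() <= p_threshold) & (
            np.abs(table["log2fc"].to_numpy()) >= np.log2(fc_threshold)
        )
    return table.loc[mask].copy()


def directions_of(table: pd.DataFrame) -> dict[str, int]:
    """Map feature -> +1/-1 for up/down records (flat records are dropped)."""
    out: dict[str, int] = {}
    for feat, direction in table["direction"].items():
        if direction == "up":
            out[feat] = 1
        elif direction == "down":
            out[feat] = -1
    return out
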