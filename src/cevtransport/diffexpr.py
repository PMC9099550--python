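"""Differential abundance testing with moderated statistics and a
fold-change-dependent significance curve.

Per-protein two-group comparisons use an empirical-Bayes moderated t:
the per-protein residual variance ``s^2`` (on ``d`` degrees of freedom)
is shrunk toward a prior variance ``s0^2`` estimated across proteins,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

and the moderated t = log2fc / (s_tilde * sqrt(1/n1 + 1/n2)) is referred
to a t distribution with ``d + d0`` degrees of freedom. The prior
parameters (d0, s0^2) are estimated by moment matching on the log sample
variances (the scaled-F model of variances across proteins).

Significance combines an adjusted-p cutoff with a fold-change-dependent
curve: a protein is significant only when |log2fc| exceeds 1 *and* its
BH-adjusted p-value falls below

    p_max * (1 - exp(-(|log2fc| - 1) / c)),

which is 0 at |log2fc| = 1 and saturates at p_max = 0.05 for large fold
changes; the curvature ``c`` defaults to the median moderated SD of the
tested proteins (the overall variance level). Because missing values are
imputed stochastically, the impute-test cycle is repeated (20 times by
default) and only proteins significant in *every* cycle are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModeratedStats",
    "SignificanceCurveParams",
    "moderated_ttest",
    "bh_adjust",
    "significance_curve",
    "significance_threshold",
    "consensus_significance",
    "welch_ttest",
    "tukey_hsd",
]


@dataclass(frozen=True)
class ModeratedStats:
    """Per-protein moderated test results plus the shared prior."""

    table: pd.DataFrame  # columns: log2fc, s, s_tilde, t, p, p_adj
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance
    residual_df: float  # per-protein residual df d


@dataclass(frozen=True)
class SignificanceCurveParams:
    """Parameters of the fold-change-dependent significance threshold."""

    fc_min: float = 1.0  # log2 units
    p_max: float = 0.05
    curvature: float = 0.5  # log2 units; typically the median moderated SD

    def __post_init__(self) -> None:
        if self.curvature <= 0:
            raise ValueError("curvature must be positive")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        d1 = _trigamma(y)
        d2 = _tetragamma(y)
        delta = d1 * (1.0 - d1 / x) / d2
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    return float(y)


def _trigamma(y: float) -> float:
    from scipy.special import polygamma

    return float(polygamma(1, y))


def _tetragamma(y: float) -> float:
    from scipy.special import polygamma

    return float(polygamma(2, y))


def estimate_prior(s_sq: np.ndarray, d: float) -> Tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from sample variances.

    Under the scaled-F model, ``z = log(s^2)`` has
    ``E[z] = log(s0^2) + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)`` and
    ``Var[z] = psi'(d/2) + psi'(d0/2)``; solving the variance equation for
    d0 via the inverse trigamma and back-substituting gives s0^2.
    Variances that are exactly zero are excluded from the fit. Returns
    ``d0 = inf`` when the empirical spread of log variances does not
    exceed what d degrees of freedom alone explain.
    """
    from scipy.special import digamma

    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if s_sq.size < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s_sq)
    if float(z.var(ddof=0)) == 0.0:
        # exactly constant variances: shrinkage to the common value
        return np.inf, float(s_sq[0])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1)) - _trigamma(d / 2.0)
    if var_e <= 0:
        return np.inf, float(np.exp(mean_e))
    d0 = 2.0 * _trigamma_inverse(var_e)
    s0_sq = float(np.exp(mean_e + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_ttest(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    d0: Optional[float] = None,
    s0_sq: Optional[float] = None,
) -> ModeratedStats:
    """Empirical-Bayes moderated two-group t-test per protein (row).

    ``group_a`` and ``group_b`` are protein-by-replicate log2 matrices
    (typically technical triplicates of the two transport modes). Rows
    with missing values are dropped — every tested protein must carry a
    full set of (possibly imputed) values. ``log2fc`` is mean(b) -
    mean(a). Passing ``d0``/``s0_sq`` overrides the prior estimation
    (``d0=0`` reduces to the ordinary t-test).
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("groups must share the same protein index")
    A = group_a.to_numpy(dtype=float)
    B = group_b.to_numpy(dtype=float)
    ok = ~(np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1))
    A, B = A[ok], B[ok]
    index = group_a.index[ok]
    n1, n2 = A.shape[1], B.shape[1]
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("no residual degrees of freedom; cannot moderate")
    log2fc = B.mean(axis=1) - A.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / d
    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_prior(s_sq, d)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s": np.sqrt(s_sq),
            "s_tilde": np.sqrt(s_tilde_sq),
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=index,
    )
    return ModeratedStats(table=table, d0=float(d0), s0_sq=float(s0_sq), residual_df=float(d))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_threshold(
    abs_log2fc: np.ndarray, params: SignificanceCurveParams = SignificanceCurveParams()
) -> np.ndarray:
    """Adjusted-p threshold as a function of |log2fc|.

    Zero at the fold-change cutoff, saturating exponentially to ``p_max``
    for asymptotically large fold changes.
    """
    x = np.asarray(abs_log2fc, dtype=float)
    excess = x - params.fc_min
    thr = params.p_max * (1.0 - np.exp(-excess / params.curvature))
    return np.where(excess > 0, thr, 0.0)


def significance_curve(
    log2fc: Sequence[float],
    p_adj: Sequence[float],
    params: SignificanceCurveParams = SignificanceCurveParams(),
) -> np.ndarray:
    """Boolean significance per protein under the fold-change curve.

    Significant iff |log2fc| > fc_min and adjusted p <= threshold(|log2fc|).
    """
    lfc = np.abs(np.asarray(log2fc, dtype=float))
    p = np.asarray(p_adj, dtype=float)
    thr = significance_threshold(lfc, params)
    return (lfc > params.fc_min) & (p <= thr)


def curve_params_from_stats(
    stats_: ModeratedStats, fc_min: float = 1.0, p_max: float = 0.05
) -> SignificanceCurveParams:
    """Curvature from the overall variance: the median moderated SD."""
    c = float(np.median(stats_.table["s_tilde"]))
    if c <= 0 or not np.isfinite(c):
        c = 0.5
    return SignificanceCurveParams(fc_min=fc_min, p_max=p_max, curvature=c)


def consensus_significance(
    cycle: Callable[[int], Set[str]],
    seeds: Sequence[int],
) -> Set[str]:
    """Intersection of per-cycle significant sets over imputation cycles.

    ``cycle(seed)`` runs one impute -> test -> adjust -> curve pass and
    returns the significant protein set; a protein must be significant in
    every cycle to be accepted. Cycle failures abort with the cycle index.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one cycle")
    result: Optional[Set[str]] = None
    for i, seed in enumerate(seeds):
        try:
            sig = set(cycle(int(seed)))
        except Exception as exc:
            raise RuntimeError(f"imputation cycle {i} (seed {seed}) failed") from exc
        result = sig if result is None else (result & sig)
    assert result is not None
    return result


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Zero variance in both groups with equal means returns (0, 1) by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if b.mean() > a.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t), float(p)


def tukey_hsd(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise comparisons.

    One-way ANOVA residual variance feeds studentized-range pairwise
    tests; returns a DataFrame with columns ``group_a``, ``group_b``,
    ``diff``, ``p_adj``. Used for four-group plasma-type x transport
    panels with significance typically called at p <= 0.01.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    ns = np.array([len(s) for s in samples])
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 values")
    means = np.array([s.mean() for s in samples])
    df_err = int(ns.sum() - len(labels))
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    mse = sse / df_err
    rows = []
    k = len(labels)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            if mse == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                p = float(stats.studentized_range.sf(q, k, df_err))
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "diff": float(diff), "p_adj": min(p, 1.0)}
            )
    return pd.DataFrame(rows)
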