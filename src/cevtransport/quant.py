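"""Label-free protein quantification: injections -> vsn -> Top3 -> imputation.

The quantification chain turns a peptide-by-sample intensity table into
imputed log2 protein abundances ("iTop3"):

1.  **Injection summing** — the two mass-spectrometry injections of each
    digest are summed (a missing partner counts as 0; two missing stay
    missing).
2.  **Variance stabilization** — per-sample affine-then-arsinh calibration
    ``h(x) = glog2((x - a_s) / b_s)`` fitted robustly against the
    row-median reference profile, so replicate differences have
    intensity-independent spread and large-intensity differences read as
    log2 ratios.
3.  **Top3** — a protein's abundance is the log2 of the sum of its three
    most intense peptides (per sample; all peptides if fewer than three
    observed).
4.  **MNAR imputation** — within each technical-replicate triplet: if two
    or three values are missing, they are drawn from a down-shifted
    Gaussian ``N(col_mean - 2.5 col_sd, (0.3 col_sd)^2)`` (missingness is
    intensity-dependent, so missing values are presumed low); a single
    missing value is filled with its conditional mean under a trivariate
    Gaussian fitted across the replicate columns by
    expectation-maximization.

Columns carry a MultiIndex with levels ``donor``, ``plasma``,
``transport``, ``replicate`` (and ``injection`` before summing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PeptideMatrix",
    "Top3Result",
    "ProteinQuant",
    "sum_injections",
    "vsn_normalize",
    "top3",
    "impute",
    "aggregate_gene_products",
    "subclass_intensity",
    "read_peptides_txt",
]

LN2 = np.log(2.0)
REPLICATE_LEVEL = "replicate"
INJECTION_LEVEL = "injection"


@dataclass(frozen=True)
class PeptideMatrix:
    """Peptide intensities (rows) by samples (MultiIndex columns), with the
    peptide -> protein-group mapping."""

    intensities: pd.DataFrame
    protein_of: pd.Series

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.protein_of.index):
            missing = self.intensities.index.difference(self.protein_of.index)
            if len(missing):
                raise ValueError(f"peptides without protein mapping: {list(missing[:5])}")
            object.__setattr__(
                self, "protein_of", self.protein_of.loc[self.intensities.index]
            )


@dataclass(frozen=True)
class Top3Result:
    """Per-protein per-sample log2 Top3 values plus the number of observed
    peptides that contributed (1-2 marks a sub-top3 value)."""

    log2: pd.DataFrame
    n_observed: pd.DataFrame


@dataclass(frozen=True)
class ProteinQuant:
    """Imputed log2 protein abundances (iTop3) with the imputation mask.

    ``mask`` holds ``""`` for observed cells, ``"gauss"`` for down-shifted
    Gaussian draws (>= 2 missing in the replicate triplet) and ``"mle"``
    for EM conditional-mean fills (exactly 1 missing).
    """

    log2: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.log2.isna().any().any():
            raise ValueError("imputed matrix must contain no missing values")
        if self.log2.shape != self.mask.shape:
            raise ValueError("mask shape must match the matrix")


def sum_injections(matrix: PeptideMatrix) -> PeptideMatrix:
    """Sum paired injection columns (missing + observed -> observed value;
    both missing -> missing)."""
    df = matrix.intensities
    if INJECTION_LEVEL not in (df.columns.names or []):
        raise ValueError("no 'injection' level in the column metadata")
    keep = [n for n in df.columns.names if n != INJECTION_LEVEL]
    sizes = df.T.groupby(level=keep).size()
    if (sizes != 2).any():
        bad = sizes[sizes != 2]
        raise ValueError(f"unpaired injections for samples: {list(bad.index)}")
    summed = df.T.groupby(level=keep).sum(min_count=1).T
    return PeptideMatrix(intensities=summed, protein_of=matrix.protein_of)


def glog2(y: np.ndarray) -> np.ndarray:
    """Generalized log2: ``log2(y + sqrt(y^2 + 1))`` (arsinh on the log2
    scale); behaves like ``log2(2y)`` for large y and stays finite at 0."""
    return np.arcsinh(y) / LN2


def _vsn_transform(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return glog2((x - a) / b)


def _vsn_sample_objective(
    params: np.ndarray, x: np.ndarray, ref: np.ndarray, trim: float
) -> float:
    """Robust profile-likelihood objective for one sample's (a, log b).

    The first term is the (trimmed) profile-Gaussian log of the residual
    sum of squares against the reference profile; the second is the
    negative log-Jacobian of the transform, which identifies the overall
    scale ``b`` (without it, any common rescaling of all samples'
    parameters would fit equally well): ``-log h'(x) = 0.5 log((x - a)^2
    + b^2) + const``.
    """
    a, logb = params
    b = np.exp(logb)
    r = _vsn_transform(x, a, b) - ref
    r2 = r * r
    n = r2.size
    keep = max(int(np.ceil(trim * n)), 2)
    kept = np.argpartition(r2, keep - 1)[:keep]
    rss = float(r2[kept].sum())
    jac = 0.5 * float(np.log((x[kept] - a) ** 2 + b * b + 1e-300).sum())
    return 0.5 * keep * np.log(rss / keep + 1e-300) + jac


def vsn_normalize(
    intensities: pd.DataFrame,
    max_iter: int = 10,
    tol: float = 1e-10,
    trim: float = 0.9,
) -> pd.DataFrame:
    """Variance-stabilizing calibration of a peptide intensity table.

    Each sample column gets an affine-then-arsinh transform
    ``h(x) = glog2((x - a_s)/b_s)``; the per-sample parameters are fitted
    by iterating between the row-median reference profile and per-sample
    robust (least-trimmed, ``trim`` fraction kept) maximum-likelihood
    fits. The likelihood's Jacobian term pins the scale ``b_s`` near the
    additive-noise level, so replicate differences become
    intensity-independent while differences between large transformed
    intensities approach log2 ratios. Missing values stay missing.
    """
    if intensities.shape[1] < 2:
        raise ValueError("variance stabilization needs at least 2 samples")
    from scipy.optimize import minimize

    # negative values are allowed: background-subtracted intensities go
    # below zero at the noise floor and the arsinh transform is odd
    X = intensities.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n_samples = X.shape[1]
    a = np.zeros(n_samples)
    b = np.empty(n_samples)
    for j in range(n_samples):
        pos = X[obs[:, j], j]
        pos = pos[pos > 0]
        if pos.size == 0:
            raise ValueError(f"sample column {j} has no positive observed intensities")
        b[j] = float(np.quantile(pos, 0.05))
    H = np.full_like(X, np.nan)
    for j in range(n_samples):
        H[obs[:, j], j] = _vsn_transform(X[obs[:, j], j], a[j], b[j])
    prev: Optional[np.ndarray] = None
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref = np.nanmedian(H, axis=1)
        for j in range(n_samples):
            rows = obs[:, j] & np.isfinite(ref)
            xj, rj = X[rows, j], ref[rows]
            sol = minimize(
                _vsn_sample_objective,
                x0=np.array([a[j], np.log(b[j])]),
                args=(xj, rj, trim),
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 600},
            )
            a[j], b[j] = float(sol.x[0]), float(np.exp(sol.x[1]))
            if not np.isfinite(b[j]) or b[j] <= 0:
                raise RuntimeError(
                    f"variance-stabilization scale for sample {j} collapsed "
                    f"(b={b[j]}); data may lack overlapping dynamic range"
                )
            H[obs[:, j], j] = _vsn_transform(X[obs[:, j], j], a[j], b[j])
        # the per-sample fits leave the common scale of all b_s on a ridge
        # (each sample's best scale matches the others'); optimize it globally
        k = _vsn_common_scale(X, obs, a, b, trim)
        b *= k
        for j in range(n_samples):
            H[obs[:, j], j] = _vsn_transform(X[obs[:, j], j], a[j], b[j])
        if prev is not None and float(np.nansum((H[obs] - prev) ** 2)) < tol:
            break
        prev = H[obs].copy()
    return pd.DataFrame(H, index=intensities.index, columns=intensities.columns)


def _vsn_common_scale(
    X: np.ndarray, obs: np.ndarray, a: np.ndarray, b: np.ndarray, trim: float
) -> float:
    """One-dimensional search over a common factor on all scale parameters.

    The common scale decides where the transform crosses from its linear
    (additive-noise) to its logarithmic (multiplicative-noise) regime; it
    is chosen to make the spread of the residuals against the reference
    profile independent of intensity: candidate factors are scored by the
    variance of the log residual-SDs across intensity deciles, on a
    log-spaced grid refined by a bounded scalar search. Returns 1.0 when
    the residuals are too small or too few to measure spread.
    """
    from scipy.optimize import minimize_scalar

    def spread_inhomogeneity(logk: float) -> float:
        k = np.exp(logk)
        H = np.full_like(X, np.nan)
        for j in range(X.shape[1]):
            H[obs[:, j], j] = _vsn_transform(X[obs[:, j], j], a[j], b[j] * k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref = np.nanmedian(H, axis=1)
        R = H - ref[:, None]
        order = np.argsort(ref, kind="mergesort")
        n_bins = min(10, max(len(order) // 20, 2))
        sds = []
        for chunk in np.array_split(order, n_bins):
            res = R[chunk][obs[chunk]]
            res = res[np.isfinite(res)]
            if res.size >= 4 and np.std(res) > 0:
                sds.append(np.std(res))
        if len(sds) < 2:
            return np.nan
        return float(np.var(np.log(sds)))

    grid = np.linspace(-2.0, 6.0, 17)
    vals = np.array([spread_inhomogeneity(g) for g in grid])
    if np.all(~np.isfinite(vals)):
        return 1.0
    i = int(np.nanargmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(np.exp(grid[i]))
    sol = minimize_scalar(
        spread_inhomogeneity, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
    )
    best = sol.x if np.isfinite(sol.fun) and sol.fun <= vals[i] else grid[i]
    return float(np.exp(best))


def top3(matrix: PeptideMatrix) -> Top3Result:
    """Log2 of the sum of each protein's three most intense peptides.

    Operates on a normalized (glog2-scale) matrix; values are
    back-transformed to the linear scale (``2**h``), the three largest
    observed peptide values per sample are summed (all of them when fewer
    than three are observed), and the log2 of the sum is returned. A
    protein-sample cell with no observed peptide stays missing.
    """
    df = matrix.intensities
    linear = np.power(2.0, df)
    groups = matrix.protein_of
    records_log2 = {}
    records_n = {}
    for protein, idx in sorted(groups.groupby(groups).groups.items()):
        sub = linear.loc[idx].to_numpy(dtype=float)
        if sub.shape[0] == 0:
            warnings.warn(f"protein group {protein} has no mapped peptides; excluded")
            continue
        n_obs = (~np.isnan(sub)).sum(axis=0)
        # sum of the 3 largest observed values per column
        filled = np.where(np.isnan(sub), -np.inf, sub)
        top = -np.sort(-filled, axis=0)[:3, :]
        top = np.where(np.isinf(top), 0.0, top)
        sums = top.sum(axis=0)
        with np.errstate(divide="ignore"):
            vals = np.where(n_obs > 0, np.log2(np.where(sums > 0, sums, 1.0)), np.nan)
        records_log2[protein] = vals
        records_n[protein] = n_obs
    log2df = pd.DataFrame.from_dict(records_log2, orient="index", columns=df.columns)
    ndf = pd.DataFrame.from_dict(records_n, orient="index", columns=df.columns)
    return Top3Result(log2=log2df.sort_index(), n_observed=ndf.sort_index())


def _em_mvn(
    Y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit a multivariate Gaussian to rows of ``Y`` with missing entries by
    expectation-maximization; returns (mean, covariance)."""
    n, d = Y.shape
    obs = ~np.isnan(Y)
    mu = np.array([np.nanmean(Y[:, j]) for j in range(d)])
    var = np.array([np.nanvar(Y[:, j]) for j in range(d)])
    var[var <= 0] = 1e-6
    sigma = np.diag(var)
    prev_ll = -np.inf
    # group rows by missingness pattern for vectorized E-steps
    keys: Dict[bytes, list] = {}
    for i in range(n):
        keys.setdefault(obs[i].tobytes(), []).append(i)
    for _ in range(max_iter):
        Ex = Y.copy()
        Exx = np.zeros((d, d))
        ll = 0.0
        for key, rows in keys.items():
            o = np.frombuffer(key, dtype=bool)
            m = ~o
            rows = np.asarray(rows)
            Yo = Y[np.ix_(rows, np.flatnonzero(o))]
            if m.any() and o.any():
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(m, o)]
                Smm = sigma[np.ix_(m, m)]
                Soo_inv = np.linalg.inv(Soo + 1e-12 * np.eye(o.sum()))
                cond_mean = mu[m] + (Yo - mu[o]) @ (Soo_inv @ Smo.T)
                cond_cov = Smm - Smo @ Soo_inv @ Smo.T
                Ex[np.ix_(rows, np.flatnonzero(m))] = cond_mean
                Exx[np.ix_(np.flatnonzero(m), np.flatnonzero(m))] += len(rows) * cond_cov
            if o.any():
                Soo = sigma[np.ix_(o, o)]
                sign, logdet = np.linalg.slogdet(Soo)
                dev = Yo - mu[o]
                Soo_inv = np.linalg.inv(Soo + 1e-12 * np.eye(o.sum()))
                ll += -0.5 * (
                    len(rows) * (logdet + o.sum() * np.log(2 * np.pi))
                    + np.einsum("ij,jk,ik->", dev, Soo_inv, dev)
                )
        mu = Ex.mean(axis=0)
        centered = Ex - mu
        sigma = (centered.T @ centered + Exx) / n
        sigma += 1e-10 * np.eye(d)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return mu, sigma


def impute(
    protein_log2: pd.DataFrame,
    seed: int,
    min_observed_per_column: int = 10,
    replicates_per_group: int = 3,
) -> ProteinQuant:
    """Two-branch MNAR imputation of a log2 protein matrix.

    Within each technical-replicate group (columns sharing all metadata
    levels except ``replicate``) and protein: when at least two of the
    replicate values are missing, each missing cell is drawn independently
    from ``N(col_mean - 2.5 * col_sd, (0.3 * col_sd)^2)`` using its own
    column's observed-value mean and SD (a left-shifted, narrowed copy of
    the sample distribution — the standard assumption for
    intensity-dependent missingness); when exactly one is missing, it is
    replaced by its conditional mean under a Gaussian fitted across the
    group's replicate columns by expectation-maximization. Identical seeds
    give bit-identical results.
    """
    df = protein_log2
    if REPLICATE_LEVEL not in (df.columns.names or []):
        raise ValueError("no 'replicate' level in the column metadata")
    n_obs = df.notna().sum(axis=0)
    low = n_obs[n_obs < min_observed_per_column]
    if len(low):
        raise ValueError(
            f"columns with fewer than {min_observed_per_column} observed values "
            f"(moment estimation unreliable): {list(low.index)}"
        )
    col_mean = df.mean(axis=0)
    col_sd = df.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    out = df.copy()
    mask = pd.DataFrame("", index=df.index, columns=df.columns)
    keep = [n for n in df.columns.names if n != REPLICATE_LEVEL]
    group_cols = df.T.groupby(level=keep).groups
    for gkey in sorted(group_cols):
        cols = list(group_cols[gkey])
        if len(cols) != replicates_per_group:
            raise ValueError(
                f"replicate group {gkey} has {len(cols)} columns, "
                f"expected {replicates_per_group}"
            )
        sub = df.loc[:, cols]
        n_missing = sub.isna().sum(axis=1)
        # branch 1: >= 2 missing -> down-shifted Gaussian per cell
        heavy = n_missing >= 2
        for col in cols:
            cells = heavy & sub[col].isna()
            k = int(cells.sum())
            if k:
                mu = col_mean[col] - 2.5 * col_sd[col]
                sd = 0.3 * col_sd[col]
                out.loc[cells, col] = mu + sd * rng.standard_normal(k)
                mask.loc[cells, col] = "gauss"
        # branch 2: exactly 1 missing -> EM conditional mean
        single = n_missing == 1
        if single.any():
            Y = sub.to_numpy(dtype=float)
            fit_rows = (~np.isnan(Y)).sum(axis=1) > 0
            mu_g, sigma_g = _em_mvn(Y[fit_rows])
            for i in np.flatnonzero(single.to_numpy()):
                row = Y[i]
                m = np.isnan(row)
                o = ~m
                Soo_inv = np.linalg.inv(
                    sigma_g[np.ix_(o, o)] + 1e-12 * np.eye(int(o.sum()))
                )
                cond = mu_g[m] + sigma_g[np.ix_(m, o)] @ Soo_inv @ (row[o] - mu_g[o])
                j = int(np.flatnonzero(m)[0])
                out.loc[out.index[i], cols[j]] = float(np.ravel(cond)[0])
                mask.loc[out.index[i], cols[j]] = "mle"
    return ProteinQuant(log2=out, mask=mask)


def aggregate_gene_products(
    quant: ProteinQuant, gene_of: pd.Series
) -> pd.DataFrame:
    """Collapse protein groups of the same gene into one log2 intensity.

    Linear-scale iTop3 values of protein groups sharing a gene name are
    summed per sample — a group contributes in a replicate group only if
    it had at least one *observed* (non-imputed) value there — and the
    per-replicate log2 sums are reduced to their median, giving a
    gene-product by (donor x transport [x plasma]) matrix.
    """
    df = quant.log2
    observed = quant.mask == ""
    keep = [n for n in df.columns.names if n != REPLICATE_LEVEL]
    group_cols = df.T.groupby(level=keep).groups
    gene_of = gene_of.loc[df.index]
    linear = np.power(2.0, df)
    per_gene_cols: Dict[Tuple, pd.Series] = {}
    for gkey in sorted(group_cols):
        cols = list(group_cols[gkey])
        detected = observed.loc[:, cols].any(axis=1)  # >=1 detection in the group
        lin = linear.loc[:, cols].where(detected, other=np.nan)
        sums = lin.groupby(gene_of).sum(min_count=1)
        log2sums = np.log2(sums)
        per_gene_cols[gkey if isinstance(gkey, tuple) else (gkey,)] = log2sums.median(
            axis=1
        )
    out = pd.DataFrame(per_gene_cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=keep)
    return out


def subclass_intensity(
    gene_matrix: pd.DataFrame, membership: Mapping[str, Set[str]]
) -> pd.DataFrame:
    """Representative per-subclass intensity: the mean of the members'
    log2 values per sample (absent members skipped; empty subclasses
    excluded with a warning)."""
    rows = {}
    for name in sorted(membership):
        members = [g for g in membership[name] if g in gene_matrix.index]
        if not members:
            warnings.warn(f"subclass {name!r} has no members in the matrix; excluded")
            continue
        rows[name] = gene_matrix.loc[members].mean(axis=0)
    if not rows:
        raise ValueError("no subclass had any member present")
    return pd.DataFrame(rows).T


def read_peptides_txt(
    path,
    intensity_prefix: str = "Intensity ",
    protein_col: str = "Proteins",
    peptide_col: str = "Sequence",
    sample_parser=None,
) -> PeptideMatrix:
    """Read a MaxQuant-style tab-separated ``peptides.txt``.

    Intensity columns are those starting with ``intensity_prefix``; zeros
    are treated as missing. ``sample_parser`` maps the column suffix (run
    name) to a metadata tuple ``(donor, plasma, transport, replicate,
    injection)``; by default the run name is split on ``_``.
    """
    df = pd.read_csv(path, sep="\t")
    runs = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not runs:
        raise ValueError(f"no columns start with {intensity_prefix!r}")
    if sample_parser is None:
        sample_parser = lambda run: tuple(run.split("_"))
    meta = [sample_parser(c[len(intensity_prefix):]) for c in runs]
    intens = df[runs].replace(0, np.nan)
    intens.columns = pd.MultiIndex.from_tuples(
        meta, names=["donor", "plasma", "transport", "replicate", "injection"][: len(meta[0])]
    )
    intens.index = df[peptide_col]
    protein_of = pd.Series(df[protein_col].to_numpy(), index=df[peptide_col], name="protein")
    return PeptideMatrix(intensities=intens, protein_of=protein_of)
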