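"""Pairwise matrices and permutation statistics: MRQAP, exact binomial, contingency tests.

MRQAP (multiple regression quadratic assignment procedure) regresses one
dyadic matrix on others: point estimates are ordinary least squares on the
vectorised upper-triangle dyads, and significance comes from node-label
permutations, which respect the row/column non-independence of dyadic data.
The default permutation scheme is Dekker's double semi-partialing (DSP): each
predictor is residualised on the remaining predictors, the residual matrix's
rows and columns are permuted jointly by a random node relabeling, and the
permuted residual's t statistic is compared with the observed one.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SightingTable

__all__ = [
    "PairwiseMatrix",
    "MRQAPResult",
    "ContingencyResult",
    "bsi_correlation_matrix",
    "centroid_distance_matrix",
    "mrqap",
    "exact_binomial_test",
    "contingency_independence_test",
    "build_glmm_frame",
]


@dataclass
class PairwiseMatrix:
    """Symmetric dyadic matrix over n individuals; NaN marks missing dyads."""

    values: np.ndarray
    ids: list[str]
    kind: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("pairwise matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def bsi_correlation_matrix(
    yearly_bsi: pd.DataFrame, min_overlap: int = 3
) -> PairwiseMatrix:
    """Pairwise Pearson correlation of per-year mean BSI vectors.

    ``yearly_bsi`` has one row per female and one column per study year, NaN
    where the yearly mean is undefined.  Each pair is correlated over the
    years where both are defined; pairs with fewer than ``min_overlap`` shared
    years, or with a constant vector on the shared years, are masked NaN.
    """
    ids = list(yearly_bsi.index)
    vals = yearly_bsi.to_numpy(dtype=float)
    n = len(ids)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            if both.sum() < max(min_overlap, 2):
                continue
            a, b = vals[i, both], vals[j, both]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue  # correlation undefined on a constant vector
            r = np.corrcoef(a, b)[0, 1]
            out[i, j] = out[j, i] = r
    return PairwiseMatrix(out, ids, "bsi_correlation")


def centroid_distance_matrix(
    table: SightingTable, subjects: Sequence[str]
) -> PairwiseMatrix:
    """Euclidean distances between per-individual sighting centroids.

    The centroid is the arithmetic mean of an individual's planar sighting
    coordinates over all its located sightings.
    """
    from scipy.spatial.distance import squareform, pdist

    df = table.records
    cents = []
    for s in subjects:
        sub = df[df["individual_id"] == s][["x", "y"]].dropna()
        if sub.empty:
            raise ValueError(f"subject {s!r} has no located sightings")
        cents.append(sub.mean().to_numpy())
    dmat = squareform(pdist(np.asarray(cents)))
    return PairwiseMatrix(dmat, list(subjects), "centroid_distance")


@dataclass
class MRQAPResult:
    """Dyadic matrix-regression output: OLS point estimates, permutation p-values."""

    coefficients: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    residual_se: float
    df: int
    n_permutations: int
    seed: int
    method: str = "dsp"
    n_dyads: int = 0

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "p_values": self.p_values,
            "adjusted_r2": self.adjusted_r2,
            "residual_se": self.residual_se,
            "df": self.df,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
            "n_dyads": self.n_dyads,
        }


def _ols_t(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """OLS fit returning (beta, t-values, adjusted R^2, residual SE)."""
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    return beta, t, adj, float(np.sqrt(s2))


def mrqap(
    dep: PairwiseMatrix,
    predictors: Sequence[PairwiseMatrix],
    n_perm: int = 999,
    seed: int = 0,
    method: str = "dsp",
) -> MRQAPResult:
    """Matrix regression of ``dep`` on ``predictors`` with node-permutation p-values.

    Point estimates are OLS on the vectorised upper-triangle dyads, masked
    dyads dropped listwise.  ``method="dsp"`` permutes each residualised
    predictor's rows and columns jointly (double semi-partialing);
    ``method="y"`` permutes the dependent matrix.  Two-tailed p is the
    proportion of permuted |t| at least the observed |t|, observed statistic
    included, hence p >= 1/(n_perm + 1).
    """
    if method not in ("dsp", "y"):
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low for stable p-values", stacklevel=2)
    n = dep.n
    for p in predictors:
        if p.n != n or p.ids != dep.ids:
            raise ValueError("matrices are not conformable over the same individuals")
    names = ["intercept"] + [p.kind or f"x{i+1}" for i, p in enumerate(predictors)]
    iu, ju = np.triu_indices(n, k=1)
    yv = dep.values[iu, ju]
    Xmats = [p.values for p in predictors]
    Xv = np.column_stack([np.ones(len(yv))] + [m[iu, ju] for m in Xmats])
    ok = ~np.isnan(yv) & ~np.isnan(Xv).any(axis=1)
    if ok.sum() <= Xv.shape[1]:
        raise ValueError("too few complete dyads for regression")
    for j in range(1, Xv.shape[1]):
        if np.nanstd(Xv[ok, j]) == 0:
            raise ValueError(f"predictor {names[j]!r} is collinear with the intercept")
    y0, X0 = yv[ok], Xv[ok]
    beta, t_obs, adj_r2, res_se = _ols_t(X0, y0)
    rng = np.random.default_rng(seed)
    p_vals: dict[str, float] = {}

    if method == "y":
        Y = dep.values
        exceed = np.zeros(len(names), dtype=int)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            yp = Y[np.ix_(perm, perm)][iu, ju]
            ok_p = ~np.isnan(yp) & ~np.isnan(Xv).any(axis=1)
            _, t_p, _, _ = _ols_t(Xv[ok_p], yp[ok_p])
            exceed += np.abs(t_p) >= np.abs(t_obs) - 1e-12
        for j, nm in enumerate(names):
            p_vals[nm] = (exceed[j] + 1) / (n_perm + 1)
        p_vals["intercept"] = np.nan
    else:
        # DSP: residualise each predictor on the others (incl. intercept) as a
        # matrix, permute the residual matrix by node relabeling.
        p_vals["intercept"] = np.nan
        for j in range(1, Xv.shape[1]):
            others = [c for c in range(Xv.shape[1]) if c != j]
            Z0 = Xv[ok][:, others]
            gamma = np.linalg.pinv(Z0.T @ Z0) @ (Z0.T @ Xv[ok, j])
            E = np.full((n, n), np.nan)
            e_v = Xv[:, j] - Xv[:, others] @ gamma
            E[iu, ju] = np.where(ok, e_v, np.nan)
            E[ju, iu] = E[iu, ju]
            base_ok = ~np.isnan(yv) & ~np.isnan(
                np.column_stack([Xv[:, c] for c in others])
            ).any(axis=1)
            # observed t of the residualised predictor (identical to full-model t)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                ev = E[np.ix_(perm, perm)][iu, ju]
                ok_p = base_ok & ~np.isnan(ev)
                Xp = np.column_stack([Xv[ok_p][:, others], ev[ok_p]])
                _, t_p, _, _ = _ols_t(Xp, yv[ok_p])
                if abs(t_p[-1]) >= abs(t_obs[j]) - 1e-12:
                    count += 1
            p_vals[names[j]] = (count + 1) / (n_perm + 1)

    coeffs = {nm: float(b) for nm, b in zip(names, beta)}
    return MRQAPResult(
        coefficients=coeffs,
        p_values=p_vals,
        adjusted_r2=float(adj_r2),
        residual_se=float(res_se),
        df=int(ok.sum() - Xv.shape[1]),
        n_permutations=n_perm,
        seed=seed,
        method=method,
        n_dyads=int(ok.sum()),
    )


def exact_binomial_test(k: int, n: int, p0: float) -> float:
    """Two-tailed exact binomial p-value by the minimum-likelihood method.

    Sums the probabilities of all outcomes whose probability under
    Binomial(n, p0) does not exceed that of the observed count (with the
    customary 1 + 1e-7 relative tolerance for floating-point ties).
    """
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    if not (0 < p0 < 1):
        raise ValueError(f"p0={p0} must be in (0, 1)")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p_value: float
    method: str


def contingency_independence_test(
    table: np.ndarray | Sequence[Sequence[int]],
    n_mc: int = 9999,
    seed: int = 0,
) -> ContingencyResult:
    """Test independence in an r x c count table.

    Reports the (uncorrected) chi-square statistic alongside an exact p for
    2 x 2 tables (hypergeometric enumeration) or a seeded Monte-Carlo p for
    larger tables: ``n_mc`` tables are sampled with fixed margins and the
    chi-square statistic compared (observed included in the numerator and
    denominator).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, _, dof, _ = stats.chi2_contingency(t, correction=False)
    if t.shape == (2, 2):
        p = stats.fisher_exact(t, alternative="two-sided")[1]
        return ContingencyResult(float(chi2), int(dof), float(p), "fisher_exact")
    rng = np.random.default_rng(seed)
    rt = stats.random_table(t.sum(axis=1), t.sum(axis=0))
    draws = rt.rvs(size=n_mc, random_state=rng)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (np.sum(stat >= chi2 - 1e-12) + 1) / (n_mc + 1)
    return ContingencyResult(float(chi2), int(dof), float(p), "monte_carlo")


def build_glmm_frame(
    table: SightingTable,
    males: Sequence[str],
    strategies: Mapping[str, str],
    age_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Model frame for an external mixed-model fit of BSI on age class x strategy.

    One row per between-sightings interval of each retained male (response =
    interval length in days); the interval is dated by its opening sighting,
    whose month and calendar year populate the random-effect columns.  No
    estimation is performed here.
    """
    rows = []
    df = table.records
    for m in males:
        sub = df[df["individual_id"] == m]
        days = np.unique(pd.to_datetime(sub["date"]).dt.normalize())
        for a, b in zip(days[:-1], days[1:]):
            a = pd.Timestamp(a)
            rows.append(
                {
                    "individual_id": m,
                    "age_class": age_classes.get(m),
                    "strategy": strategies.get(m),
                    "bsi": int((pd.Timestamp(b) - a).days),
                    "month": int(a.month),
                    "year": int(a.year),
                }
            )
    return pd.DataFrame(rows, columns=["individual_id", "age_class", "strategy", "bsi", "month", "year"])
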