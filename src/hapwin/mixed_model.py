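"""Pedigree animal-model REML with marker covariates.

The model is the standard animal model

    y = X b + Z a + e,    a ~ N(0, A sigma2_a),    e ~ N(0, I sigma2_e)

where A is the numerator relationship matrix from the pedigree, X holds the
fixed effects (breed, herd, sex, measurement day, an age covariate) plus any
genetic-marker covariates (SNP dosages, interaction products, or haplotype
copy counts), and a is the polygenic breeding value.  The restricted
likelihood is profiled over the variance ratio lambda = sigma2_a / sigma2_e
using one eigen-decomposition of A restricted to the phenotyped individuals,
so many marker models can be fitted cheaply against the same pedigree.

Substitution effects (allele or partial haplotype substitution effects) are
tested by t = b / se with df = n - rank(X).  The variance explained by a
marker set is the relative drop in the fixed-part residual sum of squares,

    R^2 = (RSS_n - RSS_w) / RSS_n,

where RSS of a fit is sum_i (y_i - x_i' b)^2 over phenotyped individuals:
residuals from the fixed part only, so the RSS retains the pedigree,
random and error variability and estimates the total phenotypic variance.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .io import PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "RelationshipEigen",
    "ModelFit",
    "PedigreeREML",
    "build_numerator_matrix",
    "build_design",
    "reml_fit",
    "substitution_tests",
    "rss_r2",
    "heritability",
]


@dataclasses.dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix over a set of individuals."""

    ids: list[str]
    a: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.ids)
        if self.a.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.a, self.a.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if (np.diag(self.a) < 1.0 - 1e-10).any():
            raise ValueError("relationship diagonal must be >= 1")

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {ind: k for k, ind in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return RelationshipMatrix(list(ids), self.a[np.ix_(idx, idx)])

    def eigen(self, ids: Optional[Sequence[str]] = None) -> "RelationshipEigen":
        sub = self if ids is None else self.submatrix(ids)
        d, u = np.linalg.eigh(sub.a)
        if d.min() < -1e-8:
            raise ValueError("relationship matrix is not positive semi-definite")
        return RelationshipEigen(ids=list(sub.ids), d=np.clip(d, 0.0, None), u=u)


@dataclasses.dataclass
class RelationshipEigen:
    """Cached eigen-decomposition of A over the phenotyped individuals."""

    ids: list[str]
    d: np.ndarray
    u: np.ndarray


def build_numerator_matrix(pedigree: PedigreeTable,
                           max_generations: int = 5) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    A_ii = 1 + F_i with F_i = A(sire,dam)/2; A_ij = (A(j,sire_i)+A(j,dam_i))/2.
    Only the most recent `max_generations` generations are used: individuals
    deeper in the past are dropped and their descendants treated as founders.
    """
    df = pedigree.df.set_index("individual")
    order = pedigree.topological_order
    gen = {}
    for ind in order:
        s, d = df.loc[ind, "sire"], df.loc[ind, "dam"]
        parents = [p for p in (s, d) if p]
        gen[ind] = 0 if not parents else max(gen[p] for p in parents) + 1
    depth = max(gen.values())
    cutoff = depth - max_generations + 1  # oldest generation kept
    keep = [ind for ind in order if gen[ind] >= max(cutoff, 0)]
    pos = {ind: k for k, ind in enumerate(keep)}
    n = len(keep)
    a = np.zeros((n, n))
    for ind in keep:
        i = pos[ind]
        s, d = df.loc[ind, "sire"], df.loc[ind, "dam"]
        si = pos.get(s, -1) if s else -1
        di = pos.get(d, -1) if d else -1
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * a[si]
        if di >= 0:
            row += 0.5 * a[di]
        a[i, :] = row
        a[:, i] = row
        f = 0.5 * a[si, di] if (si >= 0 and di >= 0) else 0.0
        a[i, i] = 1.0 + f
    # reorder rows to original pedigree order of the kept individuals
    ped_order = [ind for ind in pedigree.individuals if ind in pos]
    idx = [pos[ind] for ind in ped_order]
    return RelationshipMatrix(ped_order, a[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Design:
    y: np.ndarray
    X: np.ndarray  # without intercept; PedigreeREML prepends one
    names: list[str]
    ids: list[str]
    marker_names: list[str]


def _factor_columns(values: pd.Series, name: str, coding: str):
    levels = sorted(values.unique())
    if len(levels) < 2:
        return np.zeros((len(values), 0)), []
    cols, names = [], []
    if coding == "treatment":
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(float))
            names.append(f"{name}[{lev}]")
    elif coding == "sum":
        last = levels[-1]
        for lev in levels[:-1]:
            col = (values == lev).to_numpy(float) - (values == last).to_numpy(float)
            cols.append(col)
            names.append(f"{name}[S.{lev}]")
    else:
        raise ValueError("coding must be 'treatment' or 'sum'")
    return np.column_stack(cols), names


def build_design(phenotypes: pd.DataFrame, trait: str = "trait",
                 fixed: Sequence[str] = ("breed", "herd", "sex", "day"),
                 covariates: Sequence[str] = ("age",),
                 markers: Optional[pd.DataFrame] = None,
                 by_breed: Optional[str] = None,
                 coding: str = "treatment") -> Design:
    """Assemble y and the fixed design from a phenotype table.

    Rows with missing trait are excluded.  `markers` is a DataFrame indexed
    by individual; a phenotyped individual with a missing marker dosage is an
    error (imputation belongs upstream).  `by_breed` names one marker column
    to be nested within breed (one coefficient per breed, main effect
    absorbed).
    """
    phen = phenotypes.loc[np.isfinite(phenotypes[trait].astype(float))].copy()
    phen["individual"] = phen["individual"].astype(str)
    ids = phen["individual"].tolist()
    y = phen[trait].astype(float).to_numpy()
    blocks, names = [], []
    for f in fixed:
        cols, nms = _factor_columns(phen[f].astype(str), f, coding)
        blocks.append(cols)
        names.extend(nms)
    for c in covariates:
        blocks.append(phen[c].astype(float).to_numpy()[:, None])
        names.append(c)
    marker_names: list[str] = []
    if markers is not None:
        markers = markers.copy()
        markers.index = markers.index.astype(str)
        absent = [i for i in ids if i not in markers.index]
        if absent:
            raise ValueError(f"marker dosages missing for individuals: {absent[:5]}")
        m = markers.loc[ids]
        if m.isna().to_numpy().any():
            raise ValueError("missing marker dosages are not permitted at fit "
                             "time; impute upstream")
        if by_breed is not None:
            col = m[by_breed].to_numpy(float)
            for br in sorted(phen["breed"].astype(str).unique()):
                ind = (phen["breed"].astype(str) == br).to_numpy(float)
                blocks.append((col * ind)[:, None])
                marker_names.append(f"{by_breed}:{br}")
            rest = [c for c in m.columns if c != by_breed]
            if rest:
                blocks.append(m[rest].to_numpy(float))
                marker_names.extend(rest)
        else:
            blocks.append(m.to_numpy(float))
            marker_names.extend(str(c) for c in m.columns)
        names.extend(marker_names)
    X = np.column_stack([b for b in blocks if b.size]) if blocks else \
        np.zeros((len(ids), 0))
    return Design(y=y, X=X, names=names, ids=ids, marker_names=marker_names)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelFit:
    """REML fit summary: variance components, fixed estimates, RSS."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_a: float
    sigma2_e: float
    h2: float
    h2_se: float
    h2_se_approx: bool
    rss: float
    loglik_restricted: float
    n_used: int
    rank: int
    dropped: tuple[str, ...]
    individuals: tuple[str, ...]
    lambda_: float

    @property
    def df_resid(self) -> int:
        return self.n_used - self.rank

    def coef(self, name: str) -> tuple[float, float]:
        k = self.names.index(name)
        return float(self.beta[k]), float(self.se[k])


class PedigreeREML(BaseEstimator):
    """Animal-model REML estimator, sklearn style.

    Parameters
    ----------
    fit_intercept : prepend a column of ones to X.
    lambda_value : fix the variance ratio sigma2_a/sigma2_e instead of
        estimating it (0 gives ordinary least squares).
    lambda_bounds : search range for lambda on a log grid before scalar
        polishing.
    tol : relative convergence tolerance on the restricted log-likelihood.

    fit(X, y, eig=...) requires the eigen-decomposition of the relationship
    matrix over the n rows of X (see RelationshipMatrix.eigen), so that the
    decomposition can be shared across many marker models.
    """

    def __init__(self, fit_intercept: bool = True,
                 lambda_value: Optional[float] = None,
                 lambda_bounds: tuple[float, float] = (1e-6, 1e4),
                 grid_size: int = 40, tol: float = 1e-9,
                 compute_h2_se: bool = True):
        self.fit_intercept = fit_intercept
        self.lambda_value = lambda_value
        self.lambda_bounds = lambda_bounds
        self.grid_size = grid_size
        self.tol = tol
        self.compute_h2_se = compute_h2_se

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _drop_aliased(X: np.ndarray, names: list[str],
                      drop_preference: Sequence[str],
                      tol: float = 1e-8) -> tuple[np.ndarray, list[str], list[str]]:
        """Drop aliased columns so X has full column rank.

        Columns are admitted greedily by incremental Gram-Schmidt; a column
        whose residual after projection on the admitted span is below `tol`
        (relative) is aliased and dropped.  Columns named in
        `drop_preference` are processed last, most-preferred-to-drop very
        last, so on exact collinearity (e.g. haplotype dosages summing to a
        constant) the preferred column is the one reported non-estimable.
        The intercept (first column) is always admitted first.
        """
        n, m = X.shape
        pref_rank = {nm: k for k, nm in enumerate(drop_preference)}
        order = [0] if m else []
        rest = list(range(1, m))
        # non-preference columns in original order, then preference columns
        # from least to most preferred to drop
        order += [k for k in rest if names[k] not in pref_rank]
        order += sorted((k for k in rest if names[k] in pref_rank),
                        key=lambda k: -pref_rank[names[k]])
        q = np.zeros((n, 0))
        keep: list[int] = []
        for k in order:
            norm = np.linalg.norm(X[:, k])
            if norm == 0:
                continue
            v = X[:, k] / norm
            r = v - q @ (q.T @ v)
            r = r - q @ (q.T @ r)  # re-orthogonalize for stability
            rn = np.linalg.norm(r)
            if rn > tol:
                q = np.column_stack([q, r / rn])
                keep.append(k)
        keep = sorted(keep)
        dropped = [names[k] for k in range(m) if k not in set(keep)]
        return X[:, keep], [names[k] for k in keep], dropped

    @staticmethod
    def _profile(lam: float, dtil: np.ndarray, ytil: np.ndarray,
                 xtil: np.ndarray):
        """Profiled restricted log-likelihood and GLS solution at lambda."""
        n, p = xtil.shape
        v = lam * dtil + 1.0
        w = 1.0 / v
        xtw = xtil * w[:, None]
        g = xtw.T @ xtil
        beta = np.linalg.solve(g, xtw.T @ ytil)
        r = ytil - xtil @ beta
        q = float((r * r * w).sum())
        s2e = q / (n - p)
        sign, ldg = np.linalg.slogdet(g)
        ll = -0.5 * ((n - p) * (1.0 + np.log(2 * np.pi) + np.log(s2e))
                     + float(np.log(v).sum()) + ldg)
        return ll, beta, s2e, g, w

    def fit(self, X, y, eig: RelationshipEigen = None, names=None,
            drop_preference: Sequence[str] = (), ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if eig is None:
            raise ValueError("eig (relationship eigen-decomposition) is required")
        if len(eig.ids) != n:
            raise ValueError("eig does not cover the phenotyped individuals")
        if names is None:
            names = [f"x{k}" for k in range(X.shape[1])]
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
            names = ["(Intercept)"] + list(names)
        X, kept_names, dropped = self._drop_aliased(X, list(names),
                                                    list(drop_preference))
        p = X.shape[1]
        u, d = eig.u, eig.d
        ytil = u.T @ y
        xtil = u.T @ X

        if self.lambda_value is not None:
            lam = float(self.lambda_value)
            ll, beta, s2e, g, w = self._profile(lam, d, ytil, xtil) if lam > 0 \
                else self._profile(0.0, d, ytil, xtil)
        else:
            lo, hi = self.lambda_bounds
            grid = np.concatenate([[0.0], np.geomspace(lo, hi, self.grid_size)])
            lls = np.array([self._profile(l, d, ytil, xtil)[0] for l in grid])
            k = int(lls.argmax())
            if k == 0:
                lam = 0.0
            else:
                a = grid[max(k - 1, 1)]
                b = grid[min(k + 1, len(grid) - 1)]
                res = optimize.minimize_scalar(
                    lambda t: -self._profile(np.exp(t), d, ytil, xtil)[0],
                    bounds=(np.log(a), np.log(b)), method="bounded",
                    options={"xatol": 1e-10})
                lam = float(np.exp(res.x))
                if self._profile(0.0, d, ytil, xtil)[0] >= -res.fun:
                    lam = 0.0
            ll, beta, s2e, g, w = self._profile(lam, d, ytil, xtil)

        cov = s2e * np.linalg.inv(g)
        se = np.sqrt(np.diag(cov))
        s2a = lam * s2e
        h2 = s2a / (s2a + s2e) if (s2a + s2e) > 0 else 0.0
        if self.compute_h2_se:
            h2_se, approx = self._h2_se(s2a, s2e, d, ytil, xtil)
        else:
            h2_se, approx = float("nan"), s2a <= 1e-12
        resid = y - X @ beta
        rss = float(resid @ resid)

        self.names_ = kept_names
        self.coef_ = beta
        self.se_ = se
        self.sigma2_a_ = float(s2a)
        self.sigma2_e_ = float(s2e)
        self.lambda_ = float(lam)
        self.h2_ = float(h2)
        self.h2_se_ = h2_se
        self.h2_se_approx_ = approx
        self.rss_ = rss
        self.loglik_ = float(ll)
        self.n_used_ = n
        self.rank_ = p
        self.dropped_ = tuple(dropped)
        self.ids_ = tuple(ids) if ids is not None else tuple(eig.ids)
        self.n_features_in_ = X.shape[1] - int(self.fit_intercept)
        return self

    def _reml_ll_sig(self, s2a, s2e, d, ytil, xtil):
        n, p = xtil.shape
        v = s2a * d + s2e
        if (v <= 0).any():
            return -np.inf
        w = 1.0 / v
        xtw = xtil * w[:, None]
        g = xtw.T @ xtil
        try:
            beta = np.linalg.solve(g, xtw.T @ ytil)
        except np.linalg.LinAlgError:
            return -np.inf
        r = ytil - xtil @ beta
        sign, ldg = np.linalg.slogdet(g)
        return -0.5 * (float(np.log(v).sum()) + ldg + float((r * r * w).sum())
                       + (n - p) * np.log(2 * np.pi))

    def _h2_se(self, s2a, s2e, d, ytil, xtil):
        """Delta-method SE of h2 from the numerical observed information in
        (sigma2_a, sigma2_e); flagged approximate at the sigma2_a = 0
        boundary."""
        approx = s2a <= 1e-12
        theta = np.array([max(s2a, 1e-8 * s2e), s2e])
        h = 1e-4 * np.maximum(theta, 1e-6)
        ll = lambda t: self._reml_ll_sig(t[0], t[1], d, ytil, xtil)
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                hess[i, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-hess)
            if (np.diag(cov) <= 0).any():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            return float("nan"), True
        tot = theta.sum()
        grad = np.array([theta[1], -theta[0]]) / tot ** 2
        var = float(grad @ cov @ grad)
        return (float(np.sqrt(var)) if var > 0 else float("nan")), bool(approx)

    def to_model_fit(self) -> ModelFit:
        return ModelFit(names=list(self.names_), beta=self.coef_.copy(),
                        se=self.se_.copy(), sigma2_a=self.sigma2_a_,
                        sigma2_e=self.sigma2_e_, h2=self.h2_,
                        h2_se=self.h2_se_, h2_se_approx=self.h2_se_approx_,
                        rss=self.rss_, loglik_restricted=self.loglik_,
                        n_used=self.n_used_, rank=self.rank_,
                        dropped=self.dropped_, individuals=self.ids_,
                        lambda_=self.lambda_)


def reml_fit(phenotypes: pd.DataFrame, relationship, trait: str = "trait",
             fixed: Sequence[str] = ("breed", "herd", "sex", "day"),
             covariates: Sequence[str] = ("age",),
             markers: Optional[pd.DataFrame] = None,
             by_breed: Optional[str] = None, coding: str = "treatment",
             lambda_value: Optional[float] = None,
             drop_preference: Sequence[str] = (),
             compute_h2_se: bool = True) -> ModelFit:
    """Fit the animal model and return a ModelFit summary.

    `relationship` is a RelationshipMatrix (sub-set and eigen-decomposed
    here) or a ready RelationshipEigen over the phenotyped individuals in
    phenotype-table order.
    """
    design = build_design(phenotypes, trait=trait, fixed=fixed,
                          covariates=covariates, markers=markers,
                          by_breed=by_breed, coding=coding)
    if isinstance(relationship, RelationshipEigen):
        eig = relationship
        if list(eig.ids) != design.ids:
            raise ValueError("eigen-decomposition ids do not match the "
                             "phenotyped individuals")
    else:
        eig = relationship.eigen(design.ids)
    est = PedigreeREML(lambda_value=lambda_value, compute_h2_se=compute_h2_se)
    est.fit(design.X, design.y, eig=eig, names=design.names,
            drop_preference=drop_preference, ids=design.ids)
    return est.to_model_fit()


def substitution_tests(fit: ModelFit, columns: Sequence[str]) -> pd.DataFrame:
    """Allele / partial-haplotype substitution-effect t-tests.

    t = b / se with two-sided p from Student t, df = n_used - rank.
    Columns dropped for rank deficiency are flagged non-estimable (no p).
    """
    rows = []
    df_resid = fit.df_resid
    for col in columns:
        if col in fit.dropped or col not in fit.names:
            rows.append({"term": col, "b": np.nan, "se": np.nan, "t": np.nan,
                         "p": np.nan, "estimable": False})
            continue
        b, se = fit.coef(col)
        t = b / se
        p = 2.0 * float(stats.t.sf(abs(t), df_resid))
        rows.append({"term": col, "b": b, "se": se, "t": t, "p": p,
                     "estimable": True})
    return pd.DataFrame(rows)


def rss_r2(fit_with: ModelFit, fit_without: ModelFit) -> float:
    """R^2 = (RSS_n - RSS_w) / RSS_n from two fits on the same sample."""
    if fit_with.individuals != fit_without.individuals:
        raise ValueError("fits are not on the identical phenotype vector")
    rss_n = fit_without.rss
    rss_w = fit_with.rss
    return (rss_n - rss_w) / rss_n


def heritability(fit: ModelFit) -> tuple[float, float]:
    """Narrow-sense heritability h2 = sigma2_a / (sigma2_a + sigma2_e) with
    its delta-method SE (approximate at the sigma2_a = 0 boundary)."""
    return fit.h2, fit.h2_se
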