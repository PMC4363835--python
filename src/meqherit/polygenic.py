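"""Maximum-likelihood polygenic variance-components model.

The model partitions the phenotypic covariance of n relatives as

    Omega = 2*Phi * sigma2_a + I * sigma2_e,

with 2*Phi the additive relationship matrix from the pedigree, sigma2_a the
additive genetic variance, sigma2_e the residual environmental variance, and
narrow-sense heritability h2 = sigma2_a / (sigma2_a + sigma2_e). Writing
sigma2_p = sigma2_a + sigma2_e, the covariance is
sigma2_p * [h2*K + (1-h2)*I] with K = 2*Phi, so after rotating y and the
fixed-effect design X by the eigenvectors of K the likelihood becomes
diagonal: beta has a generalized-least-squares closed form and sigma2_p a
closed form at every candidate h2, leaving a one-dimensional profile
likelihood over h2 in [0, 1] that is maximized by deterministic bounded
search. The standard error of h2 comes from the numerical curvature of the
profile log-likelihood, and the test of h2 = 0 from a likelihood-ratio
statistic referred to the boundary-corrected null, the 50:50 mixture of a
point mass at zero and chi-square(1).

ML is the default and primary path; REML is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import Pedigree, RelationshipMatrix, kinship

__all__ = [
    "ModelSpec",
    "VarianceFit",
    "PolygenicError",
    "UnidentifiableError",
    "TABLE2_MODELS",
    "build_design",
    "spectral_decompose",
    "fit_polygenic",
    "lrt_pvalue",
    "fit_table2_suite",
    "profile_loglik_direct",
    "grid_search_direct",
    "fits_to_frame",
]

_COVARIATE_TOKENS = ("sex", "age", "age_squared", "sex_by_age", "residence")

H2_TOL = 1e-8  # optimizer tolerance on h2
PSD_TOL = 1e-8  # relative tolerance for negative eigenvalues of K


class PolygenicError(ValueError):
    pass


class UnidentifiableError(PolygenicError):
    """K carries no relatedness signal, so sigma2_a and sigma2_e exchange roles."""


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects specification; the intercept is always included."""

    name: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = [c for c in self.covariates if c not in _COVARIATE_TOKENS]
        if bad:
            raise PolygenicError(f"unknown covariates: {bad}")

    @property
    def required_columns(self) -> set[str]:
        need = set()
        for c in self.covariates:
            if c in ("sex", "sex_by_age"):
                need.add("sex")
            if c in ("age", "age_squared", "sex_by_age"):
                need.add("age")
            if c == "residence":
                need.add("residence")
        return need


#: The four covariate models of the primary analysis.
TABLE2_MODELS = (
    ModelSpec("unadjusted", ()),
    ModelSpec("sex_age", ("sex", "age")),
    ModelSpec("sex_age_age2_sexage", ("sex", "age", "age_squared", "sex_by_age")),
    ModelSpec("sex_age_residence", ("sex", "age", "residence")),
)


@dataclass
class VarianceFit:
    """ML estimates for one covariate model (one results-table row)."""

    model: str
    n: int
    h2: float
    se_h2: float
    sigma2_a: float
    sigma2_e: float
    sigma2_p: float
    beta: dict[str, float]
    loglik: float
    loglik_null: float
    p_value: float
    boundary: bool
    method: str = "ML"
    covariates: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "covariates": list(self.covariates),
            "n": self.n,
            "h2": self.h2,
            "se_h2": self.se_h2,
            "sigma2_a": self.sigma2_a,
            "sigma2_e": self.sigma2_e,
            "sigma2_p": self.sigma2_p,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "p_value": self.p_value,
            "boundary": self.boundary,
            "method": self.method,
        }
        d.update({f"beta_{k}": v for k, v in self.beta.items()})
        return d


def _sex01(values: pd.Series) -> np.ndarray:
    mapping = {
        "male": 1.0, "m": 1.0, "1": 1.0, 1: 1.0, 1.0: 1.0,
        "female": 0.0, "f": 0.0, "2": 0.0, 2: 0.0, 2.0: 0.0, 0: 0.0, 0.0: 0.0,
    }
    out = np.empty(len(values))
    for k, v in enumerate(values):
        key = v.lower() if isinstance(v, str) else v
        if key not in mapping:
            raise PolygenicError(f"unrecognized sex value {v!r}")
        out[k] = mapping[key]
    return out


def _residence01(values: pd.Series) -> np.ndarray:
    mapping = {
        "rural": 1.0, "1": 1.0, 1: 1.0, 1.0: 1.0, True: 1.0,
        "municipal": 0.0, "urban": 0.0, "0": 0.0, 0: 0.0, 0.0: 0.0, False: 0.0,
    }
    out = np.empty(len(values))
    for k, v in enumerate(values):
        key = v.lower() if isinstance(v, str) else v
        if key not in mapping:
            raise PolygenicError(f"unrecognized residence value {v!r}")
        out[k] = mapping[key]
    return out


def build_design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (scaled design, raw design, raw labels) for a covariate model.

    The scaled design z-scores age (and builds age^2 / sex-by-age from the
    z-scored age) purely for numerical conditioning of the optimization; the
    raw design is used to report back-transformed fixed effects in natural
    units. Both span the same column space.
    """
    n = len(df)
    cols_scaled: list[np.ndarray] = [np.ones(n)]
    cols_raw: list[np.ndarray] = [np.ones(n)]
    labels = ["intercept"]
    sex = _sex01(df["sex"]) if "sex" in spec.required_columns else None
    if "age" in spec.required_columns:
        age = np.asarray(df["age"], dtype=float)
        sd = age.std(ddof=1)
        if sd == 0:
            raise PolygenicError("age has zero variance; cannot include age terms")
        age_z = (age - age.mean()) / sd
    for tok in spec.covariates:
        if tok == "sex":
            cols_scaled.append(sex)
            cols_raw.append(sex)
            labels.append("sex_male")
        elif tok == "age":
            cols_scaled.append(age_z)
            cols_raw.append(age)
            labels.append("age")
        elif tok == "age_squared":
            cols_scaled.append(age_z**2)
            cols_raw.append(age**2)
            labels.append("age_squared")
        elif tok == "sex_by_age":
            cols_scaled.append(sex * age_z)
            cols_raw.append(sex * age)
            labels.append("sex_by_age")
        elif tok == "residence":
            res = _residence01(df["residence"])
            cols_scaled.append(res)
            cols_raw.append(res)
            labels.append("residence_rural")
    Xs = np.column_stack(cols_scaled)
    Xr = np.column_stack(cols_raw)
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise PolygenicError(f"model {spec.name!r}: design matrix is rank deficient")
    return Xs, Xr, labels


def spectral_decompose(
    K: np.ndarray | RelationshipMatrix, groups: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of K, exploiting block-diagonal family structure.

    ``groups`` labels rows by family; disconnected families make K
    block-diagonal, so each block is decomposed separately (a large speedup
    for multi-family cohorts). Returns (eigenvalues, eigenvectors) with
    K = U diag(d) U'.
    """
    A = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    n = A.shape[0]
    if groups is None:
        d, U = linalg.eigh(A)
        return d, U
    groups = np.asarray(groups)
    d = np.empty(n)
    U = np.zeros((n, n))
    off = 0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        block = A[np.ix_(idx, idx)]
        # family labels must actually partition K into blocks
        rest = np.delete(np.arange(n), idx)
        if rest.size and np.abs(A[np.ix_(idx, rest)]).max() > 1e-10:
            raise PolygenicError(
                "group labels do not block-diagonalize K; "
                "falling back to a dense decomposition is required"
            )
        db, Ub = linalg.eigh(block)
        cols = slice(off, off + idx.size)
        d[cols] = db
        U[idx, cols] = Ub
        off += idx.size
    return d, U


def _profile_nll_factory(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray, reml: bool):
    """Negative profile log-likelihood over h2 on rotated data."""
    n, p = Xt.shape
    dof = n - p if reml else n

    def nll(h2: float) -> float:
        lam = h2 * d + (1.0 - h2)
        if np.any(lam <= 0):
            return np.inf
        w = 1.0 / lam
        Xw = Xt * w[:, None]
        XtWX = Xt.T @ Xw
        try:
            beta = linalg.solve(XtWX, Xw.T @ yt, assume_a="pos")
        except linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        if rss <= 0:
            return np.inf
        s2 = rss / dof
        ll = -0.5 * (dof * np.log(2 * np.pi * s2) + np.sum(np.log(lam)) + dof)
        if reml:
            sign, logdet = np.linalg.slogdet(XtWX)
            ll -= 0.5 * logdet
            ll += 0.5 * p * np.log(2 * np.pi)  # constant; kept for comparability
        return -ll

    return nll


def _gls_beta_sigma(y, X, d, U, h2, reml=False):
    yt = U.T @ y
    Xt = U.T @ X
    lam = h2 * d + (1.0 - h2)
    w = 1.0 / lam
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    beta = linalg.solve(XtWX, Xw.T @ yt, assume_a="pos")
    r = yt - Xt @ beta
    dof = len(y) - X.shape[1] if reml else len(y)
    s2 = float(np.sum(w * r * r)) / dof
    return beta, s2


def lrt_pvalue(loglik_alt: float, loglik_null: float) -> float:
    """Boundary-corrected likelihood-ratio p-value for h2 = 0.

    Under the null, the LRT statistic is distributed as a 50:50 mixture of a
    point mass at 0 and chi-square(1) because h2 = 0 lies on the boundary of
    the parameter space; p = 0.5 * P(chi2_1 >= LRT), which equals 0.5 at a
    zero statistic.
    """
    delta = loglik_alt - loglik_null
    if delta < -1e-6:
        raise PolygenicError(
            f"alternative log-likelihood below null by {-delta:.3g}; "
            "the models are nested so this indicates an optimization failure"
        )
    lam = max(2.0 * delta, 0.0)
    return float(0.5 * stats.chi2.sf(lam, df=1))


def fit_polygenic(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | RelationshipMatrix | None = None,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    groups: Sequence | None = None,
    X_raw: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
    reml: bool = False,
    model_name: str = "custom",
    covariates: tuple[str, ...] = (),
) -> VarianceFit:
    """Fit the polygenic model by profiling the likelihood over h2 in [0, 1].

    ``K`` (or a precomputed eigendecomposition ``eig``) is the additive
    relationship matrix aligned with the rows of ``y`` and ``X``. ``X_raw``,
    if given, is a design spanning the same column space in natural units;
    reported fixed effects are computed against it.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise PolygenicError("y and X have different numbers of rows")
    if n < 3:
        raise PolygenicError("need at least 3 individuals")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise PolygenicError("y/X contain non-finite values; drop incomplete cases first")

    if eig is None:
        if K is None:
            raise PolygenicError("either K or its eigendecomposition is required")
        A = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
        if A.shape != (n, n):
            raise PolygenicError("K shape does not match y")
        off = A - np.diag(np.diag(A))
        if np.abs(off).max() < 1e-12:
            raise UnidentifiableError(
                "h2 unidentifiable: all individuals mutually unrelated (K = I), "
                "so sigma2_a and sigma2_e exchange roles exactly"
            )
        d, U = spectral_decompose(A, groups=groups)
    else:
        d, U = eig
        d = np.asarray(d, dtype=float)
        if d.max() - d.min() < 1e-12:
            raise UnidentifiableError("h2 unidentifiable: K has a flat spectrum")
    if d.min() < -PSD_TOL * max(d.max(), 1.0):
        raise PolygenicError(
            f"K is not positive semidefinite (min eigenvalue {d.min():.3g})"
        )
    d = np.clip(d, 0.0, None)

    yt = U.T @ y
    Xt = U.T @ X
    nll = _profile_nll_factory(yt, Xt, d, reml)

    # coarse deterministic grid bracket, then bounded scalar refinement
    grid = np.linspace(0.0, 1.0, 51)
    vals = np.array([nll(h) for h in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": H2_TOL}
    )
    h2_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the boundary itself can beat the interior optimum by a hair
    for h_edge in (0.0, 1.0):
        if -nll(h_edge) > ll_hat:
            h2_hat, ll_hat = h_edge, -nll(h_edge)
    boundary = h2_hat < 1e-6 or h2_hat > 1.0 - 1e-6

    beta_opt, s2p = _gls_beta_sigma(y, X, d, U, h2_hat, reml=reml)
    if X_raw is not None:
        beta_rep, _ = _gls_beta_sigma(y, np.asarray(X_raw, float), d, U, h2_hat, reml=reml)
    else:
        beta_rep = beta_opt
    if labels is None:
        labels = [f"b{i}" for i in range(len(beta_rep))]

    # SE from profile curvature; one-sided differences at the boundary
    step = 1e-3
    if step < h2_hat < 1.0 - step:
        d2 = (-nll(h2_hat + step) + 2 * nll(h2_hat) - nll(h2_hat - step)) / step**2
    elif h2_hat <= step:
        d2 = (-nll(h2_hat + 2 * step) + 2 * nll(h2_hat + step) - nll(h2_hat)) / step**2
    else:
        d2 = (-nll(h2_hat - 2 * step) + 2 * nll(h2_hat - step) - nll(h2_hat)) / step**2
    se_h2 = float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")

    ll_null = -nll(0.0)
    pval = lrt_pvalue(ll_hat, ll_null)

    return VarianceFit(
        model=model_name,
        n=n,
        h2=h2_hat,
        se_h2=se_h2,
        sigma2_a=h2_hat * s2p,
        sigma2_e=(1.0 - h2_hat) * s2p,
        sigma2_p=s2p,
        beta={lab: float(b) for lab, b in zip(labels, beta_rep)},
        loglik=ll_hat,
        loglik_null=ll_null,
        p_value=pval,
        boundary=boundary,
        method="REML" if reml else "ML",
        covariates=covariates,
    )


def fit_table2_suite(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    models: Sequence[ModelSpec] = TABLE2_MODELS,
    reml: bool = False,
) -> list[VarianceFit]:
    """Fit the standard four covariate models on one cohort.

    ``phenotypes`` needs individual_id, meq_total, sex, age, residence (the
    last may be missing where a model does not use it). Rows with a missing
    phenotype or any covariate the model requires are dropped per model
    (complete-case analysis), so n may differ between rows of the output.
    Relatedness is taken from the full pedigree before subsetting, so
    unphenotyped connecting relatives still contribute structure.
    """
    for col in ("individual_id", "meq_total"):
        if col not in phenotypes.columns:
            raise PolygenicError(f"phenotype table lacks required column {col!r}")
    df = phenotypes.copy()
    df["individual_id"] = df["individual_id"].astype(str)
    in_ped = df["individual_id"].isin(set(ped.ids))
    df = df[in_ped]
    A_full = kinship(ped)
    fam = ped.family_of()
    fits = []
    for spec in models:
        cols = ["meq_total"] + sorted(spec.required_columns)
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise PolygenicError(
                f"model {spec.name!r} needs columns {missing_cols} "
                "absent from the phenotype table"
            )
        sub = df.dropna(subset=cols)
        ids = list(sub["individual_id"])
        A = A_full.reorder(ids)
        groups = [fam[i] for i in ids]
        Xs, Xr, labels = build_design(sub, spec)
        fit = fit_polygenic(
            np.asarray(sub["meq_total"], dtype=float),
            Xs,
            A,
            groups=groups,
            X_raw=Xr,
            labels=labels,
            reml=reml,
            model_name=spec.name,
            covariates=spec.covariates,
        )
        fits.append(fit)
    return fits


def fits_to_frame(fits: Sequence[VarianceFit]) -> pd.DataFrame:
    """Results table mirroring the model/n/h2/SE/p layout of the analysis."""
    return pd.DataFrame([f.to_dict() for f in fits])


# --- dense reference implementations (independent cross-check path) ---------


def profile_loglik_direct(
    y: np.ndarray, X: np.ndarray, K: np.ndarray | RelationshipMatrix, h2: float
) -> tuple[float, np.ndarray, float]:
    """Un-rotated profile log-likelihood at one h2, by direct dense solves.

    Reference implementation: builds Omega0 = h2*K + (1-h2)*I explicitly and
    uses Cholesky solves and slogdet, sharing no code with the spectral
    path. Returns (loglik, beta, sigma2_p).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    A = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
    n = len(y)
    Omega0 = h2 * A + (1.0 - h2) * np.eye(n)
    sign, logdet = np.linalg.slogdet(Omega0)
    if sign <= 0:
        return -np.inf, np.full(X.shape[1], np.nan), np.nan
    Oi_X = np.linalg.solve(Omega0, X)
    Oi_y = np.linalg.solve(Omega0, y)
    beta = np.linalg.solve(X.T @ Oi_X, X.T @ Oi_y)
    r = y - X @ beta
    s2 = float(r @ np.linalg.solve(Omega0, r)) / n
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(ll), beta, s2


def grid_search_direct(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | RelationshipMatrix,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Brute-force oracle: best (h2, loglik) over a dense grid, direct solves."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    lls = [profile_loglik_direct(y, X, K, h)[0] for h in grid]
    k = int(np.argmax(lls))
    return float(grid[k]), float(lls[k])
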