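"""Fixed-effect least squares, nested-model F ratios, and pedigree machinery.

Every association statistic in the pipeline is an F ratio of residual sums of
squares between two nested fixed-effect models, so this module is the currency
exchange of the package: it builds design matrices from phenotype records
(treatment contrasts on factors, raw covariates, optional line-origin and
candidate-genotype terms), fits them by QR least squares with aliased-column
dropping, and compares them.  It also provides the numerator-relationship
(A) matrix and the mixed-model equations used to pre-correct phenotypes for
additive infinitesimal (polygenic) effects before haplotype regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "FTest",
    "AMatrix",
    "fit_ls",
    "f_ratio",
    "build_a_matrix",
    "correct_phenotypes",
]


@dataclass(frozen=True)
class ModelSpec:
    """Terms of one fixed-effect model for ear size.

    The four models of the candidate-gene framework are spanned by two
    switches on a common base (batch + sex + unlinked-QTL genotype + carcass
    weight):

    ====== ============ ===========
    model  line_origin  candidate
    ====== ============ ===========
    1      False        None
    2      True         None
    3      False        set
    4      True         set
    ====== ============ ===========
    """

    response: str = "ear_size_cm2"
    factors: tuple = ("batch", "sex", "ppard_genotype")
    covariates: tuple = ("carcass_weight",)
    line_origin: bool = False
    candidate: str | None = None

    def __post_init__(self):
        terms = list(self.factors) + list(self.covariates)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate model terms")

    def with_line_origin(self) -> "ModelSpec":
        return replace(self, line_origin=True)

    def with_candidate(self, column: str) -> "ModelSpec":
        return replace(self, candidate=column)

    def is_nested_in(self, full: "ModelSpec") -> bool:
        return (
            self.response == full.response
            and set(self.factors) <= set(full.factors)
            and set(self.covariates) <= set(full.covariates)
            and (not self.line_origin or full.line_origin)
            and (self.candidate is None or self.candidate == full.candidate)
        )

    @property
    def columns(self) -> tuple:
        cols = (self.response,) + self.factors + self.covariates
        if self.candidate is not None:
            cols = cols + (self.candidate,)
        return cols


@dataclass
class FitResult:
    """One fitted linear model: coefficients, RSS and residual df."""

    params: pd.Series
    rss: float
    df_resid: int
    n: int
    residuals: np.ndarray
    fitted: np.ndarray
    cov_unscaled: np.ndarray | None = None
    dropped: tuple = ()
    row_index: pd.Index | None = None

    @property
    def sigma2(self) -> float:
        return self.rss / self.df_resid

    def se(self, name: str) -> float:
        i = list(self.params.index).index(name)
        return float(np.sqrt(self.sigma2 * self.cov_unscaled[i, i]))


@dataclass(frozen=True)
class FTest:
    """Nested-model F ratio with its degrees of freedom and P-value."""

    f: float
    df_num: int
    df_den: int
    p_value: float

    def __str__(self):
        return (f"F({self.df_num}, {self.df_den}) = {self.f:.2f}, "
                f"P = {self.p_value:.3g}")


# ---------------------------------------------------------------------------
# design construction and fitting
# ---------------------------------------------------------------------------

def _factor_dummies(values: pd.Series, term: str):
    """Treatment-contrast dummies (first sorted level is the reference)."""
    cat = pd.Categorical(values.astype(str))
    levels = list(cat.categories)
    if len(levels) < 1:
        raise ValueError(f"factor {term!r} has no observed level")
    cols, names = [], []
    codes = cat.codes
    for k, lev in enumerate(levels[1:], start=1):
        cols.append((codes == k).astype(float))
        names.append(f"{term}[{lev}]")
    return cols, names


def design_matrix(records: pd.DataFrame, spec: ModelSpec,
                  origin: tuple | None = None):
    """Build (X, column_names, y) for ``spec`` on ``records``.

    ``origin`` supplies the line-origin regressors (c_a, c_d) when
    ``spec.line_origin`` is set; alternatively the records may carry ``c_a``
    and ``c_d`` columns.
    """
    n = len(records)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in spec.factors:
        c, nm = _factor_dummies(records[term], term)
        cols += c
        names += nm
    for term in spec.covariates:
        cols.append(records[term].to_numpy(dtype=float))
        names.append(term)
    if spec.candidate is not None:
        c, nm = _factor_dummies(records[spec.candidate], spec.candidate)
        cols += c
        names += nm
    if spec.line_origin:
        if origin is not None:
            ca, cd = origin
        elif {"c_a", "c_d"} <= set(records.columns):
            ca = records["c_a"].to_numpy(dtype=float)
            cd = records["c_d"].to_numpy(dtype=float)
        else:
            raise ValueError("line_origin model needs (c_a, c_d) regressors")
        cols += [np.asarray(ca, dtype=float), np.asarray(cd, dtype=float)]
        names += ["c_a", "c_d"]
    X = np.column_stack(cols)
    y = records[spec.response].to_numpy(dtype=float)
    return X, names, y


def drop_incomplete(records: pd.DataFrame, *specs: ModelSpec) -> pd.DataFrame:
    """Drop records with missing values in any column any spec uses (logged)."""
    cols = sorted({c for s in specs for c in s.columns if c in records.columns})
    kept = records.dropna(subset=cols)
    n_drop = len(records) - len(kept)
    if n_drop:
        logger.info("dropped %d records with missing values in %s", n_drop, cols)
    return kept


def _solve_ls(X: np.ndarray, y: np.ndarray, names):
    """QR least squares with pivoting; aliased columns dropped and reported."""
    n, p = X.shape
    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = sorted(piv[:rank])
    dropped = tuple(names[j] for j in sorted(piv[rank:]))
    Xk = X[:, keep]
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    fitted = Xk @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    cov_unscaled = np.linalg.inv(Xk.T @ Xk)
    kept_names = [names[j] for j in keep]
    return beta, kept_names, dropped, rss, fitted, resid, rank, cov_unscaled


def fit_ls(records: pd.DataFrame, spec: ModelSpec,
           origin: tuple | None = None) -> FitResult:
    """Ordinary least squares for ``spec`` on ``records``.

    Factors use treatment contrasts; rank deficiency is resolved by dropping
    aliased columns (logged).  Raises on empty data or zero residual df.
    """
    records = drop_incomplete(records, spec)
    if len(records) == 0:
        raise ValueError("no complete records to fit")
    X, names, y = design_matrix(records, spec, origin)
    beta, kept, dropped, rss, fitted, resid, rank, covu = _solve_ls(X, y, names)
    df_resid = len(records) - rank
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    if dropped:
        logger.info("dropped aliased design columns: %s", list(dropped))
    return FitResult(
        params=pd.Series(beta, index=kept),
        rss=rss, df_resid=df_resid, n=len(records),
        residuals=resid, fitted=fitted, cov_unscaled=covu,
        dropped=dropped, row_index=records.index,
    )


def f_ratio(reduced: FitResult, full: FitResult, tol: float = 1e-8) -> FTest:
    """F ratio of residual sums of squares between two nested fits.

    F = ((RSS_r - RSS_f) / (df_r - df_f)) / (RSS_f / df_f), with the P-value
    from the F distribution on (df_r - df_f, df_f) degrees of freedom.
    """
    if reduced.n != full.n:
        raise ValueError("fits use different numbers of records")
    df1 = reduced.df_resid - full.df_resid
    if df1 <= 0:
        raise ValueError("full model has no extra parameters over reduced")
    scale = max(1.0, abs(reduced.rss))
    if full.rss > reduced.rss + tol * scale:
        raise ValueError(
            "RSS of the 'full' model exceeds the reduced model's: "
            "models do not appear nested")
    num = max(reduced.rss - full.rss, 0.0) / df1
    den = full.rss / full.df_resid
    f = num / den if den > 0 else np.inf
    p = float(stats.f.sf(f, df1, full.df_resid))
    return FTest(float(f), int(df1), int(full.df_resid), p)


# ---------------------------------------------------------------------------
# pedigree relationship matrix and mixed-model correction
# ---------------------------------------------------------------------------

@dataclass
class AMatrix:
    """Additive (numerator) relationship matrix indexed by pedigree ids."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A matrix shape does not match ids")

    def loc(self, i, j) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])


def _toposort(pedigree: pd.DataFrame) -> list:
    ids = list(pedigree["id"])
    parents = {
        r.id: tuple(p for p in (r.sire, r.dam)
                    if isinstance(p, str) and p not in ("", "0") and p == p)
        for r in pedigree.itertuples()
    }
    known = set(ids)
    order, done = [], set()
    state = {}

    def visit(i, stack):
        if i in done or i not in known:
            return
        if i in stack:
            raise ValueError(f"pedigree cycle involving {i!r}")
        stack.add(i)
        for p in parents.get(i, ()):
            visit(p, stack)
        stack.discard(i)
        done.add(i)
        order.append(i)

    for i in ids:
        visit(i, set())
    return order


def build_a_matrix(pedigree: pd.DataFrame) -> AMatrix:
    """Numerator relationship matrix by the tabular method.

    Unknown parents ("" / "0" / NaN) are treated as unrelated, non-inbred
    founders.  The pedigree is topologically sorted first; cycles raise.
    """
    order = _toposort(pedigree)
    idx = {i: k for k, i in enumerate(order)}
    ped = pedigree.set_index("id")

    def parent_idx(i, col):
        p = ped.at[i, col]
        if not isinstance(p, str) or p in ("", "0") or p != p or p not in idx:
            return -1
        return idx[p]

    n = len(order)
    A = np.zeros((n, n))
    for i in order:
        k = idx[i]
        s = parent_idx(i, "sire")
        d = parent_idx(i, "dam")
        row = np.zeros(k)
        if s >= 0:
            row += 0.5 * A[s, :k]
        if d >= 0:
            row += 0.5 * A[d, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return AMatrix(order, A)


def correct_phenotypes(records: pd.DataFrame, pedigree: pd.DataFrame,
                       heritability: float,
                       spec: ModelSpec | None = None) -> pd.Series:
    """Residuals after fixed effects and additive infinitesimal effects.

    Solves Henderson's mixed-model equations with animal effects
    u ~ N(0, A sigma2_a) and lambda = sigma2_e / sigma2_a derived from the
    supplied ``heritability`` = sigma2_a / (sigma2_a + sigma2_e).  The default
    fixed part corrects for batch, sex and carcass weight.  Returns
    y - X b_hat - u_hat indexed by individual id.
    """
    if not (0.0 <= heritability < 1.0):
        raise ValueError("heritability must lie in [0, 1)")
    if spec is None:
        spec = ModelSpec(factors=("batch", "sex"),
                         covariates=("carcass_weight",))
    records = drop_incomplete(records, spec)
    X, names, y = design_matrix(records, spec)
    # drop aliased columns so the fixed block is full rank
    beta, kept, dropped, *_ = _solve_ls(X, y, names)
    keep_idx = [names.index(nm) for nm in kept]
    X = X[:, keep_idx]

    if heritability == 0.0:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return pd.Series(resid, index=records["id"].to_numpy(), name="residual")

    amat = build_a_matrix(pedigree)
    q = len(amat.ids)
    aidx = {i: k for k, i in enumerate(amat.ids)}
    rows = np.array([aidx[i] for i in records["id"]])
    lam = (1.0 - heritability) / heritability
    try:
        a_inv = np.linalg.inv(amat.values)
    except np.linalg.LinAlgError as exc:
        raise ValueError("A matrix is singular") from exc

    p = X.shape[1]
    n = len(records)
    Z = np.zeros((n, q))
    Z[np.arange(n), rows] = 1.0
    C = np.zeros((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = Z.T @ X
    C[p:, p:] = Z.T @ Z + lam * a_inv
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular mixed-model coefficient matrix") from exc
    b, u = sol[:p], sol[p:]
    resid = y - X @ b - u[rows]
    return pd.Series(resid, index=records["id"].to_numpy(), name="residual")
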