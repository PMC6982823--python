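"""Response-surface analysis of the extraction yield.

A ten-run, three-factor design (pressure, particle size, CO2 flow) is fit
with a first-order model with two-way interactions,

    Y_D = a0 + a1*x1 + a2*x2 + a3*x3 + a12*x1*x2 + a13*x1*x3 + a23*x2*x3,

on coded factors x in [-1, 1]. The module covers factor coding, the OLS
fit with t-based inference, significance-driven model reduction,
prediction surfaces, the between-term correlation matrix used to vet the
design, and D-optimal subset selection by Fedorov exchange.

Factor semantics follow the coded design table: x1 = pressure, x2 =
particle size, x3 = CO2 flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["DesignTable", "RsmFit", "code_factors", "decode_factors",
           "model_matrix", "fit_rsm", "reduce_model", "coef_correlations",
           "correlation_histogram", "d_optimal_select", "surface_grid",
           "TERMS"]

#: Model-term names, intercept first.
TERMS = ("a0", "a1", "a2", "a3", "a12", "a13", "a23")
_COLS = ("x1", "x2", "x3")


@dataclass
class DesignTable:
    """Coded factor settings and observed yields of one experiment set.

    coded holds columns x1, x2, x3 (values nominally in [-1, 1]; small
    overshoots from flow drift are tolerated); yields is the observed
    response in %, one entry per run; natural optionally carries the
    uncoded factor levels.
    """

    coded: pd.DataFrame
    yields: np.ndarray | None = None
    natural: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _COLS if c not in self.coded.columns]
        if missing:
            raise ValueError(f"coded design lacks columns {missing}")
        self.coded = self.coded.loc[:, list(_COLS)].astype(float)
        if np.any(np.abs(self.coded.to_numpy()) > 1.05):
            raise ValueError("coded values far outside [-1, 1]")
        if self.yields is not None:
            self.yields = np.asarray(self.yields, dtype=float)
            if self.yields.shape != (len(self.coded),):
                raise ValueError("one yield per run required")

    @property
    def n_runs(self) -> int:
        return len(self.coded)


@dataclass
class RsmFit:
    """OLS results for the interaction model on coded factors."""

    coefficients: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    stars: pd.Series
    r2: float
    r2_predicted: float
    residuals: np.ndarray
    n_obs: int
    design: DesignTable = field(repr=False)

    def predict(self, coded: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = model_matrix(pd.DataFrame(np.atleast_2d(coded),
                                      columns=_COLS))
        return X @ self.coefficients.to_numpy()


def code_factors(values, low, high):
    """Map natural factor values to coded units: (v - center)/half-range."""
    values = np.asarray(values, dtype=float)
    center = (high + low) / 2.0
    half = (high - low) / 2.0
    if half <= 0:
        raise ValueError("high must exceed low")
    return (values - center) / half


def decode_factors(coded, low, high):
    """Inverse of :func:`code_factors`."""
    coded = np.asarray(coded, dtype=float)
    return (high + low) / 2.0 + coded * (high - low) / 2.0


def model_matrix(coded: pd.DataFrame) -> np.ndarray:
    """[1, x1, x2, x3, x1*x2, x1*x3, x2*x3] design matrix."""
    x1 = coded["x1"].to_numpy(dtype=float)
    x2 = coded["x2"].to_numpy(dtype=float)
    x3 = coded["x3"].to_numpy(dtype=float)
    return np.column_stack([np.ones_like(x1), x1, x2, x3,
                            x1 * x2, x1 * x3, x2 * x3])


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fit_rsm(design: DesignTable) -> RsmFit:
    """Ordinary least squares of the yields on the seven model terms.

    Inference is t-based with residual df = n - 7; predicted R^2 is the
    leave-one-out PRESS statistic 1 - PRESS/SS_tot computed from the hat
    matrix.
    """
    if design.yields is None:
        raise ValueError("design carries no observed yields")
    X = model_matrix(design.coded)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} runs to fit {p} terms")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        s = np.linalg.svd(X, compute_uv=False)
        raise ValueError("design matrix is rank deficient (aliased terms); "
                         f"singular values {np.round(s, 6).tolist()}")

    res = sm.OLS(design.yields, X).fit()
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    loo = res.resid / (1.0 - np.diag(H))
    press = float(np.sum(loo ** 2))
    ss_tot = float(np.sum((design.yields - design.yields.mean()) ** 2))
    ss_res = float(np.sum(res.resid ** 2))
    # constant response: R^2 undefined, report nan instead of +/-inf
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    r2_pred = 1.0 - press / ss_tot if ss_tot > 0 else float("nan")

    idx = pd.Index(TERMS, name="term")
    return RsmFit(
        coefficients=pd.Series(res.params, index=idx),
        se=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        stars=pd.Series([_stars(p) for p in res.pvalues], index=idx),
        r2=r2,
        r2_predicted=r2_pred,
        residuals=np.asarray(res.resid),
        n_obs=n,
        design=design,
    )


def reduce_model(fit: RsmFit, alpha: float = 0.05) -> pd.Series:
    """Retain the intercept plus every term with p < alpha.

    On the study's own design this keeps only {a0, a1}: the pressure
    effect is the single significant factor at the 5% level.
    """
    keep = [t for t in TERMS
            if t == "a0" or fit.pvalues[t] < alpha]
    return fit.coefficients[keep]


def coef_correlations(design: DesignTable) -> pd.DataFrame:
    """Pairwise Pearson correlations among the six non-intercept model
    columns (x1 ... x2*x3) of the design.

    This is the between-term correlation matrix used to judge how far the
    near-saturated design departs from orthogonality; it depends on the
    factor settings only, never on the observed yields. An orthogonal
    two-level full factorial gives the identity.
    """
    X = model_matrix(design.coded)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    labels = list(TERMS[1:])
    corr = np.corrcoef(X[:, 1:], rowvar=False)
    return pd.DataFrame(corr, index=labels, columns=labels)


def correlation_histogram(matrix: pd.DataFrame,
                          band: tuple[float, float] = (0.2, 0.4)) -> float:
    """Percentage (nearest integer) of the 15 distinct off-diagonal pairs
    whose |r| lies inside the closed band."""
    M = np.asarray(matrix, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("matrix must be square and symmetric")
    iu = np.triu_indices_from(M, k=1)
    r = np.abs(M[iu])
    frac = np.mean((r >= band[0]) & (r <= band[1]))
    return float(round(100.0 * frac))


def _logdet(X: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -np.inf


def d_optimal_select(candidates: pd.DataFrame, k: int,
                     seed: int = 20200103, max_passes: int = 1000,
                     rng: np.random.Generator | None = None):
    """Select k candidate runs maximising det(X'X) by Fedorov exchange.

    Starts from a random full-rank k-subset and repeatedly applies the
    single best (selected-point, candidate-point) swap until no exchange
    improves the determinant. log det(X'X) is non-decreasing across
    iterations. Returns (row indices, log-determinant).
    """
    Xc = model_matrix(pd.DataFrame(candidates, columns=_COLS))
    n, p = Xc.shape
    if k < p:
        raise ValueError(f"k must be at least the {p} model parameters")
    if k > n:
        raise ValueError("k exceeds the number of candidates")
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("candidate set is rank deficient")

    rng = np.random.default_rng(seed) if rng is None else rng
    for _ in range(1000):
        sel = np.sort(rng.choice(n, size=k, replace=False))
        if _logdet(Xc[sel]) > -np.inf:
            break
    else:
        raise ValueError("could not find a full-rank starting subset")

    best = _logdet(Xc[sel])
    for _ in range(max_passes):
        improved = False
        pool = np.setdiff1d(np.arange(n), sel)
        move, gain = None, 1e-12
        for i, si in enumerate(sel):
            for j in pool:
                trial = sel.copy()
                trial[i] = j
                ld = _logdet(Xc[trial])
                if ld - best > gain:
                    move, gain = (i, j), ld - best
        if move is not None:
            sel[move[0]] = move[1]
            sel.sort()
            best = _logdet(Xc[sel])
            improved = True
        if not improved:
            break
    return sel, float(best)


def surface_grid(fit: RsmFit, pair: tuple[str, str] = ("x1", "x2"),
                 fixed: float = 0.0, n: int = 41):
    """Predicted-yield grid over a coded plane of two factors with the
    third held fixed. Returns (grid1, grid2, surface)."""
    if len(set(pair)) != 2 or any(f not in _COLS for f in pair):
        raise ValueError("pair must name two distinct coded factors")
    g = np.linspace(-1.0, 1.0, n)
    G1, G2 = np.meshgrid(g, g, indexing="ij")
    other = next(c for c in _COLS if c not in pair)
    coded = pd.DataFrame({pair[0]: G1.ravel(), pair[1]: G2.ravel(),
                          other: np.full(G1.size, float(fixed))})
    Z = fit.predict(coded[list(_COLS)]).reshape(G1.shape)
    return G1, G2, Z
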