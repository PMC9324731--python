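"""Construct specification equations by principal component regression.

The explanatory variables (primacy, recency, frequency — the constant
mid-range column carries no variance and is absorbed into the intercept) are
eigendecomposed (PCA1, covariance matrix of the centered, unstandardized
columns by default) and the empirical item difficulties are regressed on the
retained component scores. With all components retained the fit is identical
to ordinary least squares. Coefficient uncertainties combine the regression
standard errors with the measurement uncertainty of the input difficulties in
quadrature and are reported with coverage factor k = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .entropy_constructs import ExplanatoryMatrix
from .errors import DegeneratePCAError, DegenerateRegressionError, ParameterError

__all__ = [
    "PCA1Result",
    "CSEModel",
    "pca_explanatory",
    "explanatory_correlations",
    "fit_cse",
    "cse_contributions",
    "subgroup_cse",
]

_VAR_ZERO_TOL = 1e-12


def _as_variable_frame(X: Union[ExplanatoryMatrix, pd.DataFrame, np.ndarray]) -> pd.DataFrame:
    """Non-constant explanatory columns as a DataFrame (items x variables)."""
    if isinstance(X, ExplanatoryMatrix):
        return pd.DataFrame(X.variable_matrix(), columns=list(ExplanatoryMatrix.VARIABLES))
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        arr = np.asarray(X, dtype=float)
        df = pd.DataFrame(arr, columns=[f"x{k+1}" for k in range(arr.shape[1])])
    # drop zero-variance columns (e.g. a constant mid-range column)
    keep = [c for c in df.columns if df[c].var(ddof=1) > _VAR_ZERO_TOL]
    return df[keep]


@dataclass(frozen=True)
class PCA1Result:
    """Eigendecomposition of the explanatory variables.

    ``loadings`` has one column per component (orthonormal); the first
    component is signed so its loading on the first variable (primacy, by
    convention) is positive.
    """

    variables: tuple[str, ...]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    mode: str
    means: np.ndarray
    scales: np.ndarray

    def component(self, p: int) -> pd.Series:
        """Loadings of component ``p`` (1-based) keyed by variable name."""
        return pd.Series(self.loadings[:, p - 1], index=list(self.variables))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{p+1}" for p in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=list(self.variables), columns=cols)


def pca_explanatory(
    X: Union[ExplanatoryMatrix, pd.DataFrame, np.ndarray],
    mode: str = "covariance",
) -> PCA1Result:
    """PCA of the (centered) explanatory variables.

    ``mode='covariance'`` (default) works on unstandardized centered columns;
    ``mode='correlation'`` standardizes first. Constant columns are excluded.
    """
    if mode not in ("covariance", "correlation"):
        raise ParameterError(f"mode must be 'covariance' or 'correlation', got {mode!r}")
    df = _as_variable_frame(X)
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise DegeneratePCAError(
            f"need >= 2 items and >= 1 non-constant variable, got {df.shape}"
        )
    vals = df.to_numpy(dtype=float)
    means = vals.mean(axis=0)
    centered = vals - means
    if mode == "correlation":
        scales = centered.std(axis=0, ddof=1)
        centered = centered / scales
    else:
        scales = np.ones(vals.shape[1])
    cov = np.cov(centered, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if not np.any(np.diag(cov) > _VAR_ZERO_TOL):
        raise DegeneratePCAError("all variables have zero variance")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: PC1 positive on the first variable; later components
    # positive on their largest-magnitude loading
    if eigvec[0, 0] < 0:
        eigvec[:, 0] = -eigvec[:, 0]
    for p in range(1, eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, p]))
        if eigvec[lead, p] < 0:
            eigvec[:, p] = -eigvec[:, p]
    return PCA1Result(
        variables=tuple(df.columns),
        loadings=eigvec,
        eigenvalues=eigval,
        variance_fractions=eigval / eigval.sum(),
        mode=mode,
        means=means,
        scales=scales,
    )


def explanatory_correlations(X: Union[ExplanatoryMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlations among the non-constant explanatory
    variables; zero-variance columns are dropped beforehand."""
    df = _as_variable_frame(X)
    if df.shape[0] < 3:
        raise ParameterError(f"need >= 3 items for correlations, got {df.shape[0]}")
    return df.corr(method="pearson")


@dataclass(frozen=True)
class CSEModel:
    """Fitted construct specification equation.

    Coefficients are on the original variable scale; ``U_*`` are expanded
    (k=2) uncertainties combining regression and measurement components.
    """

    variables: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    U_intercept: float
    U_coefficients: np.ndarray
    coef_covariance: np.ndarray
    n_components: int
    fitted: np.ndarray
    U_fitted: np.ndarray
    pearson_r: float
    sigma2: float
    input_U_delta: Optional[np.ndarray]
    k: float = 2.0

    def equation(self, digits: int = 1) -> str:
        """Human-readable CSE with 1-significant-figure uncertainties in
        parentheses, e.g. ``+5(3) +0.7(5)*primacy ...``."""

        def term(value, U):
            mag = int(round(U / 10 ** np.floor(np.log10(U)))) if U > 0 else 0
            ndec = max(0, -int(np.floor(np.log10(U)))) if U > 0 else digits
            return f"{value:+.{ndec}f}({mag})" if U > 0 else f"{value:+.{digits}f}"

        parts = [term(self.intercept, self.U_intercept)]
        for name, b, U in zip(self.variables, self.coefficients, self.U_coefficients):
            parts.append(f"{term(b, U)}*{name}")
        return " ".join(parts)

    def predict(self, X: Union[ExplanatoryMatrix, pd.DataFrame, np.ndarray]) -> np.ndarray:
        df = _as_variable_frame(X)[list(self.variables)]
        return self.intercept + df.to_numpy(dtype=float) @ self.coefficients

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": np.concatenate([[self.intercept], self.coefficients]),
                "U_k2": np.concatenate([[self.U_intercept], self.U_coefficients]),
            },
            index=["intercept", *self.variables],
        )


def fit_cse(
    delta: Sequence[float],
    X: Union[ExplanatoryMatrix, pd.DataFrame, np.ndarray],
    U_delta: Optional[Sequence[float]] = None,
    n_components: Optional[int] = None,
    mode: str = "covariance",
    k: float = 2.0,
) -> CSEModel:
    """Principal component regression of item difficulties on the
    explanatory variables.

    ``U_delta`` are expanded (k=2) measurement uncertainties of the input
    difficulties; they propagate linearly through the regression map and add
    in quadrature to the modelling standard errors.
    """
    df = _as_variable_frame(X)
    y = np.asarray(delta, dtype=float)
    n, K = df.shape
    if y.shape != (n,):
        raise ParameterError(f"delta length {y.size} does not match {n} items")
    if n_components is None:
        n_components = K
    if not 1 <= n_components <= K:
        raise ParameterError(f"n_components must be in 1..{K}, got {n_components}")
    if n <= n_components + 1:
        raise ParameterError(
            f"need more items ({n}) than components + 1 ({n_components + 1})"
        )

    pca = pca_explanatory(df, mode=mode)
    if pca.eigenvalues[n_components - 1] <= _VAR_ZERO_TOL:
        raise DegenerateRegressionError(
            "retained components include a zero-variance direction"
        )
    Xv = df.to_numpy(dtype=float)
    Xc = (Xv - pca.means) / pca.scales
    V = pca.loadings[:, :n_components]
    T = Xc @ V  # component scores
    ybar = y.mean()
    yc = y - ybar

    TtT = T.T @ T
    gamma = np.linalg.solve(TtT, T.T @ yc)
    beta = (V @ gamma) / pca.scales
    intercept = ybar - float(pca.means @ beta)
    fitted = intercept + Xv @ beta
    resid = y - fitted
    dof = n - n_components - 1
    sigma2 = float(resid @ resid / dof)

    # modelling covariance of (intercept, beta): map from gamma-space OLS
    TtT_inv = np.linalg.inv(TtT)
    cov_gamma = sigma2 * TtT_inv
    Vs = V / pca.scales[:, None]
    cov_beta_model = Vs @ cov_gamma @ Vs.T
    # linear map delta -> beta for measurement propagation
    B = Vs @ TtT_inv @ T.T  # K x n
    if U_delta is not None:
        u_meas = np.asarray(U_delta, dtype=float) / k  # standard uncertainties
        cov_beta_meas = B @ np.diag(u_meas**2) @ B.T
        input_U = np.asarray(U_delta, dtype=float)
    else:
        u_meas = np.zeros(n)
        cov_beta_meas = np.zeros((K, K))
        input_U = None
    cov_beta = cov_beta_model + cov_beta_meas

    # intercept row: intercept = mean(y) - means @ beta
    a = np.ones(n) / n - pca.means @ B  # d intercept / d y_i
    var_int_model = sigma2 / n + float(pca.means @ cov_beta_model @ pca.means)
    var_int_meas = float(a @ np.diag(u_meas**2) @ a) if U_delta is not None else 0.0
    var_intercept = var_int_model + var_int_meas

    # full (intercept, beta) covariance for per-item fitted-value uncertainty
    full_cov = np.zeros((K + 1, K + 1))
    full_cov[0, 0] = var_intercept
    full_cov[1:, 1:] = cov_beta
    cross = -cov_beta_model @ pca.means  # cov(beta, intercept), modelling part
    if U_delta is not None:
        cross = cross + B @ np.diag(u_meas**2) @ a
    full_cov[0, 1:] = cross
    full_cov[1:, 0] = cross
    design_rows = np.column_stack([np.ones(n), Xv])
    U_fitted = k * np.sqrt(np.einsum("ij,jk,ik->i", design_rows, full_cov, design_rows))

    r = float(np.corrcoef(y, fitted)[0, 1]) if np.std(fitted) > 0 else np.nan
    return CSEModel(
        variables=tuple(df.columns),
        intercept=intercept,
        coefficients=beta,
        U_intercept=k * float(np.sqrt(var_intercept)),
        U_coefficients=k * np.sqrt(np.diag(cov_beta)),
        coef_covariance=full_cov,
        n_components=n_components,
        fitted=fitted,
        U_fitted=U_fitted,
        pearson_r=r,
        sigma2=sigma2,
        input_U_delta=input_U,
        k=k,
    )


def cse_contributions(model: CSEModel, X: Union[ExplanatoryMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Per-item additive decomposition of the fitted value: intercept plus
    one ``beta_k * X_k`` term per variable; the row sum equals ``z_R``."""
    df = _as_variable_frame(X)[list(model.variables)]
    out = pd.DataFrame({"intercept": np.full(df.shape[0], model.intercept)})
    for name, b in zip(model.variables, model.coefficients):
        out[name] = b * df[name].to_numpy(dtype=float)
    out["z_R"] = out.sum(axis=1)
    return out


def subgroup_cse(
    delta_by_group: Mapping[str, Sequence[float]],
    X: Union[ExplanatoryMatrix, pd.DataFrame],
    U_delta_by_group: Optional[Mapping[str, Sequence[float]]] = None,
    n_components: Optional[int] = None,
    mode: str = "covariance",
) -> dict[str, CSEModel]:
    """Independent CSE fit per cohort subgroup over the same items; use
    ``comparison_table`` on the result for a side-by-side view."""
    models = {}
    for group, d in delta_by_group.items():
        U = U_delta_by_group.get(group) if U_delta_by_group else None
        models[group] = fit_cse(d, X, U_delta=U, n_components=n_components, mode=mode)
    return models


def comparison_table(models: Mapping[str, CSEModel]) -> pd.DataFrame:
    """Side-by-side coefficient table (value and k=2 uncertainty per group)."""
    frames = {}
    for group, m in models.items():
        f = m.to_frame()
        f.columns = pd.MultiIndex.from_product([[group], f.columns])
        frames[group] = f
    return pd.concat(frames.values(), axis=1)
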