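"""Correlation-matrix containers and the standardized multiple-to-multiple fit.

The model is a standardized multivariate linear regression of p responses
(Y block) on m predictors (X block), defined entirely on the joint
correlation matrix

    R = [[Rxx, Rxy],
         [Ryx, Ryy]]

together with the sample size n.  All downstream path decompositions,
decision coefficients and hypothesis tests derive from one
:class:`StandardizedFit`:

* path coefficients ``b_star`` solve the normal equations
  ``Rxx @ b_star = Rxy`` column by column;
* the determination-coefficient matrix ``U = b_star.T @ Rxx @ b_star`` has
  the per-response squared multiple correlations R(alpha)^2 on its diagonal
  and the X-mediated parts of the Y-Y correlations off it;
* ``B = inv(Ryy) @ U`` supplies the generalized determination coefficient
  through its trace, and the likelihood-ratio statistic
  ``v_xy = det(R) / (det(Rxx) * det(Ryy))`` supplies it exactly through
  ``R2_gen = 1 - v_xy``.

Raw data enter only through :func:`correlation_from_data`; everything else
operates on the correlation scale, where the (n-1) sums-of-squares factors
cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import config

__all__ = [
    "CorrelationSystem",
    "StandardizedFit",
    "CorrelationValidationError",
    "NonSquareMatrixError",
    "DiagonalNotOneError",
    "CorrelationOutOfRangeError",
    "AsymmetricMatrixError",
    "NotPositiveDefiniteError",
    "SampleSizeError",
    "ConstantColumnError",
    "MissingDataError",
    "SingularBlockError",
    "build_system",
    "correlation_from_data",
    "fit",
]


class CorrelationValidationError(ValueError):
    """Base class for rejected correlation inputs."""


class NonSquareMatrixError(CorrelationValidationError):
    pass


class DiagonalNotOneError(CorrelationValidationError):
    pass


class CorrelationOutOfRangeError(CorrelationValidationError):
    pass


class AsymmetricMatrixError(CorrelationValidationError):
    pass


class NotPositiveDefiniteError(CorrelationValidationError):
    pass


class SampleSizeError(CorrelationValidationError):
    pass


class ConstantColumnError(CorrelationValidationError):
    pass


class MissingDataError(CorrelationValidationError):
    pass


class SingularBlockError(CorrelationValidationError):
    """A correlation block is too ill-conditioned to invert."""


@dataclass(frozen=True)
class CorrelationSystem:
    """A validated joint correlation matrix partitioned into X and Y blocks.

    Attributes
    ----------
    names_x, names_y
        Identifiers of the m predictors and p responses, in the order of
        the corresponding rows/columns of ``R`` (X block first).
    R
        The (m+p) x (m+p) joint correlation matrix.
    n
        Number of observations behind ``R``; drives every degrees-of-freedom
        computation downstream.
    """

    names_x: tuple[str, ...]
    names_y: tuple[str, ...]
    R: np.ndarray
    n: int

    @property
    def m(self) -> int:
        return len(self.names_x)

    @property
    def p(self) -> int:
        return len(self.names_y)

    @property
    def Rxx(self) -> np.ndarray:
        return self.R[: self.m, : self.m]

    @property
    def Rxy(self) -> np.ndarray:
        return self.R[: self.m, self.m :]

    @property
    def Ryy(self) -> np.ndarray:
        return self.R[self.m :, self.m :]

    def to_frame(self) -> pd.DataFrame:
        names = list(self.names_x) + list(self.names_y)
        return pd.DataFrame(self.R, index=names, columns=names)


@dataclass(frozen=True)
class StandardizedFit:
    """All quantities derived from one standardized multivariate regression.

    ``b_star[:, a]`` holds the path (standardized partial regression)
    coefficients of response ``a``; ``c_diag`` the diagonal of ``inv(Rxx)``
    (the Gauss multipliers c_jj entering every standard error); ``theta``
    is ``inv(Ryy)`` whose entries weight the division of tr(B).
    """

    system: CorrelationSystem
    b_star: np.ndarray
    c_diag: np.ndarray
    theta: np.ndarray
    U: np.ndarray
    B: np.ndarray
    trB: float
    r2_alpha: np.ndarray
    E: np.ndarray
    v_xy: float
    R2_gen: float
    r_xy: float
    residual_paths: np.ndarray
    eigvals_B: np.ndarray = field(repr=False)

    @property
    def R2_exact(self) -> float:
        """The exact generalized determination coefficient 1 - det(I - B).

        tr(B) overestimates this by the sum of eigenvalue cross-products;
        both are reported side by side in every summary.
        """
        return 1.0 - float(np.prod(1.0 - self.eigvals_B))

    @property
    def trB_gap(self) -> float:
        return self.trB - self.R2_exact


def _validate_matrix(R: np.ndarray, names: Sequence[str]) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise NonSquareMatrixError(f"correlation matrix must be square, got shape {R.shape}")
    k = R.shape[0]
    if k != len(names):
        raise NonSquareMatrixError(
            f"matrix dimension {k} does not match {len(names)} variable names"
        )
    bad_diag = np.flatnonzero(np.abs(np.diag(R) - 1.0) > config.DIAG_ATOL)
    if bad_diag.size:
        i = int(bad_diag[0])
        raise DiagonalNotOneError(
            f"diagonal entry for {names[i]!r} is {R[i, i]:.6g}, expected 1"
        )
    off = np.abs(R - np.diag(np.diag(R)))
    if np.any(off > 1.0 + config.DIAG_ATOL):
        i, j = np.unravel_index(int(np.argmax(off)), R.shape)
        raise CorrelationOutOfRangeError(
            f"correlation ({names[i]!r}, {names[j]!r}) = {R[i, j]:.6g} outside [-1, 1]"
        )
    asym = np.max(np.abs(R - R.T))
    if asym > config.SYM_ATOL:
        i, j = np.unravel_index(int(np.argmax(np.abs(R - R.T))), R.shape)
        raise AsymmetricMatrixError(
            f"asymmetry {asym:.3g} at ({names[i]!r}, {names[j]!r}) exceeds "
            f"tolerance {config.SYM_ATOL:g}"
        )
    R = 0.5 * (R + R.T)  # repair asymmetry below tolerance
    np.fill_diagonal(R, 1.0)
    eig = np.linalg.eigvalsh(R)
    if eig[0] <= config.PD_RTOL * eig[-1]:
        raise NotPositiveDefiniteError(
            f"matrix is not positive definite: smallest eigenvalue {eig[0]:.3g} "
            f"vs largest {eig[-1]:.3g}"
        )
    return R


def build_system(
    R_joint: np.ndarray,
    n: int,
    names_x: Sequence[str],
    names_y: Sequence[str],
) -> CorrelationSystem:
    """Validate a joint correlation matrix and partition it into blocks.

    Parameters
    ----------
    R_joint
        (m+p) x (m+p) correlation matrix, X variables first.
    n
        Sample size; must exceed m + 1 so the residual degrees of freedom
        n - m - 1 are at least 1.
    names_x, names_y
        Predictor and response identifiers matching the matrix ordering.

    Raises
    ------
    CorrelationValidationError
        A subclass naming the offending entry: non-square input, diagonal
        entries away from 1, off-diagonals outside [-1, 1], asymmetry above
        tolerance, a non-positive-definite matrix, or n too small.
    """
    names_x = tuple(str(s) for s in names_x)
    names_y = tuple(str(s) for s in names_y)
    if not names_x or not names_y:
        raise CorrelationValidationError("need at least one X and one Y variable")
    overlap = set(names_x) & set(names_y)
    if overlap:
        raise CorrelationValidationError(f"variables listed as both X and Y: {sorted(overlap)}")
    names = names_x + names_y
    R = _validate_matrix(R_joint, names)
    n = int(n)
    m = len(names_x)
    if n <= m + 1:
        raise SampleSizeError(f"n = {n} leaves no residual degrees of freedom (need n > {m + 1})")
    R = R.copy()
    R.flags.writeable = False
    return CorrelationSystem(names_x=names_x, names_y=names_y, R=R, n=n)


def correlation_from_data(
    data: pd.DataFrame | np.ndarray,
    x_columns: Sequence[str],
    y_columns: Sequence[str],
    *,
    dropna: bool = False,
) -> CorrelationSystem:
    """Compute the joint Pearson correlation system from a raw data table.

    Columns are ordered X block first regardless of their order in ``data``.
    Standardization uses the sample mean and the (n-1)-denominator sample
    standard deviation; the Pearson correlation itself is invariant to that
    choice of denominator.

    Missing values are rejected by default; pass ``dropna=True`` for
    complete-case row deletion.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data))
        data.columns = [str(c) for c in data.columns]
    cols = [str(c) for c in x_columns] + [str(c) for c in y_columns]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not found in data: {missing}")
    sub = data[cols].apply(pd.to_numeric, errors="raise")
    if sub.isna().any().any():
        if dropna:
            sub = sub.dropna(axis=0, how="any")
        else:
            bad = sub.columns[sub.isna().any()].tolist()
            raise MissingDataError(
                f"missing values in columns {bad}; pass dropna=True for complete-case analysis"
            )
    n = len(sub)
    if n < 3:
        raise SampleSizeError(f"need at least 3 complete rows, got {n}")
    sd = sub.std(ddof=1)
    const = sd.index[sd == 0.0].tolist()
    if const:
        raise ConstantColumnError(f"zero-variance columns: {const}")
    R = sub.corr(method="pearson").to_numpy()
    return build_system(R, n, list(map(str, x_columns)), list(map(str, y_columns)))


def _slogdet(M: np.ndarray) -> tuple[float, float]:
    sign, logdet = np.linalg.slogdet(M)
    return float(sign), float(logdet)


def fit(system: CorrelationSystem) -> StandardizedFit:
    """Fit the standardized regression and assemble every derived quantity.

    The path coefficients come from a linear solve of the normal equations
    (never an explicit inverse); ``c_diag`` and ``theta`` require the
    inverses of Rxx and Ryy, which are checked for conditioning first.
    Determinants go through sign/log-magnitude factorizations so the
    likelihood-ratio statistic v_xy is stable for large m + p, and v_xy is
    cross-checked against the block identity det(E)/det(Ryy).

    Raises
    ------
    SingularBlockError
        If Rxx or Ryy has a condition number above the configured ceiling.
    """
    Rxx, Rxy, Ryy = system.Rxx, system.Rxy, system.Ryy
    for name, M in (("Rxx", Rxx), ("Ryy", Ryy)):
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > config.MAX_CONDITION:
            raise SingularBlockError(
                f"{name} is numerically singular (condition number {cond:.3g})"
            )
    b_star = np.linalg.solve(Rxx, Rxy)
    c_diag = np.diag(np.linalg.inv(Rxx)).copy()
    theta = np.linalg.inv(Ryy)
    theta = 0.5 * (theta + theta.T)
    U = b_star.T @ Rxy  # equals b*' Rxx b* by the normal equations
    U = 0.5 * (U + U.T)
    B = theta @ U
    trB = float(np.trace(B))
    r2_alpha = np.diag(U).copy()
    E = Ryy - U
    E = 0.5 * (E + E.T)

    sign_R, log_R = _slogdet(system.R)
    sign_xx, log_xx = _slogdet(Rxx)
    sign_yy, log_yy = _slogdet(Ryy)
    v_xy = sign_R * sign_xx * sign_yy * np.exp(log_R - log_xx - log_yy)
    sign_E, log_E = _slogdet(E)
    v_xy_blocks = sign_E * sign_yy * np.exp(log_E - log_yy)
    if abs(v_xy - v_xy_blocks) > config.VXY_ROUTE_ATOL:
        warnings.warn(
            f"determinant routes to v_xy disagree: ratio form {v_xy:.12g} vs "
            f"block form {v_xy_blocks:.12g}",
            RuntimeWarning,
            stacklevel=2,
        )
    v_xy = float(v_xy)
    R2_gen = 1.0 - v_xy
    r_xy = float(np.sqrt(max(R2_gen, 0.0)))
    residual_paths = np.sqrt(np.clip(1.0 - r2_alpha, 0.0, None))
    eigvals_B = np.sort(np.real(np.linalg.eigvals(B)))[::-1]

    out = StandardizedFit(
        system=system,
        b_star=b_star,
        c_diag=c_diag,
        theta=theta,
        U=U,
        B=B,
        trB=trB,
        r2_alpha=r2_alpha,
        E=E,
        v_xy=v_xy,
        R2_gen=float(R2_gen),
        r_xy=r_xy,
        residual_paths=residual_paths,
        eigvals_B=eigvals_B,
    )
    _check_fit(out)
    return out


def _check_fit(f: StandardizedFit) -> None:
    """Internal consistency assertions run on every fit."""
    sys_ = f.system
    resid = np.max(np.abs(sys_.Rxx @ f.b_star - sys_.Rxy))
    if resid > 1e-10:
        raise FloatingPointError(f"normal-equation residual {resid:.3g} exceeds 1e-10")
    if np.any(f.r2_alpha < -1e-12) or np.any(f.r2_alpha >= 1.0):
        raise FloatingPointError(f"per-response R^2 outside [0, 1): {f.r2_alpha}")
    if np.any(f.eigvals_B < -1e-10) or np.any(f.eigvals_B > 1.0 + 1e-10):
        raise FloatingPointError(f"eigenvalues of B outside [0, 1]: {f.eigvals_B}")
    if f.R2_exact > f.trB + 1e-12:
        raise FloatingPointError(
            f"exact generalized R^2 {f.R2_exact:.12g} exceeds tr(B) {f.trB:.12g}"
        )
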