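"""Direct genomic values by GBLUP with heterogeneous residual variances.

Model: y = 1*mu + g + e with Var(g) = sigma_g^2 * G and
Var(e) = sigma_e^2 * diag(w_i).  Records y are deregressed EBV; the
residual weight of individual i is

    w_i = C + (1 - r2_i) / r2_i

with r2_i the EBV reliability and C the fraction of additive variance
not captured by the markers (default 0.25).  G is the VanRaden
(method 1) genomic relationship matrix.  Individuals in G without
records receive DGV through their genomic relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data import MISSING, GenotypeMatrix

__all__ = [
    "PredictionConfig",
    "GRM",
    "deregress",
    "residual_weight",
    "build_grm",
    "fit_gblup",
    "GBLUPResult",
    "reml_variance_ratio",
]


@dataclass(frozen=True)
class PredictionConfig:
    """C: unexplained additive-variance fraction; variance_ratio:
    sigma_e^2 / sigma_g^2; ridge stabilizes G inversion."""

    C: float = 0.25
    variance_ratio: float = 1.0
    ridge: float = 1e-6

    def __post_init__(self):
        if self.C < 0:
            raise ValueError("C must be non-negative")
        if self.variance_ratio <= 0:
            raise ValueError("variance_ratio must be positive")


@dataclass
class GRM:
    """Genomic relationship matrix with the allele frequencies used to centre it."""

    ids: list
    matrix: np.ndarray
    frequencies: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def deregress(ebv, r2):
    """Simple deregression: dEBV = EBV / r2 (r2 in (0, 1]).

    Precomputed deregressed proofs can be passed straight through to
    :func:`fit_gblup`; this helper covers the common case where only EBV
    and reliabilities are available.
    """
    ebv = np.asarray(ebv, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    return ebv / r2


def residual_weight(r2, C: float = 0.25):
    """w = C + (1 - r2) / r2, strictly decreasing in r2; w(1) = C."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    return C + (1.0 - r2) / r2


def build_grm(geno: GenotypeMatrix, frequencies: np.ndarray | None = None) -> GRM:
    """VanRaden method-1 GRM: (M - 2p)(M - 2p)' / (2 * sum p(1-p)).

    Missing dosages are mean-imputed per marker (with a warning).
    Allele frequencies default to those of the supplied individuals.
    """
    d = geno.dosage.astype(float)
    miss = geno.dosage == MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(miss, 0, d).sum(axis=0) / (~miss).sum(axis=0)
    if miss.any():
        warnings.warn(
            f"{int(miss.sum())} missing dosages mean-imputed for the GRM",
            stacklevel=2,
        )
        d = np.where(miss, col_mean[None, :], d)
    p = (
        np.asarray(frequencies, dtype=float)
        if frequencies is not None
        else col_mean / 2.0
    )
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    Z = d - 2.0 * p[None, :]
    return GRM(ids=list(geno.ids), matrix=(Z @ Z.T) / denom, frequencies=p)


@dataclass
class GBLUPResult:
    intercept: float
    dgv: pd.Series
    config: PredictionConfig


def fit_gblup(
    records: pd.DataFrame,
    grm: GRM,
    cfg: PredictionConfig = PredictionConfig(),
    predict_ids=None,
    relationship: np.ndarray | None = None,
) -> GBLUPResult:
    """Solve the weighted mixed model and return DGV.

    `records` needs columns id, debv, weight (weights from
    :func:`residual_weight`).  `relationship` substitutes an arbitrary
    relationship matrix (e.g. the pedigree A-matrix) for the GRM entries
    while keeping the GRM's id order.  All record ids must be rows of
    the relationship matrix; `predict_ids` (default: every id) selects
    the returned DGV.
    """
    ids = grm.ids
    pos = {v: k for k, v in enumerate(ids)}
    missing = [i for i in records["id"] if i not in pos]
    if missing:
        raise ValueError(f"record ids not in GRM: {missing[:5]}")
    G = relationship if relationship is not None else grm.matrix
    q = len(ids)
    ridge = cfg.ridge * max(np.mean(np.diag(G)), 1e-12)
    Greg = G + ridge * np.eye(q)
    try:
        Ginv = linalg.inv(Greg)
    except linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(
            f"relationship matrix singular after ridge (cond={np.linalg.cond(Greg):.3g})"
        ) from err
    y = records["debv"].to_numpy(dtype=float)
    w = records["weight"].to_numpy(dtype=float)
    rows = np.array([pos[i] for i in records["id"]], dtype=np.intp)
    n = len(y)
    Z = np.zeros((n, q))
    Z[np.arange(n), rows] = 1.0
    Rinv = 1.0 / w
    # mixed model equations
    lhs = np.zeros((q + 1, q + 1))
    rhs = np.zeros(q + 1)
    lhs[0, 0] = Rinv.sum()
    ZtR = Z.T * Rinv[None, :]
    lhs[0, 1:] = Rinv @ Z
    lhs[1:, 0] = lhs[0, 1:]
    lhs[1:, 1:] = ZtR @ Z + cfg.variance_ratio * Ginv
    rhs[0] = Rinv @ y
    rhs[1:] = ZtR @ y
    try:
        sol = linalg.solve(lhs, rhs, assume_a="sym")
    except linalg.LinAlgError as err:
        raise ValueError(
            f"singular mixed-model equations (cond={np.linalg.cond(lhs):.3g})"
        ) from err
    dgv = pd.Series(sol[1:], index=ids)
    if predict_ids is not None:
        dgv = dgv.loc[list(predict_ids)]
    return GBLUPResult(intercept=float(sol[0]), dgv=dgv, config=cfg)


def reml_variance_ratio(
    records: pd.DataFrame,
    grm: GRM,
    bounds: tuple = (1e-3, 1e3),
) -> float:
    """Profile-REML estimate of sigma_e^2 / sigma_g^2 on a log grid.

    One-dimensional REML for the model above with homogeneous-scale
    weights already folded into `records['weight']`.  Provided for
    convenience when no external variance components exist; a known
    ratio should be passed to :class:`PredictionConfig` directly.
    """
    pos = {v: k for k, v in enumerate(grm.ids)}
    rows = np.array([pos[i] for i in records["id"]], dtype=np.intp)
    y = records["debv"].to_numpy(dtype=float)
    w = records["weight"].to_numpy(dtype=float)
    Gn = grm.matrix[np.ix_(rows, rows)]
    n = len(y)
    X = np.ones((n, 1))

    def neg_restricted_ll(log_ratio: float) -> float:
        ratio = np.exp(log_ratio)
        V = Gn + ratio * np.diag(w)  # up to sigma_g^2 scale
        try:
            c, low = linalg.cho_factor(V + 1e-8 * np.eye(n))
        except linalg.LinAlgError:
            return np.inf
        Vinv_y = linalg.cho_solve((c, low), y)
        Vinv_X = linalg.cho_solve((c, low), X)
        XtVX = X.T @ Vinv_X
        beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
        resid = y - X @ beta
        Vinv_r = linalg.cho_solve((c, low), resid)
        quad = resid @ Vinv_r
        logdetV = 2.0 * np.log(np.diag(c)).sum()
        sigma2 = quad / (n - 1)
        return 0.5 * (
            logdetV + np.log(np.linalg.det(XtVX)) + (n - 1) * np.log(sigma2) + (n - 1)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=np.log(bounds), method="bounded"
    )
    return float(np.exp(res.x))
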