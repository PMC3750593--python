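"""Imputation and prediction-accuracy metrics.

Mask-and-impute validation, genotype error rates, coding-invariant
imputation accuracies, and the two routes to the accuracy of direct
genomic values: the naive ratio cor(DGV,EBV)/r_val and the regression
correction

    cor(DGV,EBV)_t = a0 + a1 * rVal_t + a2 * rTrain_t + e_t

whose fitted slope a1 removes the contribution of correlated EBV
prediction errors: the corrected per-trait accuracy is
cor(DGV,EBV)_t - a1_hat * (rVal_t - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, MarkerMap

__all__ = [
    "mask_panel",
    "imputation_error_rate",
    "imputation_accuracy",
    "accuracy_eq1",
    "AccuracyFit",
    "fit_accuracy_regression",
    "ErrorReport",
]


def mask_panel(geno: GenotypeMatrix, panel_markers) -> tuple[GenotypeMatrix, np.ndarray]:
    """Set every non-panel marker to MISSING; returns (masked copy, mask).

    The mask is a boolean array over the genotype matrix's marker order,
    True at masked (non-panel) markers.
    """
    panel = set(panel_markers)
    unknown = panel - set(geno.markers)
    if unknown:
        raise ValueError(f"{len(unknown)} panel markers not in the genotype matrix")
    mask = np.array([m not in panel for m in geno.markers])
    out = geno.copy()
    out.dosage[:, mask] = MISSING
    return out, mask


@dataclass
class ErrorReport:
    overall: float
    n_cells: int
    per_marker: pd.Series
    by_position_class: dict = field(default_factory=dict)
    by_chromosome: dict = field(default_factory=dict)


def imputation_error_rate(
    truth: GenotypeMatrix,
    imputed: np.ndarray | GenotypeMatrix,
    mask: np.ndarray,
    mmap: MarkerMap | None = None,
) -> ErrorReport:
    """Proportion of masked genotypes not correctly restored (0/1/2 scale).

    Cells with missing truth are excluded; a missing imputed value at an
    observed truth cell counts as an error.  With a map, rates are also
    broken down by position class (assembly vs approximated) and by
    chromosome.
    """
    T = truth.dosage
    I = imputed.dosage if isinstance(imputed, GenotypeMatrix) else np.asarray(imputed)
    if I.shape != T.shape:
        raise ValueError("truth and imputed shapes differ")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no genotypes to score")
    cells = mask[None, :] & (T != MISSING)
    errors = cells & (I != T)
    n = int(cells.sum())
    if n == 0:
        raise ValueError("no observed truth genotypes under the mask")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_marker = errors.sum(axis=0) / cells.sum(axis=0)
    report = ErrorReport(
        overall=float(errors.sum() / n),
        n_cells=n,
        per_marker=pd.Series(per_marker, index=truth.markers),
    )
    if mmap is not None:
        known = np.array(
            [mmap.position_known[mmap.index(m)] for m in truth.markers]
        )
        chrom = np.array([mmap.chromosome[mmap.index(m)] for m in truth.markers])
        for label, sel in (("known", known), ("estimated", ~known)):
            cc = cells[:, sel]
            if cc.sum():
                report.by_position_class[label] = float(errors[:, sel].sum() / cc.sum())
        for c in pd.unique(chrom):
            sel = chrom == c
            cc = cells[:, sel]
            if cc.sum():
                report.by_chromosome[c] = float(errors[:, sel].sum() / cc.sum())
    return report


def imputation_accuracy(
    truth: GenotypeMatrix,
    imputed: np.ndarray | GenotypeMatrix,
    mask: np.ndarray,
    per: str = "individual",
) -> pd.Series:
    """Squared correlation of true and imputed dosages over masked markers.

    To make the statistic independent of arbitrary allele coding, every
    marker enters twice: once as recorded and once with dosages reflected
    (g -> 2 - g) in both vectors.  Returns one r^2 per individual (or per
    marker with ``per='marker'``); units whose doubled vectors are
    constant are NaN.
    """
    T = truth.dosage
    I = imputed.dosage if isinstance(imputed, GenotypeMatrix) else np.asarray(imputed)
    mask = np.asarray(mask, dtype=bool)
    if per == "individual":
        units = range(truth.n_individuals)
        index = truth.ids
        take = lambda u: (T[u, mask], I[u, mask])
    elif per == "marker":
        cols = np.flatnonzero(mask)
        units = cols
        index = [truth.markers[c] for c in cols]
        take = lambda u: (T[:, u], I[:, u])
    else:
        raise ValueError("per must be 'individual' or 'marker'")
    out = []
    for u in units:
        t, i = take(u)
        ok = (t != MISSING) & (i != MISSING)
        t, i = t[ok].astype(float), i[ok].astype(float)
        if t.size < 2:
            out.append(np.nan)
            continue
        td = np.concatenate([t, 2.0 - t])
        im = np.concatenate([i, 2.0 - i])
        st, si = td.std(), im.std()
        if st == 0.0 or si == 0.0:
            out.append(np.nan)
            continue
        r = ((td - td.mean()) * (im - im.mean())).mean() / (st * si)
        out.append(r * r)
    return pd.Series(out, index=index)


def accuracy_eq1(cor_dgv_ebv: float, r_val: float) -> tuple[float, bool]:
    """Naive DGV accuracy: cor(DGV,EBV) / r_val; flags estimates above 1.

    Valid only when EBV prediction errors are uncorrelated between
    training and validation animals; otherwise biased upward.
    """
    if r_val <= 0:
        raise ValueError("mean validation accuracy must be positive")
    est = cor_dgv_ebv / r_val
    return float(est), bool(abs(est) > 1)


@dataclass
class AccuracyFit:
    """OLS fit of cor(DGV,EBV)_t on EBV accuracies, with corrected accuracies."""

    a0: float
    a1: float
    a2: float | None
    residuals: np.ndarray
    fitted: np.ndarray
    cor_dgv_ebv: np.ndarray
    r_val: np.ndarray
    r_train: np.ndarray | None
    mode: str

    @property
    def cor_dgv_tbv_rand(self) -> float:
        """Expected accuracy for a random trait: value of the regression at r_val = 1."""
        base = self.a0 + self.a1
        if self.a2 is not None and self.r_train is not None:
            base += self.a2 * float(np.mean(self.r_train))
        return float(base)

    def corrected_accuracies(self) -> np.ndarray:
        """Per-trait corrected accuracy: cor(DGV,EBV)_t - a1*(rVal_t - 1)."""
        return self.cor_dgv_ebv - self.a1 * (self.r_val - 1.0)


def fit_accuracy_regression(
    cor_dgv_ebv,
    r_val,
    r_train=None,
    mode: str = "multi",
) -> AccuracyFit:
    """Fit the accuracy regression across traits (or replicates).

    ``mode='multi'`` fits intercept + r_val + r_train (needs >= 4
    traits); ``mode='single'`` drops the training-accuracy term (>= 3
    replicates), for designs where only one trait is available and
    replicates vary the validation accuracy.  Collinear predictors raise
    with diagnostics.
    """
    y = np.asarray(cor_dgv_ebv, dtype=float)
    rv = np.asarray(r_val, dtype=float)
    if mode == "multi":
        if r_train is None:
            raise ValueError("multi-trait mode requires r_train")
        rt = np.asarray(r_train, dtype=float)
        if y.size < 4:
            raise ValueError("multi-trait regression needs at least 4 traits")
        X = np.column_stack([np.ones_like(y), rv, rt])
    elif mode == "single":
        if y.size < 3:
            raise ValueError("single-trait regression needs at least 3 replicates")
        rt = None
        X = np.column_stack([np.ones_like(y), rv])
    else:
        raise ValueError("mode must be 'multi' or 'single'")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sv = np.linalg.svd(X, compute_uv=False)
        raise ValueError(
            f"collinear predictors (rank {rank} < {X.shape[1]}; singular values {sv})"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return AccuracyFit(
        a0=float(beta[0]),
        a1=float(beta[1]),
        a2=float(beta[2]) if mode == "multi" else None,
        residuals=y - fitted,
        fitted=fitted,
        cor_dgv_ebv=y,
        r_val=rv,
        r_train=rt if mode == "multi" else None,
        mode=mode,
    )
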