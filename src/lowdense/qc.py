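"""Marker quality control.

Four filters, applied jointly: call rate, parent-progeny conflict rate,
minor allele frequency, and Hardy-Weinberg equilibrium.  Defaults follow
common chip-QC practice for livestock panels: call rate >= 95%, conflict
rate <= 2%, MAF >= 3%, HWE p >= 1e-4.

The HWE test is a chi-square goodness of fit with 1 df on the observed
genotype counts; the conflict rate is Mendelian incompatibilities (opposite
homozygotes) divided by the number of genotyped parent-offspring pairs
with both calls present at the marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import MISSING, GenotypeMatrix, Pedigree

__all__ = ["QCThresholds", "QCReport", "qc_filter_markers", "hwe_pvalues"]


@dataclass(frozen=True)
class QCThresholds:
    call_rate: float = 0.95
    conflict_rate: float = 0.02
    maf: float = 0.03
    hwe_p: float = 1e-4


@dataclass
class QCReport:
    retained: np.ndarray                  # bool per marker
    removed_by: dict = field(default_factory=dict)   # criterion -> bool array
    conflict_pairs: int = 0

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def counts(self) -> dict:
        out = {k: int(v.sum()) for k, v in self.removed_by.items()}
        out["removed_any"] = int((~self.retained).sum())
        out["retained"] = self.n_retained
        return out

    def retained_markers(self, geno: GenotypeMatrix):
        return [m for m, keep in zip(geno.markers, self.retained) if keep]


def hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) HWE p-values per marker column.

    Monomorphic or all-missing markers get p = 1 (they are handled by the
    MAF filter instead).
    """
    obs = dosage != MISSING
    n0 = ((dosage == 0) & obs).sum(axis=0).astype(float)
    n1 = ((dosage == 1) & obs).sum(axis=0).astype(float)
    n2 = ((dosage == 2) & obs).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    pvals = np.where(np.isfinite(chi2), stats.chi2.sf(np.nan_to_num(chi2), df=1), 1.0)
    pvals[(n == 0) | (p <= 0) | (p >= 1)] = 1.0
    return pvals


def _conflict_rates(geno: GenotypeMatrix, ped: Pedigree):
    """Per-marker Mendelian conflict rates over genotyped parent-offspring pairs."""
    pairs = []
    idx = geno._id_index
    for child in ped.individuals:
        if child not in idx:
            continue
        for parent in ped.parents(child):
            if parent is not None and parent in idx:
                pairs.append((idx[parent], idx[child]))
    if not pairs:
        return None, 0
    p_rows = np.array([p for p, _ in pairs])
    c_rows = np.array([c for _, c in pairs])
    P = geno.dosage[p_rows]
    C = geno.dosage[c_rows]
    valid = (P != MISSING) & (C != MISSING)
    conflict = (((P == 0) & (C == 2)) | ((P == 2) & (C == 0))) & valid
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = conflict.sum(axis=0) / n_valid
    return np.where(n_valid > 0, rate, 0.0), len(pairs)


def qc_filter_markers(
    geno: GenotypeMatrix,
    ped: Pedigree | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Apply the four marker filters; a marker is retained iff it passes all.

    Without a pedigree (or without any genotyped parent-offspring pair)
    the conflict filter is skipped with a warning.
    """
    d = geno.dosage
    n = geno.n_individuals
    call_rate = (d != MISSING).sum(axis=0) / n

    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
    maf = np.where(n_obs > 0, np.minimum(freq1, 1 - freq1), 0.0)

    removed = {
        "call_rate": call_rate < thresholds.call_rate,
        "maf": maf < thresholds.maf,
        "hwe": hwe_pvalues(d) < thresholds.hwe_p,
    }
    n_pairs = 0
    if ped is not None:
        rates, n_pairs = _conflict_rates(geno, ped)
        if rates is None:
            warnings.warn(
                "no genotyped parent-offspring pairs; conflict filter skipped",
                stacklevel=2,
            )
        else:
            removed["conflict"] = rates > thresholds.conflict_rate
    else:
        warnings.warn("no pedigree supplied; conflict filter skipped", stacklevel=2)
    retained = ~np.logical_or.reduce(list(removed.values()))
    return QCReport(retained=retained, removed_by=removed, conflict_pairs=n_pairs)
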