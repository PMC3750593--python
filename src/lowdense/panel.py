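"""Low-density panel design by greedy score x min-distance maximization.

The distance between two markers on the same chromosome blends physical
distance with genotype correlation below a window kappa (default 5 Mb):

    d(m', m'') = lambda*|dloc| + (1-lambda)*kappa*(1 - 0.99*|r|),
    lambda = min(1, |dloc| / kappa)

so nearby markers in weak LD still count as distant and both can enter
the panel.  Markers on different chromosomes are infinitely distant.
Each greedy step adds the candidate maximizing Score_m times its minimum
distance to the markers already selected; chromosomes not yet covered
have infinite minimum distance, so the first pick on every chromosome is
its top-scoring marker.

Scores default to MAF * u, where u = 1 for assembly positions and
u = 0.8 for LD-approximated positions (penalizing uncertain placements);
a uniform score with kappa = 0 and only assembly-placed markers gives
the naive equally-spaced design, which repeatedly picks the centre of
the largest gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, MarkerMap, genotype_correlation

__all__ = ["PanelConfig", "Panel", "marker_distance", "marker_score", "select_panel"]

INFINITE = np.inf


@dataclass(frozen=True)
class PanelConfig:
    """Knobs of the panel-design objective.

    size
        Number of markers to select.
    kappa
        Correlation window in Mb; 0 gives pure physical distance (the
        naive limit).
    corr_discount
        Weight of |r| inside the correlation term (0.99: perfectly
        correlated co-located markers keep a small positive distance).
    score_mode
        'maf_u' (MAF x u), 'uniform' (1), or 'variance'
        (2*MAF*(1-MAF)*mean squared marker effect).
    score_power
        Exponent form Score = MAF**(power*u) instead of MAF*u when set;
        None (default) uses the multiplicative form.
    chrom_length_weight
        Optional lambda_L in ((1-l)*L_m + l*max(L))/L_m, boosting short
        chromosomes; None disables the factor.
    include_estimated_positions
        When False, markers with approximated positions (u = 0.8) are
        not eligible.
    """

    size: int = 384
    kappa: float = 5.0
    corr_discount: float = 0.99
    score_mode: str = "maf_u"
    u_known: float = 1.0
    u_estimated: float = 0.8
    score_power: float | None = None
    chrom_length_weight: float | None = None
    include_estimated_positions: bool = True
    mean_sq_effect: np.ndarray | None = None

    @classmethod
    def naive(cls, size: int) -> "PanelConfig":
        """Equally-spaced design: uniform scores, kappa = 0, assembly positions only."""
        return cls(size=size, kappa=0.0, score_mode="uniform",
                   include_estimated_positions=False)


@dataclass
class Panel:
    """Selected markers with pick order and objective at pick time."""

    table: pd.DataFrame

    @property
    def marker_ids(self):
        return list(self.table["marker_id"])

    def __len__(self) -> int:
        return len(self.table)


def marker_distance(m1: str, m2: str, mmap: MarkerMap, geno: GenotypeMatrix,
                    cfg: PanelConfig = PanelConfig()) -> float:
    """Distance d(m1, m2); INFINITE across chromosomes."""
    i, j = mmap.index(m1), mmap.index(m2)
    placed = mmap.is_placed()
    if not (placed[i] and placed[j]):
        raise ValueError("both markers must be placed on a chromosome")
    if mmap.chromosome[i] != mmap.chromosome[j]:
        return INFINITE
    delta = abs(mmap.position_mb[i] - mmap.position_mb[j])
    if cfg.kappa == 0.0 or delta >= cfg.kappa:
        return float(delta)
    lam = delta / cfg.kappa
    r = genotype_correlation(geno.column(m1), geno.column(m2))
    absr = 0.0 if np.isnan(r) else abs(r)
    return float(lam * delta + (1 - lam) * cfg.kappa * (1 - cfg.corr_discount * absr))


def marker_score(marker: str, maf: np.ndarray, mmap: MarkerMap,
                 cfg: PanelConfig = PanelConfig()) -> float:
    """Score of a single marker under the configured mode."""
    j = mmap.index(marker)
    return float(_score_vector(maf, mmap, cfg)[j])


def _score_vector(maf: np.ndarray, mmap: MarkerMap, cfg: PanelConfig) -> np.ndarray:
    u = np.where(mmap.position_known, cfg.u_known, cfg.u_estimated)
    maf = np.nan_to_num(np.asarray(maf, dtype=float))
    if cfg.score_mode == "uniform":
        score = np.ones(len(mmap))
    elif cfg.score_mode == "maf_u":
        if cfg.score_power is not None:
            with np.errstate(invalid="ignore"):
                score = np.where(maf > 0, maf ** (cfg.score_power * u), 0.0)
        else:
            score = maf * u
    elif cfg.score_mode == "variance":
        a2 = cfg.mean_sq_effect if cfg.mean_sq_effect is not None else np.ones(len(mmap))
        score = 2.0 * maf * (1.0 - maf) * np.asarray(a2, dtype=float)
    else:
        raise ValueError(f"unknown score_mode {cfg.score_mode!r}")
    if cfg.chrom_length_weight is not None:
        lengths = mmap.chrom_lengths()
        if lengths:
            lmax = max(lengths.values())
            lam = cfg.chrom_length_weight
            factor = np.ones(len(mmap))
            for c, L in lengths.items():
                if L > 0:
                    factor[mmap.chromosome == c] = ((1 - lam) * L + lam * lmax) / L
            score = score * factor
    return score


def select_panel(
    candidates,
    geno: GenotypeMatrix,
    mmap: MarkerMap,
    cfg: PanelConfig,
    maf: np.ndarray | None = None,
) -> Panel:
    """Greedy panel selection.

    At every step the candidate maximizing score x min-distance to the
    current panel is added.  Candidates on a chromosome without any
    selected marker have infinite min-distance and outrank every finite
    objective; among them the highest score wins.  All ties break toward
    the lowest marker index.  Per-candidate minimum distances are updated
    incrementally after each pick (identical results to recomputing from
    scratch).
    """
    if maf is None:
        from .data import compute_maf

        maf = compute_maf(geno, recode=False).maf
    placed = mmap.is_placed()
    cand_idx = []
    for m in candidates:
        j = mmap.index(m)
        if not placed[j]:
            raise ValueError(f"candidate {m} is not placed on a chromosome")
        if not cfg.include_estimated_positions and not mmap.position_known[j]:
            continue
        cand_idx.append(j)
    cand_idx = np.array(sorted(set(cand_idx)), dtype=np.intp)
    if cfg.size > cand_idx.size:
        raise ValueError(f"panel size {cfg.size} exceeds {cand_idx.size} candidates")

    scores = _score_vector(maf, mmap, cfg)[cand_idx]
    chrom = mmap.chromosome[cand_idx]
    pos = mmap.position_mb[cand_idx]
    geno_cols = geno.marker_indices([mmap.marker_ids[j] for j in cand_idx])
    min_d = np.full(cand_idx.size, INFINITE)
    active = np.ones(cand_idx.size, dtype=bool)

    rows = []
    for rank in range(cfg.size):
        inf_mask = active & np.isinf(min_d)
        if inf_mask.any():
            # uncovered chromosome: best score wins, ties -> lowest index
            pool = np.flatnonzero(inf_mask)
            pick = pool[np.argmax(scores[pool])]
            objective = INFINITE
        else:
            obj = np.where(active, scores * min_d, -INFINITE)
            pick = int(np.argmax(obj))
            objective = float(obj[pick])
        rows.append(
            (
                rank + 1,
                mmap.marker_ids[cand_idx[pick]],
                chrom[pick],
                float(pos[pick]),
                float(scores[pick]),
                objective,
            )
        )
        active[pick] = False
        # incremental min-distance update against the new panel member
        same = active & (chrom == chrom[pick])
        if same.any():
            sidx = np.flatnonzero(same)
            delta = np.abs(pos[sidx] - pos[pick])
            d = delta.astype(float)
            if cfg.kappa > 0:
                near = delta < cfg.kappa
                if near.any():
                    absr = _abs_corr(geno.dosage[:, geno_cols[pick]],
                                     geno.dosage[:, geno_cols[sidx[near]]])
                    lam = delta[near] / cfg.kappa
                    d[near] = lam * delta[near] + (1 - lam) * cfg.kappa * (
                        1 - cfg.corr_discount * absr
                    )
            np.minimum.at(min_d, sidx, d)
    table = pd.DataFrame(
        rows, columns=["rank", "marker_id", "chrom", "pos_mb", "score", "objective"]
    )
    return Panel(table=table)


def _abs_corr(col: np.ndarray, block: np.ndarray) -> np.ndarray:
    """|corr| of one dosage column against each column of `block` (pairwise complete)."""
    x = col.astype(float)
    if not (col == MISSING).any() and not (block == MISSING).any():
        y = block.astype(float)
        xc = x - x.mean()
        yc = y - y.mean(axis=0)
        sx = np.sqrt((xc * xc).sum())
        sy = np.sqrt((yc * yc).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc) / (sx * sy)
        return np.abs(np.nan_to_num(r))
    out = np.zeros(block.shape[1])
    xm = x == MISSING
    for k in range(block.shape[1]):
        y = block[:, k].astype(float)
        ok = ~xm & (block[:, k] != MISSING)
        if ok.sum() < 2:
            continue
        xs, ys = x[ok], y[ok]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        out[k] = abs(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))
    return out
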