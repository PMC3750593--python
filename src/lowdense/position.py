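"""LD-based approximation of unknown marker positions.

Markers are grouped into equivalence classes through chains of genotype
correlation: two markers belong to the same class when a chain of markers
links them with |r| above a threshold (default 0.4) between adjacent
links, every interior chain member having MAF above a floor (default
0.15).  A class is mapped to a chromosome when more than 95% of its
known-position members agree; an unplaced marker then borrows the known
position of its best-correlated placed partner on that chromosome.

Genotype correlations (dosages 0/1/2) stand in for the haplotype LD
measure r, since haplotypes are unavailable for unplaced markers.
Absolute correlations are used throughout: under minor-allele coding the
sign of LD is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import UNKNOWN_CHROM, GenotypeMatrix, MarkerMap, correlation_matrix

__all__ = [
    "MarkerClassAssignment",
    "build_marker_classes",
    "assign_class_chromosomes",
    "approximate_positions",
]

UNASSIGNED = UNKNOWN_CHROM


@dataclass
class MarkerClassAssignment:
    """Per-marker class id, chromosome call and approximated position."""

    class_id: np.ndarray
    assigned_chromosome: np.ndarray | None = None
    approx_position_mb: np.ndarray | None = None
    remapped: np.ndarray | None = None
    report: pd.DataFrame = field(default_factory=pd.DataFrame)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller root wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_marker_classes(
    geno: GenotypeMatrix,
    maf: np.ndarray,
    r_threshold: float = 0.4,
    maf_min: float = 0.15,
    corr: np.ndarray | None = None,
) -> MarkerClassAssignment:
    """Chain-based marker classes from genotype correlations.

    High-MAF markers (MAF > `maf_min`) may appear anywhere in a chain, so
    their classes are the connected components of the |r| > `r_threshold`
    subgraph restricted to them.  Low-MAF markers may only terminate a
    chain; each joins the class of its strongest admissible neighbour
    (largest |r| above the threshold; ties broken toward the lowest
    marker index), which keeps the assignment single-valued where the
    raw chain relation is ambiguous.

    `corr` accepts a precomputed marker correlation matrix (results are
    identical to computing it here; the hook exists so callers can reuse
    one matrix across operations).
    """
    m = geno.n_markers
    maf = np.asarray(maf, dtype=float)
    if corr is None:
        corr = correlation_matrix(geno.dosage)
    absr = np.abs(np.nan_to_num(corr))
    np.fill_diagonal(absr, 0.0)
    adj = absr > r_threshold
    high = maf > maf_min

    uf = _UnionFind(m)
    hi_idx = np.flatnonzero(high)
    for a in hi_idx:
        for b in np.flatnonzero(adj[a] & high):
            if b > a:
                uf.union(a, b)
    # each low-MAF marker contributes exactly one edge: to its strongest
    # admissible neighbour (may itself be low-MAF)
    for a in np.flatnonzero(~high):
        nbrs = np.flatnonzero(adj[a])
        if nbrs.size == 0:
            continue
        best = nbrs[np.argmax(absr[a, nbrs])]  # argmax takes lowest index on ties
        uf.union(a, best)

    roots = np.array([uf.find(i) for i in range(m)])
    _, class_id = np.unique(roots, return_inverse=True)
    return MarkerClassAssignment(class_id=class_id)


def assign_class_chromosomes(
    classes: MarkerClassAssignment,
    mmap: MarkerMap,
    majority: float = 0.95,
) -> MarkerClassAssignment:
    """Map each class to a chromosome by strict known-member majority.

    A class is assigned to chromosome c iff strictly more than `majority`
    of its members with known positions lie on c; otherwise (including
    classes with no known-position member) it stays unassigned.
    """
    cid = classes.class_id
    known = mmap.position_known & (mmap.chromosome != UNKNOWN_CHROM)
    chrom = mmap.chromosome
    assigned = np.full(len(cid), UNASSIGNED, dtype=object)
    for c in np.unique(cid):
        members = np.flatnonzero(cid == c)
        km = members[known[members]]
        if km.size == 0:
            continue
        labels, counts = np.unique(chrom[km], return_counts=True)
        top = np.argmax(counts)
        if counts[top] / km.size > majority:
            assigned[members] = labels[top]
    classes.assigned_chromosome = assigned
    return classes


def approximate_positions(
    classes: MarkerClassAssignment,
    mmap: MarkerMap,
    geno: GenotypeMatrix,
    corr: np.ndarray | None = None,
    estimated_u: bool = True,
) -> tuple[MarkerMap, MarkerClassAssignment]:
    """Give unplaced markers the position of their best-correlated partner.

    Every marker that needs a position on its class chromosome — either
    its position is unknown, or its mapped chromosome disagrees with the
    class call (it is then *remapped*) — receives the known position of
    the known-position marker on that chromosome maximizing |r| with it.
    Approximated and remapped positions are flagged ``position_known =
    False`` (panel-score weight u = 0.8) unless `estimated_u` is False,
    in which case remapped markers keep full weight.

    Markers in unassigned classes, and markers whose target chromosome
    has no known-position marker, remain unplaced (reported).
    """
    if classes.assigned_chromosome is None:
        raise ValueError("run assign_class_chromosomes first")
    if corr is None:
        corr = correlation_matrix(geno.dosage)
    absr = np.abs(np.nan_to_num(corr))
    np.fill_diagonal(absr, 0.0)

    out = mmap.copy()
    chrom = out.table["chromosome"].to_numpy(dtype=object)
    pos = out.table["position_mb"].to_numpy(dtype=float)
    known = out.table["position_known"].to_numpy(dtype=bool) & (chrom != UNKNOWN_CHROM)
    orig_pos = pos.copy()  # donor lookup uses original build positions
    assigned = classes.assigned_chromosome
    remapped = np.zeros(len(chrom), dtype=bool)
    approx = np.full(len(chrom), np.nan)
    rows = []
    # candidate donors: markers with an original known position, per chromosome
    donors = {
        c: np.flatnonzero(known & (chrom == c))
        for c in pd.unique(assigned[assigned != UNASSIGNED])
    }
    for j in range(len(chrom)):
        target = assigned[j]
        if target == UNASSIGNED:
            if not known[j]:
                rows.append((out.marker_ids[j], "unassigned_class"))
            continue
        needs = (not known[j]) or chrom[j] != target
        if not needs:
            continue
        cand = donors.get(target, np.empty(0, dtype=int))
        cand = cand[cand != j]
        if cand.size == 0:
            rows.append((out.marker_ids[j], "no_known_marker_on_chromosome"))
            continue
        best = cand[np.argmax(absr[j, cand])]
        if known[j]:
            remapped[j] = True
        chrom[j] = target
        pos[j] = orig_pos[best]
        approx[j] = orig_pos[best]
        out.table.loc[j, "position_known"] = bool(remapped[j] and not estimated_u)
    out.table["chromosome"] = chrom
    out.table["position_mb"] = pos
    classes.approx_position_mb = approx
    classes.remapped = remapped
    classes.report = pd.DataFrame(rows, columns=["marker_id", "reason"])
    return out, classes
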