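"""Core containers for low-density genomic selection.

Dosage genotypes, marker maps, phased haplotype libraries, pedigrees and
trait records.  All downstream modules (position approximation, panel
design, imputation, GBLUP) operate on these types.

Conventions
-----------
* Genotypes are allele-1 dosages in {0, 1, 2}; ``MISSING`` (-1) marks a
  failed call.  After :func:`compute_maf` with ``recode=True`` allele 1 is
  the minor allele, so per-marker allele-1 frequency is at most 0.5.
* Positions are megabases (floats).  Markers without a physical position
  carry chromosome :data:`UNKNOWN_CHROM` and position NaN.
* Pedigree parent codes: the string ``"0"`` (or ``None``) means unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
UNKNOWN_CHROM: str = "UN"

__all__ = [
    "MISSING",
    "UNKNOWN_CHROM",
    "GenotypeMatrix",
    "MarkerMap",
    "HaplotypeLibrary",
    "Pedigree",
    "TraitRecords",
    "MafResult",
    "compute_maf",
    "genotype_correlation",
    "correlation_matrix",
]


class GenotypeMatrix:
    """Individuals x markers dosage matrix with id bookkeeping.

    Parameters
    ----------
    ids : sequence of str
        Individual identifiers, one per row.
    markers : sequence of str
        Marker identifiers, one per column.
    dosage : ndarray of int8, shape (n_individuals, n_markers)
        Allele-1 dosages; ``MISSING`` for no-calls.
    """

    def __init__(self, ids, markers, dosage):
        self.ids = list(ids)
        self.markers = list(markers)
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"({len(self.ids)}, {len(self.markers)})"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        self.dosage = dosage
        self._id_index = {v: k for k, v in enumerate(self.ids)}
        self._marker_index = {v: k for k, v in enumerate(self.markers)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, individual: str) -> np.ndarray:
        return self.dosage[self._id_index[individual]]

    def column(self, marker: str) -> np.ndarray:
        return self.dosage[:, self._marker_index[marker]]

    def id_indices(self, ids) -> np.ndarray:
        return np.array([self._id_index[i] for i in ids], dtype=np.intp)

    def marker_indices(self, markers) -> np.ndarray:
        return np.array([self._marker_index[m] for m in markers], dtype=np.intp)

    def subset(self, ids=None, markers=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals / markers."""
        rows = self.id_indices(ids) if ids is not None else np.arange(self.n_individuals)
        cols = (
            self.marker_indices(markers)
            if markers is not None
            else np.arange(self.n_markers)
        )
        return GenotypeMatrix(
            [self.ids[r] for r in rows],
            [self.markers[c] for c in cols],
            self.dosage[np.ix_(rows, cols)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.markers, self.dosage.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_markers} markers)"


class MarkerMap:
    """Physical marker map: chromosome, position (Mb) and position status.

    ``position_known`` distinguishes markers whose position comes from the
    genome assembly (weight u = 1 in panel scores) from markers whose
    position was approximated from LD (u = 0.8).  Markers not yet placed
    carry chromosome ``UNKNOWN_CHROM`` and NaN position.
    """

    def __init__(self, marker_ids, chromosome, position_mb, position_known):
        n = len(marker_ids)
        self.table = pd.DataFrame(
            {
                "marker_id": list(marker_ids),
                "chromosome": list(chromosome),
                "position_mb": np.asarray(position_mb, dtype=float),
                "position_known": np.asarray(position_known, dtype=bool),
            }
        )
        if self.table["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        placed = self.table["chromosome"] != UNKNOWN_CHROM
        pos = self.table.loc[placed, "position_mb"]
        if (pos < 0).any() or pos.isna().any():
            raise ValueError("placed markers must have non-negative positions")
        self._index = {m: i for i, m in enumerate(self.table["marker_id"])}
        if n != len(self._index):
            raise ValueError("duplicate marker ids in map")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerMap":
        return cls(
            frame["marker_id"],
            frame["chromosome"],
            frame["position_mb"],
            frame["position_known"],
        )

    @property
    def marker_ids(self):
        return list(self.table["marker_id"])

    @property
    def chromosome(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def position_mb(self) -> np.ndarray:
        return self.table["position_mb"].to_numpy()

    @property
    def position_known(self) -> np.ndarray:
        return self.table["position_known"].to_numpy()

    def index(self, marker: str) -> int:
        return self._index[marker]

    def is_placed(self) -> np.ndarray:
        return (self.chromosome != UNKNOWN_CHROM) & ~np.isnan(self.position_mb)

    def chromosomes(self):
        """Placed chromosome labels in order of first appearance."""
        seen = []
        for c in self.chromosome:
            if c != UNKNOWN_CHROM and c not in seen:
                seen.append(c)
        return seen

    def chrom_order(self, chrom: str) -> np.ndarray:
        """Indices of markers on `chrom` sorted by position (stable)."""
        idx = np.flatnonzero(self.chromosome == chrom)
        return idx[np.argsort(self.position_mb[idx], kind="stable")]

    def chrom_lengths(self) -> dict:
        return {
            c: float(np.nanmax(self.position_mb[self.chromosome == c]))
            for c in self.chromosomes()
        }

    def copy(self) -> "MarkerMap":
        return MarkerMap.from_frame(self.table.copy())

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover
        placed = int(self.is_placed().sum())
        return f"MarkerMap({len(self)} markers, {placed} placed)"


class HaplotypeLibrary:
    """Phased paternal/maternal allele vectors for HD-genotyped individuals.

    Alleles are {0, 1}; ``MISSING`` is allowed for unphased positions.
    The paternal haplotype is index 0, maternal index 1, matching the
    origin codes used in sire-allele tracing.
    """

    def __init__(self, markers):
        self.markers = list(markers)
        self._haps: dict[str, np.ndarray] = {}

    def add(self, individual: str, paternal, maternal) -> None:
        pat = np.asarray(paternal, dtype=np.int8)
        mat = np.asarray(maternal, dtype=np.int8)
        if pat.shape != (len(self.markers),) or mat.shape != (len(self.markers),):
            raise ValueError(f"haplotype length mismatch for {individual}")
        self._haps[individual] = np.stack([pat, mat])

    def __contains__(self, individual: str) -> bool:
        return individual in self._haps

    def __len__(self) -> int:
        return len(self._haps)

    @property
    def individuals(self):
        return list(self._haps)

    def paternal(self, individual: str) -> np.ndarray:
        return self._haps[individual][0]

    def maternal(self, individual: str) -> np.ndarray:
        return self._haps[individual][1]

    def pair(self, individual: str) -> np.ndarray:
        """(2, n_markers) array: row 0 paternal, row 1 maternal."""
        return self._haps[individual]

    def dosage(self, individual: str) -> np.ndarray:
        h = self._haps[individual]
        out = h[0].astype(np.int8) + h[1]
        out[(h[0] == MISSING) | (h[1] == MISSING)] = MISSING
        return out

    def subset_markers(self, marker_indices) -> "HaplotypeLibrary":
        idx = np.asarray(marker_indices, dtype=np.intp)
        lib = HaplotypeLibrary([self.markers[i] for i in idx])
        for ind, h in self._haps.items():
            lib.add(ind, h[0][idx], h[1][idx])
        return lib


class Pedigree:
    """Acyclic sire/dam pedigree with tabular-method relationship queries.

    Records are (individual, sire, dam); unknown parents are ``None``.
    A topological order with parents before offspring is computed at
    construction; a cycle raises ``ValueError``.
    """

    def __init__(self, records):
        self.sire: dict[str, str | None] = {}
        self.dam: dict[str, str | None] = {}
        for ind, s, d in records:
            ind = str(ind)
            if ind in self.sire:
                raise ValueError(f"duplicate pedigree entry for {ind}")
            self.sire[ind] = None if s in (None, "0", 0, "") else str(s)
            self.dam[ind] = None if d in (None, "0", 0, "") else str(d)
        # parents mentioned but without a record are founders
        for parent in list(self.sire.values()) + list(self.dam.values()):
            if parent is not None and parent not in self.sire:
                self.sire[parent] = None
                self.dam[parent] = None
        self.order = self._topological_order()
        self._rank = {ind: i for i, ind in enumerate(self.order)}

    def _topological_order(self):
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(node: str) -> None:
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    state[n] = 2
                    order.append(n)
                    continue
                if state.get(n) == 1:
                    raise ValueError(f"pedigree cycle involving {n}")
                if state.get(n) == 2:
                    continue
                state[n] = 1
                stack.append((n, True))
                for p in (self.sire[n], self.dam[n]):
                    if p is not None and state.get(p) != 2:
                        if state.get(p) == 1:
                            raise ValueError(f"pedigree cycle involving {p}")
                        stack.append((p, False))

        for ind in self.sire:
            if state.get(ind) != 2:
                visit(ind)
        return order

    def __contains__(self, ind: str) -> bool:
        return ind in self.sire

    def __len__(self) -> int:
        return len(self.sire)

    @property
    def individuals(self):
        return list(self.order)

    def parents(self, ind: str):
        return self.sire[ind], self.dam[ind]

    def founders(self):
        return [i for i in self.order if self.sire[i] is None and self.dam[i] is None]

    def _ancestor_closure(self, ids) -> list:
        seen: set[str] = set()
        stack = [i for i in ids if i in self.sire]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            for p in (self.sire[n], self.dam[n]):
                if p is not None and p not in seen:
                    stack.append(p)
        return sorted(seen, key=self._rank.__getitem__)

    def a_matrix(self, ids=None) -> pd.DataFrame:
        """Numerator relationship matrix by the tabular method.

        The matrix is built over the ancestor closure of `ids` (all
        individuals if omitted) and returned restricted to `ids`, in their
        given order.  Diagonals are 1 + F (inbreeding coefficient).
        """
        if ids is None:
            ids = self.order
        closure = self._ancestor_closure(ids)
        pos = {ind: i for i, ind in enumerate(closure)}
        n = len(closure)
        A = np.zeros((n, n))
        for i, ind in enumerate(closure):
            s, d = self.sire[ind], self.dam[ind]
            si = pos.get(s) if s is not None else None
            di = pos.get(d) if d is not None else None
            for j in range(i):
                a = 0.0
                if si is not None:
                    a += 0.5 * A[si, j]
                if di is not None:
                    a += 0.5 * A[di, j]
                A[i, j] = A[j, i] = a
            A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        rows = []
        for ind in ids:
            if ind in pos:
                rows.append(pos[ind])
            else:
                raise KeyError(f"{ind} not in pedigree")
        sub = A[np.ix_(rows, rows)]
        return pd.DataFrame(sub, index=list(ids), columns=list(ids))

    def relationship(self, i: str, j: str) -> float:
        """Additive genetic relationship a_ij (tabular method).

        Unknown individuals are unrelated to everything: returns 0 with a
        warning rather than raising, since haplotype-library members may
        legitimately be absent from the pedigree.
        """
        missing = [x for x in (i, j) if x not in self.sire]
        if missing:
            warnings.warn(
                f"individual(s) {missing} not in pedigree; relationship set to 0",
                stacklevel=2,
            )
            return 0.0
        A = self.a_matrix([i, j] if i != j else [i])
        return float(A.loc[i, j])

    def relationship_matrix(self, rows, cols) -> np.ndarray:
        """a_ij for every (row, col) pair; ids absent from the pedigree get 0."""
        known = [x for x in dict.fromkeys(list(rows) + list(cols)) if x in self.sire]
        out = np.zeros((len(rows), len(cols)))
        if not known:
            return out
        A = self.a_matrix(known)
        for r, i in enumerate(rows):
            if i not in self.sire:
                continue
            for c, j in enumerate(cols):
                if j in self.sire:
                    out[r, c] = A.loc[i, j]
        return out


@dataclass
class TraitRecords:
    """Per-(individual, trait) EBV with reliability, optionally deregressed.

    ``table`` columns: id, trait, ebv, reliability, and optionally debv.
    Reliabilities are r^2 of the conventional BLUP EBV, in (0, 1].
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        required = {"id", "trait", "ebv", "reliability"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"trait table requires columns {sorted(required)}")
        rel = self.table["reliability"]
        if (rel < 0).any() or (rel > 1).any():
            raise ValueError("reliabilities must lie in [0, 1]")

    @property
    def traits(self):
        return list(pd.unique(self.table["trait"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == trait]
        zero = sub["reliability"] <= 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-reliability records excluded for trait {trait}",
                stacklevel=2,
            )
            sub = sub[~zero]
        return sub.reset_index(drop=True)


@dataclass
class MafResult:
    """Output of :func:`compute_maf`.

    maf
        Minor allele frequency per marker; NaN where every call is missing.
    flipped
        True where allele 1 was the major allele and the dosages were
        recoded (dosage -> 2 - dosage).
    undefined
        True for all-missing markers.
    """

    maf: np.ndarray
    flipped: np.ndarray
    undefined: np.ndarray


def compute_maf(geno: GenotypeMatrix, recode: bool = True) -> MafResult:
    """Allele-1 frequencies with optional recoding to the minor allele.

    Missing dosages are excluded marker-wise.  With ``recode=True`` (the
    default) markers where allele 1 is the major allele are flipped in
    place so that dosage counts the minor allele; applying the function a
    second time is then a no-op.
    """
    d = geno.dosage
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
    undefined = n_obs == 0
    freq1 = np.where(undefined, np.nan, freq1)
    flipped = freq1 > 0.5
    if recode and flipped.any():
        cols = np.flatnonzero(flipped)
        block = d[:, cols]
        block = np.where(block == MISSING, MISSING, 2 - block).astype(np.int8)
        d[:, cols] = block
    maf = np.where(flipped, 1.0 - freq1, freq1)
    return MafResult(maf=maf, flipped=flipped, undefined=undefined)


def genotype_correlation(g1, g2) -> float:
    """Pearson correlation of two dosage vectors, pairwise complete.

    Returns NaN when fewer than two individuals are jointly observed or
    either vector is constant on the shared subset (callers treat NaN
    as "no linkage signal", i.e. correlation 0).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x = g1[ok].astype(float)
    y = g2[ok].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def correlation_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between all marker columns.

    With no missing data this reduces to ``np.corrcoef`` of the columns.
    Undefined entries (constant columns on the shared subset, < 2 shared
    observations) are NaN.  Memory is O(m^2); intended for marker counts
    up to a few thousand.
    """
    d = np.asarray(dosage, dtype=float)
    miss = d == MISSING
    if not miss.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(d, rowvar=False)
        return np.asarray(r)
    obs = (~miss).astype(float)
    x = np.where(miss, 0.0, d)
    n = obs.T @ obs                      # shared observation counts
    sx = x.T @ obs                       # sum of x over shared support
    sy = sx.T
    sxy = x.T @ x
    sxx = (x * x).T @ obs
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[n < 2] = np.nan
    return r
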