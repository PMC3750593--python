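"""Pedigree-aware imputation from low- to high-density genotypes.

The algorithm targets offspring genotyped with a low-density panel whose
sires are phased at high density while dams are not genotyped at all.

Per offspring and chromosome:

1. *Origin tracing.*  At every panel marker where the offspring is
   homozygous and the sire heterozygous, the sire haplotype that
   transmitted the paternal allele is identified with certainty
   (``Which`` = 0 paternal, 1 maternal, -1 undetermined).
2. *Origin extension.*  Runs of equal origin fill the gap between them;
   where the origin switches, the crossover is placed at the midpoint of
   the bracketing interval.  Beyond the outermost determined markers the
   nearest origin extends to the chromosome end.
3. *Paternal imputation.*  High-density paternal alleles are copied from
   the indicated sire haplotype; chromosomes with no determined origin
   fall back to the sire haplotype with fewest conflicts against the
   observed panel genotypes.
4. *Maternal derivation.*  At panel markers the maternal allele is
   dosage minus paternal allele where that is a valid allele.
5. *Library imputation.*  Remaining maternal alleles come from a phased
   haplotype library.  For a focal panel marker m, library haplotype h is
   scored against the partial maternal haplotype i as

       Score_{i,m}(h) = (1 + a_{i,h}) * sum_k c(k) * 0.75**k,   k = 0..4

   where c(k) counts panel markers m~ with exactly k conflicting markers
   between m and m~, and a_{i,h} is the pedigree relationship between the
   offspring's dam and the haplotype carrier; the winner is copied over
   the largest window around m free of conflicts with i.

All steps are deterministic; ties break toward larger relationship, then
lower individual id, then the paternal haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, GenotypeMatrix, HaplotypeLibrary, MarkerMap, Pedigree

__all__ = [
    "OriginVector",
    "ConflictProfile",
    "ImputedIndividual",
    "determine_origins",
    "extend_origins",
    "impute_paternal",
    "derive_partial_maternal",
    "conflict_counts",
    "score_haplotype",
    "impute_maternal",
    "impute_individual",
    "impute_population",
    "GenomeLayout",
]

# provenance codes per allele
PROV_OBSERVED = 0
PROV_ORIGIN = 1
PROV_LIBRARY = 2
PROV_FALLBACK = 3
PROV_CODES = {PROV_OBSERVED: "OBS", PROV_ORIGIN: "PAT",
              PROV_LIBRARY: "LIB", PROV_FALLBACK: "FBK"}

DECAY = 0.75
MAX_K = 4


@dataclass
class OriginVector:
    """Sire-haplotype origin per marker: 0 paternal, 1 maternal, -1 unknown."""

    which: np.ndarray
    mendelian_conflicts: np.ndarray | None = None   # bool mask over the same markers


@dataclass
class ConflictProfile:
    """Counts c(0..4) of markers at each conflict depth around a focal marker."""

    counts: np.ndarray
    focal: int
    haplotype: str | None = None


@dataclass
class ImputedIndividual:
    """Imputed phased genotype with per-allele provenance."""

    individual: str
    paternal: np.ndarray
    maternal: np.ndarray
    provenance_paternal: np.ndarray
    provenance_maternal: np.ndarray
    mendelian_conflicts: int = 0
    derivation_conflicts: int = 0

    @property
    def dosage(self) -> np.ndarray:
        d = self.paternal.astype(np.int8) + self.maternal
        d[(self.paternal == MISSING) | (self.maternal == MISSING)] = MISSING
        return d

    def provenance_codes(self) -> np.ndarray:
        """Worst-provenance code per marker (for VCF FORMAT/PV output)."""
        worst = np.maximum(self.provenance_paternal, self.provenance_maternal)
        return np.array([PROV_CODES[int(w)] for w in worst], dtype=object)


class GenomeLayout:
    """Per-chromosome index structure over the HD marker universe.

    `markers` fixes the HD order (typically the haplotype library's);
    positions and chromosomes come from the map.  Panel markers must be a
    subset of the HD markers.
    """

    def __init__(self, markers, mmap: MarkerMap, panel_markers):
        self.markers = list(markers)
        pos = {m: mmap.position_mb[mmap.index(m)] for m in self.markers}
        chrom = {m: mmap.chromosome[mmap.index(m)] for m in self.markers}
        panel = set(panel_markers)
        unknown = panel - set(self.markers)
        if unknown:
            raise ValueError(f"{len(unknown)} panel markers not in the HD marker set")
        self.chromosomes = []
        self.hd_idx: dict[str, np.ndarray] = {}
        self.hd_pos: dict[str, np.ndarray] = {}
        self.panel_local: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list] = {}
        for g, m in enumerate(self.markers):
            by_chrom.setdefault(chrom[m], []).append(g)
        for c, idxs in by_chrom.items():
            idxs = np.array(idxs, dtype=np.intp)
            order = np.argsort([pos[self.markers[g]] for g in idxs], kind="stable")
            idxs = idxs[order]
            self.chromosomes.append(c)
            self.hd_idx[c] = idxs
            self.hd_pos[c] = np.array([pos[self.markers[g]] for g in idxs])
            self.panel_local[c] = np.flatnonzero(
                [self.markers[g] in panel for g in idxs]
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def determine_origins(
    offspring_ld: np.ndarray,
    sire_paternal: np.ndarray,
    sire_maternal: np.ndarray,
) -> OriginVector:
    """Trace the sire haplotype of origin at each panel marker.

    Arrays are aligned over panel markers.  The origin is certain only
    when the offspring is homozygous and the sire heterozygous; an
    offspring homozygous for an allele the sire lacks is a Mendelian
    conflict (origin stays undetermined, conflict flagged).  Markers with
    a missing offspring or sire call are skipped.
    """
    d = np.asarray(offspring_ld)
    p = np.asarray(sire_paternal)
    m = np.asarray(sire_maternal)
    which = np.full(d.shape, -1, dtype=np.int8)
    usable = (d != MISSING) & (p != MISSING) & (m != MISSING)
    het = usable & (p != m)
    hom0 = usable & (d == 0)
    hom2 = usable & (d == 2)
    which[het & hom0 & (p == 0)] = 0
    which[het & hom0 & (m == 0)] = 1
    which[het & hom2 & (p == 1)] = 0
    which[het & hom2 & (m == 1)] = 1
    conflict = (hom0 & (p == 1) & (m == 1)) | (hom2 & (p == 0) & (m == 0))
    return OriginVector(which=which, mendelian_conflicts=conflict)


def extend_origins(
    origins: OriginVector,
    panel_pos: np.ndarray,
    hd_pos: np.ndarray,
) -> np.ndarray:
    """Extend panel-marker origins to every HD marker on the chromosome.

    Between equal determined origins the whole gap takes that origin;
    between different origins the crossover sits at the interval
    midpoint (positions below the midpoint take the left origin, at or
    above it the right one).  Outside the determined range the nearest
    origin extends to the chromosome end.  Returns -1 everywhere when no
    origin is determined.
    """
    which = origins.which
    hd = np.full(hd_pos.shape, -1, dtype=np.int8)
    det = np.flatnonzero(which >= 0)
    if det.size == 0:
        return hd
    bounds = [-np.inf]
    values = [which[det[0]]]
    for a, b in zip(det[:-1], det[1:]):
        if which[a] != which[b]:
            bounds.append(0.5 * (panel_pos[a] + panel_pos[b]))
            values.append(which[b])
    # segment s covers positions in [bounds[s], bounds[s+1])
    seg = np.searchsorted(np.array(bounds[1:]), hd_pos, side="right")
    hd[:] = np.array(values, dtype=np.int8)[seg]
    return hd


def impute_paternal(
    hd_origins: np.ndarray,
    sire_paternal: np.ndarray,
    sire_maternal: np.ndarray,
    offspring_ld: np.ndarray | None = None,
    panel_local: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Copy HD paternal alleles from the sire haplotype of origin.

    A chromosome with no determined origin falls back to the sire
    haplotype with fewer conflicts against the offspring's observed
    panel genotypes (ties to the paternal haplotype).  Returns the
    allele vector and per-marker provenance codes.
    """
    n = hd_origins.shape[0]
    prov = np.full(n, PROV_ORIGIN, dtype=np.int8)
    if (hd_origins >= 0).any():
        pat = np.where(hd_origins == 0, sire_paternal, sire_maternal).astype(np.int8)
        return pat, prov
    prov[:] = PROV_FALLBACK
    if offspring_ld is None or panel_local is None or panel_local.size == 0:
        return sire_paternal.astype(np.int8).copy(), prov
    d = offspring_ld[panel_local]
    conflicts = []
    for hap in (sire_paternal, sire_maternal):
        h = hap[panel_local]
        c = (((d == 0) & (h == 1)) | ((d == 2) & (h == 0))).sum()
        conflicts.append(int(c))
    chosen = sire_paternal if conflicts[0] <= conflicts[1] else sire_maternal
    return chosen.astype(np.int8).copy(), prov


def derive_partial_maternal(
    offspring_ld: np.ndarray,
    paternal: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Maternal allele = dosage - paternal allele, where that is 0 or 1.

    Arrays aligned over panel markers.  Infeasible differences (and
    missing calls) yield MISSING; infeasible ones are flagged as
    derivation conflicts.
    """
    d = np.asarray(offspring_ld)
    p = np.asarray(paternal)
    ok = (d != MISSING) & (p != MISSING)
    diff = d - p
    valid = ok & ((diff == 0) | (diff == 1))
    mat = np.where(valid, diff, MISSING).astype(np.int8)
    conflict = ok & ~valid
    return mat, conflict


def conflict_counts(
    h: np.ndarray,
    i: np.ndarray,
    focal: int,
    interval: str = "open",
) -> ConflictProfile:
    """Conflict-depth profile c(0..4) of haplotype h against partial haplotype i.

    Arrays are aligned over the panel markers of one chromosome, in
    position order.  A conflict is a marker where i is known and h
    differs.  Every other panel marker m~ contributes to c(k) when
    exactly k <= 4 conflicting markers lie between `focal` and m~ —
    endpoints excluded for ``interval='open'``; with ``'half-open'`` a
    conflict at m~ itself also counts.
    """
    x = _conflicts(h, i)
    row = _depth_row(x, focal, interval)
    counts = np.zeros(MAX_K + 1, dtype=int)
    for k in range(MAX_K + 1):
        counts[k] = int(((row == k) & _offdiag(len(x), focal)).sum())
    return ConflictProfile(counts=counts, focal=focal)


def _depth_row(x: np.ndarray, focal: int, interval: str) -> np.ndarray:
    """Conflict depth between `focal` and every panel marker (self = 0)."""
    if interval not in ("open", "half-open"):
        raise ValueError(f"unknown interval convention {interval!r}")
    t = np.cumsum(x) - x
    jj = np.arange(len(x))
    k = np.where(
        jj > focal,
        t - t[focal] - x[focal],
        np.where(jj < focal, t[focal] - t - x, 0),
    )
    if interval == "half-open":
        k = k + np.where(jj != focal, x, 0)
    return k


def _offdiag(n: int, focal: int) -> np.ndarray:
    m = np.ones(n, dtype=bool)
    m[focal] = False
    return m


def score_haplotype(profile: ConflictProfile, a_ih: float) -> float:
    """(1 + a) * sum_k c(k) * 0.75**k."""
    k = np.arange(MAX_K + 1)
    return float((1.0 + a_ih) * (profile.counts * DECAY ** k).sum())


def _conflicts(h: np.ndarray, i: np.ndarray) -> np.ndarray:
    return ((i != MISSING) & (h != MISSING) & (h != i)).astype(np.int64)


def _score_all(X: np.ndarray, a: np.ndarray, interval: str) -> np.ndarray:
    """Score matrix S[h, m] = (1 + a_h) * sum_k c_h,m(k) 0.75^k, vectorized.

    X is the (n_hap, n_panel) conflict indicator.  The depth between
    focal m and target m~ counts conflicts strictly between them
    ('half-open' additionally counts a conflict at m~ itself); each m~
    with depth <= 4 contributes 0.75**depth.  Depths follow from running
    conflict counts: with t_j = conflicts before index j, the open-depth
    between m < m~ is t[m~] - t[m] - x[m].
    """
    if interval not in ("open", "half-open"):
        raise ValueError(f"unknown interval convention {interval!r}")
    H, P = X.shape
    S = np.zeros((H, P))
    jj = np.arange(P)
    upper = jj[None, :] > jj[:, None]
    lower = upper.T
    off = upper | lower
    half = interval == "half-open"
    weights = DECAY ** np.arange(MAX_K + 1)
    for hidx in range(H):
        x = X[hidx]
        t = np.cumsum(x) - x          # conflicts strictly before each index
        T = t[None, :] - t[:, None]   # t[m~] - t[m]
        k = np.where(upper, T - x[:, None], -T - x[None, :])
        if half:
            k = k + x[None, :]
        w = np.where((k <= MAX_K) & off, weights[np.minimum(k, MAX_K)], 0.0)
        S[hidx] = w.sum(axis=1)
    return (1.0 + a)[:, None] * S


def impute_maternal(
    partial: np.ndarray,
    hap_alleles: np.ndarray,
    hap_labels,
    relationships: np.ndarray,
    panel_local: np.ndarray,
    interval: str = "open",
) -> tuple[np.ndarray, np.ndarray, list]:
    """Fill a chromosome's maternal haplotype from the library.

    Parameters
    ----------
    partial : (n_hd,) int8
        Maternal alleles known so far (MISSING elsewhere), HD order.
    hap_alleles : (n_hap, n_hd) int8
        Library haplotypes over the same HD markers.
    hap_labels : list of (individual, which)
        Identity of each library haplotype row ('pat'/'mat').
    relationships : (n_hap,) float
        Dam-carrier additive relationship per haplotype row.
    panel_local : indices of panel markers within the HD order.

    Panel markers are processed in position order; at each, the
    highest-scoring haplotype (ties: larger relationship, lower id,
    paternal first) is copied over the largest surrounding window free
    of conflicts with the known maternal alleles, writing only
    still-missing positions.  Residual gaps are filled from the globally
    best-scoring haplotype and flagged as fallback.
    """
    n_hd = partial.shape[0]
    mat = partial.astype(np.int8).copy()
    prov = np.where(mat != MISSING, PROV_OBSERVED, MISSING).astype(np.int8)
    if hap_alleles.shape[0] == 0:
        raise ValueError("empty haplotype library")
    priority = sorted(
        range(len(hap_labels)),
        key=lambda r: (-relationships[r], hap_labels[r][0], hap_labels[r][1] != "pat"),
    )
    if panel_local.size == 0:
        best = priority[0]
        fill = mat == MISSING
        mat[fill] = hap_alleles[best][fill]
        prov[fill] = PROV_FALLBACK
        return mat, prov, []
    i_panel = partial[panel_local]
    X = _conflicts_matrix(hap_alleles[:, panel_local], i_panel)
    S = _score_all(X, relationships, interval)
    chosen = []
    order = np.array(priority)
    for m in range(panel_local.size):
        if not (mat == MISSING).any():
            break
        h = order[int(np.argmax(S[order, m]))]
        chosen.append((m, hap_labels[h]))
        xs = np.flatnonzero(X[h])
        left = xs[xs < m]
        right = xs[xs > m]
        lo = panel_local[left[-1]] + 1 if left.size else 0
        hi = panel_local[right[0]] if right.size else n_hd
        window = np.arange(lo, hi)
        fill = window[mat[window] == MISSING]
        mat[fill] = hap_alleles[h][fill]
        prov[fill] = PROV_LIBRARY
    gap = mat == MISSING
    if gap.any():
        flat = int(np.argmax(S[order].max(axis=1)))
        h = order[flat]
        mat[gap] = hap_alleles[h][gap]
        prov[gap] = PROV_FALLBACK
    return mat, prov, chosen


def _conflicts_matrix(hap_panel: np.ndarray, i_panel: np.ndarray) -> np.ndarray:
    known = i_panel != MISSING
    return (
        known[None, :] & (hap_panel != MISSING) & (hap_panel != i_panel[None, :])
    ).astype(np.int64)


class Imputer:
    """Reusable imputation engine for one panel + library + pedigree."""

    def __init__(
        self,
        library: HaplotypeLibrary,
        mmap: MarkerMap,
        panel_markers,
        ped: Pedigree | None = None,
        interval: str = "open",
    ):
        self.library = library
        self.layout = GenomeLayout(library.markers, mmap, panel_markers)
        self.ped = ped
        self.interval = interval
        self.lib_ids = library.individuals
        self._hap_labels = []
        rows = []
        for ind in self.lib_ids:
            rows.append(library.paternal(ind))
            self._hap_labels.append((ind, "pat"))
            rows.append(library.maternal(ind))
            self._hap_labels.append((ind, "mat"))
        self._haps = np.vstack(rows) if rows else np.zeros((0, len(library.markers)), np.int8)
        self._rel_cache: dict[str | None, np.ndarray] = {}

    def _relationships(self, dam_id: str | None) -> np.ndarray:
        if dam_id not in self._rel_cache:
            if dam_id is None or self.ped is None:
                rel = np.zeros(len(self.lib_ids))
            else:
                rel = self.ped.relationship_matrix([dam_id], self.lib_ids)[0]
            self._rel_cache[dam_id] = np.repeat(rel, 2)
        return self._rel_cache[dam_id]

    def impute(
        self,
        individual: str,
        offspring_ld: np.ndarray,
        sire_id: str,
        dam_id: str | None = None,
    ) -> ImputedIndividual:
        """Impute one offspring; `offspring_ld` is aligned to the HD markers
        (library order) with MISSING at masked/uncalled positions."""
        if sire_id not in self.library:
            raise ValueError(f"sire {sire_id} not in the haplotype library")
        lay = self.layout
        n = lay.n_markers
        if dam_id is None and self.ped is not None and individual in self.ped:
            dam_id = self.ped.dam[individual]
        rel = self._relationships(dam_id)
        sire = self.library.pair(sire_id)
        pat = np.full(n, MISSING, dtype=np.int8)
        mat = np.full(n, MISSING, dtype=np.int8)
        ppat = np.full(n, PROV_FALLBACK, dtype=np.int8)
        pmat = np.full(n, PROV_FALLBACK, dtype=np.int8)
        mend = 0
        deriv = 0
        n_calls = 0
        for c in lay.chromosomes:
            hd = lay.hd_idx[c]
            plocal = lay.panel_local[c]
            d_hd = offspring_ld[hd]
            d_panel = d_hd[plocal]
            n_calls += int((d_panel != MISSING).sum())
            origins = determine_origins(d_panel, sire[0][hd][plocal], sire[1][hd][plocal])
            mend += int(origins.mendelian_conflicts.sum())
            # neutralize Mendelian-conflicted markers: drop their calls
            d_panel = d_panel.copy()
            d_panel[origins.mendelian_conflicts] = MISSING
            hd_orig = extend_origins(origins, lay.hd_pos[c][plocal], lay.hd_pos[c])
            pat_c, prov_c = impute_paternal(
                hd_orig, sire[0][hd], sire[1][hd], d_hd, plocal
            )
            mat_panel, conflict = derive_partial_maternal(d_panel, pat_c[plocal])
            deriv += int(conflict.sum())
            partial = np.full(hd.shape, MISSING, dtype=np.int8)
            partial[plocal] = mat_panel
            mat_c, pmat_c, _ = impute_maternal(
                partial,
                self._haps[:, hd],
                self._hap_labels,
                rel,
                plocal,
                self.interval,
            )
            pat[hd] = pat_c
            ppat[hd] = prov_c
            mat[hd] = mat_c
            pmat[hd] = pmat_c
        if n_calls == 0:
            warnings.warn(
                f"offspring {individual} has no called panel genotypes; "
                "output is all fallback",
                stacklevel=2,
            )
        return ImputedIndividual(
            individual=individual,
            paternal=pat,
            maternal=mat,
            provenance_paternal=ppat,
            provenance_maternal=pmat,
            mendelian_conflicts=mend,
            derivation_conflicts=deriv,
        )


def impute_individual(
    offspring_ld: np.ndarray,
    sire_id: str,
    library: HaplotypeLibrary,
    panel_markers,
    mmap: MarkerMap,
    ped: Pedigree | None = None,
    dam_id: str | None = None,
    individual: str = "offspring",
    interval: str = "open",
) -> ImputedIndividual:
    """One-shot convenience wrapper around :class:`Imputer`."""
    imp = Imputer(library, mmap, panel_markers, ped, interval)
    return imp.impute(individual, offspring_ld, sire_id, dam_id)


def impute_population(
    ld_geno: GenotypeMatrix,
    sire_of: dict,
    library: HaplotypeLibrary,
    panel_markers,
    mmap: MarkerMap,
    ped: Pedigree | None = None,
    interval: str = "open",
) -> dict:
    """Impute every individual of `ld_geno`; returns id -> ImputedIndividual.

    `ld_geno` must cover the library's HD marker set (masked positions
    MISSING); `sire_of` maps each offspring to its HD-genotyped sire.
    """
    imp = Imputer(library, mmap, panel_markers, ped, interval)
    cols = ld_geno.marker_indices(library.markers)
    out = {}
    for ind in ld_geno.ids:
        vec = ld_geno.row(ind)[cols]
        out[ind] = imp.impute(ind, vec, sire_of[ind])
    return out
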