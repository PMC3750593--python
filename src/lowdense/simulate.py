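"""Synthetic sire-line populations for testing and validation.

The generator mirrors the data structure the imputation method assumes:
high-density genotyped sires and maternal grandsires, ungenotyped dams,
and low-density genotyped selection candidates whose sire is always HD.

Founders are drawn in linkage equilibrium at configurable minor allele
frequencies; LD builds up through a burn-in of random-mating generations
in a small population (drift LD, the dominant source in livestock).
Meiosis follows a Haldane map: Poisson crossover counts at 1 cM/Mb with
uniform positions and no interference.  Breeding values are sums of
random-normal QTL effects; EBV are a shrinkage construction
EBV = r^2*TBV + r*sqrt(1-r^2)*e calibrated so cor(EBV, TBV) = r, with an
optional family error component shared between a sire and his offspring
to emulate the correlated prediction errors of a joint pedigree
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    GenotypeMatrix,
    HaplotypeLibrary,
    MarkerMap,
    Pedigree,
    TraitRecords,
)

__all__ = [
    "SimConfig",
    "SimPopulation",
    "simulate_founders",
    "drop_gamete",
    "simulate_population",
    "simulate_traits_and_ebv",
]


@dataclass(frozen=True)
class SimConfig:
    """Population and trait-simulation settings.

    Genome: `n_chromosomes` x `markers_per_chrom` equally spaced markers
    on `chrom_length_mb` Mb chromosomes at `cm_per_mb` recombination.
    Structure: `n_founders` burn-in animals mated at random for
    `burnin_generations`; then `n_sires` sires x `dams_per_sire` dams x
    `offspring_per_dam` offspring, each dam sired by one of
    `n_grandsires` HD maternal grandsires.  Traits: `n_qtl` random
    markers per trait; per-trait EBV reliabilities spread over
    `reliability_val` / `reliability_train`; `family_error_share` of the
    EBV error variance is shared within a sire family when
    `family_error` is on.
    """

    n_chromosomes: int = 2
    markers_per_chrom: int = 1000
    chrom_length_mb: float = 100.0
    cm_per_mb: float = 1.0
    maf_range: tuple = (0.1, 0.5)
    n_founders: int = 80
    burnin_generations: int = 20
    n_sires: int = 50
    n_grandsires: int = 50
    dams_per_sire: int = 2
    offspring_per_dam: int = 2
    n_traits: int = 1
    n_qtl: int = 100
    reliability_val: tuple = (0.25, 0.85)
    reliability_train: tuple = (0.36, 0.81)
    family_error: bool = False
    family_error_share: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "markers_per_chrom", "n_founders",
                     "n_sires", "n_grandsires", "dams_per_sire",
                     "offspring_per_dam", "n_traits", "n_qtl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.reliability_val, self.reliability_train):
            if not (0 < lo <= hi <= 1):
                raise ValueError("reliability ranges must lie in (0, 1]")


def _marker_map(cfg: SimConfig) -> MarkerMap:
    ids, chroms, pos = [], [], []
    for c in range(cfg.n_chromosomes):
        label = f"chr{c + 1}"
        step = cfg.chrom_length_mb / cfg.markers_per_chrom
        for j in range(cfg.markers_per_chrom):
            ids.append(f"{label}_m{j + 1}")
            chroms.append(label)
            pos.append((j + 0.5) * step)
    return MarkerMap(ids, chroms, pos, [True] * len(ids))


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Founder haplotypes in linkage equilibrium.

    Returns (haplotypes, map): haplotypes has shape
    (2 * n_founders, n_markers) with alleles drawn independently per
    marker at a frequency uniform on `maf_range`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mmap = _marker_map(cfg)
    m = len(mmap)
    freq = rng.uniform(*cfg.maf_range, size=m)
    haps = (rng.random((2 * cfg.n_founders, m)) < freq[None, :]).astype(np.int8)
    return haps, mmap


def drop_gamete(
    paternal: np.ndarray,
    maternal: np.ndarray,
    mmap: MarkerMap,
    rng: np.random.Generator,
    cm_per_mb: float = 1.0,
) -> np.ndarray:
    """One meiosis under the Haldane model (Poisson crossovers, no interference)."""
    out = np.empty_like(paternal)
    for c in mmap.chromosomes():
        idx = mmap.chrom_order(c)
        pos = mmap.position_mb[idx]
        length = float(pos[-1]) if len(pos) else 0.0
        morgans = length * cm_per_mb / 100.0
        ncx = rng.poisson(morgans)
        start = int(rng.integers(2))
        if ncx == 0:
            src = paternal if start == 0 else maternal
            out[idx] = src[idx]
            continue
        cx = np.sort(rng.uniform(0.0, length, size=ncx))
        strand = (np.searchsorted(cx, pos, side="right") + start) % 2
        out[idx] = np.where(strand == 0, paternal[idx], maternal[idx])
    return out


@dataclass
class SimPopulation:
    """Simulated sire-line population with truth haplotypes retained."""

    config: SimConfig
    mmap: MarkerMap
    pedigree: Pedigree
    roles: dict                     # role -> list of ids
    sire_of: dict
    dam_of: dict
    truth: HaplotypeLibrary         # every study individual, truth phase
    geno: GenotypeMatrix            # truth dosages for all study individuals

    def library(self, include_grandsires: bool = True) -> HaplotypeLibrary:
        """HD haplotype library: sires, plus maternal grandsires when requested."""
        ids = list(self.roles["sires"])
        if include_grandsires:
            ids += list(self.roles["grandsires"])
        lib = HaplotypeLibrary(self.truth.markers)
        for ind in ids:
            lib.add(ind, self.truth.paternal(ind), self.truth.maternal(ind))
        return lib

    def offspring_genotypes(self) -> GenotypeMatrix:
        return self.geno.subset(ids=self.roles["offspring"])


def simulate_population(cfg: SimConfig) -> SimPopulation:
    """Burn-in, then breed the three-generation study structure.

    Grandsires and sires are sampled from the post-burn-in pool; each
    dam is bred from a grandsire and a random pool dam (recorded unknown
    in the pedigree); offspring come from sire x dam matings.  Every
    offspring therefore has an HD sire and an HD maternal grandsire,
    while its dam is ungenotyped.
    """
    rng = np.random.default_rng(cfg.seed)
    haps, mmap = simulate_founders(cfg, rng)
    n = cfg.n_founders
    pool = haps.reshape(n, 2, -1)
    for _ in range(cfg.burnin_generations):
        nxt = np.empty_like(pool)
        for k in range(n):
            p1, p2 = rng.choice(n, size=2, replace=False)
            nxt[k, 0] = drop_gamete(pool[p1, 0], pool[p1, 1], mmap, rng, cfg.cm_per_mb)
            nxt[k, 1] = drop_gamete(pool[p2, 0], pool[p2, 1], mmap, rng, cfg.cm_per_mb)
        pool = nxt

    def pool_gamete(k: int) -> np.ndarray:
        return drop_gamete(pool[k, 0], pool[k, 1], mmap, rng, cfg.cm_per_mb)

    need = cfg.n_sires + cfg.n_grandsires
    picks = rng.choice(n, size=min(need, n), replace=False)
    if need > n:  # small pools: sample extra parents with replacement
        picks = np.concatenate([picks, rng.choice(n, size=need - n, replace=True)])
    sire_pool = picks[: cfg.n_sires]
    gs_pool = picks[cfg.n_sires:]

    truth = HaplotypeLibrary(mmap.marker_ids)
    ped_rows = []
    sires, grandsires, dams, offspring = [], [], [], []
    sire_of, dam_of = {}, {}
    for s, k in enumerate(sire_pool):
        sid = f"S{s + 1}"
        sires.append(sid)
        truth.add(sid, pool[k, 0].copy(), pool[k, 1].copy())
        ped_rows.append((sid, "0", "0"))
    gs_haps = {}
    for g, k in enumerate(gs_pool):
        gid = f"G{g + 1}"
        grandsires.append(gid)
        gs_haps[gid] = k
        truth.add(gid, pool[k, 0].copy(), pool[k, 1].copy())
        ped_rows.append((gid, "0", "0"))

    n_dams = cfg.n_sires * cfg.dams_per_sire
    for d in range(n_dams):
        did = f"D{d + 1}"
        gid = grandsires[d % cfg.n_grandsires]
        k = gs_haps[gid]
        pat = pool_gamete(k)                      # gamete from the grandsire
        kd = int(rng.integers(n))
        mat = pool_gamete(kd)                     # gamete from an unrecorded pool dam
        dams.append(did)
        truth.add(did, pat, mat)
        ped_rows.append((did, gid, "0"))

    o = 0
    for s, sid in enumerate(sires):
        for dd in range(cfg.dams_per_sire):
            did = dams[s * cfg.dams_per_sire + dd]
            for _ in range(cfg.offspring_per_dam):
                o += 1
                oid = f"O{o}"
                pat = drop_gamete(
                    truth.paternal(sid), truth.maternal(sid), mmap, rng, cfg.cm_per_mb
                )
                mat = drop_gamete(
                    truth.paternal(did), truth.maternal(did), mmap, rng, cfg.cm_per_mb
                )
                offspring.append(oid)
                truth.add(oid, pat, mat)
                ped_rows.append((oid, sid, did))
                sire_of[oid] = sid
                dam_of[oid] = did

    ids = sires + grandsires + dams + offspring
    dosage = np.vstack([truth.dosage(i) for i in ids])
    geno = GenotypeMatrix(ids, mmap.marker_ids, dosage)
    return SimPopulation(
        config=cfg,
        mmap=mmap,
        pedigree=Pedigree(ped_rows),
        roles={
            "sires": sires,
            "grandsires": grandsires,
            "dams": dams,
            "offspring": offspring,
        },
        sire_of=sire_of,
        dam_of=dam_of,
        truth=truth,
        geno=geno,
    )


def simulate_traits_and_ebv(
    pop: SimPopulation,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate TBV and reliability-calibrated EBV for every study individual.

    Returns (tbv, records): `tbv` is a DataFrame individuals x traits
    with unit-variance true breeding values; `records` is a
    :class:`TraitRecords` holding EBV and reliabilities for training
    (sires + grandsires) and validation (offspring) individuals.  The
    per-trait reliabilities are spread evenly over the configured
    validation range; training reliabilities are shuffled relative to
    them so the two are not collinear across traits.
    """
    if cfg is None:
        cfg = pop.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ids = pop.geno.ids
    d = pop.geno.dosage.astype(float)
    m = d.shape[1]
    tbv = {}
    for t in range(cfg.n_traits):
        qtl = rng.choice(m, size=min(cfg.n_qtl, m), replace=False)
        eff = rng.normal(size=qtl.size)
        g = d[:, qtl] @ eff
        sd = g.std()
        tbv[f"trait{t + 1}"] = (g - g.mean()) / (sd if sd > 0 else 1.0)
    tbv = pd.DataFrame(tbv, index=ids)

    def spread(rng_pair, k):
        lo, hi = rng_pair
        return np.full(k, 0.5 * (lo + hi)) if k == 1 else np.linspace(lo, hi, k)

    r2_val = spread(cfg.reliability_val, cfg.n_traits)
    r2_train = spread(cfg.reliability_train, cfg.n_traits)
    rng.shuffle(r2_train)

    training = pop.roles["sires"] + pop.roles["grandsires"]
    validation = pop.roles["offspring"]
    rows = []
    for t, trait in enumerate(tbv.columns):
        fam = {s: rng.normal() for s in pop.roles["sires"]}
        fam_gs = {g: rng.normal() for g in pop.roles["grandsires"]}
        rho = cfg.family_error_share if cfg.family_error else 0.0
        for group, r2 in ((training, r2_train[t]), (validation, r2_val[t])):
            r = np.sqrt(r2)
            for ind in group:
                if ind in fam:
                    shared = fam[ind]
                elif ind in fam_gs:
                    shared = fam_gs[ind]
                else:
                    shared = fam[pop.sire_of[ind]]
                e = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal()
                ebv = r2 * tbv.loc[ind, trait] + r * np.sqrt(1 - r2) * e
                rows.append((ind, trait, ebv, r2))
    records = TraitRecords(
        pd.DataFrame(rows, columns=["id", "trait", "ebv", "reliability"])
    )
    return tbv, records
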