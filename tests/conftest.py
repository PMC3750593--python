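import numpy as np
import pytest

from lowdense.data import GenotypeMatrix, HaplotypeLibrary, MarkerMap, Pedigree
from lowdense.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """Small sire-line population shared across tests (seeded)."""
    cfg = SimConfig(
        n_sires=8,
        n_grandsires=8,
        dams_per_sire=2,
        offspring_per_dam=2,
        markers_per_chrom=150,
        n_chromosomes=2,
        n_founders=40,
        burnin_generations=30,
        seed=123,
    )
    return simulate_population(cfg)


@pytest.fixture()
def toy_exact():
    """Fully informative single-chromosome family: sire heterozygous at
    every marker, offspring homozygous at all panel markers, the dam's
    transmitted haplotype carried by her sire in the library, no
    crossovers.  Imputation must recover the truth exactly."""
    M = 40
    mk = [f"m{j}" for j in range(M)]
    mmap = MarkerMap(mk, ["chr1"] * M, np.linspace(0.5, 39.5, M), [True] * M)
    rng = np.random.default_rng(4)
    sire_pat = np.zeros(M, np.int8)
    sire_mat = np.ones(M, np.int8)
    dam_hap = np.zeros(M, np.int8)
    dam_hap[1::2] = rng.integers(0, 2, M // 2)
    panel = [mk[j] for j in range(0, M, 2)]
    truth_pat = sire_pat.copy()
    truth_mat = dam_hap.copy()
    lib = HaplotypeLibrary(mk)
    lib.add("S", sire_pat, sire_mat)
    decoy = dam_hap.copy()
    decoy[1::2] = 1 - decoy[1::2]
    lib.add("GS", dam_hap, decoy)
    lib.add("U", decoy, decoy)
    ped = Pedigree([("D", "GS", "0"), ("O", "S", "D")])
    geno = GenotypeMatrix(["O"], mk, (truth_pat + truth_mat)[None, :])
    return {
        "markers": mk,
        "map": mmap,
        "panel": panel,
        "library": lib,
        "pedigree": ped,
        "truth": geno,
        "truth_pat": truth_pat,
        "truth_mat": truth_mat,
    }
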