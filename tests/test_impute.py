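"""Origin tracing, crossover midpoints, haplotype scoring and imputation."""

import numpy as np
import pytest

from lowdense.data import (
    MISSING,
    GenotypeMatrix,
    HaplotypeLibrary,
    MarkerMap,
    Pedigree,
)
from lowdense.impute import (
    ConflictProfile,
    OriginVector,
    conflict_counts,
    derive_partial_maternal,
    determine_origins,
    extend_origins,
    impute_individual,
    impute_maternal,
    impute_paternal,
    impute_population,
    score_haplotype,
    _conflicts_matrix,
    _score_all,
)
from lowdense.metrics import imputation_error_rate, mask_panel


class TestDetermineOrigins:
    def test_homozygous_offspring_het_sire(self):
        ov = determine_origins(np.array([0]), np.array([0]), np.array([1]))
        assert ov.which[0] == 0
        ov = determine_origins(np.array([0]), np.array([1]), np.array([0]))
        assert ov.which[0] == 1

    def test_het_offspring_ambiguous(self):
        ov = determine_origins(np.array([1]), np.array([0]), np.array([1]))
        assert ov.which[0] == -1 and not ov.mendelian_conflicts[0]

    def test_full_enumeration(self):
        """All 3 x 4 offspring-dosage x sire-phase configurations."""
        for d in (0, 1, 2):
            for sp in (0, 1):
                for sm in (0, 1):
                    ov = determine_origins(
                        np.array([d]), np.array([sp]), np.array([sm])
                    )
                    if d == 1 or sp == sm:
                        assert ov.which[0] == -1
                        expect_conflict = (d == 0 and sp == sm == 1) or (
                            d == 2 and sp == sm == 0
                        )
                        assert bool(ov.mendelian_conflicts[0]) == expect_conflict
                    else:
                        allele = d // 2
                        assert ov.which[0] == (0 if sp == allele else 1)
                        assert not ov.mendelian_conflicts[0]

    def test_missing_skipped(self):
        ov = determine_origins(
            np.array([MISSING, 0]), np.array([0, MISSING]), np.array([1, 1])
        )
        assert list(ov.which) == [-1, -1]


class TestExtendOrigins:
    def _ext(self, which, ppos, hpos):
        return extend_origins(
            OriginVector(which=np.asarray(which, np.int8)),
            np.asarray(ppos, float),
            np.asarray(hpos, float),
        )

    def test_equal_flanks_fill_interior(self):
        hd = self._ext([0, 0], [10, 20], [5, 12, 15, 18, 25])
        assert list(hd) == [0] * 5

    def test_midpoint_switch(self):
        hd = self._ext([0, 1], [10, 20], [5, 14.9, 15.0, 20, 25])
        assert list(hd) == [0, 0, 1, 1, 1]

    def test_single_marker_extends_whole_chromosome(self):
        hd = self._ext([-1, 1, -1], [10, 20, 30], [1, 15, 40])
        assert list(hd) == [1, 1, 1]

    def test_none_determined(self):
        hd = self._ext([-1, -1], [10, 20], [5, 15])
        assert list(hd) == [-1, -1]

    def test_never_alters_determined(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            P = int(rng.integers(2, 12))
            which = rng.choice([-1, 0, 1], P).astype(np.int8)
            ppos = np.sort(rng.uniform(0, 100, P))
            hd = self._ext(which, ppos, ppos)
            det = which >= 0
            assert np.array_equal(hd[det], which[det])


class TestImputePaternal:
    def test_uniform_origin_copies_haplotype(self):
        pat = np.array([0, 1, 0, 1], np.int8)
        mat = np.array([1, 0, 1, 0], np.int8)
        out, prov = impute_paternal(np.zeros(4, np.int8), pat, mat)
        assert np.array_equal(out, pat)

    def test_midpoint_crossover_splice(self):
        pat = np.array([0, 0, 0, 0], np.int8)
        mat = np.array([1, 1, 1, 1], np.int8)
        origins = np.array([0, 0, 1, 1], np.int8)
        out, _ = impute_paternal(origins, pat, mat)
        assert list(out) == [0, 0, 1, 1]

    def test_fallback_fewest_conflicts(self):
        pat = np.array([1, 1, 1, 1], np.int8)
        mat = np.array([0, 0, 0, 1], np.int8)
        d = np.array([0, 0, 0, 2], np.int8)       # conflicts: pat 3, mat 0
        out, prov = impute_paternal(
            np.full(4, -1, np.int8), pat, mat, d, np.arange(4)
        )
        assert np.array_equal(out, mat)
        # exhaustive conflict count confirms
        for hap, expected in ((pat, 3), (mat, 0)):
            c = sum(
                (dd == 0 and hh == 1) or (dd == 2 and hh == 0)
                for dd, hh in zip(d, hap)
            )
            assert c == expected

    def test_fallback_tie_prefers_paternal(self):
        pat = np.array([0, 1], np.int8)
        mat = np.array([1, 0], np.int8)
        d = np.array([1, 1], np.int8)             # no conflicts either way
        out, _ = impute_paternal(np.full(2, -1, np.int8), pat, mat, d, np.arange(2))
        assert np.array_equal(out, pat)


class TestDeriveMaternal:
    @pytest.mark.parametrize(
        "d,p,expected,conflict",
        [
            (2, 1, 1, False),
            (1, 0, 1, False),
            (1, 1, 0, False),
            (0, 0, 0, False),
            (0, 1, MISSING, True),
            (2, 0, MISSING, True),
            (MISSING, 1, MISSING, False),
        ],
    )
    def test_arithmetic(self, d, p, expected, conflict):
        mat, conf = derive_partial_maternal(np.array([d]), np.array([p]))
        assert mat[0] == expected
        assert bool(conf[0]) == conflict


def _brute_profile(h, i, focal, interval):
    x = [(ii != MISSING) and (hh != ii) for hh, ii in zip(h, i)]
    c = np.zeros(5, dtype=int)
    for mt in range(len(h)):
        if mt == focal:
            continue
        lo, hi = sorted([focal, mt])
        k = sum(x[lo + 1: hi]) + (x[mt] if interval == "half-open" else 0)
        if k <= 4:
            c[k] += 1
    return c


class TestConflictCounts:
    def test_conflict_free_haplotype(self):
        P = 11
        h = np.zeros(P, np.int8)
        i = np.zeros(P, np.int8)
        prof = conflict_counts(h, i, 4)
        assert prof.counts[0] == P - 1
        assert prof.counts[1:].sum() == 0

    @pytest.mark.parametrize("interval", ["open", "half-open"])
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed, interval):
        rng = np.random.default_rng(seed)
        P = int(rng.integers(3, 30))
        h = rng.integers(0, 2, P).astype(np.int8)
        i = rng.choice([MISSING, 0, 1], P).astype(np.int8)
        focal = int(rng.integers(P))
        prof = conflict_counts(h, i, focal, interval)
        assert np.array_equal(prof.counts, _brute_profile(h, i, focal, interval))

    def test_adjacent_conflict_shifts_depth(self):
        P = 23
        h = np.zeros(P, np.int8)
        i = np.zeros(P, np.int8)
        h[11] = 1                  # single conflict next to focal 10
        prof = conflict_counts(h, i, 10)
        brute = _brute_profile(h, i, 10, "open")
        assert np.array_equal(prof.counts, brute)
        # markers beyond the conflict are at depth 1
        assert prof.counts[1] == P - 12

    def test_score_matrix_matches_scalar_path(self):
        rng = np.random.default_rng(3)
        P, H = 17, 6
        i = rng.choice([MISSING, 0, 1], P).astype(np.int8)
        haps = rng.integers(0, 2, (H, P)).astype(np.int8)
        a = rng.uniform(0, 0.5, H)
        X = _conflicts_matrix(haps, i)
        for interval in ("open", "half-open"):
            S = _score_all(X, a, interval)
            for hh in range(H):
                for m in range(P):
                    prof = conflict_counts(haps[hh], i, m, interval)
                    assert S[hh, m] == pytest.approx(
                        score_haplotype(prof, a[hh]), abs=1e-10
                    )


class TestScoreHaplotype:
    def test_weighted_sum(self):
        prof = ConflictProfile(counts=np.array([6, 5, 5, 3, 3]), focal=0)
        expected = (6 + 5 * 0.75 + 5 * 0.75**2 + 3 * 0.75**3 + 3 * 0.75**4) * 1.5
        assert score_haplotype(prof, 0.5) == pytest.approx(expected)

    def test_relationship_factor(self):
        prof = ConflictProfile(counts=np.array([6, 5, 5, 3, 3]), focal=0)
        assert score_haplotype(prof, 0.5) / score_haplotype(prof, 0.0) == pytest.approx(1.5)

    def test_unit_profile(self):
        prof = ConflictProfile(counts=np.array([1, 0, 0, 0, 0]), focal=0)
        assert score_haplotype(prof, 0.0) == 1.0


class TestImputeMaternal:
    def test_relationship_breaks_profile_tie(self):
        """Dam's haplotype and an identical-profile stranger: kin wins."""
        P = 10
        markers = [f"m{j}" for j in range(P)]
        dam_hap = np.array([0, 1] * 5, np.int8)
        stranger = dam_hap.copy()
        stranger[1::2] = 1 - stranger[1::2]     # differs only off-panel
        partial = np.full(P, MISSING, np.int8)
        panel = np.arange(0, P, 2)
        partial[panel] = dam_hap[panel]
        haps = np.vstack([stranger, dam_hap])
        labels = [("U", "pat"), ("GS", "pat")]
        rel = np.array([0.0, 0.5])
        mat, prov, chosen = impute_maternal(partial, haps, labels, rel, panel)
        assert np.array_equal(mat, dam_hap)

    def test_conflict_free_haplotype_fills_whole_chromosome(self):
        P = 8
        hap = np.ones(P, np.int8)
        partial = np.full(P, MISSING, np.int8)
        panel = np.array([2, 5])
        partial[panel] = 1
        mat, prov, chosen = impute_maternal(
            partial, hap[None, :], [("A", "pat")], np.zeros(1), panel
        )
        assert np.array_equal(mat, hap)
        assert len(chosen) == 1      # one pass filled everything

    def test_window_bounded_by_conflicts(self):
        P = 9
        partial = np.full(P, MISSING, np.int8)
        panel = np.arange(P)
        partial[:] = 0
        hap_bad = np.zeros(P, np.int8)
        hap_bad[0] = hap_bad[8] = 1            # conflicts at the ends
        hap_good = np.zeros(P, np.int8)
        # bad hap has a *better* score in the middle? give good hap kinship
        mat, prov, _ = impute_maternal(
            partial,
            np.vstack([hap_bad, hap_good]),
            [("B", "pat"), ("A", "pat")],
            np.array([0.0, 0.0]),
            panel,
        )
        assert np.array_equal(mat, np.zeros(P))

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            impute_maternal(
                np.zeros(3, np.int8),
                np.zeros((0, 3), np.int8),
                [],
                np.zeros(0),
                np.arange(3),
            )


class TestEndToEnd:
    def test_identity_when_fully_genotyped(self, toy_exact):
        t = toy_exact
        res = impute_individual(
            t["truth"].dosage[0], "S", t["library"], t["markers"], t["map"],
            t["pedigree"], individual="O",
        )
        assert np.array_equal(res.dosage, t["truth"].dosage[0])

    def test_exact_recovery_on_informative_toy(self, toy_exact):
        t = toy_exact
        masked, mask = mask_panel(t["truth"], t["panel"])
        res = impute_individual(
            masked.dosage[0], "S", t["library"], t["panel"], t["map"],
            t["pedigree"], individual="O",
        )
        assert np.array_equal(res.paternal, t["truth_pat"])
        assert np.array_equal(res.maternal, t["truth_mat"])
        err = imputation_error_rate(t["truth"], res.dosage[None, :], mask)
        assert err.overall == 0.0

    def test_genotype_consistency_invariant(self, small_pop):
        """paternal + maternal equals the observed dosage at every
        non-conflicted observed panel marker."""
        pop = small_pop
        geno = pop.geno.copy()
        off = geno.subset(ids=pop.roles["offspring"][:6])
        panel = [m for j, m in enumerate(pop.mmap.marker_ids) if j % 10 == 0]
        masked, mask = mask_panel(off, panel)
        lib = pop.library()
        res = impute_population(masked, pop.sire_of, lib, panel, pop.mmap, pop.pedigree)
        cols = masked.marker_indices(lib.markers)
        for ind, r in res.items():
            obs = masked.row(ind)[cols]
            ok = obs != MISSING
            if r.mendelian_conflicts == 0 and r.derivation_conflicts == 0:
                assert np.array_equal(r.dosage[ok], obs[ok])

    def test_deterministic(self, small_pop):
        pop = small_pop
        off = pop.geno.subset(ids=pop.roles["offspring"][:3])
        panel = [m for j, m in enumerate(pop.mmap.marker_ids) if j % 15 == 0]
        masked, _ = mask_panel(off, panel)
        lib = pop.library()
        r1 = impute_population(masked, pop.sire_of, lib, panel, pop.mmap, pop.pedigree)
        r2 = impute_population(masked, pop.sire_of, lib, panel, pop.mmap, pop.pedigree)
        for ind in r1:
            assert np.array_equal(r1[ind].dosage, r2[ind].dosage)

    def test_missing_sire_rejected(self, toy_exact):
        t = toy_exact
        with pytest.raises(ValueError, match="not in the haplotype library"):
            impute_individual(
                t["truth"].dosage[0], "nosuch", t["library"], t["panel"], t["map"]
            )

    def test_zero_panel_calls_warns(self, toy_exact):
        t = toy_exact
        empty = np.full(len(t["markers"]), MISSING, np.int8)
        with pytest.warns(UserWarning, match="no called panel genotypes"):
            impute_individual(
                empty, "S", t["library"], t["panel"], t["map"], t["pedigree"]
            )


class TestSimulationProperties:
    @pytest.mark.parametrize("replicate", range(3))
    def test_error_monotone_in_panel_size(self, replicate):
        from lowdense.data import compute_maf
        from lowdense.panel import PanelConfig, select_panel
        from lowdense.simulate import SimConfig, simulate_population

        cfg = SimConfig(
            n_sires=10, n_grandsires=10, dams_per_sire=2, offspring_per_dam=2,
            markers_per_chrom=150, n_chromosomes=2, n_founders=40,
            burnin_generations=30, seed=200 + replicate,
        )
        pop = simulate_population(cfg)
        geno = pop.geno.copy()
        maf = compute_maf(geno).maf
        off = geno.subset(ids=pop.roles["offspring"])
        lib = pop.library()
        errs = []
        for size in (12, 30, 90):
            panel = select_panel(pop.mmap.marker_ids, geno, pop.mmap,
                                 PanelConfig(size=size), maf)
            masked, mask = mask_panel(off, panel.marker_ids)
            res = impute_population(masked, pop.sire_of, lib, panel.marker_ids,
                                    pop.mmap, pop.pedigree)
            imp = np.vstack([res[i].dosage for i in off.ids])
            errs.append(imputation_error_rate(off, imp, mask).overall)
        assert errs[0] > errs[1] > errs[2]

    def test_grandsire_library_does_not_hurt(self, small_pop):
        from lowdense.data import compute_maf
        from lowdense.panel import PanelConfig, select_panel

        pop = small_pop
        geno = pop.geno.copy()
        maf = compute_maf(geno).maf
        off = geno.subset(ids=pop.roles["offspring"])
        panel = select_panel(pop.mmap.marker_ids, geno, pop.mmap,
                             PanelConfig(size=30), maf)
        masked, mask = mask_panel(off, panel.marker_ids)
        errs = {}
        for gs in (False, True):
            lib = pop.library(include_grandsires=gs)
            res = impute_population(masked, pop.sire_of, lib, panel.marker_ids,
                                    pop.mmap, pop.pedigree)
            imp = np.vstack([res[i].dosage for i in off.ids])
            errs[gs] = imputation_error_rate(off, imp, mask).overall
        assert errs[True] <= errs[False]
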