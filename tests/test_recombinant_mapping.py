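"""Carrier classification, phasing by descent, recombinant detection and
interval reduction (checked against a brute-force constraint oracle)."""

import math

import numpy as np
import pytest

from fecmap.genome_model import marker_map_from_positions
from fecmap.recombinant_mapping import (
    L,
    UNKNOWN,
    WILD,
    PhasedChromosome,
    assign_carrier_chromosomes,
    classification_accuracy,
    classify_genotype_from_markers,
    detect_recombinants,
    phase_by_descent,
    reduce_interval,
)
from fecmap.synthetic_data import (
    L_LINEAGE,
    PedigreeDesign,
    SimulationConfig,
    simulate_founders,
    simulate_pedigree,
)


def small_config(**kw):
    kw.setdefault("region_length", 400_000)
    kw.setdefault("n_variant_sites", 12)
    kw.setdefault("n_wild_founders", 10)
    kw.setdefault("proxy_misclassification", 0.0)
    return SimulationConfig(**kw)


def chromosome(lineage, carries, animal="a", parent="pat"):
    lin = np.asarray(lineage, dtype=np.int8)
    return PhasedChromosome(
        animal, parent, np.full(lin.size, UNKNOWN, np.int8), lin,
        np.zeros(lin.size, bool), carries_causal=carries,
    )


class TestClassifier:
    @pytest.mark.parametrize(
        "pat, mat, expected",
        [
            ([1, 1, 1, 1], [1, 1, 1, 1], "L/L"),
            ([1, 1, 1, 1], [0, 0, 0, 0], "L/+"),
            ([0, 1, 0, 0], [0, 0, 0, 0], "+/+"),
            ([UNKNOWN] * 4, [0, 0, 0, 0], None),
        ],
    )
    def test_proxy_marker_rule(self, pat, mat, expected):
        assert classify_genotype_from_markers(pat, mat) == expected

    def test_simulated_misclassification_rate(self, rng):
        # 5000 BC animals at the configured 0.5% misclassification rate
        # reproduce ~99.5% animal-level accuracy
        cfg = small_config(
            pedigree=PedigreeDesign(n_f1=4, n_bc=5000, n_f1xbc=0),
            proxy_misclassification=0.005,
        )
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        acc = classification_accuracy(
            [a.observed_class for a in ped.non_founders],
            [a.true_class for a in ped.non_founders],
        )
        assert abs(acc - 0.995) < 4 * math.sqrt(0.005 * 0.995 / 5000)


class TestPhasing:
    def test_homozygous_parents_phase_offspring_completely(self, rng):
        cfg = small_config(pedigree=PedigreeDesign(n_f1=5, n_bc=0, n_f1xbc=0))
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        phased = phase_by_descent(ped)
        for a in ped.non_founders:
            # the L/L sire is homozygous everywhere, so every F1 site
            # resolves
            assert (phased[(a.id, "pat")].alleles != UNKNOWN).all()
            assert (phased[(a.id, "mat")].alleles != UNKNOWN).all()

    def test_phased_lineage_matches_simulator_truth(self, rng):
        cfg = small_config()
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        phased = phase_by_descent(ped)
        for a in ped.non_founders:
            for side, hap in (("pat", a.hap_pat), ("mat", a.hap_mat)):
                inferred = phased[(a.id, side)].l_lineage
                truth = (hap.lineage == L_LINEAGE).astype(int)
                known = inferred != UNKNOWN
                assert (inferred[known] == truth[known]).all()

    def test_impossible_offspring_allele_flagged(self, rng):
        cfg = small_config(pedigree=PedigreeDesign(n_f1=1, n_bc=1, n_f1xbc=0))
        pool = simulate_founders(cfg, rng)
        ped = simulate_pedigree(cfg, pool, rng)
        bc = next(a for a in ped.non_founders if a.generation == "BC")
        dam = ped.by_id(bc.dam)
        # force a genotype the dam cannot transmit
        site = 0
        bc.hap_pat.alleles[site] = 0
        bc.hap_mat.alleles[site] = 0
        dam.hap_pat.alleles[site] = 1
        dam.hap_mat.alleles[site] = 1
        phased = phase_by_descent(ped)
        assert phased[(bc.id, "mat")].mendel_error[site]
        assert phased[(bc.id, "mat")].l_lineage[site] == UNKNOWN


class TestDetectRecombinants:
    def test_uniform_chromosome_is_not_recombinant(self):
        mmap = marker_map_from_positions("c", [10, 20, 30])
        assert detect_recombinants([chromosome([L, L, L], True)], mmap) == []

    def test_single_crossover_localized_to_the_gap(self, rng):
        mmap = marker_map_from_positions("c", [100, 200, 300, 400])
        recs = detect_recombinants(
            [chromosome([L, L, WILD, WILD], True)], mmap
        )
        assert len(recs) == 1
        assert (recs[0].lo_pos, recs[0].hi_pos) == (200, 300)
        assert recs[0].side == "distal"

    def test_simulated_crossovers_recovered(self, rng):
        # every simulator crossover between informative markers appears
        # as exactly one breakpoint in that inter-marker interval
        from fecmap.synthetic_data import Haplotype, simulate_meiosis

        positions = list(range(1, 400_002, 40_000))
        n = len(positions)
        hap_l = Haplotype(np.ones(n, np.int8), np.zeros(n))
        hap_w = Haplotype(np.zeros(n, np.int8), np.ones(n))
        mmap = marker_map_from_positions("c", positions)
        found_any = False
        for _ in range(300):
            g, xo = simulate_meiosis(hap_l, hap_w, positions, 10.0, rng)
            lin = (g.lineage == 0).astype(np.int8)
            recs = detect_recombinants([chromosome(lin, True)], mmap)
            switches = np.flatnonzero(np.diff(lin)) # observable crossovers
            assert len(recs) == len(switches)
            for r, s in zip(recs, switches):
                assert (r.lo_pos, r.hi_pos) == (positions[s], positions[s + 1])
            found_any = found_any or bool(recs)
        assert found_any


def oracle_allowed(chroms, positions, region):
    """Independent brute-force constraint check: for each candidate
    position (every marker and every inter-marker midpoint), a carrier
    chromosome excludes it when every neighbouring informative lineage is
    wild, a non-carrier when every neighbour is L."""
    candidates = []
    pts = [region[0], *(int(p) for p in positions), region[1]]
    for a, b in zip(pts, pts[1:]):
        candidates.append((a + b) / 2)
    candidates.extend(int(p) for p in positions)
    candidates.sort()
    allowed = []
    for x in candidates:
        ok = True
        for c in chroms:
            info = [
                (p, c.l_lineage[i])
                for i, p in enumerate(positions)
                if c.l_lineage[i] != UNKNOWN
            ]
            left = [lin for p, lin in info if p <= x]
            right = [lin for p, lin in info if p >= x]
            bad = WILD if c.carries_causal else L
            lv = left[-1] if left else None
            rv = right[0] if right else None
            neighbours = [v for v in (lv, rv) if v is not None]
            if neighbours and all(v == bad for v in neighbours):
                ok = False
                break
        allowed.append(ok)
    return candidates, allowed


class TestReduceInterval:
    REGION = (36_899_194, 37_387_389)

    def test_two_recombinants_reproduce_the_locus_borders(self):
        positions = [
            36_899_194, 36_910_171, 36_938_224, 37_034_573, 37_107_627,
            37_387_389,
        ]
        mmap = marker_map_from_positions("OAR11", positions)
        chroms = [
            # carrier, wild lineage up to the proximal border
            chromosome([WILD, WILD, L, L, L, L], True, animal="990855"),
            # carrier, wild lineage from the distal border on
            chromosome([L, L, L, L, WILD, WILD], True, animal="60718"),
        ]
        interval, zones = reduce_interval(chroms, mmap, self.REGION)
        assert (interval.start_bp, interval.end_bp) == (36_910_171, 37_107_627)
        assert interval.span == 197_456
        assert zones.counts.max() <= 2

    def test_no_recombinants_keeps_whole_region(self):
        mmap = marker_map_from_positions("c", [100, 200, 300])
        with pytest.warns(UserWarning):
            interval, _ = reduce_interval(
                [chromosome([L, L, L], True)], mmap, (1, 1000)
            )
        assert (interval.start_bp, interval.end_bp) == (1, 1000)
        assert interval.proximal_marker is None

    def test_randomized_cases_match_bruteforce_oracle(self, rng):
        for trial in range(200):
            n = int(rng.integers(2, 7))
            positions = np.sort(
                rng.choice(np.arange(10, 1000, 10), n, replace=False)
            )
            mmap = marker_map_from_positions("c", [int(p) for p in positions])
            causal_pos = float(rng.uniform(10, 1000))
            chroms = []
            for k in range(int(rng.integers(1, 5))):
                # random lineage mosaic with <= 2 switches
                lin = np.zeros(n, dtype=np.int8)
                state = int(rng.integers(2))
                for j in range(n):
                    if rng.random() < 0.3:
                        state = 1 - state
                    lin[j] = state
                # mask some sites as uninformative
                for j in range(n):
                    if rng.random() < 0.2:
                        lin[j] = UNKNOWN
                if (lin == UNKNOWN).all():
                    continue
                # consistent carrier flag: does the mosaic put L at the
                # causal position under nearest-informative imputation?
                info = [
                    (p, lin[i]) for i, p in enumerate(positions)
                    if lin[i] != UNKNOWN
                ]
                left = [v for p, v in info if p <= causal_pos]
                right = [v for p, v in info if p >= causal_pos]
                lv = left[-1] if left else None
                rv = right[0] if right else None
                vals = [v for v in (lv, rv) if v is not None]
                carries = bool(vals and all(v == L for v in vals))
                chroms.append(chromosome(lin, carries, animal=f"t{trial}c{k}"))
            if not chroms:
                continue
            candidates, allowed = oracle_allowed(chroms, positions, (1, 1000))
            if not any(allowed):
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                interval, zones = reduce_interval(chroms, mmap, (1, 1000))
            # per-position equivalence of the exclusion logic
            pos_list = [int(p) for p in positions]
            for x, ok in zip(candidates, allowed):
                if x in pos_list:
                    atom = 2 * pos_list.index(x) + 1
                else:
                    k = int(np.searchsorted(positions, x))
                    atom = 2 * k
                assert (zones.counts[atom] == 0) == ok, (trial, x)
            # the reported interval is a zero-count run
            inside = [
                x
                for x, ok in zip(candidates, allowed)
                if interval.start_bp < x < interval.end_bp
            ]
            assert all(
                ok
                for x, ok in zip(candidates, allowed)
                if interval.start_bp < x < interval.end_bp
            )

    def test_adding_a_recombinant_never_widens(self):
        mmap = marker_map_from_positions("c", [100, 200, 300, 400, 500])
        base = [chromosome([WILD, L, L, L, L], True)]
        extra = base + [chromosome([L, L, L, WILD, WILD], True)]
        with pytest.warns(UserWarning):
            i1, _ = reduce_interval(base, mmap, (1, 1000))
        i2, _ = reduce_interval(extra, mmap, (1, 1000))
        assert i2.start_bp >= i1.start_bp and i2.end_bp <= i1.end_bp

    def test_carrier_and_noncarrier_constraints_combine(self):
        mmap = marker_map_from_positions("c", [100, 200, 300, 400])
        chroms = [
            chromosome([WILD, L, L, L], True),  # causal right of 100
            chromosome([L, L, WILD, WILD], False),  # non-carrier with L head
        ]
        with pytest.warns(UserWarning):
            interval, _ = reduce_interval(chroms, mmap, (1, 1000))
        # non-carrier's L segment (markers 100-200) excludes the left;
        # its own wild tail is uninformative about exclusion
        assert interval.start_bp == 200


class TestEndToEndSoundness:
    def test_reduced_interval_contains_causal_site(self, rng):
        cfg = small_config()
        hits = 0
        for seed in range(30):
            pool = simulate_founders(cfg, rng)
            ped = simulate_pedigree(cfg, pool, rng)
            phased = phase_by_descent(ped)
            chroms = assign_carrier_chromosomes(phased, ped)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                interval, _ = reduce_interval(
                    chroms, pool.marker_map, (1, cfg.region_length)
                )
            causal_pos = pool.marker_map.positions[pool.causal_index]
            assert interval.start_bp <= causal_pos <= interval.end_bp
            hits += 1
        assert hits == 30
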