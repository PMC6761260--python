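import numpy as np
import pytest

from mircomp.io import Alignment
from mircomp.targets import (
    EmergenceRecord,
    SITE_PRIORITY,
    call_site_conservation,
    density_slope,
    emergence_rates,
    find_seed_sites,
    relative_position,
    scan_alignment,
    select_top_fraction,
    site_strings,
    spatial_profile,
    split_by_length,
    target_counts_per_mirna,
    target_pattern_matrix,
)
from mircomp import stats

MIR = "UGGAAUGUAAAGAAGUAUGUAU"


class TestSiteStrings:
    def test_canonical_example(self):
        s = site_strings(MIR)
        assert s == {"6mer": "CAUUCC", "7mer-m8": "ACAUUCC",
                     "7mer-A1": "CAUUCCA", "8mer": "ACAUUCCA"}

    def test_homopolymer(self):
        assert site_strings("A" * 22)["6mer"] == "UUUUUU"

    def test_mutual_consistency(self):
        s = site_strings(MIR)
        assert s["8mer"] == s["7mer-m8"] + "A"
        assert s["8mer"] == s["7mer-m8"][0] + s["7mer-A1"]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            site_strings("ACGUACG")


def brute_force_sites(utr, mirna_seq):
    """Substring scan of the four match strings + subsumption rule."""
    patt = site_strings(mirna_seq)
    occ = {
        t: [i for i in range(len(utr)) if utr.startswith(s, i)]
        for t, s in patt.items()
    }
    found = set()
    for p in occ["8mer"]:
        found.add(("8mer", p))
    for p in occ["7mer-m8"]:
        if ("8mer", p) not in found:
            found.add(("7mer-m8", p))
    for p in occ["7mer-A1"]:
        if ("8mer", p - 1) in found or ("7mer-m8", p - 1) in found:
            continue
        found.add(("7mer-A1", p))
    for p in occ["6mer"]:
        if (("8mer", p - 1) in found or ("7mer-m8", p - 1) in found
                or ("7mer-A1", p) in found):
            continue
        found.add(("6mer", p))
    return found


class TestFindSites:
    def test_embedded_8mer(self):
        sites = find_seed_sites("GGACAUUCCAGG", "m", MIR)
        assert len(sites) == 1
        s = sites[0]
        assert (s.site_type, s.start, s.length) == ("8mer", 2, 8)

    def test_embedded_7mer_m8(self):
        [s] = find_seed_sites("GGACAUUCCGGG", "m", MIR)
        assert (s.site_type, s.start, s.length) == ("7mer-m8", 2, 7)

    def test_no_core_no_sites(self):
        assert find_seed_sites("GGGGGGGGGGGG", "m", MIR) == []

    def test_empty_utr(self):
        assert find_seed_sites("", "m", MIR) == []

    def test_every_site_window_matches_its_string(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGU"))
        utr = "".join(rng.choice(bases, 5000))
        for _ in range(10):
            m = "".join(rng.choice(bases, 22))
            for s in find_seed_sites(utr, "m", m):
                assert utr[s.start : s.start + s.length] == site_strings(m)[s.site_type]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGU"))
        utr = "".join(rng.choice(bases, 10_000))
        for _ in range(50):
            m = "".join(rng.choice(bases, 22))
            ours = {(s.site_type, s.start) for s in find_seed_sites(utr, "m", m)}
            assert ours == brute_force_sites(utr, m)


class TestSiteConservation:
    def _aln(self, seqs):
        return Alignment(sequences=seqs, n_columns=len(next(iter(seqs.values()))))

    def test_identical_sites_conserved_everywhere(self):
        utr = "GGACAUUCCAGG"
        aln = self._aln({f"s{i}": utr for i in range(8)})
        sites = scan_alignment("g", aln, {f"s{i}": [("m", MIR)] for i in range(8)})
        call_site_conservation(sites, aln)
        assert len(sites) == 8 and all(s.conserved_site for s in sites)

    def test_seven_of_eight_not_conserved(self):
        utr = "GGACAUUCCAGG"
        seqs = {f"s{i}": utr for i in range(7)}
        seqs["s7"] = "GGGGGGGGGGGG"
        aln = self._aln(seqs)
        sites = scan_alignment("g", aln, {sp: [("m", MIR)] for sp in seqs})
        call_site_conservation(sites, aln)
        assert sites and not any(s.conserved_site for s in sites)

    def test_disjoint_columns_not_conserved(self):
        seqs = {"s1": "GGACAUUCCAGGGGGGGGGGGGGG",
                "s2": "GGGGGGGGGGGGGGACAUUCCAGG"}
        aln = self._aln(seqs)
        sites = scan_alignment("g", aln, {sp: [("m", MIR)] for sp in seqs})
        call_site_conservation(sites, aln)
        assert len(sites) == 2 and not any(s.conserved_site for s in sites)

    def test_site_species_missing_from_alignment_rejected(self):
        aln = self._aln({"s1": "GGACAUUCCAGG"})
        sites = scan_alignment("g", aln, {"s1": [("m", MIR)]})
        for s in sites:
            s.species = "s9"
        with pytest.raises(ValueError):
            call_site_conservation(sites, aln)


class TestRelativePosition:
    def test_near_stop_codon(self):
        assert relative_position(0, 7, 1000) == pytest.approx(0.003, abs=1e-3)

    def test_midpoint(self):
        # site of length 7 centered at position 500 of a 1001-nt UTR
        assert relative_position(497, 7, 1001) == pytest.approx(0.5)

    def test_degenerate_full_length_site(self):
        assert relative_position(0, 8, 8) == 0.5

    def test_utr_shorter_than_site_rejected(self):
        with pytest.raises(ValueError):
            relative_position(0, 8, 7)


class TestSpatialProfile:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        pos = 0.3 + 0.4 * rng.random(500)  # interior mass
        grid, dens = spatial_profile(pos)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_symmetric_positions_symmetric_density(self):
        pos = [0.2, 0.8, 0.35, 0.65, 0.5]
        grid, dens = spatial_profile(pos, n_grid=513)
        assert np.max(np.abs(dens - dens[::-1])) < 1e-10

    def test_uniform_positions_flat_density(self):
        rng = np.random.default_rng(42)
        grid, dens = spatial_profile(rng.random(10_000))
        interior = (grid >= 0.2) & (grid <= 0.8)
        assert np.all(np.abs(dens[interior] - 1.0) < 0.1)

    def test_identical_positions_rejected(self):
        with pytest.raises(ValueError):
            spatial_profile([0.4, 0.4, 0.4])


class TestDensitySlope:
    def test_constant_density_zero_slope(self):
        grid = np.linspace(0, 1, 101)
        slope, _ = density_slope(grid, np.ones_like(grid))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_affine_density_exact(self):
        grid = np.linspace(0, 1, 101)
        slope, intercept = density_slope(grid, 2 - 2 * grid)
        assert slope == pytest.approx(-2.0, abs=1e-9)
        assert intercept == pytest.approx(2.0, abs=1e-9)

    def test_five_prime_biased_positions_negative_slope(self):
        rng = np.random.default_rng(7)
        pos = rng.beta(1, 3, 5000)
        grid, dens = spatial_profile(pos)
        slope, _ = density_slope(grid, dens)
        assert slope < -0.5

    def test_narrow_window_rejected(self):
        grid = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            density_slope(grid, np.ones(5), lo=0.49, hi=0.51)


class TestSplitByLength:
    def test_odd_count_strict_median(self):
        long_set, short_set = split_by_length({"a": 100, "b": 200, "c": 300})
        assert long_set == {"c"} and short_set == {"a", "b"}

    def test_all_equal_long_empty(self):
        long_set, short_set = split_by_length({"a": 5, "b": 5, "c": 5})
        assert long_set == set() and len(short_set) == 3

    def test_even_count(self):
        long_set, _ = split_by_length({"a": 1, "b": 2, "c": 3, "d": 4})
        assert long_set == {"c", "d"}


def make_site(gene, species, mirna, start=0, stype="6mer"):
    from mircomp.targets import TargetSite
    return TargetSite(gene_id=gene, species=species, mirna_id=mirna,
                      site_type=stype, start=start, length=6)


class TestEmergence:
    def test_rate_arithmetic(self):
        sites = [make_site("g1", f"s{i}", "mA") for i in range(4)]
        classes = {"mA": "species-specific"}
        lengths = {"g1": {f"s{i}": 500 for i in range(4)}}
        [rec] = emergence_rates(sites, classes, lengths)
        assert rec.rate == pytest.approx(0.002)

    def test_no_specific_mirnas_all_zero(self):
        sites = [make_site("g1", "s1", "mA")]
        recs = emergence_rates(sites, {"mA": "conserved"},
                               {"g1": {"s1": 100}, "g2": {"s1": 100}})
        assert all(r.rate == 0 for r in recs)
        assert len(recs) == 2

    def test_doubling_utrs_halves_rates(self):
        sites = [make_site("g1", "s1", "mA")]
        classes = {"mA": "species-specific"}
        r1 = emergence_rates(sites, classes, {"g1": {"s1": 500}})[0].rate
        r2 = emergence_rates(sites, classes, {"g1": {"s1": 1000}})[0].rate
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            emergence_rates([], {}, {"g1": {}})


class TestTopFraction:
    def _records(self, n):
        return [EmergenceRecord(f"g{i:03d}", i, 1000, i / 1000) for i in range(n)]

    def test_five_percent_of_hundred(self):
        assert len(select_top_fraction(self._records(100))) == 5

    def test_ceiling_of_odd_count(self):
        assert len(select_top_fraction(self._records(101))) == 6

    def test_ties_resolved_by_gene_id(self):
        recs = [EmergenceRecord("b", 1, 100, 0.01),
                EmergenceRecord("a", 1, 100, 0.01),
                EmergenceRecord("c", 2, 100, 0.02)]
        assert select_top_fraction(recs, fraction=0.5) == ["c", "a"]

    def test_stable_under_shuffling(self):
        rng = np.random.default_rng(0)
        recs = self._records(40)
        top = select_top_fraction(recs)
        for _ in range(5):
            shuffled = [recs[i] for i in rng.permutation(40)]
            assert select_top_fraction(shuffled) == top

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction([])


class TestCountsAndPatterns:
    def test_zero_count_mirnas_present(self):
        counts = target_counts_per_mirna([], ["mA", "mB"])
        assert counts == {"mA": 0, "mB": 0}

    def test_additivity_over_species(self):
        sites = [make_site("g1", "s1", "mA"), make_site("g1", "s2", "mA"),
                 make_site("g2", "s1", "mB")]
        counts = target_counts_per_mirna(sites, ["mA", "mB"])
        assert counts == {"mA": 2, "mB": 1}
        counts_wo_s2 = target_counts_per_mirna(
            [s for s in sites if s.species != "s2"], ["mA", "mB"]
        )
        assert counts_wo_s2 == {"mA": 1, "mB": 1}

    def test_pattern_matrix_blocks_separate_on_pc1(self):
        sites = []
        for i in range(6):
            for sp in ["s1", "s2"]:
                sites.append(make_site("gA", sp, f"m{i}"))
            for sp in ["s3", "s4"]:
                sites.append(make_site("gB", sp, f"m{i}"))
        matrix, pairs, species = target_pattern_matrix(
            sites, [f"m{i}" for i in range(6)], ["gA", "gB"],
            ["s1", "s2", "s3", "s4"],
        )
        shares, scores = stats.pca(matrix)
        pc1 = scores[:, 0]
        assert (pc1[:2] > 0).all() != (pc1[2:] > 0).all()

    def test_identical_rows_zero_shares(self):
        sites = [make_site("gA", sp, "m0") for sp in ["s1", "s2", "s3"]]
        matrix, _, _ = target_pattern_matrix(sites, ["m0"], ["gA"],
                                             ["s1", "s2", "s3"])
        shares, scores = stats.pca(matrix)
        assert np.allclose(shares, 0)

    def test_priority_order_constant(self):
        assert SITE_PRIORITY == ("8mer", "7mer-m8", "7mer-A1", "6mer")
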