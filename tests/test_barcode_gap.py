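import numpy as np
import pytest

from barcodegap.barcode_gap import (
    FlagCategory,
    compile_report,
    flag_deep_intra,
    flag_inversion,
    flag_shallow_inter,
    gap_histograms,
    partition_distances,
    screen,
    species_summaries,
)
from barcodegap.distance import CODE_NO_OVERLAP, CODE_SATURATED
from conftest import build_dm, random_symmetric_dm


# ---------------------------------------------------------------------------
# Brute-force re-derivation of all three flag rules, from first principles
# ---------------------------------------------------------------------------

def brute_force_flags(dm, t_intra=0.01, t_inter=0.10):
    """Independent plain-loop implementation of the distance ruler."""
    n = len(dm)

    def defined(i, j):
        return i != j and dm.codes[i, j] == 0

    deep_seq, deep_species, shallow, inversion = set(), set(), set(), set()
    for i in range(n):
        con = [dm.d[i, j] for j in range(n) if defined(i, j) and dm.species[i] == dm.species[j]]
        het = [dm.d[i, j] for j in range(n) if defined(i, j) and dm.species[i] != dm.species[j]]
        if con and min(con) > t_intra:
            deep_seq.add(dm.labels[i])
        if con and het and min(het) < min(con) and min(con) > t_intra and min(het) < t_inter:
            inversion.add(dm.labels[i])
    for sp in set(dm.species):
        rows = [i for i in range(n) if dm.species[i] == sp]
        intra = [
            dm.d[i, j] for i in rows for j in rows if j > i and defined(i, j)
        ]
        if intra and max(intra) > t_intra and not any(
            dm.labels[i] in deep_seq for i in rows
        ):
            deep_species.add(sp)
    species = sorted(set(dm.species))
    for a_i in range(len(species)):
        for b_i in range(a_i + 1, len(species)):
            a, b = species[a_i], species[b_i]
            inter = [
                dm.d[i, j]
                for i in range(n)
                for j in range(n)
                if dm.species[i] == a and dm.species[j] == b and defined(i, j)
            ]
            if inter and min(inter) < t_inter:
                shallow.add((a, b))
    return deep_seq, deep_species, shallow, inversion


def package_flag_sets(dm, t_intra=0.01, t_inter=0.10):
    deep = flag_deep_intra(dm, t_intra)
    deep_seq = {f.accession for f in deep if f.accession != f.species}
    deep_species = {f.accession for f in deep if f.accession == f.species}
    shallow = {
        tuple(f.accession.split(" / ")) for f in flag_shallow_inter(dm, t_inter)
    }
    inversion = {f.accession for f in flag_inversion(dm, t_intra, t_inter)[0]}
    return deep_seq, deep_species, shallow, inversion


class TestPartition:
    def test_label_combinatorics(self):
        dm = build_dm(
            ["A1", "A2", "B1"],
            ["Genus a", "Genus a", "Genus b"],
            [[0, 0.005, 0.15], [0.005, 0, 0.15], [0.15, 0.15, 0]],
        )
        part = partition_distances(dm)
        assert len(part.intra) == 1 and len(part.inter) == 2

    def test_single_species_has_no_inter(self):
        dm = random_symmetric_dm(np.random.default_rng(0), 5, n_species=1)
        part = partition_distances(dm)
        assert not part.inter

    def test_conservation_with_sentinels(self):
        rng = np.random.default_rng(1)
        dm = random_symmetric_dm(rng, 8)
        dm.codes[0, 1] = dm.codes[1, 0] = CODE_SATURATED
        dm.codes[2, 3] = dm.codes[3, 2] = CODE_NO_OVERLAP
        part = partition_distances(dm)
        assert len(part.intra) + len(part.inter) + part.n_excluded == 8 * 7 // 2


class TestDeepIntra:
    def test_isolated_sequence_flagged(self):
        # one sequence at ~0.19 from all conspecifics
        d = np.array(
            [
                [0, 0.003, 0.19],
                [0.003, 0, 0.191],
                [0.19, 0.191, 0],
            ]
        )
        dm = build_dm(["A1", "A2", "A3"], ["Genus a"] * 3, d)
        flags = flag_deep_intra(dm)
        assert {f.accession for f in flags} == {"A3"}
        (f,) = [f for f in flags if f.accession == "A3"]
        assert f.d_min == pytest.approx(0.19)

    def test_shallow_species_unflagged(self):
        d = np.full((4, 4), 0.009)
        np.fill_diagonal(d, 0)
        dm = build_dm([f"A{i}" for i in range(4)], ["Genus a"] * 4, d)
        assert flag_deep_intra(dm) == []

    def test_two_clusters_give_species_level_flag_only(self):
        # 3+3 split: ~0 within clusters, 0.13 between -> cryptic-complex shape
        d = np.zeros((6, 6))
        for i in range(3):
            for j in range(3, 6):
                d[i, j] = d[j, i] = 0.13
        dm = build_dm([f"A{i}" for i in range(6)], ["Genus a"] * 6, d)
        flags = flag_deep_intra(dm)
        assert len(flags) == 1 and flags[0].accession == "Genus a"
        assert flags[0].category is FlagCategory.DEEP_INTRA


class TestShallowInter:
    def test_recent_species_pair_flagged(self):
        # inter range 0.004-0.010 between two species
        d = np.array(
            [
                [0, 0.002, 0.004, 0.010],
                [0.002, 0, 0.007, 0.006],
                [0.004, 0.007, 0, 0.001],
                [0.010, 0.006, 0.001, 0],
            ]
        )
        dm = build_dm(
            ["C1", "C2", "D1", "D2"],
            ["Comephorus dybowskii"] * 2 + ["Comephorus baicalensis"] * 2,
            d,
        )
        flags = flag_shallow_inter(dm)
        assert len(flags) == 1
        assert flags[0].d_min == pytest.approx(0.004)
        assert flags[0].d_max == pytest.approx(0.010)

    def test_deep_pairs_unflagged(self):
        d = np.full((4, 4), 0.12)
        np.fill_diagonal(d, 0)
        dm = build_dm(["A1", "A2", "B1", "B2"], ["s a", "s a", "s b", "s b"], d)
        assert flag_shallow_inter(dm) == []

    def test_boundary_is_strict(self):
        d = np.array([[0, 0.0999], [0.0999, 0]])
        dm = build_dm(["A1", "B1"], ["s a", "s b"], d)
        assert len(flag_shallow_inter(dm, 0.10)) == 1
        d2 = np.array([[0, 0.1000], [0.1000, 0]])
        dm2 = build_dm(["A1", "B1"], ["s a", "s b"], d2)
        assert flag_shallow_inter(dm2, 0.10) == []


class TestInversion:
    def test_misidentified_sequence_flagged(self):
        # labeled A, 0.002 to nearest B, 0.16 to nearest conspecific
        d = np.array(
            [
                [0, 0.16, 0.002],
                [0.16, 0, 0.161],
                [0.002, 0.161, 0],
            ]
        )
        dm = build_dm(["A1", "A2", "B1"], ["s a", "s a", "s b"], d)
        flags, skipped = flag_inversion(dm)
        assert {f.accession for f in flags} == {"A1"}
        assert flags[0].partner == "B1"

    def test_gapped_data_has_no_inversions(self):
        d = np.array(
            [
                [0, 0.005, 0.15, 0.15],
                [0.005, 0, 0.15, 0.15],
                [0.15, 0.15, 0, 0.005],
                [0.15, 0.15, 0.005, 0],
            ]
        )
        dm = build_dm(["A1", "A2", "B1", "B2"], ["s a", "s a", "s b", "s b"], d)
        flags, skipped = flag_inversion(dm)
        assert flags == [] and skipped == 0

    def test_single_species_all_skipped(self):
        dm = random_symmetric_dm(np.random.default_rng(2), 5, n_species=1)
        flags, skipped = flag_inversion(dm)
        assert flags == [] and skipped == 5


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        dm = random_symmetric_dm(rng, n)
        # sprinkle sentinels on some matrices
        if seed % 3 == 0 and n > 4:
            dm.codes[0, 1] = dm.codes[1, 0] = CODE_SATURATED
        assert package_flag_sets(dm) == brute_force_flags(dm)

    def test_matches_brute_force_on_gap_structured_matrix(self):
        rng = np.random.default_rng(99)
        n = 12
        labels = [f"A{i}" for i in range(n)]
        species = [f"s sp{i // 3}" for i in range(n)]
        d = np.where(
            np.equal.outer(np.array(species), np.array(species)),
            rng.uniform(0.001, 0.02, (n, n)),
            rng.uniform(0.05, 0.2, (n, n)),
        )
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = build_dm(labels, species, d)
        assert package_flag_sets(dm) == brute_force_flags(dm)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        dm = random_symmetric_dm(rng, 12)
        prev_deep, prev_shallow = None, None
        for t in (0.005, 0.01, 0.02, 0.05, 0.1):
            deep = {(f.accession, f.category.value) for f in flag_deep_intra(dm, t)}
            shallow = {f.accession for f in flag_shallow_inter(dm, t)}
            if prev_deep is not None:
                # raising t_intra never adds DEEP_INTRA flags (sequence level)
                deep_seq = {a for a, _ in deep}
                assert deep_seq <= prev_deep
                # raising t_inter never removes SHALLOW_INTER flags
                assert prev_shallow <= shallow
            prev_deep = {a for a, _ in deep}
            prev_shallow = shallow


class TestHistograms:
    def test_empty_partition(self):
        dm = build_dm(["A", "B"], ["s a", "s a"], [[0, 0.003], [0.003, 0]])
        part = partition_distances(dm)
        intra, inter = gap_histograms(part)
        assert inter.total == 0 and intra.total == 1

    def test_identical_values_fill_one_bin(self):
        dm = random_symmetric_dm(np.random.default_rng(3), 5, n_species=1)
        dm.d[:] = 0.003
        np.fill_diagonal(dm.d, 0)
        part = partition_distances(dm)
        intra, _ = gap_histograms(part)
        assert intra.counts.max() == intra.total == 10

    def test_totals_conserved(self):
        dm = random_symmetric_dm(np.random.default_rng(4), 10)
        part = partition_distances(dm)
        intra, inter = gap_histograms(part)
        assert intra.total == len(part.intra)
        assert inter.total == len(part.inter)


class TestReport:
    def test_multi_category_sequence_keeps_one_row_per_category(self):
        d = np.array(
            [
                [0, 0.16, 0.002],
                [0.16, 0, 0.161],
                [0.002, 0.161, 0],
            ]
        )
        dm = build_dm(["A1", "A2", "B1"], ["s a", "s a", "s b"], d)
        report = screen(dm)
        a1_rows = [f for f in report.flags if f.accession == "A1"]
        assert {f.category for f in a1_rows} == {
            FlagCategory.DEEP_INTRA,
            FlagCategory.INVERSION,
        }

    def test_empty_report_keeps_summary_header(self, tmp_path):
        d = np.array([[0, 0.005], [0.005, 0]])
        dm = build_dm(["A1", "A2"], ["s a", "s a"], d)
        report = screen(dm)
        out = tmp_path / "flags.tsv"
        report.to_tsv(out)
        text = out.read_text()
        assert report.n_flag_rows == 0
        assert "# sequences: 2" in text and "accession\t" in text

    def test_sorted_by_severity_then_accession(self):
        rng = np.random.default_rng(6)
        dm = random_symmetric_dm(rng, 12)
        report = screen(dm)
        keys = [(-f.severity, f.accession) for f in report.flags]
        assert keys == sorted(keys)

    def test_byte_identical_reports_for_identical_input(self, tmp_path):
        rng = np.random.default_rng(7)
        dm = random_symmetric_dm(rng, 10)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        screen(dm).to_tsv(p1)
        screen(dm).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_species_summaries_ordering_invariants():
    rng = np.random.default_rng(8)
    dm = random_symmetric_dm(rng, 10)
    for s in species_summaries(dm).values():
        if s.intra_min is not None:
            assert s.intra_min <= s.intra_mean <= s.intra_max
        assert s.n_seqs >= 1
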