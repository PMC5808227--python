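import numpy as np
import pytest

from barcodegap.anchor_trim import (
    TrimmedAlignment,
    anchor_all,
    build_trimmed_alignment,
    select_window,
)
from barcodegap.distance import count_pq, distance_matrix, k2p
from barcodegap.simdata import (
    Anomaly,
    AnomalyRates,
    SimConfig,
    SimTruth,
    TruthEntry,
    decode,
    evolve,
    fragmentize,
    inject_anomalies,
    random_sequence,
    simulate,
    simulate_clean,
    write_simulation,
)


class TestConfig:
    def test_gap_scenario_requires_intra_below_inter(self):
        with pytest.raises(ValueError):
            SimConfig(intra_depth=0.2, inter_depth=0.1)

    def test_rates_jointly_bounded(self):
        with pytest.raises(ValueError):
            SimConfig(anomaly_rates=AnomalyRates(mislabel=0.6, chimera=0.6))

    def test_base_freqs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(base_freqs=(0.5, 0.5, 0.5, 0.5))


class TestEvolve:
    def test_zero_branch_is_identity(self):
        rng = np.random.default_rng(0)
        a = random_sequence(500, [0.25] * 4, rng)
        assert np.array_equal(evolve(a, 0.0, 4.0, rng), a)

    def test_transition_bias_matches_kappa(self):
        rng = np.random.default_rng(1)
        a = random_sequence(200_000, [0.25] * 4, rng)
        b = evolve(a, 0.05, 4.0, rng)
        counts = count_pq(decode(a), decode(b))
        # kappa=4 -> alpha=2/3, beta=1/6: transitions ~2x each transversion
        # pair, i.e. P/Q ~ 2 at small distances
        assert counts.P / counts.Q == pytest.approx(2.0, rel=0.1)


class TestSimulateClean:
    def test_zero_intra_depth_makes_conspecifics_identical(self):
        records, _, _ = simulate_clean(
            SimConfig(n_species=3, seqs_per_species=4, intra_depth=0.0, seed=0)
        )
        by_species = {}
        for r in records:
            by_species.setdefault(r.species, set()).add(r.bases)
        assert all(len(seqs) == 1 for seqs in by_species.values())

    def test_single_species_has_no_inter_pairs(self):
        records, _, _ = simulate_clean(SimConfig(n_species=1, seqs_per_species=5, seed=0))
        dm = distance_matrix(TrimmedAlignment.from_records(records))
        from barcodegap.barcode_gap import partition_distances

        assert not partition_distances(dm).inter

    def test_interspecific_divergence_scales_to_inter_depth(self):
        """Mean estimated K2P across species pairs tracks the configured depth."""
        records, _, _ = simulate_clean(
            SimConfig(n_species=30, seqs_per_species=2, inter_depth=0.10, seed=3)
        )
        dm = distance_matrix(TrimmedAlignment.from_records(records))
        sp = np.asarray(dm.species)
        mask = np.triu(sp[:, None] != sp[None, :], 1)
        vals = dm.d[mask]
        assert len(vals) >= 200
        assert abs(np.nanmean(vals) - 0.10) < 0.005

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(
            n_species=6,
            seqs_per_species=3,
            anomaly_rates=AnomalyRates(mislabel=0.1, synonym_pair=0.1),
            seed=11,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_simulation(simulate(cfg), d1)
        p2 = write_simulation(simulate(cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_gap_property_across_seeds(self):
        """Max intra < min inter in at least 95% of seeds at default depths."""
        hold = 0
        n_seeds = 20
        for seed in range(n_seeds):
            records, _, _ = simulate_clean(
                SimConfig(n_species=10, seqs_per_species=3, seed=seed)
            )
            dm = distance_matrix(TrimmedAlignment.from_records(records))
            sp = np.asarray(dm.species)
            upper = np.triu(np.ones_like(dm.d, bool), 1)
            intra = dm.d[upper & (sp[:, None] == sp[None, :])]
            inter = dm.d[upper & (sp[:, None] != sp[None, :])]
            if intra.max() < inter.min():
                hold += 1
        assert hold >= 0.95 * n_seeds


class TestInjectAnomalies:
    def test_zero_rates_bitwise_unchanged(self):
        cfg = SimConfig(n_species=5, seqs_per_species=3, seed=2)
        records, truth, tree = simulate_clean(cfg)
        records2, truth2, synonyms = inject_anomalies(records, truth, cfg, tree=tree)
        assert [(r.accession, r.species, r.bases) for r in records2] == [
            (r.accession, r.species, r.bases) for r in records
        ]
        assert len(synonyms) == 0

    def test_mislabel_count_exact(self):
        cfg = SimConfig(
            n_species=20,
            seqs_per_species=5,
            anomaly_rates=AnomalyRates(mislabel=0.05),
            seed=4,
        )
        res = simulate(cfg)
        assert len(res.truth.accessions_with(Anomaly.MISLABEL)) == 5

    def test_mislabel_has_inversion_signature(self):
        cfg = SimConfig(anomaly_rates=AnomalyRates(mislabel=0.05), seed=5)
        res = simulate(cfg)
        dm = distance_matrix(TrimmedAlignment.from_records(res.records))
        sp = np.asarray(dm.species)
        for acc in res.truth.accessions_with(Anomaly.MISLABEL):
            i = dm.index(acc)
            con = sp == dm.species[i]
            con[i] = False
            het = sp != dm.species[i]
            assert dm.d[i][het].min() < dm.d[i][con].min()

    def test_overfull_rates_rejected(self):
        # rounding: 3 sequences at 0.5 + 0.5 rates requires 2 + 2 anomalies
        cfg = SimConfig(
            n_species=3,
            seqs_per_species=1,
            anomaly_rates=AnomalyRates(mislabel=0.5, introgression=0.5),
            seed=0,
        )
        records, truth, tree = simulate_clean(cfg)
        with pytest.raises(ValueError, match="more anomalies"):
            inject_anomalies(records, truth, cfg, tree=tree)

    def test_synonym_alias_registered_and_resolves(self):
        cfg = SimConfig(
            n_species=10,
            seqs_per_species=4,
            anomaly_rates=AnomalyRates(synonym_pair=0.05),
            seed=6,
        )
        res = simulate(cfg)
        syn_accs = res.truth.accessions_with(Anomaly.SYNONYM)
        assert syn_accs
        for acc in syn_accs:
            entry = res.truth[acc]
            assert entry.labeled_species != entry.true_species
            assert res.synonyms.resolve(entry.labeled_species) == entry.true_species

    def test_cryptic_subcluster_is_species_level_deep_intra(self):
        from barcodegap.barcode_gap import FlagCategory, flag_deep_intra

        cfg = SimConfig(
            n_species=10,
            seqs_per_species=6,
            anomaly_rates=AnomalyRates(cryptic_split=0.05),
            seed=7,
        )
        res = simulate(cfg)
        dm = distance_matrix(TrimmedAlignment.from_records(res.records))
        cryptic_species = {
            res.truth[a].true_species for a in res.truth.accessions_with(Anomaly.CRYPTIC)
        }
        assert cryptic_species
        species_flags = {
            f.accession
            for f in flag_deep_intra(dm)
            if f.accession == f.species and f.category is FlagCategory.DEEP_INTRA
        }
        assert cryptic_species <= species_flags

    def test_truth_invariants(self):
        with pytest.raises(ValueError):
            TruthEntry("Genus a", "Genus b", Anomaly.NONE)
        with pytest.raises(ValueError):
            TruthEntry("Genus a", "Genus a", Anomaly.MISLABEL)


class TestFragmentize:
    def test_degenerate_distribution_unchanged(self):
        cfg = SimConfig(n_species=4, seqs_per_species=2, seed=8, fragmentation=None)
        records, _, _ = simulate_clean(cfg)
        assert fragmentize(records, cfg) == records

    def test_lengths_within_bounds(self):
        cfg = SimConfig(n_species=6, seqs_per_species=3, seed=9, fragmentation=(75, 918))
        records, _, _ = simulate_clean(cfg)
        frags = fragmentize(records, cfg)
        assert all(75 <= len(r.bases) <= 918 for r in frags)

    def test_trim_keeps_only_window_spanning_fragments(self):
        cfg = SimConfig(n_species=8, seqs_per_species=3, seed=10, fragmentation=(300, 918))
        res = simulate(cfg)
        fragments, excluded = anchor_all(res.records, res.reference)
        window = select_window(fragments)
        aln, low_cov = build_trimmed_alignment(fragments, window, 1.0)
        kept = {a for a, _s, _b in aln.rows}
        for frag in fragments:
            spans = frag.ref_start <= window[0] and frag.ref_end >= window[1]
            assert (frag.accession in kept) == spans


class TestTruthIO:
    def test_tsv_round_trip(self, tmp_path):
        cfg = SimConfig(
            n_species=6,
            seqs_per_species=3,
            anomaly_rates=AnomalyRates(mislabel=0.1, introgression=0.1),
            seed=12,
        )
        res = simulate(cfg)
        path = tmp_path / "truth.tsv"
        res.truth.to_tsv(path)
        back = SimTruth.from_tsv(path)
        assert back.entries == res.truth.entries
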