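import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escirc._seq import revcomp
from escirc.io import write_fastq
from escirc.locus_model import build_locus, enumerate_junctions
from escirc.synthetic_data import (
    Cell,
    PopulationTruth,
    SimulationConfig,
    SVSimConfig,
    _duplicate_and_segregate,
    simulate_copy_totals,
    simulate_lam_reads,
    simulate_population,
    simulate_sv_set,
    simulate_wgs_reads,
)

from conftest import manual_truth, toy_config


class TestConfigValidation:
    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, esc_replication_prob=1.5)

    def test_read_len_window(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, wgs_read_len=30)

    def test_segregation_mode(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, segregation="magic")

    def test_population_size_cap(self):
        with pytest.raises(ValueError, match="max_cells"):
            SimulationConfig(seed=1, n_founders=1000, divisions=20)


class TestPopulation:
    def test_dilution_without_replication(self, db, locus):
        # r=0, even segregation, 1 founder, 6 divisions, 1 initial ESC:
        # mean per-cell ESC copies = 1/64 = 1.5625% of the rec junction copies
        cfg = SimulationConfig(
            seed=11, n_founders=1, divisions=6, esc_replication_prob=0.0, segregation="even"
        )
        truth = simulate_population(cfg, db, locus)
        assert len(truth.cells) == 64
        summary = truth.junction_summary()
        assert summary["rec_copies"].sum() == 64
        assert summary["sj_copies"].sum() == 1  # conserved total
        assert summary["sj_copies"].sum() / summary["rec_copies"].sum() == 1 / 64

    def test_full_replication_conserves_one_per_cell(self, db, locus):
        cfg = SimulationConfig(
            seed=3, n_founders=2, divisions=5, esc_replication_prob=1.0, segregation="even"
        )
        truth = simulate_population(cfg, db, locus)
        for cell in truth.cells:
            assert sum(cell.esc_copies.values()) == 1
        s = truth.junction_summary()
        # SJ:Rec ratio = 1 at all generations
        assert (s["sj_copies"] == s["rec_copies"]).all()

    def test_rec_copies_equal_carrier_cells(self, db, locus):
        cfg = SimulationConfig(seed=5, n_founders=3, divisions=4, esc_replication_prob=0.5)
        truth = simulate_population(cfg, db, locus)
        summary = truth.junction_summary()
        for row in summary.itertuples():
            carriers = sum(
                any(ev.coding_id == row.coding_id for ev in c.events) for c in truth.cells
            )
            assert carriers == row.rec_copies

    def test_single_allele_occupancy(self, db, locus):
        cfg = SimulationConfig(
            seed=5, n_founders=4, divisions=4, secondary_event_prob=0.3
        )
        truth = simulate_population(cfg, db, locus)
        for cell in truth.cells:
            alleles = [ev.allele for ev in cell.events if not ev.is_kde]
            assert len(alleles) == len(set(alleles))

    def test_determinism(self, db, locus):
        cfg = SimulationConfig(seed=7, n_founders=2, divisions=4, esc_replication_prob=0.4)
        a = simulate_population(cfg, db, locus).junction_summary()
        b = simulate_population(cfg, db, locus).junction_summary()
        assert a.equals(b)

    def test_branching_process_expectation(self):
        # [DERIVED] independent Monte-Carlo oracle: E[total copies] = (1+r)^t
        r, t, n = 0.5, 6, 10_000
        totals = simulate_copy_totals(n, t, r, seed=42)
        expected = (1 + r) ** t
        se = totals.std(ddof=1) / np.sqrt(n)
        assert abs(totals.mean() - expected) < 4 * se
        # mean per-cell copies = (1+r)^t / 2^t
        assert abs(totals.mean() / 2**t - expected / 2**t) < 4 * se / 2**t

    def test_population_matches_total_process(self, db, locus):
        # cross-check the cell-explicit simulator against the totals process
        cfg = SimulationConfig(seed=13, n_founders=50, divisions=5, esc_replication_prob=0.5)
        truth = simulate_population(cfg, db, locus)
        mean_total = truth.junction_summary()["sj_copies"].sum() / cfg.n_founders
        expected = 1.5**5
        assert abs(mean_total - expected) < 1.2  # ~4 sigma for 50 lineages

    def test_sj_rec_slope(self):
        # with r=0 the SJ:Rec ratio halves per division; with r=1 it is constant
        for r in (0.0, 1.0):
            ratios = [
                simulate_copy_totals(2000, t, r, seed=t).mean() / 2**t for t in (2, 4, 6)
            ]
            if r == 1.0:
                assert np.allclose(ratios, 1.0)  # totals double every division
            else:
                assert np.allclose(ratios, [0.25, 0.0625, 0.015625])  # totals constant


@settings(max_examples=60, deadline=None)
@given(
    copies=st.integers(min_value=0, max_value=50),
    r=st.floats(min_value=0, max_value=1),
    mode=st.sampled_from(["binomial", "even"]),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_segregation_conserves_copies(copies, r, mode, seed):
    rng = np.random.default_rng(seed)
    d1, d2 = _duplicate_and_segregate(copies, r, mode, rng)
    assert copies <= d1 + d2 <= 2 * copies
    if mode == "even":
        assert abs(d1 - d2) <= 1


class TestWGSReads:
    def test_no_circles_no_spanning_reads(self, db):
        truth = PopulationTruth(
            [Cell(0, 0, [], {})], 0, SimulationConfig(seed=1, wgs_n_fragments=200)
        )
        locus = build_locus(toy_config())
        pairs, table = simulate_wgs_reads(truth, locus, truth.config)
        assert len(pairs) == 200
        assert not table["spans_SJ"].any()
        assert (table["origin"] == "genome").all()

    def test_junction_span_fraction(self, db, locus):
        # [DERIVED] closed form: P(fragment spans SJ) ~ f/L for circle length L
        sid = db.signal_entries()[0].junction_id
        cfg_kwargs = dict(
            wgs_n_fragments=20_000,
            wgs_circle_fraction=1.0,
            wgs_fragment_sd=0.0,
            wgs_fragment_mean=400.0,
        )
        truth = manual_truth(db, {sid: 5}, seed=21, **cfg_kwargs)
        pairs, table = simulate_wgs_reads(truth, locus, truth.config)
        e = db.get(sid)
        L = e.break_a - e.break_b  # circle length
        p = 400.0 / L
        frac = table["spans_SJ"].mean()
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / len(table))

    def test_reads_match_reference(self, db, locus):
        sid = db.signal_entries()[0].junction_id
        truth = manual_truth(db, {sid: 3}, seed=4, wgs_n_fragments=50, wgs_circle_fraction=0.5)
        pairs, table = simulate_wgs_reads(truth, locus, truth.config)
        for (r1, r2), row in zip(pairs, table.itertuples()):
            if row.origin == "genome":
                assert r1.sequence in locus.sequence
                assert revcomp(r2.sequence) in locus.sequence

    def test_determinism_bytes(self, db, locus, tmp_path):
        sid = db.signal_entries()[0].junction_id
        outs = []
        for run in (1, 2):
            truth = manual_truth(db, {sid: 2}, seed=99, wgs_n_fragments=100)
            pairs, _ = simulate_wgs_reads(truth, locus, truth.config)
            p = tmp_path / f"r{run}.fastq"
            write_fastq(p, [a for a, _ in pairs])
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_fragment_mean_too_small(self, db, locus):
        truth = manual_truth(db, {}, seed=1, wgs_fragment_mean=80.0, wgs_read_len=50)
        with pytest.raises(ValueError, match="fragment mean"):
            simulate_wgs_reads(truth, locus, truth.config)


class TestLAMReads:
    def test_error_free_reads_start_with_primer(self, db):
        from escirc.lam_junction_caller import design_primers

        sid = db.signal_entries()[0].junction_id
        truth = manual_truth(db, {sid: 10}, seed=2, lam_n_reads=100, seq_error_rate=0.0)
        primers = design_primers(db, "signal")
        pairs, _ = simulate_lam_reads(truth, db, primers, truth.config, assay="signal")
        pseqs = [p.sequence for p in primers]
        assert all(any(r1.sequence.startswith(s) for s in pseqs) for r1, _ in pairs)

    def test_read_count_ratio(self, db):
        # [DERIVED] binomial sampling oracle: copies 100 vs 50 -> ratio ~2:1
        from escirc.lam_junction_caller import design_primers

        sids = [e.junction_id for e in db.signal_entries()[:2]]
        truth = manual_truth(
            db, {sids[0]: 100, sids[1]: 50}, seed=3,
            lam_n_reads=6000, amplification_sigma=0.0,
        )
        primers = design_primers(db, "signal")
        _, table = simulate_lam_reads(truth, db, primers, truth.config, assay="signal")
        counts = table["junction_id"].value_counts()
        n, p = 6000, 2 / 3
        se = np.sqrt(n * p * (1 - p))
        assert abs(counts[sids[0]] - n * p) < 4 * se

    def test_overlap_arithmetic(self, db):
        # amplicon shorter than 2x read_len -> mates overlap by >= 2rl - A
        from escirc.lam_junction_caller import design_primers, merge_pair

        sid = db.signal_entries()[0].junction_id
        truth = manual_truth(db, {sid: 5}, seed=4, lam_n_reads=20, seq_error_rate=0.0)
        primers = design_primers(db, "signal")
        pairs, table = simulate_lam_reads(truth, db, primers, truth.config, assay="signal")
        for (r1, r2), row in zip(pairs, table.itertuples()):
            amp_len = row.amplicon_len
            merged = merge_pair(r1, r2)
            assert merged.merged
            assert len(merged.sequence) == amp_len
            assert merged.overlap >= 2 * min(250, amp_len) - amp_len

    def test_missing_junction_rejected(self, db, locus):
        from escirc.lam_junction_caller import design_primers
        from escirc.locus_model import JunctionDatabase

        sid = db.signal_entries()[0].junction_id
        truth = manual_truth(db, {sid: 5}, seed=5)
        pruned = JunctionDatabase(
            entries=[e for e in db.entries if e.junction_id != sid],
            flank_len=db.flank_len,
        )
        primers = design_primers(db, "signal")
        with pytest.raises(KeyError):
            simulate_lam_reads(truth, pruned, primers, truth.config, assay="signal")

    def test_coding_reads_carry_inserts(self, db, locus):
        from escirc.lam_junction_caller import design_primers

        cfg = SimulationConfig(seed=6, n_founders=2, divisions=2, insert_len_max=6)
        truth = simulate_population(cfg, db, locus)
        primers = design_primers(db, "coding")
        pairs, table = simulate_lam_reads(truth, db, primers, cfg, assay="coding")
        inserts = {ev.coding_id: ev.insert for c in truth.cells for ev in c.events}
        for (r1, _), row in zip(pairs, table.itertuples()):
            entry = db.get(row.junction_id)
            ins = inserts[row.junction_id]
            expected = (
                entry.sequence[: entry.junction_offset]
                + ins
                + entry.sequence[entry.junction_offset :]
            )
            assert r1.sequence == expected[:250]


class TestSVSet:
    def test_proportions_exact(self, locus):
        cfg = SVSimConfig(seed=8, n_sv=40, proportions={"none": 0.6, "single": 0.3, "double": 0.1})
        _, _, truth = simulate_sv_set(cfg, locus)
        counts = truth["true_category"].value_counts()
        assert counts["none"] == 24 and counts["single"] == 12 and counts["double"] == 4

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SVSimConfig(seed=1, proportions={"none": 0.5, "single": 0.2, "double": 0.2})

    def test_reintegration_inserts_from_locus(self, locus):
        cfg = SVSimConfig(seed=9, n_sv=30)
        sv, genome, truth = simulate_sv_set(cfg, locus)
        m = sv.merge(truth, on="sv_id")
        reint = m[m["true_mechanism"] == "reintegration"]
        assert len(reint) > 0
        for rec in reint.itertuples():
            assert rec.insert_seq in locus.sequence

    def test_none_class_clean_under_scanner(self, locus):
        # [DERIVED] the scanner is the oracle for cRSS-free windows
        from escirc.rss_sv_classifier import scan_rss

        cfg = SVSimConfig(seed=10, n_sv=30)
        sv, genome, truth = simulate_sv_set(cfg, locus)
        m = sv.merge(truth, on="sv_id")
        for rec in m[m["true_category"] == "none"].itertuples():
            for chrom, pos in ((rec.chrom, rec.pos), (rec.mate_chrom, rec.mate_pos)):
                lo = max(pos - 90, 0)
                region = genome[chrom][lo : pos + 90]
                hits = [
                    h
                    for h in scan_rss(region)
                    if h.position + lo + 6 >= pos - 50 and h.position + lo <= pos + 50
                ]
                assert hits == []

    def test_determinism(self, locus):
        cfg = SVSimConfig(seed=12, n_sv=20)
        a = simulate_sv_set(cfg, locus)
        b = simulate_sv_set(cfg, locus)
        assert a[0].equals(b[0]) and a[1] == b[1] and a[2].equals(b[2])
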