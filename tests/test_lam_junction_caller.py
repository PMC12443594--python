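import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escirc._seq import random_dna, revcomp
from escirc.io import FastqRead
from escirc.lam_junction_caller import (
    JunctionIndex,
    Primer,
    PrimerSet,
    ThresholdModel,
    apply_threshold,
    assign_junction,
    banded_local_align,
    demultiplex,
    design_primers,
    fit_threshold,
    merge_pair,
    quantify,
    run_lam_pipeline,
)
from escirc.locus_model import build_locus, enumerate_junctions
from escirc.synthetic_data import SimulationConfig, simulate_lam_reads

from conftest import manual_truth, toy_config


def _read(rid, seq, qual=None):
    return FastqRead(rid, seq, qual or "?" * len(seq))


class TestDemultiplex:
    PRIMERS = PrimerSet(
        [
            Primer("P1", "J1", "ACGTACGTACGTACGTACGT", "signal"),
            Primer("P2", "J2", "TTTTGGGGCCCCAAAATTTT", "signal"),
        ]
    )

    def _pair(self, rid, seq):
        return (_read(rid, seq + "A" * 30), _read(rid, "A" * 50))

    def test_exact_match(self):
        bins, unassigned = demultiplex([self._pair("r1", "ACGTACGTACGTACGTACGT")], self.PRIMERS)
        assert len(bins["P1"]) == 1 and not unassigned

    def test_one_mismatch_assigned(self):
        bins, unassigned = demultiplex([self._pair("r1", "CCGTACGTACGTACGTACGT")], self.PRIMERS)
        assert len(bins["P1"]) == 1

    def test_equal_best_tie_unassigned(self):
        primers = PrimerSet(
            [
                Primer("P1", "J1", "AAAAACCCCC", "signal"),
                Primer("P2", "J2", "AAAAACCCCG", "signal"),
            ]
        )
        # one mismatch to each primer
        bins, unassigned = demultiplex([self._pair("r1", "AAAAACCCCT")], primers)
        assert len(unassigned) == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            PrimerSet([Primer("P", "J1", "AAAA", "signal"), Primer("P", "J2", "CCCC", "signal")])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [self._pair(f"r{i}", random_dna(rng, 20)) for i in range(30)]
        bins, unassigned = demultiplex(pairs, self.PRIMERS)
        assert sum(len(v) for v in bins.values()) + len(unassigned) == 30


class TestMergePair:
    def test_perfect_overlap_arithmetic(self):
        rng = np.random.default_rng(0)
        amp = random_dna(rng, 470)
        r1, r2 = _read("r", amp[:250]), _read("r", revcomp(amp[-250:]))
        merged = merge_pair(r1, r2)
        assert merged.merged and len(merged.sequence) == 470 and merged.overlap == 30
        assert merged.sequence == amp

    def test_zero_overlap_falls_back_to_read1(self):
        rng = np.random.default_rng(1)
        r1, r2 = _read("r", random_dna(rng, 100)), _read("r", random_dna(rng, 100))
        merged = merge_pair(r1, r2)
        assert not merged.merged
        assert merged.sequence == r1.sequence

    def test_quality_resolves_disagreements(self):
        base = "ACGTACGTACGTACGTACGTACGT"
        r1 = _read("r", base, "I" * 10 + "!" + "I" * 13)  # low quality at pos 10
        mutated = base[:10] + "T" + base[11:]
        r2 = _read("r", revcomp(mutated), "I" * 24)
        merged = merge_pair(r1, r2, min_overlap=20)
        assert merged.sequence[10] == "T"  # r2's higher-quality base wins

    def test_tie_prefers_read1_base(self):
        base = "ACGTACGTACGTACGTACGTACGT"
        mutated = base[:10] + "T" + base[11:]
        merged = merge_pair(_read("r", base), _read("r", revcomp(mutated)), min_overlap=20)
        assert merged.sequence[10] == base[10]

    def test_brute_force_overlap_oracle(self):
        # [DERIVED] exhaustive shift enumeration with the same scoring rule
        rng = np.random.default_rng(2)
        for _ in range(25):
            amp_len = int(rng.integers(120, 200))
            amp = random_dna(rng, amp_len)
            rl = 100
            s1 = amp[:rl]
            s2 = revcomp(amp[-rl:])
            # sprinkle errors
            s1 = "".join(
                c if rng.random() > 0.02 else "ACGT"[rng.integers(4)] for c in s1
            )
            merged = merge_pair(_read("r", s1), _read("r", s2))
            best = None
            rc2 = revcomp(s2)
            for o in range(20, min(len(s1), len(rc2)) + 1):
                mism = sum(a != b for a, b in zip(s1[-o:], rc2[:o]))
                if mism > 0.1 * o:
                    continue
                score = o - 2 * mism
                if best is None or score > best[0] or (score == best[0] and o > best[1]):
                    best = (score, o)
            if best is None:
                assert not merged.merged
            else:
                assert merged.overlap == best[1]


@pytest.fixture(scope="module")
def small_db():
    locus = build_locus(toy_config(seed=4))
    return enumerate_junctions(locus)


@pytest.fixture(scope="module")
def index(small_db):
    return JunctionIndex(small_db, kind="signal")


class TestAssignment:

    def test_error_free_read(self, small_db, index):
        entry = small_db.signal_entries()[0]
        result = assign_junction(entry.sequence, index)
        assert result.status == "assigned"
        assert result.junction_id == entry.junction_id
        assert result.identity == 1.0

    def test_random_sequence_unassigned(self, index):
        rng = np.random.default_rng(5)
        result = assign_junction(random_dna(rng, 120), index)
        assert result.junction_id is None

    def test_one_sided_read_unassigned(self, small_db, index):
        # a read covering only the shared J flank must not be called
        entry = small_db.signal_entries()[0]
        j_side_only = entry.sequence[: entry.junction_offset]
        result = assign_junction(j_side_only, index)
        assert result.status != "assigned"

    def test_biopython_exhaustive_oracle(self, small_db, index):
        # [DERIVED] full Smith-Waterman against every entry via Biopython
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )
        rng = np.random.default_rng(6)
        entries = small_db.signal_entries()
        for trial in range(25):
            entry = entries[trial % len(entries)]
            read = "".join(
                c if rng.random() > 0.02 else "ACGT"[rng.integers(4)]
                for c in entry.sequence
            )
            result = assign_junction(read, index)
            scores = {e.junction_id: aligner.score(e.sequence, read) for e in entries}
            best = max(scores, key=scores.get)
            assert result.junction_id == best == entry.junction_id
            assert result.score == scores[best]

    def test_inversional_reads_never_hit_signal_entries(self):
        # signal database is deletional-only; coding reads from an
        # inversional event must not be assigned to any signal entry
        cfg = toy_config(seed=8, kde=False)
        cfg["segments"][0]["orientation"] = "-"  # V1 inverted
        locus = build_locus(cfg)
        db = enumerate_junctions(locus)
        inv = [e for e in db.coding_entries() if e.topology == "inversional"]
        assert inv
        index = JunctionIndex(db, kind="signal")
        for entry in inv:
            result = assign_junction(entry.sequence, index)
            assert result.status != "assigned"

    def test_empty_database_rejected(self, small_db):
        from escirc.locus_model import JunctionDatabase

        with pytest.raises(ValueError):
            JunctionIndex(JunctionDatabase(entries=[]), kind="signal")


class TestBandedAligner:
    def test_exact_substring(self):
        res = banded_local_align("CGTACG", "AACGTACGAA", -10, 10)
        assert res.score == 6 and res.identity == 1.0
        assert (res.ref_start, res.ref_end) == (2, 8)

    def test_band_restriction(self):
        # the true alignment lies outside the band -> weaker or no result
        res = banded_local_align("CGTACG", "AACGTACGAA", 4, 6)
        assert res is None or res.score < 6


class TestQuantify:
    def _assignments(self, counts, extra_unassigned=0):
        from escirc.lam_junction_caller import Assignment

        out = []
        i = 0
        for jid, c in counts.items():
            for _ in range(c):
                out.append(Assignment(f"r{i}", jid, "assigned"))
                i += 1
        for _ in range(extra_unassigned):
            out.append(Assignment(f"r{i}", None, "unassigned"))
            i += 1
        return out

    def test_formula(self):
        table = quantify(self._assignments({"j": 50}, extra_unassigned=950), "e", "signal")
        assert table.iloc[0]["normalized_reads"] == 0.05

    def test_scale_invariance(self):
        t1 = quantify(self._assignments({"a": 10, "b": 30}), "e", "signal")
        t2 = quantify(self._assignments({"a": 20, "b": 60}), "e", "signal")
        assert np.allclose(t1["normalized_reads"], t2["normalized_reads"])

    def test_normalized_sums_below_one(self):
        table = quantify(self._assignments({"a": 5, "b": 7}, extra_unassigned=3), "e", "signal")
        assert 0 < table["normalized_reads"].sum() <= 1

    def test_assigned_only_mode(self):
        table = quantify(
            self._assignments({"a": 5}, extra_unassigned=5), "e", "signal", assigned_only=True
        )
        assert table.iloc[0]["normalized_reads"] == 1.0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            quantify([], "e", "signal")


class TestThreshold:
    def _table(self, values, eid="ctrl"):
        return pd.DataFrame(
            {
                "junction_id": [f"j{i}" for i in range(len(values))],
                "raw_reads": [1] * len(values),
                "normalized_reads": values,
                "above_threshold": pd.NA,
                "experiment_id": eid,
                "assay": "signal",
            }
        )

    def test_boundary_strict(self):
        model = fit_threshold({"c1": self._table([0.001, 0.003])})
        assert model.threshold == 0.003
        applied = apply_threshold(self._table([0.003, 0.0031], eid="s"), model)
        assert applied["above_threshold"].tolist() == [False, True]

    def test_adding_control_only_raises(self):
        m1 = fit_threshold({"c1": self._table([0.002])})
        m2 = fit_threshold({"c1": self._table([0.002]), "c2": self._table([0.004])})
        assert m2.threshold >= m1.threshold

    def test_controls_self_consistent(self):
        controls = {"c1": self._table([0.001, 0.005]), "c2": self._table([0.002])}
        model = fit_threshold(controls)
        for table in controls.values():
            assert not apply_threshold(table, model)["above_threshold"].any()

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold({})


class TestEndToEnd:
    def test_twenty_junctions_recovered(self):
        # 20 junctions at distinct copy numbers, 0.5% error: all called,
        # Spearman(normalized reads, truth copies) >= 0.95
        from scipy.stats import spearmanr

        segs = [{"name": f"V{i:02d}", "kind": "V", "spacer_class": 12} for i in range(1, 11)]
        segs += [{"name": f"J{i}", "kind": "J", "spacer_class": 23} for i in range(1, 3)]
        locus = build_locus({"seed": 2, "name": "L", "segments": segs})
        db = enumerate_junctions(locus)
        sigs = [e.junction_id for e in db.signal_entries()][:20]
        copies = {sid: round(10 * 1.2**i) for i, sid in enumerate(sigs)}
        truth = manual_truth(db, copies, seed=5, lam_n_reads=3000, seq_error_rate=0.005)
        primers = design_primers(db, "signal")
        pairs, _ = simulate_lam_reads(truth, db, primers, truth.config, assay="signal")
        table, report = run_lam_pipeline(pairs, primers, db, "e2e", "signal")
        assert set(table["junction_id"]) == set(sigs)
        merged = table.set_index("junction_id").join(pd.Series(copies, name="truth"))
        rho = spearmanr(merged["normalized_reads"], merged["truth"]).statistic
        assert rho >= 0.95
        # no reads invented: every input pair accounted for exactly once
        assert (
            report["n_assigned"] + report["n_align_unassigned"] + report["n_ambiguous"]
            == report["n_pairs"] - report["n_demux_unassigned"]
        )
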