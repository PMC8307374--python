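import numpy as np
import pytest

from pttsminer.architecture import (ArchitectureLabel, DomainCall,
                                    DomainCallParams, LengthWindow,
                                    call_domains, classify_architecture,
                                    filter_candidates, make_candidate,
                                    read_external_domains)
from pttsminer.io import ProteinRecord
from pttsminer.motifs import MotifHit, scan_all
from pttsminer.simulate import (DECOY_KINDS, SimConfig, generate_decoy,
                                generate_proteome, generate_ptts)


def _zbss_like_record():
    """A ~700 aa chimera with the motif geometry reported for the
    characterized Z. brevis sesterevisene synthase (anchors at 95, 230,
    487 and 614)."""
    config = SimConfig(seed=11, motif_offsets=(95, 230, 487, 614),
                       ptts_length_range=(700, 700))
    return generate_ptts(config, config.rng(), rec_id="zbss_like")


class TestCallDomains:
    def test_characterized_motif_geometry(self):
        record, _ = _zbss_like_record()
        calls = {c.kind: c for c in call_domains(record)}
        assert (calls["TS"].start, calls["TS"].end) == (95, 238)
        assert (calls["PT"].start, calls["PT"].end) == (487, 618)

    def test_triad_required_for_ts_call(self):
        rec = ProteinRecord("r", "A" * 50 + "DDYYE" + "A" * 400)
        calls = call_domains(rec)
        assert all(c.kind != "TS" for c in calls)

    def test_two_pt_motifs_required(self):
        rec = ProteinRecord("r", "A" * 50 + "DDYQN" + "A" * 400)
        assert all(c.kind != "PT" for c in call_domains(rec))

    def test_pt_motifs_too_close_not_called(self):
        seq = "A" * 50 + "DDYQN" + "A" * 5 + "DDIEN" + "A" * 400
        assert call_domains(ProteinRecord("r", seq)) == []

    def test_widest_pt_pair_chosen_among_many(self):
        seq = ("A" * 50 + "DDAAN" + "A" * 40 + "DDCCN" + "A" * 40
               + "DDEEN" + "A" * 300)
        calls = call_domains(ProteinRecord("r", seq))
        pt = next(c for c in calls if c.kind == "PT")
        assert (pt.start, pt.end) == (51, 145)  # first and third motif

    def test_calls_match_planted_anchors_on_synthetic_cohort(self):
        config = SimConfig(seed=3, n_ptts=60)
        rng = config.rng()
        for i in range(config.n_ptts):
            rec, truth = generate_ptts(config, rng, rec_id=f"p{i}")
            calls = {c.kind: c for c in call_domains(rec)}
            assert calls["TS"].start == truth.ts_dde_start
            assert calls["TS"].end == truth.ts_triad_start + 8
            assert calls["PT"].start == truth.pt_first_start
            assert calls["PT"].end == truth.pt_second_start + 4


class TestClassifyArchitecture:
    def test_chimera_label(self):
        record, _ = _zbss_like_record()
        assert classify_architecture(record) is ArchitectureLabel.PTTS

    def test_order_rule(self):
        ts = DomainCall("TS", 300, 500, ())
        pt = DomainCall("PT", 10, 200, ())
        rec = ProteinRecord("r", "A" * 500)
        label = classify_architecture(rec, calls=[ts, pt], classii_hits=[])
        assert label is ArchitectureLabel.WRONG_ORDER_CHIMERA

    def test_overlapping_calls_are_ambiguous(self):
        ts = DomainCall("TS", 50, 300, ())
        pt = DomainCall("PT", 250, 450, ())
        rec = ProteinRecord("r", "A" * 500)
        assert classify_architecture(rec, [ts, pt], []) is ArchitectureLabel.NONE

    def test_classii_annotation_without_class_i_calls(self):
        rec = ProteinRecord("r", "A" * 20)
        hit = MotifHit("CLASSII_DXDD", 5, "DKDD")
        assert classify_architecture(rec, [], [hit]) is ArchitectureLabel.CLASSII_TS

    def test_dxdd_never_excludes_a_chimera(self):
        record, _ = _zbss_like_record()
        hits = scan_all(record)
        calls = call_domains(record, hits)
        label = classify_architecture(
            record, calls, [MotifHit("CLASSII_DXDD", 400, "DADD")])
        assert label is ArchitectureLabel.PTTS

    @pytest.mark.parametrize("kind,expected", [
        ("TS_only", ArchitectureLabel.TS_ONLY),
        ("PT_only", ArchitectureLabel.PT_ONLY),
        ("classII_TS", ArchitectureLabel.CLASSII_TS),
        ("wrong_order", ArchitectureLabel.WRONG_ORDER_CHIMERA),
        ("random", ArchitectureLabel.NONE),
    ])
    def test_decoys_classified_by_construction(self, kind, expected):
        config = SimConfig(seed=5)
        rng = config.rng()
        for i in range(5):
            rec, _ = generate_decoy(kind, config, rng, rec_id=f"{kind}{i}")
            assert classify_architecture(rec) is expected


class TestFilterCandidates:
    def _cand(self, length, seed=0):
        config = SimConfig(seed=seed, ptts_length_range=(length, length),
                           motif_offsets=(30, 120, 200, 240))
        rec, _ = generate_ptts(config, config.rng(), rec_id=f"len{length}")
        return make_candidate(rec, call_domains(rec))

    def test_window_membership(self):
        cands = [self._cand(n) for n in (300, 700, 1500)]
        kept = filter_candidates(cands)
        assert [c.length for c in kept] == [700]
        assert [c.length_pass for c in cands] == [False, True, False]

    @pytest.mark.parametrize("length,kept", [(500, True), (1100, True),
                                             (499, False), (1101, False)])
    def test_closed_interval_boundaries(self, length, kept):
        assert (len(filter_candidates([self._cand(length)])) == 1) is kept

    def test_bad_window_is_configuration_error(self):
        with pytest.raises(ValueError):
            LengthWindow(800, 500)

    def test_planted_length_outliers_removed_exactly(self):
        config = SimConfig(seed=9, n_ptts=10, n_decoys_per_kind=5)
        rng = config.rng()
        cands = []
        outlier_ids = set()
        for i in range(config.n_ptts):
            rec, _ = generate_ptts(config, rng, rec_id=f"p{i}")
            cands.append(make_candidate(rec, call_domains(rec)))
        for i in range(config.n_decoys_per_kind):
            rec, _ = generate_decoy("length_outlier", config, rng,
                                    rec_id=f"out{i}")
            outlier_ids.add(rec.id)
            cands.append(make_candidate(rec, call_domains(rec)))
        kept = filter_candidates(cands)
        assert {c.record.id for c in kept} == {f"p{i}" for i in range(10)}
        assert all(c.record.id in outlier_ids
                   for c in cands if not c.length_pass)


class TestInvariants:
    def test_planted_architecture_recovery_is_exact(self):
        """Precision and recall of the PTTS label are 1.0 on a noise-free
        synthetic proteome."""
        config = SimConfig(seed=21, n_ptts=30, n_decoys_per_kind=6)
        records, truths = generate_proteome(config)
        for rec, truth in zip(records, truths):
            got = classify_architecture(rec).value
            assert got == truth.label, (rec.id, got, truth.label)

    def test_motif_knockout_never_creates_chimeras(self, rng):
        """Randomly mutating required motif residues never increases the
        number of PTTS labels (monotone degradation)."""
        config = SimConfig(seed=33, n_ptts=15, n_decoys_per_kind=0)
        records, truths = generate_proteome(config)
        baseline = sum(
            classify_architecture(r) is ArchitectureLabel.PTTS for r in records)
        for frac in (0.3, 1.0):
            mutated = []
            for rec, truth in zip(records, truths):
                chars = list(rec.sequence)
                for start, end in truth.motif_intervals:
                    for i in range(start - 1, end):
                        if rng.random() < frac:
                            chars[i] = "A"
                mutated.append(ProteinRecord(rec.id, "".join(chars)))
            n_ptts = sum(
                classify_architecture(r) is ArchitectureLabel.PTTS
                for r in mutated)
            assert n_ptts <= baseline
            baseline = n_ptts


def test_external_domain_hook_roundtrip(tmp_path):
    p = tmp_path / "domains.tsv"
    p.write_text("record_id\tdomain_name\tstart\tend\n"
                 "q1\tTS\t95\t238\nq1\tPT\t487\t618\n")
    calls = read_external_domains(p)
    rec = ProteinRecord("q1", "A" * 700)
    assert classify_architecture(rec, calls["q1"], []) is ArchitectureLabel.PTTS
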