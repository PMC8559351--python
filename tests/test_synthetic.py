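"""Synthetic proteome generation, ground truth, and recovery scoring."""

import numpy as np
import pytest

from annocheck import (
    SyntheticSpec,
    evaluate_recovery,
    generate_proteome,
    sample_motif_instance,
    scan,
    validate_all,
    write_fasta,
)
from annocheck.motifs import parse_pattern
from annocheck.simulate import ConsistencyError, GenerationError, SyntheticSpecError


class TestSampleMotifInstance:
    def test_forced_positions(self, rng):
        pat = parse_pattern("D-x-D")
        for _ in range(20):
            s = sample_motif_instance(pat, rng)
            assert len(s) == 3 and s[0] == "D" and s[2] == "D"

    def test_single_choice_point_enumeration(self, rng):
        pat = parse_pattern("W-R-K-Y-G-[QK]-K")
        seen = {sample_motif_instance(pat, rng) for _ in range(100)}
        assert seen == {"WRKYGQK", "WRKYGKK"}

    def test_ef_hand_samples_accepted_by_scanner(self, patterns, rng):
        pat = patterns["EF_HAND"]
        for _ in range(50):
            s = sample_motif_instance(pat, rng)
            assert [(m.start, m.end) for m in scan(pat, s)] == [(1, len(s))]

    def test_impossible_excluded_set_is_generation_error(self, rng):
        pat = parse_pattern("{ACDEFGHIKLMNPQRSTVWY}")
        with pytest.raises(GenerationError):
            sample_motif_instance(pat, rng)


class TestSpecValidation:
    def test_rates_must_be_fractions(self):
        with pytest.raises(SyntheticSpecError, match="mislabel_rate"):
            SyntheticSpec(families={"CAM": 1}, mislabel_rate=1.5)

    def test_background_must_sum_to_one(self):
        with pytest.raises(SyntheticSpecError, match="sum"):
            SyntheticSpec(families={"CAM": 1}, background_frequencies={"A": 0.5})

    def test_unknown_family_rejected(self):
        with pytest.raises(SyntheticSpecError, match="unknown family"):
            SyntheticSpec(families={"KRAKEN": 1})

    def test_length_range_too_short_fails_before_output(self):
        spec = SyntheticSpec(families={"CDPK": 1}, length_range=(40, 50))
        with pytest.raises(SyntheticSpecError, match="length_range"):
            generate_proteome(spec)


class TestGeneration:
    def test_clean_cam_corpus_all_consistent(self, lexicons, ruleset, patterns):
        spec = SyntheticSpec(families={"CAM": 10}, seed=7)
        proteome, manifest = generate_proteome(spec, patterns, lexicons)
        assert len(proteome.records) == 10
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        cam = [v for v in verdicts if v.family_id == "CAM"]
        assert len(cam) == 10
        assert all(v.status == "CONSISTENT" for v in cam)
        assert not any(e.is_mislabeled or e.is_knockout for e in manifest.entries)

    def test_full_selenoprotein_knockout(self, lexicons, ruleset, patterns):
        spec = SyntheticSpec(families={"SELENOPROTEIN": 5}, motif_knockout_rate=1.0, seed=3)
        proteome, _ = generate_proteome(spec, patterns, lexicons)
        assert all("U" not in r.sequence for r in proteome.records)
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        assert len(verdicts) == 5
        assert all(v.status == "INCONSISTENT" for v in verdicts)

    def test_planted_motifs_found_at_recorded_positions(self, patterns):
        spec = SyntheticSpec(
            families={"CDPK": 3, "CAM": 3, "WRKY": 3, "LEGHEMOGLOBIN": 3,
                      "SELENOPROTEIN": 3, "TERPENE": 3},
            seed=13,
        )
        proteome, manifest = generate_proteome(spec)
        seqs = {r.accession: r.sequence for r in proteome.records}
        for entry in manifest.entries:
            seq = seqs[entry.accession]
            for pid, start in entry.planted_motifs:
                if pid == "SEC_U":
                    assert seq[start - 1] == "U"
                elif patterns[pid].anchored_n:
                    assert any(m.start == 1 for m in scan(patterns[pid], seq[start - 1:]))
                else:
                    assert any(m.start == start for m in scan(patterns[pid], seq))

    def test_determinism_byte_identical(self, tmp_path):
        spec = SyntheticSpec(families={"CAM": 5, "WRKY": 5}, mislabel_rate=0.2,
                             motif_knockout_rate=0.2, seed=42)
        out = []
        for name in ("a", "b"):
            proteome, manifest = generate_proteome(spec)
            fasta = tmp_path / f"{name}.fasta"
            tsv = tmp_path / f"{name}.tsv"
            write_fasta(proteome.records, fasta)
            manifest.write_tsv(tsv)
            out.append((fasta.read_bytes(), tsv.read_bytes()))
        assert out[0] == out[1]

    def test_streams_stable_under_other_family_count_changes(self):
        small, _ = generate_proteome(SyntheticSpec(families={"CAM": 3, "WRKY": 2}, seed=5))
        large, _ = generate_proteome(SyntheticSpec(families={"CAM": 3, "WRKY": 9}, seed=5))
        cam_small = [r.sequence for r in small.records if "CAM" in r.accession]
        cam_large = [r.sequence for r in large.records if "CAM" in r.accession]
        assert cam_small == cam_large

    def test_mislabels_recorded_and_labels_differ(self):
        spec = SyntheticSpec(families={"CAM": 40}, mislabel_rate=0.5, seed=9)
        _, manifest = generate_proteome(spec)
        flipped = [e for e in manifest.entries if e.is_mislabeled]
        assert flipped, "expected some mislabels at rate 0.5"
        assert all(e.label_family != e.true_family for e in flipped)
        kept = [e for e in manifest.entries if not e.is_mislabeled]
        assert all(e.label_family == e.true_family for e in kept)

    def test_knockout_fraction_within_binomial_band(self, lexicons, ruleset, patterns):
        n, p = 400, 0.3
        spec = SyntheticSpec(families={"CAM": n}, motif_knockout_rate=p, seed=77)
        proteome, manifest = generate_proteome(spec, patterns, lexicons)
        verdicts = [v for v in validate_all(proteome.records, lexicons, ruleset, patterns)
                    if v.family_id == "CAM"]
        frac = sum(v.status == "INCONSISTENT" for v in verdicts) / n
        sigma = (p * (1 - p) / n) ** 0.5
        assert abs(frac - p) <= 3 * sigma
        # the flagged set is exactly the knocked-out set
        flagged = {v.accession for v in verdicts if v.status == "INCONSISTENT"}
        assert flagged == {e.accession for e in manifest.entries if e.is_knockout}


class TestRecovery:
    def _corpus(self, knockout):
        spec = SyntheticSpec(families={"CAM": 30, "WRKY": 30},
                             motif_knockout_rate=knockout, seed=21)
        return generate_proteome(spec)

    def test_perfect_detection_on_knockout_corpus(self, lexicons, ruleset, patterns):
        proteome, manifest = self._corpus(0.4)
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        metrics = evaluate_recovery(verdicts, manifest)
        assert metrics["pooled"]["precision"] == 1.0
        assert metrics["pooled"]["recall"] == 1.0

    def test_clean_corpus_has_undefined_precision_and_recall(self, lexicons, ruleset, patterns):
        proteome, manifest = self._corpus(0.0)
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        metrics = evaluate_recovery(verdicts, manifest)
        assert metrics["pooled"]["fp"] == 0 and metrics["pooled"]["tp"] == 0
        assert metrics["pooled"]["precision"] is None
        assert metrics["pooled"]["recall"] is None

    def test_blind_detector_has_zero_recall(self, lexicons, ruleset, patterns):
        import dataclasses

        proteome, manifest = self._corpus(0.4)
        verdicts = [
            dataclasses.replace(v, status="CONSISTENT", failures=())
            for v in validate_all(proteome.records, lexicons, ruleset, patterns)
        ]
        metrics = evaluate_recovery(verdicts, manifest)
        assert metrics["pooled"]["recall"] == 0.0

    def test_scoring_is_deterministic(self, lexicons, ruleset, patterns):
        proteome, manifest = self._corpus(0.2)
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        assert evaluate_recovery(verdicts, manifest) == evaluate_recovery(verdicts, manifest)

    def test_missing_verdict_is_consistency_error(self, lexicons, ruleset, patterns):
        proteome, manifest = self._corpus(0.0)
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        with pytest.raises(ConsistencyError):
            evaluate_recovery(verdicts[:-5], manifest)
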