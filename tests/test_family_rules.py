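"""Family architecture rules and claim validation."""

import pytest

from annocheck import (
    AnnotationClaim,
    ProteinRecord,
    SyntheticSpec,
    check_nterminal_myristoylation,
    contains_selenocysteine,
    count_nonoverlapping,
    generate_proteome,
    validate,
)
from annocheck.rules import load_rules

EF_LOOP = "DKDGDGTITTKEL"


def _record(description, sequence, accession="T_1"):
    return ProteinRecord(accession, description, "Fungus a", sequence)


def _claim(family, accession="T_1"):
    return AnnotationClaim(accession, family, "term", (0, 4))


def _with_loops(n, pad=15):
    return ("A" * pad).join([""] + [EF_LOOP] * n + [""])


class TestDefaultRules:
    def test_cam_requires_exactly_four_ef_hands(self, ruleset):
        (group,) = ruleset["CAM"].motif_groups
        (req,) = group.members
        assert (req.pattern_id, req.min_count, req.max_count) == ("EF_HAND", 4, 4)

    def test_selenoprotein_requires_one_sec(self, ruleset):
        (rr,) = ruleset["SELENOPROTEIN"].residue_requirements
        assert (rr.residue, rr.min_count) == ("U", 1)

    def test_wrky_requires_core_heptapeptide(self, ruleset):
        (group,) = ruleset["WRKY"].motif_groups
        assert group.members[0].pattern_id == "WRKY_CORE"
        assert group.members[0].min_count == 1

    def test_cdpk_kinase_alternative_group(self, ruleset):
        labels = [g.label for g in ruleset["CDPK"].motif_groups]
        assert "KINASE_ATP|KINASE_ST_ACTIVE" in labels
        assert "EF_HAND" in labels
        assert "MYRISTOYL" in labels

    def test_terpene_rule_is_advisory(self, ruleset):
        assert ruleset["TERPENE"].advisory


@pytest.mark.parametrize("seq, n", [("MKVU", 1), ("MKVC", 0), ("UU", 2)])
def test_contains_selenocysteine(seq, n):
    assert contains_selenocysteine(seq) == n


class TestMyristoylation:
    def test_after_met_removal(self, patterns):
        # G at new position 1; N, A, C fill the consensus; fifth residue not P
        assert check_nterminal_myristoylation("MGNACSKLM", patterns)

    def test_no_glycine_at_either_anchor(self, patterns):
        assert not check_nterminal_myristoylation("MDELKKQW", patterns)

    def test_without_met_removal(self, patterns):
        assert check_nterminal_myristoylation("GQTASKLM", patterns)

    def test_short_sequence_is_false_not_error(self, patterns):
        assert not check_nterminal_myristoylation("GQTA", patterns)


class TestValidate:
    def test_cam_with_four_loops_is_consistent(self, ruleset, patterns):
        record = _record("calmodulin", _with_loops(4))
        verdict = validate(record, _claim("CAM"), ruleset, patterns)
        assert verdict.status == "CONSISTENT"
        assert verdict.failures == ()
        assert verdict.observed["EF_HAND"] == 4

    def test_cam_with_two_loops_is_inconsistent(self, ruleset, patterns):
        record = _record("calmodulin", _with_loops(2))
        verdict = validate(record, _claim("CAM"), ruleset, patterns)
        assert verdict.status == "INCONSISTENT"
        (failure,) = verdict.failures
        assert (failure.requirement, failure.observed, failure.required) == (
            "EF_HAND", 2, "4..4",
        )

    def test_selenoprotein_without_sec_is_inconsistent(self, ruleset, patterns):
        record = _record("selenocysteine-specific elongation factor", "M" + "K" * 60)
        verdict = validate(record, _claim("SELENOPROTEIN"), ruleset, patterns)
        assert verdict.status == "INCONSISTENT"
        (failure,) = verdict.failures
        assert failure.requirement == "residue:U"
        assert failure.observed == 0

    def test_cdpk_with_kinase_but_no_ef_hands_is_inconsistent(self, ruleset, patterns):
        """A kinase that binds no calcium is not a calcium-dependent kinase."""
        kinase = "LAHADLKAANILL"  # satisfies the Ser/Thr active-site signature
        seq = "MGNACSK" + "A" * 20 + kinase + "A" * 40
        record = _record("calcium dependent protein kinase", seq)
        verdict = validate(record, _claim("CDPK"), ruleset, patterns)
        assert verdict.status == "INCONSISTENT"
        assert verdict.observed["EF_HAND"] == 0
        assert verdict.observed["KINASE_ST_ACTIVE"] >= 1
        assert any(
            f.requirement == "EF_HAND" and f.observed == 0 and f.required == "4..4"
            for f in verdict.failures
        )

    def test_missing_family_rule_gives_indeterminate(self, ruleset, patterns):
        record = _record("calcium calmodulin dependent protein kinase", "MKL")
        verdict = validate(record, _claim("CAMK"), ruleset, patterns)
        assert verdict.status == "INDETERMINATE"
        assert verdict.failures == ()

    def test_accession_mismatch_raises(self, ruleset, patterns):
        record = _record("calmodulin", "MKL", accession="A")
        with pytest.raises(ValueError, match="accession"):
            validate(record, _claim("CAM", accession="B"), ruleset, patterns)

    def test_observed_counts_match_independent_scan(self, ruleset, patterns):
        record = _record("calmodulin", _with_loops(3))
        verdict = validate(record, _claim("CAM"), ruleset, patterns)
        assert verdict.observed["EF_HAND"] == count_nonoverlapping(
            patterns["EF_HAND"], record.sequence
        )


class TestPlantedTruth:
    """Soundness and completeness of validation on constructed records."""

    def test_soundness_on_clean_synthetic_families(self, ruleset, patterns, lexicons):
        from annocheck import validate_all

        spec = SyntheticSpec(
            families={"CDPK": 5, "CAM": 5, "CML": 5, "SELENOPROTEIN": 5,
                      "WRKY": 5, "LEGHEMOGLOBIN": 5, "TERPENE": 5},
            seed=101,
        )
        proteome, _ = generate_proteome(spec, patterns, lexicons)
        verdicts = validate_all(proteome.records, lexicons, ruleset, patterns)
        assert verdicts, "every synthetic record should be claimed"
        assert all(v.status == "CONSISTENT" for v in verdicts)

    def test_completeness_removing_one_loop_names_the_requirement(self, ruleset, patterns):
        record = _record("calmodulin", _with_loops(3))
        verdict = validate(record, _claim("CAM"), ruleset, patterns)
        assert verdict.status == "INCONSISTENT"
        assert [f.requirement for f in verdict.failures] == ["EF_HAND"]


def test_ruleset_file_round_trip(tmp_path, patterns):
    path = tmp_path / "rules.yaml"
    path.write_text(
        "CAM:\n"
        "  motifs:\n"
        "    - {pattern: EF_HAND, min: 2}\n"
        "SELENOPROTEIN:\n"
        "  residues:\n"
        "    - {residue: U, min: 1}\n"
    )
    rules = load_rules(path)
    record = _record("calmodulin", _with_loops(2))
    verdict = validate(record, _claim("CAM"), rules, patterns)
    assert verdict.status == "CONSISTENT"  # looser user policy: >=2 loops
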