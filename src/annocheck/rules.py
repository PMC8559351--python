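"""Family architecture rules and claim validation.

Each screened family carries a :class:`FamilyRule`: motif-count requirements
(possibly grouped as alternatives, e.g. either protein-kinase signature),
positional requirements (N-terminal myristoylation) and residue requirements
(selenocysteine for selenoproteins). ``validate`` scores one annotation claim
against its family's rule and returns a :class:`ValidationVerdict` with
machine-readable failure reasons and the observed motif counts, so users can
re-threshold (e.g. accept >= 2 EF-hands) without re-scanning.

Default rules reflect the canonical architectures:

* CDPK — kinase signature (ATP-binding or Ser/Thr active site), exactly four
  EF-hand loops in the regulatory domain, and an N-terminal myristoylation
  site. Fungi legitimately lack this family; fungal proteins labelled CDPK
  are expected to fail the EF-hand requirement.
* CaM / CML — exactly four EF-hands (the calcium-sensor consensus).
* Selenoprotein — at least one Sec (U) residue.
* WRKY — the WRKYG[QK]K core heptapeptide.
* Leghemoglobin — a globin proximal-histidine motif.
* Terpene synthase — the DDxx[DE] metal-binding motif; advisory only, since
  a single short motif is weak evidence either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .io import ProteinRecord
from .lexicon import AnnotationClaim
from .motifs import MotifPattern, count_nonoverlapping, default_patterns, scan

UNBOUNDED = math.inf


@dataclass(frozen=True)
class MotifRequirement:
    """Count constraint on one pattern, optionally position-restricted."""

    pattern_id: str
    min_count: int = 1
    max_count: float = UNBOUNDED
    positional: str = "none"  # "none" | "n_terminal"

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_count > self.max_count:
            raise ValueError(f"{self.pattern_id}: bad count range")
        if self.positional not in ("none", "n_terminal"):
            raise ValueError(f"{self.pattern_id}: bad positional {self.positional!r}")

    @property
    def range_text(self) -> str:
        if self.max_count == UNBOUNDED:
            return f">={self.min_count}"
        return f"{self.min_count}..{int(self.max_count)}"


@dataclass(frozen=True)
class RequirementGroup:
    """Alternative motif requirements; satisfied when any member is met."""

    members: tuple[MotifRequirement, ...]

    @property
    def label(self) -> str:
        return "|".join(m.pattern_id for m in self.members)


@dataclass(frozen=True)
class ResidueRequirement:
    residue: str
    min_count: int = 1


@dataclass(frozen=True)
class FamilyRule:
    family_id: str
    motif_groups: tuple[RequirementGroup, ...] = ()
    residue_requirements: tuple[ResidueRequirement, ...] = ()
    advisory: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.motif_groups and not self.residue_requirements:
            raise ValueError(f"{self.family_id}: rule needs at least one requirement")

    def pattern_ids(self) -> list[str]:
        return [m.pattern_id for g in self.motif_groups for m in g.members]


@dataclass(frozen=True)
class RequirementFailure:
    requirement: str
    observed: int
    required: str


@dataclass(frozen=True)
class ValidationVerdict:
    accession: str
    family_id: str
    status: str  # CONSISTENT | INCONSISTENT | INDETERMINATE
    failures: tuple[RequirementFailure, ...] = ()
    observed: Mapping[str, int] = field(default_factory=dict)
    advisory: bool = False


def _req(pattern_id: str, min_count: int = 1, max_count: float = UNBOUNDED,
         positional: str = "none") -> RequirementGroup:
    return RequirementGroup((MotifRequirement(pattern_id, min_count, max_count, positional),))


def default_rules() -> dict[str, FamilyRule]:
    """The built-in ruleset. No rule exists for CAMK: a calmodulin-regulated
    kinase has no hallmark motif this engine can assert, so CAMK claims come
    back INDETERMINATE rather than pretending to a verdict."""
    return {
        "CDPK": FamilyRule(
            "CDPK",
            motif_groups=(
                RequirementGroup(
                    (
                        MotifRequirement("KINASE_ATP", 1),
                        MotifRequirement("KINASE_ST_ACTIVE", 1),
                    )
                ),
                _req("EF_HAND", 4, 4),
                _req("MYRISTOYL", 1, positional="n_terminal"),
            ),
            notes="kinase domain + regulatory domain with four EF-hands + N-terminal acylation",
        ),
        "CAM": FamilyRule("CAM", motif_groups=(_req("EF_HAND", 4, 4),),
                          notes="calmodulin consensus: four EF-hands"),
        "CML": FamilyRule("CML", motif_groups=(_req("EF_HAND", 4, 4),),
                          notes="calmodulin-like consensus: four EF-hands"),
        "SELENOPROTEIN": FamilyRule(
            "SELENOPROTEIN",
            residue_requirements=(ResidueRequirement("U", 1),),
            notes="must contain at least one selenocysteine",
        ),
        "WRKY": FamilyRule("WRKY", motif_groups=(_req("WRKY_CORE", 1),),
                           notes="WRKY domain core heptapeptide"),
        "LEGHEMOGLOBIN": FamilyRule(
            "LEGHEMOGLOBIN", motif_groups=(_req("GLOBIN_PROXHIS", 1),),
            notes="globin proximal-histidine motif",
        ),
        "TERPENE": FamilyRule(
            "TERPENE", motif_groups=(_req("TERPENE_DDXXD", 1),), advisory=True,
            notes="DDxx[DE] alone is weak evidence; verdicts are advisory",
        ),
    }


def contains_selenocysteine(sequence: str) -> int:
    """Number of Sec (U) residues in a cleaned sequence."""
    return sequence.count("U")


def check_nterminal_myristoylation(
    sequence: str, patterns: Mapping[str, MotifPattern] | None = None
) -> bool:
    """True iff the myristoylation consensus matches at the N-terminus.

    Both the raw N-terminus and the sequence after initiator-methionine
    removal are tested, since myristoylation follows Met excision in vivo.
    Sequences shorter than the motif cannot carry it and return False.
    """
    if patterns is None:
        patterns = default_patterns()
    pat = patterns["MYRISTOYL"]
    if len(sequence) < pat.min_length:
        return False
    if scan(pat, sequence):
        return True
    if sequence.startswith("M") and len(sequence) - 1 >= pat.min_length:
        return bool(scan(pat, sequence[1:]))
    return False


def validate(
    record: ProteinRecord,
    claim: AnnotationClaim,
    ruleset: Mapping[str, FamilyRule],
    patterns: Mapping[str, MotifPattern] | None = None,
) -> ValidationVerdict:
    """Evaluate one claim against its family's rule.

    Motif counts are non-overlapping occurrences; observed counts are
    populated for every pattern the rule references. A family absent from
    the ruleset yields an INDETERMINATE verdict, never an exception.
    """
    if claim.accession != record.accession:
        raise ValueError(
            f"claim accession {claim.accession!r} != record {record.accession!r}"
        )
    rule = ruleset.get(claim.family_id)
    if rule is None:
        return ValidationVerdict(record.accession, claim.family_id, "INDETERMINATE")
    if patterns is None:
        patterns = default_patterns()

    observed: dict[str, int] = {}
    failures: list[RequirementFailure] = []
    for group in rule.motif_groups:
        satisfied = False
        for member in group.members:
            if member.positional == "n_terminal":
                count = int(check_nterminal_myristoylation(record.sequence, patterns))
            else:
                count = count_nonoverlapping(patterns[member.pattern_id], record.sequence)
            observed[member.pattern_id] = count
            if member.min_count <= count <= member.max_count:
                satisfied = True
        if not satisfied:
            best = max(observed[m.pattern_id] for m in group.members)
            required = group.members[0].range_text
            failures.append(RequirementFailure(group.label, best, required))
    for rr in rule.residue_requirements:
        count = record.sequence.count(rr.residue)
        observed[f"residue:{rr.residue}"] = count
        if count < rr.min_count:
            failures.append(
                RequirementFailure(f"residue:{rr.residue}", count, f">={rr.min_count}")
            )

    status = "CONSISTENT" if not failures else "INCONSISTENT"
    return ValidationVerdict(
        record.accession, claim.family_id, status, tuple(failures), observed,
        advisory=rule.advisory,
    )


def validate_all(
    records: Iterable[ProteinRecord],
    lexicons,
    ruleset: Mapping[str, FamilyRule],
    patterns: Mapping[str, MotifPattern] | None = None,
) -> list[ValidationVerdict]:
    """Extract claims for each record and validate every one of them."""
    from .lexicon import extract_claims

    if patterns is None:
        patterns = default_patterns()
    verdicts: list[ValidationVerdict] = []
    for record in records:
        for claim in extract_claims(record, lexicons):
            verdicts.append(validate(record, claim, ruleset, patterns))
    return verdicts


def load_rules(path: str | Path) -> dict[str, FamilyRule]:
    """Load a ruleset from YAML.

    Schema::

        CAM:
          motifs:
            - pattern: EF_HAND          # or [KINASE_ATP, KINASE_ST_ACTIVE]
              min: 4
              max: 4                    # omit for unbounded
              positional: n_terminal    # optional
          residues:
            - residue: U
              min: 1
          advisory: false
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules: dict[str, FamilyRule] = {}
    for fid, block in raw.items():
        groups = []
        for m in block.get("motifs", []):
            pats = m["pattern"]
            if isinstance(pats, str):
                pats = [pats]
            members = tuple(
                MotifRequirement(
                    p,
                    int(m.get("min", 1)),
                    float(m["max"]) if "max" in m else UNBOUNDED,
                    m.get("positional", "none"),
                )
                for p in pats
            )
            groups.append(RequirementGroup(members))
        residues = tuple(
            ResidueRequirement(r["residue"], int(r.get("min", 1)))
            for r in block.get("residues", [])
        )
        rules[fid.upper()] = FamilyRule(
            fid.upper(),
            motif_groups=tuple(groups),
            residue_requirements=residues,
            advisory=bool(block.get("advisory", False)),
            notes=str(block.get("notes", "")),
        )
    return rules
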