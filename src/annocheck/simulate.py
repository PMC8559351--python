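"""Synthetic annotated proteomes with planted family architectures.

The generator emulates what the screen consumes in the wild: proteome FASTA
files whose deflines carry free-text family labels, some of which are wrong.
Each record is a random background sequence with the motifs of its true
family planted at non-overlapping positions; with configurable probability a
record is *mislabeled* (described as a different family) or suffers a
*knockout* (one required motif removed), giving exact ground truth for
recovery testing.

Every finished record is re-verified by rescanning all patterns of its true
family's rule: if planting created an accidental extra occurrence (or a
knockout left one behind), the record is regenerated from the same
per-record pseudo-random stream. Exact-count rules (four EF-hands) therefore
hold with probability 1 on clean corpora, and the manifest's planted
positions are guaranteed to be found by the scanner.

Background residue frequencies default to uniform over the 20 standard amino
acids, with Sec (U) excluded — accidental selenoproteins are impossible and
any U in a synthetic sequence is planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, ProteomeSet, write_fasta
from .lexicon import FamilyLexicon, default_lexicons
from .motifs import (
    STANDARD_AA,
    MotifPattern,
    count_nonoverlapping,
    default_patterns,
    scan,
)
from .rules import check_nterminal_myristoylation


class GenerationError(RuntimeError):
    """Raised when a valid record cannot be constructed."""


class SyntheticSpecError(ValueError):
    """Raised on an infeasible or inconsistent generator specification."""


#: Order in which families are emitted; also indexes per-record RNG streams.
GENERATOR_FAMILIES = (
    "CDPK",
    "CAM",
    "CML",
    "SELENOPROTEIN",
    "WRKY",
    "TERPENE",
    "LEGHEMOGLOBIN",
    "NONE",
)

#: Motifs planted per family (SELENOPROTEIN plants U residues instead).
_RECIPES: dict[str, tuple[str, ...]] = {
    "CDPK": ("MYRISTOYL", "KINASE_ST_ACTIVE", "EF_HAND", "EF_HAND", "EF_HAND", "EF_HAND"),
    "CAM": ("EF_HAND",) * 4,
    "CML": ("EF_HAND",) * 4,
    "SELENOPROTEIN": (),
    "WRKY": ("WRKY_CORE",),
    "TERPENE": ("TERPENE_DDXXD",),
    "LEGHEMOGLOBIN": ("GLOBIN_PROXHIS",),
    "NONE": (),
}

#: Families a mislabel may be drawn from. CAMK is deliberately absent: it has
#: no validation rule, so a CAMK mislabel could never be detected and would
#: only dilute recovery metrics.
_LABEL_FAMILIES = tuple(f for f in GENERATOR_FAMILIES if f != "NONE")


def _uniform_background() -> dict[str, float]:
    return {aa: 1.0 / len(STANDARD_AA) for aa in STANDARD_AA}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome."""

    families: Mapping[str, int]
    background_frequencies: Mapping[str, float] = field(default_factory=_uniform_background)
    length_range: tuple[int, int] = (150, 400)
    mislabel_rate: float = 0.0
    motif_knockout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for fam, n in self.families.items():
            if fam not in GENERATOR_FAMILIES:
                raise SyntheticSpecError(f"unknown family {fam!r}")
            if n < 0:
                raise SyntheticSpecError(f"{fam}: negative record count")
        total = sum(self.background_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticSpecError(f"background frequencies sum to {total}, not 1")
        for rate, name in (
            (self.mislabel_rate, "mislabel_rate"),
            (self.motif_knockout_rate, "motif_knockout_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise SyntheticSpecError(f"{name} must lie in [0,1], got {rate}")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SyntheticSpecError(f"bad length_range {self.length_range}")


@dataclass(frozen=True)
class ManifestEntry:
    accession: str
    true_family: str
    label_family: str
    planted_motifs: tuple[tuple[str, int], ...]  # (pattern_id, 1-based start)
    is_mislabeled: bool
    is_knockout: bool
    knocked_out: str = ""


@dataclass
class TruthManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def by_accession(self) -> dict[str, ManifestEntry]:
        return {e.accession: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession": e.accession,
                "true_family": e.true_family,
                "label_family": e.label_family,
                "mislabeled": int(e.is_mislabeled),
                "knockout": int(e.is_knockout),
                "knocked_out": e.knocked_out,
                "planted": ";".join(f"{pid}:{start}" for pid, start in e.planted_motifs),
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=["accession", "true_family", "label_family", "mislabeled",
                     "knockout", "knocked_out", "planted"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sample_motif_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Draw one string satisfying ``pattern``, uniform over element choices.

    Wildcards and excluded sets draw from the 20 standard residues, so a
    sampled instance never introduces ambiguity codes or Sec.
    """
    out: list[str] = []
    standard = sorted(STANDARD_AA)
    for el in pattern.elements:
        reps = int(rng.integers(el.min_repeat, el.max_repeat + 1))
        if el.kind == "wildcard":
            choices = standard
        elif el.kind == "residue_set":
            choices = sorted(el.residues)
        else:
            choices = sorted(set(STANDARD_AA) - el.residues)
            if not choices:
                raise GenerationError(
                    f"{pattern.pattern_id}: excluded set covers every standard residue"
                )
        out.extend(choices[int(rng.integers(len(choices)))] for _ in range(reps))
    return "".join(out)


def _min_length_needed(family: str, patterns: Mapping[str, MotifPattern]) -> int:
    recipe = _RECIPES[family]
    need = sum(patterns[pid].max_length for pid in recipe)
    if family == "CDPK":
        need += 1  # initiator Met preceding the myristoylation site
    if family == "SELENOPROTEIN":
        need += 3  # up to three planted Sec residues
    return need + 10  # placement slack


def _place(
    length: int,
    motif_len: int,
    reserved: list[tuple[int, int]],
    rng: np.random.Generator,
    lo: int = 0,
) -> tuple[int, int]:
    """Sample a non-overlapping 0-based interval for a motif, or raise."""
    if length - motif_len < lo:
        raise GenerationError("sequence too short to place motif")
    for _ in range(200):
        s = int(rng.integers(lo, length - motif_len + 1))
        iv = (s, s + motif_len)
        if all(iv[1] <= a or iv[0] >= b for a, b in reserved):
            reserved.append(iv)
            return iv
    raise GenerationError("could not place motif without overlap")


def _build_record(
    family: str,
    knocked: str,
    rng: np.random.Generator,
    spec: SyntheticSpec,
    patterns: Mapping[str, MotifPattern],
) -> tuple[str, tuple[tuple[str, int], ...]]:
    """One construction attempt: background + planted motifs (minus ``knocked``)."""
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    alphabet = list(spec.background_frequencies)
    probs = np.array([spec.background_frequencies[a] for a in alphabet])
    seq = list(rng.choice(alphabet, size=length, p=probs))

    recipe = list(_RECIPES[family])
    if knocked and knocked != "SEC_U":
        recipe.remove(knocked)
    reserved: list[tuple[int, int]] = []
    planted: list[tuple[str, int]] = []
    floor = 0
    if "MYRISTOYL" in recipe:
        # The acylation consensus sits directly after the initiator Met.
        instance = sample_motif_instance(patterns["MYRISTOYL"], rng)
        seq[0] = "M"
        seq[1 : 1 + len(instance)] = instance
        reserved.append((0, 1 + len(instance)))
        planted.append(("MYRISTOYL", 2))
        recipe.remove("MYRISTOYL")
        floor = 1 + len(instance)
    elif family == "CDPK":
        floor = 1  # keep knocked-out CDPKs from accidentally regaining the site

    for pid in recipe:
        instance = sample_motif_instance(patterns[pid], rng)
        s, e = _place(length, len(instance), reserved, rng, lo=floor)
        seq[s:e] = instance
        planted.append((pid, s + 1))

    if family == "SELENOPROTEIN" and knocked != "SEC_U":
        n_sec = int(rng.integers(1, 4))
        for _ in range(n_sec):
            s, _e = _place(length, 1, reserved, rng)
            seq[s] = "U"
            planted.append(("SEC_U", s + 1))

    planted.sort(key=lambda t: t[1])
    return "".join(seq), tuple(planted)


def _verify(
    family: str,
    sequence: str,
    planted: Sequence[tuple[str, int]],
    patterns: Mapping[str, MotifPattern],
) -> bool:
    """Exactness check: scan counts equal planted counts, at planted positions."""
    expected: dict[str, list[int]] = {}
    for pid, start in planted:
        expected.setdefault(pid, []).append(start)
    check_ids = set(_RECIPES[family])
    if family == "SELENOPROTEIN":
        n_u = len(expected.get("SEC_U", []))
        if sequence.count("U") != n_u:
            return False
    if family == "CDPK":
        check_ids.add("KINASE_ATP")  # alternative member must stay silent too
        has_myr = "MYRISTOYL" in expected
        if check_nterminal_myristoylation(sequence, patterns) != has_myr:
            return False
    check_ids.discard("MYRISTOYL")
    for pid in check_ids:
        starts = expected.get(pid, [])
        if count_nonoverlapping(patterns[pid], sequence) != len(starts):
            return False
        found = {m.start for m in scan(patterns[pid], sequence)}
        if not all(s in found for s in starts):
            return False
    return True


def generate_proteome(
    spec: SyntheticSpec,
    patterns: Mapping[str, MotifPattern] | None = None,
    lexicons: Mapping[str, FamilyLexicon] | None = None,
    species_name: str = "Synthetica simulata",
    phylum: str = "Ascomycota",
) -> tuple[ProteomeSet, TruthManifest]:
    """Generate one annotated proteome plus its ground-truth manifest.

    Fully reproducible: each record draws from its own stream derived from
    (spec.seed, family ordinal, index), so corpora are stable when counts of
    other families change.
    """
    if patterns is None:
        patterns = default_patterns()
    if lexicons is None:
        lexicons = default_lexicons()
    for fam, n in spec.families.items():
        if n > 0 and spec.length_range[0] < _min_length_needed(fam, patterns):
            raise SyntheticSpecError(
                f"{fam}: length_range minimum {spec.length_range[0]} cannot host "
                f"its required motifs (needs >= {_min_length_needed(fam, patterns)})"
            )

    records: list[ProteinRecord] = []
    manifest = TruthManifest()
    for fam in GENERATOR_FAMILIES:
        n = spec.families.get(fam, 0)
        ordinal = GENERATOR_FAMILIES.index(fam)
        for i in range(n):
            rng = np.random.default_rng([spec.seed, ordinal, i])
            accession = f"SYN_{fam}_{i + 1:05d}"

            is_mislabeled = bool(rng.random() < spec.mislabel_rate)
            has_requirements = _RECIPES[fam] or fam == "SELENOPROTEIN"
            is_knockout = bool(has_requirements and rng.random() < spec.motif_knockout_rate)

            knocked = ""
            if is_knockout:
                if fam == "SELENOPROTEIN":
                    knocked = "SEC_U"
                else:
                    options = list(_RECIPES[fam])
                    knocked = options[int(rng.integers(len(options)))]

            if is_mislabeled:
                others = [f for f in _LABEL_FAMILIES if f != fam]
                label = others[int(rng.integers(len(others)))]
            else:
                label = fam

            sequence = ""
            planted: tuple[tuple[str, int], ...] = ()
            for _attempt in range(100):
                sequence, planted = _build_record(fam, knocked, rng, spec, patterns)
                if fam == "NONE" or _verify(fam, sequence, planted, patterns):
                    break
            else:
                raise GenerationError(
                    f"{accession}: no clean construction in 100 attempts"
                )

            if label == "NONE":
                description = "hypothetical protein"
            else:
                terms = lexicons[label].include_terms
                description = terms[int(rng.integers(len(terms)))]

            records.append(
                ProteinRecord(
                    accession=accession,
                    description=description,
                    organism=species_name,
                    sequence=sequence,
                    source_file="<synthetic>",
                )
            )
            manifest.entries.append(
                ManifestEntry(
                    accession=accession,
                    true_family=fam,
                    label_family=label,
                    planted_motifs=planted,
                    is_mislabeled=is_mislabeled,
                    is_knockout=is_knockout,
                    knocked_out=knocked,
                )
            )
    return ProteomeSet(species_name, phylum, records), manifest


def write_synthetic(
    spec: SyntheticSpec,
    fasta_path: str | Path,
    manifest_path: str | Path,
    **kwargs,
) -> tuple[ProteomeSet, TruthManifest]:
    proteome, manifest = generate_proteome(spec, **kwargs)
    write_fasta(proteome.records, fasta_path)
    manifest.write_tsv(manifest_path)
    return proteome, manifest


class ConsistencyError(ValueError):
    """Verdicts and manifest disagree about which records exist."""


def evaluate_recovery(verdicts: Iterable, manifest: TruthManifest) -> dict[str, dict]:
    """Score INCONSISTENT verdicts against the manifest's planted errors.

    A prediction is positive when the verdict for the record's *label* family
    is INCONSISTENT; the truth is positive when the record was mislabeled or
    knocked out. Metrics are reported per label family and pooled; precision
    and recall are omitted (None) where undefined rather than forced to 0.
    """
    by_key = {}
    for v in verdicts:
        by_key[(v.accession, v.family_id)] = v

    counts: dict[str, dict[str, int]] = {}
    for entry in manifest.entries:
        if entry.label_family == "NONE":
            continue
        verdict = by_key.get((entry.accession, entry.label_family))
        if verdict is None:
            raise ConsistencyError(
                f"no verdict for {entry.accession} / {entry.label_family}"
            )
        predicted = verdict.status == "INCONSISTENT"
        actual = entry.is_mislabeled or entry.is_knockout
        cell = ("tp" if actual else "fp") if predicted else ("fn" if actual else "tn")
        for key in (entry.label_family, "pooled"):
            counts.setdefault(key, {"tp": 0, "fp": 0, "fn": 0, "tn": 0})[cell] += 1

    metrics: dict[str, dict] = {}
    for key, c in sorted(counts.items()):
        pred_pos = c["tp"] + c["fp"]
        true_pos = c["tp"] + c["fn"]
        metrics[key] = {
            **c,
            "precision": c["tp"] / pred_pos if pred_pos else None,
            "recall": c["tp"] / true_pos if true_pos else None,
        }
    return metrics
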