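"""Corpus-level screening: run the claim-and-validate pipeline over many
proteomes and tally outcomes per family, per species and per phylum.

The survey mirrors how annotation-error screens are reported: for each
family, how many proteins (and species) carry the label, and how many of
those labels are consistent with the family's domain architecture. Phylum
fractions describe the corpus itself. Rendered percentages are truncated
(not rounded) at two decimals; full precision is kept internally.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import ProteomeSet, read_proteome
from .lexicon import FamilyLexicon, extract_claims
from .motifs import MotifPattern, default_patterns
from .rules import FamilyRule, ValidationVerdict, validate


@dataclass
class FamilyTally:
    claimed_proteins: int = 0
    claimed_species: int = 0
    consistent: int = 0
    inconsistent: int = 0
    indeterminate: int = 0
    advisory: bool = False

    def add(self, verdict: ValidationVerdict) -> None:
        self.claimed_proteins += 1
        if verdict.status == "CONSISTENT":
            self.consistent += 1
        elif verdict.status == "INCONSISTENT":
            self.inconsistent += 1
        else:
            self.indeterminate += 1
        self.advisory = self.advisory or verdict.advisory


@dataclass
class SurveyReport:
    per_family: dict[str, FamilyTally] = field(default_factory=dict)
    # species -> family -> tally; keeps per-family conservation checkable.
    per_species: dict[str, dict[str, FamilyTally]] = field(default_factory=dict)
    phylum_fractions: dict[str, float] = field(default_factory=dict)
    n_species: int = 0
    n_proteins: int = 0

    @property
    def total_inconsistent(self) -> int:
        """Inconsistent labels across non-advisory families."""
        return sum(t.inconsistent for t in self.per_family.values() if not t.advisory)


def run_survey(
    proteomes: Iterable[ProteomeSet],
    lexicons: Mapping[str, FamilyLexicon],
    ruleset: Mapping[str, FamilyRule],
    patterns: Mapping[str, MotifPattern] | None = None,
    quiet: bool = True,
) -> SurveyReport:
    """Screen every record of every proteome and accumulate tallies.

    A record claimed by several families contributes one verdict per family.
    ``claimed_species`` counts species with at least one claimed protein for
    that family. Deterministic given inputs; an empty corpus yields a zeroed
    report with every lexicon family present in ``per_family``.
    """
    if patterns is None:
        patterns = default_patterns()
    report = SurveyReport(
        per_family={fid: FamilyTally(advisory=getattr(ruleset.get(fid), "advisory", False))
                    for fid in lexicons}
    )
    species_with_claim: dict[str, set[str]] = {fid: set() for fid in lexicons}
    phylum_species: dict[str, int] = {}

    for proteome in proteomes:
        report.n_species += 1
        report.n_proteins += len(proteome.records)
        phylum_species[proteome.phylum] = phylum_species.get(proteome.phylum, 0) + 1
        sp_tallies = report.per_species.setdefault(proteome.species_name, {})
        for record in proteome.records:
            for claim in extract_claims(record, lexicons):
                verdict = validate(record, claim, ruleset, patterns)
                report.per_family[claim.family_id].add(verdict)
                sp_tallies.setdefault(claim.family_id, FamilyTally()).add(verdict)
                species_with_claim[claim.family_id].add(proteome.species_name)
        if not quiet:
            print(
                f"[annocheck] {proteome.species_name}: {len(proteome.records)} records",
                file=sys.stderr,
            )

    for fid, species in species_with_claim.items():
        report.per_family[fid].claimed_species = len(species)
    for sp, fam_tallies in report.per_species.items():
        for tally in fam_tallies.values():
            tally.claimed_species = 1
    if report.n_species:
        report.phylum_fractions = {
            ph: n / report.n_species for ph, n in sorted(phylum_species.items())
        }
    return report


def phylum_tally(species_meta: Mapping[str, str]) -> dict[str, float]:
    """Fraction of species per phylum from a species -> phylum mapping."""
    if not species_meta:
        return {}
    counts: dict[str, int] = {}
    for phylum in species_meta.values():
        counts[phylum] = counts.get(phylum, 0) + 1
    total = len(species_meta)
    return {ph: n / total for ph, n in sorted(counts.items())}


def format_pct(fraction: float, decimals: int = 2) -> str:
    """Percentage truncated (floored) at ``decimals`` places, e.g. 0.216255 -> '21.62'."""
    scale = 10 ** decimals
    value = math.floor(fraction * 100 * scale + 1e-9) / scale
    return f"{value:.{decimals}f}"


def load_species_meta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a metadata TSV (columns filename, species, phylum) into
    filename -> (species, phylum)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("UNKNOWN")
    required = {"filename", "species", "phylum"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata file must have columns {sorted(required)}")
    return {row.filename: (row.species, row.phylum) for row in df.itertuples()}


def survey_directory(
    fasta_dir: str | Path,
    lexicons: Mapping[str, FamilyLexicon],
    ruleset: Mapping[str, FamilyRule],
    meta: Mapping[str, tuple[str, str]] | None = None,
    patterns: Mapping[str, MotifPattern] | None = None,
    dialect: str = "ncbi",
    quiet: bool = True,
) -> SurveyReport:
    """Survey every ``*.fasta``/``*.fa``/``*.faa`` file in a directory.

    Species and phylum come from the metadata table when given; otherwise the
    species is the file stem and the phylum UNKNOWN.
    """
    fasta_dir = Path(fasta_dir)
    paths = sorted(
        p for p in fasta_dir.iterdir() if p.suffix.lower() in (".fasta", ".fa", ".faa")
    )

    def proteomes() -> Iterable[ProteomeSet]:
        for p in paths:
            species, phylum = (meta or {}).get(p.name, (p.stem, "UNKNOWN"))
            yield read_proteome(p, species, phylum, dialect)

    return run_survey(proteomes(), lexicons, ruleset, patterns, quiet=quiet)


# ---------------------------------------------------------------------------
# Serialization

_TALLY_COLS = ["claimed_proteins", "claimed_species", "consistent",
               "inconsistent", "indeterminate"]


def per_family_frame(report: SurveyReport) -> pd.DataFrame:
    rows = []
    for fid in sorted(report.per_family):
        t = report.per_family[fid]
        rows.append({"family": fid, **{c: getattr(t, c) for c in _TALLY_COLS},
                     "advisory": int(t.advisory)})
    return pd.DataFrame(rows, columns=["family", *_TALLY_COLS, "advisory"])


def per_species_frame(report: SurveyReport) -> pd.DataFrame:
    rows = []
    for sp in sorted(report.per_species):
        for fid in sorted(report.per_species[sp]):
            t = report.per_species[sp][fid]
            rows.append({"species": sp, "family": fid,
                         **{c: getattr(t, c) for c in _TALLY_COLS}})
    return pd.DataFrame(rows, columns=["species", "family", *_TALLY_COLS])


def phylum_frame(report: SurveyReport) -> pd.DataFrame:
    rows = [
        {"phylum": ph, "fraction": f"{frac:.6f}", "percent": format_pct(frac)}
        for ph, frac in report.phylum_fractions.items()
    ]
    return pd.DataFrame(rows, columns=["phylum", "fraction", "percent"])


def report_to_dict(report: SurveyReport) -> dict:
    return {
        "per_family": {fid: asdict(t) for fid, t in sorted(report.per_family.items())},
        "per_species": {
            sp: {fid: asdict(t) for fid, t in sorted(fams.items())}
            for sp, fams in sorted(report.per_species.items())
        },
        "phylum_fractions": report.phylum_fractions,
        "n_species": report.n_species,
        "n_proteins": report.n_proteins,
    }


def report_from_dict(data: dict) -> SurveyReport:
    return SurveyReport(
        per_family={fid: FamilyTally(**t) for fid, t in data["per_family"].items()},
        per_species={
            sp: {fid: FamilyTally(**t) for fid, t in fams.items()}
            for sp, fams in data["per_species"].items()
        },
        phylum_fractions=dict(data["phylum_fractions"]),
        n_species=data["n_species"],
        n_proteins=data["n_proteins"],
    )


def write_report(report: SurveyReport, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """Write the report as TSV tables or a single JSON document.

    Column order and row order are stable, so identical inputs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "tsv":
        for name, frame in (
            ("per_family.tsv", per_family_frame(report)),
            ("per_species.tsv", per_species_frame(report)),
            ("phylum.tsv", phylum_frame(report)),
        ):
            path = out_dir / name
            frame.to_csv(path, sep="\t", index=False)
            written.append(path)
    elif fmt == "json":
        path = out_dir / "report.json"
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return written


def read_report(path: str | Path) -> SurveyReport:
    with open(path) as fh:
        return report_from_dict(json.load(fh))
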