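"""Turn free-text annotation descriptions into structured family claims.

A :class:`FamilyLexicon` is a curated set of include/exclude phrases for one
protein family. A family claims a record when one of its include terms occurs
as a token-bounded substring of the normalized description and none of its
exclude terms do. Multiple families may claim the same record (calmodulin and
calmodulin-like descriptions overlap by construction); downstream validation
treats each claim independently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import ProteinRecord

#: Families screened by default. CAMK (calcium/calmodulin-dependent protein
#: kinase) is a legitimate fungal family kept separate from CDPK so that the
#: two are not conflated; ``conflate_camk`` merges them for users who want
#: the blanket grouping.
FAMILIES = (
    "CDPK",
    "CAMK",
    "CAM",
    "CML",
    "SELENOPROTEIN",
    "WRKY",
    "TERPENE",
    "LEGHEMOGLOBIN",
)


@dataclass(frozen=True)
class FamilyLexicon:
    family_id: str
    include_terms: tuple[str, ...]
    exclude_terms: tuple[str, ...] = ()
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.include_terms:
            raise ValueError(f"{self.family_id}: include_terms must be non-empty")
        for term in self.include_terms + self.exclude_terms:
            if term != normalize_description(term):
                raise ValueError(
                    f"{self.family_id}: term {term!r} is not in normalized form"
                )


@dataclass(frozen=True)
class AnnotationClaim:
    """A family membership asserted by a record's annotation string."""

    accession: str
    family_id: str
    matched_term: str
    char_span: tuple[int, int]  # 0-based half-open, in the normalized description


_PUNCT = re.compile(r"[-/_]")
_WS = re.compile(r"\s+")


def normalize_description(text: str) -> str:
    """Lowercase; map ``-``, ``/``, ``_`` to spaces; collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub(" ", text.lower())).strip()


def _token_bounded(term: str) -> re.Pattern[str]:
    # Token characters are [a-z0-9]; "cam" must not match inside "camphor".
    return re.compile(rf"(?<![a-z0-9]){re.escape(term)}(?![a-z0-9])")


def find_term(term: str, normalized: str) -> tuple[int, int] | None:
    """First token-bounded occurrence of a normalized term, or None."""
    m = _token_bounded(term).search(normalized)
    return (m.start(), m.end()) if m else None


def extract_claims(
    record: ProteinRecord, lexicons: dict[str, FamilyLexicon]
) -> list[AnnotationClaim]:
    """Emit one claim per family whose lexicon matches the description.

    Claims are sorted by (lexicon priority, match position); exclusion terms
    veto their family's claim without affecting other families.
    """
    normalized = normalize_description(record.description)
    claims: list[tuple[int, int, AnnotationClaim]] = []
    for lex in lexicons.values():
        if any(find_term(t, normalized) for t in lex.exclude_terms):
            continue
        best: tuple[int, int] | None = None
        best_term = ""
        for term in lex.include_terms:
            span = find_term(term, normalized)
            if span and (best is None or span < best):
                best, best_term = span, term
        if best is not None:
            claims.append(
                (
                    lex.priority,
                    best[0],
                    AnnotationClaim(record.accession, lex.family_id, best_term, best),
                )
            )
    claims.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in claims]


_DEFAULT_TERMS: dict[str, dict[str, list[str]]] = {
    "CDPK": {
        "include": ["calcium dependent protein kinase", "cdpk"],
        "exclude": ["calmodulin"],
    },
    "CAMK": {
        "include": ["calcium calmodulin dependent protein kinase"],
        "exclude": [],
    },
    # A kinase *regulated by* calmodulin is not itself a calmodulin.
    "CAM": {"include": ["calmodulin"], "exclude": ["calmodulin dependent protein kinase"]},
    "CML": {"include": ["calmodulin like"], "exclude": []},
    "SELENOPROTEIN": {
        "include": ["selenocysteine", "selenoprotein"],
        # Sec-machinery proteins legitimately lack U; the strict_sec switch
        # restores the blanket term search.
        "exclude": ["selenocysteine lyase", "selenocysteine trna"],
    },
    "WRKY": {"include": ["wrky"], "exclude": []},
    "TERPENE": {
        "include": [
            "terpene synthase",
            "monoterpene",
            "sesquiterpene",
            "indole diterpene",
        ],
        "exclude": [],
    },
    "LEGHEMOGLOBIN": {"include": ["leghemoglobin"], "exclude": []},
}


def default_lexicons(
    conflate_camk: bool = False, strict_sec: bool = False
) -> dict[str, FamilyLexicon]:
    """The built-in family lexicons.

    ``conflate_camk`` folds the CAMK terms into CDPK (and drops CDPK's
    calmodulin exclusion), reproducing a blanket calcium-kinase search;
    ``strict_sec`` drops the selenoprotein machinery exclusions so that every
    description mentioning selenocysteine/selenoprotein is claimed.
    """
    terms = {fid: {k: list(v) for k, v in d.items()} for fid, d in _DEFAULT_TERMS.items()}
    if conflate_camk:
        terms["CDPK"]["include"] += terms["CAMK"]["include"]
        terms["CDPK"]["exclude"] = []
        del terms["CAMK"]
    if strict_sec:
        terms["SELENOPROTEIN"]["exclude"] = []
    return {
        fid: FamilyLexicon(
            family_id=fid,
            include_terms=tuple(d["include"]),
            exclude_terms=tuple(d["exclude"]),
            priority=FAMILIES.index(fid),
        )
        for fid, d in terms.items()
    }


def load_lexicons(path: str | Path) -> dict[str, FamilyLexicon]:
    """Load lexicons from a YAML file: one family per block.

    Schema::

        CDPK:
          include: ["calcium dependent protein kinase", "cdpk"]
          exclude: ["calmodulin"]
          priority: 0        # optional

    Terms are normalized on load, so files may use hyphens/slashes freely.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    lexicons: dict[str, FamilyLexicon] = {}
    for i, (fid, block) in enumerate(raw.items()):
        include = [normalize_description(t) for t in block.get("include", [])]
        exclude = [normalize_description(t) for t in block.get("exclude", [])]
        lexicons[fid.upper()] = FamilyLexicon(
            family_id=fid.upper(),
            include_terms=tuple(include),
            exclude_terms=tuple(exclude),
            priority=int(block.get("priority", i)),
        )
    return lexicons
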