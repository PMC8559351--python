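"""PROSITE-dialect motif patterns: parsing, rendering and sequence scanning.

The dialect covers the subset of PROSITE pattern syntax needed for
domain-architecture screening:

* elements separated by ``-``;
* a single residue letter, e.g. ``D``;
* ``x`` — wildcard matching any residue;
* ``[ACD]`` — residue set;
* ``{ACD}`` — excluded set (any residue *not* listed);
* a repetition suffix ``(n)`` or ``(n,m)`` on any element;
* ``<`` prefix anchoring the match to the N-terminus and ``>`` suffix
  anchoring it to the C-terminus.

Scanning reports every distinct ``(start, end)`` window satisfying the
pattern (all end positions per start for variable-length patterns), in
ascending coordinate order. Coordinates in :class:`MotifMatch` are 1-based
inclusive, following PROSITE/NCBI reporting conventions; internally the
engine works with 0-based half-open offsets.

Ambiguity codes B, Z, J and X in a *sequence* match only wildcard elements,
never residue sets or excluded sets: a motif is never claimed on ambiguous
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Residue letters legal inside a pattern (the 20 standard + Sec + Pyl).
PATTERN_AA = frozenset(STANDARD_AA) | {"U", "O"}
#: Sequence-side ambiguity codes; these satisfy only wildcard elements.
AMBIGUOUS_AA = frozenset("BZJX")
#: Everything tolerated in a cleaned sequence.
SEQUENCE_AA = PATTERN_AA | AMBIGUOUS_AA

MAX_REPEAT = 1000

_RESIDUE_ORDER = {aa: i for i, aa in enumerate(STANDARD_AA + "UO")}


class PatternSyntaxError(ValueError):
    """Raised on malformed pattern text; carries the 0-based character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One unit of a pattern: a residue set, an excluded set, or a wildcard."""

    kind: str  # "residue_set" | "excluded_set" | "wildcard"
    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("residue_set", "excluded_set", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "wildcard" and self.residues:
            raise ValueError("wildcard element carries no residues")
        if self.kind != "wildcard" and not self.residues:
            raise ValueError(f"{self.kind} element needs at least one residue")
        if not (1 <= self.min_repeat <= self.max_repeat <= MAX_REPEAT):
            raise ValueError(
                f"repeat bounds ({self.min_repeat},{self.max_repeat}) out of range"
            )

    def accepts(self, residue: str) -> bool:
        if self.kind == "wildcard":
            return True
        if residue in AMBIGUOUS_AA:
            return False
        if self.kind == "residue_set":
            return residue in self.residues
        return residue not in self.residues

    def render(self) -> str:
        if self.kind == "wildcard":
            core = "x"
        else:
            letters = "".join(
                sorted(self.residues, key=lambda a: _RESIDUE_ORDER.get(a, 99))
            )
            if self.kind == "residue_set":
                core = letters if len(letters) == 1 else f"[{letters}]"
            else:
                core = "{" + letters + "}"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        if self.min_repeat == self.max_repeat:
            return f"{core}({self.min_repeat})"
        return f"{core}({self.min_repeat},{self.max_repeat})"


@dataclass(frozen=True)
class MotifPattern:
    """A parsed pattern plus its identity and original text."""

    pattern_id: str
    name: str
    elements: tuple[PatternElement, ...]
    anchored_n: bool = False
    anchored_c: bool = False
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern must contain at least one element")

    def render(self) -> str:
        body = "-".join(el.render() for el in self.elements)
        return ("<" if self.anchored_n else "") + body + (">" if self.anchored_c else "")

    @property
    def min_length(self) -> int:
        return sum(el.min_repeat for el in self.elements)

    @property
    def max_length(self) -> int:
        return sum(el.max_repeat for el in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """A located occurrence; ``start``/``end`` are 1-based inclusive."""

    pattern_id: str
    start: int
    end: int
    matched: str


def parse_pattern(text: str, pattern_id: str = "PATTERN", name: str = "") -> MotifPattern:
    """Parse PROSITE-dialect ``text`` into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` with a character offset on unbalanced
    brackets, empty sets, inverted repeat bounds or illegal residue letters.
    """
    if not text or not text.strip():
        raise PatternSyntaxError("empty pattern", 0)
    src = text.strip()
    # A trailing '.' terminates patterns in PROSITE flat files; tolerate it.
    work = src[:-1] if src.endswith(".") else src
    pos = 0
    anchored_n = False
    anchored_c = False
    if work.startswith("<"):
        anchored_n = True
        pos = 1
    if work.endswith(">") and len(work) > pos:
        anchored_c = True
        work = work[:-1]

    elements: list[PatternElement] = []
    n = len(work)
    while pos < n:
        ch = work[pos]
        start_off = pos
        if ch == "x":
            kind, residues = "wildcard", frozenset()
            pos += 1
        elif ch == "[" or ch == "{":
            closer = "]" if ch == "[" else "}"
            end = work.find(closer, pos + 1)
            if end < 0:
                raise PatternSyntaxError(f"unbalanced '{ch}'", start_off)
            letters = work[pos + 1 : end]
            if not letters:
                raise PatternSyntaxError("empty residue set", start_off)
            for i, aa in enumerate(letters):
                if aa not in PATTERN_AA:
                    raise PatternSyntaxError(
                        f"illegal residue letter {aa!r}", pos + 1 + i
                    )
            kind = "residue_set" if ch == "[" else "excluded_set"
            residues = frozenset(letters)
            pos = end + 1
        elif ch in PATTERN_AA:
            kind, residues = "residue_set", frozenset(ch)
            pos += 1
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r}", start_off)

        min_rep = max_rep = 1
        if pos < n and work[pos] == "(":
            pos += 1
            min_rep, pos = _read_int(work, pos)
            if pos < n and work[pos] == ",":
                max_rep, pos = _read_int(work, pos + 1)
            else:
                max_rep = min_rep
            if pos >= n or work[pos] != ")":
                raise PatternSyntaxError("unterminated repeat", pos)
            pos += 1
            if min_rep < 1 or max_rep > MAX_REPEAT:
                raise PatternSyntaxError("repeat count out of range", start_off)
            if min_rep > max_rep:
                raise PatternSyntaxError("repeat lower bound exceeds upper", start_off)

        elements.append(PatternElement(kind, residues, min_rep, max_rep))

        if pos < n:
            if work[pos] != "-":
                raise PatternSyntaxError("expected '-' between elements", pos)
            pos += 1
            if pos == n:
                raise PatternSyntaxError("trailing element separator", pos - 1)

    if not elements:
        raise PatternSyntaxError("pattern has no elements", 0)
    return MotifPattern(
        pattern_id=pattern_id,
        name=name,
        elements=tuple(elements),
        anchored_n=anchored_n,
        anchored_c=anchored_c,
        source_text=src,
    )


def _read_int(text: str, pos: int) -> tuple[int, int]:
    start = pos
    while pos < len(text) and text[pos].isdigit():
        pos += 1
    if pos == start:
        raise PatternSyntaxError("expected repeat count", start)
    return int(text[start:pos]), pos


def scan(pattern: MotifPattern, sequence: str) -> list[MotifMatch]:
    """Locate every distinct window of ``sequence`` satisfying ``pattern``.

    All satisfying end positions per start are reported for variable-length
    patterns; output is sorted by (start, end). Anchored patterns only test
    the forced positions.
    """
    n = len(sequence)
    if pattern.min_length > n:
        return []
    starts: Iterable[int] = (0,) if pattern.anchored_n else range(n - pattern.min_length + 1)
    out: list[MotifMatch] = []
    elements = pattern.elements
    for s in starts:
        # distinct windows only: different repeat splits may share an end
        ends = sorted(set(_match_ends(elements, 0, s, sequence)))
        for e in ends:
            if pattern.anchored_c and e != n:
                continue
            out.append(MotifMatch(pattern.pattern_id, s + 1, e, sequence[s:e]))
    return out


def _match_ends(
    elements: tuple[PatternElement, ...], idx: int, pos: int, seq: str
) -> Iterator[int]:
    """Yield every end offset reachable by matching elements[idx:] from pos."""
    if idx == len(elements):
        yield pos
        return
    el = elements[idx]
    p = pos
    # Consume the mandatory repeats.
    for _ in range(el.min_repeat):
        if p >= len(seq) or not el.accepts(seq[p]):
            return
        p += 1
    reps = el.min_repeat
    while True:
        yield from _match_ends(elements, idx + 1, p, seq)
        if reps == el.max_repeat or p >= len(seq) or not el.accepts(seq[p]):
            return
        p += 1
        reps += 1


def count_nonoverlapping(pattern: MotifPattern, sequence: str) -> int:
    """Greedy left-to-right count of non-overlapping pattern occurrences."""
    return len(select_nonoverlapping(scan(pattern, sequence)))


def select_nonoverlapping(matches: list[MotifMatch]) -> list[MotifMatch]:
    """Greedy-leftmost selection: accept the earliest match, drop overlaps, repeat."""
    chosen: list[MotifMatch] = []
    last_end = 0
    for m in sorted(matches, key=lambda m: (m.start, m.end)):
        if m.start > last_end:
            chosen.append(m)
            last_end = m.end
    return chosen


# ---------------------------------------------------------------------------
# Built-in pattern set


def default_patterns() -> dict[str, MotifPattern]:
    """The built-in, user-overridable pattern set, loaded from package data."""
    with resources.files("annocheck.data").joinpath("patterns.tsv").open() as fh:
        return _parse_pattern_file(fh)


def load_patterns(path: str | Path) -> dict[str, MotifPattern]:
    """Load a user pattern file: one ``ID<TAB>NAME<TAB>PATTERN`` per line."""
    with open(path) as fh:
        return _parse_pattern_file(fh)


def _parse_pattern_file(lines: Iterable[str]) -> dict[str, MotifPattern]:
    patterns: dict[str, MotifPattern] = {}
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"pattern line needs 3 tab-separated fields: {line!r}")
        pid, pname, ptext = fields
        patterns[pid] = parse_pattern(ptext, pattern_id=pid, name=pname)
    return patterns


_DEFAULT_DXD_POSITIONS = (1, 3)


def find_ef_hands(
    sequence: str,
    require_dxd: bool = False,
    pattern: MotifPattern | None = None,
    dxd_positions: tuple[int, int] = _DEFAULT_DXD_POSITIONS,
) -> list[MotifMatch]:
    """Non-overlapping EF-hand loop matches in ``sequence``.

    With ``require_dxd`` a candidate loop is retained only if the residues at
    ``dxd_positions`` (1-based within the loop window, default loop residues
    1 and 3) are both aspartate, the conserved calcium-coordinating D-x-D.
    """
    if pattern is None:
        pattern = default_patterns()["EF_HAND"]
    hits = scan(pattern, sequence)
    if require_dxd:
        i, j = (dxd_positions[0] - 1, dxd_positions[1] - 1)
        hits = [m for m in hits if len(m.matched) > j and m.matched[i] == "D" and m.matched[j] == "D"]
    return select_nonoverlapping(hits)
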