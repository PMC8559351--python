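import numpy as np
import pytest

from annocheck import default_lexicons, default_patterns, default_rules


@pytest.fixture(scope="session")
def patterns():
    return default_patterns()


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def ruleset():
    return default_rules()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_pattern_text(rng, max_elements=8, max_repeat=3):
    """A random syntactically valid pattern for round-trip / oracle testing."""
    from annocheck.motifs import STANDARD_AA

    aas = list(STANDARD_AA)
    n = int(rng.integers(1, max_elements + 1))
    parts = []
    for _ in range(n):
        kind = rng.choice(["residue", "set", "excluded", "wildcard"])
        if kind == "residue":
            core = aas[int(rng.integers(20))]
        elif kind == "wildcard":
            core = "x"
        else:
            k = int(rng.integers(1, 5))
            letters = "".join(rng.choice(aas, size=k, replace=False))
            core = f"[{letters}]" if kind == "set" else "{" + letters + "}"
        if rng.random() < 0.3:
            lo = int(rng.integers(1, max_repeat + 1))
            if rng.random() < 0.5:
                hi = int(rng.integers(lo, max_repeat + 1))
                core += f"({lo},{hi})" if hi > lo else f"({lo})"
            else:
                core += f"({lo})"
        parts.append(core)
    text = "-".join(parts)
    if rng.random() < 0.15:
        text = "<" + text
    if rng.random() < 0.15:
        text = text + ">"
    return text


def oracle_scan_windows(pattern, sequence):
    """Independent scan oracle: frontier reachability per start position.

    For each start, walks the elements keeping the set of offsets reachable
    after each element (explicit element-wise recursion over repeat counts),
    then reads matches off the final frontier. Shares no code with
    ``annocheck.motifs.scan``.
    """
    n = len(sequence)
    found = []
    starts = [0] if pattern.anchored_n else list(range(n + 1))
    for s in starts:
        frontier = {s}
        for el in pattern.elements:
            nxt = set()
            for pos in frontier:
                p = pos
                ok = True
                for _ in range(el.min_repeat):
                    if p >= n or not el.accepts(sequence[p]):
                        ok = False
                        break
                    p += 1
                if not ok:
                    continue
                nxt.add(p)
                extra = el.min_repeat
                while extra < el.max_repeat and p < n and el.accepts(sequence[p]):
                    p += 1
                    extra += 1
                    nxt.add(p)
            frontier = nxt
            if not frontier:
                break
        for e in frontier:
            if e > s and (not pattern.anchored_c or e == n):
                found.append((s + 1, e))
    return sorted(found)
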