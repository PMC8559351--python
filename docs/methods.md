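# Methods

## The screen

`annocheck` operationalizes a simple idea: a functional label implies a
domain architecture, and the architecture is checkable directly on the
sequence. The pipeline is claim extraction → motif scanning → rule
validation → corpus tallies. Each stage is a pure function of its inputs, so
identical inputs give byte-identical reports.

### Claim extraction

Descriptions are normalized (lowercased; `-`, `/`, `_` mapped to spaces;
whitespace collapsed) and matched against per-family include/exclude phrase
lists at token boundaries (`cam` never matches inside `camphor`). A family
claims a record iff an include term matches and no exclude term does;
several families may claim one record and each claim is validated
independently. Two deliberate choices:

* **CDPK vs CaMK.** Descriptions reading "calcium/calmodulin-dependent
  protein kinase" denote CaMK, a family fungi legitimately possess, and are
  kept out of the CDPK search by an exclusion term (the default CDPK lexicon
  excludes `calmodulin`). The `--conflate-camk` switch merges the two
  searches for users who want the blanket grouping. CaMK has no validation
  rule — no single motif asserts calmodulin-regulated kinase identity — so
  CaMK claims return INDETERMINATE rather than a fabricated verdict.
* **Selenoprotein machinery.** Proteins such as selenocysteine lyase or the
  Sec tRNA machinery mention "selenocysteine" but legitimately contain no U;
  the default lexicon excludes them, and `--strict-sec` restores the blanket
  term search.

### Motif engine

The engine implements the PROSITE pattern subset `A`, `x`, `[..]`, `{..}`,
`(n)`/`(n,m)` repeats, and `<`/`>` anchors. Scanning enumerates, per start
position, every reachable end position by explicit recursion over elements
and repeat counts, and reports distinct `(start, end)` windows in ascending
order — all end positions per start for variable-length patterns. Reported
coordinates are 1-based inclusive (PROSITE/NCBI convention); internal
arithmetic is 0-based half-open. Correctness is checked against an
independently coded frontier-reachability oracle on randomized cases.

Numerical/semantic choices:

* **Ambiguity codes.** Sequence letters B/Z/J/X satisfy only wildcard
  elements, never residue or excluded sets: a motif is never claimed on
  ambiguous evidence. U and O are ordinary residues.
* **Counting.** Motif counts use greedy-leftmost non-overlapping selection
  (accept the earliest match, skip overlaps, repeat) — deterministic and
  close to how distinct sites are reported in practice. Counts are therefore
  bounded by the raw match count, and the verdicts record the counts so
  users can re-threshold.
* **Repeat bound.** `max_repeat ≤ 1000` guards against pathological
  patterns; parse errors carry the character offset.

The built-in pattern file ships EF_HAND, KINASE_ATP, KINASE_ST_ACTIVE
(standard PROSITE operationalizations PS00018/PS00107/PS00108), WRKY_CORE,
MYRISTOYL (PS00008, N-anchored), TERPENE_DDXXD, plus GLOBIN_PROXHIS — a
simplified proximal-histidine consensus of our own design
(`F-x-[LIVMFY]-x(2)-H-x(2)-[KR]`) — and an approximate CECROPIN_LIKE
signature. All are data, not code, and overridable.

* **Myristoylation anchoring.** The acylation consensus is evaluated at the
  raw N-terminus *and* after initiator-Met removal (acylation follows Met
  excision in vivo); a hit in either counts. Sequences shorter than the
  motif return false, not an error.
* **EF-hand D-x-D.** The conserved calcium-coordinating D-x-D of CDPK
  regulatory-domain loops is checked at loop residues 1 and 3 of the
  13-residue window; the positions are a parameter of `find_ef_hands`
  because the literature's residue numbering of this pair is
  frame-dependent.

### Rules

Defaults: CDPK = kinase signature (ATP-binding *or* Ser/Thr active-site — an
alternative group satisfied by either member) + exactly four EF-hands +
N-terminal myristoylation; CaM and CML = exactly four EF-hands;
selenoprotein = ≥ 1 U; WRKY = ≥ 1 core heptapeptide; leghemoglobin = ≥ 1
globin motif. Exactly-four is the consensus calcium-sensor architecture;
because real entries show 2–4 loops, verdicts carry observed counts so a
looser ≥ 2 policy needs no re-scan (the rules file accepts `min`/`max`
per pattern). Terpene-synthase verdicts are **advisory** — a lone DDxx[DE]
pentapeptide is weak evidence in either direction, so these are reported but
never counted into error totals. No attempt is made to detect the CDPK
auto-inhibitory junction: it has no usable sequence-pattern definition.

### Survey

Per-family cells are (claimed proteins, claimed species, consistent,
inconsistent, indeterminate); per-species tables are per (species, family)
so the species-level counts sum exactly to the corpus level. Phylum
fractions are kept at full precision internally and **truncated** (not
rounded) at two decimals in rendered output — e.g. 466/689 → 67.63%,
149/689 → 21.62%.

## Synthetic proteomes

The generator emulates the input the screen consumes in the wild — proteome
FASTA files with free-text family labels, some wrong — not fungal biology:
background residues are i.i.d. uniform over the 20 standard amino acids (U
excluded, so accidental selenoproteins are impossible and any U is
planted); lengths are uniform on a configurable range (default 150–400
residues); there is no homology, no realistic length or composition
distribution, no shared evolutionary structure between records. Passing
recovery tests therefore demonstrates correctness of the *screen* (claims,
scanning, counting, verdicts) under exact ground truth, not performance on
real proteomes, where motif divergence and annotation nuance add error modes
the generator does not model.

Each record: draw background; plant the true family's motifs (sampled
uniformly from their patterns) at non-overlapping random positions — for
CDPK the Met + acylation site occupies the N-terminus; optionally **knock
out** one randomly chosen required motif (probability `motif_knockout_rate`)
or **mislabel** the record with a different family's description
(probability `mislabel_rate`; targets are restricted to rule-backed families
so every planted error is in principle detectable). The finished sequence is
re-scanned for every pattern of the true family's rule; if planting or
background created an accidental extra occurrence (or a knockout left the
architecture intact — e.g. a spontaneous N-terminal glycine consensus), the
record is regenerated from the same stream, up to 100 attempts. Exact-count
rules (four EF-hands) consequently hold with probability 1 on clean
corpora, and every manifest entry's planted motifs are found by the scanner
at their recorded positions. Each record has its own pseudo-random stream
derived from (seed, family ordinal, index), so corpora are stable when
other families' counts change, and generation is byte-reproducible.

Recovery scoring treats an INCONSISTENT verdict for the record's *label*
family as a positive prediction and `mislabeled or knockout` as the positive
truth; precision/recall are reported as absent (None), not zero, when
undefined.

## Problem sizes

The bundled checks run at: 10,000 random cases for scanner/oracle
agreement (patterns ≤ 8 elements, repeats ≤ 3, sequences ≤ 60 residues —
small enough that the brute-force oracle is itself trustworthy); 1,000
random patterns for parser round-trip; n = 1000 synthetic calmodulins for
recovery (binomial 3σ band 0.3 ± 0.0435 at 30% knockout); n = 50
selenoproteins at full knockout; 1,000 random partitions for composition
additivity. These sizes give tight statistical bands while keeping the full
suite in the tens of seconds.

## Known limitations

* Pattern matching only — no profiles, HMMs, homology search or de novo
  motif discovery; a protein can satisfy a pattern rule without being a
  family member and vice versa. Verdicts are evidence of annotation
  *inconsistency*, not proof of function.
* The globin and cecropin patterns are simplified stand-ins for
  full-profile detection and are the weakest rules in the set (globin is
  used by the advisory-adjacent leghemoglobin rule; cecropin is shipped for
  ad-hoc scanning only).
* Claim extraction is exact phrase matching; misspelled or paraphrased
  annotations escape the screen.
* Corpus-scale counts from public databases depend on the database
  snapshot; the survey reproduces the *format* of such tallies, and no
  claim is made to reproduce snapshot-specific totals.
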