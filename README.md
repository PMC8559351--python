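# annocheck

Functional annotation in public protein databases is largely computational,
and errors propagate: fungal proteomes contain entries labelled
"calcium-dependent protein kinase" (CDPK), "selenoprotein" or "WRKY
transcription factor" even though fungi encode none of these families.
`annocheck` screens annotated proteomes for such contradictions between what
a protein's free-text description *claims* and what its sequence *contains*:

1. **Claim extraction** — curated include/exclude term lists turn each
   description into zero or more family claims (CDPK, CaM, CML,
   selenoprotein, WRKY, terpene synthase, leghemoglobin, plus CaMK kept
   deliberately separate from CDPK).
2. **Motif verification** — a built-in PROSITE-dialect pattern engine
   locates and counts domain signatures: EF-hand calcium-binding loops
   (PS00018-style `D-x-[DNS]-{ILVFYW}-...-[DE]-[LIVMFYW]`), protein-kinase
   signatures, the WRKY heptapeptide `W-R-K-Y-G-[QK]-K`, N-terminal
   myristoylation consensus, the Sec (U) residue, and more.
3. **Rule validation** — each claim is checked against its family's domain
   architecture (a calmodulin must carry exactly four EF-hands; a
   selenoprotein at least one U; a CDPK a kinase domain, four EF-hands and
   an N-terminal acylation site) and receives a verdict: CONSISTENT,
   INCONSISTENT (with machine-readable failure reasons and observed counts)
   or INDETERMINATE.
4. **Survey** — tallies per family, per species and per phylum over whole
   proteome collections.

A synthetic proteome generator plants family architectures into random
background sequences with controlled mislabel and motif-knockout rates and
emits exact ground truth, so the whole pipeline is benchmarkable offline.

## Worked example

Generate a small corpus of proteins labelled "calmodulin", half of which
have one of their four EF-hand loops knocked out, then validate:

```sh
cat > spec.yaml <<EOF
families:
  CAM: 4
motif_knockout_rate: 0.5
seed: 19
EOF
annocheck simulate --spec spec.yaml --out-fasta syn.fasta --out-manifest truth.tsv
annocheck validate --fasta syn.fasta
```

which prints (observed counts abbreviated):

```
accession	family	status	observed	failures
SYN_CAM_00001	CAM	CONSISTENT	EF_HAND=4
SYN_CAM_00002	CAM	INCONSISTENT	EF_HAND=3	EF_HAND:3/4..4
SYN_CAM_00003	CAM	INCONSISTENT	EF_HAND=3	EF_HAND:3/4..4
SYN_CAM_00004	CAM	CONSISTENT	EF_HAND=4
```

Records 2 and 3 carry the calmodulin label but only three EF-hand loops —
exactly the knockouts listed in `truth.tsv`. The failure column reads
`requirement:observed/required`, so a looser policy (say ≥ 2 loops) can be
applied afterwards without re-scanning.

Other subcommands: `annocheck motif` (scan arbitrary patterns, TSV output),
`annocheck composition` (amino-acid composition tables, e.g. to demonstrate
the complete absence of U among "selenoprotein"-labelled sequences),
`annocheck survey` (directory-level screen with per-family / per-species /
per-phylum tables). Useful switches: `--strict-sec` claims every
selenocysteine/selenoprotein description including Sec-machinery proteins;
`--conflate-camk` folds calcium/calmodulin-dependent kinases into the CDPK
search; `--defline plain` for non-NCBI FASTA headers. Lexicons, rules and
patterns are all user-overridable files (YAML for lexicons/rules, TSV for
patterns; schemas in the module docstrings of `annocheck.lexicon`,
`annocheck.rules` and `annocheck.motifs`).

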