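# citrusid

Target-cultivar identification for citrus from retrotransposon insertion
polymorphisms and InDel markers, end to end in silico: simulation of
transposon-display sequencing libraries, read preprocessing, insertion-site
clustering, presence/absence genotyping, minimum marker-set search, and
band-pattern prediction for multiplex-PCR strip diagnostics.

## The problem

New citrus cultivars are protected by breeders' rights, and inspection sites
(e.g. customs) need a fast, cheap answer to one question: *is this fruit the
registered cultivar or not?*  Retrotransposon families that are
transcriptionally active in citrus (CIRE1, Tcs1, Tcs2) scatter new insertions
through the genome; each insertion site is a **dominant marker** — a PCR
fragment that is either present (1) or absent (0) in a cultivar.  Because
Japanese citrus breeding repeatedly crossed a narrow set of ancestors, a
single cultivar-specific fragment rarely exists, and identification instead
uses an **AND-combination** of fragments: a sample is called the target only
if *every* marker in the set amplifies, and the set is valid only if no other
cultivar carries all of its members.

The package covers the computational arc of building such a diagnostic:

1. **`landscape`** — simulate an insertion landscape (cultivars × sites, with
   flanking sequences) and emit per-cultivar FASTQ transposon-display
   libraries with sequencing error, PCR duplicates and a quality mixture,
   plus a read-level truth table.
2. **`preprocess`** — strip the element-end tag, trim the ligation adapter,
   drop reads with mean QV < 30, cut to 50 bp, and collapse sequences with
   ≥ 10 identical copies to a single representative.
3. **`cluster`** — greedy seeded-Hamming clustering of the 50-mers (8-mer
   seed, ≤ 2 mismatches): one cluster per insertion site, with per-cultivar
   read counts.
4. **`genotype`** — the 0.1 % rule: a site is called absent in a cultivar
   when its cluster holds < 0.1 % of that cultivar's reads; screening of
   cultivar-specific (column sum 1) and polymorphic markers.
5. **`markerselect`** — exact minimum AND-set search (subset enumeration by
   increasing size; a set `S` is unique for target `t` iff
   `∀c ≠ t ∃m ∈ S : G[c, m] = 0`), plus a greedy set-cover fallback.
6. **`kitsim`** — kit assembly (marker set + *rbcL* chloroplast positive
   control on a 4-line strip, amplicon sizes ≥ 30 bp apart for gel
   readability), band-pattern prediction and three-way diagnosis
   (`target` / `non_target` / `invalid`).

A packaged reference panel (26 cultivars × 14 markers, with per-kit amplicon
sizes) drives the marker-selection and kit analyses without any sequencing.

## Worked example

```
$ citrusid select --target Asumi
{"target": "Asumi", "members": ["Cp0419-s", "IND214-s"], "size": 2, "unique": true}
```

'Asumi' cannot be identified by any single fragment, but it is the only one
of the 26 panel cultivars carrying **both** Cp0419-s and IND214-s — the
minimum set has size 2.

```
$ citrusid kit --target Kanpei
{"target": "Kanpei", "members": ["IND265-l", "Cp0419-s", "IND44-l"],
 "lines": {"rbcL": 1, "IND265-l": 2, "Cp0419-s": 3, "IND44-l": 4},
 "fragment_sizes": {"rbcL": 622, "Cp0419-s": 246, "IND265-l": 280, "IND44-l": 152}}

$ citrusid diagnose --target Kanpei --sample Asumi
{"kit_target": "Kanpei", "sample": "Asumi", "present_lines": [1, 2, 3], "band_count": 3, "verdict": "non_target"}

$ citrusid diagnose --target Kanpei --sample NC
{"kit_target": "Kanpei", "sample": "NC", "present_lines": [], "band_count": 0, "verdict": "invalid"}
```

The 'Kanpei' kit needs all three of its markers: on 'Kanpei' itself it shows
4 bands (control + 3 markers); on 'Asumi' — which shares two of the three
fragments — only 3, so the verdict is `non_target`; a no-template control
shows no bands at all, including the *rbcL* control line, so the run is
`invalid` rather than negative.

The numbered drivers under `analysis/` run the same stages as a narrative:
`01_simulate_library.py` (simulated experiment), `02_genotype_simulated_reads.py`
(read pipeline + truth scoring), `03_screen_reference_panel.py` (marker
screening and minimum sets; prints that 3 of the 8 targets admit a
single-fragment diagnostic), `04_design_and_evaluate_kits.py` (all eight kits
× 26 cultivars; 0 misclassifications).  Tables land under `results/`.

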