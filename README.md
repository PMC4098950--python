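# phoscompare

Peptide-level case/control comparison of phosphoproteomic search-engine
results.

## The problem

A single LC-MS/MS phosphoproteomics experiment identifies thousands of
phosphopeptides, reported as peptide-spectrum matches (PSMs) by database
search engines such as Mascot, Paragon (ProteinPilot) and Sequest (via
Proteome Discoverer).  Comparing a stimulated *case* sample against a
*control* at the **protein** level hides most of the biology: a protein seen
in both samples may still carry phosphosites that appear only under
stimulation.  Doing the peptide-level comparison by hand — across replicate
files, two or three search engines and two sample groups — is laborious and
error-prone.

`phoscompare` automates that comparison.  It is aimed at proteomics
researchers who have plain-text PSM exports in hand and want, per
phosphosite set, a defensible call of *unique to case*, *unique to
control*, or *common*.

## The method

1. **Parse and filter.**  Engine export tables (CSV/TSV) are decoded into
   residue-level modification assignments.  Hits failing user-set score
   thresholds (defaults: Mascot expect ≤ 0.01, Paragon confidence ≥ 99) and
   peptides carrying no phospho/acetyl modification on a target residue
   (default S, T, Y, K) are removed.
2. **Map.**  Each peptide is located in a protein FASTA (UniProt or RefSeq
   headers) and its modification positions are translated to absolute
   1-based protein coordinates ("Ser-60").  Peptides matching more than one
   place in the proteome are flagged and logged.
3. **Group.**  Peptides on the same protein with *identical* modified-site
   sets form one **event** — the unit of counting — regardless of peptide
   length; the report shows the members' shared sequence.  For a protein
   `P` with site set `{S60, S64}`, two overlapping tryptic peptides both
   carrying phospho-S60 and phospho-S64 are one event with two members.
4. **Classify.**  An event is *unique to case* iff at least one engine
   detected it in the case sample and **no** engine detected it in the
   control sample (symmetrically for control); anything detected in both is
   *common*.  A protein is a *unique phosphoprotein* of a sample when it
   owns at least one sample-unique event whose members map unambiguously.
5. **Quantitative mode.**  For pooled labeled designs (iTRAQ/SILAC) each
   peptide carries a case/control abundance ratio *r*.  With cutoffs
   `r > 1.414` (case-enriched) and `r < 0.707` (control-enriched) —
   half a log2 fold change around parity — enriched peptides are re-labeled
   as if qualitatively present in only that sample; ratios in the neutral
   band count as present in both, so their events classify as common.
6. **Annotate and report.**  Each site is checked against flat-file
   databases of literature-described sites (UniProt/PHOSIDA/
   PhosphoSitePlus-style 4-column TSV); unmatched sites are marked *novel*.
   Outputs: a machine-readable TSV, a self-contained HTML report
   (case-unique red, control-unique blue, common black; novel sites bold;
   modified residues underlined), per-engine statistics files, a summary
   table and a plain-text warning log.

## Worked example

The package ships a synthetic-experiment generator, so a full run needs no
external data:

```bash
phoscompare fixtures --out-dir demo --seed 3 \
    --unique-case 5 --unique-control 5 --common 8
phoscompare run \
    --case demo/mascot_case.csv mascot   --case demo/paragon_case.tsv paragon \
    --control demo/mascot_control.csv mascot --control demo/paragon_control.tsv paragon \
    --fasta demo/proteome.fasta --known-sites demo/known_sites.tsv \
    --out-dir demo/out
```

prints

```
unique case peptides: 5
unique control peptides: 5
common peptides: 8
total peptides: 18
unique case proteins: 2
unique control proteins: 2
overlap proteins: 2
```

Reading the numbers: the 18 phosphosite events split into 5 detected only
in the case sample, 5 only in the control and 8 in both — exactly the
design the generator planted.  Two proteins own case-unique events, two own
control-unique events, and `overlap proteins: 2` means both proteins appear
in *both* unique sets: they were identified in both samples but with
different phosphorylation sites, the observations a protein-level
comparison would miss.  One row of `demo/out/comparison.tsv`:

```
P90000  sp|P90000|SYN0_TEST synthetic protein 0  unique_case  VVSPDSSAR  58  66  S60:phospho:known(known_sites);S64:phospho:known(known_sites)  1  ...
```

is one case-unique event: the shared sequence `VVSPDSSAR` spans protein
positions 58–66 of P90000 with phosphoserines at positions 60 and 64, both
already described in the loaded known-site database.

`phoscompare validate --input table engine` checks inputs parse cleanly
without running a comparison; `phoscompare run --quant ...` switches to
ratio-based classification.  A YAML run description can replace the flags
(`phoscompare run --config run.yaml`).

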