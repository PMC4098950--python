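# Methods

## The comparison model

The unit of comparison is the **phosphosite equivalence class** ("event"):
the set of all reported peptides on one protein whose modified-site sets —
`(protein position, residue, modification type)` tuples — are identical.
Grouping by exact site set rather than by peptide string reflects how
phosphoproteomics data actually arrive: overlapping tryptic peptides of
different lengths (missed cleavages, ragged ends) report the same
biological observation.  Two consequences of the exact-set identity:

- A peptide carrying a unique site **and** a shared site forms its own
  event (its site set differs from the shared-only peptides'), and is
  classified on that full set.
- Modification type is part of site identity, so a phosphorylated and an
  acetylated peptide at the same lysine are distinct events and appear in
  separate report rows.

Each event's representative **shared sequence** is the intersection of its
members' protein intervals.  Because every member contains every site of
the set, a non-empty intersection always covers the sites; should members
ever fail to overlap (possible only through inconsistent upstream
coordinates), the minimal site-covering interval is used and a warning
logged.

**Classification** uses a conservative multi-engine consensus: an event is
unique to the case group iff ≥ 1 engine detected it there and no engine
detected it in the control group, and symmetrically for control; everything
else is common.  Detection counts are pooled across replicate files of the
same group before classification; per-file provenance is kept for the
report.  An event with no detections at all is ill-formed and raises.

**Unique phosphoproteins.**  A protein belongs to a sample's unique set iff
it owns ≥ 1 event of the matching unique status *all of whose members map
to a single place in the proteome*.  Ambiguously mapping (multi-match)
peptides still appear in the report but never attribute protein-level
uniqueness.  The intersection of the two samples' unique sets is reported
as the proteins identified in both samples with differences in their
phosphorylation sites — typically the biologically richest slice.

## Quantitative mode

Pooled labeled designs (iTRAQ/SILAC) yield one combined LC-MS/MS run with a
per-peptide case/control abundance ratio instead of separate sample files.
Presence is therefore derived from the ratio: with cutoffs
`case_ratio_min` (default 1.414 ≈ √2) and `control_ratio_max` (default
0.707 ≈ 1/√2), a strictly larger ratio re-labels the peptide as a case
detection, a strictly smaller one as a control detection, and the neutral
band maps to presence in *both* groups, so those events classify as common.
The √2 band corresponds to half a log2 fold change on either side of
parity.  Missing or non-positive ratios fall into the neutral band with a
warning — the conservative call, since it can only move an event toward
"common", never invent uniqueness.  Because presence comes from ratios, a
quantitative run requires only ≥ 1 input file of any label, whereas a
qualitative run requires ≥ 1 case and ≥ 1 control file.

## Input dialects

Vendor export layouts vary by software version, so the package defines one
canonical, frozen layout per engine and accepts a column-mapping override
for real exports whose headers differ.

| engine     | format | columns                                                              | modification grammar      |
|------------|--------|----------------------------------------------------------------------|---------------------------|
| mascot     | CSV    | `prot_acc, pep_seq, pep_score, pep_expect, pep_var_mod, pep_loc_score, pep_ratio` | `Phospho@3; Acetyl@7`     |
| paragon    | TSV    | `Accessions, Sequence, Conf, Modifications, LocScore, Ratio`         | `Phospho(S)@3; Acetyl(K)@7` |
| sequest_pd | TSV    | `Protein Group Accessions, Sequence, Modifications, XCorr, Localization Score, Abundance Ratio` | `S3(Phospho); K7(Acetyl)` |

Positions are 1-based within the peptide; accession lists are
semicolon-separated; empty score/ratio cells mean "not reported".  Tokens
that name a residue are validated against the peptide sequence, and any
undecodable modification string rejects that row (with a logged reason)
rather than aborting the run: the parser never silently drops a row, so
`parsed + rejected = data rows` always holds.  A missing required column is
fatal and names the columns involved.  Peptide sequences are uppercased
before comparison; isoleucine and leucine are kept distinct, since
conflating them would merge genuinely different site coordinates.

FASTA headers are auto-detected as UniProt (`sp|ACC|NAME`, accession = the
middle token) or RefSeq (`ref|ACC|` or a bare accession token), overridable
by the caller.  Known-site databases are 4-column TSVs
(`accession  position  residue  mod_type`); several files union, with
per-site provenance retained.

## Score filtering

Thresholds are optional (unset = not applied) and conjunctive per engine:
Mascot expect ≤ `mascot_expect_max` (default 0.01) and, if set, ion score ≥
`mascot_ion_score_min`; Paragon confidence ≥ `paragon_confidence_min`
(default 99, on the 0–100 scale); a localization-score floor, if set,
applies to every engine.  The defaults are conventional high-confidence
settings for these engines.  A hit lacking a score that a configured
threshold references is rejected with a warning rather than passed through
unchecked, and a hit below the localization floor is dropped entirely
rather than demoted — the conservative reading, since this tool scores
nothing itself.  Site-localization confidence is consumed (as a
pass-through threshold on engine-computed scores), never computed: the
package does not assess which residue of a peptide carries the
modification.

## Site mapping

Peptides are anchored by exact substring search.  The primary protein is
the first engine-reported accession present in the FASTA that contains the
peptide; within it, the first (lowest) occurrence provides coordinates — a
deterministic tie-break, made visible by the `multi_match` flag whenever
the peptide occurs more than once anywhere in the proteome.  If no reported
accession resolves, a whole-proteome scan rescues the hit when exactly one
protein matches (logged); otherwise the hit is left unmapped with a
warning, never fatally.  Mapping is deterministic given identical inputs.

## Novelty annotation

A site is *known* iff its exact `(accession, position, residue, mod type)`
tuple appears in the union of loaded databases, else *novel*.  Residue
agreement is required, not just position, guarding against coordinate drift
between FASTA versions; a ±N positional tolerance is deliberately not
applied by default (exact matching is the safe strictness when databases
and FASTA come from the same release).  Annotation is a pure function of
the site and the union, so load order cannot change labels.

## Residue composition

Per-event modified-residue counts (S/T/Y/K by default) are summed over
non-redundant events and presented as percentages at one decimal.
Presentation is sum-preserving: every category is rounded normally except
the smallest nonzero one, which absorbs the rounding residual so the column
totals exactly 100.0 — the usual convention for published composition
tables.  The absorption can shift that one category by at most 0.05 per
other category; with a zero total all percentages are 0.0.

## The synthetic-experiment generator

The generator emulates the *structure* of a case/control phosphoproteomics
dataset: a tryptic-like proteome (segments of 8–16 residues ending in K/R,
globally unique so peptide placement is unambiguous by construction),
planted site sets on interior segments, missed-cleavage peptide variants
sharing identical sites, engine × sample detection patterns constructed to
realize each event's planned class under the consensus rule, a known-site
file covering a chosen fraction of planted sites, score values drawn on the
right side of the default thresholds (plus deliberate sub-threshold and
unmodified chaff that the pipeline must remove), and — in quantitative mode
— ratios drawn strictly inside the band realizing each class, so class
recovery is exact by design.  Phospho-residue identity is drawn
S/T/Y/K at 85/13/1/1%, mirroring the serine dominance of real
phosphoproteomes; the default acetyl fraction is 0.1 and the default
known-site coverage 0.5.

It does **not** simulate what makes real data hard upstream of this tool:
spectra, score distributions and their calibration, site-localization
ambiguity, decoy/FDR structure, shared peptides between homologous
proteins (beyond the explicit multi-match fraction) or ratio noise.
Passing the recovery tests therefore demonstrates that the bookkeeping —
parsing, mapping, grouping, consensus classification, attribution,
reporting — is exact under clean inputs; it says nothing about search-engine
error rates, which this tool consumes but does not control.  All
randomness flows from the plan's single seed; a plan reproduces
byte-identical bundles.

## Verification problem sizes

The test suite and the acceptance script work at desk scale, chosen so the
whole suite runs in seconds: exhaustive enumeration of all 3⁴ presence
matrices over 2 engines × 2 samples; brute-force grouping oracles on 200
random peptides; parser round-trips on 500 generated rows per dialect; and
end-to-end recovery on planted designs of 100/100/300 events (≈ 500 events,
~60 proteins, ~1,000 hits) in both qualitative and quantitative mode.  The
algorithms contain nothing scale-sensitive — every step is exact set/string
bookkeeping — so these sizes exercise all code paths.

## Known limitations

- No isoform-aware, gapped or variant-tolerant mapping; exact substring
  only.
- No statistical testing of abundance differences, no FDR estimation, no
  site-localization scoring; thresholds are pass-through.
- Known-site matching is exact-position; cross-release coordinate drift
  must be handled by regenerating the site databases against the FASTA in
  use.
- Multi-match peptides are excluded from protein attribution rather than
  apportioned; proteins supported only by shared peptides will not appear
  in unique-protein sets.
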