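# Methods

## Mass model

All masses derive from element-count formulas and three embedded atomic
mass tables (IUPAC 2021): *monoisotopic* (exact mass of the most
abundant isotope), *average* (standard atomic weight) and *nominal*
(integer mass number of the most abundant isotope). Embedding the
tables keeps every number bit-reproducible offline. The element set is
C, H, N, O, S, P, I — sufficient for the canonical amino acids and the
16 non-canonical monomers; unknown symbols are rejected at parse time
rather than silently dropped.

Masses are carried as `(value, mode)` pairs and arithmetic between
modes is a hard error. This is deliberate: mixing monoisotopic and
average values is the classic mass-spectrometry bookkeeping bug, and a
27.8 kDa protein is ~17 Da heavier on the average scale than on the
monoisotopic one, far outside any instrument tolerance.

Ion m/z uses `(M ± z·p)/z` with a proton of 1.00727646 Da
(monoisotopic/average) or exactly 1 on the nominal scale, matching how
low-resolution ESI quadrupole readouts are reported as integers.
Charges are limited to what the relevant spectra need (z ≥ 1; adducts
other than ±H are out of scope).

Deconvoluted intact-protein masses at ~27.8 kDa are *presumed* average
(the deconvolution of a quadrupole-TOF protein envelope reports the
abundance-weighted mass), but the mode is an explicit argument on every
mass-returning function rather than a constant.

## Monomer registry

The shipped registry (`data/monomers.tsv`) holds free-monomer formulas;
residue formula = free − H2O for amide and ester monomers alike, since
both condensations expel one water. The 16 non-canonical entries were
derived from their names and synthesis routes: compounds 6–13 are
carbamates/amides on the (S)-6-amino-2-hydroxyhexanoic acid scaffold
(itself lysine after diazotization, which replaces the alpha-NH2 by OH:
net −N −H +O), 14–16 are diazotization products of phenylalanine,
4-iodophenylalanine and 3-(2-naphthyl)alanine, and 1–5 are the
corresponding amino acids or lysine carbamates. Two algebraic builders
(`carbamate`: amine + alcohol + CO2 − H2O; `hydroxy_from_amino`:
−NH +O) make these routes executable, and the test suite requires every
registry formula to be reachable through them. Every entry with a
published low-resolution m/z reproduces it on the nominal scale, and
for all entries the monoisotopic ion m/z rounds to the nominal one — a
cheap but effective guard against formula-entry typos.

## Codon compression and reassigned translation

Compression applies TCG→AGC, TCA→AGT, TAG→TAA at codon boundaries only;
out-of-frame occurrences of the target trinucleotides are untouched
because the operation is defined on protein-coding sequences. The rule
set is validated as synonymous (or stop→stop) against the standard
codon table (Biopython's), so compression is provably silent at the
protein level; idempotence follows because no substitution target is
itself a source codon.

Reassigned translation maps TCG→monomer A and TAG→monomer B. An
in-frame TCA is a hard `UndecodableCodonError`, not a skip: in the
compressed host the TCA-decoding tRNA is deleted, and silently
accepting the codon would fabricate biology. A terminal TAA/TGA is
consumed as stop; an internal one raises. Codon indices in all reports
are 0-based (documented at the API boundary); residue positions in
protein-variant APIs are 1-based, matching construct nomenclature such
as "position 3", with conversion done once at the boundary.

Eight reassignment schemes ship as data (`data/schemes.yaml`). Scheme
definitions follow the compound *names* in the source descriptions
where name and number disagree.

## Macrocycles, esters, hydrolysis

A template is an ordered slot list with exactly one A and one B
placeholder ("A"/"B" are reserved; canonical alanine is written "Ala").
Ring bond *i* joins the carbonyl of monomer *i* to monomer *i+1 mod n*;
the bond is an ester iff the acceptor is a hydroxy acid, whose alpha-OH
esterifies the preceding carbonyl. Hydrolysis therefore cleaves
N-terminal-side | hydroxy-acid: the upstream fragment ends as a free
acid and the downstream fragment starts with the hydroxy acid carrying
its free alpha-hydroxyl. Each single cleavage adds one water; double
cleavages of two-ester rings yield complementary fragment pairs summing
to cyclic + 2 H2O. These conservation identities are enforced to 1e-6
Da in the tests.

## Fragment theory and annotation

Each of the *n* ring openings is treated as a linear peptide for ion
prediction: b_i = Σ prefix residues + proton, a_i = b_i − CO,
y_i = Σ suffix residues + H2O + proton, singly charged by default
(annotation in the source data is relative to [M+H]+). Note the *n*
linearizations share their precursor but not their b/a/y ladders, which
is exactly why observing fragments from every opening evidences
cyclicity.

Annotation matches observed peaks to all theoretical ions within a
tolerance (default 0.1 Da — appropriate for manually assigned
quadrupole-TOF spectra; no tolerance is stated in the source, so it is
configurable). A peak inside the tolerance of several ions is reported
with *all* of them and flagged ambiguous — assignment was manual in the
original workflow, and the software must not silently choose. Reports
carry both absolute m/z and the difference from the precursor [M+H]+.

## Orthogonal pair identification

The activity matrix holds RFU/OD600 values for synthetase variants
(rows, each with a class label) × monomers (columns). Missing cells are
construction-time errors, never zeros (a silent zero would fabricate
inactivity). (aaRS1, m1)/(aaRS2, m2) form a pair iff aaRS1 is active
with m1 and inactive with m2, aaRS2 active with m2 and inactive with
m1, the two synthetases belong to different classes, and none of the
four cells is excluded. Pairs are canonicalized unordered, and counts
are reported both as (aaRS, monomer) pairs and as unique substrate
pairings, the two bookkeepings differing because several enzyme
combinations can share a substrate combination.

Activity means > 10,000 RFU/OD600. The inactivity cutoff is not
recoverable from the published text (the sentence truncates before the
number); the default is 2,500 RFU/OD600, it is prominently configurable,
and `sweep_inactive_max` scans candidate cutoffs against a matrix,
reporting pair and pairing counts, so the operative value can be
recovered once a transcription of the full screen is available. The
default exclusion rule masks the six cells where aromatic hydroxy acids
meet the two tyrosyl synthetases (those readouts reflect amino-acid,
not hydroxy-acid, incorporation).

## Quantification

The standard curve is ordinary least squares of *mean* band intensity
on amount (replicates averaged first, as in a triplicate standard-curve
protocol, 0–5 nmol). The internal-standard correction is interpreted
multiplicatively — factor = known amount / curve-inverted observed
amount of the co-run standard — since only "corrected for variation" is
specified; this interpretation is a package design choice. If the
labelling control shows no visible signal the reported amount is 0
regardless of band intensity. Gel image analysis (baseline and band
integration) is upstream and out of scope; inputs are integrated
intensities.

## Synthetic data

Generators are pure functions of (spec, seed) via
`numpy.random.default_rng`.

*Activity matrices* default to the screening-campaign geometry: classes
of sizes (3, 2, 2) × 16 monomers, two planted cognate monomers per
synthetase, active levels uniform in 15,000–40,000 RFU/OD600 and
inactive levels uniform in 0–1,000, straddling the 10,000/2,500
thresholds by construction. Ground truth is enumerated from the planted
boolean pattern by an independent brute-force loop (not by the
production pair finder), because random fills can imply pairs beyond
the ones planted. Gaussian noise can be layered on to study threshold
crossing; the generators model readout levels only, not
expression-level biology (toxicity, growth).

*Coding sequences* draw background codons from the 59 sense codons that
are neither reassignment targets nor stops, then plant exact counts of
TCG/TCA/TAG, so the planted counts are the true in-frame counts.

*Spectra* plant a chosen number of theoretical ions per linearization
(m/z jitter truncated to half the match tolerance, so planted peaks
always annotate) plus decoys rejected within 2× tolerance of any
theoretical ion (error after 1,000 attempts flags an overcrowded m/z
range). What passing these tests shows is that the pipeline's own
arithmetic and matching are correct; real spectra additionally contain
isotope envelopes, multiple charge states, neutral-loss series and
intensity structure that the generator deliberately does not emulate.

## Problem sizes and numerical choices

The test suite runs the invariant suites at these sizes, chosen to make
the checks exhaustive where the space is small and broadly sampled
where it is not: all 19,530 rings of size ≤ 6 over a 5-monomer alphabet
against the brute-force fragment oracle; 1,000 random coding sequences
for compression idempotence/translation preservation; 500 random
matrices (≤ 10×20) for pair-finder/brute-force equality; 200 random
species for mass additivity and hydrolysis conservation. Floating-point
tolerances: 1e-9 Da for pure-arithmetic identities, 1e-6 Da for
conservation sums, 1e-4 Da where the independent oracle uses its own
atomic-mass tables (pyteomics).

## Optional reference inputs

Two end-to-end checks depend on reference data that ships separately
from this package: the full 7×16 fluorescence screen (expected at
`data/supplementary/fig4a_matrix.csv`, CSV with `aaRS,group,<monomer
ids>` columns) and the carrier-protein construct sequence (expected at
`data/supplementary/sfgfp_his6.fasta`). When present, the acceptance
tests sweep the inactivity cutoff against the real screen and check the
hydrolysed-fragment mass of the substituted carrier; in their absence
the same machinery is exercised on synthetic inputs with known ground
truth. Whether the construct's N-terminal methionine is processed
should be resolved against the construct sequence itself when loaded;
the package takes the sequence as given and does no automatic Met
trimming.

## Known limitations

- No isotope-pattern simulation, no adducts beyond ±H, fragment charge
  states fixed at 1 by default.
- Collision-energy-dependent fragment intensities are not predicted;
  annotation is purely m/z-based.
- Which template/scheme combinations express, cyclize or hydrolyse in
  vivo is an experimental outcome and is not modelled.
- Genome-scale recoding constraints (overlapping ORFs, regulatory
  elements) are out of scope; only supplied ORFs are recoded.
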