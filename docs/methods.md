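# Methods

## The problem

Marine picocyanobacteria (*Prochlorococcus* and marine *Synechococcus*)
share a hyper-conserved protein (PSHCP) absent from other cyanobacteria.
If that protein stabilizes ribosomal RNA, the rRNA of the clade that
carries it should tolerate substitutions that other cyanobacteria
cannot: individual helix strands changing without the compensating
change in the partner strand.  cladescan implements the comparative
screen for such sites: it takes a gapped multiple alignment of rRNA
genes partitioned into an in-group (clade members) and an out-group
(everything else), finds clade signature sites, quantifies per-site
conservation in each group on a common scale, maps the between-group
difference onto reference secondary-structure coordinates, and
cross-references fast-evolving helices with helices physically close to
a ribosomal protein in a 3D structure.  Companion modules cover the two
supporting analyses: attribution of a transcript pool to candidate
promoters from nested-amplicon RT-qPCR counts, and scanning upstream
regions for a degenerate −10 promoter element.

## Site statistics

Let *f_N(s)* be the frequency of nucleotide *N* ∈ {A, C, G, U} at
alignment site *s* within one group, with the **full group size** as
denominator.  Gapped cells (and any non-ACGU character: ambiguity codes
share the missing-data channel) therefore reduce the nucleotide
frequencies rather than being renormalized away.  This makes the
signature rule literal — "present in ≥90% of the group" means ≥90% of
all its members — and feeds the gap penalty independently of H.

* Shannon uncertainty (bits): `H(s) = −Σ_N f_N log2 f_N`, with
  `0·log2 0 = 0`.  `H_max = 2` bits (four equiprobable states).
* Total information, gap-penalized to a 0–1 scale:
  `T(s) = (1 − H(s)/H_max) · (1 − gap(s))`, using the group's own gap
  fraction.  The penalty is **multiplicative**: the source description
  states only that T is on a 0–1 scale and that a gap penalty is
  applied, so the exact form is a design choice of this package; a
  multiplicative penalty is the only simple form that preserves the 0–1
  range for every gap fraction (a subtractive one can go negative).
  This is the single most consequential modelling assumption here.
* Group average `T_avg` = arithmetic mean of T over retained sites,
  absorbing the groups' different overall divergence.
* Relative information `R(s) = T(s) / T_avg` — again a reconstruction;
  a ratio is the natural unit-free normalization implied by
  "compensate for the different level of overall sequence divergence".
* Difference score `D(s) = R_out(s) − R_in(s)`, positive where the site
  is less conserved in the in-group (the sites of interest).

Signature sites: a (column, nucleotide) pair with in-group frequency
≥ 0.90 **and** out-group frequency ≤ 0.10, both thresholds inclusive.
No multiple-testing control is applied over sites, by design: the screen
is descriptive, not inferential.

## Column filtering and coordinates

Columns gapped in **more than** 50% of all sequences (both groups
pooled) are removed before scoring; exactly 50% is retained (strict
reading of "more than half").  Whether the original screen pooled the
groups for this step is unknown; pooling is this package's choice and is
exposed as `max_gap`.  Scores are always keyed by the original 1-based
column index, and a coordinate map against a designated ungapped-or-not
reference row (e.g. *E. coli*) converts columns to reference residue
numbers; residues absent in >50% of taxa are emitted masked rather than
scored, mirroring the blacked-out sites of a structure diagram.

## Helix summaries and structure proximity

Helix definitions are an input TSV (helix id, 1-based inclusive residue
intervals, optional domain) rather than hard-coded, because the 23S
secondary-structure model they come from is an external resource.  Per
helix the mean and max D over unmasked residues are reported, helices
ranked by mean D.

From a PDB-format structure the distance of each nucleotide's phosphate
phosphorus (atom `P`) to the nearest protein α-carbon (atom `CA`) is
computed; nucleotides without a P atom are unresolved.  A k-d tree
answers the nearest-neighbour query; tests verify exact agreement with
the brute-force all-pairs minimum, which is the reference semantics.
A helix is "proximal" when its minimum resolved distance is at most a
threshold, default **15 Å** — no threshold is inherited from the source
analysis; 15 Å spans roughly one helix diameter plus a protein side
chain extension and is a surfaced config value, not a constant.  The
cross-reference report lists helices that are both in the top-k (default
5) by mean D and proximal.

The ATOM-record reader is deliberately minimal and local: the module
contract wants parse errors that cite the offending line and a
keep-first-listed alternate-conformer policy, which the common
structure parsers do not expose.  Only ATOM/HETATM records of the two
requested chains are read; parsing stops at `ENDMDL`.

## RT-qPCR transcript attribution

A dilution series fits `Cq = slope·log10(copies) + intercept` by least
squares (slope ≈ −3.32 at 100% efficiency); inversion gives absolute
copies per ng template.  Nested amplicon classes are partitioned as
`100 · copies_i / total`, half-up rounded to one decimal — the
convention of the published table this reproduces.  A printed total
takes precedence over the column sum when supplied, because published
totals computed from unrounded values can differ from the sum of rounded
counts by one.  The default partition treats each product class as a
distinct transcript pool (percentages sum to 100); an explicitly
separate `nested_differences` mode interprets classes as
"at-least-this-long" counts and differences successive classes.

## Promoter scanning

Aligned upstream regions give a per-position frequency matrix over
non-gap characters and information `2 − H` bits per position (the
content of a sequence LOGO).  No small-sample correction is applied by
default — the published use of LOGOs here is qualitative — but the
WebLOGO-style `3/(2·ln2·n)` subtraction is available as a flag.
Consensus scanning is forward-strand-only (promoters are
strand-specific relative to their gene), IUPAC-degenerate, with a
bounded mismatch count; the bundled default pattern `TATAAT` is the
canonical bacterial −10 hexamer and is a stand-in, since the
experimentally determined picocyanobacterial consensus is not published
as a sequence string.  Hit positions relative to an anchor (start
codon): upstream hits are measured from the pattern end (a hit ending
12 bases before the anchor reports −12), at-or-downstream hits from the
pattern start.

## Synthetic data

`simulate_two_clade_alignment` uses a **star phylogeny**: independent
descendants from one uniform-random ancestor, substitutions uniform
over the three alternatives (Jukes–Cantor-like).  The scored statistics
are column-wise and tree-free, so a star keeps ground truth analytic; a
realistic genealogy with covarying paired sites is exactly what this
generator does *not* emulate, which means passing recovery tests show
correctness of the screening arithmetic, not robustness to phylogenetic
correlation or alignment error in real data.  Planted signature columns
fix one state per group; planted fast columns substitute with an
elevated rate in the in-group only; gaps are i.i.d. per cell.

Default survey conditions (also the acceptance fixture): 50 sequences
per group, 1500 columns, background substitution probability 0.05, 30
signature columns at full fixation, 25 fast columns at rate 0.5
concentrated in one designated helix, gap rate 0.02, an ungapped
reference row appended to the out-group, helices tiled at 30 residues,
and a toy structure placing exactly the designated helix within contact
range (~8 Å) of a 30-residue protein while all other residues lie
≥ 60 Å away.  These sizes emulate a ~100-genome rRNA survey at
desk scale and run end-to-end in well under a second.

All generators are deterministic in their seed; the survey bundle
writer emits byte-identical files for identical seeds.

## Numerical notes

* Frequencies are validated to within 1e-9 of the simplex; H inputs to
  T within [0, 2]+1e-9.
* Half-up rounding uses exact decimal arithmetic (`decimal.Decimal` on
  `repr(x)`), so 10.35 → 10.4 regardless of binary representation.
* T_avg = 0 (a group with no information at all) is an error rather
  than an infinite R.
* Helix summaries place NA (not 0) for helices with no unmasked
  residues; ranking puts NA last.
* Pipeline outputs are written with a fixed float format so reruns are
  byte-identical.

## Known limitations

* The T(s) and R(s) forms are reconstructions (see above); absolute
  score values are comparable within this package only, though
  rankings are invariant to any order-preserving rescaling.
* Star-tree simulation ignores phylogenetic autocorrelation; real
  surveys have clumped gaps and alignment artefacts the generator does
  not model.
* The proximity analysis uses one reference-atom pair (P/CA), not
  all-atom contacts, and depends on the user naming the correct chains.
* mmCIF input is not supported; PDB format only.
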