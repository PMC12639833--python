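# Methods

`pabseq` reconstructs the chains of an antibody mixture from three layers of
mass-spectrometry evidence and groups them into whole antibodies. This note
documents the model behind each stage, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Problem setting

A polyclonal (or mixed monoclonal) antibody sample is prepared three ways:

* **bottom-up** — reduced, alkylated, multi-enzyme digested; LC-MS/MS spectra
  are de novo sequenced upstream into short peptide reads with per-residue
  local confidence and an average local confidence (ALC);
* **middle-down** — hinge-cleaved (IdeS or SpeB) and reduced into ~23–25 kDa
  subunits (LC, Fd, Fc/2); targeted ETD MS/MS of each subunit precursor is
  deconvoluted upstream into neutral c/z fragment mass lists;
* **intact** — whole (deglycosylated), reduced, and subunit samples profiled
  by LC-MS1 and deconvoluted into proteoform masses.

No sequence database is used anywhere: assembly is purely from read overlaps,
fragment masses, and intact masses.

## Mass-block overlap (chem)

Two peptide reads overlap when a suffix of one and a prefix of the other
decompose into *mass blocks*: pairs of equal-mass segments of at most two
residues each. This absorbs the classic de novo isobarics — N vs GG, Q vs
GA, SL vs TV, swapped adjacent residues — while anchoring everything in exact
residue-mass arithmetic. Block equality is symbolic (tolerance 1e-6 Da on
full-precision monoisotopic masses), not instrumental: N = GG holds exactly
in the residue table, so no ppm window is involved. The decomposition is a
small dynamic program that returns the finest (most blocks) valid
decomposition; among candidate overlap lengths the largest overlap mass wins.

Ile and Leu share a residue mass; the whole assembly works in Leu-space and
Ile is restored only at the very end from w-ion evidence.

## Intact deconvolution (intact)

A deterministic three-step procedure stands in for Bayesian charge
deconvolution: (1) a sliding RT window (default 0.1 min) merges neighboring
centroid scans, combining peaks within 0.01 Th; (2) per merged scan, peaks
are assigned charges greedily from most intense down, a neutral mass being
accepted only with supporting peaks at ≥ 2 distinct charges; (3) masses
persisting over ≥ 3 consecutive merged scans are linked into proteoforms,
each charge contributing one *feature* (m/z window × RT window), and a
proteoform must be supported by a run of ≥ 3 consecutive charges. The
inclusion list picks, per proteoform, the 4 most intense features that do
not overlap previously picked ones in *both* m/z and RT (the conjunctive
overlap rule is a choice; the disjunctive alternative would only make the
list sparser). Subunit and reduced deconvolution report monoisotopic mass;
whole-antibody deconvolution reports average mass. An averagine-based
apex-to-monoisotopic correction helper is provided for data where the
envelope apex, not the monoisotopic peak, is observed; the simulator emits
peaks at the stated mass mode so the correction defaults to off.

## Middle-down lists (middledown)

Fragment lists from the four targeted runs of one subunit are pooled by
precursor mass (50 ppm), near-duplicate masses merged to their
intensity-weighted mean. Every fragment is interpreted twice: as a c ion
(neutral mass − 17.02655 Da → prefix residue mass, PRM) and as a z ion
(− 2.00549 Da → suffix residue mass, SRM). Which z species the upstream
deconvolution reports is pipeline-dependent, so both offsets are
configuration keys. Converting SRMs to PRMs through the precursor mass would
stack the precursor's own error on every fragment (0.05 Da becomes 0.95 Da
in the worked example), so the two lists are kept separate and drive the two
assembly directions. Matching uses 50 ppm and counts each observed fragment
at most once; the match-window union makes the incremental count in the DP
identical to recounting from scratch. Middle-down coverage is matched c
sites plus matched z sites over 2 × (length − 1).

## Overlap graph and confidence accumulation (bottomup)

Reads are filtered (ALC > 0.7; longest run of residues under 0.5 local
confidence ≤ 4 — the 0.5 threshold is this package's definition of
"unconfident", reused by the assembler's NU term). Identical reads collapse
into one graph node keeping all member spectra; the node's positional
confidence is the element-wise maximum over members. An edge u → v exists
when the maximal suffix(u)/prefix(v) overlap has ≥ 3 mass blocks and v
extends past the overlap. Candidate pairs are pre-screened by exact
suffix/prefix cumulative-mass equality, which any overlap must satisfy, so
the screen is lossless.

Each node then accumulates confidence from its neighbors' overlapping
regions: one-to-one positions receive the neighbor's local confidence, any
position inside a two-residue block receives the neighbor's ALC. The update
is `min(1, original + mean(contributions))` — order-independent (neighbors
contribute their original scores), never below the original, capped at 1.
Raw unbounded summation would also rank paths consistently, but the capped
mean keeps NU (count of positions below 0.5) on a fixed scale.

Terminus classification is a pluggable contract; the default scores a read's
N-terminal (START classes) or C-terminal (END classes) residues against
shipped consensus motifs in Leu-space and returns OTHER below a 0.75
identity floor. The motif fixture is plain text and user-replaceable; any
callable mapping a peptide to one of the seven classes can be substituted.

## Assembly (assemble)

Per subunit mass, assembly is attempted three times (LC, Fd, Fc/2 start/end
sets); the attempt whose best candidate has the most middle-down matches
wins. One attempt:

* **Forward pass.** A DP table indexed by discretized path mass (width
  0.1 Da, nearest-integer index, so 111.2 Da → 1112) holds, per index, a
  bounded priority queue (capacity 10) of partial paths ranked by
  `s(p) = T + (NA − NU)`: T = matched PRMs, NA = residue mass / 111.1254 Da
  (averagine residue mass), NU = residues under the confidence threshold.
  Start peptides seed the table; paths extend along forward edges; paths
  within 4 Da of the subunit mass are terminal candidates, penalized by 5.0
  score units if their last peptide is not in the end set. Queue ties break
  toward higher T, fewer peptides, then lexicographic order.
* **Reverse pass.** Mirror image: end peptides seed, extension is leftward,
  scoring against SRMs.
* **Merge.** A forward and a reverse full-mass candidate are spliced at a
  junction where their realizations agree over a flanking window (4 residues
  before, 2 after) and the spliced mass matches the subunit within 4 Da, so
  the reverse path's covering peptide spans the joint. Junctions near the
  half-mass point are preferred (c ions cover the N-half and z ions the
  C-half, so each half comes from the direction with the better fragment
  support). Merged candidates are ranked by total middle-down matches
  (c-side + z-side recomputed on the merged sequence), ties by NA − NU,
  then lexicographically; the top 10 are reported.

Two exact prunings keep the search tractable without changing the terminal
top-1: (i) *dominance* — paths sharing (last peptide, mass index) have
identical futures, so only the best is extended; (ii) *reachability gating*
— an unscored pass over (peptide, mass index) states marks those from which
the target mass window is reachable, and the scored DP never extends into
unmarked states (removing never-terminating paths can only free queue
slots). The reachability pass closes exhaustively over *strong* edges
(overlap ≥ 5 residues, or an exact sequence overlap of ≥ 4) and treats
short isobaric-only overlaps as deviations explored in bounded tiers
(default 0 tiers, budget 150k states): coincidental 3-residue composition
matches between unrelated reads otherwise compound multiplicatively in
large read sets. The pass also refuses to extend a state into a peptide
already on its path (tracked as a visited-node bitmask): a read maps to
one position in a chain, and without this rule coincidental back-edges
form loops that pump path mass indefinitely and flood every mass bin with
states. A wide per-node register cap (24 distinct mass indices per
peptide, lowest masses first) remains as a safety net.
A mass-window beam (drop paths 30 score units below the
best path within 50 Da) additionally bounds scored exploration; it is far
wider than any legitimate isobaric alternative's deficit and can be
disabled (`beam_margin=None`), which restores the pure bounded-queue DP
(the configuration under which DP-vs-enumeration equality is tested).

## Refinement (refine)

Every read is re-aligned to the assembled sequence (exact 5-mer seeds,
cumulative-mass anchoring, mass-block verification). Single-residue identity
blocks vote for the current sequence; any other block proposes an equal-mass
rewrite of its span. A rewrite is applied when the span touches
low-agreement residues (at least min(2, span length) — a one-residue span
such as N-for-GG cannot contain two), at least 2 reads propose the identical
replacement, more than support the incumbent residues, and the supporters'
mean local confidence beats the incumbents'. Conflicting equal-support
rewrites cancel and are flagged. Accepted rewrites are isobaric by
construction, so the sequence mass is preserved exactly; the top 5 candidate
sequences (dropping the weakest edits one at a time) are retained.
The rewrite vocabulary is whatever mass-block decomposition discovers, which
subsumes the named set {N/GG, SL/TV, adjacent swaps} and is extensible by
extending the residue table rather than a rule list.

Ile/Leu: per Leu position, mapped EThcD reads with w-ion evidence vote; a
strict majority of Ile flips the residue, ties and no-evidence positions
stay Leu and are flagged. Conflicting w vs w′ evidence at one site is
weighted equally.

## Pairing (pairing)

Heavy chains are Fd + Fc/2 with one peptide bond: mass = Fd + Fc/2 − water.
A pairing requires the hinge protease motif at the junction (IdeS:
Fd ends …LLG, Fc/2 starts G…; SpeB motifs are configurable and default to
unconstrained), at least one bottom-up peptide spanning the joint, and
agreement with an observed reduced mass within 4 Da. Whole antibodies:
expected = 2 × (HC + LC) − 16 × disulfide loss (2.0159 Da per bond, two
average hydrogens; the count is configurable), accepted within 100 ppm of an
observed whole mass — lenient because partially reformed disulfides shift
the observed species. The pairing arithmetic runs in average-mass mode with
water = 18.011 Da; the expected whole mass uses the *observed reduced* HC
and LC masses rather than subunit-derived ones. All pairings passing both
gates are reported, including ambiguous extras — a mispairing that survives
the mass gates is information, not an error, and is left in the report.
Terminal modifications (C-terminal Lys loss, N-terminal pyroGlu from Gln)
are annotated as the smallest combination reconciling a sequence's
calculated mass with the observed mass.

## Synthetic data (simulate)

The generator emits all three layers from a seeded ground truth:

* **Chains.** Variable regions are sampled from vertebrate amino-acid
  frequencies behind conserved N-terminal motifs; constant regions come from
  shipped *synthetic* templates whose termini carry realistic motifs matching
  the classifier fixture (LC ends …VFNRGEC, Fd ends …CPAPELLG at the IdeS
  site, Fc/2 runs GPSVFLFP…SLSLSPGK). Defaults: LC 214, Fd 225, Fc/2 210
  residues — antibody scale, subunit masses ~23–25 kDa. With `shared_fc`,
  antibodies share Fc/2 sequences in pairs (two distinct Fc/2 chains for
  four antibodies, differing by six substitutions clustered in a
  12-residue interior window, like a real allotype motif region — reads
  spanning the window are then unambiguous about which variant they come
  from); `bispecific`
  gives the first antibody two LCs on a duplicated HC. All subunit and HC
  masses are kept ≥ 9 Da apart by rejection so the intact layer is
  unambiguous.
* **Bottom-up.** Eight independent tilings per chain (windows ~N(18, 4)
  clipped to 10–30, consecutive overlaps 6–12 residues — multi-enzyme-like
  cut-site jitter), plus junction-spanning windows over each full HC (the
  real bottom-up sample digests the whole antibody). Local confidence is
  Beta(8, 2) in read interiors and Beta(2, 2) on the two terminal residues
  (poor terminal fragmentation). Isobaric read errors (N→GG, TV→SL,
  adjacent swaps) are injected in 2% of reads away from read termini, with
  the misread region's confidence drawn low (Beta(1.5, 6)) — de novo errors
  happen where fragmentation is poor, and this is what lets the corrector's
  low-confidence gate find them. EThcD reads (half of all reads) carry
  w-ion Ile/Leu evidence for 80% of I/L positions with a 2% flip rate.
* **Middle-down.** Per chain, each of the 2(L−1) c/z sites is planted with
  probability p_hi = min(1, 1.4c) in its favored half (c sites N-terminal,
  z sites C-terminal) and p_lo = max(0, 1 − 1.4(1 − c)) in the other, which
  averages to the stated coverage c (default 0.6) and degenerates correctly
  at c ∈ {0, 1}. Gaussian 20 ppm mass noise, 5% decoy masses, fragments
  split across four emulated runs with 2 ppm precursor error.
* **Intact.** Subunit masses monoisotopic and (separately) average-mode;
  reduced and whole masses average-mode; whole = 2(HC + LC) − 16 × 2.0159.
  Mass errors 5/5/20 ppm. Optional synthesis of full charge-envelope
  centroid scans (charges 20–35, Gaussian RT profiles) exercises intact
  deconvolution end to end. Terminal modifications are available as mass
  offsets but the default scenario runs without them, keeping the assembly
  target equal to the realized chain mass; annotation is exercised by
  dedicated arithmetic fixtures.

What the generator does **not** emulate: real fragment-intensity structure,
ionization-efficiency differences beyond a scalar abundance, chimeric
spectra, glycoforms, non-isobaric de novo errors, or real antibody germline
sequence statistics. Passing the round-trip therefore shows the assembly,
scoring, refinement and pairing logic are correct under realistic mass
arithmetic and noise — not that real instrument data of arbitrary quality
would sequence at the same accuracy.

## Problem sizes and determinism

The default study scenario is four antibodies at 3:2:1:1 abundance with
shared Fc pairs — ten unique chains, ~1 900 reads, ~26 000 graph edges.
The round-trip suite runs this over 20 seeds; the acceptance script uses 5
seeds derived from its `--seed` argument; unit tests mostly use a shared
one-antibody bundle. Every random choice flows from a single integer seed
through `numpy.random.default_rng`, and a rerun with the same seed is
byte-identical down to the output FASTA.

## Known limitations

* The reachability gate's strong/weak edge split means an assembly that
  *requires* a 3-residue isobaric-only overlap between consecutive reads is
  found only if weak tiers are enabled; with tiling depth ≥ 2 this does not
  occur in practice.
* The stage outputs written to the run directory make a crashed run
  inspectable, but there is no automatic resume.
* SpeB junction motifs default to unconstrained; IdeS is the worked rule.
* Abundance reporting is relative summed intensity; no attempt is made to
  correct for ionization efficiency.
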