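# Methods

This note documents the models, conventions and design choices behind
crisprakit, in the order a user meets them.

## Coordinate frame and TSS distances

Internally every interval is 0-based and half-open. Reports use the
promoter-biology convention: the TSS is +1, the first upstream base is −1,
and there is no position 0. A target site's "distance to the TSS" is the
number of bases between a single **anchor base** of the site and the +1
base. Which protospacer base anchors the measurement is not standardized in
the field, so the anchor is a parameter with four options:

* `pam_proximal_end` (default) — the protospacer base adjacent to the PAM;
* `pam_distal_end` — the 5′ end of the protospacer (19 bases further for a
  site pointing away from the TSS, 19 nearer for one pointing toward it);
* `protospacer_center` — the 10th base from the 5′ end;
* `pam_start` — the first PAM base.

The synthetic fixtures are calibrated to whichever anchor the caller
requests, so the convention round-trips exactly. Sites downstream of the
TSS are reported with their (negative-convention) positions — they are the
relevant targets for CRISPRi roadblock repression — but always score 0 in
the activation window model.

## Target-site model

A target site is any occurrence of a 20-nt protospacer followed by an NGG
PAM, on either strand, requiring the full 20 nt of context. The PAM is
strictly NGG; the weaker NAG is deliberately excluded because activation
site design in bacteria uses NGG only. Overlapping sites are all reported.
Strand class is defined relative to the gene: a site is **non-template**
iff its protospacer lies on the coding (mRNA-identical) strand.

The window model assigns a score in [0, 1] per (strand class, distance
band). The default bands are the empirically effective CRISPRa regions:
non-template 80–90 bases upstream, template 50–80 bases upstream, score 1.0
inside and 0 outside. Two caveats are worth knowing:

* Reported characterizations of the template-strand window vary between
  50–80 and 60–80 bases upstream; the default uses the broader 50–80 band.
  Users who want the conservative band can load their own model
  (`WindowModel.from_yaml`), which accepts arbitrary non-overlapping bands
  with fractional scores.
* The binary default is a deliberate simplification: the underlying
  position–activity relationship is sharply peaked but not literally a step
  function. Band scores between 0 and 1 are supported for users who want to
  encode graded preferences.

## PAM-tiling array generation

Candidates are concatenations of the 10-nt repeat 5′-NNNCCNNNGG-3′. The
fixed GG yields a + strand NGG PAM in every repeat and the fixed CC a −
strand PAM, so anchored target sites recur with period exactly 10 on each
strand (50 per strand in a 500-nt array).

Each N is drawn i.i.d. with per-base G/C probability
`p = (L·g − f)/n` where `L` is the unit length, `g` the whole-sequence GC
target, `f` the count of fixed G/C bases per unit (4) and `n` the count of
N positions (6); G/C split the GC mass equally and A/T the remainder. This
makes the **whole-sequence** expected GC equal the target — the quantity
with biological meaning — rather than the GC of the N positions alone. The
fixed bases impose a floor: targets at or below f/L = 0.4 are infeasible
and rejected with an explanatory error. The default target of 0.508 is the
*E. coli* genomic GC content; it is a configurable default, not a derived
constant.

Filters run in the fixed order homopolymer → TF sites → genome homology.
They are independent predicates, so the order cannot change any candidate's
verdict — only which filter a rejection is attributed to in the attrition
table. Choices within each filter:

* **Homopolymer**: fail iff any run of one base reaches 4 (runs of 3 pass);
  the run-length cap is a parameter.
* **TF sites**: exact substring matching of each listed site on the
  candidate and its reverse complement. Exact matching is the only
  threshold-free reading; motif/PWM scanning is out of scope.
* **Genome homology**: exact shared-k-mer screening with k = 15 by default,
  counting query positions whose k-mer occurs anywhere in the genome on
  either strand. This is a deterministic, alignment-free homology screen; k
  is configurable (k = 15 makes chance hits against a ~4.6 Mb genome rare
  while catching any meaningful identity).

The generation scale defaults to 10,000 candidates of 500 nt. The "pick
one arbitrarily" step among passing candidates is made reproducible as
*first passing index under the seed*: determinism beats fidelity to an
unrecorded arbitrary choice. The 170-nt fragment placed upstream of the
minimal promoter defaults to the promoter-proximal (3′) end of the array;
which window of the original array was used in published constructs is not
recorded, so the placement is configurable.

## Guide assembly

Scaffold templates are data, not code: an RNA-alphabet string with exactly
one `[SPACER]` placeholder plus labelled hairpin intervals. The shipped
templates are **synthetic stubs** assembled from the canonical S. pyogenes
guide scaffold and wild-type MS2/PP7 aptamers. They preserve the structural
facts the toolkit checks — hairpin counts per variant, terminator presence
or absence, and the single-base b1/b2 difference (placed at the 3′ end of
the scaffold core, the 5′ junction of the terminator hairpin in
terminator-bearing designs) — but they are not the exact published
construct sequences, which ship with the original reagents. Real sequences
go in a YAML config (`load_scaffold_config`).

Validation is a pure report: spacer/protospacer identity when a target site
is attached, expected hairpin complement per variant, and an efficacy
warning for sgRNA 2.0, which shows no significant activity in *E. coli*
despite working well in eukaryotes. Guides are emitted as DNA for cloning
by default, with an RNA flag.

## Quantification

All formulas are the standard ones: Miller units
`1000·A420/(OD600·volume·time)` with the assay volume a parameter
(default 0.02 mL); ΔΔCt fold change `E^(−ΔΔCt)` with the amplification
efficiency defaulting to the classic 2 (no efficiency correction);
fluorescence/OD600; yield = titer / initial glucose (default 20 g/L, i.e.
2% w/v). Linker geometry uses the contour-length approximation of
3.8 Å/residue and the B-DNA rise of 3.3 Å/bp; `reach_in_bp` floors, since
partial base pairs are meaningless, with a 1e-9 epsilon so exact multiples
of the rise are not lost to float rounding. Replicate summaries offer both
mean±sd (plate-reader convention) and median±sd (flow-cytometry
convention).

## Synthetic fixtures

`make_promoter_with_sites` builds a background in which the entire upstream
window (plus a 25-nt margin past the TSS) contains no GG or CC
dinucleotide — hence no NGG PAM on either strand — then plants
protospacer+PAM cassettes so the configured anchor lands at exactly the
requested distance on the requested strand class. Stray PAMs that
planting could create at cassette junctions are repaired by mutating the
background member of the offending dinucleotide to A/T, and the finished
promoter is verified against the scanner before it is returned, so the
expected-site list is a true oracle. The PAM-free constraint is applied
only within the scanned window; fully PAM-free sequences would be
unrealistically AT-rich. Downstream decoy PAMs can be added at a chosen
density to exercise the downstream-flagging path.

Each generator draws from its own seeded substream (promoter, TF list,
genome), so fixtures built from the same seed are statistically
independent of each other while remaining byte-reproducible from
(seed, spec).

What the fixtures do **not** emulate: real promoter base composition
(backgrounds are uniform-random subject to the PAM constraint), chromatin
or supercoiling context, and — most importantly — expression outcomes.
Measured activation levels are wet-lab quantities; a passing test here
shows the geometry, scanning and scoring machinery is exact, not that a
scored site will activate.

## Problem sizes and numerics

The test suite runs the scanner-oracle comparison on 200 random sequences
up to 1 kb, each filter against its brute-force oracle on 100 random
instances, and the GC calibration on 2,000 (unit test) and 10,000
(acceptance script) seeded 500-nt candidates, judged within three standard
errors of the binomial sampling bound — sizes chosen so the whole suite
runs in seconds while leaving the stochastic checks well-powered. All
randomness is seeded; hypothesis runs derandomized.

## Known limitations

* No genome-wide off-target scoring or mismatch-tolerance model; the
  homology filter is an exact-k-mer screen, not an aligner.
* No CRISPRi efficacy model: downstream sites are reported, not scored.
* No RNA secondary-structure prediction for assembled guides; validation is
  structural bookkeeping, not folding.
* The binary window default ignores activator identity, though the
  effective window is known to vary somewhat between activators and
  recruitment hairpins (PP7-recruited activators, for instance, behave
  differently on the two strands).
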