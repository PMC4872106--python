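# Methods

## The charge-state model

The scaffold model reduces an Ocr-family variant to a boolean vector over
the chargeable positions of a 116-residue reference: position *i* is
either acidic (Asp/Glu, as in wild-type Ocr) or neutral (the isogenic
Asn/Gln, as in pocr). This is exact for the design space under study —
every construct differs from the reference only by isogenic
acidic↔neutral swaps — and makes the sequence space literally 2³⁴. The
model deliberately carries no structural information: regions are
positional sets, not 3-D objects, and folding, dimerisation and thermal
stability are outside the model.

Each chargeable position belongs to exactly one of three regions mapping
onto the parts of the Type I recognition footprint that Ocr mimics
(central/orange, specific/green, flanking/purple), with two overlay sets
(loop 1, loop 2) and the single helix-D position 88. The published record
constrains |central| = 9, |loop 1| = 5, |loop 2| = 7 and the identity of
position 88, but not the residue numbers of the regions; the packaged
canonical map (|specific| = 10 with loop 1 and position 88 inside it,
|flanking| = 15, loop 2 inside central) is therefore a **config file
default, not a fact** — every analysis accepts a user map, and the
shipped scaffold sequence is synthetic (it reproduces the charge
architecture, not the real Ocr sequence, which users can supply as
FASTA + YAML). Position numbering is 1-based over the monomer.

Artifact classes: an empty sequence is an `empty_vector`; a length
mismatch or internal stop is a `frameshift_deletion`. Both are excluded
from profiling and classification (`NonExpressing`), mirroring constructs
that cannot express the scaffold.

## Isoelectric points

pI is computed from ionisable-group counts by bisection (tolerance 10⁻³
pH) on the Henderson–Hasselbalch net-charge function; the function is
strictly monotone in pH, so the root is unique. Default pKa values are
the Bjellqvist set used by the common pI/Mw web calculators (Asp 4.05,
Glu 4.45, Cys 9.0, Tyr 10.0, His 5.98, Lys 10.0, Arg 12.0, N-term 7.5,
C-term 3.55); the `PkaSet` is injectable so alternative scales can be
compared. Compositions are read from the actual sequence when one exists
(the synthetic backbone contains no Cys/Tyr/His, keeping abstract
compositions clean); for a fixed scaffold a clone's composition depends
only on its (nD, nE) acidic counts, which the screen exploits via a
lookup table. The test suite checks the bisection against a 0.001-step
grid scan and, inside its limited search window, against biopython's
independent implementation.

## The activity and toxicity rules

Activity requires all five conditions simultaneously: pI ≤ 4.5, total
acidic ≥ 14, central ≥ 6, specific ≥ 3, flanking ≤ 47 % of total. All
bounds are inclusive, following the wording of the source conditions
("at least", "no more than", "4.5 or less"). The flanking share is
compared as an exact rational (100·f ≤ 47·t), never rounded first; a
variant with zero total charge has an undefined share and fails closed —
pocr must classify inactive. On the canonical scaffold the pI condition
is never the binding constraint near the boundary (14 acidic vs 6 basic
already gives pI ≈ 4.15), so the 14-charge threshold is what separates
actives; whether pI ≤ 4.5 is ever independently binding for realistic
compositions is left open, and both conditions are evaluated as stated.

Toxicity is predicted from the single stated rule — neutrality at
position 88 removes the hydrogen bonds pinning loop 2 and correlates with
host toxicity — and is a heuristic with known exceptions. Phenotype
precedence: `Toxic` is emitted only for otherwise-active clones (the
"3.11" situation of full activity plus toxicity); charge-rule failures
are `Inactive` regardless of position 88, since pocr itself is inactive,
not toxic. The `toxic_risk` flag is raised for any intact pos88-neutral
clone. `PartiallyActive` is never produced by the rules: the observed
partially active group overlaps the inactive and toxic groups in charge
composition, and inventing a discriminator would overstate the model; the
label exists only for imported experimental datasets.

## The ISOR simulator

Each round, every output clone derives from a uniformly sampled intact
parent (with replacement — total DNA is pooled between rounds; empty
vectors are lost during re-amplification and frameshifts contribute no
usable template). The number of new acidic substitutions is
k ~ Poisson(μ·m/34) truncated at the parent's m remaining neutral
positions. The thinning factor m/34 models oligonucleotides that target
codons regardless of current state (hits on already-acidic codons are
silent), which yields the closed-form expected load 34·(1−(1−μ/34)ʳ)
after r rounds; the Poisson shape itself is a modelling choice — the wet
data report only means and ranges.

Positions are selected sequentially without replacement with two weights:

* **pool balance** — candidates are down-weighted by 1/(1+p) where p is
  the number of picks already made this round in the candidate's pool
  (default pools: positions interleaved mod 4, so each pool contains only
  non-contiguous codons, as the four separate mutagenesis reactions
  require);
* **adjacency penalty** — while active (rounds 1–2 by default, factor
  0.5), a candidate's weight is multiplied by bias^(number of
  already-acidic neighbours in position order, previous rounds included).
  This reproduces the observed library bias against consecutively mutated
  codons introduced by fragment reassembly; the final round, which used
  degenerate oligonucleotides covering successive sites, runs with the
  penalty off (factor 1.0).

Substitutions are irreversible. Artifact fractions are applied after
mutagenesis: 10 % frameshift/deletion in the final round, 2 % empty
vector in round 1, both configurable. A single seeded NumPy generator
drives a run; identical seeds reproduce libraries bit for bit.

**Calibration to the sequenced per-round ranges.** The reference
three-round protocol (`default_protocol_params`) uses μ = 5 in round 1
(the measured first-round mean) and μ = 4.5 afterwards, and clips each
clone's cumulative load into the sequenced support of the corresponding
wet library: ≤ 13 through rounds 1–2 and 8–17 after round 3
(`cumulative_range`). Physically, oligo incorporation is self-limiting
(raising oligo concentration beyond ~2× the working value inhibits
reassembly altogether), so an unbounded Poisson tail is unrealistic; the
sequenced ranges are the best available description of the realised
support. This truncation is what makes the protocol recapitulation sharp:
no clone can cross the 14-charge activity boundary before round 3, so
rounds 1–2 are silent and positives first appear in round 3, at every
seed. Standalone `RoundParams` default to no truncation, preserving the
closed-form mean-growth behaviour.

## The selection screen

The 2AP plate assay is abstracted to a boolean filter: a clone survives
iff the activity rule passes. Toxic-risk actives are recovered by default
(the wet screen did recover the toxic active 3.11); `exclude_toxic`
drops them. Partial activity confers no survival in the model — the
screen is binary, as the degree of growth advantage of partially active
clones on 2AP is not quantified. `run_protocol` always seeds the next
round with the full current library, not the positives.

## Sequence-space estimate

`estimate_space` keeps the arithmetic exact: 2ⁿ as an integer, the active
fraction and expected actives as `Fraction`s; log₂ is taken only at the
end and `implied_charges` uses round-half-to-even. For the published
inputs (n = 34, 1.2 × 10⁶ screened, 4 unique actives) the exact expected
count is 2³⁴·(4/1.2 × 10⁶) ≈ 5.7 × 10⁴ ≈ 2^15.8, reported both as the
real log₂ and as the rounded 2¹⁶; the fraction is formatted at one
significant figure (0.0003 %) while the exact ratio stays in the data
model.

## What the synthetic data do and do not show

The generator reproduces the *statistical* structure of the study:
mutation-load means and ranges per round, artifact fractions, pool and
adjacency structure, the charge-count architecture of the named clones,
and labelled groups with prescribed charge composition. It does not model
nucleotide-level mechanism (fragment sizes, reassembly thermodynamics,
oligo kinetics), folding or expression beyond the artifact classes, or
the real positional identities of regions. Consequently, passing tests
show the pipeline's logic and calibration are right, not that the rule
set would generalise to real sequences; in particular the simulated
round-3 positive rate (~2.6 % at the calibrated load) is far above the
observed 7 in 1.2 × 10⁶, because every constraint on activity beyond
charge composition (folding, stability, expression) is outside the
model — the simulator's classifier *is* the ground truth of the
simulation. Problem sizes in the tests and the acceptance script (10⁵
clones per round, 10 seeds; 10⁴ clones for artifact fractions; 30-clone
sequencing samples) are the package's default working sizes and scale up
via parameters.

## Numerical and degenerate-input choices

* Bisection bracket [0, 14] pH; error if no sign change (no ionisable
  groups, or pathological compositions).
* Weighted sampling uses cumulative-sum inversion per clone row;
  ties are impossible with continuous uniforms.
* Zero-total profiles: flanking share undefined → all ratio rules fail.
* `mutation_count_stats` errors when a sample contains no intact clone;
  artifact fractions are reported over the whole sample.
* Empty libraries, missing RNGs, mismatched scaffolds, non-partition
  region maps and out-of-range positions raise typed errors naming the
  offending quantity.
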