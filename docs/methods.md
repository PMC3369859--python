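# Methods

This note records the models, conventions, and numerical choices behind
`bovmito`, in the spirit of a package vignette: what is computed, under what
assumptions, and where the edges are.

## Coordinate system and variant notation

The reference mitogenome is circular, 1-based, and carries named regions;
the canonical bovine layout places the control region at nps 15718–517
(wrapping the origin of the numbering) and the coding region at nps
364–15791, i.e. 15,428 sites. Intervals with `start > end` denote
wrap-around, and membership, length, and iteration all honour the circle.

Variants are written relative to the reference in the compact field
notation: a bare position is a transition (the purine↔purine or
pyrimidine↔pyrimidine exchange is implied by the reference base), an
explicit base suffix denotes a transversion, `+X` an insertion after the
position, `d` a deletion, a leading `@` a back mutation (reversion toward
the reference state, meaningful relative to a haplogroup or tree context),
and a trailing `h` heteroplasmy. Labels round-trip through the parser. As an
extension of the printed single-base convention, a multi-base insertion is
one entry with the full inserted string (`2055+CC`) rather than several
identical single-base entries, which set semantics would collapse.

## Variant calling

`call_variants` aligns a sample sequence to the reference over a region with
edlib's global (Needleman–Wunsch) edit-distance alignment and converts the
alignment path to variant calls. For mitogenomes that differ by isolated
point changes and short indels this is exact and fast; affine gap costs
would change nothing at these divergences. Indels are left-normalised to
their 5'-most equivalent coordinate after alignment, matching the convention
in which `2055+C` and `1600d` are written. Two-base IUPAC codes (R/Y/W/S/K/M)
in a sample are read as heteroplasmic positions; a heteroplasmic position
counts as carrying the variant for classification and distance. Samples
shorter than the region minus a 50-bp indel slack raise a coverage error
rather than producing a truncated profile.

## Classification

The haplogroup hierarchy ships as a versioned YAML file (name, parent,
marker labels, unstable positions) and can be extended without code changes;
only the T1 portion is validated. Marker region class (control vs coding) is
derived from the marker's coordinate.

Scoring: a matched coding-region marker scores 2, a matched control-region
marker 1, and a matched declared-absence (`@`) marker 0.5 — absences are
weaker evidence than observed mutations. Positions known to recur (16050,
16113, 16122) are flagged unstable and carry control weight. The root screen
accepts the full 16050–16113–16255 motif or any two of the three including
16255, the motif's stable anchor; a profile whose covered region does not
span the motif raises a coverage error, which is distinct from a negative
screen.

Below the root, every positive marker on a node's path must be present, with
one exception: a single missing marker is tolerated when a coding-region
marker at the same or a deeper node confirms the path (the survey's
reversion cases: lacking 16050 while carrying 7542 is still T1b). A node
whose definition includes an absence is excluded outright when the profile
carries that mutation. Nodes with exactly one unjustified missing marker are
not eligible as the assignment but are reported as ranked alternatives when
they match evidence the best path does not explain; the call is flagged
ambiguous when the runner-up scores within one marker weight of the best.
This reproduces the behaviour a curator applies to profiles like
16113–16255–16122 (assigned T1c, ambiguous against T1e) without admitting
arbitrary matches. Profiles carrying incompatible sub-haplogroup markers
(e.g. both 7542 and 6235) are reported ambiguous with both candidates rather
than resolved by fiat.

Frequency aggregation pools deep clades into their top-level sub-haplogroup,
emits per-breed rows with country, continent, and grand totals, and rounds
percentages half-up to one decimal — the convention of printed survey
tables. Samples without metadata go to a rejects list and are excluded from
all totals.

## Parsimony trees

Haplotypes are presence/absence vectors over the observed variant
positions; a tree explains them by mutations accumulating from a supplied
ancestral profile, with internal nodes acting as Steiner points. Identical
haplotypes collapse to one tip with a multiplicity.

For up to 8 distinct haplotypes (configurable) the search is exact:
branch-and-bound over leaf-labelled binary topologies (the ancestral profile
enters as an extra leaf), scored by bit-parallel Fitch counting. Parsimony
scores are monotone under leaf insertion, so partial topologies at or above
the incumbent are pruned. The default threshold reflects the worst case of
the topology space, (2n−5)!! for n leaves: 9 leaves mean at most 135,135
topologies, which is instantaneous, while each further taxon multiplies the
space by ~2n. Above the threshold a greedy agglomeration attaches
haplotypes (sorted by distance from the root) to their nearest node and then
factors mutations shared by two or more children of a node into new internal
nodes until no sharing remains; this recovers star-like and shallowly nested
structure well, which is the regime mitogenome surveys live in.

Ancestral states come from a Fitch backtrace that resolves ties toward the
parent state, which makes labellings deterministic; remaining co-optimal
topologies are resolved by the deterministic insertion order (haplotypes
sorted by distance from root, then sample id). Each edge carries its ordered
mutation list; a change away from the ancestral state is a gain, a change
back is annotated as a back mutation, and any position mutating on more than
one edge is flagged recurrent. Newick output embeds the mutation lists as
bracket comments; an edge table TSV carries the same information.

## Dating

ρ is the multiplicity-weighted mean number of qualifying mutations on the
clade-root→tip path; by default only substitutions inside the coding region
qualify (indels and control-region changes are excluded, both togglable).
Back mutations of substitutions count as substitution events; heteroplasmic
substitutions count once. The heuristic standard error is

σ² = n⁻² Σ_e l_e·m_e², with l_e the qualifying mutations on edge e and m_e
the multiplicity-weighted tips below it. For a star tree with unit terminal
branches σ = √(ρ/n); the implementation is validated against this closed
form and against the two-tip value 0.707, which holds for both partitions
{1,1} and {2,0} of two mutations.

Time is T = ρ·r with r = 3,172 years per substitution over the whole coding
region. Ages are reported in ka rounded half-up to one decimal; ρ and σ to
three decimals. A per-site divergence d converts as T = d·L·r with
L = 15,428 sites. Note that converting a divergence value already rounded to
five decimals can disagree in the first decimal with an age computed from
the unrounded estimate (0.00026 converts to 12.72 ka here); the shipped
regression table therefore anchors on the ρ/σ columns, where the printed
precision is sufficient for exact round-tripping of all twelve rows.
Printed σ values for multi-level clades depend on branch structure not fully
recoverable from text; the table marks which rows are validated under a
star assumption.

## PCR-RFLP simulation

Primer binding allows up to 3 mismatches (configurable) outside the
3'-terminal 2 bases; any mismatch in those terminal bases abolishes
amplification — the standard polymerase-extension behaviour. A primer
binding at more than one site is an ambiguity error, none at all a
no-amplification error. The product spans the outer primer ends and carries
the primer bases, so engineered mismatches (the HinfI site across np 7542)
exist only in the amplicon. Digestion scans the forward strand with IUPAC
degeneracy; GANTC is its own reverse complement, so one strand suffices (a
property the tests verify against explicit double-strand scanning).
Fragment calls tolerate ±2 bp per fragment, mimicking 4% agarose
resolution.

The assay template is synthetic: the constitutive GANTC site is placed with
its G at np 7396, the coordinate implied by the printed fragment sizes
(7335–7396 = 62, 7397–7542 = 146, 7543–7569 = 27) but not itself printed.
If the true reference places it elsewhere, the fragment multiset logic is
unaffected but the fragment order along the amplicon could differ.

## Synthetic data

The generators exist so every pipeline stage can be exercised end to end
without downloads, at the study's scale.

* `generate_reference` draws a random circular sequence (default 16,338 bp,
  GC 0.4) with the canonical region coordinates, scaled proportionally at
  other lengths. At the canonical length the two marker-indel sites are
  given the anchoring context of the real reference (no C immediately at
  np 2055, distinct bases at nps 1599/1600) so that `2055+C` and `1600d`
  remain the 5'-most representations, as they are on the real sequence.
* `generate_cohort` synthesises full genomes at specified
  breed × sub-haplogroup counts; the shipped count table totals 281 samples
  across 28 breeds. Each sample carries its node's complete marker path,
  Poisson(λ = 1 by default) private mutations at positions diagnostic for
  nothing, and optional reversions of control-region diagnostics at a
  stated per-position rate. With zero noise, re-classification recovers the
  generating counts exactly — the round trip the tests assert.
* `simulate_expansion` models a neutral founder expansion of known age:
  every root-to-tip path accumulates Poisson(age·1000/r) substitutions at
  uniformly drawn coding-region positions (transitions with probability
  0.95; positions 16050/16113/16122 receive 20× weight when the drawing
  region includes them). Topology is a star by default — the signature of a
  rapid expansion — or a random binary split tree whose node ages are drawn
  uniform below their parent, which preserves the Poisson root-to-tip
  marginal. Both the tip profiles and the true genealogy are returned, so ρ
  on the true tree isolates mutational noise from tree-estimation error.

What the generators do not emulate: demographic structure (bottlenecks,
migration, selection), rate heterogeneity beyond the three hotspots,
sequencing error, and alignment artefacts of real chromatograms or reads.
Passing round-trip tests therefore demonstrate the internal consistency of
the pipeline, not its robustness to real-world noise.

## Pipeline

`run_pipeline` executes variants → classification → frequency tables →
parsimony tree → clade dating, writes TSV/newick outputs, and records a
manifest with SHA-256 digests of every product; identical configurations
produce identical digests. Validation (missing files, malformed records,
id mismatches, duplicates) runs first and never mutates inputs. Stage
failures halt with the stage name and the offending sample ids.

## Known limitations

* The exact parsimony search is practical only to ~8–10 distinct
  haplotypes; beyond that the greedy heuristic gives no optimality
  guarantee (the oracle tests bound its behaviour only at small sizes).
* The classifier's tolerance rule admits exactly one missing path marker;
  profiles with two independent reversions on one path fall back to the
  deepest defensible node rather than the curated assignment.
* Maximum-likelihood branch lengths are out of scope; per-site divergences
  can be stored and converted to ages but are never estimated here.
* In-silico PCR models binding by mismatch counting only — no melting
  temperature, secondary structure, or multi-enzyme digests.
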