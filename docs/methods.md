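# Methods

## The assay being modelled

Lineages of *Pocillopora damicornis* carry fixed indels in the
mitochondrial putative control region (between *atp8* and *cox1*): an 8 bp
deletion fixed in Type α and a 6 bp deletion fixed in Type β. The primer
pair Pdam-F (`AAGAAGATTCGGGCTCGTTT`) / Pdam-R (`CGCCTCCTCTACCAAGACAG`)
brackets both indel sites, giving amplicons of 705 bp (α), 707 bp (β) and
713 bp (all other *Pocillopora*). Because 705 vs 713 bp is hard to resolve
on a routine gel, the amplicon is digested with AluI; the deletions sit in
different restriction fragments, so each lineage gets an unmistakable band
pattern: α {84, 116, 389}, β {92, 110, 116, 389}, other {92, 116, 389}.
This package reproduces every step of that logic on sequences.

## Primer binding and amplification

A primer anneals where all of its bases pair with the template under IUPAC
set-intersection (`N` pairs with everything), subject to two stringency
controls:

* `max_mismatch` (default **0**) — non-intersecting base pairs tolerated.
  The default models the assay's reliance on exact binding; the wet
  chemistry's true tolerance is unknown, so 0 is an in-silico convention,
  not a claim about the polymerase.
* `require_3prime_exact` (default **3**) — 3′-terminal bases that must pair
  regardless of budget, mirroring the polymerase's extension requirement.

Both strands are searched; a minus-strand site is an occurrence of the
primer's reverse complement, reported in plus-strand coordinates
(0-based, half-open internally; 1-based inclusive in CLI output).

An amplicon is produced for every upstream/downstream site pair in either
orientation (forward primer on plus with reverse primer on minus, or the
mirror arrangement), provided the sites do not overlap and the product is
at most `max_product` (default **5000 bp**). Product length runs from the
upstream primer's 5′ base through the base pairing the downstream primer's
5′ base inclusive, which is how PCR product sizes are conventionally
reported — the 705/707/713 bp lengths include both 20 bp primer regions.
Multiple products are returned rather than raising: downstream typing
flags such templates as `MULTI_AMPLICON`, the in-silico analogue of an
ambiguous lane. Templates are treated as linear; a circular mitochondrial
genome must be linearised outside the target region first.

## Digestion and band patterns

Digestion is complete: every occurrence of the recognition site is cut,
including overlapping occurrences. Sites are matched on the plus strand
with IUPAC awareness; for palindromic sites (AluI, AG^CT with
`cut_offset=2`) this equals a double-strand search, and a warning is
logged for non-palindromic enzymes since minus-strand nicking is not
modelled. A site overlapping an `N` counts as a cut and logs a warning —
surfacing uncertainty was preferred over silently dropping fragments. The
AluI cut offset is standard enzymology (it is what makes the fragment
arithmetic close), not something the band sizes alone could determine.

Fragment sizes collapse to a band pattern in two steps: sizes below
`min_detectable_bp` (default **0**) vanish, then single-linkage grouping
merges adjacent sizes differing by at most `resolution_bp` (default **0**)
into one band whose size is the group mean rounded to the nearest bp and
whose multiplicity is the group count. Single linkage makes band count
monotone non-increasing in resolution, and guarantees adjacent reported
bands differ by more than the resolution. The `--gel` preset
(`resolution_bp=4`, `min_detectable_bp=50`) emulates a 4% high-density
agarose gel, which still separates 110 from 116 bp.

## Typing

Classification mechanises manual lane scoring. Observed band sizes are
deduplicated — a gel cannot count co-migrating fragments, so multiplicity
is ignored — and an entry of the pattern table matches when the distinct
observed sizes pair one-to-one with the entry's sizes, each pair within
`tolerance_bp`. The built-in table uses tolerance **2 bp**: the closest
same-cardinality entries (α vs other) differ by 8 bp in one band, and the
table constructor rejects any entry set in which a single lane could match
two entries at the configured tolerance. Outcomes form a closed
enumeration: the three lineage calls plus `NO_AMPLIFICATION`,
`MULTI_AMPLICON` and `UNKNOWN_PATTERN`. Sequence typing digests at
resolution 0 (exact in-silico sizes); the tolerance exists for observed,
gel-estimated sizes.

## Indel discovery and assay evaluation

Given a gapped alignment with a lineage label per row, a diagnostic
deletion for lineage L is a maximal run of columns gapped in **every** L
row and in **no** other row; an insertion is the converse. Support is
therefore always 1.0 — fixed differences are what a presence/absence assay
needs — though the column test, not a threshold scan, enforces this.
Runs shorter than `min_length` are dropped; runs for the same lineage
separated by a non-gap column stay separate. With exactly two lineages,
one lineage's deletion is formally the other's insertion over the same
columns; the reported call is the minority lineage's (its state deviates
from the alignment consensus), with deletion preferred on ties.

`evaluate_assay` runs amplify → digest → band pattern for the first
template of each lineage (cross-checking any further templates and
flagging discordance rather than failing), then tests each lineage pair
for distinguishability: two patterns are confusable at a resolution when
they have equally many distinct sizes and corresponding sorted sizes
co-migrate. `select_enzyme` ranks a catalog by distinguishable pairs
(descending), then total band count (fewer bands — simpler gels — first),
then name.

## The synthetic-template generator

Real templates are GenBank mitochondrial sequences; the generator emulates
only the features the assay reads, so the whole pipeline is testable
offline and deterministically. The reference ("other") amplicon is built
from four segments of 92, 116, 116 and 389 bp with an AluI site straddling
each junction (`…AG|CT…`), the forward primer as its first 20 bp and the
reverse-primer binding region as its last 20 bp, embedded in 50 bp flanks
(default) of non-amplified context so that amplicon extraction exercises
real coordinate logic. The α variant deletes amplicon positions 40–48
(8 bp, inside segment 1); the β variant deletes 147–153 (6 bp, centred in
segment 2). Published data do not locate the indels within the amplicon,
nor say which of the two 116 bp fragments shrinks to 110 bp; these
positions are conventions of this generator — the resulting band patterns
are identical for any compliant choice.

Filler bases are drawn uniformly from {A,C,G,T} by a per-seed PRNG stream,
with a suffix rule that never completes an `AGCT`, and the assembled
template is rejected (and regenerated from a derived sub-seed) unless all
constraints hold: AluI sites exactly at the three junctions, both in the
reference and after either deletion; exactly one binding site per primer
and none in any other orientation. Panels apply independent per-base
substitution noise (`noise_rate` default **0.01**, capped at 0.05) outside
protected motifs — primer regions, junction sites, deletion windows — and
a substitution that would create a new `AGCT` is resampled, so every panel
member's cut positions equal its noiseless progenitor's. The alignment
generator places gap runs at the known deletion windows instead of
invoking an aligner, since producing alignments is out of scope.

What the generator deliberately does not emulate: real control-region
sequence composition (microsatellite-like repeats, AT bias), the γ/δ/ε
lineages and *P. verrucosa* as distinct sequences (all are represented by
the single "other" reference), the Lord-Howe-Island α variant, and
circular genomes. Passing tests therefore demonstrate the correctness of
the assay logic — coordinate arithmetic, digestion, pattern matching,
discovery — on sequences with the published geometry, not the assay's
sensitivity to real-world sequence diversity; validating against real
GenBank templates remains a (network-requiring) exercise for the user.

## Problem sizes and determinism

The test suite and the acceptance script work at the assay's natural
scale: templates around 0.8 kb, a 145-member panel (61 α / 54 β / 30
other, matching the published validation panel) at 1% noise, label
recovery across 20 seeds, and brute-force cross-checks of primer search
and digestion on random sequences up to 2 kb. Everything derives from
explicit integer seeds; repeated runs, including CLI fixture output, are
byte-identical.

## Known limitations

* Partial digestion, star activity, methylation sensitivity and
  double-offset enzymes are not modelled.
* No thermodynamics: primer sites are found by string matching, not
  melting temperature, so the specificity screen is a necessary but not
  sufficient wet-lab check.
* Band intensities are not modelled; multiplicity is carried through the
  pipeline but ignored in classification, as on a real gel.
* SNP-based (CAPS) marker design from substitutions is out of scope, as is
  automatic primer placement around discovered indels.
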