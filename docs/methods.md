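# Methods

This note documents the models, rules and numerical choices behind
`mitoscaffold`, and what the synthetic benchmarks do and do not show.

## The genome model

A plant mitogenome is represented as a set of **molecules**, each a
circular or linear arrangement of **pieces**: unique single-copy
segments and copies of **structural repeat families**. Each molecule
carries an integer stoichiometry (its relative abundance among
mitochondrial DNA molecules). Repeat-mediated recombination is modelled
structurally: the same repeat family placed between different pairs of
unique segments (A–R–B in one molecule, C–R–D in another) creates the
alternative junctions seen in real data as one high-coverage contig
with four long-read-supported partners.

Two repeat tiers are distinguished deliberately. Repeats longer than
what paired 150 bp reads resolve (structural families, default
2.5–6 kb) collapse into a single contig in a short-read assembly —
they are the units the scaffolder must multi-place. Repeats in the
50–200 bp bulk of the organelle repeat-size spectrum are *embedded*
inside unique segments: a short-read assembler walks straight through
them, so they never appear as separate contigs, but the repeat finder
must still count them. A heavy tail of very long repeats (≥ 10 kb) can
be simulated by widening the structural length range; planting ≥ 10 kb
identical blocks *inside* "unique" contigs would contradict the
premise that those contigs are unique, which is why the embedded tier
is capped at sub-insert scale.

### Generator defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| GC target | 0.46 | conifer mitogenome GC content |
| unique segments | 8 × 8–30 kb | contig-scale pieces; total genome 100–300 kb so suites run in minutes (real mitogenomes are Mb-scale; all thresholds scale via config) |
| molecules | 1 circular + 1 linear, stoichiometry 1 | the mixed circular/linear population |
| structural repeats | 2 families × 2 placements, 2.5–6 kb | collapse-scale repeats; one family gets four distinct flanks (alternative junction) |
| embedded repeats | 4 pairs, 50–200 bp | the bulk of the repeat-size spectrum |
| long reads | log-normal, mean 14 kb, σ=0.45, truncated [1 kb, molecule], depth 20 | matches the length profile of the long-read data the method is designed for |
| short reads | 2×150 bp, insert 450±50, depth 30 | standard paired-end input |
| MTPT inserts | off by default; tests plant 100–500 bp at identity 0.95 | plastome-derived regions are a property of the genome, not of every simulation |

Gene-hit labels (the stand-in for BLAST against known mitochondrial
genes) are assigned to a random half of the contigs **plus the
lowest- and highest-coverage contigs**: in real data the gene-based
selection spans low-stoichiometry and repeat contigs (gene fragments
occur in repeat regions), and that span is precisely what defines the
coverage range used by the second selection criterion. Without this,
noise-free simulated coverage would give a degenerate range.

`fragment_to_contigs(junction_trim=g)` optionally trims up to `g`
bases (≤ ¼ of the piece) from junction-facing contig ends, emulating
assemblies that stop short of junctions; the missing sequence can then
only be restored from long-read junction fills, which is what makes
the polishing benchmark meaningful. The default is 0, which preserves
the exact conservation identity Σ(contig length × expected relative
coverage) = Σ(molecule length × stoichiometry).

## Selection and copy classes

Criterion 1 selects any contig with a mitochondrial gene hit,
regardless of size or coverage; the coverage range [min, max] of those
contigs then defines criterion 2 (length ≥ 2000 bp, coverage inside
the range, boundaries inclusive — ties at the exact boundary are kept
because exclusion would have to discard data on a measurement that is
itself noisy). Copy classes use the ratio to the median coverage of
the selected set: `low` < 0.80, `single` in [0.80, 1.25), `multiple(k)`
when the ratio is within ±0.15 of an integer k ≥ 2, otherwise
`intermediate(k, k+1)` between the bracketing integers. The
0.80/1.25/±0.15 constants are package defaults chosen to reproduce the
canonical verbal partition of coverage classes (32–71× low, 79–107×
single, 120–204× repeat-like at a median of 89×) and are exposed in
`ClassBands`. Everything at ratio ≥ 1.25 is flagged *repeat-like* and
becomes eligible for multi-placement.

## Scaffolding

Alignment is k-mer seeding (k = 15, query stride 7) with diagonal
clustering, edlib verification, and an exact-match fast path; per
(read, contig, location) only the best hit survives, but a read that
traverses a repeat twice legitimately keeps two hits at its two
locations — collapsing them would fabricate adjacencies between the
repeat's flanks.

A read contributes evidence for the junction between two consecutive
anchored hits when (i) both hits reach their junction-facing contig
terminus (±50 bp slack), (ii) the gap or overlap between the contig
projections on the read is ≤ 1 kb (rejects chimeric joins), and
(iii) at least one side carries the strong anchor — full contig
coverage or a terminal overlap ≥ min(10 kb, 0.9 × contig length). The
asymmetry reflects how the manual procedure works: the 10 kb rule
selects reads relative to the current seed; the adjacent partner is
then identified from any convincing terminal match (≥ 500 bp here).
For contigs shorter than the thresholds both shrink to 0.9 × length.

Junctions are canonical unordered pairs of (contig, end∈{5′,3′}),
which encodes relative orientation without reference to a scaffold
strand; orientation conflicts among a junction's reads therefore
cannot arise — conflicting orientations are simply different end
pairs, and they compete under the ambiguity rule. Extension accepts a
partner only with ≥ 3 supporting reads; with two or more qualifying
partners at a non-repeat end, extension stops and the alternatives go
to the adjacency report (a dominant repeat partner is the one
exception, since repeats genuinely take several paths). Extension
*through* a repeat uses only reads that thread the current flank
context across the repeat, and continues only when they agree on a
unique far side. Seeds are non-repeat contigs in descending length;
repeat contigs never seed a scaffold and may be placed repeatedly;
unplaced contigs become singleton scaffolds.

Circularity: a scaffold is circular when its two terminal ends are
linked by ≥ 3 qualifying reads, or when the walk around a circle
re-places the same repeat at both ends (the duplicate is dropped). A
linear molecule with the same repeat at both termini is genuinely
indistinguishable from that circle by junction evidence alone, which
is why the flag is "potentially circular" in spirit.

Junction sequence comes from the best supporting read (largest minimal
anchor span, ties by total span then read id — deterministic); when
the read shows the contigs overlapping, the duplicated bases are
emitted once. "Best hit" ties in alignment use (identity, length,
lexicographic id).

The recovery benchmark measures its own precondition: a junction is
*expected* to be recovered only when ≥ 3 reads qualify for it, counted
from read provenance (molecule, start, length) — no alignment
involved. Junctions the read sample never covered adequately are
invisible to any method, and at depth 20× a ~150 kb genome leaves a
small tail of such junctions; the benchmark asserts 100% recall over
the qualifying set and zero false adjacencies overall, which is the
strongest statement the sampling allows.

## Polishing

The mapper assigns each read to its single best location (edlib edit
distance), requiring ≥ 0.9 of the read aligned at the pass's
similarity; reads with two equally good distinct locations — typical
of repeats placed in several scaffolds — are dropped rather than
smeared across copies, and reads whose best location is on the
plastome decoy are consumed by it. Consensus is per-position majority
over {A,C,G,T,gap} with indels applied on majority support; ties keep
the current base. Below the low-coverage threshold (default 5) the
current base is kept (an `N` mode exists, but reference fill is the
default because final scaffolds are expected gapless and the
downstream interval report already flags the positions). Passes:
similarity 0.90 then 0.95 restricted to the read-derived junction
spans (+100 bp flank), then a final whole-scaffold pass at 0.95.
Circular scaffolds are extended by one read length during mapping and
the pileup folded back, so reads spanning the linearization point
still count; the extension is kept just under the read length so no
read can map wholly inside the duplicated stretch and become
spuriously ambiguous.

Because multi-placed repeat interiors receive no unambiguous reads,
they are polished only within ~a read length of their unique flanks —
exactly the region junction fills can corrupt (fills extend ≤ trim ≈
100 bp into a repeat), so error-free short reads at 30× suffice to
recover molecules exactly.

## Repeats

A repeat family is a **maximal exactly-repeated substring** (≥ min_len,
≥ 2 occurrences over both strands): occurrences share the unit, and
neither a common left nor a common right extension exists. Detection
builds a suffix array (numpy prefix doubling) over the sequences and
their reverse complements joined by unique separators, takes Kasai
LCP, and enumerates branching LCP intervals with a capped left-character
summary for the left-diversity test; unique separator symbols make
boundary cases exact. Units are canonicalized to the lexicographically
smaller strand; copies deduplicate by genomic interval. Exactness is
the point: it admits an unambiguous brute-force oracle, and organelle
repeat copies are near-identical (a per-copy divergence knob exists in
the simulator for stress tests). Directly adjacent copies (gap ≤
`tandem_gap`, default 0) collapse into tandem runs; families with
fewer than two separated runs are excluded from the interspersed tier.

Three accounting modes for the repeat proportion are provided because
published repeat-proportion figures depend on the tool's bookkeeping:
`union` (default; a true genomic fraction in [0,1]), `family_sum`
(Σ unit lengths / genome) and `all_copies` (Σ unit × copies / genome).
Which mode matches a given published number must be determined against
that tool's output, not assumed.

## MTPTs

Plastome-vs-mitogenome local alignment reuses the k-mer seeding
(stride 2 for sensitivity at 90% identity) but — unlike read
anchoring — extends seed clusters only by exact base matching before
edlib scoring, because both sides are local. Hits > 50 bp at > 90%
identity merge on the mitochondrial side when within 10 bp (the merge
radius is a package choice; published "distinct regions" are reported
merged without a stated rule). Detected boundaries on diverged inserts
are conservative by up to a few tens of bases (extension stops at the
first mismatching flank base); at identity 1.0 recovery is exact.
Plastid-read removal may legitimately consume reads from high-identity
MTPTs — the regions are still recovered from the assembled sequence,
which is the point of detecting them there.

## Copy number and the size–repeat correlation

Copies per cell = mito coverage / (input bases / haploid genome size);
the estimate is scale-invariant in the numerator pair and reported
both raw and at 2 significant figures (the quantity is a rough
cellular average; more digits would overstate it). The cross-genome
analysis computes the repeat proportion per assembly and the Pearson r
(p from the t transform, n−2 df) of proportion against size in Mbp;
with tiny n the p-value is reported but never used as a pass/fail
criterion.

## What the synthetic benchmarks do not show

The simulator omits chimeric and adapter-artifact long reads, nuclear
background reads, quality-score structure, diverged repeat copies (by
default) and substoichiometric isoform mixtures beyond integer
stoichiometries. Passing benchmarks therefore demonstrate the
correctness of the selection/scaffolding/polishing logic under clean
multipartite structure, not robustness to every artifact of real
sequencing runs. Problem sizes in the test suite (100–300 kb genomes,
depth 20–30×) are the package's chosen desk scale; all thresholds are
exposed in config and scale to megabase genomes unchanged.
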