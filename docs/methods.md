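# Methods

This note records the models, conventions, parameters and design choices
behind `triggerscan`, and what the synthetic-data tests do and do not show
about real data.

## Coordinates and alphabets

All sequences are held in the RNA alphabet; DNA input is converted (T→U) on
read, because the pairing rules distinguish G:U wobbles. Intervals on
transcript regions are 0-based half-open, 5′→3′. Positions on a miRNA are
1-based from the 5′ end, so "nucleotide 12" is the twelfth nucleotide of
the mature guide and "the last position" is L (typically 22).

## Canonical seed matches

A site is the Watson–Crick complement of the seed (miRNA nucleotides 2–7)
in the target, optionally extended by pairing to nucleotide 8 (m8) and/or
an A opposite nucleotide 1 (A1): 6mer, 7mer-A1, 7mer-m8, 8mer. Wobbles are
never accepted in the seed — canonical sites are WC by definition. At one
seed locus only the strongest requested type is reported (an 8mer locus is
not additionally reported as its contained 7mers); overlapping sites at
*different* loci are all reported. The default type set is
{8mer, 7mer-m8, 7mer-A1}; 6mers, which are weak and would flood the scan,
are behind an off-by-default flag. Windows or intervals containing N are
skipped and logged.

## The 3′-complementarity score

For each seed match, the up-to-30-nt target window immediately 5′ of the
site is searched for the pairing configuration of the miRNA 3′ region
(positions 9..L searchable, scoring from 13) maximising

```
total = match_points + end_bonus + wobble_end_bonus
        − gap_penalty − mismatch_penalty − offset_penalty
```

with: one `match_point` (default 1.0) per WC pair at positions ≥ 13; an
`end_bonus` of 0.5 per paired position among {L−1, L−2} (either pair kind
counts; the rule's singular "an additional 0.5 point" is read per position,
and the weight is a parameter); `wobble_end_bonus` 0.5 if position L is
wobble-paired (a WC pair at L scores as an ordinary match instead); 1.0 per
gap nucleotide and per mismatch inside the paired span (a 2-nt bulge costs
2 — the scheme is size-dependent by design, penalising large bulges and
internal loops); and 0.5 per offset nucleotide beyond `offset_free` = 3.

**Offset convention.** offset = (unpaired target nucleotides between the
seed match and the first 3′ pair) − (unpaired miRNA nucleotides between
position 8 and the first 3′-paired position). Only *positive* offsets
beyond 3 are penalised: a positive offset is a target loop larger than the
miRNA loop, whereas a negative offset simply means the 3′ helix engages
deeper into the miRNA — the normal trigger architecture bridging positions
9–12 — and costs nothing. (Penalising |offset| would charge the canonical
contiguous 13–22 helix 0.5 point and make its hand-derived total 10.5
instead of 11.0.) The absolute offset still participates in tie-breaking.

**Maximisation.** A dynamic program over monotone (non-crossing,
antiparallel) pairings with per-nucleotide gap/mismatch relay costs; the
offset penalty is charged at the first pair and trailing unpaired sequence
is free. Cells carry lexicographic tie-break tuples — (total, WC pairs,
−|offset|, −gap nucleotides, seed-proximal start) — so the returned
configuration is fully deterministic. Correctness is defined by exhaustive
enumeration over all monotone configurations, which the tests check
exactly on ~hundreds of random small instances. Between consecutive pairs
the penalty decomposes as `min(a,b)` mismatches plus `|a−b|` gap
nucleotides; the relay formulation reproduces this whenever
`mismatch_penalty ≤ 2 × gap_penalty_per_nt` (true of the defaults; exotic
parameterisations outside that regime would make the decomposition
penalty-minimising rather than opposition-maximal). If no configuration
scores above zero the empty configuration with total 0 is returned —
reported totals are never negative.

## Duplex energy

The co-ranking metric is the intermolecular minimum free energy of
(upstream window + site substring) against miRNA positions 9..L, computed
with the RNAduplex algorithm of ViennaRNA (nearest-neighbor stacking, no
intramolecular structure). `None` is returned when no stabilising duplex
exists. The two operand choices (window+site; positions 9..L) are recorded
here because "the miRNA-binding site and the miRNA 3′ region" admits
several readings; both operands are exposed through
`scoring.duplex_operands`.

## Candidate pipeline

Two branches feed the same scorer: a de novo scan for all canonical seed
matches, and rescoring of sites from a conserved-site table (validated
row-by-row against the region sequences; invalid rows are rejected with
reasons, not exceptions). Candidates on transcripts below `tpm_min`
(default 1.0 TPM — a minimal-expression convention; the threshold is
configurable because no canonical value exists) are retained but excluded
from ranking. Ranks are per miRNA, 1..n along the deterministic order
(total descending, then match points, transcript, position); a second rank
orders by duplex energy ascending. No combined score is invented — both
axes are reported.

## Conservation

Each species' mature miRNA is inferred as the same-length substring of its
genomic hairpin minimising Hamming distance to the reference mature,
rejected (`mirna_unresolved`) above `max_subst_frac` = 0.25 — minimal-edit
matching is the simplest faithful mechanisation of "predicted from the
genomic sequence", and the threshold is exposed. The species site is
located by alignment-column projection: the minimal degapped interval
covering the reference seed columns. A deletion shortening the seed, or an
insertion inside it, breaks contiguous seed pairing and sets `site_lost`.
Intact sites are rescored with the standard pipeline on the species' own
window and miRNA. The covariation report tabulates, per species and miRNA
position, sequence changes on either side and whether pairing is
preserved (compensatory), lost, or gained.

## Small-RNA quantification

Reads are assigned by exact match of their first 19 nt to a dictionary of
mature sequences — no mismatches, shorter reads unassigned. miRNAs sharing
a 19-nt prefix are indistinguishable under this rule and are merged into
one group (reported under a concatenated id) rather than fractionally
multimapped. Counts-per-million uses assigned miRNA reads as the
denominator after removing spike-in groups and the unassigned tally.

The fold-change estimator divides the target's cpm by the (geometric, by
default; arithmetic available) mean cpm of its cotranscribed normalizer
strands, then by the mean of that ratio over WT samples. Because a clone's
production factor multiplies both strands of a hairpin, it cancels in the
ratio; the estimator is also exactly invariant to per-sample sequencing
depth. Both invariances are asserted in tests.

## Repression statistic

Genes below 10 TPM (mean across samples by default; an "every sample"
variant is available) are excluded. The target sets are all predicted
targets and the ceil(10%) with the lowest cumulative context-style scores
(ties at the cutoff broken by gene id). Each iteration samples a nontarget
cohort 1:1 without replacement from genes not predicted to be targets of
the family, matching on log10 3′-UTR length by nearest-neighbour
assignment in random target order (ties random) — "matching the
distribution" mechanised as greedy nearest-neighbour matching. The metric
is median(target log2FC) − median(nontarget log2FC); the test is a
two-sided Mann–Whitney U (exact for both cohorts ≤ 20 without ties,
tie-corrected normal approximation otherwise). Twenty-one iterations are
summarised by the mean metric, its SD, and the median p-value; a
representative cumulative-distribution table is emitted from the
median-p iteration.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed).

* **Transcriptomes** — random regions (lognormal lengths, configurable GC)
  with decoy seed-only sites implanted at a per-region rate and trigger
  sites written as the exact antisense nucleotides of a requested
  architecture. The implanted helix is anchored at the miRNA 3′ *end*
  (known triggers pair through the 3′ terminus), and the rest of the
  search window is filled with an inert nucleotide that WC-pairs no scored
  miRNA position and wobble-pairs none of the bonus-carrying terminal
  positions. The miRNA simulator rejection-samples guides that admit such
  a filler and whose 3′ regions are not period-1/2 self-similar; under
  those conditions the intended configuration is provably undominated for
  contiguous architectures, so truth labels (match points, offset, total)
  are exact for that class, and are guaranteed lower bounds for
  architectures with wobbles or bulges — where the maximiser may
  legitimately realise the same or a better total through a different
  decomposition. Tests assert exactly this split.
* **DE tables** — nontargets log2FC ~ N(0, σ) and targets
  ~ N(−δ·w, σ) with w averaging 1 and optionally coupled to the
  context-style score; σ = 0.3 and δ = 0.2 by default, a repression depth
  typical of miRNA perturbations; lognormal UTR lengths and TPM, with a
  TPM tail below the 10-TPM floor so the filter is exercised.
* **Reads** — multinomial draws per miRNA with 3′-end length jitter that
  never touches the first 19 nt, plus spike-ins; assignment therefore
  recovers the drawn counts exactly, which tests the bookkeeping, not
  robustness to sequencing error (not modelled).
* **Strand counts** — negative-binomial counts (dispersion 100) with a
  shared lognormal clone production factor (1.5×) on both strands and a
  3-fold strand-specific elevation in mutants — the structure that
  cotranscribed-strand normalisation must cancel.
* **Alignments** — a star phylogeny with i.i.d. substitutions per species
  at a configurable rate on site and hairpin (optional deletions outside
  the seed). No indel realism, no rate heterogeneity, no tree structure.

Passing these tests shows the machinery is correct and calibrated under
its stated statistical assumptions; it does not show performance on real
transcriptomes, where sites sit in structured, biased-composition
sequence, expression estimates are noisy, and conservation follows a real
phylogeny.

## Numerical and degenerate-input choices

Scores are small multiples of 0.25, so exact float comparison is safe;
determinism is enforced by explicit tie-breaks, seeded generators, and
fixed output formatting (byte-identical CLI re-runs are tested). Empty
windows, sites at the region start, miRNAs with no sites, empty candidate
tables, and alignment rows lacking a miRNA all take defined non-exception
paths. Problem sizes in the test-suite simulations (500-region
transcriptomes, 2 000–10 000-gene DE tables, 100 000-read samples, 20
species × 50 replicates) were chosen as the smallest scales at which the
checked properties are statistically stable.

## Known limitations

* The scheme scores pairing geometry only; it does not model AGO
  conformation, target-site accessibility, or expression stoichiometry.
* Seed-match discovery is exact-WC; non-canonical or compensatory seed
  sites are out of scope.
* 19-nt-prefix collisions are merged, not resolved; isomiRs and UMIs are
  not handled.
* The conserved-site branch validates but does not compute conservation
  calls; phyloP-style scoring is out of scope.
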