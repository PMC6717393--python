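# Methods

## Splice-site scoring model

Splice sites are modelled positionally independent: a position probability
matrix (PPM) gives per-position base frequencies; the log-odds transform
against a uniform background, `M_{k,j} = log2(M_{k,j}/0.25)`, turns window
scoring into a sum. Zero probabilities are replaced by a pseudocount of
1e-4 *before* the transform, so the worst achievable entry is
`log2(0.0004) ≈ −11.29` rather than −∞. Raw scores are rescaled piecewise
onto 0–100 anchored at the least/neutral/best achievable windows
(`m_min → 0`, `0 → 50`, `m_max → 100`); the map is monotone, and scores
outside `[m_min, m_max]` (possible only for malformed inputs) are clamped
with a warning.

Window geometry: donor = 3 exonic + 9 intronic nt (positions −3..+9 with no
position 0, −1 being the last exonic base); acceptor = 13 intronic + 1
exonic nt (−13..+1); branch points = all 12-nt windows sliding by 1 nt over
the intronic region −40..−1, i.e. 29 windows for any intron with ≥49
intronic nt past the donor. The branch-point score of an intron is the best
rescaled score over all windows × both matrix variants (adenosine fixed at
position 9 or 10); ties break to the smaller window index, then A9.
Ambiguity codes score as the column minimum (the most conservative choice);
windows with more than two ambiguous bases are flagged unscorable.

### Minor-intron criteria

An intron is minor if any of the following holds (evaluated in order; the
first satisfied criterion is reported, the call itself is an OR):

1. AT-AC minor 5′SS score > 50 and ≥10 points above every other 5′SS score;
2. GT-AG minor 5′SS score > 50, ≥25 above the GT-AG major 5′SS and ≥10
   above the remaining two;
3. GT-AG minor 5′SS score > 50, ≥10 above every other 5′SS score, and
   branch-point score > 65;
4. minor 5′SS + branch-point + minor 3′SS scores sum > 150.

"Over" thresholds are strict (>); margins are non-strict (≥). Criterion 4
uses the larger of the two minor 5′SS scores and the minor 3′SS matrix of
the matching subtype — the criterion names "the minor 5′SS" without a
variant, and the maximum is the symmetric permissive reading. Introns whose
donor window cannot be extracted (sequence boundary, too many Ns) are
flagged and left major: no criterion can be evaluated without all four 5′SS
scores.

### Canonical transcripts and context

One transcript represents each gene: among CCDS-tagged coding transcripts
the longest CDS; else among Ensembl/Havana-merged coding transcripts; else
any coding transcript by CDS length; else the longest transcript by summed
exon length; ties break to the lexicographically smallest transcript id.
Minor introns are then labelled by position: only intron in the transcript >
first/last intron > adjacent to another minor intron > flanked by two major
introns (precedence in that order).

Coordinates follow GTF convention (1-based inclusive) in all external
files and 0-based half-open arithmetic internally; the parser and table
writers are the only conversion points.

## Retention (mis-splicing index)

Per intron and sample, `MSI = 100 · ½ [b₅/(b₅+s) + b₃/(b₃+s)]`, the mean of
the two per-boundary retention ratios; `compute_msi_pooled` provides the
pooled alternative `100·(b₅+b₃)/(b₅+b₃+2s)` behind the same record types,
so swapping conventions is a one-line change. A boundary read must align
contiguously across the junction with ≥3 nt on each side (configurable
anchor); a spliced read must gap exactly over the intron; coverage counts
all uniquely-mapped read bases (spliced-read gaps contribute nothing). On
the minus strand the genomic-left junction is the 3′SS; counts are swapped
accordingly.

Filters per replicate: total boundary reads > 4 (the per-boundary minimum
is covered separately by the ≥1-per-splice-site rule), coverage > 0.95,
both strict. A tissue-level retained call requires a pass in **all**
replicates (mouse-style) or **≥3** replicates (human-style). Introns are
also classed three ways: retained in all replicates of ≥1 tissue / ever in
1–2 replicates / never. For minors flanked by two major introns, joint bins
I–VI enumerate minor × flanking-major retention (I: minor only; II: +1
major; III: +both; IV: none; V: one major only; VI: both majors only).

## Alternative-splicing categories

All uniquely mapped spliced reads with ≥2-nt overhangs whose junctions touch
the region from the neighbouring exons through the minor intron are
collected; multi-gap reads contribute one junction per gap but count once in
the denominator. Categories: CAT1 canonical junction (denominator only,
never reported as an event); CAT2/3/4 both/upstream/downstream flanking-exon
skipping; CAT5–8 cryptic splice sites generated as side × location
(5′/3′ × exonic/intronic): CAT5 = 5′ exonic (upstream-exon truncation),
CAT6 = 5′ intronic, CAT7 = 3′ exonic, CAT8 = 3′ intronic (downstream-exon
extension); CAT9 = junction end strictly inside the minor intron
(cryptic-exon support). The CAT6/CAT7 assignment of the two unanchored
cryptic classes is a module-level mapping table
(`altsplice.CRYPTIC_CATEGORY_MAP`), not hard-coded, because only the exonic
5′ and intronic 3′ classes are unambiguous; a read with an intron-internal
junction end deliberately co-assigns CAT9 with the intronic cryptic class —
multi-assignment keeps the decomposition lossless.

Cryptic detection is two-pass: pass 1 keeps junctions with one end exactly
canonical and the other > 2 nt from its canonical counterpart; pass 2 pools
reads sharing a pass-1 cryptic coordinate without canonical anchoring.

Event MSI = 100 × supporting reads / distinct spliced reads at the locus.
Tissue acceptance: replicate-mean MSI > 10% **and** replicate-mean
supporting reads > 1 per 3×10⁶ uniquely mapped reads, both strict.
Annotated isoforms of a gene are binned, in order, as constitutive /
truncated before the minor intron / terminal exon within it / AS across it.

## Expression signatures

A gene is expressed in a tissue when its replicate-mean TPM exceeds 1
(mean, not median or all-replicates — the aggregation is a package choice).
The default DE engine is a replicate bootstrap: resample replicates with
replacement B times (default 1000; 500 in the validation loops), fold-change
= ratio of replicate-mean TPMs with a 0.1 pseudocount, p = two-sided
bootstrap tail probability of the log2 fold-change crossing zero with an
add-one correction (so p ≥ 1/(B+1), and B ≥ 200 is needed before p < 0.01
is attainable). The engine is pluggable: any per-pair table with
fold_change and p_value columns can be injected, since the package's
substance is the intersection logic, not the DE test. A gene enters a
tissue's UpSignature when called up (FC > 2, p < 0.01) in all T−1
comparisons; disjointness of UpSignatures across tissues is asserted on
every run, not merely tested.

## ORF fate

Events are applied one at a time to the canonical exon chain (no
combinatorial stacking): retention merges the intron into its flanking
exons; skipping removes exons; a cryptic splice site moves the
corresponding exon boundary to the observed junction coordinate; a cryptic
exon (CAT9) is inserted when a start/end coordinate pair inside the intron
can be paired from the accepted junctions — unpaired CAT9 events are
reported as unresolved rather than guessed. Translation starts at the
annotated start codon; if the edit removes it the record is flagged
`start_lost` and no fate is called. No stop before the transcript end →
NSD (the poly(A) signal is approximated by the annotated transcript end; no
motif scan). A stop ending > 50 nt upstream of the **last** exon–exon
junction → NMD; the distance is measured from the final base of the stop
codon, and the last-junction convention is the standard 50-nt rule (a
strict any-junction variant would only enlarge the NMD class). Otherwise
protein, with truncated/extended/unchanged decided by comparing ORF
nucleotide lengths against the canonical transcript. Events whose read
support passes the filters only as a sum over multiple distinct junction
coordinates, none passing alone, are excluded from fate analysis.

## Synthetic data: what it emulates and what it does not

The generator plants: splice sites sampled from the simulated PPMs (minor
vs major consensus differing at canonical positions; per-position
information content 1.8 bits by default, terminal dinucleotides and the
branch adenosine held at ≥0.97); log-normal intron lengths with a shorter
median for minor introns (150 vs 400 nt, σ_log = 0.4, floor 80 nt — toy
scale, roughly one order below mammalian medians, chosen so desk runs stay
in seconds); 1–3 minor introns per MIG with probabilities (0.90, 0.08,
0.02); a pseudogene and lincRNA fraction (4% each); both strands. Reads:
per intron and replicate, spliced reads s ~ Binomial(N, 1−p) and boundary
reads b₅, b₃ ~ Binomial(N, p) at junction depth N = 100 around the planted
MSI p, coverage-fill reads strictly inside the intron (so they can never
masquerade as boundary evidence); AS-event introns instead split their N
junction reads binomially between the event and the canonical junction.
Expression: log-normal TPMs (meanlog = log 20, sdlog = 1), a 10% silent
fraction below 1 TPM, signature genes multiplied 8-fold in their target
tissue, replicate noise σ_log2 = 0.3. Every dataset ships with truth
tables, and all randomness flows from one integer seed.

Deliberately **not** modelled: sequencing errors, GC and positional
coverage bias, fragment-length effects, multimapping ambiguity, annotation
errors, correlated replicate structure, partial intron coverage of real
libraries. Passing recovery tests therefore demonstrates correctness of
the counting, filtering and decision logic under sampling noise — not
robustness to alignment artefacts on real data.

## Validation experiments and problem sizes

The acceptance script and the deep tests run, per seed: criteria evaluator
vs an independently written brute-force rule enumeration on 1000 random
score vectors (30% drawn near the decision boundaries); junction binner vs
a brute-force interval-predicate oracle on 1000 random junctions over a toy
five-exon locus (cryptic rescue disabled so both routes see identical
information); classifier label recovery on a 50-gene genome; MSI recovery
at planted {5, 20, 50, 80}% over 200 trials at depth 100, judged against
the 95% binomial interval at that depth; AS-event detection at 25% planted
MSI and rejection at 5% over 200 trials of a 3-replicate tissue;
signature recovery over 100 trials of a 30-gene, 4-tissue, 3-replicate
design at B = 500; and a six-case constructed ORF-fate panel whose fates
are decidable by construction. These sizes keep the full suite under a
minute while leaving the binomial/bootstrap granularity fine enough for the
stated thresholds.

## Known limitations

* The MSI denominator convention (mean-of-boundaries) and the AS-MSI
  denominator (all distinct spliced reads at the locus) are each one of
  several defensible readings; both are isolated behind single functions
  and the alternatives are available.
* Criterion margins at exact equality (a score of exactly 50, a margin of
  exactly 10) follow the strict/non-strict readings stated above; introns
  sitting exactly on a boundary could flip under the other convention.
* The bootstrap DE stand-in has the granularity and anticonservatism of
  resampling 2–3 replicates; it is a placeholder for a real count-based DE
  engine, which should be injected for real data.
* Prior-catalog comparison intersects coordinates exactly (slack
  configurable); assemblies differing by small shifts need a nonzero slack.
* Fate prediction ignores uORFs, NMD-efficiency modulation and poly(A)
  motif location.
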