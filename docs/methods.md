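# Methods

## Genome model and coordinates

A genome is a set of contigs with annotated ORFs carrying translated
proteins. External files use GFF conventions (1-based inclusive
coordinates); internally every clustering rule operates on ORF
*ordinals* — the 0-based rank of an ORF along its contig by start
coordinate (ties broken by end, then feature ID) — so the base-pair
convention never influences island detection. The simplified tabular
dialect (`genome_id contig_id orf_id start end strand protein`) carries
proteins directly and is what the synthetic generator writes, avoiding a
FASTA round trip. Contigs can be flagged as plasmids; islands inherit
the flag.

## Homology search

The built-in backend is local Smith–Waterman alignment
(`Bio.Align.PairwiseAligner`) with BLOSUM62 and BLAST-style affine gaps
(a gap of length *g* costs 11 + *g*); `X` is scored 0 against
everything. Raw scores convert to bits with fixed gapped Karlin–Altschul
parameters for this scheme (λ = 0.267, K = 0.041) and E-values use a
configurable database size, by default the total residue count of the
scanned proteome (set it globally for cross-genome comparability).
Default reporting thresholds — E ≤ 1e-5, query coverage ≥ 0.3, bit score
≥ 50 — are package choices, recorded in every hit table; externally
produced hit tables can be imported from TSV and are validated against
their recorded thresholds.

Per ORF, the best hit per panel gene is kept, then a greedy best-first
interval selection admits additional gene labels whose aligned interval
overlaps previously accepted intervals by < 25% of its own length; this
lets a fused ORF carry each constituent gene. Selection runs *before*
threshold filtering, and hits below a fixed 25-bit candidate floor (the
random-similarity regime) are never materialized, so the accepted set
for strong hits depends only on stronger hits. Consequence: tightening
any threshold can only remove assignments (monotonicity), which the test
suite asserts. A fission product must still clear the coverage
threshold, so each half of a split gene needs ≥ 30% of the query — at
default settings halves of a two-way split are borderline by design.

## Island definition, classification, ranking

Hit ORFs on one contig form a cluster when consecutive hits are
separated by at most `max_gap` intervening non-hit ORFs. The default is
3, reading the published "separated by ≤ 3 ORFs" as an intervening-ORF
count; the parameter is exposed because the alternative reading (ordinal
difference ≤ 3) differs by one. Clusters never span contigs and ignore
strand. Distinct-gene counting is over labels, so duplications add
nothing and fusions add each label.

Classes: ≥ 7 distinct hgl-panel genes → `hgl`; ≥ 10 → `hgl_extended`;
distinct set exactly {hgdC, hgdB, hglE_A, hglF, hglG, hglC, hglA} →
`hgl_like` (checked before the generic 7–9 label; a config tolerance can
admit ± N labels, off by default); ≥ 5 distinct nif-panel genes → `nif`;
otherwise `none`. Single-hit clusters are retained as class `none` for
size histograms. Ranking within a genome is by distinct-gene count
("first" = most extended island), with deterministic tie-breaks: higher
summed bit score, then leftmost start, then contig id.

The packaged hgl panel definition lists 18 member labels named in the
source literature plus one explicitly marked placeholder (`orf19`) whose
authoritative label requires the source annotation; sequences are always
supplied separately (user FASTA or generator), keyed by label. The nif
panel lists the 14 canonical nitrogenase-region genes of *Anabaena* sp.
PCC 7120.

## Heterocyte inference and benchmark

Default predictor: a genome is heterocyte-capable iff it has an `hgl` or
`hgl_extended` island. `hgl_like`-only genomes are excluded because
compact islands occur as the sole island in strains that have lost
heterocyte formation; `include_hgl_like` restores them. The alternative
`hgl_and_nif` mode additionally requires a nif island (the two predictor
modes differ exactly on genomes with an hgl island but no nif island).
The benchmark treats heterocytous and ramified morphologies as positive
(ramified strains carry heterocytes), skips `unknown`, warns on labels
without a matching genome, and reports the confusion matrix,
sensitivity, specificity, accuracy and the discordant genome list (from
which the metrics are recomputable).

## Phylogenetics

**ANI.** The query genome is cut into 1,000-bp fragments; each fragment
is placed at its best infix position in the subject by edit-distance
alignment (edlib), fragment identity is 1 − dist/len, fragments below
30% identity or shorter than 70% of the fragment length are discarded,
and the two directional means are averaged. On the no-rearrangement
synthetic genomes this equals the conventional reciprocal recipe.
Species groups are single-linkage components at ANI ≥ threshold
(default 95, boundary inclusive); the representative is the longest
assembly. Raising the threshold always refines the grouping.

**Alignments.** Per-locus alignments are column-trimmed (drop columns
with > 50% gaps, configurable — a stand-in for the unstated published
trimming mode) and concatenated; a taxon missing a locus (e.g. an
outgroup lacking island genes) gets that locus's span filled with gaps.
Synthetic loci evolve without indels so columns align trivially;
externally aligned FASTA can be imported instead.

**Trees.** Distances are p-distances with pairwise deletion of gap
sites; a pair with zero comparable sites is an error. The tree engine is
classic neighbor joining with the Q-criterion; exact ties break on the
lexicographically smallest taxon-name pair, making results independent
of input order, and negative branch lengths clamp to zero. Trees are
unrooted internally; rooting by a named outgroup is an explicit
operation. Maximum-likelihood inference is deliberately out of scope —
externally built Newick trees can be imported. Congruence is the
Robinson–Foulds distance (bipartitions present in exactly one tree),
normalized by 2(n − 3); identical leaf sets are required (no silent
pruning).

## Lipid model

An HG is (headgroup, chain length, functionalization pattern).
Positions of functional groups do not affect the formula and are not
modeled. Two counting conventions coexist in the field and both are
honored: pattern *labels* follow parent-chain nomenclature, which counts
the C1 hydroxyl that carries the headgroup ("diol" = C1-OH plus one free
chain OH), while the *functional-group count* used for grouping is
n_hydroxyl + n_keto + 1 (the C1 position always bears an oxygen) and is
constrained to 1–4 — this makes "diols/keto-ols" bifunctional,
"keto-diols/triols" trifunctional, a bare glycosylated alkanol
monofunctional, and keto-triol-type structures tetrafunctional, which is
the only reading under which the published class names form a consistent
series. Formula bookkeeping: alkane C_nH_{2n+2} + O (C1) + O per
hydroxyl + (O, −2H) per keto + (free sugar − H2O) per residue. Free
sugars: hexose C6H12O6, pentose C5H10O5, methylhexose C7H14O6,
deoxyhexose C6H12O5; the undetermined C6 sugar is modeled as a hexose
isomer (same formula, distinct name); dipentose is two pentose residues.
Monoisotopic masses use embedded IUPAC atomic masses; mass additivity
over glycosylation is exact to 1e-6 Da.

Target prediction: precursor m/z per adduct ([M+H]+, [M+Na]+ positive;
[M−H]− negative; adduct list configurable), diagnostic fragments from
successive sugar-residue neutral losses plus up to n_hydroxyl + 1 water
losses. Screening matches the lowest-|ppm| peak per target within the
precursor tolerance (default 3 ppm; fragments 10 ppm); `ms2_required`
additionally demands one diagnostic fragment in the peak's MS2 list.
Detection is monotone in the tolerance. Isobaric targets (e.g.
methylhexose HG_n vs hexose HG_{n+1}, or deoxyhexose triol vs hexose
diol) are *both* reported — separating them needs retention time or
class-specific fragments, which is why quantitative screens should be
targeted to the structures of interest. Relative abundances normalize
each structure's summed adduct intensity to the strain total (rows sum
to 100%), with margins by headgroup, chain length and functional-group
count. Literature symbols convert as +++ → 90, ++ → 40, + → 15,
tr. → 1, absent → 0 (percent).

The packaged 88-structure target grid and the 19-entry
previously-reported registry are synthetic stand-ins (marked as such in
their filenames and headers): the authoritative versions live in
supplementary tables not bundled here. The grid's 80-structure core is
the full 4-headgroup × 4-even-chain × 5-pattern product; the 8 extras
are the structure kinds the main text names (odd-chain C27/C29 hexose
HGs, pentose HG30 keto-triol, unknown-C6-sugar HGs, monofunctional HGs,
a four-functional-group HG), with chain assignments fixed here where the
text is silent.

## Synthetic data: what it emulates and what it does not

`simulate_genomes` plants panel-gene homologs as consecutive ORFs
(optionally spread by gap patterns, fused, duplicated, or on a plasmid
contig) among random decoy proteins; homolog identity is set by uniform
random substitution without indels (an indel-free model; coverage
thresholds are exercised via fissions instead). Decoys are random
sequences, far below the 30% identity cap by construction; requesting a
planting identity at or below the cap is an error because ground truth
would be ambiguous. Real genomes differ in ways the generator ignores:
GC skew, operon structure, paralog families, and genuinely ambiguous
homology — so passing recovery tests shows the detection rules behave
as specified, not that real-data sensitivity equals the synthetic rate.

`simulate_morphology` labels a genome heterocytous iff it carries a
planted hgl/hgl_extended island, flipping each label with the configured
noise rate (default experiments use 5%); benchmark accuracy therefore
has expectation 1 − noise.

`simulate_peaklist` emits one precursor peak per structure × adduct at
the theoretical m/z × (1 + ε), ε ~ N(0, jitter·1e-6) with 1 ppm the
default, lognormal intensity noise (CV 0.1), fixed relative adduct
responses (1.0, 0.4), MS2 fragment entries under the same jitter, and
uniform decoy peaks kept ≥ 25 ppm from every target. The ground truth
records both the nominal weights and the *realized* per-structure
intensity shares; recovery is assessed against the realized shares,
since multiplicative intensity noise is part of the generated sample,
not of the screening method. Chromatography (peak shape, co-elution,
in-source fragmentation) is not simulated.

`simulate_loci` evolves sites independently on a known tree (random
topology by sequential joining, or a user Newick) under a symmetric
20-state substitution process (Poisson event counts per branch, uniform
replacement among the other 19 residues; expected p-distance
(19/20)(1 − e^(−20t/19))), without indels. Optional per-locus taxon
dropout exercises gap-filled concatenation. `simulate_genome_pair`
produces nucleotide pairs at a set substitution rate for ANI tests.
All generators are pure functions of their config, seed included.

## Numerical and test-design choices

- Problem sizes in the shipped tests and the acceptance script (50-decoy
  genomes, 100–500 trial batches, 5,000-site alignments, 40–60 kb ANI
  genomes) were chosen as the smallest scales at which the binomial or
  sampling error of each property is far below its assertion margin.
- Stochastic assertions use 4σ binomial bands around the configured
  expectation rather than point equality.
- Composition-recovery experiments screen with a ±5 ppm window against
  1-ppm jitter (± 5 sd), so Gaussian tails do not clip whole adducts out
  of a structure's intensity; with the window matched to the jitter the
  recovery is exact to floating-point precision. Compositions are drawn
  mass-resolvable (pairwise Δm > 0.02 Da) because precursor-only
  screening cannot separate isobars.
- NJ on p-distances is consistent here because simulated branch lengths
  (0.02–0.15 substitutions/site) keep distances in the near-additive
  regime; at saturation p-distances compress and a correction would be
  needed.
- The hgl-like class check precedes the generic 7–9-gene label, so the
  canonical compact island is never reported as a plain hgl island.

## Known limitations

- No profile-HMM or iterative search; very remote homologs (< ~30%
  identity) are outside the built-in backend's reliable range — import
  an external hit table for those.
- ANI assumes collinear genomes (no rearrangement-aware fragment
  filtering); adequate for the simulated data and close strains.
- Maximum-likelihood phylogenetics, bootstrap support, and dated trees
  are out of scope by design.
- Absolute lipid quantitation is out of scope; the internal-standard
  pathway is limited to an externally supplied per-strain scalar.
- mzML ingestion is not implemented; convert peak lists to the CSV/TSV
  dialect upstream.
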