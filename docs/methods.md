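# Methods

## The problem

Multimeric [FeFe]-hydrogenases and formate dehydrogenases share a
flavin-containing, NADH-binding beta subunit (HydB / NuoF / Nqo1 homologs).
Some of these enzymes are flavin-based electron bifurcators (BF): they
oxidise NADH and reduced ferredoxin together, which lets them produce
hydrogen at pressures around 10³ Pa. Others are non-bifurcating (non-BF):
they run on NADH alone and can only produce hydrogen at tens of pascals,
so organisms relying on them are obligate syntrophs — a hydrogen-consuming
partner must keep the product low. This package implements, as a tested
pipeline on desk-scale inputs, the comparative analysis that separates the
two groups from sequence, together with the equilibrium thermodynamics
connecting the cell's NADH/NAD⁺ poise to hydrogen partial pressure.

## Reference-frame mapping

All diagnostic positions are quoted in *T. maritima* HydB numbering.
Rather than one multiple alignment, each query is aligned pairwise to the
reference scaffold and a position map is built: an injective, monotone map
from reference residue numbers (1-based, inclusive) to query positions,
with an explicit gap sentinel. This keeps classification deterministic,
order-independent and testable per sequence; a multiple-alignment mode is a
non-goal.

The aligner is an affine-gap Needleman–Wunsch (Gotoh). Conventions that
matter for reproducibility:

* gap of length L costs `gap_open + (L−1)·gap_extend`; switching gap sides
  opens a new gap;
* end gaps are penalised (true global alignment);
* traceback ties break diagonal > up > left, and among states M > up-gap >
  left-gap;
* default scheme BLOSUM62 with open −11 / extend −1. The source analysis
  used Clustal W defaults without naming a matrix, so the conventional
  protein default is shipped and everything is configurable via NCBI-format
  matrix files. Published percent identities are therefore not exactly
  reproducible and are treated as soft context, not targets.

The dynamic program is vectorised row-wise in numpy (the left-gap
recurrence becomes a running maximum), so a 600×600 alignment costs a few
milliseconds; scores are integers throughout, so traceback equality tests
are exact.

## Fingerprint rules and the verdict

Four shipped rules (JSON-serialisable, user-extensible): 232 ∈ {A,E} vs
{T,S}; 234 ∈ {M} vs {K,S,A}; 367 ∈ {F} vs {Y}; 427–431 = `GGPSG` for BF,
any gap-free non-match counting as non-BF. A gap at any rule position, or a
residue outside both sets, makes that rule indeterminate (absence of
evidence). The published framing counts three differential sequence regions
plus the cluster-count comparison as four criteria; internally the NADH
site is two rules because the two positions vary independently.

The overall decision rule is this package's own choice (none was published):
**unanimity of non-indeterminate rules with a quorum of ≥ 2**, otherwise
ambiguous. Cluster-count support never overrides residue evidence, because
the cluster count is explicitly non-diagnostic — both groups vary widely in
cluster-domain number. Whether the original database screen demanded all
criteria or a subset is unstated; unanimity is the conservative reading and
is what the synthetic recovery tests certify. Queries whose alignment
identity (matches / alignment columns) falls below a floor (default 0.15)
are refused — overall ambiguous with a logged reason — rather than
classified from an untrustworthy map.

## Fe-S motif grammar

The published domain inventory is annotation-based, with no sequence rule
given, so the scanner is a transparently parameterised stand-in validated
against the synthetic generator, not against any figure. Motifs are chains
of anchor cysteines with configurable spacer windows:

* `[4Fe-4S]` (4 Fe): C x(2) C x(2) C x(2,4) C
* `[2Fe-2S]` (2 Fe): C x(4,6) C x(1,3) C x(20,40) C
* H-cluster (6 Fe): C x(2) C x(2) C plus a downstream C within x(5,24)

The H-cluster window deliberately starts at 5 so it is disjoint from the
[4Fe-4S] tail window, keeping the two types unambiguous on planted data.
Spacer content is unconstrained; reported cysteine positions are anchors
only and are asserted to index a C. Overlaps resolve deterministically:
leftmost first, longer candidate at equal starts, then type priority
([4Fe-4S] > [2Fe-2S] > H-cluster, configurable). Iron stoichiometry is the
plain sum of per-cluster contributions (5·4 + 2·2 + 6 = 30 Fe for the full
heterodimer complement).

## Phylogeny

A deliberate downgrade from the published maximum-likelihood/JTT analysis
to a desk-scale, dependency-free surrogate: star alignment through the
reference scaffold (insertions relative to the reference are dropped),
occupancy trimming (default threshold 0.5; the published manual trim to a
fixed column count is not algorithmically reproducible and is not a
target), p- or Poisson-corrected distances, and neighbor joining. NJ ties
break on the lowest index pair; negative branch-length estimates are
clamped to zero and counted. Additive matrices are recovered exactly
(machine precision), which the tests check by inverting randomly built
trees; an independent cross-check against dendropy's NJ guards the
implementation. A JTT-based distance is not implemented (stretch goal in
the design; Poisson is the stated surrogate).

## Thermodynamics

Half-cell potentials in mV:

    E = E°′ − s·(m/n)·(pH − 7) + (s/n)·log₁₀(ox/red),   s = ln(10)·RT/F

with E°′(NAD⁺/NADH) = −320 mV (n = 2, m = 1) and E°′(2H⁺/H₂) = −414 mV
(n = 2, m = 2) at pH 7, 25 °C; for the hydrogen couple ox/red = p°/p with
p° = 101325 Pa. The slope is computed from temperature (59.159 mV at
298.15 K) rather than fixed at 59.16 — the difference is below 0.01%.
Setting the two couples equal gives the equilibrium hydrogen pressure in
closed form; the two-electron stoichiometry cancels, so p is exactly
proportional to the NADH/NAD⁺ ratio, and the inverse map is a division.
At pH 7.5 and 25 °C this reproduces the published predicted pressures
(105.9 / 21.3 / 4.24 Pa at ratios 5.0 / 1.0 / 0.2) within 0.5%.

Two published asides are *not* reproducible from these constants and are
excluded from any check: the "1,000 Pa ≡ E′ = −367 mV" equivalence (no
stated constants recover it at pH 7 or 7.5), and the nanomole column of
the equilibrium assay table, which is inconsistent with pV = nRT for the
stated 5.5 ml headspace (the effective volume/temperature is unstated).
`headspace_amount` implements the plain ideal-gas conversion.

Sign convention worth stating: at fixed ratio the predicted pressure
*increases* as pH decreases (the H₂ couple shifts by −s per pH unit against
−s/2 for the NAD couple); this is asserted in the tests.

## Biochemistry arithmetic

Average (not monoisotopic) residue masses via Biopython, matching kDa-scale
predictions; sequences containing X are rejected. pI is the root of the
Henderson–Hasselbalch net charge over D, E, C, Y, H, K, R and the termini,
solved by bracketing on [0, 14] (xtol 10⁻⁶, tighter than the 10⁻⁴ needed);
the EMBOSS pKa table is shipped and overridable — pI values are always
pKa-table-dependent, and published values from unnamed tools (e.g. 3.63
for a ferredoxin that requires its GenBank sequence) are validation-only.
Specific activity is `ΔA/min ÷ (ε·l) × V ÷ mg ÷ stoich`, with the viologen
two-electron stoichiometry factor exposed (default 1, pass 2 for dye
assays). Purification fold and yield are relative to the first step and
invariant under global activity rescaling. `per_subcomplex` divides and,
only when asked, rounds to the 1-decimal reporting convention (71.7/2 →
35.9; 1.06/2 → 0.53, printed elsewhere as 0.5).

## Synthetic generator: the stated world

The generator emulates the *statistical* structure of the published
comparison, not evolution:

* scaffold length 600 (beta subunits run ~420–620 aa), random over the 19
  non-cysteine residues, BF fingerprint at the HydB-frame positions;
* planted sequences draw fingerprint residues uniformly from the class's
  allowed sets (non-BF SLBB = any non-`GGPSG` 5-mer);
* Fe-S motifs are planted in reserved unguarded zones with ≥ 42
  cysteine-free residues between motifs, so no spacing window (max 40) can
  bridge two motifs; defaults give BF subunits extra clusters
  (4×[4Fe-4S] + 2×[2Fe-2S] vs 2 + 1), mirroring the observed tendency;
* background identity is exact-count: the number of mismatches to the
  scaffold (planted differences included) is fixed at round((1−identity)·L),
  so the realised identity is deterministic up to rounding; substitutions
  are uniform over the 19 non-cysteine alternatives — the classifier must
  not depend on background composition;
* indels (1–3 residues) stay outside a ±5 guard band around fingerprint
  positions and outside motif spans, so fingerprint positions survive
  re-alignment and motif counts survive mutation;
* one integer seed drives one stream per sequence: fixtures are
  bit-reproducible.

For phylogeny, `generate_clade_dataset` derives a diverged non-BF scaffold
(default 65% identity to the base) and samples each class around its own
scaffold (default 90%), giving elevated between-class divergence without
tree-structured simulation — explicitly all a green monophyly test
establishes. Green classification tests establish that the pipeline
recovers planted fingerprints through realistic divergence and indels; they
do not establish performance on real homologs, where indel structure,
compositional bias and domain rearrangements are richer.

## Numerical and degenerate-input choices

* Alignment scores are int64; −2⁴⁰ is the −∞ sentinel (safe under sums).
* Distance matrices must be symmetric within 10⁻¹², finite, zero-diagonal.
* Poisson distance errors on p ≥ 1; distances error when no shared
  non-gap columns exist; trimming errors when no column survives.
* NJ requires ≥ 3 taxa; the 3-taxon case is the closed-form star.
* Equilibrium round-trip (pressure → ratio → pressure) holds to 10⁻⁹
  relative over [10⁻², 10⁵] Pa by construction (pure closed form).

## Known limitations

* The screen of published homolog databases needs the GenBank sequences
  (not shipped; no download at test time), so the published count of
  reclassified homologs is not a test target here — `classify_batch` plus
  `write_report` is that screen once sequences are provided.
* NJ over Poisson distances is a surrogate for ML/JTT; topologies can
  differ on real data.
* The motif grammar is a curatable stand-in; window defaults were chosen
  once against the generator's stated world and are config, not truth.
* No activity-coefficient corrections, CO₂/formate couples, or dissolved
  gas partitioning in the thermodynamics.
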