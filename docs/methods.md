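# Methods

## Library model

The library is a two-set combinatorial design on a central scaffold: building
blocks A (amines; 191 primary, 36 secondary, 72 heteroaromatic, plus one code
reserved for an ammonia control) and building blocks B (480 carboxylic acids
attached by amide coupling, 131 terminal alkynes attached by azide–alkyne
cycloaddition). Each block owns one DNA barcode (CodeA appended in step 1,
CodeB ligated in step 2). The scaffold is used as a 1:1 mixture of its R and
S stereoisomers and chirality is *not* DNA-encoded: both stereoisomers of a
(A, B) combination carry the same code pair. Enumeration therefore yields
`|stereo|·|A|·|B|` members (366,600 for the reference composition) collapsing
onto `|A|·|B|` = 183,300 sequencing-level code pairs, and every
sequencing-side quantity lives on that grid. Member order is deterministic
(stereo-major, then A index, then B index) so all outputs are
byte-reproducible.

## Barcodes

No oligo sequences are published for this design, so codebooks are generated
by the package: random greedy accretion over {A,C,G,T}^L keeping a candidate
only if its Hamming distance to every accepted code is ≥ d_min, seeded and
reproducible. Defaults are L = 8 nt and d_min = 3, the smallest standard
design that guarantees unique single-substitution correction (1-balls of
distinct codes cannot overlap when d_min ≥ 3). The greedy search places the
required 300 and 611 codes in a few thousand attempts out of 4⁸ = 65,536
words; a budget-exhaustion error suggests longer codes when the request is
infeasible (e.g. 5 codes of length 3 at d_min = 3 exceeds the Singleton
bound). An independent O(n²L) pairwise verification runs on every manifest
load, naming the offending pair on failure.

## Read architecture

Reads are fixed-layout: `prefix(6 nt) + CodeA + spacer(4 nt) + CodeB +
suffix(4 nt)`, constant quality "I" (Phred 40). Slots are located by offset
from the read start; adapter scanning, indels, paired ends and quality-aware
matching are out of scope. The layout content is arbitrary but fixed — only
the offsets matter to decoding.

## Selection simulator

Capture is modelled as one round of independent molecular capture: member
*m* enters with n₀ copies and each copy survives with probability
`min(1, p₀·fold_m)`, giving captured counts `Binomial(n₀, ·)`. Defaults
n₀ = 10⁷ (the per-compound aliquot size used for selections) and p₀ = 10⁻⁵,
so an unenriched member yields ≈100 captured molecules and a fold-1000
binder ≈10⁵. PCR amplification bias is not modelled separately; it is folded
into the capture probability. In dual-pharmacophore (DP) mode the effective
fold is `fold_m × multiplier_m`, capped at probability 1 with a warning.

Sequencing draws exactly `depth` reads multinomially with probabilities
proportional to captured counts summed over stereoisomers per code pair,
then applies i.i.d. per-base substitution errors (each error picks one of
the three other bases uniformly). Substitutions only — the fixed-position
layout keeps decoding well-posed. All randomness flows from one explicit
seed through a named generator; triplicates use seed, seed+1, seed+2.

Scenario presets pin the study conditions: `unselected` at depth 17,046,900
(ACs 93 on the grid, matching the full-library fingerprint), `sp_selection`
and `triplicate` at depth 232,900 (ACs 1.27) with three planted binders at
folds 1000/300/100 — enrichment factors on the 10²–10³ scale reported for
the strongest sulfonamide controls — and `dp_maturation` with one pair at
SP fold 3 boosted 373× by the paired hit moiety (DP-effective fold 1119,
emulating the published SP EF ≈ 3 → DP EF ≈ 1119 maturation call) plus one
mode-independent pair at fold 112 in both formats. The default sequencing
error rate is 0.005 per base, a typical short-read substitution scale.

What the simulator does *not* emulate: bead-level stochasticity, PCR
duplicate structure, chimeric reads, indels, read-quality variation, and
target-specific chemistry. Passing tests therefore demonstrate that the
decoding and enrichment statistics are correct under a clean multinomial
selection model, not that real selections are free of those artifacts.

## Decoding

Each slot is matched against its codebook; a read is assigned when both
slots resolve to a unique code within `max_mismatch` substitutions.
`max_mismatch ≥ d_min` is refused (correction would not be unique in the
worst case). Matches tying between two codes at the minimum qualifying
distance are discarded as ambiguous rather than arbitrarily assigned, which
protects enrichment factors from systematic misassignment at the price of a
slightly lower assigned fraction. Discards are accounted by reason
(no-match-A checked first, then no-match-B, with ambiguity in either slot
taking precedence) so reads in = assigned + discarded always holds. The bulk
decoder resolves exact slots through a hash lookup and sends only inexact
slots to a vectorised Hamming computation; a test pins its agreement with
the scalar reference matcher.

With 8-nt codes and error rate e, the probability that a slot carries at
most one substitution is `(1−e)⁸ + 8e(1−e)⁷`; the assigned read fraction at
`max_mismatch=1` matches the square of that quantity to within binomial
sampling error (misassignment of ≥2-error slots to a neighbouring code is
possible but rare enough not to register at the tested depths).

TCs is the grid sum of assigned counts; ACs = TCs / (|A|·|B|) is kept as an
exact rational until display, where integers print unrounded and other
values round half-up to 2 decimals. Half-up is pinned by the depth pair
342,600 / 183,300 → 1.87, which truncation would print as 1.86; one
published caption (252,500 → "1.34", arithmetically 1.378) is internally
inconsistent with every other caption and is not used anywhere.

## Enrichment and synergy

The default enrichment factor is uniform-baseline, `EF_i = c_i·N/TCs`,
chosen because every reproducible published summary statistic (the ACs
values) normalises against the full grid; the exact published EF equations
live in supplementary material that is not available here, so the
unselected-library baseline `(c_i/TCs)/((c⁰_i+π)/(TCs⁰+πN))`, π = 0.5, is
offered as an explicit option rather than a guess at those equations.
Uniform-baseline EF satisfies `mean(EF) = 1` exactly and is scale-invariant;
both identities are tested.

Hit calling keeps rows with `EF ≥ ef_min` (default 10) and `count ≥
count_min` (default 3), ranked by EF with a lexicographic (code_a, code_b)
tie-break. Replicate concordance intersects the hit lists of ≥2 replicates
and reports per-combination min/median EF. No multiple-testing correction
is applied — the original analysis performs none — and the null
false-positive behaviour is instead characterised empirically by simulation
in the test suite.

Synergy uses `ratio = EF_dp / max(EF_sp, 1)`; the floor prevents
sub-background SP values from inflating the ratio. Classes (mutually
exclusive): synergistic (`ratio ≥ 5` and `EF_dp ≥ 10`), independent (both
EFs ≥ 10, ratio < 5), sp-only (`EF_sp ≥ 10`, `EF_dp < 10`), background
(otherwise). The thresholds are fixed defaults chosen so that
published-scale exemplars classify as narrated: (EF_sp, EF_dp) = (3, 22)
and (3, 1119) are synergistic, a pair at ≈112 in both modes is independent,
and (1, 1) is background.

## Numerical and design choices

- ACs and the EF mean identity are exact statements about rational/float
  arithmetic; tests use 1e−9 (far looser than the observed ≈1e−16).
- Stochastic checks use closed-form expectations with ~5σ binomial bands.
- Problem sizes: simulation-based tests and the acceptance script run at
  depth 2×10⁵ (the published per-selection depth scale) on the full
  2×300×611 library; the 17M-read unselected depth is exercised only as the
  preset's ACs arithmetic, since the fingerprint statistic depends on depth
  alone, not on the identity of 17 million simulated reads.
- Lipinski evaluation uses inclusive bounds (MW ≤ 500, HBD ≤ 5, HBA ≤ 10,
  logP ≤ 5) with additive block contributions plus a linkage mass delta
  (−18.011 g/mol for amide condensation, 0 for cycloaddition). The published
  MW distribution mean is not reproducible — it requires the real, unpublished
  structures — so the reference manifest's property contributions are
  synthetic, seeded stand-ins.
- Plots (3D stem and pseudo-2D jet-coloured scatter) are advisory; every
  quantitative claim is made on tabular data.

## Limitations

Real selection data would additionally require adapter trimming, possibly
indel-tolerant matching, and an empirically measured unselected reference;
the package's error model and capture model are deliberately minimal.
Enrichment factors at ACs ≈ 1 are shot-noise dominated for weak binders
(EF ≲ 10), which is why hit calling couples an EF threshold with a raw count
threshold and replicate concordance.
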