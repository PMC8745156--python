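# Methods

## Scope and data

The package annotates the 72 printed disease-associated missense variants of
human MTHFR (UniProt P42898) from the packaged TSV transcription
(`src/mthfrvar/data/mthfr_variants.tsv`). The transcription is row-faithful:
the duplicated M338T row is kept, styling (bold/footnotes) is dropped, and
destabilization is always recomputed from the three ΔΔG columns, never read
from styling. Two normalizations were applied: Unicode minus signs became
ASCII hyphens, and numbers are stored in canonical `%g` form (−1.00 → -1) so
that parse → serialize is byte-identical. Free-text effect annotations that
were run together in the source are separated with "; ". Downstream
statistics always operate on the 71 unique variants (first occurrence kept);
the parser itself never drops rows, so diagnostics can report the printed
72/41/31 row counts alongside the deduplicated ones.

The domain boundary is fixed at 335/336: the last catalytic-section row is
R335C, the first regulatory row is M338T, and the regulatory model region is
336–566. Positions beyond 566 (e.g. L628P) belong to the regulatory domain
for counting purposes but fall outside the profile model and are flagged
unmapped in the architecture view.

## Consensus stability calls

ΔΔG = ΔG_wt − ΔG_mut (kcal/mol): negative values destabilize. The consensus
rule calls a variant destabilizing when ≥ 2 of the 3 method predictions are
≤ −1 kcal/mol. The threshold is *inclusive*: V253F carries a printed −1
entry and is only recovered as destabilizing (completing the 22-variant
catalytic set) under the inclusive rule, which pins the convention. Votes
are unweighted and the three values are never averaged. `reverse_variant`
negates a triplet computed for the reverse substitution (used when the
crystal carries the mutant allele, as for E429A) and is an involution.

On the packaged table this yields 22 catalytic + 20 regulatory = 42
destabilizing variants, i.e. 59.2% of the 71 unique variants (58.3% of 72
rows). The pipeline reports this recomputed fraction as is. Exactly three
variants — G387D, Y506D, L628P — are both destabilizing and
interaction-flagged.

## Solvent accessibility

Shrake–Rupley SASA: each heavy atom's van der Waals sphere is inflated by
the probe radius (default 1.4 Å) and sampled with a deterministic
golden-spiral quadrature (default 960 points/atom); a point is accessible
iff it lies strictly outside every other atom's inflated sphere, and the
atom's ASA is 4π(r+w)² × (accessible fraction). Defaults: radii C 1.76,
N 1.65, O 1.40, S 1.85 Å (extendable per call); probe 1.4 Å; 960 points.
Neighbor candidates come from a KD-tree, with an `all_pairs` mode kept as an
internal oracle — the two must agree bit-for-bit.

Coordinates are first expressed in a canonical molecule-fixed frame
(centroid origin, principal axes with moment-based sign fixing, right-handed)
so that computed areas are invariant under rigid motion of the input to
~1e-13, tested at 1e-6. For near-symmetric point sets the axis choice can be
numerically ambiguous; none of the supported inputs (proteins, the toy
fixtures) are in that regime.

RSA% = 100 × ASA / maxASA(residue type), rounded to the nearest integer and
clamped to [0, 100]. The normalization table is the theoretical Gly-X-Gly
maximum set of Tien et al. (2013) and is a configuration item — published
max-ASA tables differ by a few percent, so exact agreement of every printed
RSA integer with another program's output is not promised; buried (0%)
calls and threshold-level classifications are robust to the table choice.
Exposure: exposed iff RSA ≥ threshold, default 20% (inclusive), calibrated
so the catalytic domain yields its 14 exposed non-interaction variants; the
published regulatory-domain exposure sentence is not consistent with any
single threshold, so the threshold remains a flag.

Ligands (FAD, SAH) and waters are excluded from surfaces by default;
hydrogens are always dropped; altlocs resolve to highest occupancy, ties to
the lowest identifier. Residue numbering is taken verbatim from the
structure file and assumed to coincide with UniProt positions.

## Interface detection

A residue is an interface residue when ASA(isolated component) −
ASA(complex) ≥ 1 Å². Both computations use identical quadrature settings and
the *complex's* canonical frame, which makes per-atom burial exactly
non-negative (removing atoms can only uncover quadrature points), so the
≥ comparison is never corrupted by frame jitter.

## Variation types and the chi-square

Classes: apolar {G,A,V,I,L,P,M}, polar {S,T,C,N,Q,H}, aromatic {F,W,Y},
charged {D,E,K,R} — asserted at import to partition the alphabet. Each
variant contributes one count to the 4×4 (source, target) matrix of its
domain; multiple substitutions at one position count separately. The two
domains are compared by a Pearson chi-square of homogeneity on the 2×16
table formed by flattening both matrices and adding 0.5 to every cell
(df = 15, no continuity correction). This is the simplest symmetric reading
of "chi-square with 0.5 pseudocounts"; it is invariant under swapping the
groups. On the packaged table it gives χ² = 8.936, p = 0.881 — the two
domains' fingerprints are *not* distinguishable at these sample sizes, and
the pipeline reports the computed p-value rather than a significance claim.
A comparison against a background distribution (user TSV or the synthetic
background sampler) is exposed through the same function.

## Domain profile model

Built directly from an aligned FASTA/Stockholm alignment: a column is a
match column iff its gap fraction ≤ 0.5; emissions per match column are
Laplace-smoothed frequencies (count + 1)/(total + 20); transition
probabilities between match/insert/delete states are estimated the same way
from observed column-to-column paths (inserts before the first match column
are ignored, as from a begin state). No Dirichlet mixtures, no sequence
weighting, no scoring — the model exists to define match columns and the
reference-position mapping for the architecture view. With weighting and
priors disabled, HMMER's fast architecture with a Laplace prior is the same
estimator, and the test suite uses pyhmmer in that configuration as an
independent oracle for match-state assignment and emission values.

`ref_map` sends reference positions (offset by `ref_start`, 336 for the
regulatory alignment) to match columns; reference residues in insert columns
map to None. Catalytic variants are placed by the 1–335 span; the public
family model for the catalytic domain is deliberately not rebuilt.

## Synthetic data

Generators are pure functions of their configuration (fixed seed ⇒
byte-identical output):

- toy structures (single atom, 5-atom residue, ideal-geometry peptides, a
  shell that fully buries its central atom) with documented bond lengths;
- a translated-copy dimer whose chains are exact translates, so the
  chain-A/chain-B interface sets mirror exactly; at the documented 5 Å
  contact offset every residue buries ≥ 1 Å², at 50 Å none do;
- simulated variant tables: exactly round(n × fraction) destabilizing
  variants, ΔΔG triplets resampled from N(−2, 0.5) (destabilizing) or
  N(0, 0.5) (neutral) until the consensus label is unambiguous. These
  distributions are not thermodynamics — they guarantee label separability
  so classifier recovery is exact by construction;
- a background type sampler (multinomial over the 16 types, default uniform,
  default n = 22,763 emulating a large pathogenic-variant survey).

Defaults mirror the study conditions: 72 variants, 41 catalytic, 42
destabilizing, 3 interface-flagged.

What passing tests on synthetic data do **not** show: realistic protein
energetics, evolutionary covariation, or DSSP-equivalent per-residue RSA on
real structures. Table-derived statistics, by contrast, are exact
reproductions of the printed data.

## Numerical choices and problem sizes

Quadrature convergence: doubling 960 → 1920 points moves the total ASA of
the multi-residue fixtures by < 0.5% (single spheres are exact at any point
count). The ≥10⁶-point two-sphere oracle in the tests agrees with the
closed-form spherical-cap area to 0.5% and with the 960-point implementation
to 1%. Test fixtures use 3–8 residue peptides and 100-atom shells; the
full-protein path (≈ 9,000 heavy atoms for the MTHFR homodimer) runs in
minutes at default settings and is exercised only when a user supplies the
structure file.

## Known limitations

- Per-residue RSA integers for exposed residues can differ by a few percent
  from DSSP-style values (different algorithm, radii and max-ASA table);
  buried (0%) calls and set-level interface results are the robust outputs.
- The profile estimator is intentionally minimal; it is not a substitute for
  a full profile-HMM trainer when scoring or database search is needed.
- The domain-comparison chi-square has low power at n = 41 vs 30 over 16
  categories; interpret the reported p-value, not a significance label.
- Structures with residue numbering that does not match UniProt positions
  are not renumbered.
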