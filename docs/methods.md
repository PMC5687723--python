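# Methods

This note records the model, the conventions, and the judgement calls the
package makes, in enough detail that a maintainer can predict its output
without reading the code.

## Sequence model and coordinates

Sequences live on the 15-letter IUPAC alphabet; `U` is accepted on input
and mapped to `T`, whitespace/digits/gap characters are stripped so FASTA
bodies and numbered alignment rows can be pasted directly. All internal
coordinates are 0-based, half-open; reports print 1-based inclusive
positions.

Two symbols *match* iff their base sets intersect (`C` matches `Y`,
`N` matches anything, `R` does not match `Y`); the degeneracy-aware
distance counts non-matching positions. On concrete strings it is the
classic Hamming distance and a true pseudometric; between degenerate
strings the triangle inequality can fail (`A`–`N`–`G` has distance
0 + 0 < 1), which is inherent to set-intersection matching and harmless
here because motifs are compared against mostly concrete templates.

## Allele decomposition

Two alleles of one locus are split as: longest common prefix (shared
upstream), then longest common suffix of the remainders (shared
downstream), the rest being the per-allele unshared regions. A SNP yields
unshared lengths (1, 1); a pure k-bp indel yields (k, 0). Ties at
homopolymers/microsatellites resolve by maximizing the prefix first, which
pushes the unshared region as far 3′ as possible — deterministic, and the
prefix is what anchors the primer. When prefix + suffix would overlap, the
suffix is truncated for the same reason. Equal-length unshared blocks
longer than 1 whose interiors still agree are rejected as two separated
substitutions (`MultipleVariantRegions`): the tool's contract is one local
variant per comparison. Inputs identical after normalization are rejected
(`IdenticalSequences`). Flanks shorter than 20 nt warn but proceed.

## Candidate search

For each enzyme (nicking and double-cutting enzymes are excluded; motifs
< 4 nt are rejected as cutting too frequently), each motif orientation,
each allele as the would-be cleaved allele, and every placement touching
the variant region:

* distance to the template must be ≤ the mismatch budget (default 1);
* every mismatching position must lie in the shared upstream region —
  those are the bases the primer will overwrite, and the primer may not
  extend past the last shared base;
* the motif must overlap ≥ 1 base of shared and ≥ 1 base of unshared
  sequence; an exact (distance-0) site wholly inside an unshared region is
  also kept, as a plain CAPS candidate. For the allele whose unshared
  region is empty (the deletion side), "overlapping the unshared region"
  means spanning the junction;
* the completed site — template with the lexicographically-first
  compatible concrete base substituted at each mismatch — must be absent
  from the other allele's variant window after applying the same
  substitutions (they sit in the shared prefix, hence apply to both).

If the other allele *is* still cut at the variant (distance 0 in both),
the assay is reported as `both_differently` only when the indel length
difference is ≥ 5 bp, the smallest band shift we treat as resolvable on a
gel; smaller shifts are discarded as unreadable.

Everything runs twice — on the input orientation and on the reverse
complement of both sequences — because the downstream-rejection rule is
one-sided: an enzyme with a second exact site 3′ of the variant is
rejected in that orientation (within `amplicon_len`, default 150 nt,
measured from the primer anchor; a window truncated by the end of the
supplied sequence carries a warning) but may be clean from the other side.
Near-matches downstream are deliberately not rejected, only exact sites.

## Primer construction

The primer's 3′ terminus sits at the last shared base. Construction
applies the site-completing substitutions, then destroys any *other*
exact occurrence of the same recognition site under the primer footprint
with one additional mismatch each — preferring transversions, never at
the 3′ terminus, and skipping substitutions that would create an exact
site for any other catalogue enzyme within the footprint. Designs whose
total mismatch count exceeds the budget are rejected, as are designs
requiring a mismatch at the 3′-terminal base — unless the G/T-wobble
option is enabled and the mismatch pairs G with T (the default assumes 3′
mismatches kill amplification, the conservative reading of a conflicted
literature). Every emitted design is verified by simulation: the
primer-substituted amplicon of the cleaved allele contains the site, the
other allele's does not at the variant.

Length selection: `fixed_length` returns exactly the requested length;
`target_tm` evaluates lengths 18–36 nt (bounded below by the 5′-most
required mismatch and above by the shared region) and returns the length
whose Tm is closest to the target, ties to the shorter primer. 18–36 nt
are ordinary oligo-synthesis bounds. Only the best primer per
enzyme/orientation is reported unless `--all` is given. The reverse
primer is left to the user, as is checking sequence beyond what was
supplied.

## Melting temperature

Tm = 1000·ΔH / (ΔS + R·ln(C_T/x)) − 273.15 + 16.6·log₁₀[Na⁺], with ΔH,
ΔS summed over Sugimoto nearest-neighbor stacks plus the initiation term
(ΔH = +0.6 kcal/mol, ΔS = −9.0 cal/mol/K), R = 1.987 cal/(mol·K), x = 4
for non-self-complementary oligos and 1 for self-complementary ones.
Defaults: 50 nM primer, 50 mM Na⁺; both configurable. Two deliberate
approximations: (1) Tm is computed for the primer as synthesized against a
perfect complement — engineered mismatches are not thermodynamically
penalized, so reported Tm slightly overestimates the first-cycle annealing
of mismatch-bearing primers; (2) no symmetry-entropy term is added for
self-complementary primers (only the x = 1 factor), so values for
self-complementary oligos differ by ~1.8 °C from implementations that add
ΔS_sym = −1.4. No Mg²⁺/dNTP corrections.

## CRISPR screening

The 20-nt protospacer must occur exactly once across both strands of the
wild-type sequence; the cut bond is 3 bp 5′ of the PAM (between
protospacer positions 17|18). The default outcome profile is five
uniformly weighted single-base events: insertion of each base at the blunt
cut and deletion of the base 5′ of it — the most common repair products
at desk resolution; deleting the 3′-adjacent base instead is a judgement
call, configurable through custom profiles (any weighted set of
insertions/deletions at the cut, weights summing to 1).

The primer anchor is the last wild-type base shared with *all* simulated
variants, which inside homopolymer runs retreats 5′ of the naive cut
position automatically. An assay's *loss fraction* is the weighted share
of events whose edited, primer-patched sequence still contains an exact
recognition site anywhere from one motif-length 5′ of the diagnostic
placement to the end of the amplicon window — a re-cut anywhere in the
amplicon looks like wild type on a gel, whatever its position. The
acceptable-loss threshold is inclusive (loss = threshold is kept). An
assay that misses every simulated event is never reported at any
threshold. With the default profile, loss fractions live on
{0, 0.2, 0.4, 0.6, 0.8, 1.0}.

## Assay audit (productive / problematic / non-productive)

Any primer/enzyme/allele-pair triple can be audited independently of how
the primer was designed. The primer is placed on each allele by ungapped
sliding (fewest set-intersection mismatches; first position on ties).
Amplicons are simulated by substituting the primer at its footprint.
The verdict is:

* **non_productive** — no diagnostic digest: neither amplicon cut, or
  both cut with no band differing by ≥ 5 bp;
* **problematic** — diagnostic, but an amplification defect is tagged:
  a 3′-terminal mismatch against either template (G/T optionally
  excused), more than 5 mismatches at the best placement, or an
  *alignment gap* — > 3 clustered mismatches that a single 1–3 nt gap
  between two well-matching primer halves explains with ≤ 1 residual
  mismatch;
* **productive** — diagnostic and defect-free.

Every design the pipeline emits must audit `productive`; the test suite
enforces this closure on random fixtures.

## Synthetic data

The fixture generator emulates clean, Sanger-confirmed allele sequences:
uniform-random flanks (seeded, byte-reproducible), one planted variant per
pair — SNPs, 1–3 bp indels, CRISPR loci with a unique protospacer, and
"planted assay" pairs built backward from an EcoRI near-site. It does not
emulate sequencing noise, heterozygous traces, repeat-rich genomic
context, or base-composition bias; a green test therefore establishes the
combinatorial correctness of scanning/design, not performance on
low-quality input. The published wild-type digestion geometry (90-bp
amplicon cutting to 36 + 54 bp with a single-mismatch primer, 1-bp
insertions uncut) is exercised against a *synthetic stand-in locus* that
embeds the real Cas9 target with constructed flanks reproducing that
geometry; the genomic flanks of the original locus are not bundled, so
that test validates the pipeline's mechanics, not the original
experiment.

## Known limitations

* No primer-dimer/hairpin screening and no genome-wide specificity check;
  candidate primers should still be BLASTed against the target genome.
* Near-matches (not just exact sites) downstream of the variant, and
  near-matches under the primer, are not disrupted/rejected; with mismatch
  budgets > 1 a polymerase-tolerated partial site is conceivable.
* Enzymes whose cut offsets are unknown participate in presence/absence
  calls only and are flagged in reports; fragment sizes are not predicted
  for them.
* The enzyme snapshot is a point-in-time catalogue of commercially
  available single-cut enzymes; a different catalogue version changes
  which (and how many) assays are reported.
* Editing-outcome profiles model only insertions/deletions at the cut
  bond — no substitutions, microhomology-mediated large deletions, or
  asymmetric resection.
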