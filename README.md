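# dcapskit

Design of CAPS and dCAPS genotyping assays for SNP and small-indel
alleles — including the 1–2 bp indels that CRISPR/Cas9 editing typically
leaves behind, which are invisible on an agarose gel and tedious to
sequence one plant (or colony, or clone) at a time.

**Who it is for.** Anyone genotyping by PCR + restriction digest: you have
two allele sequences (or a wild-type sequence and a CRISPR target) and want
a primer + enzyme pair whose digest tells the alleles apart on a gel.

## The method

A **CAPS** assay amplifies a short product centred on a restriction site
present in only one allele; the digest cuts one genotype and not the other.
When no such differential site exists, a **dCAPS** assay engineers one: the
forward primer carries one or more deliberate template mismatches so that,
after amplification, a recognition site is completed in one allele's
product only.

dcapskit decomposes the two alleles into shared and unshared regions
(longest common prefix, then longest common suffix of the remainder), and
anchors every primer's 3′ end at the **last shared base**. Candidate
enzymes are found by sliding each recognition motif over the variant
region and scoring a degeneracy-aware Hamming distance *d(x, y)* = number
of positions whose IUPAC base sets do not intersect (so `GCAT` vs `GGTT`
is 2, but `GCAT` vs `GYTT` is 1, because C ∈ Y = {C,T}). A placement
within the mismatch budget whose completed site is absent from the other
allele is a candidate; two core constraints apply — the primer must lie
wholly in the shared region, and the motif must overlap both shared and
unshared sequence — plus a rejection rule for enzymes that cut again in
the shared downstream region within the amplicon. Everything is scanned
on both strands and in both orientations.

For **CRISPR screening** (allele unknown in advance), the package
simulates an editing-outcome profile at the Cas9 cut site (−3 bp from the
PAM; default: ±1 bp events — insertion of A/C/G/T or deletion of the base
5′ of the cut), anchors the primer at the last base shared by wild type
and *all* simulated variants, and keeps assays that cut wild type while
missing at most a user-chosen *loss fraction* of events.

Primer melting temperatures use the nearest-neighbor model with the
Sugimoto thermodynamic parameters and a 16.6·log₁₀[Na⁺] salt correction,
Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log₁₀[Na⁺] (defaults
50 nM primer, 50 mM Na⁺).

## Worked example

Two alleles differing by one SNP (a planted test fixture):

```sh
dcapskit known \
  TAAAATTGAACCGCCAGGAACCTGCCGGACTTCCCGGGTCTAATTCACATGGACATCACG \
  TAAAATTGAACCGCCAGGAACCTGCCGGACTTGCCGGGTCTAATTCACATGGACATCACG \
  --include EcoRI
```

prints (provenance header trimmed):

```
enzyme  motif   orientation  cleaved_allele  is_caps  mismatch_count  primer                     primer_length  mismatch_positions  tm_celsius  motif_start  amplicon_len  warnings  fragments_allele1  fragments_allele2
EcoRI   GAATTC  forward      1               False    1               GAACCGCCAGGAACCTGCCGGAATT  25             23                  59.87       28           53            ...       21,32              53
```

Read: EcoRI can discriminate the alleles as a dCAPS assay. The 25-nt
primer carries **1 mismatch** at primer position 23 (1-based from the 5′
end), which completes a `GAATTC` site starting at sequence position 28 in
allele 1 only. The simulated allele-1 amplicon digests into **21 + 32 bp**
fragments while allele 2 stays **uncut (53 bp)** — a band pattern easily
read on a 3 % gel. Tm of the primer at default salt/primer concentrations
is 59.9 °C. Pick any reported enzyme you have in the freezer; the reverse
primer (placed anywhere downstream) is your choice.

Screening mode works the same way from a wild-type sequence plus a 20-nt
protospacer (5′→3′, no PAM, either strand):

```sh
dcapskit screen <wild-type sequence> GGTTGAGATCAAGATAGACA --loss-threshold 0
```

and reports, per assay, the loss fraction and a per-event cut/uncut call
for each simulated editing outcome.

## Enzyme catalogue

A snapshot of 232 commercially available single-cut enzymes ships with the
package (`src/dcapskit/data/enzymes.tsv`). The TSV dialect is
`name<TAB>site<TAB>[extra]` with `^` marking the top-strand cut
(`EcoRI  G^AATTC`), `top/bottom` offsets for enzymes cutting outside their
site (`AcuI  CTGAAG  22/20`), and `nick`/`double` flags for enzymes that
are excluded from scanning. Supply your own file with `--enzymes`.

## Layout

- `dcapskit.alphabet` — IUPAC alphabet, reverse complement, degenerate distance
- `dcapskit.enzymes` — catalogue loading/filtering, TSV dialect
- `dcapskit.compare` — shared/unshared decomposition of two alleles
- `dcapskit.scan` — candidate assay search, downstream rejection, in-silico digests
- `dcapskit.primers` — mismatch patching, site disruption, length/Tm selection
- `dcapskit.thermo` — nearest-neighbor Tm (Sugimoto parameters)
- `dcapskit.screen` — CRISPR edit simulation and screening assays
- `dcapskit.classify` — productive / problematic / non-productive audit
- `dcapskit.pipeline`, `dcapskit.cli`, `dcapskit.reports`, `dcapskit.fixtures`

See `docs/methods.md` for the model details, numerical conventions and
known limitations.
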