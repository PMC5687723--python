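"""Scan for restriction motifs that discriminate two alleles.

A candidate assay is an enzyme whose recognition motif, placed over the
variant region of one allele, either matches exactly (a CAPS assay) or
comes within the user's mismatch budget of matching (a dCAPS assay, where
the missing bases will be supplied by deliberate primer-template
mismatches).  Two constraints shape the search:

1. primers must lie wholly within the shared upstream region with their 3'
   end at the last shared base, so any engineered mismatch has to fall in
   that region; and
2. a discriminating motif must overlap both the shared and the unshared
   region by at least one base (an exact site wholly inside an unshared
   region also discriminates and is kept as a CAPS candidate).

Every pair of alleles is scanned twice — as supplied and as reverse
complements — because an enzyme rejected for cutting again downstream in
one direction can be clean in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .alphabet import BASE_SETS, bases_match, is_concrete, reverse_complement
from .compare import AlleleComparison
from .enzymes import RestrictionEnzyme

__all__ = [
    "CandidateAssay",
    "UnknownCutOffset",
    "scan_assays",
    "reject_downstream_cutters",
    "predict_fragments",
    "find_exact_sites",
    "cut_positions",
    "MIN_BAND_DIFF",
    "DEFAULT_AMPLICON_LEN",
]

DEFAULT_AMPLICON_LEN = 150
#: minimum band-size difference (bp) considered resolvable on a gel
MIN_BAND_DIFF = 5


class UnknownCutOffset(ValueError):
    """The enzyme's cut offsets are unknown; only presence/absence calls."""


@dataclass(frozen=True)
class CandidateAssay:
    """An enzyme + placement that can discriminate the two alleles.

    ``motif_start`` is 0-based in the primer-bearing (oriented) sequence of
    the cleaved allele; ``strand`` records whether the motif or its reverse
    complement matched; ``patches`` are the (absolute position, base)
    substitutions the primer must carry to complete the site.
    """

    enzyme: RestrictionEnzyme
    motif_start: int
    strand: str  # '+' | '-'
    orientation: str  # forward | reverse_complement
    cleaved_allele: int | str  # 1 | 2 | 'both_differently'
    mismatch_count: int
    is_caps: bool
    overlap_shared: int
    overlap_unshared: int
    patches: tuple[tuple[int, str], ...]
    comparison: AlleleComparison = field(repr=False)
    warnings: tuple[str, ...] = ()

    @property
    def site_motif(self) -> str:
        """The motif as it reads on the scanned (top) strand."""
        m = self.enzyme.motif
        return m if self.strand == "+" else reverse_complement(m)

    def key(self) -> tuple:
        """Identity for set comparisons (independent of bookkeeping fields)."""
        return (
            self.enzyme.name,
            self.motif_start,
            self.orientation,
            self.cleaved_allele,
            self.mismatch_count,
        )


def _motif_variants(enzyme: RestrictionEnzyme) -> list[tuple[str, str]]:
    if enzyme.is_palindromic:
        return [(enzyme.motif, "+")]
    return [(enzyme.motif, "+"), (reverse_complement(enzyme.motif), "-")]


def find_exact_sites(
    seq: str, enzyme: RestrictionEnzyme, *, start: int = 0, end: int | None = None
) -> list[tuple[int, str]]:
    """Exact (degeneracy-aware, distance-0) occurrences of the recognition
    site on either strand, as (0-based start, strand), within
    ``[start, end)`` — occurrences must lie fully inside the window."""
    end = len(seq) if end is None else min(end, len(seq))
    hits: list[tuple[int, str]] = []
    for motif, strand in _motif_variants(enzyme):
        m = len(motif)
        for s in range(max(start, 0), end - m + 1):
            if all(bases_match(motif[i], seq[s + i]) for i in range(m)):
                hits.append((s, strand))
    hits.sort()
    return hits


def cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cleavage coordinates of every exact site (both strands).

    A site read on the bottom strand cuts the top strand at
    ``start + len(motif) - cut_bottom``.  Cuts falling outside the sequence
    (offset cutters near an end) are dropped.
    """
    if not enzyme.has_cut_offsets:
        raise UnknownCutOffset(enzyme.name)
    m = len(enzyme.motif)
    cuts = set()
    for s, strand in find_exact_sites(seq, enzyme):
        pos = s + enzyme.cut_top if strand == "+" else s + m - enzyme.cut_bottom
        if 0 < pos < len(seq):
            cuts.add(pos)
    return sorted(cuts)


def predict_fragments(amplicon: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths after a complete digest of a concrete amplicon.

    Lengths always sum to ``len(amplicon)``; a single fragment means no
    site.  Raises :class:`UnknownCutOffset` for enzymes usable only for
    presence/absence calls.
    """
    if not is_concrete(amplicon):
        raise ValueError("amplicon must be concrete (ACGT only)")
    cuts = cut_positions(amplicon, enzyme)
    bounds = [0] + cuts + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _patches_for(motif: str, seq: str, s: int, mism: Sequence[int]) -> tuple[tuple[int, str], ...]:
    """Concrete substitutions completing ``motif`` at ``s`` on ``seq``.

    At each mismatching position the lexicographically first concrete base
    compatible with the motif symbol is chosen (the template base is kept
    wherever it is compatible).
    """
    out = []
    for pos in mism:
        sym = motif[pos - s]
        out.append((pos, min(BASE_SETS[sym])))
    return tuple(out)


def _apply_patches(seq: str, patches: Iterable[tuple[int, str]]) -> str:
    chars = list(seq)
    for pos, base in patches:
        chars[pos] = base
    return "".join(chars)


def _variant_window_hit(
    seq: str, enzyme: RestrictionEnzyme, prefix_len: int, unshared_len: int
) -> bool:
    """Does ``seq`` carry an exact site overlapping its variant region?

    The variant region is ``[prefix_len, prefix_len + unshared_len)``; for a
    zero-length unshared region the site must span the junction.
    """
    p, u = prefix_len, unshared_len
    for motif, _ in _motif_variants(enzyme):
        m = len(motif)
        lo = max(0, p - m + 1)
        hi = (p + u - 1) if u > 0 else (p - 1)
        for t in range(lo, min(hi, len(seq) - m) + 1):
            if all(bases_match(motif[i], seq[t + i]) for i in range(m)):
                return True
    return False


def _scan_oriented(
    cmp: AlleleComparison,
    enzymes: Sequence[RestrictionEnzyme],
    max_mismatch: int,
) -> list[CandidateAssay]:
    out: list[CandidateAssay] = []
    p = cmp.shared_upstream_len
    seen: set[tuple] = set()
    for allele in (1, 2):
        sa = cmp.seq(allele)
        other = 2 if allele == 1 else 1
        sb = cmp.seq(other)
        ua = len(cmp.unshared(allele))
        ub = len(cmp.unshared(other))
        ds_a = p + ua
        for enzyme in enzymes:
            if enzyme.is_excluded:
                continue
            for motif, strand in _motif_variants(enzyme):
                m = len(motif)
                lo = max(0, p - m + 1)
                hi = (p + ua - 1) if ua > 0 else (p - 1)
                hi = min(hi, len(sa) - m)
                for s in range(lo, hi + 1):
                    mism = [
                        s + i
                        for i in range(m)
                        if not bases_match(motif[i], sa[s + i])
                    ]
                    d = len(mism)
                    if d > max_mismatch:
                        continue
                    if any(pos >= p for pos in mism):
                        continue  # unpatchable: primer cannot reach past the anchor
                    ov_unsh = max(0, min(s + m, ds_a) - max(s, p))
                    ov_sh = m - ov_unsh
                    if d > 0 and (ov_sh < 1 or (ua > 0 and ov_unsh < 1)):
                        continue
                    patches = _patches_for(motif, sa, s, mism)
                    sb_p = _apply_patches(sb, patches)
                    other_cut = _variant_window_hit(sb_p, enzyme, p, ub)
                    if not other_cut:
                        cand = CandidateAssay(
                            enzyme=enzyme,
                            motif_start=s,
                            strand=strand,
                            orientation=cmp.orientation,
                            cleaved_allele=allele,
                            mismatch_count=d,
                            is_caps=(d == 0),
                            overlap_shared=ov_sh,
                            overlap_unshared=ov_unsh,
                            patches=patches,
                            comparison=cmp,
                        )
                        if cand.key() not in seen:
                            seen.add(cand.key())
                            out.append(cand)
                    elif (
                        d == 0
                        and allele == 1
                        and enzyme.has_cut_offsets
                        and abs(ua - ub) >= MIN_BAND_DIFF
                    ):
                        # both alleles cut, but the indel shifts a band by a
                        # gel-resolvable amount
                        cand = CandidateAssay(
                            enzyme=enzyme,
                            motif_start=s,
                            strand=strand,
                            orientation=cmp.orientation,
                            cleaved_allele="both_differently",
                            mismatch_count=0,
                            is_caps=True,
                            overlap_shared=ov_sh,
                            overlap_unshared=ov_unsh,
                            patches=(),
                            comparison=cmp,
                        )
                        if cand.key() not in seen:
                            seen.add(cand.key())
                            out.append(cand)
    return out


def scan_assays(
    cmp: AlleleComparison,
    enzymes: Sequence[RestrictionEnzyme],
    max_mismatch: int = 1,
    *,
    both_orientations: bool = True,
) -> list[CandidateAssay]:
    """Enumerate every candidate CAPS/dCAPS assay for an allele pair.

    Scans every enzyme's motif (and its reverse complement for
    non-palindromic motifs) at every placement overlapping the variant
    region of either allele, in the supplied orientation and — when
    ``both_orientations`` — on the reverse complement of both sequences.
    Candidates are sorted by (mismatch count, enzyme name, position).  An
    empty list is a legal result.
    """
    cands = _scan_oriented(cmp, enzymes, max_mismatch)
    if both_orientations:
        cands += _scan_oriented(cmp.reverse_complement(), enzymes, max_mismatch)
    cands.sort(key=lambda c: (c.mismatch_count, c.enzyme.name, str(c.orientation), c.motif_start))
    return cands


def reject_downstream_cutters(
    candidates: Iterable[CandidateAssay],
    amplicon_len: int = DEFAULT_AMPLICON_LEN,
) -> list[CandidateAssay]:
    """Drop candidates whose enzyme cuts again in the shared downstream region.

    A second exact site within ``amplicon_len`` of the primer 3' anchor
    would complicate reading the diagnostic digest.  Only exact matches are
    considered.  When the supplied sequence ends before the amplicon window
    does, the remaining sequence is what gets checked and the candidate
    carries a truncated-window warning.
    """
    kept: list[CandidateAssay] = []
    for cand in candidates:
        cmp = cand.comparison
        alleles = (1, 2) if cand.cleaved_allele == "both_differently" else (cand.cleaved_allele,)
        rejected = False
        truncated = False
        for allele in alleles:
            sa = cmp.seq(allele)
            p = cmp.shared_upstream_len
            ds_start = p + len(cmp.unshared(allele))
            window_end = (p - 1) + amplicon_len
            if window_end > len(sa):
                truncated = True
            hits = find_exact_sites(sa, cand.enzyme, start=ds_start, end=window_end)
            if hits:
                rejected = True
                break
        if rejected:
            continue
        if truncated:
            cand = replace(
                cand,
                warnings=cand.warnings
                + ("amplicon window truncated at end of supplied sequence",),
            )
        kept.append(cand)
    return kept
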