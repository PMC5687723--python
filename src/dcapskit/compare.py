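"""Decomposition of two allele sequences into shared and unshared regions.

Two sequences of the same locus differing by one local mutation are split
into a shared upstream region (longest common prefix), per-sequence
unshared regions, and a shared downstream region (longest common suffix of
the remainders).  For a SNP both unshared regions have length 1; for a pure
indel one unshared region is empty and the other has the indel length.  The
last upstream shared base anchors all primer design.

Ambiguity at homopolymers or microsatellites (deleting one A from AAAA) is
resolved by maximizing the shared prefix first, which pushes the unshared
region as far 3' as possible — deterministic, and the prefix is what
anchors the primer.  When prefix and suffix claims overlap (their combined
length would exceed a sequence), the suffix is truncated for the same
reason.  Degenerate input codes participate through set-intersection
matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alphabet import bases_match, normalize, reverse_complement

__all__ = [
    "AlleleComparison",
    "IdenticalSequences",
    "MultipleVariantRegions",
    "find_shared_regions",
    "MIN_RECOMMENDED_FLANK",
]

MIN_RECOMMENDED_FLANK = 20  # homology arm length the interface asks for


class IdenticalSequences(ValueError):
    """The two inputs do not differ; there is nothing to discriminate."""


class MultipleVariantRegions(ValueError):
    """Inputs appear to differ at two separated loci; refusing to guess."""


@dataclass(frozen=True)
class AlleleComparison:
    """Shared/unshared decomposition of two allele sequences.

    ``seq_i == shared_upstream_i + unshared_i + shared_downstream_i`` holds
    for both sequences by construction.  The shared regions of the two
    sequences are equal under set-intersection matching (and literally
    equal for concrete inputs).
    """

    seq1: str
    seq2: str
    shared_upstream_len: int
    shared_downstream_len: int
    orientation: str = "forward"  # forward | reverse_complement
    warnings: tuple[str, ...] = field(default_factory=tuple)

    # -- derived regions -------------------------------------------------
    @property
    def shared_upstream(self) -> str:
        return self.seq1[: self.shared_upstream_len]

    @property
    def unshared1(self) -> str:
        return self.seq1[self.shared_upstream_len : len(self.seq1) - self.shared_downstream_len]

    @property
    def unshared2(self) -> str:
        return self.seq2[self.shared_upstream_len : len(self.seq2) - self.shared_downstream_len]

    @property
    def shared_downstream(self) -> str:
        return self.seq1[len(self.seq1) - self.shared_downstream_len :]

    @property
    def last_shared_index_1(self) -> int:
        """0-based index of the final upstream shared base (-1 if none)."""
        return self.shared_upstream_len - 1

    last_shared_index_2 = last_shared_index_1

    def seq(self, allele: int) -> str:
        return self.seq1 if allele == 1 else self.seq2

    def unshared(self, allele: int) -> str:
        return self.unshared1 if allele == 1 else self.unshared2

    @property
    def is_snp(self) -> bool:
        return len(self.unshared1) == len(self.unshared2) == 1

    def swapped(self) -> "AlleleComparison":
        return replace(self, seq1=self.seq2, seq2=self.seq1)

    def reverse_complement(self) -> "AlleleComparison":
        """The same pair of alleles viewed from the opposite strand."""
        cmp_rc = find_shared_regions(
            reverse_complement(self.seq1), reverse_complement(self.seq2)
        )
        flipped = "reverse_complement" if self.orientation == "forward" else "forward"
        return replace(cmp_rc, orientation=flipped)


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if not bases_match(a[i], b[i]):
            return i
    return n


def find_shared_regions(seq1: str, seq2: str) -> AlleleComparison:
    """Decompose two allele sequences of one locus.

    Raises :class:`IdenticalSequences` when nothing differs and
    :class:`MultipleVariantRegions` when the residue between prefix and
    suffix looks like two separated substitutions rather than one local
    variant.  Short inputs and missing flanks produce warnings, not errors.
    """
    s1 = normalize(seq1)
    s2 = normalize(seq2)

    p = _common_prefix_len(s1, s2)
    if p == len(s1) == len(s2):
        raise IdenticalSequences("the two sequences do not differ")

    # longest common suffix of the remainders, truncated so prefix wins
    r1, r2 = s1[p:], s2[p:]
    sfx = _common_prefix_len(r1[::-1], r2[::-1])
    sfx = min(sfx, len(r1), len(r2))

    u1 = s1[p : len(s1) - sfx]
    u2 = s2[p : len(s2) - sfx]

    # Equal-length unshared blocks (> 1) whose interiors still agree are a
    # sign of two separated SNPs, which is outside this tool's contract.
    if len(u1) == len(u2) > 1 and any(bases_match(a, b) for a, b in zip(u1, u2)):
        raise MultipleVariantRegions(
            "inputs differ at more than one separated position; supply one "
            "local variant per comparison"
        )

    warns: list[str] = []
    if p < MIN_RECOMMENDED_FLANK or sfx < MIN_RECOMMENDED_FLANK:
        warns.append(
            f"short homology flank (upstream {p} nt, downstream {sfx} nt; "
            f">= {MIN_RECOMMENDED_FLANK} nt recommended)"
        )
    if p == 0 or sfx == 0:
        warns.append("no shared flank on one side of the variant")

    return AlleleComparison(
        seq1=s1,
        seq2=s2,
        shared_upstream_len=p,
        shared_downstream_len=sfx,
        warnings=tuple(warns),
    )
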