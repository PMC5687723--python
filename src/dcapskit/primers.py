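"""Turn a candidate assay into a concrete mismatch-bearing primer.

The diagnostic primer lies wholly within the shared upstream region with
its 3' end at the last shared base.  Bases under the motif footprint are
patched so the recognition site is completed on the allele to be cleaved;
any *other* exact occurrence of the same site under the primer footprint is
destroyed with one additional mismatch, preferring a transversion that does
not create a site for any catalogue enzyme.  The total number of
primer-template mismatches must stay within the user's budget, and a
mismatch at the 3'-terminal base is rejected (by default — G/T wobble pairs
can be allowed, some polymerases extend them).

Primer length is chosen afterwards: either a fixed length, or the length in
18-36 nt whose nearest-neighbor Tm lands closest to a target (ties go to
the shorter primer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .alphabet import BASE_SETS, reverse_complement
from .compare import AlleleComparison
from .enzymes import RestrictionEnzyme
from .scan import CandidateAssay, _apply_patches, _variant_window_hit, find_exact_sites
from .thermo import TmParameters, melting_temperature

__all__ = [
    "PrimerOptions",
    "PrimerDesign",
    "DesignError",
    "MismatchBudgetExceeded",
    "TerminalMismatchRejected",
    "PrimerOutsideSharedRegion",
    "SharedRegionTooShort",
    "DesignRejected",
    "build_primer",
    "extend_primer",
    "design_primer",
]

MIN_PRIMER_LEN = 18
MAX_PRIMER_LEN = 36


class DesignError(ValueError):
    pass


class MismatchBudgetExceeded(DesignError):
    pass


class TerminalMismatchRejected(DesignError):
    pass


class PrimerOutsideSharedRegion(DesignError):
    pass


class SharedRegionTooShort(DesignError):
    pass


class DesignRejected(DesignError):
    """No safe disruption substitution or failed diagnostic verification."""


@dataclass(frozen=True)
class PrimerOptions:
    """User knobs for primer construction.

    ``mode`` is ``"target_tm"`` (pick the 18-36 nt extension whose Tm is
    closest to ``target_tm``) or ``"fixed_length"`` (exactly ``length`` nt).
    ``catalogue`` is consulted when choosing disruption substitutions so a
    repair does not quietly create a site for another enzyme.
    """

    max_mismatch: int = 1
    allow_3prime_GT: bool = False
    mode: str = "target_tm"
    length: int = 25
    target_tm: float = 60.0
    tm_params: TmParameters = field(default_factory=TmParameters)
    catalogue: tuple[RestrictionEnzyme, ...] = ()

    def __post_init__(self):
        if self.mode not in ("target_tm", "fixed_length"):
            raise ValueError(f"unknown primer mode {self.mode!r}")


@dataclass(frozen=True)
class PrimerDesign:
    """A concrete 5'->3' oligonucleotide for one candidate assay.

    ``sequence`` reads 5'->3' in the orientation of the scanned strand
    (check ``assay.orientation`` to know whether that is the supplied
    strand or its reverse complement).  ``mismatch_positions`` are 0-based
    primer coordinates from the 5' end.
    """

    sequence: str
    anchor_3prime: int
    length: int
    mismatch_positions: tuple[int, ...]
    mismatch_count: int
    tm_celsius: float
    assay: CandidateAssay
    warnings: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        """Absolute start of the primer footprint in the oriented sequence."""
        return self.anchor_3prime + 1 - self.length

    def amplicon(self, allele: int, length: int | None = None) -> str:
        """Simulated amplicon: primer substituted into the given allele's
        template, extended downstream (to ``length`` nt when supplied and
        available)."""
        cmp = self.assay.comparison
        template = cmp.seq(1 if allele == "both_differently" else allele)
        body = self.sequence + template[self.anchor_3prime + 1 :]
        return body if length is None else body[:length]


def _breaks_motif(base: str, motif_sym_set: frozenset[str]) -> bool:
    return base not in motif_sym_set


def _creates_new_site(
    footprint: str, catalogue: Sequence[RestrictionEnzyme]
) -> set[tuple[str, int, str]]:
    found = set()
    for e in catalogue:
        if e.is_excluded:
            continue
        for s, strand in find_exact_sites(footprint, e):
            found.add((e.name, s, strand))
    return found


# transversions first: they destabilize enzyme binding most reliably
_SUBSTITUTION_ORDER = {
    "A": "CTG",
    "G": "CTA",
    "C": "AGT",
    "T": "AGC",
}


def _finalize(
    assay: CandidateAssay,
    cmp: AlleleComparison,
    opts: PrimerOptions,
    length: int,
    *,
    check_other: bool = True,
) -> PrimerDesign:
    """Build the primer of exactly ``length`` nt, patching and disrupting."""
    p = cmp.shared_upstream_len
    allele = 1 if assay.cleaved_allele == "both_differently" else assay.cleaved_allele
    sa = cmp.seq(allele)
    anchor = p - 1
    start = anchor + 1 - length

    if length > p:
        raise SharedRegionTooShort(
            f"primer of {length} nt does not fit in a {p} nt shared upstream region"
        )

    patches = dict(assay.patches)
    if patches and min(patches) < start:
        raise PrimerOutsideSharedRegion(
            "required mismatch positions are not covered at this primer length"
        )

    # 3'-terminal mismatch policy
    if anchor in patches:
        pair = {patches[anchor], sa[anchor]}
        if not (opts.allow_3prime_GT and pair == {"G", "T"}):
            raise TerminalMismatchRejected(
                "engineered mismatch at the 3'-terminal base"
            )

    warnings: list[str] = []
    diag_span = range(assay.motif_start, assay.motif_start + len(assay.enzyme.motif))

    # destroy stray exact occurrences of the same site under the footprint
    for _round in range(4):  # a footprint of <= 36 nt cannot need more
        footprint = _apply_patches(sa, patches.items())[start : anchor + 1]
        stray = [
            (s, strand)
            for s, strand in find_exact_sites(footprint, assay.enzyme)
            if (start + s) != assay.motif_start
        ]
        if not stray:
            break
        s_rel, strand = stray[0]
        motif = assay.site_motif if strand == assay.strand else reverse_complement(
            assay.site_motif
        )
        placed = False
        before = _creates_new_site(footprint, opts.catalogue)
        for i in range(len(motif)):
            pos = start + s_rel + i
            if pos == anchor or pos in patches or pos in diag_span:
                continue
            current = footprint[s_rel + i]
            for base in _SUBSTITUTION_ORDER[current]:
                if not _breaks_motif(base, BASE_SETS[motif[i]]):
                    continue
                trial = dict(patches)
                trial[pos] = base
                trial_fp = _apply_patches(sa, trial.items())[start : anchor + 1]
                after = _creates_new_site(trial_fp, opts.catalogue)
                if after - before:
                    continue  # substitution would create a site for another enzyme
                if any(
                    (t + start) != assay.motif_start
                    for t, _ in find_exact_sites(trial_fp, assay.enzyme)
                ):
                    continue  # did not actually destroy it
                patches = trial
                placed = True
                break
            if placed:
                break
        if not placed:
            raise DesignRejected(
                f"cannot disrupt extra {assay.enzyme.name} site under the primer "
                "without creating a new catalogue site"
            )

    if len(patches) > opts.max_mismatch:
        raise MismatchBudgetExceeded(
            f"{len(patches)} mismatches needed, budget is {opts.max_mismatch}"
        )

    primer = _apply_patches(sa, patches.items())[start : anchor + 1]

    # definitional check: the primer-bearing amplicon of the cleaved allele
    # carries the diagnostic site; the other allele's does not get cut in
    # its variant window
    amp_a = primer + sa[anchor + 1 :]
    diag_hits = {s for s, _ in find_exact_sites(amp_a, assay.enzyme)}
    if assay.motif_start - start not in diag_hits:
        raise DesignRejected("diagnostic site absent after disruption pass")
    if check_other and assay.cleaved_allele != "both_differently":
        other = 2 if allele == 1 else 1
        sb = cmp.seq(other)
        sb_p = _apply_patches(sb, patches.items())
        if _variant_window_hit(sb_p, assay.enzyme, p, len(cmp.unshared(other))):
            raise DesignRejected("other allele still cut at the variant site")

    mism_rel = tuple(sorted(pos - start for pos in patches))
    try:
        tm = melting_temperature(primer, opts.tm_params)
    except ValueError:
        tm = float("nan")
        warnings.append("Tm unavailable (degenerate base under primer footprint)")
    return PrimerDesign(
        sequence=primer,
        anchor_3prime=anchor,
        length=length,
        mismatch_positions=mism_rel,
        mismatch_count=len(patches),
        tm_celsius=tm,
        assay=assay,
        warnings=tuple(warnings),
    )


def _min_length(assay: CandidateAssay, cmp: AlleleComparison) -> int:
    p = cmp.shared_upstream_len
    if assay.patches:
        return max(MIN_PRIMER_LEN, p - min(pos for pos, _ in assay.patches))
    return MIN_PRIMER_LEN


def build_primer(
    assay: CandidateAssay,
    cmp: AlleleComparison | None = None,
    opts: PrimerOptions | None = None,
) -> PrimerDesign:
    """Minimal-length primer realizing ``assay`` (before length selection).

    Applies the site-completing patches, the 3'-mismatch policy, the
    shared-site disruption pass and the mismatch budget.  Use
    :func:`extend_primer` (or :func:`design_primer`) to pick the final
    length.
    """
    cmp = cmp or assay.comparison
    opts = opts or PrimerOptions()
    needed = _min_length(assay, cmp)
    if needed > cmp.shared_upstream_len:
        raise SharedRegionTooShort(
            f"shared upstream region of {cmp.shared_upstream_len} nt is shorter "
            f"than the {needed} nt primer the motif requires"
        )
    return _finalize(assay, cmp, opts, needed)


def extend_primer(
    design: PrimerDesign,
    cmp: AlleleComparison | None = None,
    opts: PrimerOptions | None = None,
) -> PrimerDesign:
    """Extend a primer 5' to its final length.

    ``fixed_length`` mode returns exactly the requested length;
    ``target_tm`` mode searches lengths 18-36 nt (bounded by the shared
    region) for the Tm closest to the target, breaking ties toward the
    shorter primer.
    """
    assay = design.assay
    cmp = cmp or assay.comparison
    opts = opts or PrimerOptions()
    lo = _min_length(assay, cmp)
    if opts.mode == "fixed_length":
        if opts.length > cmp.shared_upstream_len:
            raise SharedRegionTooShort(
                f"requested {opts.length} nt primer, shared upstream region is "
                f"{cmp.shared_upstream_len} nt"
            )
        if opts.length < lo:
            raise PrimerOutsideSharedRegion(
                f"requested {opts.length} nt primer does not cover the required "
                f"mismatch at {lo} nt from the 3' end"
            )
        return _finalize(assay, cmp, opts, opts.length)

    hi = min(MAX_PRIMER_LEN, cmp.shared_upstream_len)
    if hi < lo:
        raise SharedRegionTooShort(
            f"shared upstream region of {cmp.shared_upstream_len} nt cannot hold "
            f"a primer covering the motif"
        )
    best: PrimerDesign | None = None
    best_key: tuple | None = None
    last_err: DesignError | None = None
    for length in range(lo, hi + 1):
        try:
            cand = _finalize(assay, cmp, opts, length)
        except DesignError as exc:
            last_err = exc
            continue
        key = (abs(cand.tm_celsius - opts.target_tm), cand.length)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    if best is None:
        raise last_err or DesignRejected("no feasible primer length")
    return best


def design_primer(
    assay: CandidateAssay, opts: PrimerOptions | None = None
) -> PrimerDesign:
    """Convenience: build + extend in one call."""
    opts = opts or PrimerOptions()
    return extend_primer(build_primer(assay, assay.comparison, opts), assay.comparison, opts)
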