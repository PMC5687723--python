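"""Pre-hoc screening assays for unknown CRISPR/Cas9 editing outcomes.

Before any plants (or cells) are genotyped, the editing outcome at a Cas9
target is unknown.  This module simulates a profile of plausible outcomes
— by default the five single-base events: insertion of A, C, G or T at the
blunt cut, or deletion of the base 5' of it — and designs assays whose
recognition site spans the cut so that the wild-type amplicon is cleaved
while (most) edited amplicons are not.  The fraction of simulated events an
assay fails to distinguish from wild type (because the edited amplicon is
still cut somewhere) is its *loss fraction*; assays above the user's
acceptable-loss threshold are discarded.  Losses typically arise when an
insertion lands inside a run of degenerate (N) positions of the motif.

Cas9 cleaves 3 bp 5' of the PAM, i.e. between positions 17 and 18 of the
20-nt protospacer.  The protospacer may sit on either strand of the
supplied wild-type sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alphabet import bases_match, normalize, reverse_complement
from .compare import AlleleComparison
from .enzymes import RestrictionEnzyme
from .primers import (
    DesignError,
    PrimerDesign,
    PrimerOptions,
    _finalize,
    _min_length,
    extend_primer,
)
from .scan import (
    CandidateAssay,
    DEFAULT_AMPLICON_LEN,
    _apply_patches,
    _motif_variants,
    _patches_for,
    find_exact_sites,
    predict_fragments,
)

__all__ = [
    "EditProfile",
    "EditEvent",
    "ScreeningResult",
    "ProtospacerNotFound",
    "MultipleProtospacerHits",
    "locate_cut_site",
    "simulate_edits",
    "last_shared_base_all",
    "screen_assays",
    "DEFAULT_PROFILE",
]

PROTOSPACER_LEN = 20
CUT_OFFSET = 17  # bases of the protospacer 5' of the cleaved bond (-3 rule)


class ProtospacerNotFound(ValueError):
    pass


class MultipleProtospacerHits(ValueError):
    pass


@dataclass(frozen=True)
class EditEvent:
    """One simulated outcome: an insertion of ``payload`` (a base) at the
    cut bond, or a deletion of ``payload`` (a length) bases ending at it."""

    kind: str  # insertion | deletion
    payload: str | int
    weight: float

    def label(self) -> str:
        if self.kind == "insertion":
            return f"+{self.payload}"
        return f"-{self.payload}bp"

    def apply(self, wt: str, cut: int) -> str:
        if self.kind == "insertion":
            return wt[:cut] + str(self.payload) + wt[cut:]
        k = int(self.payload)
        return wt[: cut - k] + wt[cut:]


@dataclass(frozen=True)
class EditProfile:
    """A weighted set of editing outcomes (weights sum to 1)."""

    events: tuple[EditEvent, ...]

    def __post_init__(self):
        total = sum(e.weight for e in self.events)
        if self.events and abs(total - 1.0) > 1e-9:
            raise ValueError(f"event weights sum to {total}, expected 1")
        for e in self.events:
            if e.kind not in ("insertion", "deletion"):
                raise ValueError(f"unknown event kind {e.kind!r}")


#: four single-base insertions + one single-base deletion, uniform weights
DEFAULT_PROFILE = EditProfile(
    events=tuple(
        [EditEvent("insertion", b, 0.2) for b in "ACGT"]
        + [EditEvent("deletion", 1, 0.2)]
    )
)


@dataclass(frozen=True)
class ScreeningResult:
    """One surviving screening assay with its per-event digest calls."""

    assay: CandidateAssay
    primer: PrimerDesign
    loss_fraction: float
    per_event_calls: tuple[tuple[str, str], ...]  # (event label, cut|uncut)
    cut_position: int
    warnings: tuple[str, ...] = ()


def locate_cut_site(wt: str, protospacer: str) -> tuple[int, str]:
    """Locate the Cas9 cut bond for a 20-nt protospacer in ``wt``.

    Returns ``(bond, strand)`` where ``bond`` is the 0-based index of the
    first base 3' of the cleaved bond in wild-type coordinates and strand is
    ``"+"`` or ``"-"``.  The protospacer must occur exactly once over both
    strands.
    """
    wt = normalize(wt)
    ps = normalize(protospacer)
    if len(ps) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt, got {len(ps)}")
    hits: list[tuple[int, str]] = []
    for strand, query in (("+", ps), ("-", reverse_complement(ps))):
        start = 0
        while True:
            i = wt.find(query, start)
            if i < 0:
                break
            hits.append((i, strand))
            start = i + 1
    if not hits:
        raise ProtospacerNotFound("protospacer not found on either strand")
    if len(hits) > 1:
        raise MultipleProtospacerHits(f"{len(hits)} protospacer matches")
    q, strand = hits[0]
    bond = q + CUT_OFFSET if strand == "+" else q + (PROTOSPACER_LEN - CUT_OFFSET)
    return bond, strand


def simulate_edits(wt: str, cut_pos: int, profile: EditProfile = DEFAULT_PROFILE) -> list[str]:
    """One edited sequence per event of the profile, in profile order."""
    wt = normalize(wt)
    return [ev.apply(wt, cut_pos) for ev in profile.events]


def last_shared_base_all(wt: str, variants: Sequence[str]) -> int:
    """Index of the last wild-type base shared with *all* variants.

    The maximal prefix length L with every variant starting with
    ``wt[:L]``, minus one.  Inside homopolymers this lands 5' of the naive
    cut position, which is exactly what anchors a primer that works for
    every outcome.
    """
    if not variants:
        raise ValueError("at least one variant required")
    lcp = len(wt)
    for v in variants:
        n = min(lcp, len(v))
        i = 0
        while i < n and wt[i] == v[i]:
            i += 1
        lcp = min(lcp, i)
    return lcp - 1


def _screen_oriented(
    wt: str,
    variants: list[tuple[EditEvent, str]],
    enzymes: Sequence[RestrictionEnzyme],
    orientation: str,
    *,
    max_mismatch: int,
    loss_threshold: float,
    amplicon_len: int,
    opts: PrimerOptions,
) -> list[ScreeningResult]:
    lsb = last_shared_base_all(wt, [v for _, v in variants])
    p = lsb + 1  # primer-region length; all variants share wt[:p]
    results: list[ScreeningResult] = []
    seen: set[tuple] = set()

    # a pseudo-comparison so primer construction can reuse the known-allele
    # machinery: the "other allele" slot gets the first variant; the
    # discriminating checks below run against *all* variants instead
    for enzyme in enzymes:
        if enzyme.is_excluded:
            continue
        for motif, strand in _motif_variants(enzyme):
            m = len(motif)
            lo = max(0, p - m + 1)
            hi = min(p - 1, len(wt) - m)
            for s in range(lo, hi + 1):
                mism = [
                    s + i for i in range(m) if not bases_match(motif[i], wt[s + i])
                ]
                d = len(mism)
                if d > max_mismatch or any(pos >= p for pos in mism):
                    continue
                patches = _patches_for(motif, wt, s, mism)
                wt_p = _apply_patches(wt, patches)

                # downstream re-cut rejection (exact second site in the
                # wild-type amplicon window past the variant region)
                window_end = lsb + amplicon_len
                extra = [
                    t
                    for t, _ in find_exact_sites(
                        wt_p, enzyme, start=p + 1, end=window_end
                    )
                    if t != s
                ]
                if extra:
                    continue

                calls: list[tuple[str, str]] = []
                loss = 0.0
                uncut_variant: str | None = None
                for ev, var in variants:
                    var_p = _apply_patches(var, patches)
                    shift = max(0, len(var) - len(wt))
                    scan_end = lsb + amplicon_len + shift  # full edited amplicon window
                    cut = bool(
                        find_exact_sites(
                            var_p, enzyme, start=max(0, s - m), end=scan_end
                        )
                    )
                    calls.append((ev.label(), "cut" if cut else "uncut"))
                    if cut:
                        loss += ev.weight
                    elif uncut_variant is None:
                        uncut_variant = var
                if loss > loss_threshold + 1e-12:
                    continue
                if uncut_variant is None:
                    continue  # misses every simulated event: never diagnostic

                key = (enzyme.name, s, orientation)
                if key in seen:
                    continue

                # pair the wild type with an uncut variant so the primer
                # finalizer's discrimination check does not veto a design
                # whose residual (tolerated) loss comes from a cut variant
                pseudo = AlleleComparison(
                    seq1=wt,
                    seq2=uncut_variant,
                    shared_upstream_len=p,
                    shared_downstream_len=0,
                    orientation=orientation,
                )
                assay = CandidateAssay(
                    enzyme=enzyme,
                    motif_start=s,
                    strand=strand,
                    orientation=orientation,
                    cleaved_allele=1,
                    mismatch_count=d,
                    is_caps=(d == 0),
                    overlap_shared=max(0, p - s),
                    overlap_unshared=max(0, s + m - p),
                    patches=patches,
                    comparison=pseudo,
                )
                try:
                    design = extend_primer(
                        _finalize(assay, pseudo, opts, _min_length(assay, pseudo)),
                        pseudo,
                        opts,
                    )
                except DesignError:
                    continue
                if enzyme.has_cut_offsets:
                    # the wild-type amplicon must really yield two bands;
                    # an offset cutter can land its cut past the amplicon
                    try:
                        wt_amp = design.amplicon(1, amplicon_len)
                        if len(predict_fragments(wt_amp, enzyme)) < 2:
                            continue
                    except ValueError:
                        pass  # degenerate template: presence call only
                seen.add(key)
                results.append(
                    ScreeningResult(
                        assay=assay,
                        primer=design,
                        loss_fraction=round(loss, 12),
                        per_event_calls=tuple(calls),
                        cut_position=lsb,
                    )
                )
    return results


def screen_assays(
    wt: str,
    protospacer: str,
    enzymes: Sequence[RestrictionEnzyme],
    *,
    profile: EditProfile = DEFAULT_PROFILE,
    max_mismatch: int = 1,
    loss_threshold: float = 0.0,
    amplicon_len: int = DEFAULT_AMPLICON_LEN,
    primer_options: PrimerOptions | None = None,
    both_orientations: bool = True,
) -> list[ScreeningResult]:
    """Design screening assays cleaving wild type but not simulated edits.

    The loss threshold is inclusive: an assay missing exactly the threshold
    fraction of events is kept.  Results are sorted by (loss fraction,
    mismatch count, enzyme name).  Everything is deterministic.
    """
    wt = normalize(wt)
    if not 0.0 <= loss_threshold <= 1.0:
        raise ValueError("loss_threshold must lie in [0, 1]")
    opts = primer_options or PrimerOptions(max_mismatch=max_mismatch)
    bond, _strand = locate_cut_site(wt, protospacer)
    edited = simulate_edits(wt, bond, profile)
    fwd_variants = list(zip(profile.events, edited))

    results = _screen_oriented(
        wt,
        fwd_variants,
        enzymes,
        "forward",
        max_mismatch=max_mismatch,
        loss_threshold=loss_threshold,
        amplicon_len=amplicon_len,
        opts=opts,
    )
    if both_orientations:
        rc_variants = [(ev, reverse_complement(v)) for ev, v in fwd_variants]
        results += _screen_oriented(
            reverse_complement(wt),
            rc_variants,
            enzymes,
            "reverse_complement",
            max_mismatch=max_mismatch,
            loss_threshold=loss_threshold,
            amplicon_len=amplicon_len,
            opts=opts,
        )
    results.sort(
        key=lambda r: (r.loss_fraction, r.assay.mismatch_count, r.assay.enzyme.name, r.assay.motif_start)
    )
    return results
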