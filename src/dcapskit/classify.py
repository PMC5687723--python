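"""Three-way audit of a primer/enzyme/allele-pair combination.

Given any primer (not necessarily one this package designed), an enzyme and
two allele sequences, simulate the amplicon each allele would yield and ask
two questions:

* does the digest distinguish the two amplicons — either exactly one is cut
  at the diagnostic position, or both are cut but with gel-resolvable
  fragment differences (>= 5 bp in some band)?
* would the PCR itself likely work — no mismatch at the primer's
  3'-terminal base against either template (unless G/T wobble is allowed),
  no gap between primer and template, not an excessive number of
  mismatches?

The verdict is ``productive`` (distinguishes, amplifies), ``problematic``
(distinguishes, but an amplification defect is present) or
``non_productive`` (nothing to distinguish).  The categories are rule-based
judgements about assay design, not a thermodynamic PCR predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alphabet import bases_match, normalize
from .enzymes import RestrictionEnzyme
from .scan import MIN_BAND_DIFF, cut_positions, find_exact_sites

__all__ = [
    "AssayVerdict",
    "ClassifyPolicy",
    "PrimerNotLocatable",
    "classify_assay",
]


class PrimerNotLocatable(ValueError):
    """The primer does not anneal anywhere useful on a template."""


@dataclass(frozen=True)
class ClassifyPolicy:
    max_scan_mismatches: int = 5  # most mismatches tolerated when locating the primer
    gap_trigger: int = 3  # clustered mismatches beyond this trigger a gapped check
    max_gap: int = 3
    allow_3prime_GT: bool = False
    band_diff: int = MIN_BAND_DIFF


@dataclass(frozen=True)
class AssayVerdict:
    category: str  # productive | problematic | non_productive
    reasons: tuple[str, ...] = ()
    fragments1: tuple[int, ...] = ()
    fragments2: tuple[int, ...] = ()


@dataclass(frozen=True)
class _Placement:
    start: int
    mismatches: tuple[int, ...]  # primer coordinates


def _best_ungapped(primer: str, template: str) -> _Placement | None:
    n, m = len(template), len(primer)
    best: _Placement | None = None
    for s in range(0, n - m + 1):
        mism = tuple(
            i for i in range(m) if not bases_match(primer[i], template[s + i])
        )
        if best is None or len(mism) < len(best.mismatches):
            best = _Placement(s, mism)
    return best


def _gapped_rescue(primer: str, template: str, policy: ClassifyPolicy) -> bool:
    """Can a single template/primer gap explain the primer far better?

    Splits the primer at every point and allows a gap of 1..max_gap between
    the two ungapped halves; returns True when some split aligns with at
    most one residual mismatch.
    """
    m = len(primer)
    n = len(template)
    for split in range(4, m - 4):
        left, right = primer[:split], primer[split:]
        for s in range(0, n - m + 1):
            left_mism = sum(
                0 if bases_match(left[i], template[s + i]) else 1 for i in range(split)
            )
            if left_mism > 1:
                continue
            for gap in range(-policy.max_gap, policy.max_gap + 1):
                if gap == 0:
                    continue
                t0 = s + split + gap
                if t0 < 0 or t0 + len(right) > n:
                    continue
                right_mism = sum(
                    0 if bases_match(right[i], template[t0 + i]) else 1
                    for i in range(len(right))
                )
                if left_mism + right_mism <= 1:
                    return True
    return False


def _clustered(mismatches: Sequence[int], run: int = 6) -> bool:
    """Are the mismatches concentrated (several within a short run)?"""
    if len(mismatches) < 2:
        return False
    ms = sorted(mismatches)
    for i in range(len(ms) - 1):
        if ms[i + 1] - ms[i] < run:
            return True
    return False


def classify_assay(
    primer: str,
    enzyme: RestrictionEnzyme,
    allele1: str,
    allele2: str,
    policy: ClassifyPolicy | None = None,
    *,
    amplicon_len: int | None = None,
) -> AssayVerdict:
    """Classify an assay as productive, problematic or non-productive.

    The primer is located on each allele by ungapped sliding (the placement
    with fewest degeneracy-aware mismatches); amplicons are simulated by
    substituting the primer at its footprint and keeping the template
    downstream.  Raises :class:`PrimerNotLocatable` when the primer cannot
    be placed on either allele within the policy's mismatch allowance and
    no gapped placement exists either.
    """
    policy = policy or ClassifyPolicy()
    primer = normalize(primer)
    s1 = normalize(allele1)
    s2 = normalize(allele2)

    reasons: list[str] = []
    placements = []
    for tpl in (s1, s2):
        best = _best_ungapped(primer, tpl)
        if best is None:
            raise PrimerNotLocatable("template shorter than primer")
        placements.append(best)

    gap_tag = False
    for tpl, best in zip((s1, s2), placements):
        nm = len(best.mismatches)
        if nm > policy.gap_trigger and _clustered(best.mismatches):
            if _gapped_rescue(primer, tpl, policy):
                gap_tag = True
                continue
        if nm > policy.max_scan_mismatches:
            raise PrimerNotLocatable(
                f"best ungapped placement has {nm} mismatches "
                f"(> {policy.max_scan_mismatches}) and no gapped placement"
            )
    if gap_tag:
        reasons.append("alignment_gap")

    # amplification defects ------------------------------------------------
    for tpl, best in zip((s1, s2), placements):
        term = best.start + len(primer) - 1
        if not bases_match(primer[-1], tpl[term]):
            pair = {primer[-1], tpl[term]}
            if not (policy.allow_3prime_GT and pair == {"G", "T"}):
                if "terminal_3prime_mismatch" not in reasons:
                    reasons.append("terminal_3prime_mismatch")
        if len(best.mismatches) > policy.max_scan_mismatches:
            if "excessive_mismatches" not in reasons:
                reasons.append("excessive_mismatches")

    # diagnostic digest ----------------------------------------------------
    amps = []
    for tpl, best in zip((s1, s2), placements):
        amp = primer + tpl[best.start + len(primer) :]
        if amplicon_len is not None:
            amp = amp[:amplicon_len]
        amps.append(amp)

    frags = []
    cuts = []
    for amp in amps:
        if enzyme.has_cut_offsets:
            c = cut_positions(amp, enzyme)
        else:
            c = [s for s, _ in find_exact_sites(amp, enzyme)]
        cuts.append(c)
        bounds = [0] + [x for x in c] + [len(amp)]
        frags.append(tuple(b - a for a, b in zip(bounds, bounds[1:])))

    cut1, cut2 = bool(cuts[0]), bool(cuts[1])
    if cut1 != cut2:
        diagnostic = True
    elif cut1 and cut2:
        # both cut: distinguishable only if some band differs resolvably
        f1 = sorted(frags[0])
        f2 = sorted(frags[1])
        if f1 == f2:
            diagnostic = False
            reasons.append("indistinguishable_fragments")
        else:
            diffs = set(f1).symmetric_difference(f2)
            if any(
                min(abs(a - b) for b in (f2 if a in f1 else f1)) >= policy.band_diff
                for a in diffs
            ):
                diagnostic = True
            else:
                diagnostic = False
                reasons.append("indistinguishable_fragments")
    else:
        diagnostic = False
        reasons.append("no_diagnostic_site")

    if not diagnostic:
        category = "non_productive"
    elif any(
        r in ("terminal_3prime_mismatch", "alignment_gap", "excessive_mismatches")
        for r in reasons
    ):
        category = "problematic"
    else:
        category = "productive"
    return AssayVerdict(
        category=category,
        reasons=tuple(reasons),
        fragments1=frags[0],
        fragments2=frags[1],
    )
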