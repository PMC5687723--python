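"""End-to-end pipelines: compare -> scan -> reject -> design -> report.

These functions are what the CLI calls; they are equally usable from
Python.  Both run the full analysis on the inputs as supplied and on their
reverse complements, and both are fully deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

from .compare import find_shared_regions
from .enzymes import RestrictionEnzyme, default_catalogue, filter_enzymes
from .primers import DesignError, PrimerDesign, PrimerOptions, design_primer
from .reports import SCHEMA_VERSION
from .scan import (
    DEFAULT_AMPLICON_LEN,
    UnknownCutOffset,
    predict_fragments,
    reject_downstream_cutters,
    scan_assays,
)
from .screen import DEFAULT_PROFILE, EditProfile, ScreeningResult, screen_assays
from .thermo import TmParameters

__all__ = ["RunConfig", "run_known", "run_screen"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a run, with the documented defaults."""

    max_mismatch: int = 1
    amplicon_len: int = DEFAULT_AMPLICON_LEN
    primer_mode: str = "target_tm"  # target_tm | fixed_length
    primer_length: int = 25
    target_tm: float = 60.0
    allow_3prime_GT: bool = False
    loss_threshold: float = 0.0
    primer_conc: float = 50e-9
    na_conc: float = 50e-3
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()
    report_all: bool = False  # all feasible primers, not just best-per-assay

    def primer_options(self, catalogue: Sequence[RestrictionEnzyme]) -> PrimerOptions:
        return PrimerOptions(
            max_mismatch=self.max_mismatch,
            allow_3prime_GT=self.allow_3prime_GT,
            mode=self.primer_mode,
            length=self.primer_length,
            target_tm=self.target_tm,
            tm_params=TmParameters(primer_conc=self.primer_conc, na_conc=self.na_conc),
            catalogue=tuple(catalogue),
        )

    def echo(self) -> dict:
        d = asdict(self)
        d["primer_conc_nM"] = round(self.primer_conc * 1e9, 6)
        d["na_conc_mM"] = round(self.na_conc * 1e3, 6)
        del d["primer_conc"], d["na_conc"]
        return d


def _fragments_or_none(amplicon: str, enzyme: RestrictionEnzyme):
    try:
        return predict_fragments(amplicon, enzyme)
    except (UnknownCutOffset, ValueError):
        return None


def _cut_realizable(design: PrimerDesign, cand, amplicon_len: int) -> bool:
    """Does the diagnostic digest actually produce >= 2 fragments?"""
    if not cand.enzyme.has_cut_offsets:
        return True  # presence/absence call only; nothing to verify
    alleles = (1, 2) if cand.cleaved_allele == "both_differently" else (cand.cleaved_allele,)
    for allele in alleles:
        frags = _fragments_or_none(design.amplicon(allele, amplicon_len), cand.enzyme)
        if frags is not None and len(frags) < 2:
            return False
    return True


def _known_row(design: PrimerDesign, cfg: RunConfig) -> dict:
    assay = design.assay
    cmp = assay.comparison
    row = {
        "enzyme": assay.enzyme.name,
        "motif": assay.enzyme.motif,
        "orientation": assay.orientation,
        "cleaved_allele": str(assay.cleaved_allele),
        "is_caps": assay.is_caps,
        "mismatch_count": design.mismatch_count,
        "primer": design.sequence,
        "primer_length": design.length,
        "mismatch_positions": [i + 1 for i in design.mismatch_positions],
        "tm_celsius": round(design.tm_celsius, 2),
        "motif_start": assay.motif_start + 1,
        "amplicon_len": min(cfg.amplicon_len, len(design.amplicon(1))),
        "warnings": list(assay.warnings + design.warnings),
    }
    for allele in (1, 2):
        amp = design.amplicon(allele, cfg.amplicon_len)
        frags = _fragments_or_none(amp, assay.enzyme)
        row[f"fragments_allele{allele}"] = frags if frags else ["presence/absence only"]
    return row


def run_known(
    seq1: str,
    seq2: str,
    cfg: RunConfig | None = None,
    enzymes: Sequence[RestrictionEnzyme] | None = None,
) -> tuple[dict, list[PrimerDesign]]:
    """Known-allele mode: design assays that tell two sequences apart.

    No assumption is made about which sequence is wild type; the report
    says which allele each assay cleaves.  Returns ``(report, designs)``.
    """
    cfg = cfg or RunConfig()
    catalogue = list(enzymes) if enzymes is not None else default_catalogue()
    catalogue = filter_enzymes(catalogue, cfg.include or None, cfg.exclude or None)

    cmp = find_shared_regions(seq1, seq2)
    candidates = scan_assays(cmp, catalogue, cfg.max_mismatch)
    candidates = reject_downstream_cutters(candidates, cfg.amplicon_len)

    opts = cfg.primer_options(catalogue)
    designs: list[PrimerDesign] = []
    dropped: list[str] = []
    for cand in candidates:
        try:
            design = design_primer(cand, opts)
        except DesignError as exc:
            dropped.append(f"{cand.enzyme.name}@{cand.motif_start + 1}: {exc}")
            continue
        # offset cutters can place their cleavage point past the end of
        # the obtainable amplicon; such an assay never actually cuts
        if not _cut_realizable(design, cand, cfg.amplicon_len):
            dropped.append(
                f"{cand.enzyme.name}@{cand.motif_start + 1}: cleavage position "
                "falls outside the amplicon"
            )
            continue
        designs.append(design)
    if not cfg.report_all:
        # best (first) design per enzyme+orientation; candidates are already
        # sorted by mismatch count then name/position
        best: dict[tuple, PrimerDesign] = {}
        for d in designs:
            key = (d.assay.enzyme.name, d.assay.orientation, str(d.assay.cleaved_allele))
            best.setdefault(key, d)
        designs = list(best.values())

    report = {
        "schema_version": SCHEMA_VERSION,
        "mode": "known",
        "config": cfg.echo(),
        "warnings": list(cmp.warnings) + dropped,
        "results": [_known_row(d, cfg) for d in designs],
    }
    return report, designs


def _screen_row(res: ScreeningResult, cfg: RunConfig) -> dict:
    design = res.primer
    assay = res.assay
    wt_amp = design.amplicon(1, cfg.amplicon_len)
    frags = _fragments_or_none(wt_amp, assay.enzyme)
    return {
        "enzyme": assay.enzyme.name,
        "motif": assay.enzyme.motif,
        "orientation": assay.orientation,
        "is_caps": assay.is_caps,
        "mismatch_count": design.mismatch_count,
        "primer": design.sequence,
        "primer_length": design.length,
        "mismatch_positions": [i + 1 for i in design.mismatch_positions],
        "tm_celsius": round(design.tm_celsius, 2),
        "motif_start": assay.motif_start + 1,
        "loss_fraction": res.loss_fraction,
        "per_event_calls": [f"{ev}:{call}" for ev, call in res.per_event_calls],
        "fragments_wildtype": frags if frags else ["presence/absence only"],
        "warnings": list(assay.warnings + design.warnings + res.warnings),
    }


def run_screen(
    wt: str,
    protospacer: str,
    cfg: RunConfig | None = None,
    enzymes: Sequence[RestrictionEnzyme] | None = None,
    profile: EditProfile = DEFAULT_PROFILE,
) -> tuple[dict, list[ScreeningResult]]:
    """Screening mode: assays cleaving wild type but not simulated edits."""
    cfg = cfg or RunConfig()
    catalogue = list(enzymes) if enzymes is not None else default_catalogue()
    catalogue = filter_enzymes(catalogue, cfg.include or None, cfg.exclude or None)

    results = screen_assays(
        wt,
        protospacer,
        catalogue,
        profile=profile,
        max_mismatch=cfg.max_mismatch,
        loss_threshold=cfg.loss_threshold,
        amplicon_len=cfg.amplicon_len,
        primer_options=cfg.primer_options(catalogue),
    )
    report = {
        "schema_version": SCHEMA_VERSION,
        "mode": "screen",
        "config": cfg.echo(),
        "warnings": [],
        "results": [_screen_row(r, cfg) for r in results],
    }
    return report, results
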