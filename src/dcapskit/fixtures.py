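"""Deterministic synthetic fixture generation for tests and demos.

All fixtures are generated from a seed (numpy PCG64) and are byte-identical
across runs.  Each fixture carries a ground-truth sidecar describing what
was planted, so a test can check the pipeline recovers it.  These emulate
clean Sanger-confirmed allele sequences: no sequencing noise, one variant
per pair.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .alphabet import reverse_complement

__all__ = ["generate_fixtures", "random_sequence", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("snp_pair", "indel_pair", "crispr_locus", "planted_assay")

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _avoid_motif(rng: np.random.Generator, length: int, motifs: tuple[str, ...]) -> str:
    # rejection sampling; motifs are rare enough that this converges fast
    for _ in range(200):
        s = random_sequence(rng, length)
        if not any(m in s or reverse_complement(m) in s for m in motifs):
            return s
    raise RuntimeError("could not sample a motif-free sequence")


def _snp_pair(rng: np.random.Generator, length: int = 60) -> dict[str, Any]:
    s1 = random_sequence(rng, length)
    pos = int(rng.integers(20, length - 20))
    alt = rng.choice([b for b in "ACGT" if b != s1[pos]])
    s2 = s1[:pos] + str(alt) + s1[pos + 1 :]
    return {
        "records": [("allele1", s1), ("allele2", s2)],
        "truth": {"kind": "snp", "position": pos, "ref": s1[pos], "alt": str(alt)},
    }


def _indel_pair(rng: np.random.Generator, length: int = 60, k: int | None = None) -> dict[str, Any]:
    s1 = random_sequence(rng, length)
    if k is None:
        k = int(rng.integers(1, 4))
    pos = int(rng.integers(20, length - 20 - k))
    s2 = s1[:pos] + s1[pos + k :]
    return {
        "records": [("allele1", s1), ("allele2", s2)],
        "truth": {"kind": "deletion", "position": pos, "length": k, "deleted": s1[pos : pos + k]},
    }


def _crispr_locus(rng: np.random.Generator, length: int = 120) -> dict[str, Any]:
    for _ in range(200):
        wt = random_sequence(rng, length)
        q = int(rng.integers(25, length - 45))
        protospacer = wt[q : q + 20]
        hits = wt.count(protospacer) + wt.count(reverse_complement(protospacer))
        if hits == 1:
            return {
                "records": [("wildtype", wt)],
                "truth": {
                    "kind": "crispr_locus",
                    "protospacer": protospacer,
                    "protospacer_start": q,
                    "cut_bond": q + 17,
                },
            }
    raise RuntimeError("could not sample a unique protospacer")


def _planted_assay(rng: np.random.Generator, length: int = 60) -> dict[str, Any]:
    """Plant a 1-mismatch EcoRI dCAPS opportunity at a SNP.

    Both alleles carry ``GACTTC`` ending at the SNP position; allele 1
    keeps the reference base so that patching the C at motif offset 2 to A
    completes ``GAATTC`` on allele 1 only.
    """
    motif = "GAATTC"
    near = "GACTTC"
    s = _avoid_motif(rng, length, (motif, near))
    pos = int(rng.integers(25, length - 20))  # SNP position = last motif base
    start = pos - 5
    s1 = s[:start] + near + s[pos + 1 :]
    alt = rng.choice([b for b in "ACGT" if b != "C"])
    s2 = s1[:pos] + str(alt) + s1[pos + 1 :]
    if motif in s2 or reverse_complement(motif) in s2:  # pragma: no cover
        return _planted_assay(rng, length)
    return {
        "records": [("allele1", s1), ("allele2", s2)],
        "truth": {
            "kind": "planted_assay",
            "enzyme": "EcoRI",
            "mismatch_count": 1,
            "cleaved_allele": 1,
            "motif_start": start,
            "snp_position": pos,
        },
    }


_MAKERS = {
    "snp_pair": _snp_pair,
    "indel_pair": _indel_pair,
    "crispr_locus": _crispr_locus,
    "planted_assay": _planted_assay,
}


def generate_fixtures(
    seed: int, n: int, kind: str, outdir: str | Path | None = None
) -> list[dict[str, Any]]:
    """Generate ``n`` fixtures of ``kind``; optionally write FASTA + JSON.

    Written files are ``<kind>_<i>.fasta`` with a ``<kind>_<i>.json``
    ground-truth sidecar.
    """
    if kind not in _MAKERS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    fixtures = []
    for i in range(n):
        fx = _MAKERS[kind](rng)
        fx["name"] = f"{kind}_{i}"
        fixtures.append(fx)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fx in fixtures:
            fasta = "".join(f">{rid}\n{seq}\n" for rid, seq in fx["records"])
            (outdir / f"{fx['name']}.fasta").write_text(fasta)
            (outdir / f"{fx['name']}.json").write_text(
                json.dumps(fx["truth"], indent=2, sort_keys=True) + "\n"
            )
    return fixtures
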