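"""Independent brute-force oracles used by the test suite.

Everything here is written from the rules themselves with plain loops and
its own IUPAC table, deliberately not importing the package's scanning or
screening internals, so that agreement between the two routes is evidence
rather than tautology.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def match(a: str, b: str) -> bool:
    return any(x in IUPAC[b] for x in IUPAC[a])


def exact_at(motif: str, seq: str, s: int) -> bool:
    if s < 0 or s + len(motif) > len(seq):
        return False
    return all(match(motif[i], seq[s + i]) for i in range(len(motif)))


def motif_forms(enzyme) -> list[str]:
    forms = [enzyme.motif]
    r = rc(enzyme.motif)
    if r != enzyme.motif:
        forms.append(r)
    return forms


def decompose(s1: str, s2: str) -> tuple[int, str, str]:
    """(prefix_len, unshared1, unshared2): max prefix, then max suffix."""
    p = 0
    while p < min(len(s1), len(s2)) and match(s1[p], s2[p]):
        p += 1
    r1, r2 = s1[p:], s2[p:]
    k = 0
    while k < min(len(r1), len(r2)) and match(r1[-1 - k], r2[-1 - k]):
        k += 1
    return p, r1[: len(r1) - k], r2[: len(r2) - k]


def patch_bases(motif: str, seq: str, s: int) -> dict[int, str]:
    out = {}
    for i, sym in enumerate(motif):
        if not match(sym, seq[s + i]):
            out[s + i] = min(IUPAC[sym])
    return out


def apply_patches(seq: str, patches: dict[int, str]) -> str:
    chars = list(seq)
    for pos, base in patches.items():
        chars[pos] = base
    return "".join(chars)


def scan_oracle(seq1: str, seq2: str, enzymes, max_mismatch: int) -> set[tuple]:
    """All candidate keys (name, motif_start, orientation, cleaved, d)."""
    found: set[tuple] = set()
    for orientation, (a1, a2) in (
        ("forward", (seq1, seq2)),
        ("reverse_complement", (rc(seq1), rc(seq2))),
    ):
        p, u1, u2 = decompose(a1, a2)
        for allele, (sa, sb, ua, ub) in (
            (1, (a1, a2, len(u1), len(u2))),
            (2, (a2, a1, len(u2), len(u1))),
        ):
            for e in enzymes:
                if e.is_nicking or e.is_double_cutter:
                    continue
                for motif in motif_forms(e):
                    m = len(motif)
                    for s in range(0, len(sa) - m + 1):
                        if ua > 0:
                            covers = s < p + ua and s + m > p
                        else:
                            covers = s < p and s + m > p
                        if not covers:
                            continue
                        mism = [
                            s + i
                            for i in range(m)
                            if not match(motif[i], sa[s + i])
                        ]
                        if len(mism) > max_mismatch:
                            continue
                        if any(pos >= p for pos in mism):
                            continue
                        inside_unsh = max(0, min(s + m, p + ua) - max(s, p))
                        if len(mism) > 0 and (m - inside_unsh) < 1:
                            continue
                        patched_b = apply_patches(sb, patch_bases(motif, sa, s))
                        hit_b = False
                        for form in motif_forms(e):
                            mf = len(form)
                            for t in range(0, len(patched_b) - mf + 1):
                                if ub > 0:
                                    c = t < p + ub and t + mf > p
                                else:
                                    c = t < p and t + mf > p
                                if c and exact_at(form, patched_b, t):
                                    hit_b = True
                        if not hit_b:
                            found.add((e.name, s, orientation, allele, len(mism)))
                        elif (
                            len(mism) == 0
                            and allele == 1
                            and e.cut_top is not None
                            and abs(ua - ub) >= 5
                        ):
                            found.add((e.name, s, orientation, "both_differently", 0))
    return found


def loss_oracle(
    oriented_wt: str,
    oriented_variants: list[tuple[float, str]],
    enzyme,
    motif_start: int,
    patches: dict[int, str],
    amplicon_len: int,
) -> float:
    """Weighted fraction of events whose patched amplicon is still cut.

    Mirrors the documented convention: an event is missed when the edited,
    primer-patched sequence carries an exact site anywhere from one motif
    length 5' of the diagnostic placement to the end of the amplicon
    window.
    """
    lcp = len(oriented_wt)
    for _, v in oriented_variants:
        i = 0
        while i < min(lcp, len(v)) and oriented_wt[i] == v[i]:
            i += 1
        lcp = min(lcp, i)
    lsb = lcp - 1
    m = len(enzyme.motif)
    loss = 0.0
    for weight, var in oriented_variants:
        vp = apply_patches(var, patches)
        shift = max(0, len(var) - len(oriented_wt))
        lo = max(0, motif_start - m)
        hi = lsb + amplicon_len + shift
        cut = False
        for form in motif_forms(enzyme):
            for t in range(lo, min(hi, len(vp)) - len(form) + 1):
                if exact_at(form, vp, t):
                    cut = True
        if cut:
            loss += weight
    return round(loss, 12)
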