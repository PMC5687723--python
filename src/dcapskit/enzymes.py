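"""Restriction-enzyme catalogue: loading, validation, filtering, writing.

The scanner iterates over a catalogue of recognition motifs.  A static
snapshot of commercially supplied single-cut (Type IIP, plus a few
offset-cutting Type IIS) enzymes ships with the package as a TSV file;
users can substitute their own file in the same dialect.

TSV dialect (tab-separated, ``#`` comment lines ignored)::

    name<TAB>site<TAB>[extra]

* A ``^`` inside ``site`` marks the top-strand cut offset; the bottom-strand
  offset defaults to the palindromic mirror (``len(site) - cut_top``) and is
  given explicitly in the third column when it differs.
* A site without ``^`` and with ``extra`` of the form ``top/bottom`` is an
  offset cutter cleaving outside its recognition site (e.g. ``BsaI
  GGTCTC 7/11``).
* A site without ``^`` and no third column has unknown cut offsets: the
  enzyme is usable for presence/absence calls only and is flagged in
  reports.
* ``extra`` equal to ``nick`` or ``double`` flags nicking respectively
  double-cutting enzymes; these are excluded from all scans.

Enzymes with motifs shorter than 4 nt are rejected: such sites cut too
frequently to give a diagnostic digest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .alphabet import IUPAC_LETTERS, reverse_complement

__all__ = [
    "RestrictionEnzyme",
    "MalformedEnzymeRecord",
    "UnknownEnzymeNameWarning",
    "load_enzymes",
    "write_enzyme_table",
    "filter_enzymes",
    "default_catalogue",
]

_HEADER = (
    "# dcapskit restriction enzyme catalogue\n"
    "# dialect: name<TAB>site-with-^-top-cut<TAB>[bottom-cut | top/bottom | nick | double]\n"
)

MIN_MOTIF_LEN = 4


class MalformedEnzymeRecord(ValueError):
    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class UnknownEnzymeNameWarning(UserWarning):
    pass


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition motif with cut offsets.

    ``cut_top``/``cut_bottom`` are signed offsets of top/bottom strand
    cleavage relative to the motif start (may lie outside the motif for
    offset cutters); ``None`` when unknown.
    """

    name: str
    motif: str
    cut_top: int | None
    cut_bottom: int | None
    is_nicking: bool = False
    is_double_cutter: bool = False

    @property
    def is_palindromic(self) -> bool:
        return self.motif == reverse_complement(self.motif)

    @property
    def has_cut_offsets(self) -> bool:
        return self.cut_top is not None and self.cut_bottom is not None

    @property
    def is_excluded(self) -> bool:
        """Excluded from every scan (nicking or double-cutting)."""
        return self.is_nicking or self.is_double_cutter

    def __len__(self) -> int:
        return len(self.motif)


def _validate_motif(site: str, line_no: int) -> None:
    if len(site) < MIN_MOTIF_LEN:
        raise MalformedEnzymeRecord(line_no, f"motif {site!r} shorter than {MIN_MOTIF_LEN} nt")
    bad = [ch for ch in site if ch not in IUPAC_LETTERS]
    if bad:
        raise MalformedEnzymeRecord(line_no, f"non-IUPAC character {bad[0]!r} in motif {site!r}")


def _parse_record(fields: Sequence[str], line_no: int) -> RestrictionEnzyme:
    if len(fields) < 2:
        raise MalformedEnzymeRecord(line_no, "expected at least name<TAB>site")
    name = fields[0].strip()
    raw_site = fields[1].strip().upper()
    extra = fields[2].strip() if len(fields) > 2 else ""
    if not name:
        raise MalformedEnzymeRecord(line_no, "empty enzyme name")
    if raw_site.count("^") > 1:
        raise MalformedEnzymeRecord(line_no, "more than one '^' in site")

    if extra == "nick":
        site = raw_site.replace("^", "")
        _validate_motif(site, line_no)
        return RestrictionEnzyme(name, site, None, None, is_nicking=True)
    if extra == "double":
        site = raw_site.replace("^", "")
        _validate_motif(site, line_no)
        return RestrictionEnzyme(name, site, None, None, is_double_cutter=True)

    if "^" in raw_site:
        cut_top = raw_site.index("^")
        site = raw_site.replace("^", "")
        _validate_motif(site, line_no)
        if extra:
            try:
                cut_bottom = int(extra)
            except ValueError:
                raise MalformedEnzymeRecord(line_no, f"bad bottom-cut offset {extra!r}")
        else:
            cut_bottom = len(site) - cut_top
        return RestrictionEnzyme(name, site, cut_top, cut_bottom)

    site = raw_site
    _validate_motif(site, line_no)
    if extra:
        try:
            top_s, bottom_s = extra.split("/")
            return RestrictionEnzyme(name, site, int(top_s), int(bottom_s))
        except ValueError:
            raise MalformedEnzymeRecord(line_no, f"bad cut-offset field {extra!r}")
    return RestrictionEnzyme(name, site, None, None)


def _format_record(e: RestrictionEnzyme) -> str:
    if e.is_nicking:
        return f"{e.name}\t{e.motif}\tnick"
    if e.is_double_cutter:
        return f"{e.name}\t{e.motif}\tdouble"
    if not e.has_cut_offsets:
        return f"{e.name}\t{e.motif}"
    if 0 <= e.cut_top <= len(e.motif):
        site = e.motif[: e.cut_top] + "^" + e.motif[e.cut_top :]
        if e.cut_bottom == len(e.motif) - e.cut_top:
            return f"{e.name}\t{site}"
        return f"{e.name}\t{site}\t{e.cut_bottom}"
    return f"{e.name}\t{e.motif}\t{e.cut_top}/{e.cut_bottom}"


def load_enzymes(
    source: str | Path | Iterable[str] | None = None,
    *,
    keep_flagged: bool = False,
) -> list[RestrictionEnzyme]:
    """Load an enzyme catalogue.

    ``source`` may be a path to a TSV file in the documented dialect, an
    iterable of lines, or ``None`` for the packaged snapshot.  Nicking and
    double-cutting enzymes are filtered out unless ``keep_flagged`` is set
    (they are never eligible for scans either way).  Records sort stably by
    name.
    """
    if source is None:
        text = resources.files("dcapskit.data").joinpath("enzymes.tsv").read_text()
        lines: Iterable[str] = text.splitlines()
    elif isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = source

    records: list[RestrictionEnzyme] = []
    for line_no, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        records.append(_parse_record(stripped.split("\t"), line_no))
    records.sort(key=lambda e: e.name)
    if not keep_flagged:
        records = [e for e in records if not e.is_excluded]
    return records


def write_enzyme_table(enzymes: Iterable[RestrictionEnzyme]) -> str:
    """Serialize enzymes to the canonical TSV dialect (stable name order)."""
    body = "\n".join(_format_record(e) for e in sorted(enzymes, key=lambda e: e.name))
    return _HEADER + body + "\n"


def filter_enzymes(
    enzymes: Sequence[RestrictionEnzyme],
    include: Sequence[str] | None = None,
    exclude: Sequence[str] | None = None,
) -> list[RestrictionEnzyme]:
    """Restrict a catalogue by name.

    ``include`` (case-insensitive) wins over the default set: when given,
    exactly the named enzymes are returned.  ``exclude`` removes names.
    Unresolvable names emit :class:`UnknownEnzymeNameWarning` rather than
    failing, so a shared config file can mention enzymes absent from a
    trimmed catalogue.
    """
    by_lower = {e.name.lower(): e for e in enzymes}
    if include is not None:
        out = []
        for name in include:
            e = by_lower.get(name.lower())
            if e is None:
                warnings.warn(f"unknown enzyme name {name!r}", UnknownEnzymeNameWarning)
            else:
                out.append(e)
        out.sort(key=lambda e: e.name)
        result = out
    else:
        result = list(enzymes)
    if exclude:
        known = {e.name.lower() for e in enzymes}
        drop = set()
        for name in exclude:
            if name.lower() not in known:
                warnings.warn(f"unknown enzyme name {name!r}", UnknownEnzymeNameWarning)
            drop.add(name.lower())
        result = [e for e in result if e.name.lower() not in drop]
    return result


def default_catalogue() -> list[RestrictionEnzyme]:
    """The packaged snapshot with flagged enzymes removed."""
    return load_enzymes(None)
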