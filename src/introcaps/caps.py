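"""In-silico PCR and restriction (CAPS) marker analysis.

A CAPS (Cleaved Amplified Polymorphic Sequence) marker distinguishes two
alleles of a locus by a restriction site that is present in one allele and
destroyed in the other by a polymorphism.  This module locates primer
binding sites with a mismatch budget and a strict 3' anchor, extracts
amplicons, scans IUPAC-degenerate recognition patterns on both strands,
predicts linear digest fragments, and searches an enzyme table for enzymes
whose fragment patterns discriminate two alleles.

All template coordinates are 1-based closed; cut positions are expressed as
the number of bases left of the cut (so a cut at position ``c`` splits a
sequence into ``seq[:c]`` and ``seq[c:]``).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, supporting IUPAC degeneracy codes."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for code in pattern.upper():
        bases = IUPAC_CODES.get(code)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        parts.append(next(iter(bases)) if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: recognition pattern and cut offset.

    ``cut_offset`` counts bases from the 5' end of the pattern to the cut on
    the strand being scanned (RsaI GT^AC has pattern ``GTAC``, offset 2).
    """

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        for code in self.pattern.upper():
            if code not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {code!r} in pattern for {self.name}")
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError(f"cut offset {self.cut_offset} outside pattern for {self.name}")


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers (both written 5'->3')."""

    forward: str
    reverse: str
    max_mismatch: int = 2
    anchor: int = 3

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if len(seq) < 15:
                raise ValueError("primers must be at least 15 nt")
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"primer {seq!r} contains non-ACGT characters")
        if self.anchor > min(len(self.forward), len(self.reverse)):
            raise ValueError("3' anchor longer than primer")


@dataclass(frozen=True)
class BindingSite:
    position: int  # 1-based start of the footprint on the plus strand
    strand: str    # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int  # 1-based closed, on the template plus strand
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("amplicon sequence length does not match coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    enzyme: str
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]


@dataclass(frozen=True)
class CapsMarker:
    """An enzyme whose predicted fragment pattern differs between two alleles."""

    enzyme: EnzymeSpec
    amplicon_a: Amplicon
    amplicon_b: Amplicon
    fragments_a: tuple[int, ...]
    fragments_b: tuple[int, ...]

    def faint_fragments(self, floor: int = 20) -> tuple[int, ...]:
        """Fragments below the gel-resolution floor, likely invisible on agarose."""
        return tuple(f for f in self.fragments_a + self.fragments_b if f < floor)


def find_binding_sites(template: str, primer: str, max_mismatch: int = 2,
                       anchor: int = 3) -> list[BindingSite]:
    """Locate primer binding sites on both strands of ``template``.

    A site qualifies when the total mismatch count is at most ``max_mismatch``
    and the ``anchor`` 3'-terminal bases of the primer match exactly (the
    polymerase extends from the 3' end, so mismatches there abort priming).
    """
    if anchor > len(primer):
        raise ValueError("anchor exceeds primer length")
    template = template.upper()
    primer = primer.upper()
    m = len(primer)
    sites: list[BindingSite] = []
    if m > len(template):
        return sites
    rc = revcomp(primer)
    for i in range(len(template) - m + 1):
        window = template[i:i + m]
        # plus strand: primer 3' end is the right end of the footprint
        if anchor == 0 or window[m - anchor:] == primer[m - anchor:]:
            mm = sum(a != b for a, b in zip(window, primer))
            if mm <= max_mismatch:
                sites.append(BindingSite(i + 1, "+", mm))
        # minus strand: primer anneals to the plus strand as its reverse
        # complement; the primer 3' end maps to the left end of the footprint
        if anchor == 0 or window[:anchor] == rc[:anchor]:
            mm = sum(a != b for a, b in zip(window, rc))
            if mm <= max_mismatch:
                sites.append(BindingSite(i + 1, "-", mm))
    return sites


def in_silico_pcr(template: str, pair: PrimerPair, max_product: int = 5000,
                  template_id: str = "template") -> list[Amplicon]:
    """Predict PCR products of a primer pair on a linear template.

    Every orientation-valid combination of a forward-primer plus-strand site
    and a reverse-primer minus-strand site with non-overlapping footprints and
    product length <= ``max_product`` yields one amplicon; zero or multiple
    products are reported as such, never collapsed.
    """
    if max_product <= len(pair.forward) + len(pair.reverse):
        raise ValueError("max_product must exceed the combined primer length")
    template = template.upper()
    fwd = [s for s in find_binding_sites(template, pair.forward, pair.max_mismatch, pair.anchor)
           if s.strand == "+"]
    rev = [s for s in find_binding_sites(template, pair.reverse, pair.max_mismatch, pair.anchor)
           if s.strand == "-"]
    products = []
    for f in fwd:
        for r in rev:
            start = f.position
            end = r.position + len(pair.reverse) - 1
            length = end - start + 1
            if length < len(pair.forward) + len(pair.reverse) or length > max_product:
                continue
            products.append(Amplicon(template_id, start, end, template[start - 1:end]))
    products.sort(key=lambda a: (a.start, a.end))
    return products


def scan_sites(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """Cut positions of ``enzyme`` in ``seq``, scanning both strands.

    Returns the sorted, deduplicated positions (bases left of each cut) on the
    given strand.  A palindromic pattern matches both strands at the same
    locus and is counted once.
    """
    seq = seq.upper()
    pat = enzyme.pattern.upper()
    plen = len(pat)
    cuts: set[int] = set()
    for m in _iupac_regex(pat).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset)
    # a minus-strand recognition at plus position i cuts the plus strand
    # cut_offset bases from the pattern's 3' (plus-strand right) end
    for m in _iupac_regex(revcomp(pat)).finditer(seq):
        cuts.add(m.start() + plen - enzyme.cut_offset)
    return sorted(cuts)


def digest(amplicon: Amplicon | str, enzyme: EnzymeSpec) -> DigestResult:
    """Linear digest: fragment lengths along the sequence, 5'->3'.

    With no recognition site the amplicon remains a single undigested
    fragment; each internal cut adds one fragment.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    n = len(seq)
    cuts = tuple(c for c in scan_sites(seq, enzyme) if 0 < c < n)
    bounds = (0, *cuts, n)
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(enzyme.name, cuts, fragments)


def find_discriminating_enzymes(amp_a: Amplicon, amp_b: Amplicon,
                                table: Iterable[EnzymeSpec]) -> list[CapsMarker]:
    """Enzymes whose fragment-length multiset differs between two alleles."""
    if not len(amp_a) or not len(amp_b):
        raise ValueError("amplicons must be non-empty")
    markers = []
    for enz in table:
        da = digest(amp_a, enz)
        db = digest(amp_b, enz)
        if Counter(da.fragment_lengths) != Counter(db.fragment_lengths):
            markers.append(CapsMarker(enz, amp_a, amp_b, da.fragment_lengths, db.fragment_lengths))
    return markers


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[int, float]:
    """Difference count and percent identity of two aligned sequences.

    Sequences must be equal length (an alignment); a column containing a gap
    character counts as a difference.  Percent identity is reported to two
    decimals: 100 x (L - differences) / L.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a, b = seq_a.upper(), seq_b.upper()
    diffs = sum(1 for x, y in zip(a, b) if x != y or x == "-" or y == "-")
    pct = round(100.0 * (len(a) - diffs) / len(a), 2)
    return diffs, pct


def load_enzyme_table(path: str | Path | None = None) -> list[EnzymeSpec]:
    """Load a TSV enzyme table (columns: name, pattern, cut_offset).

    With no path the small editable table shipped with the package is used.
    """
    if path is None:
        with resources.as_file(resources.files("introcaps").joinpath("data/enzymes.tsv")) as p:
            return load_enzyme_table(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    return [EnzymeSpec(str(r["name"]), str(r["pattern"]), int(r["cut_offset"]))
            for _, r in df.iterrows()]


def get_enzyme(name: str, table: Iterable[EnzymeSpec] | None = None) -> EnzymeSpec:
    for enz in (table if table is not None else load_enzyme_table()):
        if enz.name == name:
            return enz
    raise KeyError(f"enzyme {name!r} not in table")


def marker_report(markers: Sequence[CapsMarker], gel_floor: int = 20) -> pd.DataFrame:
    """Tabulate candidate CAPS markers (one row per enzyme)."""
    rows = []
    for mk in markers:
        rows.append({
            "enzyme": mk.enzyme.name,
            "pattern": mk.enzyme.pattern,
            "fragments_allele_a": ",".join(map(str, mk.fragments_a)),
            "fragments_allele_b": ",".join(map(str, mk.fragments_b)),
            "faint_fragments": ",".join(map(str, mk.faint_fragments(gel_floor))),
        })
    return pd.DataFrame(rows, columns=["enzyme", "pattern", "fragments_allele_a",
                                       "fragments_allele_b", "faint_fragments"])
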