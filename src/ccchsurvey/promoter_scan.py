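"""Promoter extraction and cis-element scanning on both strands.

Stress-responsive promoter analysis in plants typically scans a fixed
window upstream of the translation start (2,000 bp here by default) for
short regulatory cores.  The shipped lexicon carries the two classic
abiotic-stress elements — the ABA-responsive element (ABRE) core ``ACGTG``
and the dehydration-responsive element (DRE/CRT) core ``RCCGAC`` — as an
editable YAML file with per-entry source notes, since different databases
print slightly different cores.

Coordinates are 1-based, sense-strand, inclusive; position ``length + 1``
would be the A of the ATG.  Overlapping occurrences are all reported
(occurrences are counted per position), and ``N`` in a promoter never
matches, not even degenerate codes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def expand_iupac(code: str) -> str:
    """The set of concrete bases an IUPAC code stands for."""
    try:
        return IUPAC[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Element:
    name: str
    pattern: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"element {self.name!r} has an empty pattern")
        for ch in self.pattern:
            expand_iupac(ch)


class ElementLexicon(dict):
    """Mapping element name -> Element, loadable from a YAML file."""

    @classmethod
    def from_entries(cls, entries: dict[str, dict | str]) -> "ElementLexicon":
        lex = cls()
        for name, entry in entries.items():
            if isinstance(entry, str):
                lex[name] = Element(name, entry)
            else:
                lex[name] = Element(name, entry["pattern"], entry.get("note", ""))
        return lex

    @classmethod
    def from_yaml(cls, path) -> "ElementLexicon":
        with open(path) as fh:
            return cls.from_entries(yaml.safe_load(fh))


def default_lexicon() -> ElementLexicon:
    ref = resources.files("ccchsurvey") / "data" / "cis_elements.yaml"
    return ElementLexicon.from_entries(yaml.safe_load(ref.read_text()))


DEFAULT_LEXICON = None  # populated at import end (needs the data file)


@dataclass(frozen=True)
class CisElementHit:
    """One cis-element occurrence in a promoter.

    ``position`` is the 1-based sense-strand offset of the leftmost matched
    base; ``matched`` is the sense-strand subsequence (its reverse
    complement matches the pattern for ``-`` strand hits).
    """

    promoter_id: str
    element: str
    strand: str
    position: int
    matched: str


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead makes overlapping occurrences visible
    body = "".join(
        ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]" for ch in pattern
    )
    return re.compile(f"(?=({body}))")


def scan_elements(
    promoter: str,
    lexicon: ElementLexicon | None = None,
    promoter_id: str = "",
) -> list[CisElementHit]:
    """All occurrences of every lexicon pattern on both strands.

    Hits are sorted by position then element name then strand; overlaps are
    allowed.  The promoter may contain A/C/G/T/N; N matches nothing.
    """
    lexicon = lexicon if lexicon is not None else DEFAULT_LEXICON
    seq = promoter.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid promoter characters: {sorted(bad)}")
    L = len(seq)
    rc = reverse_complement(seq)
    hits: list[CisElementHit] = []
    for name, elem in lexicon.items():
        rx = _pattern_regex(elem.pattern)
        m = len(elem.pattern)
        for match in rx.finditer(seq):
            pos = match.start() + 1
            hits.append(CisElementHit(promoter_id, name, "+", pos, match.group(1)))
        for match in rx.finditer(rc):
            rc_pos = match.start() + 1
            pos = L - rc_pos - m + 2  # sense-strand offset of the match start
            hits.append(
                CisElementHit(promoter_id, name, "-", pos, seq[pos - 1 : pos - 1 + m])
            )
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def extract_promoter(
    chromosome: str,
    atg_position: int,
    strand: str = "+",
    length: int = 2000,
) -> str:
    """The ``length`` bases immediately 5' of a translation start.

    ``atg_position`` is the 1-based chromosome coordinate of the A of the
    ATG for ``+`` strand genes, or of the last base of the (reverse-strand)
    start codon for ``-`` strand genes — i.e. the gene's ``start``/``end``
    coordinate respectively.  Reverse-strand promoters are returned
    reverse-complemented so the ATG-proximal end is always on the right.
    Truncated with a warning at chromosome ends.
    """
    n = len(chromosome)
    if not (1 <= atg_position <= n):
        raise ValueError(f"ATG position {atg_position} outside chromosome (1..{n})")
    if strand == "+":
        lo = max(1, atg_position - length)
        region = chromosome[lo - 1 : atg_position - 1]
    elif strand == "-":
        hi = min(n, atg_position + length)
        region = reverse_complement(chromosome[atg_position:hi])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(region) < length:
        warnings.warn(
            f"promoter truncated to {len(region)} bp at a chromosome end",
            stacklevel=2,
        )
    return region


def element_counts(hits: list[CisElementHit]):
    """Per-promoter, per-element occurrence counts as a tidy DataFrame."""
    import pandas as pd

    rows = [(h.promoter_id, h.element, h.strand) for h in hits]
    df = pd.DataFrame(rows, columns=["promoter_id", "element", "strand"])
    if df.empty:
        return pd.DataFrame(columns=["promoter_id", "element", "count"])
    out = (
        df.groupby(["promoter_id", "element"]).size().reset_index(name="count")
    )
    return out


DEFAULT_LEXICON = default_lexicon()
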