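"""CCCH zinc-finger motif scanning and class summaries.

The CCCH zinc finger is a Cys-Cys-Cys-His metal-coordinating motif.  Plant
family surveys match it with the degenerate-spacer consensus

    C-X(a)-C-X(b)-C-X3-H        4 <= a <= 17, 4 <= b <= 6

where X is any amino acid and the spacer triple (a, b, 3) names a motif
class, e.g. ``C-X8-C-X5-C-X3-H``.  The classical plant consensus caps the
first spacer at 15; the default here admits 17 because a maize survey
recorded one genuine C-X17-C-X6-C-X3-H finger.  Bounds are configuration,
not constants.

A cysteine cluster can admit several (C, C, C, H) parses.  The scanner
enumerates every candidate quadruple within the bounds and greedily accepts
by (leftmost start, then smallest total span, then smallest first spacer,
then smallest second spacer), discarding candidates that overlap an accepted
hit.  This is deterministic and favors compact canonical motifs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")  # X: unknown residue


@dataclass(frozen=True)
class SpacerBounds:
    """Spacer-length bounds of the degenerate consensus C-Xa-C-Xb-C-Xc-H."""

    a_min: int = 4
    a_max: int = 17
    b_min: int = 4
    b_max: int = 6
    c: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.a_min <= self.a_max and 0 < self.b_min <= self.b_max):
            raise ValueError(f"inconsistent spacer bounds: {self}")
        if self.c < 0:
            raise ValueError("third spacer must be non-negative")


DEFAULT_BOUNDS = SpacerBounds()


@dataclass(frozen=True)
class MotifHit:
    """One located CCCH motif.

    Coordinates are 1-based residue indices: ``start`` is the first C,
    ``end`` the H.  ``spacers`` holds the inter-anchor gap lengths (a, b, c);
    ``end - start == a + b + c + 3``.
    """

    protein_id: str
    start: int
    end: int
    spacers: tuple[int, int, int]
    subsequence: str

    @property
    def signature(self) -> str:
        a, b, c = self.spacers
        return f"C-X{a}-C-X{b}-C-X{c}-H"

    def __post_init__(self) -> None:
        a, b, c = self.spacers
        if self.end - self.start != a + b + c + 3:
            raise ValueError(f"span/spacer mismatch in {self}")
        if len(self.subsequence) != self.end - self.start + 1:
            raise ValueError(f"subsequence length mismatch in {self}")


def classify(hit: MotifHit) -> str:
    """Render the class signature of a hit, e.g. ``C-X8-C-X5-C-X3-H``."""
    return hit.signature


def _validate_sequence(sequence: str) -> None:
    for i, ch in enumerate(sequence):
        if ch not in _VALID_RESIDUES:
            raise ValueError(
                f"illegal residue {ch!r} at position {i + 1}; expected one of "
                f"the 20 standard amino acids or X"
            )


def enumerate_candidates(
    sequence: str, bounds: SpacerBounds = DEFAULT_BOUNDS
) -> list[tuple[int, int, int, int]]:
    """All (C, C, C, H) index quadruples (0-based) satisfying the bounds.

    X never matches an anchor position.  Exposed for the exhaustive-oracle
    tests; `find_motifs` builds on the same enumeration.
    """
    c_pos = [i for i, ch in enumerate(sequence) if ch == "C"]
    h_set = {i for i, ch in enumerate(sequence) if ch == "H"}
    quads = []
    for i in c_pos:
        for j in c_pos:
            a = j - i - 1
            if a < bounds.a_min:
                continue
            if a > bounds.a_max:
                break
            for k in c_pos:
                b = k - j - 1
                if b < bounds.b_min:
                    continue
                if b > bounds.b_max:
                    break
                h = k + bounds.c + 1
                if h in h_set:
                    quads.append((i, j, k, h))
    return quads


def find_motifs(
    sequence: str,
    bounds: SpacerBounds = DEFAULT_BOUNDS,
    protein_id: str = "",
) -> list[MotifHit]:
    """Scan one protein sequence for CCCH motifs under the consensus bounds.

    Returns mutually non-overlapping hits sorted by start position, resolved
    by the greedy policy described in the module docstring.

    Raises
    ------
    ValueError
        If the sequence contains a character outside the 20 standard
        residues plus X.
    """
    _validate_sequence(sequence)
    candidates = []
    for i, j, k, h in enumerate_candidates(sequence, bounds):
        a, b = j - i - 1, k - j - 1
        candidates.append((i, h - i, a, b, h))
    candidates.sort()
    hits: list[MotifHit] = []
    occupied: set[int] = set()
    for i, span, a, b, h in candidates:
        if any(p in occupied for p in (i, h)) or not occupied.isdisjoint(
            range(i, h + 1)
        ):
            continue
        occupied.update(range(i, h + 1))
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=i + 1,
                end=h + 1,
                spacers=(a, b, bounds.c),
                subsequence=sequence[i : h + 1],
            )
        )
    hits.sort(key=lambda m: m.start)
    return hits


def scan_proteome(
    records: dict[str, str], bounds: SpacerBounds = DEFAULT_BOUNDS
) -> list[MotifHit]:
    """Scan every protein of a ``{id: sequence}`` mapping."""
    hits: list[MotifHit] = []
    for pid, seq in records.items():
        hits.extend(find_motifs(seq, bounds=bounds, protein_id=pid))
    return hits


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassTally:
    """Per-signature motif counts and percentages over a whole proteome."""

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    @property
    def percentages(self) -> dict[str, float]:
        """Percent of total per signature, one decimal, half-up rounding."""
        if self.total == 0:
            return {}
        return {
            sig: _round_half_up(100.0 * n / self.total, 1)
            for sig, n in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "signature": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [pct[s] for s in self.counts],
            }
        )


def tally_classes(hits: list[MotifHit]) -> ClassTally:
    """Count motif classes; percentages are 100*count/total to one decimal."""
    counter = Counter(h.signature for h in hits)
    # most common class first, ties by signature text
    ordered = dict(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
    return ClassTally(counts=ordered, total=sum(counter.values()))


def count_histogram(
    hits: list[MotifHit], protein_ids: list[str] | None = None
) -> tuple[dict[int, int], int]:
    """Histogram of motif-count -> number of proteins.

    Proteins with at least one hit populate the histogram; the second return
    value is the number of proteins (from ``protein_ids``) with zero hits.
    """
    per_protein = Counter(h.protein_id for h in hits)
    hist = Counter(per_protein.values())
    n_zero = 0
    if protein_ids is not None:
        n_zero = sum(1 for pid in protein_ids if pid not in per_protein)
    return dict(sorted(hist.items())), n_zero


@dataclass
class LogoProfile:
    """Position-frequency matrix with per-column information content.

    ``frequencies`` is positions x 20 amino acids, each row summing to 1
    (rows with no coverage are NaN); ``information_bits`` is
    R = log2(20) - H(column) with H the Shannon entropy in bits.
    ``anchor_columns`` marks the 0-based columns of the C/C/C/H anchors
    (for combined logos, the anchors shared by all member classes).
    """

    frequencies: pd.DataFrame
    information_bits: np.ndarray
    n_sequences: int
    anchor_columns: tuple[int, ...]


def build_logo(hits: list[MotifHit], combined: bool = False) -> LogoProfile:
    """Build a sequence-logo profile from motif hits.

    All hits must share one spacer signature unless ``combined`` is true, in
    which case signatures may differ only in the first spacer and the motifs
    are right-justified on the second C so the variable-length first spacer
    absorbs the offset (shorter motifs leave leading columns uncovered).
    """
    if not hits:
        raise ValueError("cannot build a logo from an empty hit set")
    sigs = {h.spacers for h in hits}
    if not combined and len(sigs) > 1:
        raise ValueError(f"mixed signatures {sigs}; pass combined=True")
    if combined and len({(b, c) for _, b, c in sigs}) > 1:
        raise ValueError("combined logos require identical b and c spacers")

    width = max(h.end - h.start + 1 for h in hits)
    counts = np.zeros((width, len(AMINO_ACIDS)), dtype=float)
    coverage = np.zeros(width, dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for h in hits:
        pad = width - (h.end - h.start + 1)  # right-justify on second C
        for off, ch in enumerate(h.subsequence):
            col = pad + off
            if ch == "X":
                continue
            counts[col, aa_index[ch]] += 1
            coverage[col] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / coverage[:, None]
    ent = np.zeros(width)
    for col in range(width):
        p = freq[col][freq[col] > 0]
        ent[col] = -(p * np.log2(p)).sum() if p.size else np.nan
    info = np.log2(len(AMINO_ACIDS)) - ent

    a_max = max(a for a, _, _ in sigs)
    _, b, c = next(iter(sigs))
    anchors = [1 + a_max, 1 + a_max + 1 + b, width - 1]  # C2, C3, H (0-based)
    if len(sigs) == 1:
        anchors.insert(0, 0)  # first C shared only in single-class logos
    return LogoProfile(
        frequencies=pd.DataFrame(freq, columns=list(AMINO_ACIDS)),
        information_bits=info,
        n_sequences=len(hits),
        anchor_columns=tuple(anchors),
    )


def save_logo_figure(profile: LogoProfile, path: str) -> None:
    """Render a simple information-scaled letter-height logo to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = profile.frequencies.to_numpy()
    width = freq.shape[0]
    fig, ax = plt.subplots(figsize=(max(4, width * 0.4), 2.5))
    for col in range(width):
        heights = freq[col] * (
            profile.information_bits[col]
            if math.isfinite(profile.information_bits[col])
            else 0.0
        )
        order = np.argsort(heights)
        y = 0.0
        for idx in order:
            if heights[idx] <= 0:
                continue
            ax.text(
                col + 0.5,
                y + heights[idx] / 2,
                AMINO_ACIDS[idx],
                ha="center",
                va="center",
                fontsize=8 + 10 * heights[idx] / math.log2(20),
            )
            y += heights[idx]
    ax.set_xlim(0, width)
    ax.set_ylim(0, math.log2(20))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
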