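"""Duplicate-pair classification, NG86 Ka/Ks, selection calls and dating.

Paralog pairs are classified *tandem* when they sit on one chromosome
separated by at most five intervening gene loci in annotation order, and
*segmental* when the two genes fall inside the two mates of a duplicated
chromosomal block (the block catalogue is an input; detecting blocks is out
of scope).  A pair qualifying as both is reported tandem — physically
clustered copies are tandem duplicates regardless of the block context they
sit in.

Ka and Ks are estimated with the Nei–Gojobori (1986) counting method:
per-codon synonymous/nonsynonymous site fractions averaged over both
sequences, substitution counts averaged with equal weight over all minimal
substitution pathways between differing codons (pathways crossing a stop
codon are excluded), and the Jukes–Cantor correction
d = -3/4 ln(1 - 4p/3) applied to both proportions.

Duplication dates follow the synonymous molecular clock T = Ks / (2λ),
reported in millions of years (Mya); the default rate λ = 6.5e-9
synonymous substitutions per site per year is the standard grass rate.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_AA_OF = dict(standard_dna_table.forward_table)
_NT = "ACGT"

GRASS_LAMBDA = 6.5e-9


@dataclass(frozen=True)
class EvolutionParams:
    """Clock parameters: lambda_rate in substitutions/synonymous site/year."""

    lambda_rate: float = GRASS_LAMBDA

    def __post_init__(self) -> None:
        if not self.lambda_rate > 0:
            raise ValueError("lambda must be positive")


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ka_sites: float  # nonsynonymous sites (N)
    ks_sites: float  # synonymous sites (S)

    @property
    def ratio(self) -> float | None:
        """Ka/Ks, or None when Ks = 0 (undefined)."""
        if self.ks == 0:
            return None
        return self.ka / self.ks

    @property
    def selection_call(self) -> str:
        return selection_call(self.ka, self.ks)


# ---------------------------------------------------------------------------
# tandem / segmental classification


def _locus_of(loci: pd.DataFrame, gene: str) -> pd.Series:
    rows = loci[loci["gene_id"] == gene]
    if rows.empty:
        raise KeyError(f"gene {gene!r} not found in locus table")
    return rows.iloc[0]


def classify_tandem(
    gene_a: str,
    gene_b: str,
    loci: pd.DataFrame,
    max_gap: int = 5,
    convention: str = "intervening",
) -> bool:
    """Tandem iff same chromosome and close in gene order.

    ``convention="intervening"`` (default): at most ``max_gap`` gene loci lie
    between the pair, i.e. |locus_index difference| - 1 <= max_gap.
    ``convention="index"``: |locus_index difference| <= max_gap.
    """
    a, b = _locus_of(loci, gene_a), _locus_of(loci, gene_b)
    if a["chromosome"] != b["chromosome"]:
        return False
    diff = abs(int(a["locus_index"]) - int(b["locus_index"]))
    if diff == 0:
        raise ValueError(f"{gene_a} and {gene_b} share a locus index")
    if convention == "intervening":
        return diff - 1 <= max_gap
    if convention == "index":
        return diff <= max_gap
    raise ValueError(f"unknown convention {convention!r}")


def classify_segmental(
    gene_a: str, gene_b: str, loci: pd.DataFrame, blocks: pd.DataFrame
) -> bool:
    """Segmental iff the genes fall inside the two mates of one block pairing.

    ``blocks`` columns: chr_a, start_a, end_a, chr_b, start_b, end_b.
    Either orientation of the pairing counts; block pairing is symmetric.
    """
    a, b = _locus_of(loci, gene_a), _locus_of(loci, gene_b)

    def inside(locus, chrom, lo, hi) -> bool:
        return (
            locus["chromosome"] == chrom
            and int(locus["start"]) >= int(lo)
            and int(locus["end"]) <= int(hi)
        )

    for blk in blocks.itertuples(index=False):
        mate_a = (blk.chr_a, blk.start_a, blk.end_a)
        mate_b = (blk.chr_b, blk.start_b, blk.end_b)
        if inside(a, *mate_a) and inside(b, *mate_b):
            return True
        if inside(a, *mate_b) and inside(b, *mate_a):
            return True
    return False


def classify_pair(
    gene_a: str,
    gene_b: str,
    loci: pd.DataFrame,
    blocks: pd.DataFrame | None = None,
    max_gap: int = 5,
    convention: str = "intervening",
) -> str:
    """Duplicate type: ``tandem`` | ``segmental`` | ``unclassified``."""
    if classify_tandem(gene_a, gene_b, loci, max_gap=max_gap, convention=convention):
        return "tandem"
    if blocks is not None and classify_segmental(gene_a, gene_b, loci, blocks):
        return "segmental"
    return "unclassified"


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    Each of the nine single-nucleotide changes contributes 1/3 of a site;
    changes producing a stop codon count as nonsynonymous.
    """
    syn = 0.0
    for i in range(3):
        for nt in _NT:
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt not in STOP_CODONS and _AA_OF[alt] == _AA_OF[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weight over all orderings of the differing
    positions; orderings that pass through a stop codon are excluded (and
    the average renormalized).  Falls back to per-position classification in
    the ancestor context if every pathway is blocked.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = codon_a
        syn = non = 0
        ok = True
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _AA_OF[cur] == _AA_OF[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:
        syn = non = 0
        for i in diff:
            alt = codon_a[:i] + codon_b[i] + codon_a[i + 1 :]
            if alt not in STOP_CODONS and _AA_OF[alt] == _AA_OF[codon_a]:
                syn += 1
            else:
                non += 1
        return float(syn), float(non)
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -3/4 ln(1 - 4p/3); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_ka_ks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei–Gojobori (1986) Ka and Ks for a gap-free codon alignment.

    Codons containing gaps are dropped pairwise with a warning; internal
    stop codons are rejected.  Raises when a corrected proportion reaches
    the JC69 saturation bound.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3:
        raise ValueError("alignment length not divisible by 3")
    a, b = cds_a.upper(), cds_b.upper()
    syn_sites = non_sites = 0.0
    syn_diff = non_diff = 0.0
    dropped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb:
            dropped += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at alignment position {i + 1}")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        syn_sites += (sa + sb) / 2.0
        non_sites += (na + nb) / 2.0
        # pathway counting is direction-symmetric; average both anyway
        s_ab, n_ab = _pathway_counts(ca, cb)
        s_ba, n_ba = _pathway_counts(cb, ca)
        syn_diff += (s_ab + s_ba) / 2.0
        non_diff += (n_ab + n_ba) / 2.0
    if dropped:
        warnings.warn(f"dropped {dropped} gapped codon(s)", stacklevel=2)
    if syn_sites == 0 or non_sites == 0:
        raise ValueError("no comparable codons in alignment")
    ks = jukes_cantor(syn_diff / syn_sites)
    ka = jukes_cantor(non_diff / non_sites)
    return KaKsResult(ka=ka, ks=ks, ka_sites=non_sites, ks_sites=syn_sites)


# ---------------------------------------------------------------------------
# selection calls and dating


def selection_call(ka: float, ks: float) -> str:
    """``purifying`` (Ka/Ks < 1) | ``neutral`` (= 1) | ``positive`` (> 1) |
    ``undefined`` (Ks = 0)."""
    if ka < 0 or ks < 0:
        raise ValueError("Ka and Ks must be non-negative")
    if ks == 0:
        return "undefined"
    ratio = ka / ks
    if ratio < 1:
        return "purifying"
    if ratio > 1:
        return "positive"
    return "neutral"


def duplication_date(ks: float, params: EvolutionParams | None = None) -> float:
    """Duplication age T = Ks / (2 lambda), in Mya."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    params = params or EvolutionParams()
    return ks / (2.0 * params.lambda_rate) * 1e-6


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pair_report(
    pairs: pd.DataFrame,
    params: EvolutionParams | None = None,
) -> pd.DataFrame:
    """Recompute ratio, selection and date from a (gene_a, gene_b, ka, ks[,
    duplicate_type]) table; ratio to three decimals, date to two (half-up)."""
    params = params or EvolutionParams()
    out = pairs.copy()
    ratios, calls, dates = [], [], []
    for row in pairs.itertuples(index=False):
        call = selection_call(row.ka, row.ks)
        ratios.append(
            _round_half_up(row.ka / row.ks, 3) if row.ks > 0 else float("nan")
        )
        calls.append(call)
        dates.append(_round_half_up(duplication_date(row.ks, params), 2))
    out["ratio"] = ratios
    out["selection"] = calls
    out["date_mya"] = dates
    return out


def load_maize_duplicate_pairs() -> pd.DataFrame:
    """The published 17 duplicated maize CCCH paralog pairs (packaged TSV)."""
    ref = resources.files("ccchsurvey") / "data" / "maize_ccch_duplicate_pairs.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
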