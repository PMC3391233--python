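"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator plants a structure (motif, substitution, duplicate pair,
cis-element, fold change) into an otherwise random background and
guarantees, by construction plus rejection sampling of the background, that
the corresponding analysis stage recovers the plan exactly when noise is
zero.  Backgrounds are uniform over their alphabet — the simplest null;
composition realism is a non-goal.

Rejection sampling only ever redraws background segments, never planted
content; after ``MAX_REJECTIONS`` failed redraws the plan is reported as
infeasible rather than silently altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import motif_scan
from .motif_scan import AMINO_ACIDS, DEFAULT_BOUNDS, SpacerBounds
from .promoter_scan import (
    DEFAULT_LEXICON,
    ElementLexicon,
    expand_iupac,
    reverse_complement,
    scan_elements,
)

MAX_REJECTIONS = 10_000

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(standard_dna_table.forward_table)
_AA_OF = dict(standard_dna_table.forward_table)


# ---------------------------------------------------------------------------
# proteomes with planted CCCH motifs


@dataclass(frozen=True)
class MotifPlan:
    """Planted CCCH motifs for one protein.

    ``planted_motifs`` holds (position, (a, b, 3)) pairs where position is
    the 1-based residue index of the motif's first cysteine.
    """

    protein_id: str
    planted_motifs: tuple[tuple[int, tuple[int, int, int]], ...] = ()

    def motif_span(self, spacers: tuple[int, int, int]) -> int:
        a, b, c = spacers
        return a + b + c + 4

    def validate(self, bounds: SpacerBounds = DEFAULT_BOUNDS) -> None:
        occupied: set[int] = set()
        for pos, (a, b, c) in self.planted_motifs:
            if not (bounds.a_min <= a <= bounds.a_max):
                raise ValueError(
                    f"{self.protein_id}: first spacer {a} outside "
                    f"[{bounds.a_min}, {bounds.a_max}]"
                )
            if not (bounds.b_min <= b <= bounds.b_max):
                raise ValueError(
                    f"{self.protein_id}: second spacer {b} outside "
                    f"[{bounds.b_min}, {bounds.b_max}]"
                )
            if c != bounds.c:
                raise ValueError(
                    f"{self.protein_id}: third spacer must be {bounds.c}, got {c}"
                )
            if pos < 1:
                raise ValueError(f"{self.protein_id}: position {pos} < 1")
            span = range(pos, pos + self.motif_span((a, b, c)))
            if not occupied.isdisjoint(span):
                raise ValueError(
                    f"{self.protein_id}: planted motifs overlap at position {pos}"
                )
            occupied.update(span)


def _render_motif(
    spacers: tuple[int, int, int], rng: np.random.Generator, spacer_alphabet: str
) -> str:
    a, b, c = spacers
    draw = lambda n: "".join(rng.choice(list(spacer_alphabet), size=n))
    return "C" + draw(a) + "C" + draw(b) + "C" + draw(c) + "H"


def generate_proteome(
    plans: list[MotifPlan],
    background_length: int = 120,
    seed: int = 0,
    bounds: SpacerBounds = DEFAULT_BOUNDS,
    fill: str | None = None,
) -> dict[str, str]:
    """Generate protein records whose scan result equals the plan exactly.

    Each protein consists of its planted motifs at their planned 1-based
    positions, with all remaining residues (spacers and background) drawn
    uniformly; ``background_length`` residues of trailing background are
    appended after the last motif.  The assembled sequence is re-scanned and
    background redrawn until the hit set equals the plan (anchors in random
    background can otherwise create spurious or alternative parses).

    ``fill`` forces a single residue for every non-anchor position
    (test hook; e.g. ``fill="A"`` makes the minimal (4,4,3) motif exactly
    ``CAAAACAAAACAAAH``).
    """
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    for plan in plans:
        plan.validate(bounds)
        planted = sorted(plan.planted_motifs)
        records[plan.protein_id] = _assemble_protein(
            plan, planted, background_length, rng, bounds, fill
        )
    return records


def _assemble_protein(plan, planted, background_length, rng, bounds, fill):
    spacer_alphabet = AMINO_ACIDS if fill is None else fill
    # background excludes nothing a priori; rejection handles accidents
    for _ in range(MAX_REJECTIONS):
        pieces: list[str] = []
        cursor = 1
        for pos, spacers in planted:
            if pos < cursor:
                raise ValueError(f"{plan.protein_id}: planted motifs overlap")
            gap = pos - cursor
            if fill is None:
                pieces.append("".join(rng.choice(list(AMINO_ACIDS), size=gap)))
            else:
                pieces.append(fill * gap)
            pieces.append(_render_motif(spacers, rng, spacer_alphabet))
            cursor = pos + plan.motif_span(spacers)
        if fill is None:
            pieces.append(
                "".join(rng.choice(list(AMINO_ACIDS), size=background_length))
            )
        else:
            pieces.append(fill * background_length)
        seq = "".join(pieces)
        hits = motif_scan.find_motifs(seq, bounds=bounds)
        found = [(h.start, h.spacers) for h in hits]
        if found == list(planted):
            return seq
        if fill is not None:
            raise ValueError(
                f"{plan.protein_id}: plan not recoverable with fixed fill "
                f"{fill!r} (planted {planted}, scanned {found})"
            )
    raise ValueError(
        f"{plan.protein_id}: could not realize plan after {MAX_REJECTIONS} "
        f"background redraws"
    )


def random_motif_plans(
    n_proteins: int,
    seed: int,
    max_motifs: int = 7,
    bounds: SpacerBounds = DEFAULT_BOUNDS,
    signature_pool: list[tuple[int, int, int]] | None = None,
) -> list[MotifPlan]:
    """Random non-overlapping motif plans, 0..max_motifs motifs per protein."""
    rng = np.random.default_rng(seed)
    if signature_pool is None:
        signature_pool = [
            (int(a), int(b), bounds.c)
            for a in range(bounds.a_min, bounds.a_max + 1)
            for b in range(bounds.b_min, bounds.b_max + 1)
        ]
    plans = []
    for p in range(n_proteins):
        n_motifs = int(rng.integers(0, max_motifs + 1))
        pos = 1 + int(rng.integers(0, 30))
        planted = []
        for _ in range(n_motifs):
            sig = signature_pool[int(rng.integers(len(signature_pool)))]
            planted.append((pos, sig))
            pos += sum(sig) + 4 + int(rng.integers(5, 40))
        plans.append(MotifPlan(f"SYN{p + 1:03d}", tuple(planted)))
    return plans


# ---------------------------------------------------------------------------
# CDS pairs with controlled synonymous / nonsynonymous divergence


@dataclass(frozen=True)
class DivergencePlan:
    """Ground truth for one paralog CDS pair.

    Exactly ``syn_changes`` codons receive a single synonymous substitution
    and ``nonsyn_changes`` a single nonsynonymous one, each in a distinct
    codon, relative to a shared ancestor.
    """

    pair_id: str
    n_codons: int
    syn_changes: int
    nonsyn_changes: int
    seed: int

    def validate(self) -> None:
        if min(self.n_codons, self.syn_changes, self.nonsyn_changes) < 0:
            raise ValueError(f"{self.pair_id}: negative counts")
        if self.syn_changes + self.nonsyn_changes > self.n_codons:
            raise ValueError(
                f"{self.pair_id}: {self.syn_changes}+{self.nonsyn_changes} "
                f"changes exceed {self.n_codons} codons"
            )


def _single_nt_neighbors(codon: str) -> list[str]:
    out = []
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[i]:
                out.append(codon[:i] + nt + codon[i + 1 :])
    return out


_SYN_OPTIONS = {
    c: [n for n in _single_nt_neighbors(c) if n not in STOP_CODONS and _AA_OF[n] == _AA_OF[c]]
    for c in SENSE_CODONS
}
_NONSYN_OPTIONS = {
    c: [n for n in _single_nt_neighbors(c) if n not in STOP_CODONS and _AA_OF[n] != _AA_OF[c]]
    for c in SENSE_CODONS
}


def generate_cds_pair(plan: DivergencePlan) -> tuple[str, str]:
    """Generate an (ancestor, descendant) in-frame, stop-free CDS pair.

    The ancestor is drawn codon-uniform over the 61 sense codons (avoids
    composition artifacts in NG86 site counting); the descendant carries the
    planned single-nucleotide changes.  Codons with no synonymous
    single-nucleotide option (Met, Trp) are resampled when drawn for a
    synonymous slot.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    for _ in range(MAX_REJECTIONS):
        ancestor = [
            SENSE_CODONS[int(i)]
            for i in rng.integers(0, len(SENSE_CODONS), size=plan.n_codons)
        ]
        slots = rng.permutation(plan.n_codons)
        syn_slots = slots[: plan.syn_changes]
        nonsyn_slots = slots[plan.syn_changes : plan.syn_changes + plan.nonsyn_changes]
        if any(not _SYN_OPTIONS[ancestor[int(s)]] for s in syn_slots):
            continue  # Met/Trp drawn in a synonymous slot: resample
        descendant = list(ancestor)
        for s in syn_slots:
            opts = _SYN_OPTIONS[ancestor[int(s)]]
            descendant[int(s)] = opts[int(rng.integers(len(opts)))]
        for s in nonsyn_slots:
            opts = _NONSYN_OPTIONS[ancestor[int(s)]]
            descendant[int(s)] = opts[int(rng.integers(len(opts)))]
        return "".join(ancestor), "".join(descendant)
    raise ValueError(f"{plan.pair_id}: no valid codon assignment found")


# ---------------------------------------------------------------------------
# gene orders with planted tandem / segmental duplicates


def generate_gene_order(
    n_genes: int,
    tandem_pairs: list[tuple[str, str]],
    segmental_pairs: list[tuple[str, str]],
    block_map: pd.DataFrame,
    seed: int = 0,
    n_chromosomes: int = 10,
    max_gap: int = 5,
    gene_spacing: int = 10_000,
    gene_length: int = 3_000,
) -> pd.DataFrame:
    """Place genes on chromosomes so planted duplicate labels are recoverable.

    Tandem pairs land on one chromosome separated by at most ``max_gap``
    intervening loci and outside every duplicated block; segmental pairs
    land inside the two mates of a block pairing.  Remaining genes fill free
    slots.  Returns a locus table (gene_id, chromosome, start, end,
    locus_index).

    ``block_map`` columns: chr_a, start_a, end_a, chr_b, start_b, end_b.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    named = [g for p in tandem_pairs + segmental_pairs for g in p]
    if len(set(named)) != len(named):
        raise ValueError("a gene may appear in only one planted pair")
    n_named = len(named)
    if n_named > n_genes:
        raise ValueError(f"{n_named} planted genes exceed n_genes={n_genes}")

    slots_per_chrom = max(2 * max_gap + 4, math.ceil(n_genes / n_chromosomes) + max_gap + 2)
    if len(block_map):
        # extend the slot range so every block interval contains slots
        max_block_end = int(max(block_map["end_a"].max(), block_map["end_b"].max()))
        slots_per_chrom = max(slots_per_chrom, max_block_end // gene_spacing + 2)

    def slot_interval(slot: int) -> tuple[int, int]:
        start = slot * gene_spacing + 1
        return start, start + gene_length - 1

    def slots_inside(chrom: str, lo: int, hi: int) -> list[int]:
        return [
            s
            for s in range(slots_per_chrom)
            if slot_interval(s)[0] >= lo and slot_interval(s)[1] <= hi
        ]

    free: dict[str, set[int]] = {c: set(range(slots_per_chrom)) for c in chroms}
    placement: dict[str, tuple[str, int]] = {}

    blocks = list(block_map.itertuples(index=False))
    block_slots: dict[str, set[int]] = {c: set() for c in chroms}
    for b in blocks:
        for chrom, lo, hi in ((b.chr_a, b.start_a, b.end_a), (b.chr_b, b.start_b, b.end_b)):
            if chrom not in free:
                raise ValueError(f"block chromosome {chrom} not in genome")
            block_slots[chrom].update(slots_inside(chrom, lo, hi))

    if segmental_pairs and not blocks:
        raise ValueError("segmental pairs requested but block map is empty")
    for idx, (g1, g2) in enumerate(segmental_pairs):
        b = blocks[idx % len(blocks)]
        cand_a = sorted(free[b.chr_a] & set(slots_inside(b.chr_a, b.start_a, b.end_a)))
        cand_b = sorted(free[b.chr_b] & set(slots_inside(b.chr_b, b.start_b, b.end_b)))
        if not cand_a or not cand_b:
            raise ValueError(
                f"no free slot inside block pairing {idx % len(blocks)} "
                f"for segmental pair ({g1}, {g2})"
            )
        sa = cand_a[int(rng.integers(len(cand_a)))]
        sb = cand_b[int(rng.integers(len(cand_b)))]
        if b.chr_a == b.chr_b and sa == sb:
            raise ValueError(f"cannot co-place ({g1}, {g2}) in a self-paired block")
        placement[g1] = (b.chr_a, sa)
        free[b.chr_a].discard(sa)
        placement[g2] = (b.chr_b, sb)
        free[b.chr_b].discard(sb)

    for g1, g2 in tandem_pairs:
        placed = False
        for chrom in rng.permutation(chroms):
            avail = sorted(free[chrom] - block_slots[chrom])
            pairs = [
                (s1, s2)
                for s1 in avail
                for s2 in avail
                if 0 < s2 - s1 <= max_gap + 1
            ]
            if pairs:
                s1, s2 = pairs[int(rng.integers(len(pairs)))]
                placement[g1] = (chrom, s1)
                placement[g2] = (chrom, s2)
                free[chrom] -= {s1, s2}
                placed = True
                break
        if not placed:
            raise ValueError(f"no room for tandem pair ({g1}, {g2})")

    fillers = [f"GENE{i + 1:04d}" for i in range(n_genes - n_named)]
    open_slots = [(c, s) for c in chroms for s in sorted(free[c] - block_slots[c])]
    if len(open_slots) < len(fillers):
        open_slots = [(c, s) for c in chroms for s in sorted(free[c])]
    if len(open_slots) < len(fillers):
        raise ValueError("not enough free slots for filler genes")
    order = rng.permutation(len(open_slots))[: len(fillers)]
    for g, k in zip(fillers, order):
        chrom, s = open_slots[int(k)]
        placement[g] = (chrom, s)
        free[chrom].discard(s)

    rows = []
    for chrom in chroms:
        on_chrom = sorted(
            ((s, g) for g, (c, s) in placement.items() if c == chrom)
        )
        for locus_index, (s, g) in enumerate(on_chrom, start=1):
            start, end = slot_interval(s)
            rows.append((g, chrom, start, end, locus_index))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "locus_index"]
    )


def default_block_map(
    n_blocks: int = 8, n_chromosomes: int = 10, gene_spacing: int = 10_000
) -> pd.DataFrame:
    """A simple symmetric duplicated-block catalogue for synthetic genomes.

    Intervals are sized in units of ``gene_spacing`` so they overlap the
    gene slots laid down by `generate_gene_order` (four slots per block).
    """
    rows = []
    for i in range(n_blocks):
        chr_a = f"chr{(2 * i) % n_chromosomes + 1}"
        chr_b = f"chr{(2 * i + 1) % n_chromosomes + 1}"
        rep = (2 * i) // n_chromosomes  # stack extra blocks further along
        lo = (3 + 6 * rep) * gene_spacing + 1
        hi = (7 + 6 * rep) * gene_spacing
        rows.append((chr_a, lo, hi, chr_b, lo, hi))
    return pd.DataFrame(
        rows, columns=["chr_a", "start_a", "end_a", "chr_b", "start_b", "end_b"]
    )


# ---------------------------------------------------------------------------
# promoters with planted cis-elements


def generate_promoters(
    n: int,
    length: int = 2000,
    planted: dict[str, list[tuple[str, str, int]]] | None = None,
    seed: int = 0,
    lexicon: ElementLexicon | None = None,
) -> dict[str, str]:
    """Generate promoter sequences whose element scan equals the plan.

    ``planted`` maps promoter id -> list of (element_name, strand, offset)
    with 1-based sense-strand offsets; ids default to P001..P00n, unplanted
    ids get pure background.  Background is uniform A/C/G/T, redrawn until
    the scanner reports exactly the planted hits.
    """
    lexicon = lexicon if lexicon is not None else DEFAULT_LEXICON
    planted = planted or {}
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    unknown = set(planted) - set(ids)
    if unknown:
        raise ValueError(f"planted promoter ids not generated: {sorted(unknown)}")
    records: dict[str, str] = {}
    for pid in ids:
        records[pid] = _assemble_promoter(
            pid, length, sorted(planted.get(pid, []), key=lambda t: t[2]), rng, lexicon
        )
    return records


def _assemble_promoter(pid, length, plants, rng, lexicon):
    spans = []
    for name, strand, offset in plants:
        if name not in lexicon:
            raise ValueError(f"{pid}: element {name!r} absent from lexicon")
        if strand not in "+-":
            raise ValueError(f"{pid}: strand must be '+' or '-'")
        m = len(lexicon[name].pattern)
        if not (1 <= offset <= length - m + 1):
            raise ValueError(f"{pid}: offset {offset} outside [1, {length - m + 1}]")
        spans.append((offset, offset + m - 1, name, strand))
    spans.sort()
    for (s1, e1, *_), (s2, *_rest) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"{pid}: planted elements overlap at offset {s2}")

    expected = sorted(
        (offset, name, strand) for name, strand, offset in plants
    )
    for _ in range(MAX_REJECTIONS):
        seq = list(rng.choice(list(NUCLEOTIDES), size=length))
        for start, end, name, strand in spans:
            instance = _instantiate(lexicon[name].pattern, rng)
            if strand == "-":
                instance = reverse_complement(instance)
            seq[start - 1 : end] = list(instance)
        s = "".join(seq)
        hits = scan_elements(s, lexicon, promoter_id=pid)
        found = sorted((h.position, h.element, h.strand) for h in hits)
        if found == expected:
            return s
    raise ValueError(
        f"{pid}: could not realize promoter plan after {MAX_REJECTIONS} redraws"
    )


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(expand_iupac(ch))[int(rng.integers(len(expand_iupac(ch))))]
        for ch in pattern
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtPlan:
    """True fold changes behind a synthetic Ct table.

    ``true_fold_changes[gene][condition]`` is the true expression of the
    gene in that condition relative to the calibrator; the calibrator's own
    fold must be 1.  Per-measurement Gaussian noise of SD ``replicate_sd``
    (Ct cycles) is added independently to every well.  Three technical
    replicates mirror common qPCR practice.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    true_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    replicate_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    reference_gene: str = "Actin1"
    calibrator: str = "CK"

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.calibrator not in self.conditions:
            raise ValueError(f"calibrator {self.calibrator!r} not in conditions")
        for g in self.genes:
            for cond in self.conditions:
                f = self.true_fold_changes.get(g, {}).get(cond, 1.0)
                if not f > 0:
                    raise ValueError(f"non-positive fold change for {g}/{cond}")


def generate_ct_table(plan: CtPlan) -> pd.DataFrame:
    """Emit a tidy Ct table (gene, condition, replicate, replicate_type, ct).

    The reference gene is measured in every (condition, replicate) at a
    fixed baseline; target Ct values encode the planned fold change via
    Ct_target = Ct_ref + dCt_calibrator - log2(fold).  With replicate_sd = 0
    the 2^-ddCt pipeline recovers the plan exactly.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    ref_base, dct_base = 20.0, 5.0
    rows = []
    for cond in plan.conditions:
        for rep in range(1, plan.n_replicates + 1):
            noise = rng.normal(0.0, plan.replicate_sd) if plan.replicate_sd else 0.0
            rows.append((plan.reference_gene, cond, rep, "technical", ref_base + noise))
            for g in plan.genes:
                fold = plan.true_fold_changes.get(g, {}).get(cond, 1.0)
                ct = ref_base + dct_base - math.log2(fold)
                noise = rng.normal(0.0, plan.replicate_sd) if plan.replicate_sd else 0.0
                rows.append((g, cond, rep, "technical", ct + noise))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "replicate", "replicate_type", "ct"]
    )


# ---------------------------------------------------------------------------
# clade-structured protein alignments (fixture for the phylogeny stage)


def generate_clade_alignment(
    clade_sizes: list[int],
    length: int = 200,
    seed: int = 0,
    within_divergence: float = 0.02,
    between_divergence: float = 0.45,
) -> tuple[dict[str, str], dict[str, str]]:
    """Aligned protein rows with planted clades and strong clade signal.

    Each clade gets a consensus sequence differing from a shared root at a
    ``between_divergence`` fraction of positions; members differ from their
    consensus at a ``within_divergence`` fraction.  Returns (alignment rows,
    taxon -> clade label); taxa are C{i}T{j}.
    """
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    root = rng.choice(aas, size=length)
    rows: dict[str, str] = {}
    truth: dict[str, str] = {}
    for ci, size in enumerate(clade_sizes, start=1):
        consensus = root.copy()
        k = int(round(between_divergence * length))
        sites = rng.choice(length, size=k, replace=False)
        consensus[sites] = rng.choice(aas, size=k)
        for ti in range(1, size + 1):
            member = consensus.copy()
            k = int(round(within_divergence * length))
            if k:
                sites = rng.choice(length, size=k, replace=False)
                member[sites] = rng.choice(aas, size=k)
            name = f"C{ci}T{ti}"
            rows[name] = "".join(member)
            truth[name] = f"clade{ci}"
    return rows, truth
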