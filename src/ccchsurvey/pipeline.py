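"""End-to-end survey orchestration and the synthetic demo bundle.

`run_survey` chains the stages — motif scan, NJ tree with bootstrap
grouping, duplicate-pair evolution, promoter element scan, and qPCR
expression — from one YAML configuration, writing TSV/newick outputs plus a
JSON run manifest (parameters, seed, per-stage counts) under one output
directory.  Stages can be individually disabled; a stage failure aborts
with the stage name and leaves a FAILED marker.

`make_demo` materializes a complete synthetic dataset with known ground
truth: 68 proteins carrying planted CCCH motifs across classes (one
7-motif protein, one C-X17-C-X6-C-X3-H finger), a 3-clade alignment, 17
duplicate pairs (15 segmental + 2 tandem) with controlled divergence,
promoters with planted ABRE/DRE cores on both strands, and Ct tables with
specified fold changes — together with a plan manifest for oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dup_evolution, io, motif_scan, phylo, promoter_scan
from . import qpcr_expression, synthetic_data
from .motif_scan import SpacerBounds


@dataclass
class SurveyConfig:
    """Paths and parameters of one survey run; see ``from_yaml``."""

    out_dir: Path
    proteins_fasta: Path | None = None
    alignment_fasta: Path | None = None
    cds_pairs_fasta: Path | None = None
    pairs_tsv: Path | None = None
    loci_tsv: Path | None = None
    blocks_tsv: Path | None = None
    promoters_fasta: Path | None = None
    ct_tsv: Path | None = None
    lexicon_path: Path | None = None
    a_min: int = 4
    a_max: int = 17
    b_min: int = 4
    b_max: int = 6
    bootstrap_reps: int = 1000
    seed: int = 0
    group_threshold: float = 50.0
    inclusive_threshold: bool = False
    lambda_rate: float = dup_evolution.GRASS_LAMBDA
    max_gap: int = 5
    reference_gene: str = "Actin1"
    calibrator: str = "CK"

    @property
    def bounds(self) -> SpacerBounds:
        return SpacerBounds(self.a_min, self.a_max, self.b_min, self.b_max)

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw["out_dir"] = Path(raw.get("out_dir", "survey_out"))
        for key in (
            "proteins_fasta", "alignment_fasta", "cds_pairs_fasta", "pairs_tsv",
            "loci_tsv", "blocks_tsv", "promoters_fasta", "ct_tsv", "lexicon_path",
        ):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for key in (
            "proteins_fasta", "alignment_fasta", "cds_pairs_fasta", "pairs_tsv",
            "loci_tsv", "blocks_tsv", "promoters_fasta", "ct_tsv", "lexicon_path",
        ):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        if self.cds_pairs_fasta is not None and self.pairs_tsv is None:
            raise ValueError("cds_pairs_fasta requires pairs_tsv naming the pairs")
        if self.pairs_tsv is not None and self.loci_tsv is None:
            raise ValueError("duplicates stage requires loci_tsv")


def _header(config: SurveyConfig) -> list[str]:
    return [
        f"ccchsurvey {__version__}",
        f"seed={config.seed} bounds=({config.a_min},{config.a_max},"
        f"{config.b_min},{config.b_max}) bootstrap={config.bootstrap_reps} "
        f"threshold={config.group_threshold} lambda={config.lambda_rate} "
        f"max_gap={config.max_gap}",
    ]


def run_survey(config: SurveyConfig) -> dict:
    """Run every configured stage; returns the survey report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    hdr = _header(config)
    stage = "none"
    try:
        if config.proteins_fasta is not None:
            stage = "scan"
            report["stages"]["scan"] = _stage_scan(config, out, hdr)
        if config.alignment_fasta is not None:
            stage = "tree"
            report["stages"]["tree"] = _stage_tree(config, out, hdr)
        if config.cds_pairs_fasta is not None or config.pairs_tsv is not None:
            stage = "dups"
            report["stages"]["dups"] = _stage_dups(config, out, hdr)
        if config.promoters_fasta is not None:
            stage = "promoters"
            report["stages"]["promoters"] = _stage_promoters(config, out, hdr)
        if config.ct_tsv is not None:
            stage = "qpcr"
            report["stages"]["qpcr"] = _stage_qpcr(config, out, hdr)
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _stage_scan(config: SurveyConfig, out: Path, hdr: list[str]) -> dict:
    proteins = io.read_fasta(config.proteins_fasta)
    hits = motif_scan.scan_proteome(proteins, bounds=config.bounds)
    hits_df = pd.DataFrame(
        [
            (h.protein_id, h.start, h.end, h.signature, h.subsequence)
            for h in hits
        ],
        columns=["protein_id", "start", "end", "signature", "subsequence"],
    )
    io.write_tsv(hits_df, out / "motif_hits.tsv", hdr)
    tally = motif_scan.tally_classes(hits)
    io.write_tsv(tally.to_frame(), out / "motif_classes.tsv", hdr)
    hist, n_zero = motif_scan.count_histogram(hits, protein_ids=list(proteins))
    io.write_tsv(
        pd.DataFrame(
            {"motif_count": list(hist), "n_proteins": list(hist.values())}
        ),
        out / "motif_histogram.tsv",
        hdr + [f"proteins_without_motifs={n_zero}"],
    )
    for sig, count in list(tally.counts.items())[:2]:  # top two classes
        class_hits = [h for h in hits if h.signature == sig]
        profile = motif_scan.build_logo(class_hits)
        io.write_tsv(
            profile.frequencies.assign(
                information_bits=profile.information_bits
            ),
            out / f"logo_{sig.replace('-', '_')}.tsv",
            hdr + [f"class={sig} n={profile.n_sequences}"],
        )
    return {
        "n_proteins": len(proteins),
        "n_proteins_with_motifs": len({h.protein_id for h in hits}),
        "motif_total": tally.total,
        "class_tallies": tally.counts,
        "histogram": {str(k): v for k, v in hist.items()},
    }


def _stage_tree(config: SurveyConfig, out: Path, hdr: list[str]) -> dict:
    aln = phylo.Alignment.from_fasta(config.alignment_fasta)
    tree = phylo.bootstrap(
        aln, n_reps=config.bootstrap_reps, seed=config.seed
    )
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    groups = phylo.assign_groups(
        tree,
        threshold=config.group_threshold,
        inclusive=config.inclusive_threshold,
    )
    io.write_tsv(
        pd.DataFrame(
            {"taxon": list(groups), "group": [groups[t] or "ungrouped" for t in groups]}
        ),
        out / "groups.tsv",
        hdr,
    )
    sizes: dict[str, int] = {}
    for g in groups.values():
        if g is not None:
            sizes[g] = sizes.get(g, 0) + 1
    pairs = phylo.sister_pairs(tree)
    io.write_tsv(
        pd.DataFrame(pairs, columns=["taxon_a", "taxon_b", "support"]),
        out / "sister_pairs.tsv",
        hdr,
    )
    return {
        "n_taxa": aln.n_taxa,
        "n_groups": len(sizes),
        "group_sizes": dict(sorted(sizes.items())),
        "n_sister_pairs": len(pairs),
    }


def _stage_dups(config: SurveyConfig, out: Path, hdr: list[str]) -> dict:
    pairs = io.read_tsv(config.pairs_tsv)
    loci = io.read_tsv(config.loci_tsv) if config.loci_tsv else None
    blocks = io.read_tsv(config.blocks_tsv) if config.blocks_tsv else None
    cds = io.read_fasta(config.cds_pairs_fasta) if config.cds_pairs_fasta else None
    params = dup_evolution.EvolutionParams(config.lambda_rate)
    rows = []
    for row in pairs.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if cds is not None:
            res = dup_evolution.ng86_ka_ks(cds[a], cds[b])
            ka, ks = res.ka, res.ks
        else:
            ka, ks = float(row.ka), float(row.ks)
        dup_type = dup_evolution.classify_pair(
            a, b, loci, blocks, max_gap=config.max_gap
        )
        rows.append((a, b, ka, ks, dup_type))
    table = dup_evolution.pair_report(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "ka", "ks", "duplicate_type"]),
        params,
    )
    io.write_tsv(table, out / "duplicate_pairs.tsv", hdr)
    return {
        "n_pairs": len(table),
        "n_tandem": int((table["duplicate_type"] == "tandem").sum()),
        "n_segmental": int((table["duplicate_type"] == "segmental").sum()),
        "n_purifying": int((table["selection"] == "purifying").sum()),
        "n_positive": int((table["selection"] == "positive").sum()),
    }


def _stage_promoters(config: SurveyConfig, out: Path, hdr: list[str]) -> dict:
    lexicon = (
        promoter_scan.ElementLexicon.from_yaml(config.lexicon_path)
        if config.lexicon_path
        else promoter_scan.default_lexicon()
    )
    promoters = io.read_fasta(config.promoters_fasta)
    hits: list[promoter_scan.CisElementHit] = []
    for pid, seq in promoters.items():
        hits.extend(promoter_scan.scan_elements(seq, lexicon, promoter_id=pid))
    io.write_tsv(
        pd.DataFrame(
            [(h.promoter_id, h.element, h.strand, h.position, h.matched) for h in hits],
            columns=["promoter_id", "element", "strand", "position", "matched"],
        ),
        out / "cis_element_hits.tsv",
        hdr,
    )
    counts = promoter_scan.element_counts(hits)
    io.write_tsv(counts, out / "cis_element_counts.tsv", hdr)
    per_element: dict[str, int] = {}
    for h in hits:
        per_element[h.element] = per_element.get(h.element, 0) + 1
    return {
        "n_promoters": len(promoters),
        "n_hits": len(hits),
        "hits_per_element": dict(sorted(per_element.items())),
    }


def _stage_qpcr(config: SurveyConfig, out: Path, hdr: list[str]) -> dict:
    table = io.read_tsv(config.ct_tsv)
    results = qpcr_expression.delta_delta_ct(
        table,
        reference_gene=config.reference_gene,
        calibrator=config.calibrator,
    )
    io.write_tsv(results, out / "expression.tsv", hdr)
    return {
        "n_genes": int(results["gene"].nunique()),
        "n_conditions": int(results["condition"].nunique()),
        "calibrator_mean_fold": float(
            results.loc[results["condition"] == config.calibrator, "fold"].mean()
        ),
    }


# ---------------------------------------------------------------------------
# synthetic demo bundle


def make_demo(out_dir, seed: int = 0) -> dict:
    """Write a complete synthetic survey dataset plus its plan manifest.

    The bundle echoes the shape of a real single-family survey: 68 proteins
    with planted motifs across classes (one protein carrying seven motifs,
    one carrying a C-X17-C-X6-C-X3-H finger), a 12-taxon 3-clade alignment,
    17 duplicate pairs (15 segmental + 2 tandem) with CDS divergence ground
    truth, 12 promoters with planted ABRE/DRE elements, and a 3-replicate
    Ct table with known fold changes.  Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan: dict = {"seed": seed}

    # proteins: 67 random plans plus one fixed 7-motif protein; ensure one
    # protein carries the novel 17-residue first spacer
    plans = synthetic_data.random_motif_plans(66, seed=seed, max_motifs=5)
    seven = []
    pos = 5
    for i in range(7):
        sig = (8, 5, 3) if i % 2 == 0 else (7, 5, 3)
        seven.append((pos, sig))
        pos += sum(sig) + 4 + 12
    plans.append(synthetic_data.MotifPlan("SYN7COPY", tuple(seven)))
    plans.append(synthetic_data.MotifPlan("SYNX17", ((10, (17, 6, 3)),)))
    proteins = synthetic_data.generate_proteome(plans, seed=seed + 1)
    io.write_fasta(proteins, out / "proteins.fasta")
    plan["motifs"] = {
        p.protein_id: [[pos, list(sig)] for pos, sig in p.planted_motifs]
        for p in plans
    }

    # alignment with three planted clades
    rows, clade_truth = synthetic_data.generate_clade_alignment(
        [4, 4, 4], length=200, seed=seed + 2
    )
    io.write_fasta(rows, out / "alignment.fasta")
    plan["clades"] = clade_truth

    # duplicate pairs: 15 segmental + 2 tandem with CDS ground truth
    tandem = [(f"TDUP{i}A", f"TDUP{i}B") for i in range(1, 3)]
    segmental = [(f"SDUP{i}A", f"SDUP{i}B") for i in range(1, 16)]
    blocks = synthetic_data.default_block_map()
    loci = synthetic_data.generate_gene_order(
        n_genes=60,
        tandem_pairs=tandem,
        segmental_pairs=segmental,
        block_map=blocks,
        seed=seed + 3,
    )
    io.write_tsv(loci, out / "gene_loci.tsv")
    io.write_tsv(blocks, out / "duplicated_blocks.tsv")
    cds_records: dict[str, str] = {}
    pair_rows = []
    truth_changes = {}
    for idx, (a, b) in enumerate(tandem + segmental):
        syn = 6 + 4 * idx  # tandem pairs (listed first) get older/noisier Ks
        nonsyn = max(1, syn // 4)
        p = synthetic_data.DivergencePlan(f"{a}-{b}", 300, syn, nonsyn, seed + 10 + idx)
        cds_records[a], cds_records[b] = synthetic_data.generate_cds_pair(p)
        pair_rows.append((a, b))
        truth_changes[f"{a}-{b}"] = {"syn": syn, "nonsyn": nonsyn}
    io.write_fasta(cds_records, out / "cds_pairs.fasta")
    io.write_tsv(
        pd.DataFrame(pair_rows, columns=["gene_a", "gene_b"]), out / "pairs.tsv"
    )
    plan["duplicates"] = {
        "tandem": [list(p) for p in tandem],
        "segmental": [list(p) for p in segmental],
        "changes": truth_changes,
    }

    # promoters with planted elements
    planted: dict[str, list[tuple[str, str, int]]] = {}
    rng_offsets = [150, 420, 700, 1010, 1300, 1650]
    for i in range(12):
        pid = f"P{i + 1:03d}"
        n_elem = i % 4
        planted[pid] = [
            (
                "ABRE" if (i + j) % 2 == 0 else "DRE",
                "+" if j % 2 == 0 else "-",
                rng_offsets[j],
            )
            for j in range(n_elem)
        ]
    promoters = synthetic_data.generate_promoters(
        12, length=2000, planted=planted, seed=seed + 4
    )
    io.write_fasta(promoters, out / "promoters.fasta")
    plan["cis_elements"] = {
        pid: [[name, strand, off] for name, strand, off in items]
        for pid, items in planted.items()
    }

    # Ct table: 7 genes, calibrator plus three time points
    genes = tuple(f"SYNQ{i}" for i in range(1, 8))
    conditions = ("CK", "T1", "T2", "T3")
    folds = {
        g: {c: round(2.0 ** ((i + j) % 5 - 2), 3) for j, c in enumerate(conditions[1:], 1)}
        for i, g in enumerate(genes)
    }
    ct_plan = synthetic_data.CtPlan(
        genes=genes,
        conditions=conditions,
        true_fold_changes=folds,
        replicate_sd=0.0,
        n_replicates=3,
        seed=seed + 5,
    )
    io.write_tsv(synthetic_data.generate_ct_table(ct_plan), out / "ct_table.tsv")
    plan["fold_changes"] = folds

    with open(out / "plan.json", "w") as fh:
        json.dump(plan, fh, indent=2, sort_keys=True)

    config = SurveyConfig(
        out_dir=out / "results",
        proteins_fasta=out / "proteins.fasta",
        alignment_fasta=out / "alignment.fasta",
        cds_pairs_fasta=out / "cds_pairs.fasta",
        pairs_tsv=out / "pairs.tsv",
        loci_tsv=out / "gene_loci.tsv",
        blocks_tsv=out / "duplicated_blocks.tsv",
        promoters_fasta=out / "promoters.fasta",
        ct_tsv=out / "ct_table.tsv",
        bootstrap_reps=200,
        seed=seed,
        calibrator="CK",
    )
    config_dict = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in config.__dict__.items()
    }
    with open(out / "survey_config.yaml", "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)
    return plan
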