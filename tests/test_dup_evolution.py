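"""Duplicate classification, NG86 Ka/Ks, selection calls, clock dating."""

import itertools
import math
from fractions import Fraction

import pandas as pd
import pytest
from Bio.Data.CodonTable import standard_dna_table

from ccchsurvey import dup_evolution as de
from ccchsurvey import synthetic_data as sd

FWD = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)


def oracle_ng86(a: str, b: str):
    """Brute-force NG86 oracle in exact rational arithmetic."""
    S = N = Fraction(0)
    Sd = Nd = Fraction(0)
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        for codon in (ca, cb):
            syn = Fraction(0)
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    alt = codon[:pos] + nt + codon[pos + 1 :]
                    if alt not in STOPS and FWD[alt] == FWD[codon]:
                        syn += Fraction(1, 3)
            S += syn / 2
            N += (3 - syn) / 2
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, s, n, ok = ca, 0, 0, True
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if nxt in STOPS:
                    ok = False
                    break
                if FWD[cur] == FWD[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                paths.append((s, n))
        assert paths, "oracle fixture should not need the blocked-path fallback"
        Sd += Fraction(sum(p[0] for p in paths), len(paths))
        Nd += Fraction(sum(p[1] for p in paths), len(paths))
    ps, pn = Sd / S, Nd / N
    ks = -0.75 * math.log(1 - 4 * float(ps) / 3)
    ka = -0.75 * math.log(1 - 4 * float(pn) / 3)
    return ka, ks


@pytest.fixture(scope="module")
def table1():
    return de.load_maize_duplicate_pairs()


class TestTandem:
    @pytest.fixture()
    def loci(self):
        rows = [(f"g{i}", "chr1", i * 1000, i * 1000 + 100, i) for i in range(1, 12)]
        rows.append(("h1", "chr2", 1000, 1100, 1))
        return pd.DataFrame(
            rows, columns=["gene_id", "chromosome", "start", "end", "locus_index"]
        )

    def test_adjacent_loci_are_tandem(self, loci):
        assert de.classify_tandem("g1", "g2", loci)

    def test_different_chromosomes_are_not(self, loci):
        assert not de.classify_tandem("g1", "h1", loci)

    def test_five_intervening_boundary(self, loci):
        assert de.classify_tandem("g1", "g7", loci)  # 5 intervening loci
        assert not de.classify_tandem("g1", "g8", loci)  # 6 intervening

    def test_index_convention_variant(self, loci):
        assert de.classify_tandem("g1", "g6", loci, convention="index")
        assert not de.classify_tandem("g1", "g7", loci, convention="index")

    def test_order_invariant(self, loci):
        assert de.classify_tandem("g7", "g1", loci) == de.classify_tandem(
            "g1", "g7", loci
        )

    def test_unknown_gene_raises(self, loci):
        with pytest.raises(KeyError, match="nope"):
            de.classify_tandem("g1", "nope", loci)


class TestSegmental:
    @pytest.fixture()
    def scenario(self):
        blocks = sd.default_block_map(n_blocks=15)  # one block pairing per pair
        segmental = [(f"S{i}A", f"S{i}B") for i in range(1, 16)]
        loci = sd.generate_gene_order(
            40, tandem_pairs=[], segmental_pairs=segmental, block_map=blocks, seed=17
        )
        return loci, blocks, segmental

    def test_planted_pairs_all_and_only_recovered(self, scenario):
        loci, blocks, segmental = scenario
        planted = set(map(frozenset, segmental))
        genes = list(loci["gene_id"])
        got = {
            frozenset((a, b))
            for a, b in itertools.combinations(genes, 2)
            if de.classify_segmental(a, b, loci, blocks)
        }
        assert got == planted

    def test_order_invariant(self, scenario):
        loci, blocks, segmental = scenario
        a, b = segmental[0]
        assert de.classify_segmental(a, b, loci, blocks) == de.classify_segmental(
            b, a, loci, blocks
        )

    def test_gene_outside_every_block_is_not_segmental(self, scenario):
        loci, blocks, segmental = scenario
        filler = [g for g in loci["gene_id"] if g.startswith("GENE")][0]
        assert not de.classify_segmental(segmental[0][0], filler, loci, blocks)


class TestNg86:
    def test_identical_sequences(self):
        res = de.ng86_ka_ks("ATGGCT", "ATGGCT")
        assert res.ka == 0.0 and res.ks == 0.0
        assert res.ratio is None
        assert res.selection_call == "undefined"

    def test_single_synonymous_change(self):
        # one Phe->Phe change (TTT -> TTC) in a short gene; the glycine
        # padding keeps the synonymous proportion below the JC69 bound
        res = de.ng86_ka_ks("TTTGGGGGGGGG", "TTCGGGGGGGGG")
        assert res.ka == 0.0
        assert res.ks > 0.0
        assert res.selection_call == "purifying"

    def test_lone_saturated_codon_is_flagged(self):
        # a single codon carries 1/3 synonymous site, so one synonymous
        # change saturates the JC69 correction and Ks is undefined
        with pytest.raises(ValueError, match="undefined"):
            de.ng86_ka_ks("TTT", "TTC")

    def test_matches_exact_pathway_oracle(self):
        a, b = sd.generate_cds_pair(sd.DivergencePlan("p", 300, 15, 6, 7))
        res = de.ng86_ka_ks(a, b)
        ka, ks = oracle_ng86(a, b)
        assert res.ka == pytest.approx(ka, abs=1e-12)
        assert res.ks == pytest.approx(ks, abs=1e-12)

    def test_matches_biopython_reference(self):
        analysis = pytest.importorskip("Bio.Align.analysis")
        from Bio.Align import Alignment as BioAlignment

        a, b = sd.generate_cds_pair(sd.DivergencePlan("p", 200, 12, 9, 21))
        res = de.ng86_ka_ks(a, b)
        dn, ds = analysis.calculate_dn_ds(BioAlignment([a, b]), method="NG86")
        assert res.ka == pytest.approx(dn, abs=1e-9)
        assert res.ks == pytest.approx(ds, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 8, 13])
    def test_symmetry(self, seed):
        a, b = sd.generate_cds_pair(sd.DivergencePlan("p", 150, 10, 5, seed))
        r1, r2 = de.ng86_ka_ks(a, b), de.ng86_ka_ks(b, a)
        assert r1.ka == pytest.approx(r2.ka, abs=1e-15)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-15)

    def test_gapped_codons_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="gapped"):
            res = de.ng86_ka_ks("TTTGGGGGG---", "TTCGGGGGGAAA")
        assert res.ks > 0 and res.ka == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            de.ng86_ka_ks("TTT", "TTTAAA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            de.ng86_ka_ks("TAAGGG", "TACGGG")

    def test_ordering_tracks_planted_change_ratio(self):
        # more nonsynonymous changes at fixed synonymous -> higher Ka/Ks
        ratios = []
        for nonsyn in (2, 8, 20):
            a, b = sd.generate_cds_pair(
                sd.DivergencePlan("p", 400, 12, nonsyn, 31)
            )
            ratios.append(de.ng86_ka_ks(a, b).ratio)
        assert ratios == sorted(ratios)


class TestSelectionCall:
    @pytest.mark.parametrize(
        "ka,ks,ratio,call",
        [
            (0.044, 0.143, 0.308, "purifying"),
            (0.095, 0.067, 1.418, "positive"),
            (0.0, 0.1, 0.0, "purifying"),
        ],
    )
    def test_published_examples(self, ka, ks, ratio, call):
        assert de.selection_call(ka, ks) == call
        assert round(ka / ks, 3) == ratio

    def test_neutral_and_undefined(self):
        assert de.selection_call(0.1, 0.1) == "neutral"
        assert de.selection_call(0.1, 0.0) == "undefined"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            de.selection_call(-0.1, 0.2)


class TestDating:
    @pytest.mark.parametrize(
        "ks,expected", [(0.143, 11.0), (0.965, 74.23), (0.0, 0.0)]
    )
    def test_grass_clock_examples(self, ks, expected):
        assert round(de.duplication_date(ks), 2) == expected

    def test_linear_and_monotone_in_ks(self):
        assert de.duplication_date(0.2) == pytest.approx(2 * de.duplication_date(0.1))
        assert de.duplication_date(0.3) > de.duplication_date(0.2)

    def test_halving_lambda_doubles_date(self):
        p1 = de.EvolutionParams(6.5e-9)
        p2 = de.EvolutionParams(3.25e-9)
        assert de.duplication_date(0.5, p2) == pytest.approx(
            2 * de.duplication_date(0.5, p1)
        )

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            de.EvolutionParams(0.0)


class TestPublishedTable:
    def test_ratio_column_reproduced_to_three_decimals(self, table1):
        out = de.pair_report(table1)
        assert (out["ratio"] == table1["reported_ratio"]).all()

    def test_date_column_reproduced_to_two_decimals(self, table1):
        out = de.pair_report(table1)
        assert (out["date_mya"] == table1["reported_date_mya"]).all()

    def test_selection_column_matches_purifying_flags(self, table1):
        out = de.pair_report(table1)
        got = out["selection"] == "purifying"
        want = table1["reported_purifying"] == "Yes"
        assert (got == want).all()
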