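"""PWM construction, exact score distributions, threshold calibration,
scanning, enrichment statistics, and reporting."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from rkit.fixtures import FixtureSpec, consensus_motif, make_genome
from rkit.io import ChromTable, GeneSet
from rkit.motif import (
    EnrichmentRow,
    Motif,
    MotifSet,
    associate_genes,
    bh_adjust,
    build_pwm,
    discretize,
    enrich_gene_assoc,
    enrich_input_vs_background,
    enrich_promoters,
    fisher_enrichment_p,
    match_regions,
    promoter_region,
    read_report_tsv,
    report,
    reverse_complement_pwm,
    scan,
    score_distribution,
    threshold_for_fpr,
)
from rkit.regions import Region, RegionSet

BASES = "ACGT"


def random_motif(rng, L, peaked=True):
    if peaked:
        counts = rng.integers(0, 4, size=(4, L)).astype(float)
        counts[rng.integers(0, 4, size=L), np.arange(L)] += rng.integers(5, 30, size=L)
    else:
        counts = rng.integers(0, 20, size=(4, L)).astype(float)
    return Motif(f"R{rng.integers(1e9)}", "rand", counts)


def enumerate_pmf(motif, granularity=0.01):
    """Brute-force background pmf over all 4^L sequences (discretized)."""
    grid = discretize(motif.pwm, granularity)
    bg = motif.background
    pmf = {}
    L = grid.shape[1]
    for word in itertools.product(range(4), repeat=L):
        s = int(sum(grid[b, j] for j, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        pmf[s] = pmf.get(s, 0.0) + p
    return pmf


def enumerated_tail(pmf, t_grid):
    return sum(p for s, p in pmf.items() if s >= t_grid)


class TestBuildPwm:
    def test_uniform_column_scores_zero_bits(self):
        m = build_pwm(Motif("M", "M", np.ones((4, 3))))
        np.testing.assert_allclose(m.pwm, 0.0, atol=1e-12)

    def test_single_base_column_arithmetic(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 10
        m = build_pwm(Motif("M", "M", counts), pseudocount=1.0)
        want = np.log2((10.25 / 11) / 0.25)
        assert m.pwm[0, 0] == pytest.approx(want)

    def test_limit_converges_to_log_odds_of_frequency(self):
        base = np.array([[6.0, 0], [2, 8], [1, 0], [1, 0]])
        scores = []
        for scale in (1, 10, 1000, 1e6):
            m = build_pwm(Motif("M", "M", base * scale))
            scores.append(m.pwm[0, 0])
        assert scores[-1] == pytest.approx(np.log2(0.6 / 0.25), rel=1e-4)
        diffs = np.abs(np.array(scores) - np.log2(0.6 / 0.25))
        assert (np.diff(diffs) <= 1e-12).all()

    def test_nonuniform_background(self):
        bg = [0.2, 0.3, 0.3, 0.2]
        m = build_pwm(Motif("M", "M", np.ones((4, 2))), background=bg)
        # uniform counts vs skewed background: rare bases score up
        assert m.pwm[0, 0] > 0 > m.pwm[1, 0]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            Motif("M", "M", -np.ones((4, 2)))
        with pytest.raises(ValueError):
            Motif("M", "M", np.ones((3, 2)))
        with pytest.raises(ValueError):
            Motif("M", "M", np.ones((4, 2)), background=np.array([0.5, 0.5, 0.0, 0.0]))


class TestScoreDistribution:
    def test_trivial_single_uniform_column(self):
        m = build_pwm(Motif("M", "M", np.ones((4, 1))))
        d = score_distribution(m)
        assert d.probs.sum() == pytest.approx(1.0)
        assert len(d.probs) == 1 and d.offset == 0

    @pytest.mark.parametrize("L", [2, 4, 6])
    @pytest.mark.parametrize("peaked", [True, False])
    def test_matches_enumeration_exactly(self, rng, L, peaked):
        m = build_pwm(random_motif(rng, L, peaked))
        d = score_distribution(m)
        pmf = enumerate_pmf(m)
        got = {d.offset + i: p for i, p in enumerate(d.probs) if p > 0}
        assert set(got) == set(s for s, p in pmf.items() if p > 0)
        for s, p in pmf.items():
            if p > 0:
                assert got[s] == pytest.approx(p, abs=1e-12)

    def test_nonuniform_background_enumeration(self, rng):
        bg = [0.1, 0.4, 0.4, 0.1]
        m = build_pwm(random_motif(rng, 5), background=bg)
        d = score_distribution(m)
        pmf = enumerate_pmf(m)
        for i, p in enumerate(d.probs):
            s = d.offset + i
            assert p == pytest.approx(pmf.get(s, 0.0), abs=1e-12)


class TestThreshold:
    def test_fpr_one_gives_minimum_score(self, rng):
        m = build_pwm(random_motif(rng, 4))
        d = score_distribution(m)
        res = threshold_for_fpr(m, fpr=1.0)
        assert res.threshold == pytest.approx(d.grid_scores[0])

    def test_deterministic_motif_tail_boundary(self):
        # one base per column, tiny pseudocount: only the consensus scores high
        m = build_pwm(consensus_motif("ACGTA"), pseudocount=1e-9)
        res3 = threshold_for_fpr(m, fpr=1e-3)
        assert res3.reachable
        # only the exact consensus (probability 4^-5 ~ 9.77e-4) passes
        assert res3.attained_fpr == pytest.approx(4 ** -5, rel=1e-6)
        assert [h.strand for h in scan("ACGTA", m)] == ["+"]
        assert scan("ACGTT", m) == []  # one mismatch is below threshold
        res4 = threshold_for_fpr(m, fpr=1e-4)
        assert not res4.reachable
        assert scan("ACGTA", m, res4.threshold) == []

    @pytest.mark.parametrize("fpr", [1e-2, 1e-3])
    def test_threshold_brackets_fpr_against_enumeration(self, rng, fpr):
        for _ in range(10):
            m = build_pwm(random_motif(rng, 6))
            res = threshold_for_fpr(m, fpr=fpr)
            pmf = enumerate_pmf(m)
            t_grid = round(res.threshold / 0.01)
            if res.reachable:
                assert enumerated_tail(pmf, t_grid) <= fpr
                assert enumerated_tail(pmf, t_grid - 1) > fpr
            else:
                assert enumerated_tail(pmf, t_grid) == 0.0


class TestScan:
    def _motif(self):
        return build_pwm(consensus_motif("ACGGT"))

    def test_consensus_found_on_plus_strand(self):
        m = self._motif()
        threshold_for_fpr(m, 1e-3)
        hits = scan("TTTACGGTTTT", m)
        assert [(h.start, h.strand) for h in hits] == [(3, "+")]
        assert hits[0].score == pytest.approx(m.max_score())

    def test_reverse_complement_found_on_minus_strand(self):
        m = self._motif()
        threshold_for_fpr(m, 1e-3)
        hits = scan("TTTACCGTTTT", m)  # revcomp(ACGGT) = ACCGT
        assert [(h.start, h.strand) for h in hits] == [(3, "-")]

    def test_all_n_sequence_has_no_matches(self):
        m = self._motif()
        assert scan("N" * 50, m, threshold=-100.0) == []

    def test_n_windows_skipped_but_clean_windows_scored(self):
        m = self._motif()
        grid_max = 0.01 * discretize(m.pwm).max(axis=0).sum()
        hits = scan("ACGGTNNACGGT", m, threshold=grid_max)
        assert [(h.start, h.end) for h in hits] == [(0, 5), (7, 12)]
        assert all(h.score >= grid_max for h in hits)

    def test_revcomp_sequence_mirrors_matches(self, rng):
        from rkit.fixtures import revcomp

        m = build_pwm(random_motif(rng, 5))
        seq = "".join(rng.choice(list(BASES), size=300))
        thr = m.max_score() - 3.0
        fwd = scan(seq, m, thr)
        rev = scan(revcomp(seq), m, thr)
        n = len(seq)
        mirrored = sorted(
            (n - h.end, n - h.start, "+" if h.strand == "-" else "-") for h in rev
        )
        assert mirrored == sorted((h.start, h.end, h.strand) for h in fwd)

    def test_short_sequence_yields_nothing(self):
        m = self._motif()
        assert scan("ACG", m, threshold=-100) == []


class TestMatchRegions:
    def test_planted_consensus_recovered_at_genomic_coordinates(self):
        motif = consensus_motif("ACGTAGGCAT", motif_id="P1")
        loci = [("chr1", p, s) for p, s in [(500, "+"), (2000, "-"), (3500, "+")]]
        spec = FixtureSpec(
            seed=8, genome=[("chr1", 5000)], planted_motifs=[(motif, loci)]
        )
        seqs = make_genome(spec)
        genome = {c: s for c, s in seqs.items()}
        regions = RegionSet([Region("chr1", 0, 5000)])
        mpbs = match_regions(regions, genome, MotifSet([motif]), fpr=1e-4)
        found = {(r.start, r.strand) for r in mpbs}
        assert {(500, "+"), (2000, "-"), (3500, "+")} <= found
        for r in mpbs:
            assert r.name == "P1"
            assert r.score == pytest.approx(
                round(100 * motif.max_score())
            ) or r.score <= round(100 * motif.max_score())

    def test_empty_region_set(self):
        motif = build_pwm(consensus_motif("ACGT"))
        out = match_regions(RegionSet(), {"chr1": "ACGT"}, MotifSet([motif]))
        assert len(out) == 0


def hypergeom_sf_oracle(a, b, c, d):
    """Exact Fraction-arithmetic upper-tail hypergeometric sum."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


class TestFisherBh:
    def test_fisher_worked_table(self):
        assert fisher_enrichment_p(2, 8, 8, 2) == pytest.approx(
            hypergeom_sf_oracle(2, 8, 8, 2), rel=1e-12
        )

    def test_fisher_matches_oracle_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            assert fisher_enrichment_p(a, b, c, d) == pytest.approx(
                hypergeom_sf_oracle(a, b, c, d), rel=1e-12, abs=1e-300
            )

    def test_bh_single_and_equal_p(self):
        assert bh_adjust([0.03]).tolist() == [0.03]
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_bh_hand_stepped_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, want, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), want, rtol=1e-12)

    def test_bh_monotone_and_bounded(self, rng):
        p = np.sort(rng.random(30))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()


class TestEnrichment:
    def _setup(self, seed=21):
        target_motif = consensus_motif("ACGTAGGCATCG", motif_id="GOOD")
        decoy = consensus_motif("TTATCCGGATAA", motif_id="DECOY")
        table = ChromTable()
        table["chr1"] = 60_000
        # plant GOOD in 80% of the target regions
        targets = [Region("chr1", 1000 * i + 100, 1000 * i + 300) for i in range(20)]
        loci = [("chr1", t.start + 50, "+") for t in targets[:16]]
        spec = FixtureSpec(
            seed=seed, genome=[("chr1", 60_000)],
            planted_motifs=[(target_motif, loci)],
        )
        genome = make_genome(spec)
        return table, genome, RegionSet(targets), MotifSet([target_motif, decoy])

    def test_planted_motif_ranks_first(self):
        table, genome, targets, motifs = self._setup()
        rows = enrich_input_vs_background(
            targets, None, genome, motifs, fpr=1e-4, chrom_table=table, seed=1,
            min_background=200,
        )
        assert rows[0].motif_id == "GOOD"
        assert rows[0].a >= 16
        assert rows[0].adjusted_p < 1e-6
        assert rows[0].adjusted_p >= rows[0].p_value

    def test_target_equals_background_not_significant(self):
        table, genome, targets, motifs = self._setup()
        rows = enrich_input_vs_background(
            targets, targets, genome, motifs, fpr=1e-4
        )
        assert all(r.p_value > 0.4 for r in rows)  # identical margins

    def test_table_margins_consistent(self):
        table, genome, targets, motifs = self._setup()
        rows = enrich_input_vs_background(
            targets, None, genome, motifs, chrom_table=table, seed=2,
            min_background=100,
        )
        for r in rows:
            assert r.a + r.b == len(targets)
            assert r.c + r.d == 100
        assert rows == sorted(
            rows, key=lambda r: (r.adjusted_p, r.p_value, r.motif_id)
        )

    def test_empty_target_rejected(self):
        table, genome, _, motifs = self._setup()
        with pytest.raises(ValueError):
            enrich_input_vs_background(RegionSet(), None, genome, motifs,
                                       chrom_table=table)


class TestGeneAssociation:
    def _genes(self):
        return GeneSet([
            Region("chr1", 10_000, 14_000, "geneA", strand="+"),
            Region("chr1", 40_000, 44_000, "geneB", strand="-"),
        ])

    def test_promoter_window_strand_aware(self):
        genes = self._genes()
        pa = promoter_region(genes.gene("geneA"), 1000)
        assert (pa.start, pa.end) == (9000, 10_000)
        pb = promoter_region(genes.gene("geneB"), 1000)
        assert (pb.start, pb.end) == (44_000, 45_000)

    def test_region_inside_gene_body_associates(self):
        labels = associate_genes(
            RegionSet([Region("chr1", 11_000, 11_200)]), self._genes()
        )
        assert labels == ["geneA"]

    def test_promoter_proximal_upstream_region(self):
        labels = associate_genes(
            RegionSet([Region("chr1", 9400, 9600)]), self._genes(), promoter_len=1000
        )
        assert labels == ["geneA"]

    def test_far_region_unassociated(self):
        labels = associate_genes(
            RegionSet([Region("chr1", 200_000, 200_100)]), self._genes(),
            distal_len=50_000,
        )
        assert labels == [None]

    def test_nearest_gene_wins(self):
        labels = associate_genes(
            RegionSet([Region("chr1", 20_000, 20_100)]), self._genes(),
            distal_len=50_000,
        )
        assert labels == ["geneA"]  # 6 kb away vs 19.9 kb

    def test_gene_assoc_enrichment_flags_planted_motif(self):
        motif = consensus_motif("ACGTAGGCATCG", motif_id="NEAR")
        decoy = consensus_motif("TTATCCGGATAA", motif_id="FAR")
        genes = self._genes()
        near = [Region("chr1", 11_000 + 100 * i, 11_000 + 100 * i + 60) for i in range(8)]
        far = [Region("chr1", 100_000 + 200 * i, 100_000 + 200 * i + 60) for i in range(8)]
        spec = FixtureSpec(
            seed=4, genome=[("chr1", 150_000)],
            planted_motifs=[(motif, [("chr1", r.start + 10, "+") for r in near])],
        )
        genome = make_genome(spec)
        rows = enrich_gene_assoc(
            RegionSet(near + far), genes, ["geneA"], genome,
            MotifSet([motif, decoy]), fpr=1e-4, distal_len=5_000,
        )
        assert rows[0].motif_id == "NEAR"
        assert rows[0].a == 8 and rows[0].p_value < 1e-3

    def test_gene_assoc_error_cases(self):
        genes = self._genes()
        regions = RegionSet([Region("chr1", 11_000, 11_100)])
        with pytest.raises(ValueError):
            enrich_gene_assoc(regions, genes, [], {}, MotifSet())
        with pytest.raises(ValueError):  # every region associated -> no background
            enrich_gene_assoc(regions, genes, ["geneA", "geneB"], {}, MotifSet())


class TestPromoterEnrichment:
    def test_planted_promoter_motif_top_ranked(self):
        motif = consensus_motif("ACGTAGGCATCG", motif_id="PROM")
        genes = GeneSet(
            [Region("chr1", 5000 + 3000 * i, 6000 + 3000 * i, f"g{i}",
                    strand="+") for i in range(10)]
        )
        listed = [f"g{i}" for i in range(5)]
        loci = [("chr1", genes.gene(g).start - 500, "+") for g in listed]
        spec = FixtureSpec(
            seed=6, genome=[("chr1", 40_000)], planted_motifs=[(motif, loci)]
        )
        genome = make_genome(spec)
        rows = enrich_promoters(listed, genes, genome, MotifSet([motif]),
                                promoter_len=1000, fpr=1e-4)
        assert rows[0].motif_id == "PROM"
        assert rows[0].a == 5 and rows[0].c == 0

    def test_unknown_gene_list_rejected(self):
        genes = GeneSet([Region("chr1", 100, 500, "gX", strand="+")])
        with pytest.raises(ValueError):
            enrich_promoters(["nope"], genes, {}, MotifSet())
        with pytest.raises(ValueError):  # all genes listed -> empty background
            enrich_promoters(["gX"], genes, {}, MotifSet())

    def test_one_bp_promoters(self):
        genes = GeneSet([
            Region("chr1", 100, 500, "gA", strand="+"),
            Region("chr1", 900, 1200, "gB", strand="-"),
        ])
        pa = promoter_region(genes.gene("gA"), 1)
        pb = promoter_region(genes.gene("gB"), 1)
        assert len(pa) == 1 and len(pb) == 1


class TestReport:
    def _rows(self):
        return [
            EnrichmentRow("M1", 10, 5, 2, 13, 13.0, 0.001, 0.002),
            EnrichmentRow("M2", 3, 12, 4, 11, 0.7, 0.8, 0.8),
        ]

    def test_empty_rows_valid_outputs(self, tmp_path):
        report([], tmp_path / "r.html")
        html = (tmp_path / "r.html").read_text()
        assert "<table>" in html
        assert read_report_tsv(tmp_path / "r.tsv") == []

    def test_tsv_roundtrip_and_html_rows(self, tmp_path):
        rows = self._rows()
        report(rows, tmp_path / "r.html", tmp_path / "r.tsv")
        back = read_report_tsv(tmp_path / "r.tsv")
        assert back == rows
        html = (tmp_path / "r.html").read_text()
        assert html.count("<tr>") == 1 + len(rows)  # header + one per motif
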