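import math
import random

import numpy as np
import pandas as pd
import pytest

from teactivity import (
    FunctionalSplit,
    GenomicInterval,
    assemble_matrix,
    filter_subfamilies,
    gene_susceptibility_hard,
    gene_susceptibility_weighted,
    kernel_weight,
    merge_fragments,
    split_functional,
)
from teactivity.susceptibility import FUNCTIONAL_SUFFIX, NONFUNCTIONAL_SUFFIX

from conftest import make_gene, make_te


class TestKernel:
    def test_maximum_at_zero_distance(self):
        assert kernel_weight(0, 1e5) == 1.0

    def test_strictly_decreasing(self):
        d = np.linspace(0, 1e6, 50)
        w = kernel_weight(d, 2.5e5)
        assert np.all(np.diff(w) < 0)

    def test_closed_form(self):
        assert kernel_weight(1e5, 1e5) == pytest.approx(math.exp(-0.5))
        assert kernel_weight(3e5, 1e5) == pytest.approx(math.exp(-4.5))

    @pytest.mark.parametrize("L", [0, -1.0])
    def test_nonpositive_bandwidth_rejected(self, L):
        with pytest.raises(ValueError):
            kernel_weight(100, L)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_weight(-1, 1e5)


class TestHardCounts:
    def test_te_inside_window_counts(self, toy_genes):
        gA = toy_genes[0]  # promoter (99500, 100500), window (49500, 150500)
        tes = [make_te("chr1", 120_000, 120_500, "LTR5")]
        assert gene_susceptibility_hard(gA, tes) == {"LTR5": 1}

    def test_te_touching_exon_is_excluded(self, toy_genes):
        gA = toy_genes[0]  # exon (101000, 102000)
        tes = [make_te("chr1", 100_600, 101_001, "LTR5")]  # 1 bp into exon
        assert gene_susceptibility_hard(gA, tes) == {}

    def test_te_overlapping_promoter_is_excluded(self, toy_genes):
        gA = toy_genes[0]
        tes = [make_te("chr1", 100_400, 100_700, "LTR5")]
        assert gene_susceptibility_hard(gA, tes) == {}

    def test_te_just_outside_window_does_not_count(self, toy_genes):
        gA = toy_genes[0]
        inside = make_te("chr1", 150_400, 150_900, "LTR5")  # overlaps window end
        outside = make_te("chr1", 150_500, 150_900, "SVA_B")  # abuts window end
        assert gene_susceptibility_hard(gA, [inside, outside]) == {"LTR5": 1}

    def test_exclusion_is_per_gene(self, toy_genes):
        # a TE inside gB's exon may still count for neighbouring gA
        gA, gB = toy_genes[0], toy_genes[1]
        tes = [make_te("chr1", 301_200, 301_700, "SVA_B")]
        assert gene_susceptibility_hard(gB, tes) == {}
        assert gene_susceptibility_hard(gA, tes, flank=250_000) == {"SVA_B": 1}


class TestWeighted:
    def test_excluded_te_contributes_zero_even_at_center(self, toy_genes):
        gA = toy_genes[0]
        (prom,) = gA.promoters
        te = make_te("chr1", prom.center - 50, prom.center + 50, "LTR5")
        assert gene_susceptibility_weighted(gA, [te], L=1e5) == {}

    def test_single_te_at_distance_L(self, toy_genes):
        gA = toy_genes[0]
        (prom,) = gA.promoters
        L = 50_000.0
        te = make_te("chr1", prom.center + int(L) - 100, prom.center + int(L) + 100,
                     "LTR5")
        out = gene_susceptibility_weighted(gA, [te], L=L)
        assert out["LTR5"] == pytest.approx(math.exp(-0.5), abs=1e-6)

    def test_nearest_promoter_is_used(self):
        g = make_gene("g2p", "chr1", [100_000, 500_000], [(900_000, 901_000)])
        assert len(g.promoters) == 2
        te = make_te("chr1", 499_000, 499_400, "LTR5")
        out = gene_susceptibility_weighted(g, [te], L=1e4)
        d = abs(te.interval.center - g.promoters[1].center)
        assert out["LTR5"] == pytest.approx(math.exp(-(d**2) / (2 * 1e8)))

    def test_tad_restriction_zeroes_cross_domain_weights(self, toy_genes):
        gA = toy_genes[0]
        te = make_te("chr1", 180_000, 180_400, "LTR5")
        tads = [GenomicInterval("chr1", 0, 150_000),
                GenomicInterval("chr1", 150_000, 400_000)]
        free = gene_susceptibility_weighted(gA, [te], L=1e5)
        restricted = gene_susceptibility_weighted(gA, [te], L=1e5, tads=tads)
        assert free["LTR5"] > 0
        assert restricted == {}

    def test_center_in_no_tad_gets_zero(self, toy_genes):
        gA = toy_genes[0]
        te = make_te("chr1", 120_000, 120_400, "LTR5")
        tads = [GenomicInterval("chr1", 0, 110_000)]  # TE center outside all TADs
        assert gene_susceptibility_weighted(gA, [te], L=1e5, tads=tads) == {}

    def test_monotone_in_L_and_bounded_by_count(self, toy_genes):
        rng = random.Random(5)
        tes = [make_te("chr1", s, s + 400, "LTR5")
               for s in rng.sample(range(0, 900_000, 700), 30)]
        gA = toy_genes[0]
        previous = None
        for L in [1e3, 1e4, 1e5, 1e6]:
            val = gene_susceptibility_weighted(gA, tes, L=L).get("LTR5", 0.0)
            if previous is not None:
                assert val >= previous - 1e-12
            previous = val
        assert previous <= len(tes)


def brute_force_matrix(genes, tes, mode, flank=50_000, L=None, tads=None):
    """Literal per-(gene, TE) application of the exclusion/distance rules."""
    subfams = sorted({t.subfamily for t in tes})
    mat = pd.DataFrame(
        0.0,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=subfams,
    )
    for g in genes:
        windows = g.cis_windows(flank)
        for te in tes:
            iv = te.interval
            if iv.chrom != g.chrom:
                continue
            if any(iv.overlaps(p) for p in g.promoters):
                continue
            if any(iv.overlaps(e) for e in g.exon_union):
                continue
            if mode == "hard":
                if any(iv.overlaps(w) for w in windows):
                    mat.loc[g.gene_id, te.subfamily] += 1
            else:
                d, prom = min(
                    (abs(iv.center - p.center), p) for p in g.promoters
                )
                w = math.exp(-(d**2) / (2 * L**2))
                if tads is not None:
                    def tad_of(pos):
                        for i, t in enumerate(tads):
                            if t.chrom == g.chrom and t.start <= pos < t.end:
                                return i
                        return None
                    t1, t2 = tad_of(iv.center), tad_of(prom.center)
                    if t1 is None or t1 != t2:
                        w = 0.0
                mat.loc[g.gene_id, te.subfamily] += w
    return mat


def random_fixture(seed, n_genes=12, n_tes=80):
    rng = random.Random(seed)
    genes = []
    for i in range(n_genes):
        chrom = rng.choice(["chr1", "chr2"])
        anchor = rng.randrange(60_000, 2_000_000)
        tss = [anchor] + [anchor + rng.randrange(100, 3000)
                          for _ in range(rng.randrange(0, 2))]
        exons = [(anchor + 1000, anchor + 1000 + rng.randrange(200, 2000))]
        genes.append(make_gene(f"g{i}", chrom, tss, exons))
    tes = []
    for k in range(n_tes):
        chrom = rng.choice(["chr1", "chr2"])
        start = rng.randrange(0, 2_100_000)
        tes.append(make_te(chrom, start, start + rng.randrange(100, 2000),
                           rng.choice(["SVA_B", "LTR5", "AluY"]),
                           strand=rng.choice("+-"), instance=f"i{k}"))
    return genes, merge_fragments(tes)


class TestAssembleMatrix:
    def test_no_tes_yields_zero_matrix(self, toy_genes):
        N = assemble_matrix(toy_genes, [])
        assert N.values.shape == (3, 0)
        assert N.gene_ids == ["gA", "gB", "gC"]

    def test_duplicate_gene_ids_rejected(self, toy_genes):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix(toy_genes + [toy_genes[0]], [])

    def test_rows_follow_gene_order_columns_sorted(self, toy_genes):
        tes = [make_te("chr1", 120_000, 120_400, "Z_sub"),
               make_te("chr1", 130_000, 130_400, "A_sub")]
        N = assemble_matrix(toy_genes, tes)
        assert N.gene_ids == ["gA", "gB", "gC"]
        assert N.subfamilies == ["A_sub", "Z_sub"]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_hard_matches_brute_force(self, seed):
        genes, tes = random_fixture(seed)
        N = assemble_matrix(genes, tes, mode="hard")
        expected = brute_force_matrix(genes, tes, "hard")
        pd.testing.assert_frame_equal(
            N.values.astype(float), expected, check_like=True
        )

    @pytest.mark.parametrize("seed,L", [(4, 1e4), (5, 2.5e5)])
    def test_weighted_matches_brute_force(self, seed, L):
        genes, tes = random_fixture(seed)
        N = assemble_matrix(genes, tes, mode="weighted", L=L)
        expected = brute_force_matrix(genes, tes, "weighted", L=L)
        pd.testing.assert_frame_equal(N.values, expected, check_like=True,
                                      atol=1e-10)

    def test_weighted_with_tads_matches_brute_force(self):
        genes, tes = random_fixture(6)
        tads = [GenomicInterval("chr1", 0, 1_000_000),
                GenomicInterval("chr1", 1_000_000, 2_200_000),
                GenomicInterval("chr2", 0, 2_200_000)]
        N = assemble_matrix(genes, tes, mode="weighted", L=1e5, tads=tads)
        expected = brute_force_matrix(genes, tes, "weighted", L=1e5, tads=tads)
        pd.testing.assert_frame_equal(N.values, expected, check_like=True,
                                      atol=1e-10)

    def test_tad_restriction_never_increases_entries(self):
        genes, tes = random_fixture(7)
        tads = [GenomicInterval("chr1", 0, 1_500_000),
                GenomicInterval("chr2", 500_000, 2_200_000)]
        free = assemble_matrix(genes, tes, mode="weighted", L=1e5)
        restricted = assemble_matrix(genes, tes, mode="weighted", L=1e5, tads=tads)
        assert (restricted.values <= free.values + 1e-12).all().all()

    def test_weighted_approaches_hard_for_close_tes(self, toy_genes):
        # all TEs within 0.01 L of a promoter: every retained weight ~ 1
        gA = toy_genes[0]
        (prom,) = gA.promoters
        tes = [make_te("chr1", prom.center + off, prom.center + off + 200, "LTR5",
                       instance=f"i{off}")
               for off in (600, 1200, 1800)]
        hard = assemble_matrix([gA], tes, mode="hard", flank=50_000)
        weighted = assemble_matrix([gA], tes, mode="weighted", L=1e9)
        assert np.allclose(weighted.values, hard.values.astype(float), atol=1e-4)


class TestFilterSubfamilies:
    def _matrix(self, sums):
        genes = [make_gene("g1", "chr1", [10_000], [(11_000, 12_000)])]
        values = pd.DataFrame([sums], index=["g1"])
        from teactivity import SusceptibilityMatrix

        return SusceptibilityMatrix(values=values, mode="weighted", bandwidth_L=1e5)

    def test_strict_threshold(self):
        N = self._matrix({"a": 149.9, "b": 150.0, "c": 151.0})
        kept = filter_subfamilies(N, min_total=150)
        assert kept.subfamilies == ["b", "c"]

    def test_zero_threshold_is_identity(self):
        N = self._matrix({"a": 0.5, "b": 3.0})
        assert filter_subfamilies(N, min_total=0).subfamilies == ["a", "b"]

    def test_all_dropped_is_an_error(self):
        with pytest.raises(ValueError):
            filter_subfamilies(self._matrix({"a": 1.0}), min_total=150)


class TestSplitFunctional:
    def _fixture(self):
        rng = random.Random(9)
        genes = [make_gene(f"g{i}", "chr1", [i * 200_000 + 100_000],
                           [(i * 200_000 + 101_000, i * 200_000 + 102_000)])
                 for i in range(8)]
        tes = []
        for k in range(60):
            start = rng.randrange(0, 1_700_000)
            tes.append(make_te("chr1", start, start + 500,
                               rng.choice(["SVA_B", "LTR5"]), instance=f"i{k}"))
        return genes, merge_fragments(tes)

    def test_conservation_and_label_scheme_hard(self):
        genes, tes = self._fixture()
        reference = assemble_matrix(genes, tes, mode="hard")
        functional = [t.interval for t in tes[::3]]
        split = FunctionalSplit(functional_ranges=functional,
                                protected_subfamilies={"SVA_B", "LTR5"})
        N = split_functional(genes, tes, split, reference)
        for sf in reference.subfamilies:
            total = (N.values[sf + FUNCTIONAL_SUFFIX]
                     + N.values[sf + NONFUNCTIONAL_SUFFIX])
            assert (total == reference.values[sf]).all()

    def test_conservation_weighted(self):
        genes, tes = self._fixture()
        reference = assemble_matrix(genes, tes, mode="weighted", L=2.5e5)
        split = FunctionalSplit(functional_ranges=[t.interval for t in tes[::4]],
                                protected_subfamilies={"SVA_B", "LTR5"})
        N = split_functional(genes, tes, split, reference)
        for sf in reference.subfamilies:
            total = (N.values[sf + FUNCTIONAL_SUFFIX]
                     + N.values[sf + NONFUNCTIONAL_SUFFIX]).to_numpy()
            assert np.allclose(total, reference.values[sf].to_numpy(), atol=1e-9)

    def test_collapse_rule_below_100(self):
        genes, tes = self._fixture()
        reference = assemble_matrix(genes, tes, mode="hard")
        # tiny functional fraction: only one integrant overlaps
        split = FunctionalSplit(functional_ranges=[tes[0].interval])
        N = split_functional(genes, tes, split, reference)
        assert set(N.subfamilies) == set(reference.subfamilies)
        pd.testing.assert_frame_equal(
            N.values.astype(float),
            reference.values.astype(float)[N.subfamilies],
        )

    def test_protected_subfamily_stays_split(self):
        genes, tes = self._fixture()
        reference = assemble_matrix(genes, tes, mode="hard")
        split = FunctionalSplit(functional_ranges=[tes[0].interval],
                                protected_subfamilies={tes[0].subfamily})
        N = split_functional(genes, tes, split, reference)
        sf = tes[0].subfamily
        assert sf + FUNCTIONAL_SUFFIX in N.subfamilies
        assert sf + NONFUNCTIONAL_SUFFIX in N.subfamilies

    def test_absent_subfamilies_stay_absent(self):
        genes, tes = self._fixture()
        reference = assemble_matrix(genes, tes, mode="hard")
        reference = filter_subfamilies(reference, min_total=0)
        dropped = reference.subfamilies[0]
        from teactivity import SusceptibilityMatrix

        smaller = SusceptibilityMatrix(
            values=reference.values.drop(columns=[dropped]),
            mode="hard", flank=50_000,
        )
        split = FunctionalSplit(functional_ranges=[t.interval for t in tes],
                                protected_subfamilies={s for s in reference.subfamilies})
        N = split_functional(genes, tes, split, smaller)
        assert not any(c.startswith(dropped + ".") for c in N.subfamilies)

    def test_empty_functional_ranges_rejected(self):
        with pytest.raises(ValueError):
            FunctionalSplit(functional_ranges=[])
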