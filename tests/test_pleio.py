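"""LD loci, interval algebra and the pleiotropy statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twaspleio import pleio
from twaspleio.formats import Locus, ValidationError, VariantKey

from conftest import make_panel


class TestLdR2:
    def test_variant_with_itself(self):
        panel = make_panel(np.array([[0.0], [1.0], [2.0]]))
        assert pleio.ld_r2(panel, "v0", "v0") == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        panel = make_panel(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
        assert pleio.ld_r2(panel, "v0", "v1") == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        panel = make_panel(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]))
        assert pleio.ld_r2(panel, "v0", "v1") == 0.0

    def test_constant_vector_defined_as_zero(self):
        panel = make_panel(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert pleio.ld_r2(panel, "v0", "v1") == 0.0

    def test_absent_variant_is_error(self):
        panel = make_panel(np.array([[1.0], [0.0]]))
        with pytest.raises(ValidationError, match="absent"):
            pleio.ld_r2(panel, "v0", "nope")


class TestBuildR2Locus:
    def test_isolated_lead_gives_point_locus(self, rng):
        panel = make_panel(rng.integers(0, 3, size=(50, 3)).astype(float),
                           positions=[1000, 2000, 3000])
        lead = panel.variants[1]
        locus = pleio.build_r2_locus(panel, lead)
        # random independent columns at n=50: r^2 ~ 1/n, far below 0.5
        assert (locus.start, locus.end) == (2000, 2000)

    def test_linked_set_spans_min_to_max(self):
        base = np.tile([0.0, 1.0, 2.0, 1.0], 5)
        unlinked = np.ones_like(base)  # constant -> r^2 defined as 0
        d = np.column_stack([base, base, unlinked, base])
        panel = make_panel(d, positions=[8000, 9500, 10000 - 1, 15000])
        lead = VariantKey("chr1", 9500, "v1", "A", "G")
        locus = pleio.build_r2_locus(panel, lead)
        assert (locus.start, locus.end) == (8000, 15000)

    def test_r2_exactly_half_excluded(self):
        # columns with r^2 exactly 0.5: [0,0,1,1] vs [0,1,1,2]
        d = np.column_stack([[0.0, 0, 1, 1], [0.0, 1, 1, 2]])
        panel = make_panel(d, positions=[1000, 2000])
        assert pleio.ld_r2(panel, "v0", "v1") == pytest.approx(0.5)
        locus = pleio.build_r2_locus(panel, panel.variants[0])
        assert (locus.start, locus.end) == (1000, 1000)

    def test_lead_absent_is_error(self):
        panel = make_panel(np.array([[1.0], [0.0]]))
        with pytest.raises(ValidationError, match="lead"):
            pleio.build_r2_locus(panel, VariantKey("chr1", 5, "zz", "A", "G"))

    def test_search_window_bounds_scan(self):
        base = np.tile([0.0, 1.0, 2.0, 1.0], 5)
        panel = make_panel(np.column_stack([base, base]), positions=[1000, 5_001_000])
        locus = pleio.build_r2_locus(panel, panel.variants[0], search_window_bp=2_000_000)
        assert (locus.start, locus.end) == (1000, 1000)


def bruteforce_merge(intervals):
    """Per-bp union oracle for small coordinates."""
    if not intervals:
        return []
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end + 1))
    out = []
    for pos in sorted(covered):
        if out and pos == out[-1][1] + 1:
            out[-1][1] = pos
        else:
            out.append([pos, pos])
    return [tuple(x) for x in out]


class TestMergeLoci:
    def test_basic_merge(self):
        loci = [Locus("chr1", 100, 200), Locus("chr1", 150, 300), Locus("chr1", 400, 500)]
        merged = pleio.merge_loci(loci)
        assert [(l.start, l.end) for l in merged] == [(100, 300), (400, 500)]

    def test_touching_inclusive_coordinates_merge(self):
        merged = pleio.merge_loci([Locus("chr1", 100, 200), Locus("chr1", 200, 300)])
        assert [(l.start, l.end) for l in merged] == [(100, 300)]

    def test_traits_union_on_merge(self):
        merged = pleio.merge_loci(
            [
                Locus("chr1", 100, 200, frozenset({"AMD"}), frozenset({"AMD"})),
                Locus("chr1", 150, 250, frozenset({"migraine"}), frozenset({"neuro"})),
            ]
        )
        assert merged[0].traits == {"AMD", "migraine"}
        assert merged[0].categories == {"AMD", "neuro"}

    def test_matches_per_bp_oracle(self, rng):
        for _ in range(200):
            k = rng.integers(1, 8)
            ivs = []
            for _ in range(k):
                s = int(rng.integers(1, 9000))
                ivs.append((s, s + int(rng.integers(0, 1000))))
            merged = pleio.merge_loci([Locus("chr1", s, e) for s, e in ivs])
            assert [(l.start, l.end) for l in merged] == bruteforce_merge(ivs)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(0, 80)),
            min_size=1, max_size=8,
        ),
        st.randoms(use_true_random=False),
    )
    def test_total_length_invariant_to_order_and_splitting(self, raw, pyrand):
        ivs = [(s, s + w) for s, w in raw]
        loci = [Locus("chr1", s, e) for s, e in ivs]
        total = sum(l.length for l in pleio.merge_loci(loci))
        shuffled = list(loci)
        pyrand.shuffle(shuffled)
        assert sum(l.length for l in pleio.merge_loci(shuffled)) == total
        # split the first interval in two adjoining pieces
        s, e = ivs[0]
        if e > s:
            mid = (s + e) // 2
            split = [Locus("chr1", s, mid), Locus("chr1", mid + 1, e)] + loci[1:]
            assert sum(l.length for l in pleio.merge_loci(split)) == total


class TestExtendLoci:
    def test_symmetric_extension(self):
        out = pleio.extend_loci([Locus("chr1", 2_000_000, 2_100_000)], 1_000_000)
        assert (out[0].start, out[0].end) == (1_000_000, 3_100_000)

    def test_start_clamped_at_one(self):
        out = pleio.extend_loci([Locus("chr1", 500_000, 600_000)], 1_000_000)
        assert out[0].start == 1

    def test_nearby_loci_merge_after_extension(self):
        loci = [Locus("chr1", 3_000_000, 3_000_000), Locus("chr1", 4_500_000, 4_500_000)]
        assert len(pleio.extend_loci(loci, 1_000_000)) == 1


class TestOverlapGenes:
    ANN = pd.DataFrame(
        [("G1", "chr1", 250, 350), ("G2", "chr1", 301, 400), ("G3", "chr2", 1, 100)],
        columns=["gene", "chrom", "start", "end"],
    )

    def test_partial_overlap_assigns(self):
        loci = [Locus("chr1", 100, 300, frozenset({"t"}), frozenset({"AMD"}))]
        table = pleio.overlap_genes(loci, self.ANN)
        assert table.categories["G1"] == {"AMD"}

    def test_adjacent_but_disjoint_not_assigned(self):
        loci = [Locus("chr1", 100, 300, frozenset({"t"}), frozenset({"AMD"}))]
        table = pleio.overlap_genes(loci, self.ANN)
        assert table.categories["G2"] == set() and not table.in_any_locus["G2"]

    def test_two_categories_make_gene_pleiotropic(self):
        loci = [
            Locus("chr1", 100, 300, frozenset({"a"}), frozenset({"AMD"})),
            Locus("chr1", 320, 360, frozenset({"b"}), frozenset({"neuro"})),
        ]
        table = pleio.overlap_genes(loci, self.ANN)
        assert table.pleiotropic["G1"] and table.categories["G1"] == {"AMD", "neuro"}


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive enumeration over tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pr = stats.hypergeom.pmf(x, n, col1, row1)
        if pr <= obs * (1 + 1e-9):
            total += pr
    return min(total, 1.0)


class TestCategoryEnrichment:
    def _setup(self, target_hits, target_miss, other_hits, other_miss):
        genes, cats = {}, {}
        target = set()
        i = 0
        for cnt, is_target, hit in [
            (target_hits, True, True), (target_miss, True, False),
            (other_hits, False, True), (other_miss, False, False),
        ]:
            for _ in range(cnt):
                g = f"g{i}"; i += 1
                cats[g] = {"X"} if hit else set()
                if is_target:
                    target.add(g)
        table = pleio.OverlapTable(categories=cats)
        return target, set(cats), table

    def test_degenerate_column_margin_p_one(self):
        target, universe, table = self._setup(0, 10, 0, 90)
        *_, p = pleio.category_enrichment(target, universe, table, "X")
        assert p == 1.0

    def test_balanced_table_p_one(self):
        target, universe, table = self._setup(1, 1, 1, 1)
        *_, p = pleio.category_enrichment(target, universe, table, "X")
        assert p == pytest.approx(1.0)

    def test_diagonal_table_p_one_third(self):
        target, universe, table = self._setup(2, 0, 0, 2)
        a, b, c, d, _, p = pleio.category_enrichment(target, universe, table, "X")
        assert (a, b, c, d) == (2, 0, 0, 2)
        assert p == pytest.approx(1 / 3)

    def test_non_subset_target_rejected(self):
        target, universe, table = self._setup(1, 1, 1, 1)
        with pytest.raises(ValidationError):
            pleio.category_enrichment(target | {"alien"}, universe, table, "X")

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            target, universe, table = self._setup(a, b, c, d)
            *_, p = pleio.category_enrichment(target, universe, table, "X")
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney by enumeration of all group assignments."""
    combined = list(x) + list(y)
    nx = len(x)

    def ustat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    obs = ustat(x, y)
    mu = nx * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), nx):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        total += 1
        if abs(ustat(xs, ys) - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


class TestTissueCountComparison:
    def _frame(self, counts):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(counts))], "n_significant_tissues": counts}
        )

    def _table(self, n_in, n_out):
        cats = {f"g{i}": ({"X"} if i < n_in else set()) for i in range(n_in + n_out)}
        return pleio.OverlapTable(categories=cats)

    def test_separated_groups_exact_p(self):
        frame = self._frame([1, 2, 3, 4, 5, 6])
        u, p = pleio.tissue_count_comparison(frame, self._table(3, 3))
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        frame = self._frame([1, 2, 3, 1, 2, 3])
        _, p = pleio.tissue_count_comparison(frame, self._table(3, 3))
        assert p == pytest.approx(1.0)

    def test_group_label_swap_invariance(self):
        frame = self._frame([4, 1, 5, 2, 0, 3])
        _, p1 = pleio.tissue_count_comparison(frame, self._table(3, 3))
        frame_sw = self._frame([2, 0, 3, 4, 1, 5])
        _, p2 = pleio.tissue_count_comparison(frame_sw, self._table(3, 3))
        assert p1 == pytest.approx(p2)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            pleio.tissue_count_comparison(self._frame([1, 2]), self._table(2, 0))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            nx = int(rng.integers(2, 5))
            ny = int(rng.integers(2, 5))
            vals = rng.choice(20, size=nx + ny, replace=False)  # no ties
            frame = self._frame(list(vals))
            _, p = pleio.tissue_count_comparison(frame, self._table(nx, ny))
            assert p == pytest.approx(mwu_exact_oracle(vals[:nx], vals[nx:]), rel=1e-9)
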