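"""Run decomposition, cycle inference, dyadic fitting (vs. an exhaustive
triple-enumeration oracle), and the model-comparison classifier."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segmod.inference import (
    VERDICT_CONTIGUOUS_ANOMALY,
    VERDICT_CONTIGUOUS_EXTENSION,
    VERDICT_MULTIPLICATIVE,
    VERDICT_UNINFORMATIVE,
    compare_models,
    decompose_runs,
    dyadic_fit,
    gonopod_positions,
    infer_cycles,
)
from segmod.splitting_model import DomainError, DyadicNode


class TestDecomposeRuns:
    @pytest.mark.parametrize(
        "G,runs,spacings",
        [
            ([8, 9, 10, 11, 24, 25, 26, 27], [(8, 11), (24, 27)], (16,)),
            ([4, 8, 12], [(4, 4), (8, 8), (12, 12)], (4, 4)),
            ([5], [(5, 5)], ()),
            ([], [], ()),
        ],
    )
    def test_examples(self, G, runs, spacings):
        decomp = decompose_runs(G)
        assert list(decomp.runs) == runs
        assert decomp.spacings == spacings

    @given(st.sets(st.integers(1, 200), max_size=40))
    def test_runs_partition_the_set(self, G):
        decomp = decompose_runs(G)
        covered = [p for lo, hi in decomp.runs for p in range(lo, hi + 1)]
        assert covered == sorted(G)
        # maximality: runs are separated by at least one gap
        for (_, hi), (lo2, _) in zip(decomp.runs, decomp.runs[1:]):
            assert lo2 > hi + 1


class TestInferCycles:
    @pytest.mark.parametrize(
        "G,k,reason",
        [
            ([8, 9, 10, 11, 24, 25, 26, 27], 4, None),
            ([4, 8, 12], 2, None),
            ([1, 7], None, "not a power of 2"),
            ([1, 5, 11], None, "unequal spacings"),
            ([5], None, "no spacings"),
        ],
    )
    def test_examples(self, G, k, reason):
        result = infer_cycles(decompose_runs(G))
        assert result.k == k
        assert result.reason == reason


def oracle_fit(G, k, m_max=None):
    """Independent oracle: enumerate every (anchor, node, contiguous block)
    triple, generate its marked set directly from the coordinate formula, and
    keep the triples that reproduce G exactly (markers clipped by the
    truncation excluded).  Returns the optimum under the documented ordering
    (depth, most-posterior node, smallest anchor), or None."""
    G = set(G)
    width = 2**k
    if m_max is None:
        m_max = (max(G) + width - 1) // width + 1
    feasible = []
    for t in range(width):
        for depth in range(k + 1):
            w = 2 ** (k - depth)
            for index in range(2**depth):
                lo = index * w + 1
                for m_lo in range(1, m_max + 1):
                    if m_lo == 1 and lo <= t:
                        continue
                    for m_hi in range(m_lo, m_max + 1):
                        gen = {
                            (m - 1) * width + o - t
                            for m in range(m_lo, m_hi + 1)
                            for o in range(lo, lo + w)
                        }
                        if gen == G:
                            feasible.append(
                                (depth, -index, t, DyadicNode(depth, index), (m_lo, m_hi))
                            )
    if not feasible:
        return None
    depth, _, t, node, block = min(feasible)
    return t, node, block


class TestDyadicFit:
    def test_homeotic_julidan_pattern(self):
        fit = dyadic_fit([8, 9, 10, 11, 24, 25, 26, 27], k=4)
        assert fit.feasible
        assert fit.anchor == 5
        assert fit.node == DyadicNode(2, 3)
        assert fit.primary_block == (1, 2)
        assert fit.multiplicative_cost == 1
        assert fit.sequential_cost == 2

    def test_homeotic_polydesmidan_pattern(self):
        fit = dyadic_fit([4, 8, 12], k=2)
        assert fit.feasible
        assert (fit.anchor, fit.node, fit.primary_block) == (0, DyadicNode(2, 3), (1, 3))

    def test_normal_julidan_pattern(self):
        # the anchor is identifiable only mod 2 from {8,9}; the posterior
        # tie-break selects the posterior-most aligned pair
        fit = dyadic_fit([8, 9], k=4)
        assert fit.feasible
        assert fit.node.depth == 3
        assert fit.primary_block == (1, 1)
        assert (fit.anchor, fit.node) == (7, DyadicNode(3, 7))

    def test_contiguous_extension_fits_only_one_block(self):
        # a run adjacent to the normal gonopods needs no translated pattern:
        # it fits trivially inside a single primary segment
        fit = dyadic_fit([7, 8], k=4)
        assert fit.feasible
        assert fit.block_size == 1

    def test_non_dyadic_spacing_is_infeasible(self):
        fit = dyadic_fit([8, 9, 11], k=4)
        assert not fit.feasible
        assert fit.multiplicative_cost == 2
        assert fit.sequential_cost == 2

    def test_rejects_invalid_input(self):
        with pytest.raises(DomainError):
            dyadic_fit([8, 9], k=-1)
        with pytest.raises(DomainError):
            dyadic_fit([], k=4)

    @pytest.mark.parametrize(
        "G,k",
        [
            ([8, 9, 10, 11, 24, 25, 26, 27], 4),
            ([8, 9], 4),
            ([4, 8, 12], 2),
            ([7, 8], 4),
            ([1, 2, 5, 6], 2),
            ([3, 7, 11, 15], 2),
            ([2, 3, 6, 7, 10, 11], 2),
        ],
    )
    def test_agrees_with_oracle_on_named_patterns(self, G, k):
        fit = dyadic_fit(G, k)
        expected = oracle_fit(G, k)
        if expected is None:
            assert not fit.feasible
        else:
            assert fit.feasible
            assert (fit.anchor, fit.node, fit.primary_block) == expected

    @given(
        G=st.sets(st.integers(1, 20), min_size=1, max_size=12),
        k=st.integers(0, 3),
    )
    @settings(max_examples=150)
    def test_oracle_equivalence_small(self, G, k):
        fit = dyadic_fit(G, k, min_events=False)
        expected = oracle_fit(G, k)
        if expected is None:
            assert not fit.feasible
        else:
            assert fit.feasible
            assert (fit.anchor, fit.node, fit.primary_block) == expected

    def test_translation_invariance(self):
        G = [8, 9, 10, 11, 24, 25, 26, 27]
        fit = dyadic_fit(G, 4)
        shifted = dyadic_fit([p + 16 for p in G], 4)
        assert shifted.feasible
        assert shifted.node == fit.node
        assert shifted.anchor == fit.anchor
        assert shifted.primary_block == (fit.primary_block[0] + 1, fit.primary_block[1] + 1)

    def test_tolerance_mode_absorbs_one_mismatch(self):
        # the Madeira pattern {8,9,11} with a one-position hole at 10
        exact = dyadic_fit([8, 9, 11], k=4)
        assert not exact.feasible
        tolerant = dyadic_fit([8, 9, 11], k=4, max_mismatch=1)
        assert tolerant.feasible
        assert tolerant.mismatches == 1


class TestCompareModels:
    def test_homeotic_consistent_at_k4_only(self, catalog):
        report = compare_models(catalog["homeotic_ommatoiulus"], k_range=range(1, 6))
        assert report.verdict == VERDICT_MULTIPLICATIVE
        assert report.best_k == 4
        assert [f.k for f in report.fits if f.feasible and f.multiplicative_cost == 1] == [4]
        assert report.regenerated_diff == ()

    def test_nannaria_consistent_at_k2(self, catalog):
        report = compare_models(catalog["homeotic_nannaria"])
        assert report.verdict == VERDICT_MULTIPLICATIVE
        assert report.best_k == 2

    def test_madeira_is_contiguous_anomaly(self, catalog):
        report = compare_models(catalog["madeira_ommatoiulus"])
        assert report.verdict == VERDICT_CONTIGUOUS_ANOMALY
        assert all(not (f.feasible and f.multiplicative_cost == 1) for f in report.fits)

    def test_normal_male_is_uninformative(self, catalog):
        report = compare_models(catalog["normal_ommatoiulus"])
        assert report.verdict == VERDICT_UNINFORMATIVE

    def test_pseudoeurydesmus_is_contiguous_extension(self, catalog):
        report = compare_models(catalog["pseudoeurydesmus"])
        assert report.verdict == VERDICT_CONTIGUOUS_EXTENSION

    def test_exclude_normal_mode(self, catalog):
        # treating the normal gonopods as baseline leaves runs of unequal
        # length ({10,11} vs {24..27}, spacing 14): the dyadic reading needs
        # the normal positions as part of the pattern
        report = compare_models(catalog["homeotic_ommatoiulus"], exclude_normal=True)
        assert report.positions == (10, 11, 24, 25, 26, 27)
        assert report.decomposition.spacings == (14,)
        assert report.verdict == VERDICT_CONTIGUOUS_ANOMALY

    def test_report_serializes(self, catalog):
        report = compare_models(catalog["homeotic_ommatoiulus"])
        d = report.to_dict()
        assert d["verdict"] == VERDICT_MULTIPLICATIVE
        assert d["spacings"] == [16]
        assert {f["k"]: f["feasible"] for f in d["fits"]}[4] is True
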