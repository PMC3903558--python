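"""Unit and property tests for the generative binary-splitting core."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from segmod.splitting_model import (
    JULIDAN,
    POLYDESMIDAN,
    AppendageState,
    DomainError,
    DyadicNode,
    GONOPOD_STATES,
    MarkerPlacement,
    SpecificationError,
    SplittingSpec,
    TruncatedMarkerWarning,
    apply_markers,
    expand,
    leaf_interval,
    simulate_phenotype,
)


def brute_leaf_interval(depth, index, k):
    """Independent oracle: enumerate all 2**k leaves and keep those whose
    depth-d ancestor is `index` (ancestor of leaf l is (l-1) >> (k-d))."""
    leaves = [l for l in range(1, 2**k + 1) if (l - 1) >> (k - depth) == index]
    return min(leaves), max(leaves)


class TestLeafInterval:
    @pytest.mark.parametrize(
        "depth,index,k,expected",
        [
            (0, 0, 4, (1, 16)),  # root covers the whole module
            (2, 3, 4, (13, 16)),
            (3, 6, 4, (13, 14)),
            (2, 3, 2, (4, 4)),
        ],
    )
    def test_examples(self, depth, index, k, expected):
        assert leaf_interval(DyadicNode(depth, index), k) == expected
        assert brute_leaf_interval(depth, index, k) == expected

    def test_matches_brute_force_everywhere(self):
        for k in range(6):
            for depth in range(k + 1):
                for index in range(2**depth):
                    assert leaf_interval(DyadicNode(depth, index), k) == \
                        brute_leaf_interval(depth, index, k)

    def test_partition_property(self):
        # at every depth d <= k the 2**d nodes partition [1, 2**k]
        for k in range(6):
            for depth in range(k + 1):
                covered = []
                for index in range(2**depth):
                    lo, hi = leaf_interval(DyadicNode(depth, index), k)
                    covered.extend(range(lo, hi + 1))
                assert covered == list(range(1, 2**k + 1))

    def test_invalid_node_errors_name_the_bound(self):
        with pytest.raises(DomainError, match="depth"):
            leaf_interval(DyadicNode(3, 0), k=2)
        with pytest.raises(DomainError, match="index"):
            DyadicNode(2, 4)
        with pytest.raises(DomainError, match="depth"):
            DyadicNode(-1, 0)


valid_specs = st.builds(
    lambda k, P, t_frac: SplittingSpec(
        taxon_profile=JULIDAN, k=k, P=P, t=min(int(t_frac * 2**k), 2**k - 1)
    ),
    k=st.integers(0, 6),
    P=st.integers(1, 5),
    t_frac=st.floats(0, 1, exclude_max=True),
)


class TestExpand:
    @pytest.mark.parametrize(
        "k,P,t,count", [(4, 2, 5, 27), (0, 3, 0, 3), (2, 4, 0, 16)]
    )
    def test_unit_counts(self, k, P, t, count):
        units = expand(SplittingSpec(JULIDAN, k=k, P=P, t=t))
        assert len(units) == count
        assert [u.leg_pair for u in units] == list(range(1, count + 1))

    def test_coordinates(self):
        units = {u.leg_pair: u for u in expand(SplittingSpec(JULIDAN, k=4, P=2, t=5))}
        assert (units[8].primary_segment, units[8].offset) == (1, 13)
        assert (units[24].primary_segment, units[24].offset) == (2, 13)
        units = {u.leg_pair: u for u in expand(SplittingSpec(POLYDESMIDAN, k=2, P=4))}
        assert (units[8].primary_segment, units[8].offset) == (2, 4)

    def test_no_splitting_offsets(self):
        units = expand(SplittingSpec(JULIDAN, k=0, P=3))
        assert [u.offset for u in units] == [1, 1, 1]

    def test_excessive_truncation_rejected(self):
        with pytest.raises(SpecificationError, match="t must satisfy"):
            SplittingSpec(JULIDAN, k=2, P=2, t=4)

    @given(spec=valid_specs)
    def test_unit_count_conservation(self, spec):
        units = expand(spec)
        assert len(units) == spec.P * 2**spec.k - spec.t
        assert [u.leg_pair for u in units] == list(range(1, len(units) + 1))
        for u in units:
            assert u.leg_pair == (u.primary_segment - 1) * 2**spec.k + u.offset - spec.t
            assert all(s is AppendageState.WALKING_LEG for s in u.states())

    @given(spec=valid_specs)
    def test_monotone_truncation(self, spec):
        # t -> t+1 removes exactly the anterior-most realized unit
        if spec.t + 1 >= 2**spec.k:
            return
        more = SplittingSpec(spec.taxon_profile, spec.k, spec.P, spec.t + 1)
        a, b = expand(spec), expand(more)
        assert len(b) == len(a) - 1
        assert [(u.primary_segment, u.offset) for u in b] == \
            [(u.primary_segment, u.offset) for u in a[1:]]


def marked_positions(units):
    return [u.leg_pair for u in units if u.state_left in GONOPOD_STATES]


class TestApplyMarkers:
    def test_normal_julidan_male(self):
        spec = SplittingSpec(
            JULIDAN, k=4, P=2, t=5,
            markers=(MarkerPlacement(1, DyadicNode(3, 6)),),
            anterior_marker_positions=(8,),
        )
        units = apply_markers(expand(spec), spec)
        states = {u.leg_pair: u.state_left for u in units}
        assert states[8] is AppendageState.ANTERIOR_GONOPOD
        assert states[9] is AppendageState.POSTERIOR_GONOPOD
        assert all(
            s is AppendageState.WALKING_LEG
            for j, s in states.items() if j not in (8, 9)
        )

    def test_homeotic_julidan_male(self):
        spec = SplittingSpec(
            JULIDAN, k=4, P=2, t=5,
            markers=(
                MarkerPlacement(1, DyadicNode(2, 3)),
                MarkerPlacement(2, DyadicNode(2, 3)),
            ),
            anterior_marker_positions=(8,),
        )
        units = apply_markers(expand(spec), spec)
        assert marked_positions(units) == [8, 9, 10, 11, 24, 25, 26, 27]
        assert units[7].state_left is AppendageState.ANTERIOR_GONOPOD
        assert units[8].state_left is AppendageState.POSTERIOR_GONOPOD

    def test_polydesmidan_generic_gonopods(self):
        spec = SplittingSpec(
            POLYDESMIDAN, k=2, P=4,
            markers=tuple(MarkerPlacement(ps, DyadicNode(2, 3)) for ps in (1, 2, 3)),
        )
        units = apply_markers(expand(spec), spec)
        assert marked_positions(units) == [4, 8, 12]
        assert all(
            u.state_left is AppendageState.GONOPOD_GENERIC
            for u in units if u.leg_pair in (4, 8, 12)
        )

    def test_empty_markers(self):
        spec = SplittingSpec(JULIDAN, k=3, P=2)
        units = apply_markers(expand(spec), spec)
        assert marked_positions(units) == []

    def test_truncated_marker_warns_without_effect(self):
        # node (2,0) covers offsets 1-4, all inside the t=5 truncated region
        spec = SplittingSpec(
            JULIDAN, k=4, P=2, t=5, markers=(MarkerPlacement(1, DyadicNode(2, 0)),)
        )
        with pytest.warns(TruncatedMarkerWarning):
            units = apply_markers(expand(spec), spec)
        assert marked_positions(units) == []

    def test_translation_homology_property(self):
        # the same node in consecutive primary segments marks sets 2**k apart
        for k in (2, 3, 4):
            for depth in range(1, k + 1):
                node = DyadicNode(depth, 2**depth - 1)
                spec1 = SplittingSpec(JULIDAN, k=k, P=3, markers=(MarkerPlacement(2, node),))
                spec2 = SplittingSpec(JULIDAN, k=k, P=3, markers=(MarkerPlacement(3, node),))
                m1 = marked_positions(apply_markers(expand(spec1), spec1))
                m2 = marked_positions(apply_markers(expand(spec2), spec2))
                assert m2 == [p + 2**k for p in m1]

    def test_marker_order_independence_and_idempotence(self):
        posterior = (
            MarkerPlacement(1, DyadicNode(2, 3)),
            MarkerPlacement(2, DyadicNode(2, 3)),
        )
        spec_fwd = SplittingSpec(JULIDAN, 4, 2, 5, posterior, (8,))
        spec_rev = SplittingSpec(JULIDAN, 4, 2, 5, posterior[::-1], (8,))
        spec_dup = SplittingSpec(JULIDAN, 4, 2, 5, posterior + posterior, (8, 8))
        results = [
            [(u.state_left, u.state_right) for u in apply_markers(expand(s), s)]
            for s in (spec_fwd, spec_rev, spec_dup)
        ]
        assert results[0] == results[1] == results[2]


class TestSimulatePhenotype:
    def test_normal_spec_confines_gonopods_to_ring_7(self):
        spec = SplittingSpec(
            JULIDAN, 4, 2, 5,
            markers=(MarkerPlacement(1, DyadicNode(3, 6)),),
            anterior_marker_positions=(8,),
        )
        ph = simulate_phenotype(spec)
        rings = {
            ph.ring_map.leg_pair_to_ring(u.leg_pair)[0]
            for u in ph.units if u.state_left in GONOPOD_STATES
        }
        assert rings == {7}

    def test_degenerate_single_unit(self):
        ph = simulate_phenotype(SplittingSpec(JULIDAN, k=0, P=1, t=0))
        assert ph.L == 1


class TestSpecJson:
    def test_round_trip(self, tmp_path):
        spec = SplittingSpec(
            JULIDAN, 4, 2, 5,
            markers=(MarkerPlacement(1, DyadicNode(2, 3)),),
            anterior_marker_positions=(8,),
        )
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert SplittingSpec.from_json(path) == spec

    @pytest.mark.parametrize(
        "payload,match",
        [
            ({"taxon_profile": "julidan", "k": 4, "P": 2}, "missing keys"),
            ({"taxon_profile": "julidan", "k": 4, "P": 2, "t": 5, "bogus": 1}, "unknown keys"),
            ({"taxon_profile": "julidan", "k": "4", "P": 2, "t": 0}, "integer"),
            ({"taxon_profile": "centipede", "k": 4, "P": 2, "t": 0}, "taxon_profile"),
            ({"taxon_profile": "julidan", "k": 4, "P": 2, "t": 5,
              "markers": [{"ps": 3, "depth": 2, "index": 3}]}, "exceeds P"),
        ],
    )
    def test_invalid_payloads_rejected(self, payload, match):
        with pytest.raises(SpecificationError, match=match):
            SplittingSpec.from_dict(payload)
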