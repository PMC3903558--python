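"""Generative core of the multiplicative (binary-splitting) segmentation model.

Millipede trunks are modeled as a small number of embryonic *primary segments*,
each of which subdivides through ``k`` cycles of regular binary antero-posterior
division into ``2**k`` definitive ventral units (leg pairs).  Positional markers
set on nodes of the binary splitting tree of a primary segment are inherited by
the whole dyadic block of descendant units and later trigger the non-systemic
metamorphosis of walking legs into gonopods.  The model is purely combinatorial:
no spatial tissue mechanics, no RNG anywhere in this module.

Coordinates
-----------
Leg pairs are numbered 1-based along the trunk, excluding the legless collum.
Within a primary segment, leaf units carry 1-based *offsets* in ``[1, 2**k]``.
An anterior truncation ``t`` removes the first ``t`` virtual offsets of primary
segment 1 (the region that develops into the collum and the haplosegmental
rings), so global coordinates obey::

    leg_pair = (primary_segment - 1) * 2**k + offset - t

Dyadic tree nodes are addressed by ``(depth, index)`` with 0-based indices;
the node at depth ``d``, index ``i`` covers offsets
``[i * 2**(k-d) + 1, (i+1) * 2**(k-d)]``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "JULIDAN",
    "POLYDESMIDAN",
    "TAXON_PROFILES",
    "AppendageState",
    "GONOPOD_STATES",
    "DomainError",
    "SpecificationError",
    "TruncatedMarkerWarning",
    "DyadicNode",
    "MarkerPlacement",
    "SplittingSpec",
    "VentralUnit",
    "leaf_interval",
    "expand",
    "apply_markers",
    "simulate_phenotype",
]

JULIDAN = "julidan"
POLYDESMIDAN = "polydesmidan"
TAXON_PROFILES = (JULIDAN, POLYDESMIDAN)


class DomainError(ValueError):
    """An argument violates a documented bound of the model's coordinate system."""


class SpecificationError(ValueError):
    """A SplittingSpec (or its serialized form) violates a model invariant."""


class TruncatedMarkerWarning(UserWarning):
    """A marker placement lies entirely in the truncated region: no phenotypic effect."""


class AppendageState(str, Enum):
    """State of one appendage of a leg pair (one body side)."""

    WALKING_LEG = "WALKING_LEG"
    ANTERIOR_GONOPOD = "ANTERIOR_GONOPOD"
    POSTERIOR_GONOPOD = "POSTERIOR_GONOPOD"
    GONOPOD_GENERIC = "GONOPOD_GENERIC"
    ATROPHIED_LEG = "ATROPHIED_LEG"
    ABSENT = "ABSENT"


#: States that count as "gonopod" for position queries.
GONOPOD_STATES = frozenset(
    {
        AppendageState.ANTERIOR_GONOPOD,
        AppendageState.POSTERIOR_GONOPOD,
        AppendageState.GONOPOD_GENERIC,
    }
)


@dataclass(frozen=True, order=True)
class DyadicNode:
    """A node of the binary splitting tree of one primary segment.

    ``depth`` counts splitting cycles from the whole primary segment (depth 0);
    ``index`` numbers nodes left (anterior) to right (posterior) within a depth,
    0-based.  A node addresses the power-of-2 block of leaf units it will give
    rise to.
    """

    depth: int
    index: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise DomainError(f"node depth must be >= 0, got {self.depth}")
        if not 0 <= self.index < 2**self.depth:
            raise DomainError(
                f"node index must satisfy 0 <= index < 2**depth "
                f"(= {2 ** self.depth}), got {self.index}"
            )

    def leaf_interval(self, k: int) -> tuple[int, int]:
        return leaf_interval(self, k)


def leaf_interval(node: DyadicNode, k: int) -> tuple[int, int]:
    """Offset interval ``[lo, hi]`` (1-based, inclusive) of the leaves below *node*.

    ``k`` is the total number of splitting cycles of the owning spec; the
    interval width is ``2**(k - node.depth)``.
    """
    if k < 0:
        raise DomainError(f"splitting cycle count k must be >= 0, got {k}")
    if node.depth > k:
        raise DomainError(
            f"node depth {node.depth} exceeds splitting cycle count k={k}"
        )
    width = 2 ** (k - node.depth)
    lo = node.index * width + 1
    return lo, lo + width - 1


@dataclass(frozen=True)
class MarkerPlacement:
    """An early positional marker placed on a dyadic node of one primary segment.

    All realized descendant leaf units inherit the marker and develop posterior
    gonopods in place of walking legs.
    """

    primary_segment: int
    node: DyadicNode
    marker_kind: str = "posterior_gonopod"

    def __post_init__(self) -> None:
        if self.primary_segment < 1:
            raise SpecificationError(
                f"primary_segment must be >= 1, got {self.primary_segment}"
            )
        if self.marker_kind != "posterior_gonopod":
            raise SpecificationError(
                f"unknown marker_kind {self.marker_kind!r}"
            )


@dataclass(frozen=True)
class SplittingSpec:
    """Parameters of the generative model.

    Parameters
    ----------
    taxon_profile:
        ``"julidan"`` (anterior + posterior gonopod types) or ``"polydesmidan"``
        (a single generic gonopod type).
    k:
        Binary splitting cycles per primary segment (module width ``2**k``).
    P:
        Number of realized primary segments.
    t:
        Anterior truncation: virtual leg-pair positions of primary segment 1
        that are never realized (``0 <= t < 2**k``).
    markers:
        Early posterior-gonopod markers on dyadic nodes.
    anterior_marker_positions:
        Global leg-pair indices carrying the late, strictly localized
        anterior-gonopod marker (applied after segmentation is complete).
    """

    taxon_profile: str
    k: int
    P: int
    t: int = 0
    markers: tuple[MarkerPlacement, ...] = ()
    anterior_marker_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(
            self, "anterior_marker_positions", tuple(self.anterior_marker_positions)
        )
        if self.taxon_profile not in TAXON_PROFILES:
            raise SpecificationError(
                f"taxon_profile must be one of {TAXON_PROFILES}, got "
                f"{self.taxon_profile!r}"
            )
        if self.k < 0:
            raise SpecificationError(f"k must be >= 0, got {self.k}")
        if self.P < 1:
            raise SpecificationError(f"P must be >= 1, got {self.P}")
        if not 0 <= self.t < 2**self.k:
            raise SpecificationError(
                f"truncation t must satisfy 0 <= t < 2**k (= {2 ** self.k}), "
                f"got {self.t}"
            )
        for mp in self.markers:
            if mp.primary_segment > self.P:
                raise SpecificationError(
                    f"marker on primary segment {mp.primary_segment} exceeds P={self.P}"
                )
            leaf_interval(mp.node, self.k)  # raises if node invalid for k
        L = self.leg_pair_count
        for pos in self.anterior_marker_positions:
            if not 1 <= pos <= L:
                raise SpecificationError(
                    f"anterior marker position {pos} outside realized range [1, {L}]"
                )
        if self.anterior_marker_positions and self.taxon_profile != JULIDAN:
            # Polydesmidans have a single gonopod type; the late anterior marker
            # is a julidan concept.  Positions are accepted but will be mapped
            # to the generic gonopod state.
            pass

    @property
    def module_width(self) -> int:
        return 2**self.k

    @property
    def leg_pair_count(self) -> int:
        """Total realized leg pairs L = P * 2**k - t."""
        return self.P * 2**self.k - self.t

    # -- JSON serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "taxon_profile": self.taxon_profile,
            "k": self.k,
            "P": self.P,
            "t": self.t,
            "markers": [
                {"ps": mp.primary_segment, "depth": mp.node.depth, "index": mp.node.index}
                for mp in self.markers
            ],
            "anterior_marker_positions": list(self.anterior_marker_positions),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SplittingSpec":
        if not isinstance(data, dict):
            raise SpecificationError("splitting spec must be a JSON object")
        required = {"taxon_profile", "k", "P", "t"}
        missing = required - data.keys()
        if missing:
            raise SpecificationError(f"splitting spec missing keys: {sorted(missing)}")
        unknown = data.keys() - (required | {"markers", "anterior_marker_positions"})
        if unknown:
            raise SpecificationError(f"splitting spec has unknown keys: {sorted(unknown)}")
        for key in ("k", "P", "t"):
            if not isinstance(data[key], int) or isinstance(data[key], bool):
                raise SpecificationError(f"spec field {key!r} must be an integer")
        markers = []
        for i, m in enumerate(data.get("markers", [])):
            if not isinstance(m, dict) or not {"ps", "depth", "index"} <= m.keys():
                raise SpecificationError(
                    f"marker #{i} must be an object with keys ps, depth, index"
                )
            markers.append(
                MarkerPlacement(
                    primary_segment=m["ps"],
                    node=DyadicNode(depth=m["depth"], index=m["index"]),
                )
            )
        anterior = data.get("anterior_marker_positions", [])
        if not isinstance(anterior, list) or not all(
            isinstance(p, int) and not isinstance(p, bool) for p in anterior
        ):
            raise SpecificationError("anterior_marker_positions must be a list of integers")
        return cls(
            taxon_profile=data["taxon_profile"],
            k=data["k"],
            P=data["P"],
            t=data["t"],
            markers=tuple(markers),
            anterior_marker_positions=tuple(anterior),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SplittingSpec":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SpecificationError(f"invalid JSON in {path}: {exc}") from exc
        return cls.from_dict(data)


@dataclass
class VentralUnit:
    """One leg-pair position, with per-side appendage states.

    ``primary_segment`` and ``offset`` are model coordinates; they are ``None``
    for observed specimens, where only the global position is known.
    """

    leg_pair: int
    primary_segment: int | None = None
    offset: int | None = None
    state_left: AppendageState = AppendageState.WALKING_LEG
    state_right: AppendageState = AppendageState.WALKING_LEG
    note_left: str = ""
    note_right: str = ""

    def states(self) -> tuple[AppendageState, AppendageState]:
        return (self.state_left, self.state_right)


def expand(spec: SplittingSpec) -> list[VentralUnit]:
    """Expand *spec* into its ordered list of realized ventral units.

    Each of the ``P`` primary segments contributes ``2**k`` leaf offsets; the
    first ``t`` offsets of primary segment 1 are virtual (truncated).  Exactly
    ``P * 2**k - t`` units are returned, with contiguous ``leg_pair`` from 1 and
    all states initialized to ``WALKING_LEG``.
    """
    width = spec.module_width
    units: list[VentralUnit] = []
    for ps in range(1, spec.P + 1):
        for offset in range(1, width + 1):
            leg_pair = (ps - 1) * width + offset - spec.t
            if leg_pair >= 1:
                units.append(
                    VentralUnit(leg_pair=leg_pair, primary_segment=ps, offset=offset)
                )
    return units


def apply_markers(
    units: Sequence[VentralUnit], spec: SplittingSpec
) -> list[VentralUnit]:
    """Apply *spec*'s markers to expanded *units*; returns new units.

    Early posterior-gonopod markers act per dyadic block: every realized unit of
    the marked primary segment whose offset lies in the node's leaf interval is
    set to ``POSTERIOR_GONOPOD`` on both sides.  The late anterior marker is
    applied afterwards (it acts on completed segmentation) and overrides its
    position to ``ANTERIOR_GONOPOD``.  Under the polydesmidan profile every
    gonopod state collapses to the single generic type.

    A marker whose leaf interval lies entirely in the truncated region emits a
    :class:`TruncatedMarkerWarning` and has no effect.
    """
    out = [replace(u) for u in units]
    by_coord = {(u.primary_segment, u.offset): u for u in out}
    by_pos = {u.leg_pair: u for u in out}

    for mp in spec.markers:
        lo, hi = leaf_interval(mp.node, spec.k)
        hit = [
            by_coord[(mp.primary_segment, o)]
            for o in range(lo, hi + 1)
            if (mp.primary_segment, o) in by_coord
        ]
        if not hit:
            warnings.warn(
                f"marker on primary segment {mp.primary_segment}, node "
                f"(depth={mp.node.depth}, index={mp.node.index}) lies entirely in "
                f"the truncated region: no phenotypic effect",
                TruncatedMarkerWarning,
                stacklevel=2,
            )
            continue
        for u in hit:
            u.state_left = AppendageState.POSTERIOR_GONOPOD
            u.state_right = AppendageState.POSTERIOR_GONOPOD

    for pos in spec.anterior_marker_positions:
        u = by_pos[pos]
        u.state_left = AppendageState.ANTERIOR_GONOPOD
        u.state_right = AppendageState.ANTERIOR_GONOPOD

    if spec.taxon_profile == POLYDESMIDAN:
        for u in out:
            if u.state_left in GONOPOD_STATES:
                u.state_left = AppendageState.GONOPOD_GENERIC
            if u.state_right in GONOPOD_STATES:
                u.state_right = AppendageState.GONOPOD_GENERIC
    return out


def simulate_phenotype(
    spec: SplittingSpec,
    fusions: Iterable[tuple[int, int]] = (),
    provenance: str = "",
):
    """Simulate the observable phenotype predicted by *spec*.

    Composition of :func:`expand`, :func:`apply_markers` and the taxon-default
    ring map (no fusions unless given).  Returns a
    :class:`segmod.phenotype.Phenotype`.
    """
    from .body_plan import build_ring_map
    from .phenotype import Phenotype

    units = apply_markers(expand(spec), spec)
    ring_map = build_ring_map(spec.leg_pair_count, fusions=fusions)
    return Phenotype(
        taxon_profile=spec.taxon_profile,
        units=units,
        ring_map=ring_map,
        provenance=provenance or f"simulated from spec {spec.to_dict()}",
    )
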