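"""Dorsal ring <-> ventral leg-pair correspondence for the millipede trunk.

The standard antero-posterior layout is: a legless collum (ring 1), three
haplosegmental rings each carrying one leg pair (rings 2-4 <- leg pairs 1-3),
then diplosegments carrying two leg pairs each (comparative ring ``r >= 5``
carries leg pairs ``2r - 6`` and ``2r - 5``).  Because dorsal and ventral
segmentation are partly decoupled, local anomalies occur in which two adjacent
diplosegment positions are expressed as a single physical ring carrying four
leg pairs; the map therefore carries *two* ring numberings everywhere:

* ``comparative_index`` — numbering aligned to a normal specimen;
* ``physical_index``   — count along the actual animal (shifts distal to a fusion).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .splitting_model import DomainError

__all__ = [
    "Ring",
    "RingMap",
    "build_ring_map",
    "leg_pair_to_ring",
    "ring_to_leg_pairs",
    "write_ring_map",
]

#: First comparative ring index that is a diplosegment.
FIRST_DIPLO_RING = 5


@dataclass(frozen=True)
class Ring:
    """One physical ring.

    ``comparative_indices`` holds a single index for a normal ring and the two
    merged indices for a fusion product.  ``comparative_index`` (the lowest) is
    kept as the ring's canonical comparative label.
    """

    comparative_indices: tuple[int, ...]
    physical_index: int
    leg_pairs: tuple[int, ...]
    flags: tuple[str, ...] = ()

    @property
    def comparative_index(self) -> int:
        return self.comparative_indices[0]

    @property
    def label(self) -> str:
        """Human-readable comparative label, e.g. ``"13+14"`` for a fused ring."""
        return "+".join(str(i) for i in self.comparative_indices)


@dataclass(frozen=True)
class RingMap:
    """Ordered physical rings covering leg pairs ``1..L`` exactly once."""

    L: int
    rings: tuple[Ring, ...]
    fusions: tuple[tuple[int, int], ...] = ()

    def leg_pair_to_ring(self, j: int) -> tuple[int, int]:
        return leg_pair_to_ring(j, self)

    def ring_to_leg_pairs(self, r: int) -> list[int]:
        return ring_to_leg_pairs(r, self)

    def physical_ring(self, comparative_index: int) -> Ring:
        """The physical ring containing the given comparative index."""
        for ring in self.rings:
            if comparative_index in ring.comparative_indices:
                return ring
        raise DomainError(
            f"comparative ring index {comparative_index} not in map "
            f"(valid range 1..{self.max_comparative_index})"
        )

    @property
    def max_comparative_index(self) -> int:
        return self.rings[-1].comparative_indices[-1]

    @property
    def physical_ring_count(self) -> int:
        return len(self.rings)


def _comparative_layout(L: int) -> list[tuple[int, tuple[int, ...], tuple[str, ...]]]:
    """Normal-specimen layout as (comparative_index, leg_pairs, flags) triples."""
    layout: list[tuple[int, tuple[int, ...], tuple[str, ...]]] = [(1, (), ())]
    for r in range(2, 5):
        j = r - 1
        if j <= L:
            layout.append((r, (j,), ()))
    r = FIRST_DIPLO_RING
    j = 4
    while j <= L:
        pairs = tuple(p for p in (j, j + 1) if p <= L)
        flags = ("incomplete",) if len(pairs) == 1 else ()
        layout.append((r, pairs, flags))
        j += 2
        r += 1
    return layout


def build_ring_map(L: int, fusions: Iterable[tuple[int, int]] = ()) -> RingMap:
    """Build the ring map for ``L`` leg pairs with optional fusion anomalies.

    ``fusions`` lists pairs of *adjacent* comparative diplosegment indices
    (each ``>= 5``) that are expressed as a single physical ring carrying their
    combined leg pairs.  A trailing odd leg pair, if any, sits on a final
    one-pair ring flagged ``"incomplete"``.
    """
    if L < 1:
        raise DomainError(f"leg-pair count L must be >= 1, got {L}")
    layout = _comparative_layout(L)
    max_comp = layout[-1][0]

    fusions = tuple(tuple(f) for f in fusions)
    fused_lo: set[int] = set()
    seen: set[int] = set()
    for f in fusions:
        if len(f) != 2 or f[1] != f[0] + 1:
            raise DomainError(
                f"fusion {f} must name two adjacent comparative rings (r, r+1)"
            )
        if f[0] < FIRST_DIPLO_RING:
            raise DomainError(
                f"fusion {f} references the collum or a haplosegmental ring "
                f"(only diplosegment rings >= {FIRST_DIPLO_RING} can fuse)"
            )
        if f[1] > max_comp:
            raise DomainError(
                f"fusion {f} references ring {f[1]} beyond the trunk "
                f"(last comparative ring is {max_comp})"
            )
        if f[0] in seen or f[1] in seen:
            raise DomainError(f"fusion {f} overlaps another fusion")
        seen.update(f)
        fused_lo.add(f[0])

    rings: list[Ring] = []
    physical = 0
    i = 0
    while i < len(layout):
        comp, pairs, flags = layout[i]
        physical += 1
        if comp in fused_lo:
            comp2, pairs2, flags2 = layout[i + 1]
            rings.append(
                Ring(
                    comparative_indices=(comp, comp2),
                    physical_index=physical,
                    leg_pairs=pairs + pairs2,
                    flags=("fused",) + flags + flags2,
                )
            )
            i += 2
        else:
            rings.append(
                Ring(
                    comparative_indices=(comp,),
                    physical_index=physical,
                    leg_pairs=pairs,
                    flags=flags,
                )
            )
            i += 1
    return RingMap(L=L, rings=tuple(rings), fusions=fusions)


def leg_pair_to_ring(j: int, ring_map: RingMap) -> tuple[int, int]:
    """Return ``(comparative_index, physical_index)`` of the ring bearing leg pair *j*.

    The comparative index follows the normal-specimen layout even across a
    fusion (leg pair 22 of a 13+14 fused ring still reports comparative 14).
    """
    if not 1 <= j <= ring_map.L:
        raise DomainError(
            f"leg pair {j} out of range [1, {ring_map.L}]"
        )
    comparative = j + 1 if j <= 3 else (j + 6) // 2
    for ring in ring_map.rings:
        if j in ring.leg_pairs:
            return comparative, ring.physical_index
    raise AssertionError("ring map does not cover its own leg-pair range")


def ring_to_leg_pairs(r: int, ring_map: RingMap) -> list[int]:
    """Leg pairs of comparative ring *r* in the normal layout (empty for the collum).

    Inverse of :func:`leg_pair_to_ring`: for every returned ``j``,
    ``leg_pair_to_ring(j)[0] == r``.
    """
    if not 1 <= r <= ring_map.max_comparative_index:
        raise DomainError(
            f"comparative ring index {r} out of range "
            f"[1, {ring_map.max_comparative_index}]"
        )
    if r == 1:
        return []
    if r <= 4:
        return [r - 1]
    return [p for p in (2 * r - 6, 2 * r - 5) if p <= ring_map.L]


def write_ring_map(ring_map: RingMap, path: str | Path) -> None:
    """Serialize *ring_map* as TSV (one row per physical ring)."""
    lines = ["comparative_index\tphysical_index\tleg_pairs\tflags"]
    for ring in ring_map.rings:
        lines.append(
            "\t".join(
                [
                    ring.label,
                    str(ring.physical_index),
                    ",".join(str(p) for p in ring.leg_pairs),
                    ",".join(ring.flags),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
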