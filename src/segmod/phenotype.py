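"""The observable object: per-leg-pair, per-side appendage states plus ring map.

A phenotype is serialized as a plain TSV with header
``position  side  state  annotation`` (``side`` in ``{L, R, B}``, ``B`` = both
sides) preceded by ``#``-prefixed metadata lines (taxon profile, provenance,
fusions, stadium, podous ring count, free-text notes).  Reading is strict:
duplicate ``(position, side)`` rows, gaps in the position sequence and unknown
state names are parse errors reported with their line number.  A position given
for one side only gets ``ABSENT`` on the other side.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .body_plan import RingMap, build_ring_map
from .splitting_model import AppendageState, VentralUnit

__all__ = ["Phenotype", "PhenotypeError", "ParseError", "read_phenotype", "write_phenotype"]


class PhenotypeError(ValueError):
    """A Phenotype violates a structural invariant."""


class ParseError(ValueError):
    """A phenotype TSV file is malformed; the message carries the line number."""


@dataclass
class Phenotype:
    taxon_profile: str
    units: list[VentralUnit]
    ring_map: RingMap
    provenance: str = ""
    stadium: int | None = None
    podous_ring_count: int | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.notes = tuple(self.notes)
        self.validate()

    def validate(self) -> None:
        from .splitting_model import TAXON_PROFILES

        if self.taxon_profile not in TAXON_PROFILES:
            raise PhenotypeError(
                f"taxon_profile must be one of {TAXON_PROFILES}, got "
                f"{self.taxon_profile!r}"
            )
        positions = [u.leg_pair for u in self.units]
        if positions != list(range(1, len(positions) + 1)):
            raise PhenotypeError(
                "unit positions must be contiguous from 1; got "
                f"{positions[:5]}{'...' if len(positions) > 5 else ''}"
            )
        if self.ring_map.L != len(self.units):
            raise PhenotypeError(
                f"ring map covers {self.ring_map.L} leg pairs but phenotype has "
                f"{len(self.units)} units"
            )
        for u in self.units:
            if (
                u.state_left is AppendageState.ABSENT
                and u.state_right is AppendageState.ABSENT
            ):
                raise PhenotypeError(
                    f"leg pair {u.leg_pair}: both sides ABSENT (at least one side "
                    "must be present)"
                )

    @property
    def L(self) -> int:
        return len(self.units)

    def unit(self, position: int) -> VentralUnit:
        return self.units[position - 1]


def write_phenotype(phenotype: Phenotype, path: str | Path) -> None:
    """Write *phenotype* as TSV.  Symmetric positions collapse to one ``B`` row."""
    lines = [f"# taxon_profile: {phenotype.taxon_profile}"]
    if phenotype.provenance:
        lines.append(f"# provenance: {phenotype.provenance}")
    if phenotype.stadium is not None:
        lines.append(f"# stadium: {phenotype.stadium}")
    if phenotype.podous_ring_count is not None:
        lines.append(f"# podous_rings: {phenotype.podous_ring_count}")
    for lo, hi in phenotype.ring_map.fusions:
        lines.append(f"# fusion: {lo}+{hi}")
    for note in phenotype.notes:
        lines.append(f"# note: {note}")
    lines.append("position\tside\tstate\tannotation")
    for u in phenotype.units:
        if u.state_left == u.state_right and u.note_left == u.note_right:
            lines.append(f"{u.leg_pair}\tB\t{u.state_left.value}\t{u.note_left}")
        else:
            lines.append(f"{u.leg_pair}\tL\t{u.state_left.value}\t{u.note_left}")
            lines.append(f"{u.leg_pair}\tR\t{u.state_right.value}\t{u.note_right}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a phenotype TSV.  Round-trip stable with :func:`write_phenotype`."""
    path = Path(path)
    taxon_profile = None
    provenance = ""
    stadium = None
    podous = None
    fusions: list[tuple[int, int]] = []
    notes: list[str] = []
    rows: list[tuple[int, int, str, str, str]] = []  # (lineno, pos, side, state, ann)
    header_seen = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            key, value = key.strip(), value.strip()
            if key == "taxon_profile":
                taxon_profile = value
            elif key == "provenance":
                provenance = value
            elif key == "stadium":
                stadium = int(value)
            elif key == "podous_rings":
                podous = int(value)
            elif key == "fusion":
                lo, _, hi = value.partition("+")
                fusions.append((int(lo), int(hi)))
            elif key == "note":
                notes.append(value)
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields[:3]] != ["position", "side", "state"]:
                raise ParseError(
                    f"{path}:{lineno}: expected header 'position\\tside\\tstate"
                    f"\\tannotation', got {line!r}"
                )
            header_seen = True
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        try:
            pos = int(fields[0])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: position {fields[0]!r} is not an integer")
        side = fields[1].strip()
        if side not in ("L", "R", "B"):
            raise ParseError(f"{path}:{lineno}: side must be L, R or B, got {side!r}")
        state = fields[2].strip()
        try:
            AppendageState(state)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unknown appendage state {state!r}")
        ann = fields[3] if len(fields) > 3 else ""
        rows.append((lineno, pos, side, state, ann))

    if not header_seen or not rows:
        raise ParseError(f"{path}: no phenotype rows found (empty body)")
    if taxon_profile is None:
        raise ParseError(f"{path}: missing '# taxon_profile:' metadata line")

    seen_sides: dict[tuple[int, str], int] = {}
    for lineno, pos, side, state, ann in rows:
        covered = ("L", "R") if side == "B" else (side,)
        for s in covered:
            if (pos, s) in seen_sides:
                raise ParseError(
                    f"{path}:{lineno}: duplicate entry for position {pos} side {s} "
                    f"(first given on line {seen_sides[(pos, s)]})"
                )
            seen_sides[(pos, s)] = lineno

    positions = sorted({pos for _, pos, *_ in rows})
    if positions != list(range(1, len(positions) + 1)):
        missing = sorted(set(range(1, max(positions) + 1)) - set(positions))
        raise ParseError(
            f"{path}: positions must be contiguous from 1; missing {missing}"
        )

    units = [VentralUnit(leg_pair=p, state_left=AppendageState.ABSENT,
                         state_right=AppendageState.ABSENT) for p in positions]
    for lineno, pos, side, state, ann in rows:
        u = units[pos - 1]
        st = AppendageState(state)
        if side in ("L", "B"):
            u.state_left, u.note_left = st, ann
        if side in ("R", "B"):
            u.state_right, u.note_right = st, ann
    for u in units:
        if (pos_sides := {s for (p, s) in seen_sides if p == u.leg_pair}) != {"L", "R"}:
            missing_side = ({"L", "R"} - pos_sides).pop()
            note = "side not recorded"
            if missing_side == "L":
                u.note_left = note
            else:
                u.note_right = note

    ring_map = build_ring_map(len(units), fusions=fusions)
    return Phenotype(
        taxon_profile=taxon_profile,
        units=units,
        ring_map=ring_map,
        provenance=provenance,
        stadium=stadium,
        podous_ring_count=podous,
        notes=tuple(notes),
    )
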