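"""Catalog of the observed specimens, encoded as Phenotype records.

Six specimens are shipped, built programmatically (no data files): the normal
and the homeotic *Ommatoiulus moreleti* males (Julida), the normal and the
homeotic *Nannaria conservata* males (Polydesmida), the *Pseudoeurydesmus
baguassuensis* male with a unilateral extra gonopod, and the Madeiran
*O. moreleti* male with an atrophied leg and one malformed extra gonopod.

Trunk lengths: the homeotic *O. moreleti* had 46 podous rings, one of which is
a fusion product equivalent to rings 13+14 of a normal animal — i.e. 44
comparative diplosegments and 91 leg pairs.  The other julidan specimens are
encoded at the same stadium-typical length; the polydesmidan specimens at the
lineage-typical 31 leg pairs.  States posterior to the described region are
walking legs by default and flagged low-confidence in the record notes.
"""
from __future__ import annotations

from .body_plan import build_ring_map
from .phenotype import Phenotype
from .splitting_model import JULIDAN, POLYDESMIDAN, AppendageState, VentralUnit

__all__ = ["fixtures", "FIXTURE_NAMES", "JULIDAN_TRUNK_LEG_PAIRS", "POLYDESMIDAN_TRUNK_LEG_PAIRS"]

#: Leg pairs of the homeotic O. moreleti trunk: 46 podous physical rings with one
#: 13+14 fusion -> 3 haplosegmental pairs + 2 * 44 comparative diplosegments.
JULIDAN_TRUNK_LEG_PAIRS = 91

#: Typical adult polydesmidan trunk length in leg pairs.
POLYDESMIDAN_TRUNK_LEG_PAIRS = 31

FIXTURE_NAMES = (
    "normal_ommatoiulus",
    "homeotic_ommatoiulus",
    "normal_nannaria",
    "homeotic_nannaria",
    "pseudoeurydesmus",
    "madeira_ommatoiulus",
)

_A = AppendageState.ANTERIOR_GONOPOD
_P = AppendageState.POSTERIOR_GONOPOD
_G = AppendageState.GONOPOD_GENERIC
_ATR = AppendageState.ATROPHIED_LEG
_W = AppendageState.WALKING_LEG


def _build(
    taxon: str,
    L: int,
    states: dict[int, tuple[AppendageState, AppendageState]],
    annotations: dict[int, str] | None = None,
    fusions=(),
    provenance: str = "",
    stadium: int | None = None,
    podous_ring_count: int | None = None,
    notes=(),
) -> Phenotype:
    annotations = annotations or {}
    units = []
    for j in range(1, L + 1):
        left, right = states.get(j, (_W, _W))
        ann = annotations.get(j, "")
        units.append(
            VentralUnit(
                leg_pair=j,
                state_left=left,
                state_right=right,
                note_left=ann,
                note_right=ann,
            )
        )
    return Phenotype(
        taxon_profile=taxon,
        units=units,
        ring_map=build_ring_map(L, fusions=fusions),
        provenance=provenance,
        stadium=stadium,
        podous_ring_count=podous_ring_count,
        notes=tuple(notes),
    )


def fixtures() -> dict[str, Phenotype]:
    """Return the named specimen records, freshly built."""
    out: dict[str, Phenotype] = {}

    out["normal_ommatoiulus"] = _build(
        JULIDAN,
        JULIDAN_TRUNK_LEG_PAIRS,
        {8: (_A, _A), 9: (_P, _P)},
        annotations={
            8: "anterior gonopod (promerite) on ring 7",
            9: "posterior gonopod on ring 7; spermatozoa in fovea",
        },
        provenance="normal male Ommatoiulus moreleti (Julida: Julidae)",
        notes=("reference normal julidan male",),
    )

    out["homeotic_ommatoiulus"] = _build(
        JULIDAN,
        JULIDAN_TRUNK_LEG_PAIRS,
        {
            8: (_A, _A),
            9: (_P, _P),
            10: (_P, _P),
            11: (_P, _P),
            24: (_P, _P),
            25: (_P, _P),
            26: (_P, _P),
            27: (_P, _P),
        },
        annotations={
            8: "normal anterior gonopod",
            9: "normal posterior gonopod; spermatozoa in fovea",
            10: "ectopic posterior gonopod, ring 8; mesomerite compressed, solenomerite reduced, fovea empty",
            11: "ectopic posterior gonopod, ring 8; larger than the anterior one of the pair",
            24: "ectopic posterior gonopod, ring 15; asymmetrical, left solenomerite lacking msp",
            25: "ectopic posterior gonopod, ring 15; rod-like mesal process on left side only",
            26: "ectopic posterior gonopod, ring 16; paracoxites reduced to slender processes",
            27: "ectopic posterior gonopod, ring 16; solenomerites highly reduced, fovea empty",
        },
        fusions=((13, 14),),
        provenance=(
            "homeotic male Ommatoiulus moreleti, Puerto de la Morcuera, Madrid; "
            "MNCN 20.07/759"
        ),
        stadium=10,
        podous_ring_count=46,
        notes=(
            "left antenna atrophied, reduced to two antennomeres",
            "leg pairs 20-23 attached to a single ring equivalent to rings 13+14",
            "no apodous rings",
            "states posterior to ring 16 are defaults (low confidence)",
        ),
    )

    out["normal_nannaria"] = _build(
        POLYDESMIDAN,
        POLYDESMIDAN_TRUNK_LEG_PAIRS,
        {8: (_G, _G)},
        annotations={8: "normal polydesmidan gonopod pair"},
        provenance="normal male Nannaria conservata (Polydesmida)",
        notes=("reference normal polydesmidan male",),
    )

    out["homeotic_nannaria"] = _build(
        POLYDESMIDAN,
        POLYDESMIDAN_TRUNK_LEG_PAIRS,
        {4: (_G, _G), 8: (_G, _G), 12: (_G, _G)},
        annotations={
            4: "extra gonopod pair, 4 leg positions in front of the normal pair",
            8: "normal gonopod pair",
            12: "extra gonopod pair, 4 leg positions behind the normal pair",
        },
        provenance="homeotic male Nannaria conservata with two extra gonopod pairs",
        notes=("trunk length typical for the lineage (not reported)",),
    )

    out["pseudoeurydesmus"] = _build(
        POLYDESMIDAN,
        POLYDESMIDAN_TRUNK_LEG_PAIRS,
        {7: (_G, _W), 8: (_G, _G)},
        annotations={
            7: "left leg replaced by an extra gonopod; right leg normal",
            8: "normal gonopod pair",
        },
        provenance="teratological male Pseudoeurydesmus baguassuensis (Polydesmida)",
        notes=("unilateral transformation contiguous with the normal gonopods",),
    )

    out["madeira_ommatoiulus"] = _build(
        JULIDAN,
        JULIDAN_TRUNK_LEG_PAIRS,
        {
            8: (_A, _A),
            9: (_P, _P),
            10: (_ATR, _ATR),
            11: (_P, _P),
        },
        annotations={
            8: "normal anterior gonopod",
            9: "normal posterior gonopod",
            10: "atrophied leg",
            11: "additional malformed posterior gonopod",
        },
        provenance="teratological male Ommatoiulus moreleti from Madeira",
        notes=("trunk length assumed stadium-typical (not reported)",),
    )

    return out
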