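"""Dyadic-pattern inference over observed phenotypes.

Given the set of gonopod-bearing leg-pair positions of a specimen, this module

* decomposes it into maximal contiguous runs and measures the spacing between
  consecutive run starts;
* infers the splitting-cycle count ``k`` when all spacings equal one power of 2;
* fits the multiplicative model exactly: an anchor (truncation) ``t̂``, a single
  dyadic node, and a contiguous block of primary segments that regenerate the
  observed set — the single-marker-event explanation;
* compares the parsimony of that explanation against a sequential null in which
  every maximal run is an independent marker event.

Feasibility of the dyadic fit is exact-match: for some anchor ``t̂`` in
``[0, 2**k)``, every occupied primary segment must carry the *same* offset set,
that set must equal the leaf interval of a single node, and the occupied
segments must form a contiguous block.  Markers clipped by the anterior
truncation are not accepted as explanations (a clipped marker would produce
unequal run lengths, which is a different observable).

Because the observed set constrains offsets only up to a joint rotation of
(anchor, node) modulo ``2**k``, ties among feasible anchors are broken toward
the *most posterior* node of the (uniquely determined) depth — the model's
reading that markers are inherited by a posterior subset of a primary
segment's progeny — and then toward the smallest anchor.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .phenotype import Phenotype
from .splitting_model import (
    GONOPOD_STATES,
    JULIDAN,
    POLYDESMIDAN,
    DomainError,
    DyadicNode,
    MarkerPlacement,
    SplittingSpec,
    apply_markers,
    expand,
    leaf_interval,
)

__all__ = [
    "NORMAL_GONOPOD_POSITIONS",
    "RunDecomposition",
    "FitResult",
    "CycleInference",
    "ModelComparison",
    "gonopod_positions",
    "decompose_runs",
    "infer_cycles",
    "dyadic_fit",
    "compare_models",
    "DEFAULT_K_RANGE",
    "VERDICT_MULTIPLICATIVE",
    "VERDICT_UNINFORMATIVE",
    "VERDICT_CONTIGUOUS_EXTENSION",
    "VERDICT_CONTIGUOUS_ANOMALY",
]

#: Gonopod-bearing leg pairs of a normal male, per taxon profile.
NORMAL_GONOPOD_POSITIONS = {JULIDAN: frozenset({8, 9}), POLYDESMIDAN: frozenset({8})}

DEFAULT_K_RANGE = range(1, 7)

VERDICT_MULTIPLICATIVE = "multiplicative-consistent"
VERDICT_UNINFORMATIVE = "uninformative: one run"
VERDICT_CONTIGUOUS_EXTENSION = "contiguous-extension: multiplicative model not required"
VERDICT_CONTIGUOUS_ANOMALY = "contiguous-anomaly: no single-event dyadic fit"


@dataclass(frozen=True)
class RunDecomposition:
    """Maximal contiguous runs of a position set, plus run-start spacings."""

    runs: tuple[tuple[int, int], ...]
    spacings: tuple[int, ...]

    @property
    def run_count(self) -> int:
        return len(self.runs)

    @property
    def run_lengths(self) -> tuple[int, ...]:
        return tuple(hi - lo + 1 for lo, hi in self.runs)


@dataclass(frozen=True)
class CycleInference:
    """Result of :func:`infer_cycles`: ``k`` or None with a reason."""

    k: int | None
    reason: str | None = None


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`dyadic_fit` for one cycle count ``k``."""

    feasible: bool
    k: int
    anchor: int | None = None
    node: DyadicNode | None = None
    primary_block: tuple[int, int] | None = None
    multiplicative_cost: int | None = None
    sequential_cost: int = 0
    mismatches: int = 0

    @property
    def block_size(self) -> int | None:
        if self.primary_block is None:
            return None
        return self.primary_block[1] - self.primary_block[0] + 1

    def to_spec(self, taxon_profile: str = JULIDAN) -> SplittingSpec:
        """SplittingSpec that regenerates the fitted gonopod set."""
        if not self.feasible:
            raise DomainError("cannot build a spec from an infeasible fit")
        markers = tuple(
            MarkerPlacement(primary_segment=m, node=self.node)
            for m in range(self.primary_block[0], self.primary_block[1] + 1)
        )
        return SplittingSpec(
            taxon_profile=taxon_profile,
            k=self.k,
            P=self.primary_block[1],
            t=self.anchor,
            markers=markers,
        )

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "k": self.k,
            "anchor": self.anchor,
            "node": None
            if self.node is None
            else {"depth": self.node.depth, "index": self.node.index},
            "primary_block": None
            if self.primary_block is None
            else list(self.primary_block),
            "multiplicative_cost": self.multiplicative_cost,
            "sequential_cost": self.sequential_cost,
            "mismatches": self.mismatches,
        }


def gonopod_positions(phenotype: Phenotype, bilateral_only: bool = False) -> list[int]:
    """Sorted leg-pair positions bearing any gonopod type.

    A position counts if *either* side is transformed; with ``bilateral_only``
    both sides must be (two literature teratologies are unilateral).
    """
    out = []
    for u in phenotype.units:
        left = u.state_left in GONOPOD_STATES
        right = u.state_right in GONOPOD_STATES
        if (left and right) if bilateral_only else (left or right):
            out.append(u.leg_pair)
    return out


def decompose_runs(G: Iterable[int]) -> RunDecomposition:
    """Maximal-run decomposition of a sorted positive-integer position set."""
    positions = sorted(set(G))
    if any(p < 1 for p in positions):
        raise DomainError("positions must be positive integers")
    runs: list[tuple[int, int]] = []
    for p in positions:
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    spacings = tuple(
        runs[i + 1][0] - runs[i][0] for i in range(len(runs) - 1)
    )
    return RunDecomposition(runs=tuple(runs), spacings=spacings)


def infer_cycles(decomp: RunDecomposition) -> CycleInference:
    """Infer the splitting-cycle count from run-start spacings.

    Defined only when all spacings are equal to a single power of 2; otherwise
    returns ``k=None`` with the reason (``"no spacings"``, ``"unequal
    spacings"`` or ``"not a power of 2"``).
    """
    if not decomp.spacings:
        return CycleInference(k=None, reason="no spacings")
    values = set(decomp.spacings)
    if len(values) > 1:
        return CycleInference(k=None, reason="unequal spacings")
    (m,) = values
    if m < 1 or m & (m - 1):
        return CycleInference(k=None, reason="not a power of 2")
    return CycleInference(k=m.bit_length() - 1)


def _module_offset(p: int, t: int, width: int) -> tuple[int, int]:
    """Map global position *p* to (primary segment, offset) under anchor *t*."""
    shifted = p + t
    return (shifted - 1) // width + 1, (shifted - 1) % width + 1


def _feasible_at_anchor(
    positions: Sequence[int], k: int, t: int
) -> tuple[DyadicNode, tuple[int, int]] | None:
    """Single-node, contiguous-block fit at anchor *t*, or None."""
    width = 2**k
    by_module: dict[int, set[int]] = {}
    for p in positions:
        m, o = _module_offset(p, t, width)
        by_module.setdefault(m, set()).add(o)
    modules = sorted(by_module)
    if modules != list(range(modules[0], modules[-1] + 1)):
        return None
    offset_sets = list(by_module.values())
    first = offset_sets[0]
    if any(s != first for s in offset_sets[1:]):
        return None
    lo, hi = min(first), max(first)
    w = hi - lo + 1
    if len(first) != w:  # not contiguous
        return None
    if w & (w - 1):  # not a power of 2
        return None
    if (lo - 1) % w:  # not aligned to the dyadic grid
        return None
    depth = k - (w.bit_length() - 1)
    node = DyadicNode(depth=depth, index=(lo - 1) // w)
    if lo <= t and modules[0] == 1:
        # marker clipped by the truncation: not accepted as an explanation
        return None
    return node, (modules[0], modules[-1])


def _min_marker_events(positions: Sequence[int], k: int) -> int:
    """Minimal number of (node, contiguous-block) marker events covering the set exactly.

    Exhaustive depth-first exact cover over all anchors; used only for
    parsimony reporting on small sets.
    """
    pos = sorted(set(positions))
    if not pos:
        return 0
    if len(pos) > 32:
        raise DomainError("minimal-event search supported for <= 32 positions")
    width = 2**k
    best = len(pos)

    for t in range(width):
        points = frozenset(_module_offset(p, t, width) for p in pos)
        modules = sorted({m for m, _ in points})
        offsets_by_m = {m: {o for mm, o in points if mm == m} for m in modules}

        # candidate rectangles: (module block) x (node leaf interval), wholly
        # inside the point set, not clipped by the truncation
        intervals = []
        for depth in range(k + 1):
            w = 2 ** (k - depth)
            for index in range(2**depth):
                lo = index * w + 1
                intervals.append((lo, lo + w - 1))

        def rectangles_containing(point):
            m0, o0 = point
            out = []
            for lo, hi in intervals:
                if not lo <= o0 <= hi:
                    continue
                if m0 == 1 and lo <= t:
                    continue
                cols = set(range(lo, hi + 1))
                if not cols <= offsets_by_m.get(m0, set()):
                    continue
                # grow the maximal contiguous module block around m0
                m_lo = m0
                while m_lo - 1 in offsets_by_m and cols <= offsets_by_m[m_lo - 1] \
                        and not (m_lo - 1 == 1 and lo <= t):
                    m_lo -= 1
                m_hi = m0
                while m_hi + 1 in offsets_by_m and cols <= offsets_by_m[m_hi + 1]:
                    m_hi += 1
                covered = frozenset((m, o) for m in range(m_lo, m_hi + 1) for o in cols)
                out.append(covered)
            # keep only maximal rectangles (others are dominated)
            out.sort(key=len, reverse=True)
            maximal = []
            for r in out:
                if not any(r <= q for q in maximal):
                    maximal.append(r)
            return maximal

        def search(uncovered: frozenset, used: int) -> None:
            nonlocal best
            if used >= best:
                return
            if not uncovered:
                best = used
                return
            pivot = min(uncovered)
            for rect in rectangles_containing(pivot):
                search(uncovered - rect, used + 1)

        search(points, 0)
        if best == 1:
            break
    return best


def dyadic_fit(
    G: Iterable[int], k: int, max_mismatch: int = 0, min_events: bool = True
) -> FitResult:
    """Fit the single-marker-event multiplicative model to position set *G*.

    Exhaustive search over anchors ``t̂`` in ``[0, 2**k)``.  Feasible iff one
    (anchor, node, contiguous primary-segment block) triple regenerates *G*
    exactly (up to ``max_mismatch`` positions in tolerance mode; the default is
    exact).  Ties among anchors: most-posterior node, then smallest anchor.

    ``multiplicative_cost`` is 1 when feasible, else the minimal number of
    marker events covering *G* exactly; ``sequential_cost`` is the number of
    maximal runs (one independent event per run under the sequential model).
    """
    if k < 0:
        raise DomainError(f"splitting cycle count k must be >= 0, got {k}")
    positions = sorted(set(G))
    if not positions:
        raise DomainError("dyadic_fit requires a non-empty position set")
    decomp = decompose_runs(positions)
    seq_cost = decomp.run_count
    width = 2**k

    candidates: list[tuple[int, int, int, DyadicNode, tuple[int, int]]] = []
    for t in range(width):
        fit = _feasible_at_anchor(positions, k, t)
        if fit is not None:
            node, block = fit
            candidates.append((node.depth, -node.index, t, node, block))

    if candidates:
        depth, _, t, node, block = min(candidates)
        result = FitResult(
            feasible=True,
            k=k,
            anchor=t,
            node=node,
            primary_block=block,
            multiplicative_cost=1,
            sequential_cost=seq_cost,
        )
        # soundness: the fitted spec must regenerate G exactly
        regenerated = _regenerate(result)
        if regenerated != positions:
            raise AssertionError(
                f"fit soundness violated: regenerated {regenerated} != {positions}"
            )
        return result

    if max_mismatch > 0:
        tol = _tolerant_fit(positions, k, max_mismatch)
        if tol is not None:
            return FitResult(
                feasible=True,
                k=k,
                anchor=tol[0],
                node=tol[1],
                primary_block=tol[2],
                multiplicative_cost=1,
                sequential_cost=seq_cost,
                mismatches=tol[3],
            )

    return FitResult(
        feasible=False,
        k=k,
        multiplicative_cost=_min_marker_events(positions, k) if min_events else None,
        sequential_cost=seq_cost,
    )


def _regenerate(fit: FitResult) -> list[int]:
    """Gonopod positions produced by the fitted spec, via the generative model."""
    spec = fit.to_spec()
    units = apply_markers(expand(spec), spec)
    return [u.leg_pair for u in units if u.state_left in GONOPOD_STATES]


def _tolerant_fit(
    positions: list[int], k: int, max_mismatch: int
) -> tuple[int, DyadicNode, tuple[int, int], int] | None:
    """Best (anchor, node, block) with <= max_mismatch symmetric differences."""
    width = 2**k
    G = set(positions)
    m_max = (max(positions) + width - 1) // width + 1
    best = None
    for t in range(width):
        for depth in range(k + 1):
            for index in range(2**depth):
                node = DyadicNode(depth=depth, index=index)
                lo, hi = leaf_interval(node, k)
                if lo <= t:
                    continue
                for m_lo in range(1, m_max + 1):
                    for m_hi in range(m_lo, m_max + 1):
                        gen = {
                            (m - 1) * width + o - t
                            for m in range(m_lo, m_hi + 1)
                            for o in range(lo, hi + 1)
                        }
                        gen = {p for p in gen if p >= 1}
                        miss = len(gen ^ G)
                        if miss <= max_mismatch:
                            key = (miss, depth, -index, t, m_lo)
                            if best is None or key < best[0]:
                                best = (key, t, node, (m_lo, m_hi), miss)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


@dataclass(frozen=True)
class ModelComparison:
    """Report of :func:`compare_models` over a phenotype."""

    positions: tuple[int, ...]
    decomposition: RunDecomposition
    cycle_inference: CycleInference
    fits: tuple[FitResult, ...]
    verdict: str
    best_k: int | None
    regenerated_diff: tuple[int, ...]

    @property
    def best_fit(self) -> FitResult | None:
        for f in self.fits:
            if f.k == self.best_k:
                return f
        return None

    def to_dict(self) -> dict:
        return {
            "positions": list(self.positions),
            "runs": [list(r) for r in self.decomposition.runs],
            "spacings": list(self.decomposition.spacings),
            "k_hat": self.cycle_inference.k,
            "k_hat_reason": self.cycle_inference.reason,
            "fits": [f.to_dict() for f in self.fits],
            "verdict": self.verdict,
            "best_k": self.best_k,
            "regenerated_diff": list(self.regenerated_diff),
        }


def _classify_positions(
    positions: Sequence[int],
    taxon_profile: str,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    min_events: bool = True,
) -> ModelComparison:
    positions = tuple(sorted(set(positions)))
    if not positions:
        raise DomainError("model comparison requires at least one gonopod position")
    decomp = decompose_runs(positions)
    cycles = infer_cycles(decomp)

    fits = [dyadic_fit(positions, k, min_events=min_events) for k in k_range]
    feasible_ks = [
        f.k for f in fits if f.feasible and f.multiplicative_cost == 1
    ]

    normal = NORMAL_GONOPOD_POSITIONS[taxon_profile]
    diff: tuple[int, ...] = ()
    best_k: int | None = None

    if decomp.run_count == 1:
        if set(positions) == set(normal):
            verdict = VERDICT_UNINFORMATIVE
        elif set(positions) & set(normal) or any(
            abs(p - q) == 1 for p in positions for q in normal
        ):
            verdict = VERDICT_CONTIGUOUS_EXTENSION
        else:
            verdict = VERDICT_UNINFORMATIVE
    elif cycles.k is not None and feasible_ks:
        verdict = VERDICT_MULTIPLICATIVE
        best_k = cycles.k if cycles.k in feasible_ks else feasible_ks[0]
        best = next(f for f in fits if f.k == best_k)
        regenerated = _regenerate(best)
        diff = tuple(sorted(set(regenerated) ^ set(positions)))
    else:
        verdict = VERDICT_CONTIGUOUS_ANOMALY

    return ModelComparison(
        positions=positions,
        decomposition=decomp,
        cycle_inference=cycles,
        fits=tuple(fits),
        verdict=verdict,
        best_k=best_k,
        regenerated_diff=diff,
    )


def compare_models(
    phenotype: Phenotype,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    bilateral_only: bool = False,
    exclude_normal: bool = False,
) -> ModelComparison:
    """Compare the multiplicative and sequential readings of a phenotype.

    For each ``k`` in *k_range* a :func:`dyadic_fit` is computed.  The verdict
    is ``"multiplicative-consistent"`` iff some ``k`` admits a feasible
    single-event fit *and* the run spacing is a power of 2; a single run is
    uninformative (or a contiguous extension of the normal gonopods, which
    needs no multiplicative explanation); anything else is a contiguous
    anomaly.  With ``exclude_normal`` the taxon's normal gonopod positions are
    treated as baseline and removed before scoring.
    """
    G = gonopod_positions(phenotype, bilateral_only=bilateral_only)
    if exclude_normal:
        G = [p for p in G if p not in NORMAL_GONOPOD_POSITIONS[phenotype.taxon_profile]]
    return _classify_positions(G, phenotype.taxon_profile, k_range=k_range)
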