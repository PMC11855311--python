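"""Karyotype-composition change under chromosomal rearrangement events.

Compositions are counted at the resolution the comparative data support:
numbers of chromosome pairs per coarse morphology class (biarmed,
subtelocentric, acrocentric), optionally with a multiset of relative pair
sizes for tracking tandem fusions. No ordered markers exist for these taxa,
so genome-order distances (DCJ, reversal) do not apply; the event algebra
is instead:

  centric fusion         two monoarmed pairs -> one biarmed pair (2n - 2)
  tandem fusion          two acrocentric pairs -> one acrocentric pair (2n - 2)
  fission                one biarmed pair -> two monoarmed pairs (2n + 2)
  pericentric inversion  toggles one pair monoarmed <-> biarmed (2n fixed)
  polyploidization       doubles every count (2n doubled)

``min_scenario`` finds a provably minimal event sequence between two
compositions by breadth-first search over the composition space.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

__all__ = [
    "KaryotypeComposition",
    "RearrangementEvent",
    "Scenario",
    "EVENT_KINDS",
    "apply_event",
    "enumerate_events",
    "min_scenario",
    "validate_scenario",
]

EVENT_KINDS = (
    "centric_fusion",
    "tandem_fusion",
    "fission",
    "pericentric_inversion",
    "polyploidization",
)

_MONO_CLASSES = ("st", "a")
_SIZE_TOL = 0.01  # relative tolerance for size-multiset matching


@dataclass(frozen=True)
class KaryotypeComposition:
    """Counts of chromosome pairs by coarse morphology.

    ``sizes`` (optional) is a tuple of relative pair sizes in arbitrary
    units, one per pair, used only when tracking tandem fusions.
    """

    biarmed: int = 0
    st: int = 0
    a: int = 0
    sizes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.biarmed, self.st, self.a) < 0:
            raise ValueError("pair counts must be non-negative")
        if self.sizes is not None and len(self.sizes) != self.n_pairs:
            raise ValueError(
                f"{len(self.sizes)} sizes for {self.n_pairs} pairs"
            )

    @property
    def n_pairs(self) -> int:
        return self.biarmed + self.st + self.a

    @property
    def monoarmed(self) -> int:
        return self.st + self.a

    @property
    def diploid_number(self) -> int:
        return 2 * self.n_pairs

    def counts_key(self) -> tuple[int, int, int]:
        return (self.biarmed, self.st, self.a)

    def normalized_sizes(self) -> tuple[float, ...] | None:
        if self.sizes is None:
            return None
        total = sum(self.sizes)
        return tuple(sorted(s / total for s in self.sizes))

    def matches(self, other: "KaryotypeComposition", size_aware: bool = False) -> bool:
        if self.counts_key() != other.counts_key():
            return False
        if not size_aware:
            return True
        a, b = self.normalized_sizes(), other.normalized_sizes()
        if a is None or b is None:
            return a is b
        return len(a) == len(b) and all(
            abs(x - y) <= _SIZE_TOL * max(x, y) for x, y in zip(a, b)
        )

    @classmethod
    def parse(cls, text: str) -> "KaryotypeComposition":
        """Parse e.g. "a=11" or "biarmed=17,st=2,a=19"."""
        counts = {"biarmed": 0, "st": 0, "a": 0}
        aliases = {"bi": "biarmed", "biarmed": "biarmed", "st": "st", "a": "a",
                   "mono": "a", "monoarmed": "a"}
        for term in text.split(","):
            key, _, val = term.strip().partition("=")
            key = key.strip().lower()
            if key not in aliases:
                raise ValueError(f"unknown morphology key {key!r} in {text!r}")
            counts[aliases[key]] += int(val)
        return cls(**counts)


@dataclass(frozen=True)
class RearrangementEvent:
    """One event; operands name the morphology classes consumed/produced.

    ``operands`` meaning per kind:
      centric_fusion        the two monoarmed classes consumed, e.g. ("a", "a")
      tandem_fusion         ("a", "a") always
      fission               the two monoarmed classes produced
      pericentric_inversion (from_class, to_class), one mono and one "biarmed"
      polyploidization      ()
    ``size_operands`` optionally selects pairs by index for size tracking.
    """

    kind: str
    operands: tuple[str, ...] = ()
    size_operands: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class Scenario:
    start: KaryotypeComposition
    events: list[RearrangementEvent] = field(default_factory=list)

    @property
    def end(self) -> KaryotypeComposition:
        comp = self.start
        for e in self.events:
            comp = apply_event(comp, e)
        return comp

    def event_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in EVENT_KINDS}
        for e in self.events:
            counts[e.kind] += 1
        return {k: v for k, v in counts.items() if v}


def _counts_after(key: tuple[int, int, int], event_kind: str,
                  operands: tuple[str, ...]) -> tuple[int, int, int] | None:
    """Pure count transition; None when operands are unavailable."""
    bi, st, a = key
    c = {"biarmed": bi, "st": st, "a": a}
    # consume operands first and check availability before adding products,
    # so an event can never operate on a pair it itself produces
    if event_kind == "centric_fusion":
        x, y = operands
        c[x] -= 1
        c[y] -= 1
        if min(c.values()) < 0:
            return None
        c["biarmed"] += 1
    elif event_kind == "tandem_fusion":
        c["a"] -= 2
        if c["a"] < 0:
            return None
        c["a"] += 1
    elif event_kind == "fission":
        x, y = operands
        c["biarmed"] -= 1
        if c["biarmed"] < 0:
            return None
        c[x] += 1
        c[y] += 1
    elif event_kind == "pericentric_inversion":
        src, dst = operands
        c[src] -= 1
        if c[src] < 0:
            return None
        c[dst] += 1
    elif event_kind == "polyploidization":
        c = {k: 2 * v for k, v in c.items()}
    return (c["biarmed"], c["st"], c["a"])


def apply_event(comp: KaryotypeComposition, event: RearrangementEvent) -> KaryotypeComposition:
    """Apply one event, updating counts and (when present) pair sizes."""
    operands = event.operands or _default_operands(event.kind)
    key = _counts_after(comp.counts_key(), event.kind, operands)
    if key is None:
        raise ValueError(
            f"event {event.kind} {operands} not applicable to {comp.counts_key()}"
        )
    sizes = comp.sizes
    if sizes is not None:
        sizes = _sizes_after(comp, event)
    return KaryotypeComposition(biarmed=key[0], st=key[1], a=key[2], sizes=sizes)


def _default_operands(kind: str) -> tuple[str, ...]:
    if kind in ("centric_fusion", "tandem_fusion", "fission"):
        return ("a", "a")
    if kind == "pericentric_inversion":
        return ("a", "biarmed")
    return ()


def _sizes_after(comp: KaryotypeComposition, event: RearrangementEvent) -> tuple[float, ...]:
    sizes = list(comp.sizes)  # type: ignore[arg-type]
    if event.kind in ("centric_fusion", "tandem_fusion"):
        if event.size_operands is not None:
            i, j = sorted(event.size_operands, reverse=True)
        else:
            # default: fuse the two smallest pairs
            order = sorted(range(len(sizes)), key=sizes.__getitem__)
            i, j = sorted(order[:2], reverse=True)
        merged = sizes[i] + sizes[j]
        del sizes[i]
        del sizes[j]
        sizes.append(merged)
    elif event.kind == "fission":
        i = event.size_operands[0] if event.size_operands else max(
            range(len(sizes)), key=sizes.__getitem__
        )
        half = sizes.pop(i) / 2.0
        sizes.extend([half, half])
    elif event.kind == "polyploidization":
        sizes = sizes * 2
    # inversions leave sizes untouched
    return tuple(sizes)


def enumerate_events(
    key: tuple[int, int, int],
    allowed_kinds: Iterable[str],
    coarse: bool = True,
    max_pairs: int = 60,
) -> list[tuple[RearrangementEvent, tuple[int, int, int]]]:
    """All distinct count transitions from ``key`` under the allowed kinds.

    ``coarse`` restricts inversions to the monoarmed <-> biarmed toggle
    without distinguishing st from a targets beyond what the counts force;
    fine mode also proposes a <-> st inversions.
    """
    out: list[tuple[RearrangementEvent, tuple[int, int, int]]] = []
    seen: set[tuple[str, tuple[int, int, int]]] = set()

    def push(kind: str, operands: tuple[str, ...]) -> None:
        nxt = _counts_after(key, kind, operands)
        if nxt is None or sum(nxt) > max_pairs:
            return
        tag = (kind, nxt)
        if tag in seen:
            return
        seen.add(tag)
        out.append((RearrangementEvent(kind, operands), nxt))

    for kind in allowed_kinds:
        if kind == "centric_fusion":
            for ops in itertools.combinations_with_replacement(_MONO_CLASSES, 2):
                push(kind, ops)
        elif kind == "tandem_fusion":
            push(kind, ("a", "a"))
        elif kind == "fission":
            for ops in itertools.combinations_with_replacement(_MONO_CLASSES, 2):
                push(kind, ops)
        elif kind == "pericentric_inversion":
            targets = [("a", "biarmed"), ("st", "biarmed"),
                       ("biarmed", "a"), ("biarmed", "st")]
            if not coarse:
                targets += [("a", "st"), ("st", "a")]
            for ops in targets:
                push(kind, ops)
        elif kind == "polyploidization":
            push(kind, ())
    return out


def min_scenario(
    src: KaryotypeComposition,
    tgt: KaryotypeComposition | Callable[[KaryotypeComposition], bool],
    allowed_kinds: Sequence[str] = EVENT_KINDS,
    size_aware: bool = False,
    coarse_inversions: bool = True,
    max_pairs: int = 60,
    max_events: int = 64,
) -> tuple[dict[str, int], Scenario] | None:
    """Breadth-first search for a minimal event sequence from src to tgt.

    ``tgt`` is either a composition (matched on counts, and on the size
    multiset when ``size_aware``) or a predicate over compositions.
    Returns ``(per-kind event counts, witness Scenario)`` for one optimal
    witness, or None when the target is unreachable within the bounds.
    BFS on unit edge costs guarantees the witness length is globally
    minimal.
    """
    if callable(tgt):
        done = tgt
    else:
        done = lambda c: c.matches(tgt, size_aware=size_aware)  # noqa: E731

    if size_aware:
        return _min_scenario_sized(src, done, allowed_kinds, coarse_inversions,
                                   max_pairs, max_events)

    start_key = src.counts_key()
    if done(src):
        return {}, Scenario(start=src, events=[])
    parent: dict[tuple[int, int, int],
                 tuple[tuple[int, int, int], RearrangementEvent]] = {}
    depth = {start_key: 0}
    queue: deque[tuple[int, int, int]] = deque([start_key])
    while queue:
        key = queue.popleft()
        if depth[key] >= max_events:
            continue
        for event, nxt in enumerate_events(key, allowed_kinds,
                                           coarse=coarse_inversions,
                                           max_pairs=max_pairs):
            if nxt in depth:
                continue
            depth[nxt] = depth[key] + 1
            parent[nxt] = (key, event)
            comp = KaryotypeComposition(*nxt)
            if done(comp):
                events: list[RearrangementEvent] = []
                cur = nxt
                while cur != start_key:
                    prev, ev = parent[cur]
                    events.append(ev)
                    cur = prev
                events.reverse()
                scen = Scenario(start=replace(src, sizes=None), events=events)
                return scen.event_counts(), scen
            queue.append(nxt)
    return None


def _min_scenario_sized(src, done, allowed_kinds, coarse_inversions,
                        max_pairs, max_events):
    """BFS over (counts, rounded normalized size multiset) states."""
    if src.sizes is None:
        raise ValueError("size_aware search requires src.sizes")

    def state_of(comp: KaryotypeComposition):
        norm = comp.normalized_sizes()
        return (comp.counts_key(), tuple(round(s, 6) for s in norm))

    if done(src):
        return {}, Scenario(start=src, events=[])
    start_state = state_of(src)
    seen = {start_state}
    queue: deque[tuple[KaryotypeComposition, list[RearrangementEvent], int]] = deque(
        [(src, [], 0)]
    )
    while queue:
        comp, events, d = queue.popleft()
        if d >= max_events:
            continue
        for event, _nxt in enumerate_events(comp.counts_key(), allowed_kinds,
                                            coarse=coarse_inversions,
                                            max_pairs=max_pairs):
            candidates = [event]
            if event.kind in ("centric_fusion", "tandem_fusion") and comp.sizes:
                # size-aware fusion outcome depends on which pairs merge
                n = len(comp.sizes)
                candidates = [
                    replace(event, size_operands=(i, j))
                    for i, j in itertools.combinations(range(n), 2)
                ]
            for ev in candidates:
                try:
                    nxt_comp = apply_event(comp, ev)
                except ValueError:
                    continue
                state = state_of(nxt_comp)
                if state in seen:
                    continue
                seen.add(state)
                nxt_events = events + [ev]
                if done(nxt_comp):
                    scen = Scenario(start=src, events=nxt_events)
                    return scen.event_counts(), scen
                queue.append((nxt_comp, nxt_events, d + 1))
    return None


def validate_scenario(
    src: KaryotypeComposition,
    events: Sequence[RearrangementEvent],
    expected: KaryotypeComposition | None = None,
    size_aware: bool = False,
) -> tuple[KaryotypeComposition, dict]:
    """Replay events from src; report the end state and consistency.

    Raises ValueError naming the failing step when an event is not
    applicable. The report notes whether the end matches ``expected``.
    """
    comp = src
    for k, event in enumerate(events, start=1):
        try:
            comp = apply_event(comp, event)
        except ValueError as exc:
            raise ValueError(f"event {k} ({event.kind}) inapplicable: {exc}") from exc
    report = {
        "end": comp,
        "n_events": len(events),
        "event_counts": Scenario(start=src, events=list(events)).event_counts(),
        "matches_expected": None,
    }
    if expected is not None:
        report["matches_expected"] = comp.matches(expected, size_aware=size_aware)
    return comp, report
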