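"""Dynamic page layout: components, AOI groupings, scroll and pop-up state.

The stimulus is a one-page layout taller than the viewport.  Components are
axis-aligned rectangles in page coordinates, except *sticky* components
(e.g. a floating menu bar) which stay put in viewport/screen coordinates
while the page scrolls underneath.  AOIs are disjoint groups of components;
one AOI may be a pop-up that, while open, occludes everything below it.

Gaze is recorded in screen space; hit-testing reconciles screen points with
the scrolled page using the event-derived :class:`LayoutState`.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .gaze_io import InteractionEvent

WHITESPACE = "whitespace"


@dataclass(frozen=True)
class Component:
    id: str
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1), page px
    sticky: bool = False

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"component {self.id}: degenerate rect {self.rect}")

    def contains(self, x: float, y: float) -> bool:
        # Half-open containment: deterministic at shared borders.
        x0, y0, x1, y1 = self.rect
        return x0 <= x < x1 and y0 <= y < y1


@dataclass(frozen=True)
class AOIDefinition:
    index: int  # 1-based AOI index j
    components: tuple[str, ...]
    dynamic: bool = False
    occludes_below: bool = False


@dataclass
class Layout:
    screen: tuple[float, float]
    components: list[Component]
    aois: list[AOIDefinition]
    _comp_by_id: dict[str, Component] = field(init=False, repr=False)
    _aoi_of_comp: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._comp_by_id = {}
        for c in self.components:
            if c.id in self._comp_by_id:
                raise ValueError(f"duplicate component id {c.id}")
            self._comp_by_id[c.id] = c
        self._aoi_of_comp = {}
        seen: set[str] = set()
        for aoi in self.aois:
            for cid in aoi.components:
                if cid not in self._comp_by_id:
                    raise ValueError(f"AOI {aoi.index} references unknown component {cid}")
                if cid in seen:
                    raise ValueError(f"component {cid} appears in two AOIs")
                seen.add(cid)
                self._aoi_of_comp[cid] = aoi.index
        self._validate_overlap()

    def _validate_overlap(self) -> None:
        """Components within one layer must not overlap.

        The pop-up layer legitimately covers page content and the sticky
        layer floats above it, so overlap is only forbidden between
        components of the same layer.
        """
        popup_ids = set()
        for aoi in self.aois:
            if aoi.occludes_below:
                popup_ids.update(aoi.components)
        layers: dict[str, list[Component]] = {"sticky": [], "page": [], "popup": []}
        for c in self.components:
            if c.id in popup_ids:
                layers["popup"].append(c)
            elif c.sticky:
                layers["sticky"].append(c)
            else:
                layers["page"].append(c)
        for name, comps in layers.items():
            for i, a in enumerate(comps):
                for b in comps[i + 1 :]:
                    if _rects_overlap(a.rect, b.rect):
                        raise ValueError(
                            f"components {a.id} and {b.id} overlap in the {name} layer"
                        )

    @property
    def n_aois(self) -> int:
        return len(self.aois)

    @property
    def popup_aoi(self) -> AOIDefinition | None:
        for aoi in self.aois:
            if aoi.occludes_below:
                return aoi
        return None

    def component(self, cid: str) -> Component:
        return self._comp_by_id[cid]

    def aoi_of(self, component_id: str) -> int | None:
        return self._aoi_of_comp.get(component_id)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "screen": list(self.screen),
            "components": [
                {"id": c.id, "rect": list(c.rect), "sticky": c.sticky}
                for c in self.components
            ],
            "aois": [
                {
                    "index": a.index,
                    "components": list(a.components),
                    "dynamic": a.dynamic,
                    "occludes_below": a.occludes_below,
                }
                for a in self.aois
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Layout":
        return cls(
            screen=tuple(d["screen"]),
            components=[
                Component(c["id"], tuple(c["rect"]), bool(c.get("sticky", False)))
                for c in d["components"]
            ],
            aois=[
                AOIDefinition(
                    int(a["index"]),
                    tuple(a["components"]),
                    bool(a.get("dynamic", False)),
                    bool(a.get("occludes_below", False)),
                )
                for a in d["aois"]
            ],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Layout":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _rects_overlap(a: tuple, b: tuple) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


@dataclass
class LayoutState:
    """Scroll offsets and pop-up intervals derived from interaction events.

    Scroll is a step function of time (no interpolation between events);
    pop-up visibility is a set of non-overlapping ``[open, close)`` spans.
    An unclosed pop-up stays open until the end of the recording.
    """

    scroll_times: list[float] = field(default_factory=list)
    scroll_offsets: list[tuple[float, float]] = field(default_factory=list)
    popup_intervals: list[tuple[float, float]] = field(default_factory=list)

    @classmethod
    def from_events(
        cls, events: Sequence[InteractionEvent], duration_ms: float = float("inf")
    ) -> "LayoutState":
        state = cls()
        open_t: float | None = None
        for ev in sorted(events, key=lambda e: e.t_ms):
            if ev.kind == "scroll":
                # Payload is the new vertical offset; horizontal supported via tuple.
                off = ev.payload
                dx, dy = (off if isinstance(off, (tuple, list)) else (0.0, float(off)))
                state.scroll_times.append(ev.t_ms)
                state.scroll_offsets.append((float(dx), float(dy)))
            elif ev.kind == "popup_open" and open_t is None:
                open_t = ev.t_ms
            elif ev.kind == "popup_close" and open_t is not None:
                state.popup_intervals.append((open_t, ev.t_ms))
                open_t = None
        if open_t is not None:
            state.popup_intervals.append((open_t, duration_ms))
        return state

    def scroll_at(self, t_ms: float) -> tuple[float, float]:
        """Offset in force at time t (step function; (0,0) before any event)."""
        i = bisect.bisect_right(self.scroll_times, t_ms) - 1
        return self.scroll_offsets[i] if i >= 0 else (0.0, 0.0)

    def popup_open_at(self, t_ms: float) -> bool:
        return any(a <= t_ms < b for a, b in self.popup_intervals)


def to_page_point(
    point: tuple[float, float], layout_state: LayoutState, t_ms: float
) -> tuple[float, float]:
    """Map a screen-space point to page coordinates at time t.

    Page = screen + scroll offset.  Sticky components are tested in screen
    space and do not use this mapping.
    """
    dx, dy = layout_state.scroll_at(t_ms)
    return (point[0] + dx, point[1] + dy)


def hit_test(
    point: tuple[float, float],
    t_ms: float,
    layout: Layout,
    layout_state: LayoutState,
) -> tuple[str, int | None]:
    """Resolve a screen-space gaze point to ``(component_id, aoi_index)``.

    Total function: every point resolves to exactly one component (or
    ``"whitespace"``) and one AOI (or ``None``).  While the pop-up is open
    only its own rectangle is active — every other point is whitespace, the
    occluded AOIs being deactivated.  Otherwise sticky components are tested
    first in screen space, then page-fixed components in scrolled page
    space.  Ungrouped components hit with ``aoi_index=None``.
    """
    popup = layout.popup_aoi
    popup_ids = set(popup.components) if popup is not None else set()
    if popup is not None and layout_state.popup_open_at(t_ms):
        for cid in popup.components:
            # Pop-ups live in screen space (they float over the viewport).
            if layout.component(cid).contains(*point):
                return cid, popup.index
        return WHITESPACE, None
    for c in layout.components:
        if c.sticky and c.id not in popup_ids and c.contains(*point):
            return c.id, layout.aoi_of(c.id)
    px, py = to_page_point(point, layout_state, t_ms)
    for c in layout.components:
        if c.sticky or c.id in popup_ids:
            continue
        if c.contains(px, py):
            return c.id, layout.aoi_of(c.id)
    return WHITESPACE, None
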