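"""Event-type schema for the nine GENIA event types.

The GENIA event extraction task defines nine event types grouped into three
classes: simple events (SVT) take exactly one protein Theme; Binding (BIND)
takes up to two protein Themes; regulation events (REG) take a Theme and an
optional Cause, either of which may itself be an event (nesting).  Only
primary arguments are modelled; secondary arguments (Site, AtLoc, ToLoc,
CSite) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

SVT = "SVT"
BIND = "BIND"
REG = "REG"

EVENT_CLASSES = (SVT, BIND, REG)


@dataclass(frozen=True)
class EventTypeSpec:
    """Allowed primary-argument structure for one event type."""

    name: str
    event_class: str
    max_themes: int
    allows_cause: bool
    theme_may_be_event: bool


_SPECS: dict[str, EventTypeSpec] = {
    s.name: s
    for s in (
        EventTypeSpec("Gene_expression", SVT, 1, False, False),
        EventTypeSpec("Transcription", SVT, 1, False, False),
        EventTypeSpec("Protein_catabolism", SVT, 1, False, False),
        EventTypeSpec("Localization", SVT, 1, False, False),
        EventTypeSpec("Phosphorylation", SVT, 1, False, False),
        EventTypeSpec("Binding", BIND, 2, False, False),
        EventTypeSpec("Regulation", REG, 1, True, True),
        EventTypeSpec("Positive_regulation", REG, 1, True, True),
        EventTypeSpec("Negative_regulation", REG, 1, True, True),
    )
}

EVENT_TYPES: tuple[str, ...] = tuple(_SPECS)
SVT_TYPES: tuple[str, ...] = tuple(t for t, s in _SPECS.items() if s.event_class == SVT)
BIND_TYPES: tuple[str, ...] = tuple(t for t, s in _SPECS.items() if s.event_class == BIND)
REG_TYPES: tuple[str, ...] = tuple(t for t, s in _SPECS.items() if s.event_class == REG)

NEGATIVE_LABEL = "neg"


def spec_for(event_type: str) -> EventTypeSpec:
    try:
        return _SPECS[event_type]
    except KeyError:
        raise ValueError(f"unknown event type: {event_type!r}") from None


def event_class(event_type: str) -> str:
    """Map an event type to its class (SVT, BIND or REG)."""
    return spec_for(event_type).event_class


def validate_event(
    event_type: str,
    n_themes: int,
    has_cause: bool,
    theme_is_event: bool = False,
) -> None:
    """Raise ValueError when the argument structure violates the schema."""
    s = spec_for(event_type)
    if n_themes < 1:
        raise ValueError(f"{event_type}: Theme is mandatory")
    if n_themes > s.max_themes:
        raise ValueError(f"{event_type}: at most {s.max_themes} Theme(s) allowed")
    if has_cause and not s.allows_cause:
        raise ValueError(f"{event_type}: Cause only allowed for REG-class events")
    if theme_is_event and not s.theme_may_be_event:
        raise ValueError(f"{event_type}: Theme must be a protein")
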