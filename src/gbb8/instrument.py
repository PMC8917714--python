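"""Default instrument definition for the GBB-8.

The GBB-8 is the eight-item short form of the Giessen Subjective Complaints
List. Respondents rate eight common somatic complaints on a five-point scale
from 0 ("not at all") to 4 ("very much"). The items pair up into four
two-item subscales — exhaustion, gastrointestinal, musculoskeletal and
cardiovascular complaints — and the subscales are conceived as indicators of
a single higher-order construct, general somatic symptom burden.

Other instruments with a paired-item structure can be analysed by passing a
custom item list and subscale map wherever these defaults are accepted.
"""

from __future__ import annotations

#: Item column names in questionnaire order.
ITEM_NAMES: tuple[str, ...] = (
    "exhausted",        # Being easily exhausted
    "tiredness",        # Tiredness
    "bloated",          # Feeling bloated or distended
    "stomachache",      # Stomachache
    "backache",         # Backache
    "neck_pain",        # Neck or shoulder pain
    "palpitations",     # Palpitations or heart pounding
    "dizziness",        # Dizziness
)

#: Subscale -> ordered item pair. The order defines the factor order used in
#: all model specifications.
SUBSCALES: dict[str, tuple[str, str]] = {
    "exhaustion": ("exhausted", "tiredness"),
    "gastrointestinal": ("bloated", "stomachache"),
    "musculoskeletal": ("backache", "neck_pain"),
    "cardiovascular": ("palpitations", "dizziness"),
}

#: Response scale bounds (inclusive).
MIN_RESPONSE: int = 0
MAX_RESPONSE: int = 4

#: Number of response categories.
N_CATEGORIES: int = MAX_RESPONSE - MIN_RESPONSE + 1


def subscale_of(item: str, subscales: dict[str, tuple[str, str]] | None = None) -> str:
    """Return the subscale name an item belongs to."""
    table = subscales if subscales is not None else SUBSCALES
    for scale, items in table.items():
        if item in items:
            return scale
    raise KeyError(f"item {item!r} is not part of any subscale")


def partner_item(item: str, subscales: dict[str, tuple[str, str]] | None = None) -> str:
    """Return the other item of the two-item subscale containing ``item``."""
    table = subscales if subscales is not None else SUBSCALES
    pair = table[subscale_of(item, table)]
    return pair[1] if pair[0] == item else pair[0]
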