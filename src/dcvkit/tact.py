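"""TACT placeholder grammar and questionnaire rendering.

Items are phrased generically using the TACT principle — specify the Target,
Action, Context, and Time of a behavior — so one item bank can be tailored
to any implementation setting. A placeholder is a bracketed group of one or
more comma-separated tokens, e.g. ``[A]``, ``[C, T]``, ``[Ta]``,
``[innovation/guideline]``, ``[profession]``; Dutch items use the surface
forms ``[innovatie/richtlijn]`` and ``[beroep]`` for the same slots. Each
token resolves to one of six canonical keys, which is what a
:class:`~dcvkit.model.TactMapping` supplies text for.
"""

from __future__ import annotations

import re

from .errors import DcvValidationError
from .model import ItemSpec, TactMapping

PLACEHOLDER_RE = re.compile(r"\[([^\[\]]+)\]")

CANONICAL_KEYS = ("A", "C", "T", "Ta", "innovation", "profession")

# surface token -> canonical key; lookups also try a lower-cased first letter
# so sentence-initial "[Innovation/guideline]" resolves (and is re-capitalized).
_ALIASES = {
    "A": "A",
    "C": "C",
    "T": "T",
    "Ta": "Ta",
    "innovation": "innovation",
    "innovation/guideline": "innovation",
    "innovatie": "innovation",
    "innovatie/richtlijn": "innovation",
    "profession": "profession",
    "beroep": "profession",
}


def _resolve_token(token: str) -> tuple[str, bool]:
    """Return (canonical key, was_capitalized) or raise for an unknown token."""
    token = token.strip()
    if token in _ALIASES:
        return _ALIASES[token], False
    decap = token[:1].lower() + token[1:]
    if decap in _ALIASES and decap not in ("a", "c", "t", "ta"):
        return _ALIASES[decap], True
    raise DcvValidationError(f"unknown placeholder token {token!r}")


def placeholders_in(template: str) -> frozenset[str]:
    """Canonical placeholder keys used by a template (raises on unknown tokens)."""
    keys: set[str] = set()
    for match in PLACEHOLDER_RE.finditer(template):
        for token in match.group(1).split(","):
            key, _ = _resolve_token(token)
            keys.add(key)
    return frozenset(keys)


def is_placeholder_group(text: str) -> bool:
    """Whether a bracketed group's content parses under the placeholder grammar."""
    try:
        for token in text.split(","):
            _resolve_token(token)
    except DcvValidationError:
        return False
    return True


def render_text(template: str, tact: TactMapping) -> str:
    """Substitute every placeholder group in ``template``.

    A group like ``[C, T]`` renders as the comma-joined replacements of its
    tokens. Raises if the mapping lacks a key the template needs. Text with
    no placeholders is returned unchanged (rendering is idempotent).
    """

    def _sub(match: re.Match[str]) -> str:
        parts = []
        capitalize_first = False
        for i, token in enumerate(match.group(1).split(",")):
            key, capped = _resolve_token(token)
            if i == 0 and capped:
                capitalize_first = True
            if key not in tact.mapping:
                raise DcvValidationError(
                    f"TACT mapping ({tact.language}) is missing placeholder {key!r} "
                    f"needed by {match.group(0)!r}"
                )
            parts.append(tact.mapping[key])
        out = ", ".join(parts)
        if capitalize_first and out:
            out = out[0].upper() + out[1:]
        return out

    return PLACEHOLDER_RE.sub(_sub, template)


def render_item(item: ItemSpec, tact: TactMapping) -> str:
    """Render one item's text in the mapping's language, fully substituted."""
    template = item.text(tact.language)
    rendered = render_text(template, tact)
    leftover = [
        m.group(0)
        for m in PLACEHOLDER_RE.finditer(rendered)
        if is_placeholder_group(m.group(1))
    ]
    if leftover:
        raise DcvValidationError(
            f"item {item.item_id}: unsubstituted placeholders remain: {leftover}"
        )
    return rendered
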