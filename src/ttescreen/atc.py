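"""Utilities for the Anatomical Therapeutic Chemical (ATC) drug hierarchy.

A full ATC code has five levels encoded positionally: one letter (anatomical
main group), two digits (therapeutic subgroup), one letter (pharmacological
subgroup), one letter (chemical subgroup) and two digits (chemical
substance), e.g. ``A02BA02`` (ranitidine).  Prefixes of length 1, 3, 4 and 5
address levels 1-4 and are valid group keys in their own right.
"""

from __future__ import annotations

import re

__all__ = ["AtcError", "parse_atc_levels", "same_group", "atc_level"]

# full shape: letter, 2 digits, letter, letter, 2 digits
_FULL = re.compile(r"^[A-Z]\d{2}[A-Z][A-Z]\d{2}$")

# prefix length -> level
_LEVEL_BY_LEN = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
_LEN_BY_LEVEL = {v: k for k, v in _LEVEL_BY_LEN.items()}


class AtcError(ValueError):
    """Raised for malformed ATC codes or impossible level requests."""


def _validate(code: str) -> None:
    if not isinstance(code, str):
        raise AtcError(f"ATC code must be a string, got {type(code).__name__}")
    if len(code) not in _LEVEL_BY_LEN:
        raise AtcError(
            f"malformed ATC code {code!r}: length {len(code)} is not a "
            "valid code or prefix length (1, 3, 4, 5 or 7)"
        )
    # validate against the full pattern truncated to the prefix length
    padded = code + "A00AA00"[len(code):]
    if not _FULL.match(padded):
        raise AtcError(f"malformed ATC code {code!r}: wrong letter/digit alternation")


def atc_level(code: str) -> int:
    """Return the deepest hierarchy level a code or prefix resolves."""
    _validate(code)
    return _LEVEL_BY_LEN[len(code)]


def parse_atc_levels(code: str) -> dict[int, str]:
    """Split an ATC code or prefix into its hierarchical level prefixes.

    Parameters
    ----------
    code
        A syntactically valid ATC code (7 characters) or prefix
        (1, 3, 4 or 5 characters).

    Returns
    -------
    dict
        Mapping of level (1..5) to prefix; levels beyond the resolution of
        ``code`` are absent.

    Examples
    --------
    >>> parse_atc_levels("A02BA02")
    {1: 'A', 2: 'A02', 3: 'A02B', 4: 'A02BA', 5: 'A02BA02'}
    >>> sorted(parse_atc_levels("N04BD"))
    [1, 2, 3, 4]
    """
    _validate(code)
    max_level = _LEVEL_BY_LEN[len(code)]
    return {lvl: code[: _LEN_BY_LEVEL[lvl]] for lvl in range(1, max_level + 1)}


def same_group(code_a: str, code_b: str, level: int) -> bool:
    """True iff two codes share the same ATC prefix at ``level``.

    Raises
    ------
    AtcError
        If either code is malformed, if ``level`` is outside 1..5, or if it
        exceeds the resolution of either code.
    """
    if level not in _LEN_BY_LEVEL:
        raise AtcError(f"ATC level must be in 1..5, got {level}")
    la = parse_atc_levels(code_a)
    lb = parse_atc_levels(code_b)
    if level not in la or level not in lb:
        raise AtcError(
            f"level {level} exceeds the resolution of {code_a!r} or {code_b!r}"
        )
    return la[level] == lb[level]
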