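"""Shared text primitives: tokenization, surface normalization, underscore joining.

Disease and plant names are mixtures of letters, digits and punctuation
("Van der Woude syndrome", "C7 deficiency", "MODY-2"), so the tokenizer
splits on whitespace and punctuation but keeps internal hyphens and
underscores, which carry meaning in identifiers and in underscore-joined
multi-word names.
"""

from __future__ import annotations

import re

# A token is a maximal run of word characters, allowing internal hyphens;
# leading/trailing hyphens are stripped by construction.
_TOKEN_RE = re.compile(r"\w(?:[\w-]*\w)?")

_WS_RE = re.compile(r"\s+")


def tokenize(text: str) -> list[str]:
    """Split text into tokens, keeping internal hyphens and underscores.

    >>> tokenize("Van der Woude syndrome (VWS).")
    ['Van', 'der', 'Woude', 'syndrome', 'VWS']
    >>> tokenize("non-small cell lung_cancer")
    ['non-small', 'cell', 'lung_cancer']
    """
    return _TOKEN_RE.findall(text)


def underscore_join(name: str) -> str:
    """Join a multi-word name into a single token with underscores.

    Internal whitespace runs become single underscores; single-word names
    are returned unchanged.
    """
    return _WS_RE.sub("_", name.strip())


def normalize_surface(surface: str, *, ignore_hyphens: bool = False) -> str:
    """Normalize a surface form for exact dictionary matching.

    Case-insensitive, with whitespace runs collapsed to single spaces.
    Hyphens are discriminative by default; ``ignore_hyphens=True`` treats
    them as spaces.
    """
    s = surface.strip()
    if ignore_hyphens:
        s = s.replace("-", " ")
    return _WS_RE.sub(" ", s).casefold()
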