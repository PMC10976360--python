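"""Seq2seq-safe encoding of SPARQL queries.

Sequence-to-sequence language models with natural-language tokenizers
mishandle two things in raw SPARQL: the characters ``< > { }`` fall outside
the vocabulary, and whitespace before a ``?`` is stripped because the
tokenizer treats it as sentence punctuation, which makes the variable
prefix ambiguous.  The encoding therefore rewrites

* ``<`` ``>`` ``{`` ``}``  ->  ``&lt;`` ``&gt;`` ``&lcub;`` ``&rcub;``
* the variable marker ``?name`` -> ``var_name`` (outside quoted literals)

and :func:`decode` inverts it exactly.  Queries containing any of the
target sequences are rejected up front so the substitution stays a
bijection.
"""

from __future__ import annotations

import re

__all__ = ["encode", "decode", "EncodeError", "DecodeError", "CHAR_MAP"]

#: Structural-character substitutions (applied globally, literals included).
CHAR_MAP = {"<": "&lt;", ">": "&gt;", "{": "&lcub;", "}": "&rcub;"}

_RESERVED = ("var_", "&lt;", "&gt;", "&lcub;", "&rcub;")

_VAR_NAME = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_ENC_VAR = re.compile(r"var_([A-Za-z_][A-Za-z0-9_]*)")
_DANGLING = re.compile(r"&(?:lt|gt|lcub|rcub)\b(?!;)")


class EncodeError(ValueError):
    """Input query contains a reserved target sequence."""


class DecodeError(ValueError):
    """Encoded text is malformed (e.g. a dangling entity fragment)."""


def encode(query: str) -> str:
    """Encode a SPARQL query into its model-facing representation.

    Variable substitution applies only to ``?name`` tokens outside quoted
    literals; the four structural characters are substituted everywhere.
    Whitespace is preserved byte-for-byte.
    """
    for seq in _RESERVED:
        if seq in query:
            raise EncodeError(f"query contains reserved sequence {seq!r}")
    out: list[str] = []
    i, n = 0, len(query)
    quote: str | None = None
    while i < n:
        c = query[i]
        if quote is not None:
            if c == "\\" and i + 1 < n:
                out.append(query[i : i + 2])
                i += 2
                continue
            if c == quote:
                quote = None
            out.append(CHAR_MAP.get(c, c))
            i += 1
            continue
        if c in "\"'":
            quote = c
            out.append(c)
            i += 1
            continue
        boundary = not out or not (out[-1].isalnum() or out[-1] == "_")
        if c == "?" and boundary:
            m = _VAR_NAME.match(query, i + 1)
            if m:
                out.append("var_" + m.group(0))
                i = m.end()
                continue
        out.append(CHAR_MAP.get(c, c))
        i += 1
    return "".join(out)


def decode(encoded: str) -> str:
    """Invert :func:`encode`, recovering the original SPARQL text.

    Raises :class:`DecodeError` on dangling entity fragments such as
    ``&lcub`` without the closing semicolon — the signature of truncated
    or malformed model output.
    """
    if _DANGLING.search(encoded):
        raise DecodeError("dangling entity fragment in encoded query")
    inverse = {v: k for k, v in CHAR_MAP.items()}
    out: list[str] = []
    i, n = 0, len(encoded)
    quote: str | None = None
    prev_word = False  # previous emitted char is a name character
    while i < n:
        c = encoded[i]
        if c == "&":
            for ent, ch in inverse.items():
                if encoded.startswith(ent, i):
                    out.append(ch)
                    i += len(ent)
                    prev_word = False
                    break
            else:
                out.append(c)
                i += 1
                prev_word = False
            continue
        if quote is not None:
            if c == "\\" and i + 1 < n:
                out.append(encoded[i : i + 2])
                i += 2
                continue
            if c == quote:
                quote = None
            out.append(c)
            i += 1
            continue
        if c in "\"'":
            quote = c
            out.append(c)
            i += 1
            prev_word = False
            continue
        if c == "v" and not prev_word:
            m = _ENC_VAR.match(encoded, i)
            if m:
                out.append("?" + m.group(1))
                i = m.end()
                prev_word = True
                continue
        out.append(c)
        prev_word = c.isalnum() or c == "_"
        i += 1
    return "".join(out)
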