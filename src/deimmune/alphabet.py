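"""Amino-acid alphabets shared across modules.

The family model works over the 20 standard residues plus the alignment gap
as a 21st state; epitope scoring and sequence design operate on gap-free
sequences over the 20 standard residues.
"""

from __future__ import annotations

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA_GAP = AA20 + GAP

_EQUIV_GAPS = ".~"  # common alternative gap glyphs in A2M/Stockholm


def clean_symbol(c: str) -> str:
    """Map a raw alignment character to the canonical alphabet.

    Lower case (A2M insert states) is upper-cased; '.', '~' and unknown
    codes (B, Z, X, ...) become the gap symbol.
    """
    c = c.upper()
    if c in _EQUIV_GAPS:
        return GAP
    return c if c in AA_GAP else GAP


def encode(seq: str, alphabet: str = AA_GAP) -> np.ndarray:
    """Encode a sequence as integer indices into ``alphabet``.

    Raises ``ValueError`` on symbols outside the alphabet.
    """
    lut = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([lut[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet {alphabet!r}") from None


def decode(idx: np.ndarray, alphabet: str = AA_GAP) -> str:
    return "".join(alphabet[i] for i in idx)
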