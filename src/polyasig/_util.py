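"""Small shared helpers: strand arithmetic, alphabet transforms, hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA on the sense strand (T/t -> U/u)."""
    return seq.replace("T", "U").replace("t", "u")


def back_transcribe(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
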