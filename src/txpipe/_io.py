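"""Transparent text access to plain, gzip- and bzip2-compressed files."""

from __future__ import annotations

import bz2
import gzip
from pathlib import Path
from typing import IO, Union

PathLike = Union[str, Path]


def open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a possibly-compressed text file by extension (.gz / .bz2)."""
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    if p.endswith(".bz2"):
        return bz2.open(p, mode)
    return open(p, mode)
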