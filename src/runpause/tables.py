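"""CSV round-tripping with a commented provenance header.

Every table written by the CLI starts with ``# key=value`` lines capturing
the full parameter set, so any figure can be regenerated from its data file
alone.  Floats are written at 12 significant digits.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Dict, TextIO, Tuple, Union

import pandas as pd

__all__ = ["write_table", "read_table"]

_FLOAT_FMT = "%.12g"


def write_table(
    frame: pd.DataFrame,
    dest: Union[str, Path, TextIO],
    header: Dict[str, object],
) -> None:
    """Write a DataFrame as CSV preceded by ``# key=value`` header lines."""
    lines = "".join(f"# {k}={v}\n" for k, v in header.items())
    body = frame.to_csv(index=False, float_format=_FLOAT_FMT)
    if hasattr(dest, "write"):
        dest.write(lines + body)
    else:
        Path(dest).write_text(lines + body)


def read_table(src: Union[str, Path, TextIO]) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a CSV written by :func:`write_table`; returns (frame, header)."""
    if hasattr(src, "read"):
        text = src.read()
    else:
        text = Path(src).read_text()
    header: Dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                header[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    frame = pd.read_csv(io.StringIO("\n".join(body_lines)))
    return frame, header
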