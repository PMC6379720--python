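"""TSV output with provenance comment headers.

Every table the pipeline writes starts with ``#``-prefixed comment lines
recording the tool version, the run's config hash and seed, and the stage
that produced it, so any output file is traceable to its run configuration.
Float formatting is fixed so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

FLOAT_FORMAT = "%.10g"


def provenance_header(meta: Mapping[str, object]) -> str:
    lines = ["# paircons output"]
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as handle:
        if meta:
            handle.write(provenance_header(meta))
        df.to_csv(handle, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_text(text: str, path: str | Path,
               meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with path.open("w") as handle:
        if meta:
            handle.write(provenance_header(meta))
        handle.write(text)
        if not text.endswith("\n"):
            handle.write("\n")
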