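"""Sample sheet parsing.

A mutation-accumulation analysis compares one founding ("t0") sample against
one or more outgrowth samples propagated from it.  The sample sheet is a
tab-delimited file with a header row and one row per sample::

    name    role    ploidy  generations     counts_path     depth_path

``role`` is ``t0`` or ``outgrowth``; ``generations`` may be empty for the t0
sample.  Exactly one t0 row is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = ["SampleConfig", "read_sample_sheet", "write_sample_sheet"]

_REQUIRED_COLUMNS = ("name", "role", "ploidy", "counts_path", "depth_path")
_ROLES = ("t0", "outgrowth")


@dataclass(frozen=True)
class SampleConfig:
    """Per-sample attributes needed by the pipeline."""

    name: str
    role: str  # "t0" or "outgrowth"
    ploidy: int
    generations: Optional[float] = None
    counts_path: Optional[str] = None
    depth_path: Optional[str] = None
    # optional adapter extension: per-repeat traversing-coverage observations
    observations_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r} for sample {self.name!r}")
        if not isinstance(self.ploidy, int) or self.ploidy < 1:
            raise ValueError(f"ploidy must be an integer >= 1, got {self.ploidy!r}")
        if self.generations is not None and self.generations < 0:
            raise ValueError("generations must be >= 0")

    @property
    def is_t0(self) -> bool:
        return self.role == "t0"


def read_sample_sheet(path: str | Path) -> list[SampleConfig]:
    """Parse and validate a sample sheet.

    Raises ``ValueError`` on a missing column, unknown role, non-integer
    ploidy, duplicate sample name, or when the sheet does not contain exactly
    one t0 row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s): {', '.join(missing)}")

    configs: list[SampleConfig] = []
    for _, row in df.iterrows():
        ploidy_raw = row["ploidy"].strip()
        try:
            ploidy = int(ploidy_raw)
        except ValueError:
            raise ValueError(f"non-integer ploidy {ploidy_raw!r} for sample {row['name']!r}")
        if str(ploidy) != ploidy_raw and ploidy_raw.lstrip("+") != str(ploidy):
            raise ValueError(f"non-integer ploidy {ploidy_raw!r} for sample {row['name']!r}")
        gen_raw = str(row.get("generations", "")).strip()
        generations = float(gen_raw) if gen_raw else None
        configs.append(
            SampleConfig(
                name=row["name"],
                role=row["role"].strip(),
                ploidy=ploidy,
                generations=generations,
                counts_path=row["counts_path"] or None,
                depth_path=row["depth_path"] or None,
                observations_path=str(row.get("observations_path", "")) or None,
            )
        )

    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sample name(s): {', '.join(dupes)}")
    n_t0 = sum(c.is_t0 for c in configs)
    if n_t0 == 0:
        raise ValueError("sample sheet contains no t0 sample")
    if n_t0 > 1:
        raise ValueError("multiple t0 samples in sheet; exactly one required")
    return configs


def write_sample_sheet(configs: Sequence[SampleConfig], path: str | Path) -> None:
    rows = [
        {
            "name": c.name,
            "role": c.role,
            "ploidy": c.ploidy,
            "generations": "" if c.generations is None else c.generations,
            "counts_path": c.counts_path or "",
            "depth_path": c.depth_path or "",
            "observations_path": c.observations_path or "",
        }
        for c in configs
    ]
    columns = (
        list(_REQUIRED_COLUMNS[:3])
        + ["generations"]
        + list(_REQUIRED_COLUMNS[3:])
        + ["observations_path"]
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
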