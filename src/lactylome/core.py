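"""Shared containers for the lactylome pipeline.

Intensity and relative-quantification tables are plain pandas DataFrames
(rows = features, columns = samples, NaN = missing); :class:`GroupDesign`
carries the two-group sample assignment that every downstream stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"


@dataclass(frozen=True)
class GroupDesign:
    """Two-group (control vs case) sample design.

    Parameters
    ----------
    control, case
        Sample identifiers for each group.  At least two samples per group
        are required for any between-group inference.
    """

    control: tuple[str, ...]
    case: tuple[str, ...]

    def __post_init__(self) -> None:
        control = tuple(self.control)
        case = tuple(self.case)
        object.__setattr__(self, "control", control)
        object.__setattr__(self, "case", case)
        samples = control + case
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique across groups")
        if len(control) < 2 or len(case) < 2:
            raise ValueError("each group needs at least 2 samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.control + self.case

    def labels(self) -> pd.Series:
        """Sample id -> group label ('control' / 'case')."""
        lab = {s: CONTROL for s in self.control}
        lab.update({s: CASE for s in self.case})
        return pd.Series(lab, name="group")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroupDesign":
        """Build from a design table with columns ``sample`` and ``group``."""
        if not {"sample", "group"} <= set(frame.columns):
            raise ValueError("design table needs 'sample' and 'group' columns")
        control = tuple(frame.loc[frame["group"] == CONTROL, "sample"])
        case = tuple(frame.loc[frame["group"] == CASE, "sample"])
        unknown = set(frame["group"]) - {CONTROL, CASE}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        return cls(control=control, case=case)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.samples),
             "group": [CONTROL] * len(self.control) + [CASE] * len(self.case)}
        )


def validate_intensity_table(table: pd.DataFrame, design: GroupDesign | None = None) -> None:
    """Check the intensity-table contract: unique features, positive values.

    Raises ``ValueError`` on violation; NaN cells (missing values) are allowed.
    """
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    values = table.to_numpy(dtype=float)
    bad = np.asarray((values <= 0) & ~np.isnan(values)).nonzero()
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise ValueError(
            f"non-positive intensity at feature {table.index[r]!r}, "
            f"sample {table.columns[c]!r}"
        )
    if design is not None:
        missing = set(design.samples) - set(table.columns)
        if missing:
            raise ValueError(f"design samples absent from table: {sorted(missing)}")


@dataclass
class SiteCatalog:
    """Catalog of modified lysine sites.

    ``frame`` columns: ``site_id``, ``accession``, ``position`` (1-based),
    ``flank`` (window of width 2w+1, centre K, '_'-padded at termini).
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["site_id", "accession", "position", "flank"]))

    def __post_init__(self) -> None:
        required = {"site_id", "accession", "position", "flank"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"site catalog needs columns {sorted(required)}")
        if self.frame["site_id"].duplicated().any():
            raise ValueError("duplicate site ids in catalog")
        pairs = self.frame[["accession", "position"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (protein, position) pairs in catalog")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def site_ids(self) -> list[str]:
        return self.frame["site_id"].tolist()

    @property
    def proteins(self) -> list[str]:
        return sorted(self.frame["accession"].unique())

    def site_protein_map(self) -> pd.Series:
        """site id -> parent protein accession (total map)."""
        return self.frame.set_index("site_id")["accession"]

    def windows(self) -> list[str]:
        return self.frame["flank"].tolist()
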