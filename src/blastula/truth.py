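"""Ground-truth container for simulated embryo movies.

The truth is a set of plain tables keyed by nucleus id (and frame, for the
per-frame focus table), so it can be written/read as CSV and compared
against pipeline output without any image processing.

Conventions
-----------
* A nucleus (track) is *born* at the start of telophase, i.e. the moment the
  two anaphase masses of its mother have fully separated.
* Its own anaphase interval ``[division_s, ana_end_s)`` still belongs to it:
  during anaphase the two sister-chromatid masses are closer than a nuclear
  diameter and appear as one (two-component) object.  The daughters exist
  from ``ana_end_s`` on.
* Cell-cycle length is anaphase-start to anaphase-start, matching how cycle
  length is measured from chromatin movies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: legal phase progression of one track, birth -> division
PHASE_ORDER = ("telophase", "S", "prophase", "prometaphase", "metaphase", "anaphase")

NUCLEI_COLUMNS = [
    "nucleus_id", "mother_id", "generation", "birth_s", "division_s",
    "ana_end_s", "cycle_s", "s_len_s", "m_len_s", "x_um", "y_um", "z_um",
    "radius_um", "expressing", "onset_s", "end_s",
]


@dataclass
class GroundTruth:
    """Simulated truth: lineage + phase timelines (+ expression and foci)."""

    nuclei: pd.DataFrame
    phases: pd.DataFrame
    meta: dict
    expression: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None
    foci: pd.DataFrame | None = None

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.meta["n_frames"])

    @property
    def frame_interval_s(self) -> float:
        return float(self.meta["frame_interval_s"])

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def alive_at(self, t_s: float) -> pd.DataFrame:
        n = self.nuclei
        return n[(n.birth_s <= t_s) & (t_s < n.ana_end_s)]

    def phase_at(self, nucleus_id: int, t_s: float) -> str | None:
        """Truth phase label of one nucleus at time ``t_s`` (None if absent)."""
        ph = self.phases
        rows = ph[(ph.nucleus_id == nucleus_id)
                  & (ph.start_s <= t_s) & (t_s < ph.end_s)]
        if len(rows) == 0:
            return None
        return str(rows.iloc[0].phase)

    def phase_series(self, nucleus_id: int) -> pd.Series:
        """Per-frame truth phase labels for one nucleus, indexed by frame."""
        times = self.frame_times()
        ph = self.phases[self.phases.nucleus_id == nucleus_id]
        out = {}
        for _, row in ph.iterrows():
            frames = np.nonzero((times >= row.start_s) & (times < row.end_s))[0]
            for f in frames:
                out[int(f)] = str(row.phase)
        return pd.Series(out, dtype="object").sort_index()

    def leaves(self) -> pd.DataFrame:
        mothers = set(self.nuclei.mother_id[self.nuclei.mother_id >= 0])
        return self.nuclei[~self.nuclei.nucleus_id.isin(mothers)]

    # ------------------------------------------------------------------
    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.nuclei.to_csv(out / "nuclei.csv", index=False)
        self.phases.to_csv(out / "phases.csv", index=False)
        if self.expression is not None:
            self.expression.to_csv(out / "expression.csv", index=False)
        if self.sites is not None:
            self.sites.to_csv(out / "sites.csv", index=False)
        if self.foci is not None:
            self.foci.to_csv(out / "foci.csv", index=False)
        with open(out / "truth_meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, default=_jsonable)

    @classmethod
    def read(cls, in_dir) -> "GroundTruth":
        src = Path(in_dir)
        with open(src / "truth_meta.json") as fh:
            meta = json.load(fh)

        def _opt(name):
            p = src / name
            return pd.read_csv(p) if p.exists() else None

        return cls(
            nuclei=pd.read_csv(src / "nuclei.csv"),
            phases=pd.read_csv(src / "phases.csv"),
            meta=meta,
            expression=_opt("expression.csv"),
            sites=_opt("sites.csv"),
            foci=_opt("foci.csv"),
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple)):
        return list(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
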