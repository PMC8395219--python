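"""TrajectorySet: the common currency of all analysis stages.

A :class:`TrajectorySet` wraps a long-format :class:`pandas.DataFrame` of
particle localizations together with the acquisition metadata needed to
interpret them (frame interval ``dt``, pixel size, cell area).

Conventions (enforced everywhere in the package):

* coordinates in μm, origin at the image top-left, y increasing downward
  (image convention); frames are 0-based integers
* one row per particle per frame; particles are identified by
  ``(cell_id, particle_id)``
* intensities are background-subtracted integrated counts in a.u., one
  column per color channel
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

#: required columns of the underlying frame
CORE_COLUMNS = ["cell_id", "particle_id", "frame", "x_um", "y_um"]
#: optional columns written when present
OPTIONAL_COLUMNS = ["intensity_ch1", "intensity_ch2", "state", "state_true", "inferred"]


@dataclass
class TrajectorySet:
    """Per-cell collection of 2-D particle tracks with acquisition metadata.

    Parameters
    ----------
    data
        Long-format table with at least :data:`CORE_COLUMNS`.
    dt
        Frame interval in seconds.
    pixel_size_um
        Pixel size in μm (0.067 for the reference acquisition geometry).
    cell_area_um2
        Imaged membrane area in μm², used for density computations.
    """

    data: pd.DataFrame
    dt: float
    pixel_size_um: float = 0.067
    cell_area_um2: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return self.data.groupby(["cell_id", "particle_id"]).ngroups

    @property
    def n_frames(self) -> int:
        return 0 if self.data.empty else int(self.data["frame"].max()) + 1

    def __len__(self) -> int:
        return len(self.data)

    def iter_tracks(self) -> Iterator[tuple[tuple, pd.DataFrame]]:
        """Yield ``((cell_id, particle_id), frame-sorted track)`` pairs."""
        for key, g in self.data.groupby(["cell_id", "particle_id"], sort=True):
            yield key, g.sort_values("frame")

    def steps(self, min_steps: int = 1) -> pd.DataFrame:
        """Per-step displacement table.

        Returns a frame with columns ``cell_id, particle_id, frame, dx, dy``
        where ``(dx, dy)`` is the displacement from ``frame`` to the next
        consecutive frame of the same track. Steps across frame gaps are
        excluded. Tracks contributing fewer than ``min_steps`` steps are
        dropped.
        """
        df = self.data.sort_values(["cell_id", "particle_id", "frame"])
        grp = df.groupby(["cell_id", "particle_id"], sort=False)
        dx = grp["x_um"].diff().shift(-1)
        dy = grp["y_um"].diff().shift(-1)
        dframe = grp["frame"].diff().shift(-1)
        ok = dframe == 1
        out = pd.DataFrame(
            {
                "cell_id": df["cell_id"],
                "particle_id": df["particle_id"],
                "frame": df["frame"],
                "dx": dx,
                "dy": dy,
            }
        )[ok.fillna(False).to_numpy(bool)]
        if min_steps > 1:
            counts = out.groupby(["cell_id", "particle_id"])["frame"].transform("size")
            out = out[counts >= min_steps]
        return out.reset_index(drop=True)

    def subset_channel(self, channel: int) -> "TrajectorySet":
        """Rows visible in the given color channel (positive intensity)."""
        col = f"intensity_ch{channel}"
        if col not in self.data.columns:
            raise KeyError(f"no column {col}")
        return replace(self, data=self.data[self.data[col] > 0].reset_index(drop=True))

    # ------------------------------------------------------------------
    # I/O — plain CSV, schema shared by simulation and tracking output
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        cols = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in self.data.columns]
        header = (
            f"# dt={self.dt} pixel_size_um={self.pixel_size_um} "
            f"cell_area_um2={self.cell_area_um2}\n"
        )
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(header)
            self.data[cols].to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectorySet":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            meta: dict[str, float] = {}
            if first.startswith("#"):
                for tok in first[1:].split():
                    k, _, v = tok.partition("=")
                    meta[k] = float(v) if v not in ("None", "") else None
                data = pd.read_csv(fh)
            else:
                fh.seek(0)
                data = pd.read_csv(fh)
        return cls(
            data=data,
            dt=meta.get("dt", 0.0305),
            pixel_size_um=meta.get("pixel_size_um", 0.067),
            cell_area_um2=meta.get("cell_area_um2"),
        )


def concat(sets: list[TrajectorySet]) -> TrajectorySet:
    """Concatenate trajectory sets sharing dt/pixel size (cells kept distinct)."""
    if not sets:
        raise ValueError("nothing to concatenate")
    dts = {s.dt for s in sets}
    if len(dts) > 1:
        raise ValueError(f"mismatched dt values: {sorted(dts)}")
    data = pd.concat([s.data for s in sets], ignore_index=True)
    return TrajectorySet(
        data=data,
        dt=sets[0].dt,
        pixel_size_um=sets[0].pixel_size_um,
        cell_area_um2=sets[0].cell_area_um2,
    )
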