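"""Coarse-grained peptide dimer detection and orientation classification.

Works on per-frame marker coordinates (nm) of membrane-adsorbed helical
peptides: center of mass (COM), N-terminus and C-terminus.  Two peptides
count as a dimer in a frame when at least two of the marker-pair distances
fall below a cutoff (default 1 nm); the default distance set is
{COM-COM, N-N, C-C, N-C, C-N}.  A dimer is *parallel* when the N->C axis
vectors of the two helices have positive dot product (angle < 90 deg) and
*antiparallel* otherwise (ties break toward antiparallel).  Per-frame
pairing is greedy and exclusive by ascending COM distance, so a peptide
joins at most one dimer per frame and trimeric contacts are not
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeptideMarkers",
    "DimerRecord",
    "GeometryError",
    "marker_distances",
    "is_dimer",
    "classify_orientation",
    "dimer_statistics",
    "load_markers_csv",
]

MARKERS = ("COM", "N", "C")

#: Marker pairs entering the ">= 2 below cutoff" dimer criterion.
DEFAULT_DISTANCE_SET: tuple[tuple[str, str], ...] = (
    ("COM", "COM"), ("N", "N"), ("C", "C"), ("N", "C"), ("C", "N"),
)


class GeometryError(ValueError):
    """Missing frames or degenerate marker geometry."""


@dataclass
class PeptideMarkers:
    """Marker trajectories of one peptide.

    ``coords`` maps marker name -> (n_frames, 3) array in nm.
    """

    peptide_id: str
    species: str
    coords: dict[str, np.ndarray]

    def __post_init__(self):
        shapes = set()
        for m in MARKERS:
            if m not in self.coords:
                raise GeometryError(f"peptide {self.peptide_id}: missing marker {m}")
            arr = np.asarray(self.coords[m], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or not np.isfinite(arr).all():
                raise GeometryError(
                    f"peptide {self.peptide_id}: marker {m} must be finite (n, 3)")
            self.coords[m] = arr
            shapes.add(arr.shape[0])
        if len(shapes) != 1:
            raise GeometryError(
                f"peptide {self.peptide_id}: inconsistent frame counts {shapes}")

    @property
    def n_frames(self) -> int:
        return self.coords["COM"].shape[0]

    def at(self, marker: str, frame: int) -> np.ndarray:
        if not 0 <= frame < self.n_frames:
            raise GeometryError(f"frame {frame} out of range")
        return self.coords[marker][frame]

    def axis(self, frame: int) -> np.ndarray:
        """N->C axis vector at a frame."""
        return self.at("C", frame) - self.at("N", frame)


@dataclass(frozen=True)
class DimerRecord:
    frame: int
    pair: frozenset
    orientation: str  # parallel | antiparallel
    kind: str         # homo | hetero


def _mic(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box."""
    if box is None:
        return d
    return d - box * np.round(d / box)


def marker_distances(
    a: PeptideMarkers, b: PeptideMarkers, frame: int,
    distance_set=DEFAULT_DISTANCE_SET, box=None,
) -> np.ndarray:
    box = None if box is None else np.asarray(box, dtype=float)
    out = np.empty(len(distance_set))
    for i, (ma, mb) in enumerate(distance_set):
        d = _mic(a.at(ma, frame) - b.at(mb, frame), box)
        out[i] = np.linalg.norm(d)
    return out


def is_dimer(
    a: PeptideMarkers, b: PeptideMarkers, frame: int, cutoff: float = 1.0,
    distance_set=DEFAULT_DISTANCE_SET, box=None,
) -> bool:
    """True iff >= 2 marker-pair distances are below ``cutoff`` (nm)."""
    d = marker_distances(a, b, frame, distance_set, box)
    return int(np.count_nonzero(d < cutoff)) >= 2


def classify_orientation(a: PeptideMarkers, b: PeptideMarkers, frame: int) -> str:
    """'parallel' when the N->C axes make an angle < 90 deg, else 'antiparallel'."""
    va, vb = a.axis(frame), b.axis(frame)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise GeometryError("zero-length N->C axis vector")
    return "parallel" if float(va @ vb) > 0.0 else "antiparallel"


def dimer_statistics(
    peptides: list[PeptideMarkers],
    cutoff: float = 1.0,
    distance_set=DEFAULT_DISTANCE_SET,
    box=None,
    return_records: bool = False,
):
    """Time-averaged dimer counts per (orientation, kind).

    Greedy exclusive pairing: candidate pairs satisfying the dimer criterion
    are accepted in ascending COM-COM distance, each peptide joining at most
    one dimer per frame.  Returns a dict
    ``{(orientation, kind): mean count per frame}`` (and the per-frame
    records when requested).
    """
    if not peptides:
        raise GeometryError("no peptides supplied")
    n_frames = peptides[0].n_frames
    if n_frames < 1 or any(p.n_frames != n_frames for p in peptides):
        raise GeometryError("all peptides need the same (>=1) frame count")
    box_arr = None if box is None else np.asarray(box, dtype=float)

    counts = {(o, k): 0 for o in ("parallel", "antiparallel")
              for k in ("homo", "hetero")}
    records: list[DimerRecord] = []
    for f in range(n_frames):
        candidates = []
        for i, j in combinations(range(len(peptides)), 2):
            a, b = peptides[i], peptides[j]
            if is_dimer(a, b, f, cutoff, distance_set, box_arr):
                d_com = np.linalg.norm(
                    _mic(a.at("COM", f) - b.at("COM", f), box_arr))
                candidates.append((d_com, i, j))
        used: set[int] = set()
        for _, i, j in sorted(candidates):
            if i in used or j in used:
                continue
            used.update((i, j))
            a, b = peptides[i], peptides[j]
            orientation = classify_orientation(a, b, f)
            kind = "homo" if a.species == b.species else "hetero"
            counts[(orientation, kind)] += 1
            records.append(DimerRecord(
                frame=f,
                pair=frozenset((a.peptide_id, b.peptide_id)),
                orientation=orientation, kind=kind))

    averages = {key: n / n_frames for key, n in counts.items()}
    if return_records:
        return averages, records
    return averages


def load_markers_csv(path: str | Path) -> tuple[list[PeptideMarkers], np.ndarray | None]:
    """Read marker coordinates from CSV.

    Columns: ``frame, peptide_id, species, marker, x, y, z`` and optionally
    ``box_x, box_y, box_z`` (constant; used for minimum-image distances).
    Frames may be any sorted labels; every peptide must report every marker
    in every frame.
    """
    df = pd.read_csv(path)
    required = {"frame", "peptide_id", "species", "marker", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise GeometryError(f"{path}: missing columns {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    frame_index = {fr: i for i, fr in enumerate(frames)}
    peptides = []
    for pid, sub in df.groupby("peptide_id", sort=True):
        species = sub["species"].iloc[0]
        coords = {}
        for m in MARKERS:
            block = sub[sub["marker"] == m]
            if len(block) != len(frames):
                raise GeometryError(
                    f"peptide {pid}: marker {m} present in {len(block)} of "
                    f"{len(frames)} frames")
            arr = np.empty((len(frames), 3))
            idx = block["frame"].map(frame_index).to_numpy()
            arr[idx] = block[["x", "y", "z"]].to_numpy()
            coords[m] = arr
        peptides.append(PeptideMarkers(str(pid), str(species), coords))
    box = None
    if {"box_x", "box_y", "box_z"} <= set(df.columns):
        box = df[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(dtype=float)
    return peptides, box


def records_to_frame(records: list[DimerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"frame": r.frame, "pair": "|".join(sorted(r.pair)),
          "orientation": r.orientation, "kind": r.kind} for r in records])
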