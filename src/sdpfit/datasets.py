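"""Scattering datasets: containers and 3-column ASCII I/O."""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["ScatteringDataset", "DataError", "load_dataset", "save_dataset"]

#: Default fitted q-window lower edge (1/A): vesicle-scale scattering below
#: this is excluded so only bilayer structure is analysed.
DEFAULT_Q_MIN = 0.05


class DataError(ValueError):
    """Malformed scattering data."""


@dataclass(frozen=True)
class ScatteringDataset:
    """One contrast's (q, I, sigma) curve.

    ``q`` in 1/A, strictly increasing; ``sigma`` > 0.  ``x_D`` is the solvent
    D2O mole fraction (0 for x-rays).  ``q_window`` bounds the fitted range;
    ``weight`` multiplies this dataset's chi-square term in joint fits.
    """

    probe: str
    x_D: float
    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    name: str = ""
    q_window: tuple[float, float | None] = (DEFAULT_Q_MIN, None)
    weight: float = 1.0
    scale: float | None = None       # fixed instrument scale, None = free
    background: float | None = None  # fixed flat background, None = free

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if not (q.shape == I.shape == s.shape) or q.ndim != 1 or q.size == 0:
            raise DataError("q, I, sigma must be equal-length 1-D arrays")
        if np.any(np.diff(q) <= 0):
            raise DataError("q must be strictly increasing")
        if np.any(s <= 0):
            raise DataError("sigma must be positive")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "sigma", s)

    @property
    def window_mask(self) -> np.ndarray:
        lo, hi = self.q_window
        mask = self.q >= (lo if lo is not None else -np.inf)
        if hi is not None:
            mask &= self.q <= hi
        return mask

    def windowed(self) -> "ScatteringDataset":
        m = self.window_mask
        if not m.any():
            raise DataError(f"dataset {self.name or self.probe}: empty fit window")
        return replace(self, q=self.q[m], I=self.I[m], sigma=self.sigma[m])

    def label(self) -> str:
        if self.name:
            return self.name
        if self.probe == "xray":
            return "SAXS"
        return f"SANS {self.x_D:.0%} D2O"


def load_dataset(
    path: str | Path,
    probe: str,
    x_D: float = 0.0,
    name: str = "",
    q_window: tuple[float, float | None] = (DEFAULT_Q_MIN, None),
    weight: float = 1.0,
) -> ScatteringDataset:
    """Read a whitespace- or comma-separated (q, I, sigma) ASCII file.

    Lines starting with ``#`` are comments; extra columns are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise DataError(f"{path}: need 3 columns, got {line!r}")
            rows.append([float(x) for x in parts[:3]])
    if not rows:
        raise DataError(f"{path}: no data rows")
    arr = np.asarray(rows)
    return ScatteringDataset(
        probe=probe, x_D=x_D, q=arr[:, 0], I=arr[:, 1], sigma=arr[:, 2],
        name=name or Path(path).stem, q_window=q_window, weight=weight)


def save_dataset(ds: ScatteringDataset, path: str | Path) -> None:
    """Write a 3-column ASCII file (q [1/A], I, sigma)."""
    buf = io.StringIO()
    buf.write(f"# {ds.label()}  probe={ds.probe}  x_D={ds.x_D}\n")
    buf.write("# q[1/A]  I  sigma\n")
    for q, I, s in zip(ds.q, ds.I, ds.sigma):
        buf.write(f"{q:.8g} {I:.8g} {s:.8g}\n")
    Path(path).write_text(buf.getvalue())
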