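"""Derived structural parameters and comparative / thermal analyses.

From a fitted SDP model: the Luzzati bilayer thickness D_B = 2 V_LP / A_U
(equal to the water-deficit integral), the hydrocarbon half-thickness
D_C = V_HC / A_U (the outer edge of the methylene region), the projected
carbonyl-glycerol-to-phosphate distance D_HD = z_PO4 - z_CG (a headgroup
tilt proxy), and the peptide center z_p.  Ensemble results propagate
uncertainties by evaluating every derived quantity run by run and taking
center-of-mass / second-moment statistics, matching the convention used for
the primary parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .bilayer import SDPModel

__all__ = [
    "StructureReport",
    "ThermalSeries",
    "luzzati_thickness",
    "chain_length",
    "headgroup_distance",
    "compare_to_reference",
    "thermal_expansion",
]


def luzzati_thickness(model: SDPModel) -> float:
    """D_B = 2 V_LP / A_U (A); identical to the water-deficit integral."""
    if model.A_U <= 0:
        raise ValueError("A_U must be > 0")
    return 2.0 * model.V_LP / model.A_U


def chain_length(model: SDPModel) -> float:
    """Hydrocarbon half-thickness D_C = V_HC / A_U (A), by volume closure."""
    return model.hc.D_C


def headgroup_distance(model: SDPModel) -> float:
    """Signed projected CG-to-PO4 distance D_HD = z_PO4 - z_CG (A)."""
    try:
        z_po4 = model.component("PO4").z_c
        z_cg = model.component("CG").z_c
    except KeyError as exc:
        raise ValueError(f"model lacks group {exc}") from exc
    return z_po4 - z_cg


@dataclass
class StructureReport:
    """Structural parameters with uncertainties (all Angstrom / Angstrom^2)."""

    name: str = ""
    A_U: float = float("nan")
    u_A_U: float = 0.0
    D_B: float = float("nan")
    u_D_B: float = 0.0
    D_C: float = float("nan")
    u_D_C: float = 0.0
    D_HD: float = float("nan")
    u_D_HD: float = 0.0
    z_p: float | None = None
    u_z_p: float = 0.0

    @classmethod
    def from_model(cls, model: SDPModel, name: str = "") -> "StructureReport":
        """Point estimates from a single model (zero uncertainties)."""
        return cls(
            name=name,
            A_U=model.A_U,
            D_B=luzzati_thickness(model),
            D_C=chain_length(model),
            D_HD=headgroup_distance(model),
            z_p=model.peptide.z_c if model.peptide is not None else None,
        )

    @classmethod
    def from_ensemble(cls, result, name: str = "") -> "StructureReport":
        """Moment statistics of the derived quantities over the GA ensemble."""
        if result.model is None:
            raise ValueError("ensemble result is not attached to a model")
        rows = []
        for x in result.runs:
            p = {n: float(v) for n, v in zip(result.names, x)}
            m = result.model.build(p)
            row = [m.A_U, luzzati_thickness(m), chain_length(m),
                   headgroup_distance(m)]
            row.append(m.peptide.z_c if m.peptide is not None else np.nan)
            rows.append(row)
        arr = np.asarray(rows)
        est = arr.mean(axis=0)
        unc = arr.std(axis=0)  # second central moment, ensemble convention
        has_pep = not math.isnan(est[4])
        return cls(
            name=name,
            A_U=est[0], u_A_U=unc[0],
            D_B=est[1], u_D_B=unc[1],
            D_C=est[2], u_D_C=unc[2],
            D_HD=est[3], u_D_HD=unc[3],
            z_p=est[4] if has_pep else None,
            u_z_p=unc[4] if has_pep else 0.0,
        )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "A_U": self.A_U, "u_A_U": self.u_A_U,
            "D_B": self.D_B, "u_D_B": self.u_D_B,
            "D_C": self.D_C, "u_D_C": self.u_D_C,
            "D_HD": self.D_HD, "u_D_HD": self.u_D_HD,
        }
        if self.z_p is not None:
            d["z_p"], d["u_z_p"] = self.z_p, self.u_z_p
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructureReport":
        d = json.loads(Path(path).read_text())
        return cls(**{k: v for k, v in d.items()})

    def __str__(self) -> str:
        rows = [
            ("A_U [A^2]", self.A_U, self.u_A_U),
            ("D_B [A]", self.D_B, self.u_D_B),
            ("D_C [A]", self.D_C, self.u_D_C),
            ("D_HD [A]", self.D_HD, self.u_D_HD),
        ]
        if self.z_p is not None:
            rows.insert(3, ("z_p [A]", self.z_p, self.u_z_p))
        head = f"Structure report{': ' + self.name if self.name else ''}"
        body = "\n".join(
            f"  {label:<11} {v:8.2f} +/- {u:.2f}" for label, v, u in rows)
        return head + "\n" + body


def compare_to_reference(
    report: StructureReport, reference: StructureReport, decimals: int = 1
) -> dict[str, tuple[float, float]]:
    """Delta table vs. a reference system.

    Returns ``{quantity: (delta, uncertainty)}`` with uncertainties combined
    in quadrature and deltas rounded to ``decimals`` (1 decimal, the
    convention used for quoted changes).  ``2dD_C`` is twice the change of
    the hydrocarbon half-thickness — the peptide-free measure of membrane
    thinning; ``dD_B`` also carries the added peptide volume.
    """
    def delta(v, vr, u, ur):
        return (round(v - vr, decimals), round(math.hypot(u, ur), decimals))

    out = {
        "dA_U": delta(report.A_U, reference.A_U, report.u_A_U, reference.u_A_U),
        "dD_B": delta(report.D_B, reference.D_B, report.u_D_B, reference.u_D_B),
        "2dD_C": delta(2 * report.D_C, 2 * reference.D_C,
                       2 * report.u_D_C, 2 * reference.u_D_C),
        "dD_HD": delta(report.D_HD, reference.D_HD,
                       report.u_D_HD, reference.u_D_HD),
    }
    if report.z_p is not None and reference.z_p is not None:
        out["dz_p"] = delta(report.z_p, reference.z_p,
                            report.u_z_p, reference.u_z_p)
    return out


@dataclass
class ThermalSeries:
    """Area per unit cell vs. temperature with a fitted expansion slope."""

    temperatures: np.ndarray  # degC
    A_U: np.ndarray           # A^2
    u_A_U: np.ndarray | None = None
    slope: float = field(init=False, default=float("nan"))
    slope_se: float = field(init=False, default=float("nan"))
    intercept: float = field(init=False, default=float("nan"))

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.A_U = np.asarray(self.A_U, dtype=float)
        if self.temperatures.size < 2:
            raise ValueError("need >= 2 temperatures for a slope")


def thermal_expansion(
    temperatures, A_U, u_A_U=None
) -> ThermalSeries:
    """OLS slope dA_U/dT (A^2/K) with its standard error.

    ``u_A_U`` is carried for bookkeeping; the fit itself is ordinary least
    squares, matching the statistical-averaging treatment of ensemble
    solutions across temperatures.
    """
    series = ThermalSeries(temperatures, A_U,
                           None if u_A_U is None else np.asarray(u_A_U, float))
    t, a = series.temperatures, series.A_U
    if np.allclose(t, t[0]):
        raise ValueError("all temperatures equal: slope is undefined")
    if t.size == 2:  # exact line, no residual dof
        slope = (a[1] - a[0]) / (t[1] - t[0])
        series.slope, series.slope_se = float(slope), float("nan")
        series.intercept = float(a[0] - slope * t[0])
        return series
    res = stats.linregress(t, a)
    series.slope = float(res.slope)
    series.slope_se = float(res.stderr)
    series.intercept = float(res.intercept)
    return series
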