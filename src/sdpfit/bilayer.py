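"""Symmetric scattering-density-profile (SDP) unit cell.

The bilayer is described per unit cell of lateral area ``A_U`` containing
one averaged lipid in each leaflet, an adsorbed-peptide share of ``P:L``
peptides per lipid, and water filling the rest.  Each quasimolecular group
is a mirrored pair of Gaussian volume-probability functions; the hydrocarbon
core is an error-function envelope of half-width ``D_C`` fixed by volume
closure, ``D_C = V_HC / A_U``.  The methylene (CH2) probability is the
envelope minus the CH and CH3 Gaussians, so the core is filled exactly.

z is measured from the bilayer midplane in Angstrom; leaflet symmetry is
enforced throughout (peptides are assumed to distribute equally in both
leaflets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .composition import (
    CompositionError,
    GroupDef,
    PeptideSpec,
    Solvent,
    _merge,
    default_lipid_groups,
)

__all__ = [
    "GaussianComponent",
    "HydrocarbonEnvelope",
    "SDPModel",
    "ProfileSet",
    "ModelConfigError",
    "build_unit_cell",
    "combine_peptides",
    "volume_probability",
    "water_probability",
    "check_overfill",
    "DEFAULT_STRUCTURE_PARAMS",
]

#: Lower bound on any Gaussian width, Angstrom.
SIGMA_MIN = 1.0

HEADGROUP_NAMES = ("ENX", "PG2", "PO4", "CG")
CHAIN_NAMES = ("CH", "CH2", "CH3")


class ModelConfigError(ValueError):
    """Inconsistent or incomplete SDP model configuration."""


@dataclass(frozen=True)
class GaussianComponent:
    """A mirrored Gaussian volume-probability component.

    ``z_c >= 0``; the mirror image at ``-z_c`` is implied.  The occupied
    volume per leaflet is ``group.volume * group.multiplicity`` for lipid
    groups, or ``volume * P:L`` for a peptide (the peptide's multiplicity is
    the peptide-per-lipid ratio).
    """

    group: GroupDef | PeptideSpec
    z_c: float
    sigma: float
    multiplicity: float | None = None  # overrides group.multiplicity

    def __post_init__(self):
        if self.sigma < SIGMA_MIN - 1e-12:
            raise ModelConfigError(
                f"{self.name}: sigma {self.sigma} < minimum {SIGMA_MIN}")
        if self.z_c < 0:
            raise ModelConfigError(f"{self.name}: z_c must be >= 0")

    @property
    def name(self) -> str:
        return self.group.name

    @property
    def mult(self) -> float:
        if self.multiplicity is not None:
            return self.multiplicity
        return getattr(self.group, "multiplicity", 1.0)

    @property
    def volume_per_leaflet(self) -> float:
        return self.group.volume * self.mult

    def probability(self, z: np.ndarray, A_U: float) -> np.ndarray:
        """P(z) of the mirrored pair on ``z`` (may be a full or half grid)."""
        c = self.volume_per_leaflet / (A_U * self.sigma * math.sqrt(2 * math.pi))
        return c * (
            np.exp(-((z - self.z_c) ** 2) / (2 * self.sigma**2))
            + np.exp(-((z + self.z_c) ** 2) / (2 * self.sigma**2))
        )

    def amplitude(self, q: np.ndarray, A_U: float) -> np.ndarray:
        """Fourier cosine amplitude of the mirrored pair (unit contrast)."""
        return (
            2.0 * self.volume_per_leaflet / A_U
            * np.cos(q * self.z_c)
            * np.exp(-(q**2) * self.sigma**2 / 2.0)
        )


@dataclass(frozen=True)
class HydrocarbonEnvelope:
    """Smeared-box envelope of the hydrocarbon core."""

    D_C: float
    sigma: float

    def __post_init__(self):
        if self.D_C <= 0:
            raise ModelConfigError("D_C must be > 0")
        if self.sigma < SIGMA_MIN - 1e-12:
            raise ModelConfigError(f"sigma_HC {self.sigma} < minimum {SIGMA_MIN}")

    def probability(self, z: np.ndarray) -> np.ndarray:
        s = self.sigma * math.sqrt(2.0)
        return 0.5 * (erf((self.D_C - z) / s) + erf((self.D_C + z) / s))

    def amplitude(self, q: np.ndarray) -> np.ndarray:
        """Fourier amplitude: 2 sin(q D_C)/q * exp(-q^2 sigma^2 / 2)."""
        q = np.asarray(q, dtype=float)
        core = 2.0 * self.D_C * np.sinc(q * self.D_C / math.pi)
        return core * np.exp(-(q**2) * self.sigma**2 / 2.0)


@dataclass(frozen=True)
class SDPModel:
    """Complete symmetric bilayer + peptide unit cell."""

    A_U: float
    headgroups: tuple[GaussianComponent, ...]
    chain_gaussians: tuple[GaussianComponent, ...]  # CH, CH3
    ch2: GroupDef
    hc: HydrocarbonEnvelope
    peptide: GaussianComponent | None
    PL_ratio: float
    lipid_fractions: dict[str, float]
    solvent: Solvent = field(default_factory=Solvent)

    @property
    def V_HC(self) -> float:
        """Hydrocarbon-core volume per lipid (CH2 + CH + CH3)."""
        v = self.ch2.volume * self.ch2.multiplicity
        v += sum(c.volume_per_leaflet for c in self.chain_gaussians)
        return v

    @property
    def V_L(self) -> float:
        """Volume of one averaged lipid, A^3."""
        return self.V_HC + sum(c.volume_per_leaflet for c in self.headgroups)

    @property
    def V_LP(self) -> float:
        """Volume of the lipid + peptide-share unit cell, per leaflet."""
        v = self.V_L
        if self.peptide is not None:
            v += self.peptide.volume_per_leaflet
        return v

    @property
    def D_C(self) -> float:
        return self.hc.D_C

    def component(self, name: str) -> GaussianComponent:
        for c in self.headgroups + self.chain_gaussians:
            if c.name == name:
                return c
        if self.peptide is not None and self.peptide.name == name:
            return self.peptide
        raise KeyError(name)

    def all_gaussians(self) -> tuple[GaussianComponent, ...]:
        out = self.headgroups + self.chain_gaussians
        if self.peptide is not None:
            out = out + (self.peptide,)
        return out


@dataclass
class ProfileSet:
    """Volume-probability profiles on a z grid (A)."""

    z: np.ndarray
    components: dict[str, np.ndarray]
    hc_envelope: np.ndarray
    water: np.ndarray
    ch2_min: float  # most negative CH2 probability encountered (0 if none)

    @property
    def total(self) -> np.ndarray:
        return 1.0 - self.water

    def to_frame(self):
        import pandas as pd

        data = {"z": self.z}
        data.update(self.components)
        data["water"] = np.clip(self.water, 0.0, None)
        return pd.DataFrame(data)


# Default structural parameters (A or A^2) for the averaged POPE/POPG
# bilayer; headgroup centers/widths follow published SDP magnitudes and are
# all adjustable in the fit.
DEFAULT_STRUCTURE_PARAMS: dict[str, float] = {
    "A_U": 60.56,
    "sigma_HC": 2.4,
    "z_ENX": 21.0, "sigma_ENX": 3.0,
    "z_PG2": 21.3, "sigma_PG2": 3.0,
    "z_PO4": 20.49, "sigma_PO4": 2.6,
    "z_CG": 16.3, "sigma_CG": 2.2,
    # CH sits at the oleoyl double bond, parameterised as a fraction of D_C;
    # terminal methyls at the midplane.
    "f_CH": 0.45, "sigma_CH": 3.0,
    "sigma_CH3": 2.7,
    # peptide Gaussian (ignored when P:L = 0)
    "z_p": 15.75, "sigma_p": 4.5,
}


def combine_peptides(
    peptides: list[PeptideSpec], fractions: list[float] | None = None
) -> PeptideSpec:
    """Mole-fraction-averaged composite peptide (single-Gaussian mixtures)."""
    if fractions is None:
        fractions = [1.0 / len(peptides)] * len(peptides)
    if len(fractions) != len(peptides) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ModelConfigError("peptide fractions must sum to 1")
    if len(peptides) == 1:
        return peptides[0]
    formula = _merge(*(p.formula for p in peptides), weights=fractions)
    return PeptideSpec(
        name="+".join(p.name for p in peptides),
        sequence=peptides[0].sequence,
        cterm_amidated=peptides[0].cterm_amidated,
        volume=sum(f * p.volume for f, p in zip(fractions, peptides)),
        formula=formula,
        n_exchangeable=sum(
            f * p.n_exchangeable for f, p in zip(fractions, peptides)),
    )


def build_unit_cell(
    lipid_fractions: dict[str, float] | None = None,
    peptides: list[PeptideSpec] | None = None,
    PL_ratio: float = 0.0,
    params: dict[str, float] | None = None,
    groups: dict[str, GroupDef] | None = None,
    solvent: Solvent | None = None,
    peptide_fractions: list[float] | None = None,
) -> SDPModel:
    """Assemble the hybrid-lipid SDP unit cell.

    The POPE fraction sets the ENX multiplicity and the POPG fraction the
    PG2 multiplicity; phosphate, carbonyl glycerol and the chain groups are
    shared at common positions (molecular averaging of the two lipids).
    Equimolar peptide mixtures are merged into a single Gaussian with
    averaged composition and the summed P:L ratio.
    """
    lipid_fractions = lipid_fractions or {"POPE": 0.75, "POPG": 0.25}
    if abs(sum(lipid_fractions.values()) - 1.0) > 1e-9:
        raise ModelConfigError("lipid fractions must sum to 1")
    groups = dict(groups or default_lipid_groups())
    # explicit parameter sets are taken as-is; defaults only when absent
    p = dict(DEFAULT_STRUCTURE_PARAMS) if params is None else dict(params)

    f_pope = lipid_fractions.get("POPE", 0.0)
    f_popg = lipid_fractions.get("POPG", 0.0)
    if "ENX" in groups and groups["ENX"].multiplicity != f_pope:
        g = groups["ENX"]
        groups["ENX"] = GroupDef(g.name, g.formula, g.volume,
                                 g.n_exchangeable, multiplicity=f_pope)
    if "PG2" in groups and groups["PG2"].multiplicity != f_popg:
        g = groups["PG2"]
        groups["PG2"] = GroupDef(g.name, g.formula, g.volume,
                                 g.n_exchangeable, multiplicity=f_popg)

    try:
        A_U = p["A_U"]
    except KeyError as exc:
        raise ModelConfigError(f"missing structural parameter {exc}") from exc
    if A_U <= 0:
        raise ModelConfigError("A_U must be > 0")

    heads = []
    for name in HEADGROUP_NAMES:
        if name not in groups:
            raise ModelConfigError(f"missing group definition: {name}")
        if groups[name].multiplicity == 0.0:
            continue
        try:
            z, s = p[f"z_{name}"], p[f"sigma_{name}"]
        except KeyError as exc:
            raise ModelConfigError(f"missing structural parameter {exc}") from exc
        heads.append(GaussianComponent(groups[name], z_c=z, sigma=s))

    ch2 = groups["CH2"]
    V_HC = (ch2.volume * ch2.multiplicity
            + groups["CH"].volume * groups["CH"].multiplicity
            + groups["CH3"].volume * groups["CH3"].multiplicity)
    D_C = V_HC / A_U
    try:
        chain = (
            GaussianComponent(groups["CH"], z_c=p["f_CH"] * D_C,
                              sigma=p["sigma_CH"]),
            GaussianComponent(groups["CH3"], z_c=0.0, sigma=p["sigma_CH3"]),
        )
        hc = HydrocarbonEnvelope(D_C=D_C, sigma=p["sigma_HC"])
    except KeyError as exc:
        raise ModelConfigError(f"missing structural parameter {exc}") from exc

    pep_component = None
    if PL_ratio > 0:
        if not peptides:
            raise ModelConfigError("PL_ratio > 0 but no peptide specified")
        composite = combine_peptides(list(peptides), peptide_fractions)
        if composite.volume <= 1.0:
            raise ModelConfigError(
                f"peptide {composite.name} needs a molecular volume")
        try:
            pep_component = GaussianComponent(
                composite, z_c=p["z_p"], sigma=p["sigma_p"],
                multiplicity=PL_ratio)
        except KeyError as exc:
            raise ModelConfigError(
                f"missing structural parameter {exc}") from exc

    return SDPModel(
        A_U=A_U,
        headgroups=tuple(heads),
        chain_gaussians=chain,
        ch2=ch2,
        hc=hc,
        peptide=pep_component,
        PL_ratio=PL_ratio,
        lipid_fractions=dict(lipid_fractions),
        solvent=solvent or Solvent(),
    )


def volume_probability(model: SDPModel, z_grid: np.ndarray) -> ProfileSet:
    """Evaluate all volume-probability profiles on ``z_grid``."""
    z = np.asarray(z_grid, dtype=float)
    comps: dict[str, np.ndarray] = {}
    for c in model.headgroups:
        comps[c.name] = c.probability(z, model.A_U)

    p_hc = model.hc.probability(z)
    p_ch = model.chain_gaussians[0].probability(z, model.A_U)
    p_ch3 = model.chain_gaussians[1].probability(z, model.A_U)
    p_ch2 = p_hc - p_ch - p_ch3
    comps["CH"] = p_ch
    comps["CH3"] = p_ch3
    comps["CH2"] = p_ch2
    ch2_min = float(min(p_ch2.min(), 0.0))

    if model.peptide is not None:
        comps[model.peptide.name] = model.peptide.probability(z, model.A_U)

    total = sum(comps[name] for name in comps)
    water = 1.0 - total
    return ProfileSet(z=z, components=comps, hc_envelope=p_hc, water=water,
                      ch2_min=ch2_min)


def water_probability(profiles: ProfileSet) -> np.ndarray:
    """P_W(z) = 1 - sum of component probabilities (not clipped)."""
    return profiles.water


def check_overfill(profiles: ProfileSet) -> float:
    """Maximum packing excess max(sum P_i - 1, 0) over the grid."""
    excess = profiles.total - 1.0
    return float(max(excess.max(), 0.0))
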