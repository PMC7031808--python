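"""Chemical composition database for x-ray and neutron scattering.

Turns chemical formulas and peptide sequences into the quantities the
scattering-density-profile (SDP) machinery needs: electron counts for x-ray
work (electron-density units, arbitrary intensity scale per dataset) and
coherent neutron scattering lengths with H/D-exchange handling for contrast
variation.  Ships built-in quasimolecular group definitions for the averaged
POPE/POPG (3:1) lipid — ethanolamine (ENX), headgroup glycerol (PG2),
phosphate (PO4), carbonyl glycerol (CG), CH (oleoyl double bond), CH2 and
CH3 — plus the two magainin-family peptides L18W-PGLa and MG2a.

Conventions
-----------
* Scattering lengths in fm; neutron SLDs reported in 1e-6 / Angstrom^2;
  electron densities in e / Angstrom^3; volumes in Angstrom^3.
* Labile (exchangeable) hydrogens equilibrate fully with the solvent, so a
  group's effective deuteration of those sites equals the solvent D2O mole
  fraction ``x_D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "GroupDef",
    "PeptideSpec",
    "Solvent",
    "CompositionError",
    "formula_electrons",
    "formula_b_coherent",
    "formula_hydrogens",
    "xray_sld",
    "neutron_sld",
    "neutron_b",
    "peptide_from_sequence",
    "default_lipid_groups",
    "default_peptides",
    "load_groups",
    "water_volume",
    "B_HYDROGEN",
    "B_DEUTERIUM",
]

# Atomic number and bound coherent scattering length (fm), Sears tables.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, -3.7406),
    "D": (1, 6.671),
    "C": (6, 6.6511),
    "N": (7, 9.36),
    "O": (8, 5.803),
    "P": (15, 5.13),
    "S": (16, 2.847),
}

B_HYDROGEN = ELEMENTS["H"][1]
B_DEUTERIUM = ELEMENTS["D"][1]


class CompositionError(ValueError):
    """Invalid chemical composition or solvent specification."""


def formula_electrons(formula: dict[str, float]) -> float:
    """Electron count of a formula (element -> count map)."""
    try:
        return sum(n * ELEMENTS[el][0] for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise CompositionError(f"unknown element {exc}") from exc


def formula_b_coherent(formula: dict[str, float]) -> float:
    """Coherent neutron scattering length of a formula, fm (all-protiated H)."""
    return sum(n * ELEMENTS[el][1] for el, n in formula.items())


def formula_hydrogens(formula: dict[str, float]) -> float:
    return formula.get("H", 0.0) + formula.get("D", 0.0)


def _merge(*formulas: dict[str, float], weights=None) -> dict[str, float]:
    out: dict[str, float] = {}
    if weights is None:
        weights = [1.0] * len(formulas)
    for w, f in zip(weights, formulas):
        for el, n in f.items():
            out[el] = out.get(el, 0.0) + w * n
    return {el: n for el, n in out.items() if abs(n) > 1e-12}


@dataclass(frozen=True)
class GroupDef:
    """One quasimolecular fragment of the unit cell.

    ``multiplicity`` counts occurrences per averaged-lipid unit cell and may
    be fractional (e.g. 0.75 for the ethanolamine group of a POPE/POPG 3:1
    hybrid lipid).  ``volume`` is per single occurrence.
    """

    name: str
    formula: dict[str, float]
    volume: float
    n_exchangeable: float = 0.0
    multiplicity: float = 1.0
    n_electrons: float = field(default=None)  # type: ignore[assignment]
    b_H: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.volume <= 0:
            raise CompositionError(f"group {self.name}: volume must be > 0")
        ne = formula_electrons(self.formula)
        bh = formula_b_coherent(self.formula)
        if self.n_electrons is None:
            object.__setattr__(self, "n_electrons", ne)
        elif abs(self.n_electrons - ne) > 1e-6:
            raise CompositionError(
                f"group {self.name}: n_electrons {self.n_electrons} inconsistent "
                f"with formula sum {ne}"
            )
        if self.b_H is None:
            object.__setattr__(self, "b_H", bh)
        nH = formula_hydrogens(self.formula)
        if not 0 <= self.n_exchangeable <= nH + 1e-9:
            raise CompositionError(
                f"group {self.name}: n_exchangeable {self.n_exchangeable} outside "
                f"[0, {nH}]"
            )


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide treated as one scattering unit.

    The molecular volume is an *input* (the built-in defaults are the
    experimentally determined totals for L18W-PGLa and MG2a); it is not
    derived from residue-volume tables.
    """

    name: str
    sequence: str
    cterm_amidated: bool
    volume: float
    formula: dict[str, float]
    n_exchangeable: float
    n_electrons: float = field(default=None)  # type: ignore[assignment]
    b_H: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.volume <= 0:
            raise CompositionError(f"peptide {self.name}: volume must be > 0")
        ne = formula_electrons(self.formula)
        if self.n_electrons is None:
            object.__setattr__(self, "n_electrons", ne)
        if self.b_H is None:
            object.__setattr__(self, "b_H", formula_b_coherent(self.formula))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Solvent:
    """Aqueous solvent at a given D2O mole fraction.

    V_W defaults to 30.0 A^3 per water molecule (35 degC); use
    :func:`water_volume` for other temperatures.
    """

    x_D: float = 0.0
    V_W: float = 30.0

    def __post_init__(self):
        if not 0.0 <= self.x_D <= 1.0:
            raise CompositionError(f"x_D must be in [0, 1], got {self.x_D}")
        if self.V_W <= 0:
            raise CompositionError("V_W must be > 0")

    @property
    def xray_sld(self) -> float:
        """Electron density of the solvent, e/A^3 (10 electrons per water)."""
        return 10.0 / self.V_W

    @property
    def neutron_sld(self) -> float:
        """Neutron SLD of the solvent, 1e-6/A^2."""
        b = 2.0 * ((1 - self.x_D) * B_HYDROGEN + self.x_D * B_DEUTERIUM)
        b += ELEMENTS["O"][1]
        return 10.0 * b / self.V_W


#: d(V_W)/dT around 35 degC, A^3/K (liquid-water expansivity).
WATER_VOLUME_SLOPE = 0.0093


def water_volume(temperature_c: float, v35: float = 30.0,
                 slope: float = WATER_VOLUME_SLOPE) -> float:
    """Water molecular volume (A^3) linear in temperature around 35 degC."""
    return v35 + slope * (temperature_c - 35.0)


def xray_sld(group: GroupDef | PeptideSpec) -> float:
    """Electron density of a group or peptide, e/A^3."""
    if group.volume <= 0:
        raise CompositionError("volume must be > 0")
    return group.n_electrons / group.volume


def neutron_b(group: GroupDef | PeptideSpec, solvent: Solvent) -> float:
    """Coherent scattering length (fm) after H/D exchange with the solvent."""
    return group.b_H + group.n_exchangeable * solvent.x_D * (B_DEUTERIUM - B_HYDROGEN)


def neutron_sld(group: GroupDef | PeptideSpec, solvent: Solvent) -> float:
    """Neutron SLD of a group or peptide in the given solvent, 1e-6/A^2."""
    return 10.0 * neutron_b(group, solvent) / group.volume


# ---------------------------------------------------------------------------
# Peptides from sequence
# ---------------------------------------------------------------------------

# Residue (amino acid minus water) formulas, neutral side chains.
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

# Labile side-chain hydrogens per residue (neutral forms; Lys amine 2,
# Arg guanidino 4, His ring NH 1, hydroxyls/thiols/amides as drawn).
SIDECHAIN_LABILE_H: dict[str, int] = {
    "G": 0, "A": 0, "S": 1, "P": 0, "V": 0, "T": 1, "C": 1, "L": 0,
    "I": 0, "N": 2, "D": 1, "Q": 2, "K": 2, "E": 1, "M": 0, "H": 1,
    "F": 0, "R": 4, "Y": 1, "W": 1,
}

_WATER = {"H": 2, "O": 1}


def peptide_from_sequence(
    sequence: str,
    cterm_amidated: bool = False,
    volume: float | None = None,
    name: str | None = None,
) -> PeptideSpec:
    """Build a :class:`PeptideSpec` from a one-letter sequence.

    The formula is the residue sum plus one water (peptide-bond
    condensation), with the C-terminal acid replaced by an amide
    (-OH -> -NH2) when ``cterm_amidated``.  Exchangeable hydrogens count the
    backbone amide NH of every non-proline residue after the first, two for
    the free N-terminal amine, the side-chain labile hydrogens, and one
    (acid) or two (amide) at the C-terminus.

    ``volume`` (A^3) is required for scattering-density use; peptides built
    without one get a volume of 1 A^3 placeholder refused by the model layer.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise CompositionError("empty peptide sequence")
    bad = sorted(set(sequence) - set(RESIDUE_FORMULAS))
    if bad:
        raise CompositionError(f"unknown residue letter(s): {''.join(bad)}")

    formula = _merge(*(RESIDUE_FORMULAS[aa] for aa in sequence), _WATER)
    if cterm_amidated:
        formula = _merge(formula, {"O": -1, "N": 1, "H": 1})

    n_exch = sum(1 for aa in sequence[1:] if aa != "P")  # backbone NH
    n_exch += 2  # N-terminal amine
    n_exch += sum(SIDECHAIN_LABILE_H[aa] for aa in sequence)
    n_exch += 2 if cterm_amidated else 1  # C-terminus

    return PeptideSpec(
        name=name or sequence,
        sequence=sequence,
        cterm_amidated=cterm_amidated,
        volume=volume if volume is not None else 1.0,
        formula=formula,
        n_exchangeable=float(n_exch),
    )


# ---------------------------------------------------------------------------
# Built-in definitions
# ---------------------------------------------------------------------------

#: Experimentally determined peptide molecular volumes, A^3.
V_L18W_PGLA = 4927.8
V_MG2A = 5748.0

L18W_PGLA_SEQUENCE = "GMASKAGAIAGKIAKVAWKAL"
MG2A_SEQUENCE = "GIGKFLHSAKKFGKAFVGEIMNS"


def default_peptides() -> dict[str, PeptideSpec]:
    """L18W-PGLa and MG2a (both C-terminally amidated) with default volumes."""
    return {
        "L18W-PGLa": peptide_from_sequence(
            L18W_PGLA_SEQUENCE, cterm_amidated=True, volume=V_L18W_PGLA,
            name="L18W-PGLa"),
        "MG2a": peptide_from_sequence(
            MG2A_SEQUENCE, cterm_amidated=True, volume=V_MG2A, name="MG2a"),
    }


def default_lipid_groups() -> dict[str, GroupDef]:
    """Quasimolecular parsing of the averaged POPE/POPG (3:1) lipid.

    Multiplicities are per averaged lipid: the two headgroup identities keep
    independent groups (ENX at 0.75, PG2 at 0.25) while phosphate, carbonyl
    glycerol and the chain groups are shared.  Volumes follow published
    POPE/POPG SDP parameterisations at 35 degC and are configurable.
    """
    return {
        "ENX": GroupDef("ENX", {"C": 2, "H": 7, "N": 1}, volume=56.0,
                        n_exchangeable=3, multiplicity=0.75),
        "PG2": GroupDef("PG2", {"C": 3, "H": 7, "O": 2}, volume=90.0,
                        n_exchangeable=2, multiplicity=0.25),
        "PO4": GroupDef("PO4", {"P": 1, "O": 4}, volume=53.7),
        "CG": GroupDef("CG", {"C": 5, "H": 5, "O": 4}, volume=145.0),
        "CH": GroupDef("CH", {"C": 2, "H": 2}, volume=50.0),
        "CH2": GroupDef("CH2", {"C": 1, "H": 2}, volume=27.5, multiplicity=28),
        "CH3": GroupDef("CH3", {"C": 1, "H": 3}, volume=55.0, multiplicity=2),
    }


def load_groups(path) -> dict[str, GroupDef]:
    """Load group definitions from a YAML mapping.

    Each entry: ``name: {formula: {C: 5, ...}, volume: 145.0,
    n_exchangeable: 0, multiplicity: 1.0}``.  Missing fields default as in
    :class:`GroupDef`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    groups = {}
    for name, spec in raw.items():
        groups[name] = GroupDef(
            name=name,
            formula={el: float(n) for el, n in spec["formula"].items()},
            volume=float(spec["volume"]),
            n_exchangeable=float(spec.get("n_exchangeable", 0.0)),
            multiplicity=float(spec.get("multiplicity", 1.0)),
        )
    return groups


def with_volume(peptide: PeptideSpec, volume: float) -> PeptideSpec:
    """Copy of ``peptide`` with a different molecular volume."""
    return replace(peptide, volume=volume)
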