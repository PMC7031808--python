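"""Synthetic four-contrast scattering studies with known ground truth.

Emulates the joint SAXS/SANS experiment on POPE/POPG (3:1) vesicles with
adsorbed magainin peptides: one x-ray curve (q = 0.0098-0.9 1/A) and three
neutron contrasts at 100/75/50% D2O (q = 0.005-0.42 1/A), generated from a
known SDP parameter set with multiplicative Gaussian noise.  Ground-truth
parameter sets are shipped for the four studied systems (pure bilayer,
+L18W-PGLa, +MG2a, and the equimolar mixture) so that every stage of the
fitting pipeline can be exercised as a round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bilayer import DEFAULT_STRUCTURE_PARAMS, SDPModel, build_unit_cell
from .composition import PeptideSpec, Solvent, default_peptides
from .datasets import DataError, ScatteringDataset, save_dataset
from .formfactor import form_factor_analytic, intensity

__all__ = [
    "ContrastSpec",
    "StudyRecipe",
    "SYSTEM_PRESETS",
    "system_recipe",
    "build_truth_model",
    "simulate_dataset",
    "make_study",
    "load_study",
]

# Instrument q-ranges (1/A).
SAXS_Q_RANGE = (0.0098, 0.9)
SANS_Q_RANGE = (0.005, 0.42)


@dataclass(frozen=True)
class ContrastSpec:
    probe: str
    x_D: float
    q_min: float
    q_max: float
    n_q: int
    scale: float = 1.0
    background: float = 0.0

    def q_grid(self) -> np.ndarray:
        return np.geomspace(self.q_min, self.q_max, self.n_q)


def default_contrasts(n_saxs: int = 400, n_sans: int = 150) -> tuple[ContrastSpec, ...]:
    """SAXS plus SANS at 100/75/50% D2O over the instrument windows."""
    return (
        ContrastSpec("xray", 0.0, *SAXS_Q_RANGE, n_saxs),
        ContrastSpec("neutron", 1.0, *SANS_Q_RANGE, n_sans),
        ContrastSpec("neutron", 0.75, *SANS_Q_RANGE, n_sans),
        ContrastSpec("neutron", 0.50, *SANS_Q_RANGE, n_sans),
    )


# Ground-truth structural parameters for the four studied systems.  A_U,
# z_p and the CG->PO4 headgroup distance follow the joint-fit results for
# POPE/POPG (3:1) at 35 degC and P:L = 1:200; Gaussian widths are the
# package defaults (they are not printed per system).
SYSTEM_PRESETS: dict[str, dict] = {
    "pure": {
        "peptides": [],
        "PL_ratio": 0.0,
        "params": {"A_U": 60.56, "z_CG": 16.30, "z_PO4": 20.49},
    },
    "L18W-PGLa": {
        "peptides": ["L18W-PGLa"],
        "PL_ratio": 1 / 200,
        "params": {"A_U": 61.26, "z_CG": 16.10, "z_PO4": 20.17,
                   "z_p": 15.75, "sigma_p": 4.5},
    },
    "MG2a": {
        "peptides": ["MG2a"],
        "PL_ratio": 1 / 200,
        "params": {"A_U": 62.00, "z_CG": 15.90, "z_PO4": 19.70,
                   "z_p": 16.29, "sigma_p": 4.5},
    },
    "mixture": {
        "peptides": ["L18W-PGLa", "MG2a"],
        "PL_ratio": 1 / 200,
        "params": {"A_U": 63.29, "z_CG": 15.70, "z_PO4": 20.15,
                   "z_p": 15.98, "sigma_p": 4.5},
    },
}


@dataclass
class StudyRecipe:
    """Everything needed to generate one synthetic four-contrast study."""

    name: str = "pure"
    params: dict = field(default_factory=dict)      # ground-truth structure
    peptides: list[str] = field(default_factory=list)
    PL_ratio: float = 0.0
    lipid_fractions: dict = field(
        default_factory=lambda: {"POPE": 0.75, "POPG": 0.25})
    contrasts: tuple[ContrastSpec, ...] = field(default_factory=default_contrasts)
    noise_rel: float = 0.01
    sigma_floor: float | None = None  # absolute; default 1e-6 * max(I)
    seed: int = 0

    def __post_init__(self):
        if self.noise_rel < 0:
            raise DataError("noise must be >= 0")
        if not self.contrasts:
            raise DataError("need at least one contrast")


def system_recipe(system: str, noise_rel: float = 0.01, seed: int = 0,
                  **overrides) -> StudyRecipe:
    """Recipe for one of the four shipped systems."""
    preset = SYSTEM_PRESETS[system]
    params = dict(DEFAULT_STRUCTURE_PARAMS)
    params.update(preset["params"])
    return StudyRecipe(
        name=system, params=params, peptides=list(preset["peptides"]),
        PL_ratio=preset["PL_ratio"], noise_rel=noise_rel, seed=seed,
        **overrides)


def _peptide_specs(names: list[str]) -> list[PeptideSpec]:
    library = default_peptides()
    return [library[n] for n in names]


def build_truth_model(recipe: StudyRecipe) -> SDPModel:
    """The SDP model encoded by a recipe's ground-truth parameters."""
    return build_unit_cell(
        lipid_fractions=recipe.lipid_fractions,
        peptides=_peptide_specs(recipe.peptides),
        PL_ratio=recipe.PL_ratio,
        params=recipe.params,
        solvent=Solvent(),
    )


def simulate_dataset(
    model: SDPModel,
    probe: str,
    x_D: float,
    q_grid: np.ndarray,
    noise_rel: float = 0.01,
    seed: int = 0,
    scale: float = 1.0,
    background: float = 0.0,
    sigma_floor: float | None = None,
    name: str = "",
) -> ScatteringDataset:
    """One noisy synthetic curve: I = scale |F|^2/q^2 + bg, times (1 + eps).

    ``eps`` is zero-mean Gaussian with sd ``noise_rel``; the sigma column is
    the generating standard deviation, floored at ``sigma_floor`` (default
    1e-6 of the curve maximum) so it is strictly positive even at zero noise.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise DataError("empty q grid")
    ff = form_factor_analytic(model, probe, x_D, q)
    I_true = intensity(ff, scale=scale, background=background)
    floor = sigma_floor if sigma_floor is not None else 1e-6 * float(I_true.max())
    sigma = np.maximum(noise_rel * np.abs(I_true), floor)
    rng = np.random.default_rng(seed)
    I = I_true + rng.normal(0.0, 1.0, size=q.size) * sigma if noise_rel > 0 \
        else I_true.copy()
    q_hi = SANS_Q_RANGE[1] if probe == "neutron" else None
    return ScatteringDataset(probe=probe, x_D=x_D, q=q, I=I, sigma=sigma,
                             name=name, q_window=(0.05, q_hi))


def simulate_study(recipe: StudyRecipe) -> list[ScatteringDataset]:
    """All contrasts of a recipe, with per-contrast child seeds."""
    model = build_truth_model(recipe)
    seeds = np.random.SeedSequence(recipe.seed).generate_state(len(recipe.contrasts))
    out = []
    for cs, s in zip(recipe.contrasts, seeds):
        label = "saxs" if cs.probe == "xray" else f"sans_{int(round(cs.x_D * 100))}"
        out.append(simulate_dataset(
            model, cs.probe, cs.x_D, cs.q_grid(), noise_rel=recipe.noise_rel,
            seed=int(s), scale=cs.scale, background=cs.background,
            sigma_floor=recipe.sigma_floor, name=f"{recipe.name}_{label}"))
    return out


def make_study(recipe: StudyRecipe, outdir: str | Path) -> Path:
    """Write curves + manifest + ground truth to ``outdir``; returns manifest path.

    Produces one 3-column ASCII file per contrast, ``manifest.yaml``
    describing probe/x_D/window per file, and ``ground_truth.json`` with the
    generating parameter set for later scoring.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets = simulate_study(recipe)
    entries = []
    for ds in datasets:
        fname = f"{ds.name}.dat"
        save_dataset(ds, outdir / fname)
        entries.append({
            "file": fname, "probe": ds.probe, "x_D": float(ds.x_D),
            "q_window": [ds.q_window[0], ds.q_window[1]], "weight": ds.weight,
        })
    manifest = {
        "name": recipe.name,
        "lipid_fractions": recipe.lipid_fractions,
        "peptides": recipe.peptides,
        "PL_ratio": recipe.PL_ratio,
        "datasets": entries,
    }
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    truth = {
        "name": recipe.name,
        "params": {k: float(v) for k, v in recipe.params.items()},
        "peptides": recipe.peptides,
        "PL_ratio": recipe.PL_ratio,
        "lipid_fractions": recipe.lipid_fractions,
        "noise_rel": recipe.noise_rel,
        "seed": recipe.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return mpath


def load_study(manifest_path: str | Path) -> tuple[dict, list[ScatteringDataset]]:
    """Read a study manifest and its datasets back from disk."""
    from .datasets import load_dataset

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    datasets = []
    for e in manifest["datasets"]:
        lo, hi = e.get("q_window", [0.05, None])
        datasets.append(load_dataset(
            manifest_path.parent / e["file"], probe=e["probe"], x_D=e["x_D"],
            q_window=(lo, hi), weight=e.get("weight", 1.0)))
    return manifest, datasets


def truth_model_from_json(path: str | Path) -> SDPModel:
    """Rebuild the generating SDPModel from a ground_truth.json file."""
    truth = json.loads(Path(path).read_text())
    return build_unit_cell(
        lipid_fractions=truth["lipid_fractions"],
        peptides=_peptide_specs(truth["peptides"]),
        PL_ratio=truth["PL_ratio"],
        params=truth["params"],
    )
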