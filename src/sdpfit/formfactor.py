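"""Contrast profiles, the flat-bilayer form factor, and model intensities.

For dilute unilamellar vesicles analysed at q above the vesicle regime,
I(q) = scale * |F(q)|^2 / q^2 + background, with F the Fourier cosine
amplitude of the contrast profile of the symmetric flat bilayer.  Every
Gaussian component contributes analytically

    F_i(q) = 2 (V_i m_i / A_U) (rho_i - rho_ref) cos(q z_i) exp(-q^2 s_i^2/2)

and the hydrocarbon envelope contributes
``2 drho_CH2 sin(q D_C)/q exp(-q^2 s_HC^2/2)``; the CH and CH3 Gaussians
carry their contrast *relative to CH2* so that the envelope-minus-Gaussians
construction of the methylene profile is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bilayer import SDPModel
from .composition import Solvent, neutron_sld, xray_sld

__all__ = [
    "ContrastProfile",
    "FormFactor",
    "ProbeError",
    "contrast_profile",
    "form_factor_analytic",
    "intensity",
    "average_form_factors",
    "form_factor_discrepancy",
    "smear_gaussian",
    "group_sld",
]

class ProbeError(ValueError):
    """Unknown probe or mismatched form-factor grids."""


@dataclass(frozen=True)
class ContrastProfile:
    """Contrast vs. solvent along the bilayer normal."""

    z: np.ndarray
    drho: np.ndarray  # e/A^3 (xray) or 1e-6/A^2 (neutron)
    probe: str
    x_D: float


@dataclass(frozen=True)
class FormFactor:
    """Signed flat-bilayer scattering amplitude per unit area."""

    q: np.ndarray
    F: np.ndarray
    probe: str = "xray"
    x_D: float = 0.0


def group_sld(group, probe: str, solvent: Solvent) -> float:
    """Scattering density of a group for the given probe/contrast."""
    if probe == "xray":
        return xray_sld(group)
    if probe == "neutron":
        return neutron_sld(group, solvent)
    raise ProbeError(f"unknown probe {probe!r}")


def _solvent_sld(probe: str, solvent: Solvent) -> float:
    if probe == "xray":
        return solvent.xray_sld
    if probe == "neutron":
        return solvent.neutron_sld
    raise ProbeError(f"unknown probe {probe!r}")


def _solvent_at(model: SDPModel, x_D: float) -> Solvent:
    return Solvent(x_D=x_D, V_W=model.solvent.V_W)


def contrast_profile(
    model: SDPModel, probe: str, x_D: float, z_grid: np.ndarray
) -> ContrastProfile:
    """Delta-rho(z): each component's probability scaled by its contrast."""
    from .bilayer import volume_probability

    solvent = _solvent_at(model, x_D)
    rho_s = _solvent_sld(probe, solvent)
    profiles = volume_probability(model, np.asarray(z_grid, dtype=float))

    drho = np.zeros_like(profiles.z)
    for c in model.all_gaussians():
        drho += profiles.components[c.name] * (group_sld(c.group, probe, solvent) - rho_s)
    drho += profiles.components["CH2"] * (group_sld(model.ch2, probe, solvent) - rho_s)
    return ContrastProfile(z=profiles.z, drho=drho, probe=probe, x_D=x_D)


def form_factor_analytic(
    model: SDPModel, probe: str, x_D: float, q_grid: np.ndarray
) -> FormFactor:
    """Closed-form flat-bilayer form factor for one probe/contrast."""
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    solvent = _solvent_at(model, x_D)
    rho_s = _solvent_sld(probe, solvent)
    rho_ch2 = group_sld(model.ch2, probe, solvent)

    F = (rho_ch2 - rho_s) * model.hc.amplitude(q)
    for c in model.chain_gaussians:  # CH, CH3 relative to the CH2 background
        F += (group_sld(c.group, probe, solvent) - rho_ch2) * c.amplitude(q, model.A_U)
    for c in model.headgroups:
        F += (group_sld(c.group, probe, solvent) - rho_s) * c.amplitude(q, model.A_U)
    if model.peptide is not None:
        F += (group_sld(model.peptide.group, probe, solvent) - rho_s) \
            * model.peptide.amplitude(q, model.A_U)
    return FormFactor(q=q, F=F, probe=probe, x_D=x_D)


def intensity(
    ff: FormFactor, scale: float = 1.0, background: float = 0.0
) -> np.ndarray:
    """Model intensity I(q) = scale |F|^2 / q^2 + background."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return scale * ff.F**2 / ff.q**2 + background


def smear_gaussian(q: np.ndarray, I: np.ndarray, rel_sigma: float) -> np.ndarray:
    """Gaussian q-resolution smearing with sigma_q = rel_sigma * q.

    Intended for SANS wavelength spread (e.g. Delta-lambda/lambda = 0.1
    FWHM corresponds to rel_sigma ~ 0.042); off by default in the pipeline.
    """
    if rel_sigma <= 0:
        return I
    out = np.empty_like(I)
    for i, qi in enumerate(q):
        s = rel_sigma * qi
        w = np.exp(-((q - qi) ** 2) / (2 * s**2))
        out[i] = np.trapezoid(w * I, q) / np.trapezoid(w, q)
    return out


def average_form_factors(
    ff_a: FormFactor, ff_b: FormFactor, weights: tuple[float, float] = (0.5, 0.5)
) -> FormFactor:
    """Pointwise weighted mean of two form factors on identical q grids.

    Used to test the non-interaction hypothesis: if two individually added
    peptides did not interact, the scattering of the equimolar mixture would
    be the average of the single-peptide form factors.
    """
    if ff_a.q.shape != ff_b.q.shape or not np.allclose(ff_a.q, ff_b.q):
        raise ProbeError("form factors are on different q grids")
    wa, wb = weights
    tot = wa + wb
    return FormFactor(
        q=ff_a.q, F=(wa * ff_a.F + wb * ff_b.F) / tot, probe=ff_a.probe,
        x_D=ff_a.x_D)


def form_factor_discrepancy(
    ff: FormFactor, reference: FormFactor, sigma: np.ndarray | None = None
) -> float:
    """Reduced chi-square-style discrepancy between two form factors.

    With no ``sigma`` the per-point uncertainty defaults to the rms of the
    reference amplitude, making the metric a dimensionless shape distance
    (0 iff identical).
    """
    if ff.q.shape != reference.q.shape or not np.allclose(ff.q, reference.q):
        raise ProbeError("form factors are on different q grids")
    resid = ff.F - reference.F
    if sigma is None:
        sigma = np.sqrt(np.mean(reference.F**2)) * np.ones_like(resid)
    return float(np.mean((resid / sigma) ** 2))
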