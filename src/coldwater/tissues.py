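"""Tissue parameter records for the whole-body thermal model.

The model resolves four tissue compartments — muscle, skin, head (brain
average) and internal organs — each described by its thermal conductivity,
density, specific heat, blood perfusion rate and basal metabolic heat
generation.  Arterial blood is treated as a separate lumped pool whose
properties match the perfused-tissue lineage of whole-body models
(density 1060 kg/m³, specific heat 3800 J/(kg·°C), ~5 L volume).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TissueProperties",
    "tissue_properties",
    "TISSUES",
    "BLOOD_DENSITY",
    "BLOOD_SPECIFIC_HEAT",
    "BLOOD_VOLUME_L",
]

#: blood density, kg/m³ (same as the average tissue density)
BLOOD_DENSITY = 1060.0
#: blood specific heat, J/(kg·°C)
BLOOD_SPECIFIC_HEAT = 3800.0
#: circulating blood volume, litres
BLOOD_VOLUME_L = 5.0


@dataclass(frozen=True)
class TissueProperties:
    """Thermal and physiological parameters of one tissue compartment.

    Attributes
    ----------
    name : str
        Tissue label.
    k : float
        Thermal conductivity, W/(m·°C).
    rho : float
        Density, kg/m³.
    cp : float
        Specific heat, J/(kg·°C).
    w_b : float
        Blood perfusion rate, 1/s (volumetric blood flow per tissue volume).
    q_m : float
        Basal volumetric metabolic heat generation, W/m³.
    """

    name: str
    k: float
    rho: float
    cp: float
    w_b: float
    q_m: float

    def __post_init__(self) -> None:
        for field in ("k", "rho", "cp", "w_b", "q_m"):
            value = getattr(self, field)
            if not (value > 0):
                raise ValueError(
                    f"tissue {self.name!r}: {field} must be > 0, got {value!r}"
                )

    @property
    def rho_cp(self) -> float:
        """Volumetric heat capacity ρ·cp, J/(m³·°C)."""
        return self.rho * self.cp


TISSUES: dict[str, TissueProperties] = {
    t.name: t
    for t in (
        TissueProperties("muscle", k=0.5, rho=1060.0, cp=3800.0, w_b=0.0005, q_m=553.5),
        TissueProperties("skin", k=0.3, rho=1060.0, cp=2802.0, w_b=0.0005, q_m=553.5),
        TissueProperties("head", k=0.5, rho=1060.0, cp=3800.0, w_b=0.00833, q_m=9225.0),
        TissueProperties(
            "internal_organs", k=0.5, rho=1060.0, cp=3800.0, w_b=0.001266, q_m=1401.5
        ),
    )
}


def tissue_properties(name: str) -> TissueProperties:
    """Look up the bundled parameter record for a tissue.

    Parameters
    ----------
    name : str
        One of ``muscle``, ``skin``, ``head``, ``internal_organs``.

    Returns
    -------
    TissueProperties
        The immutable parameter record.

    Raises
    ------
    KeyError
        If ``name`` is not a defined tissue.
    """
    try:
        return TISSUES[name]
    except KeyError:
        known = ", ".join(sorted(TISSUES))
        raise KeyError(f"unknown tissue {name!r}; defined tissues: {known}") from None
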