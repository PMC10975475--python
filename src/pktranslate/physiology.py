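"""Species physiology library.

Constants used throughout the pipeline: body-surface-area conversion (Km)
factors, hepatic blood flow, plasma/extracellular/remainder water volumes for
the Oie-Tozer volume-of-distribution method, whole-body organ volumes and
perfusion fractions for the PBPK model, and tissue composition fractions for
Rodgers-Rowland partition-coefficient calculation.

Every constant carries a provenance string.  Values are defaults of the
package's physiology library, overridable through run configuration; they are
standard literature values (FDA 2005 BSA guidance, Davies & Morris 1993,
Brown et al. 1997, Rodgers & Rowland 2006), not measurements of this study.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class OieTozerVolumes:
    """Physiological volumes (L/kg) for the Oie-Tozer Vss decomposition.

    vp: plasma volume; ve: extracellular (interstitial) water;
    vr: remainder (intracellular) water; re_i: ratio of extravascular to
    intravascular binding protein.
    """

    vp: float
    ve: float
    vr: float
    re_i: float
    provenance: str = "Davies & Morris 1993 / Obach 1997 compilation"


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition for Rodgers-Rowland equations.

    f_ew: extracellular water, f_iw: intracellular water, f_nl: neutral
    lipid, f_np: neutral phospholipid (all volume fractions); ra: tissue to
    plasma albumin ratio.
    """

    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    ra: float


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    body_weight: float                 # kg, representative animal
    km_factor: float                   # BSA conversion factor (FDA 2005)
    q_hepatic: float                   # hepatic blood flow, mL/min/kg
    oie_tozer: OieTozerVolumes
    liver_weight_fraction: float       # g liver / g body weight
    hepatocellularity: float = 120.0   # 1e6 cells / g liver
    cardiac_output: float | None = None        # L/h/kg blood
    organ_volume_fractions: dict[str, float] = field(default_factory=dict)
    organ_flow_fractions: dict[str, float] = field(default_factory=dict)
    blood_volume_fraction: float | None = None
    tissue_compositions: dict[str, TissueComposition] = field(default_factory=dict)
    provenance: str = "physiology library default"

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be positive, got {self.body_weight}")
        if self.km_factor <= 0:
            raise ValueError(f"km_factor must be positive, got {self.km_factor}")

    @property
    def q_hepatic_total(self) -> float:
        """Hepatic blood flow for the whole animal, mL/min."""
        return self.q_hepatic * self.body_weight


# Rodgers & Rowland 2006 rat tissue composition (also applied to human, the
# standard practice when human fractions are unavailable).  Plasma neutral
# lipid / phospholipid fractions appear as PLASMA_F_NL / PLASMA_F_NP.
_TISSUE_COMPOSITION: dict[str, TissueComposition] = {
    "adipose": TissueComposition(0.135, 0.017, 0.853, 0.0016, 0.049),
    "bone":    TissueComposition(0.100, 0.346, 0.017, 0.0017, 0.100),
    "brain":   TissueComposition(0.162, 0.620, 0.039, 0.0015, 0.048),
    "gut":     TissueComposition(0.282, 0.475, 0.038, 0.0125, 0.158),
    "heart":   TissueComposition(0.320, 0.456, 0.014, 0.0111, 0.157),
    "kidney":  TissueComposition(0.273, 0.483, 0.012, 0.0242, 0.130),
    "liver":   TissueComposition(0.161, 0.573, 0.014, 0.0240, 0.086),
    "lung":    TissueComposition(0.336, 0.446, 0.022, 0.0128, 0.212),
    "muscle":  TissueComposition(0.118, 0.630, 0.010, 0.0072, 0.064),
    "skin":    TissueComposition(0.382, 0.291, 0.060, 0.0044, 0.277),
    "spleen":  TissueComposition(0.207, 0.579, 0.0077, 0.0113, 0.097),
    # lumped remainder: muscle-like water, modest lipid
    "rest":    TissueComposition(0.200, 0.500, 0.040, 0.0070, 0.100),
}

PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013

# Organ volumes as fraction of body weight (density 1 assumed) and perfusion
# as fraction of cardiac output (Brown et al. 1997).  "rest" closes both
# balances so that volumes plus blood sum below 1 and flows sum to exactly 1.
_RAT_VOLUMES = {
    "lung": 0.005, "heart": 0.0033, "brain": 0.0057, "muscle": 0.404,
    "adipose": 0.070, "skin": 0.190, "bone": 0.073, "kidney": 0.0073,
    "spleen": 0.002, "gut": 0.027, "liver": 0.0366, "rest": 0.1061,
}
_RAT_FLOWS = {
    "heart": 0.050, "brain": 0.020, "muscle": 0.280, "adipose": 0.070,
    "skin": 0.060, "bone": 0.120, "kidney": 0.140, "spleen": 0.0125,
    "gut": 0.130, "hepatic_artery": 0.030, "rest": 0.0875,
}

_HUMAN_VOLUMES = {
    "lung": 0.0076, "heart": 0.0047, "brain": 0.020, "muscle": 0.400,
    "adipose": 0.190, "skin": 0.0371, "bone": 0.0856, "kidney": 0.0044,
    "spleen": 0.0026, "gut": 0.0171, "liver": 0.0257, "rest": 0.1262,
}
_HUMAN_FLOWS = {
    "heart": 0.040, "brain": 0.120, "muscle": 0.170, "adipose": 0.050,
    "skin": 0.050, "bone": 0.050, "kidney": 0.190, "spleen": 0.020,
    "gut": 0.160, "hepatic_artery": 0.0788, "rest": 0.0712,
}


def _species(name, bw, km, qh, ot, lw, co=None, vols=None, flows=None, bvf=None):
    return SpeciesProfile(
        name=name, body_weight=bw, km_factor=km, q_hepatic=qh,
        oie_tozer=ot, liver_weight_fraction=lw, cardiac_output=co,
        organ_volume_fractions=vols or {}, organ_flow_fractions=flows or {},
        blood_volume_fraction=bvf,
        tissue_compositions=dict(_TISSUE_COMPOSITION),
        provenance="FDA 2005 (Km); Davies & Morris 1993 (flows, volumes); "
                   "Brown et al. 1997 (PBPK organ fractions)",
    )


MOUSE = _species(
    "mouse", 0.025, 3.0, 90.0,
    OieTozerVolumes(vp=0.050, ve=0.265, vr=0.364, re_i=0.136),
    lw=0.0875,
)

RAT = _species(
    "rat", 0.245, 6.0, 55.2,
    OieTozerVolumes(vp=0.0313, ve=0.265, vr=0.364, re_i=0.173),
    lw=0.040, co=55.2 * 60e-3 / 0.1725,   # hepatic flow is 17.25% of CO
    vols=_RAT_VOLUMES, flows=_RAT_FLOWS, bvf=0.074,
)

DOG = _species(
    "dog", 7.21, 20.0, 30.9,
    OieTozerVolumes(vp=0.0515, ve=0.216, vr=0.450, re_i=0.183),
    lw=0.032,
)

HUMAN = _species(
    "human", 60.0, 37.0, 20.7,
    OieTozerVolumes(vp=0.0436, ve=0.151, vr=0.380, re_i=1.40),
    lw=0.0257, co=20.7 * 60e-3 / 0.2588,  # hepatic flow is 25.88% of CO
    vols=_HUMAN_VOLUMES, flows=_HUMAN_FLOWS, bvf=0.079,
)

SPECIES: dict[str, SpeciesProfile] = {
    s.name: s for s in (MOUSE, RAT, DOG, HUMAN)
}


def get_species(name: str, **overrides) -> SpeciesProfile:
    """Look up a species profile, optionally overriding scalar fields.

    Overrides cover the config-exposed constants (body_weight, km_factor,
    q_hepatic, hepatocellularity, liver_weight_fraction).
    """
    try:
        base = SPECIES[name]
    except KeyError:
        raise KeyError(f"unknown species {name!r}; known: {sorted(SPECIES)}") from None
    if not overrides:
        return base
    from dataclasses import replace

    return replace(base, **overrides)
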