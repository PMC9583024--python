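"""Literature-default parameter sets for the axonal cytoskeleton model.

These are the package's canonical defaults: Tau protein Kelvin-Voigt
constants, axoplasmic matrix stiffness, the RVE geometry presets (see
:mod:`axonve.rve`), and the characterized orthotropic Prony coefficients of
the cytoskeletal core used as the synthetic generator's ground truth.
"""

from __future__ import annotations

from .viscoelastic import OrthotropicRelaxationMatrix, PronyRelaxation

#: Tau Kelvin-Voigt constants: modulus (Pa) and retardation time (s).
TAU_E = 5.0e6
TAU_RETARDATION_TIME = 0.35
TAU_NU = 0.33
#: Branch-stiffness multiplier for the General Maxwell creep match.
TAU_GM_MULTIPLIER = 100.0

#: Matrix (combined neurofilament/microfilament) effective stiffness.
MATRIX_E = 1.47e3
MATRIX_NU = 0.33

#: Relaxation-test protocol: ramp/hold/unload/recovery times (s) and the
#: driven-face displacement amplitude (nm).
LOAD_TIMES = (0.0, 3.0e-3, 12.0e-3, 15.0e-3, 40.0e-3)
DELTA_NM = 3.0

#: Characterized orthotropic Prony coefficients of the cytoskeletal core:
#: short-term modulus (Pa), branch fractions and relaxation times (s).
#: Mean values over the homogenization observations; the axial function C33
#: is the stiffest (microtubules run along axis 3), the shear functions the
#: softest.
AXON_CORE_PRONY_MEANS: dict[str, dict] = {
    "C11": {"C0": 389.60e3, "h": (0.43, 0.55), "tau": (4.54e-3, 5.66e-3)},
    "C12": {"C0": 133.09e3, "h": (0.35, 0.65), "tau": (4.63e-3, 4.64e-3)},
    "C22": {"C0": 383.44e3, "h": (0.31, 0.68), "tau": (3.32e-3, 6.01e-3)},
    "C13": {"C0": 87.68e3, "h": (0.41, 0.59), "tau": (7.02e-3, 7.06e-3)},
    "C23": {"C0": 67.27e3, "h": (0.43, 0.57), "tau": (5.37e-3, 5.27e-3)},
    "C33": {"C0": 1601.38e3, "h": (0.19, 0.75), "tau": (19.27e-3, 23.84e-3)},
    "C44": {"C0": 68.68e3, "h": (0.22, 0.76), "tau": (7.70e-3, 4.77e-3)},
    "C55": {"C0": 48.46e3, "h": (0.18, 0.80), "tau": (8.80e-3, 4.74e-3)},
    "C66": {"C0": 80.55e3, "h": (0.36, 0.62), "tau": (5.91e-3, 9.29e-3)},
}


def default_core_matrix() -> OrthotropicRelaxationMatrix:
    """The default orthotropic relaxation matrix of the cytoskeletal core."""
    return OrthotropicRelaxationMatrix(
        {
            key: PronyRelaxation(v["C0"], tuple(zip(v["h"], v["tau"])))
            for key, v in AXON_CORE_PRONY_MEANS.items()
        }
    )


#: Cytoskeletal failure criteria: microtubule and Tau failure strains.
EPS_MT_FAIL = 0.50
EPS_TAU_FAIL = 0.40
#: Calibrated Tau strain-concentration factor (local Tau principal strain per
#: unit volume-averaged axial strain), chosen so the Tau criterion maps to an
#: axon-level failure strain of 40%/5.48 = 7.3%.
TAU_CONCENTRATION_FACTOR = 5.48

#: Effective transverse cross-section defaults (nm and Pa).
AXON_RADIUS_NM = 500.0
MEMBRANE_THICKNESS_NM = 10.0
INNER_REGION_THICKNESS_NM = 200.0
E_MEMBRANE = 4.23e3
E_INNER = 1.47e3
K_MYELIN = 54.0e6
NU_MYELIN = 0.44
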