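"""Published parameter sets for thrombin variants, usable as generator inputs.

Rate constants are values at the 288.15 K reference temperature
(kon uM^-1 s^-1, koff s^-1), activation energies in kcal/mol. Midpoints
of GuHCl denaturation are in M; Na+ dissociation constants in mM.
"""

from __future__ import annotations

from relaxkin.global_fit import ArrheniusLaw, GlobalKineticModel, T0_DEFAULT

__all__ = [
    "lk_model",
    "LK_VARIANTS",
    "DENATURATION_MIDPOINTS",
    "NA_KD_MM",
]

#: lock-and-key kinetic constants at T0 = 288.15 K: (koff, kon, Eoff, Eon)
LK_VARIANTS: dict[str, tuple[float, float, float, float]] = {
    "prethrombin2": (46.0, 0.46, 17.0, 8.6),
    "I16T": (29.0, 0.73, 23.0, 3.0),
    "D194A": (7.8, 1.6, 13.0, 8.9),
}

#: GuHCl denaturation midpoints, M, without and with the active-site
#: inhibitor PPACK
DENATURATION_MIDPOINTS: dict[str, dict[str, float]] = {
    "wild-type": {"apo": 1.32, "ppack": 3.75},
    "I16T": {"apo": 1.13, "ppack": 1.65},
    "D194A": {"apo": 1.29, "ppack": 1.58},
    "D189A": {"apo": 1.50, "ppack": 2.10},
    "prethrombin2": {"apo": 0.85, "ppack": 0.73},
}

#: Na+ dissociation constants, mM
NA_KD_MM: dict[str, float] = {
    "wild-type": 16.0,
    "I16T": 1100.0,
    "D194A": 80.0,
}


def lk_model(variant: str, T0: float = T0_DEFAULT) -> GlobalKineticModel:
    """Lock-and-key global model for a named variant."""
    try:
        koff, kon, e_off, e_on = LK_VARIANTS[variant]
    except KeyError:
        raise KeyError(
            f"unknown variant {variant!r}; available: {sorted(LK_VARIANTS)}"
        ) from None
    return GlobalKineticModel(
        kind="lk",
        laws={
            "kon": ArrheniusLaw(k0=kon, E=e_on, T0=T0),
            "koff": ArrheniusLaw(k0=koff, E=e_off, T0=T0),
        },
    )
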