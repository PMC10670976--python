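"""Bundled registries and worked-example datasets.

The component registry carries molar masses, liquid molar volumes and
(where the species is a room-temperature liquid) densities for the HEMWat
solvents, the NADES hydrogen-bond acceptors/donors, and the two stilbenoid
targets; a provenance column distinguishes handbook-style values from
subcooled-liquid estimates.

Sigma profiles attached to the registry are *synthetic*: Gaussian-bump
emulations of each species' qualitative surface-charge character (see
:mod:`stilbex.synth`), sized so the cavity volume is consistent with the
liquid molar volume.  They support trend-faithful, fully reproducible
calculations — not numeric agreement with profiles from quantum-chemical
workflows.

Also bundled: the four HEMWat volumetric recipes, a worked-example table
of externally calculated partition ratios for those systems, the five
prepared NADES formulations with their experimental preparability, the
stilbenoid monoisotopic-mass table, and a representative negative-mode
ion list of a grapevine-cane extract.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Dict, List, Optional

import pandas as pd

from .lle import SolventRecipe
from .nades import NADESSpec
from .partition import PartitionTable
from .sigma import ComponentRecord
from .synth import ProfileSpec, make_profile

__all__ = [
    "PROFILE_SPECS",
    "load_registry",
    "registry_by_abbrev",
    "hemwat_recipes",
    "hemwat_calculated_kd",
    "prepared_nades",
    "heatmap_specs",
    "stilbenoid_mass_table",
    "grapevine_extract_ions",
]

#: cm^3/mol -> A^3/molecule
_CM3MOL_TO_A3 = 1.0e24 / 6.02214076e23

# Qualitative bump recipes (center e/A^2, width e/A^2, area A^2).
# Apolar surface sits near sigma = 0; hydrogen-bond donor hydrogens screen
# negative (centers near -0.015), acceptor lone pairs positive.  Areas are
# rough cavity-surface magnitudes scaled with molecular size.
PROFILE_SPECS: Dict[str, ProfileSpec] = {
    spec.name: spec
    for spec in [
        ProfileSpec("n-hexane", ((0.0, 0.004, 225.0),)),
        ProfileSpec(
            "ethyl acetate",
            ((0.0, 0.005, 100.0), (0.012, 0.0025, 25.0)),
        ),
        ProfileSpec(
            "methanol",
            ((0.0, 0.005, 40.0), (-0.015, 0.0025, 12.0), (0.013, 0.0025, 16.0)),
        ),
        ProfileSpec(
            "water",
            ((0.0, 0.003, 3.0), (-0.015, 0.004, 19.0), (0.015, 0.004, 21.0)),
        ),
        ProfileSpec(
            "choline chloride",  # undissociated ion pair, single profile
            ((-0.005, 0.005, 120.0), (-0.014, 0.003, 15.0), (0.017, 0.003, 65.0)),
        ),
        ProfileSpec(
            "betaine",
            ((-0.005, 0.005, 80.0), (0.0, 0.004, 15.0), (0.015, 0.003, 55.0)),
        ),
        ProfileSpec(
            "glucose",
            ((0.0, 0.004, 60.0), (-0.015, 0.003, 55.0), (0.014, 0.003, 65.0)),
        ),
        ProfileSpec(
            "fructose",
            ((0.0, 0.004, 58.0), (-0.015, 0.003, 53.0), (0.014, 0.003, 64.0)),
        ),
        ProfileSpec(
            "urea",
            ((0.0, 0.004, 10.0), (-0.014, 0.003, 40.0), (0.015, 0.003, 35.0)),
        ),
        ProfileSpec(
            "glycerol",
            ((0.0, 0.004, 50.0), (-0.015, 0.0028, 35.0), (0.014, 0.0028, 40.0)),
        ),
        ProfileSpec(
            "1,2-propanediol",
            ((0.0, 0.005, 75.0), (-0.014, 0.0028, 25.0), (0.013, 0.0028, 30.0)),
        ),
        ProfileSpec(
            "1,4-butanediol",
            ((0.0, 0.005, 95.0), (-0.014, 0.0028, 25.0), (0.013, 0.0028, 30.0)),
        ),
        ProfileSpec(
            "sorbitol",
            ((0.0, 0.004, 70.0), (-0.015, 0.003, 60.0), (0.014, 0.003, 70.0)),
        ),
        ProfileSpec(
            "sucrose",
            ((0.0, 0.004, 110.0), (-0.015, 0.003, 95.0), (0.014, 0.003, 115.0)),
        ),
        ProfileSpec(
            "acetic acid",  # protonated neutral form
            ((0.0, 0.005, 45.0), (-0.016, 0.0025, 20.0), (0.013, 0.0028, 25.0)),
        ),
        ProfileSpec(
            "lactic acid",
            ((0.0, 0.005, 45.0), (-0.016, 0.0026, 30.0), (0.013, 0.0028, 35.0)),
        ),
        ProfileSpec(
            "malic acid",
            ((0.0, 0.005, 50.0), (-0.016, 0.0027, 40.0), (0.013, 0.0028, 50.0)),
        ),
        ProfileSpec(
            "citric acid",
            ((0.0, 0.005, 55.0), (-0.016, 0.0027, 55.0), (0.013, 0.0028, 70.0)),
        ),
        ProfileSpec(
            "oxalic acid",
            ((0.0, 0.005, 15.0), (-0.016, 0.0026, 35.0), (0.013, 0.0028, 45.0)),
        ),
        ProfileSpec(
            "benzoic acid",
            ((0.0, 0.006, 100.0), (-0.016, 0.0025, 18.0), (0.013, 0.0028, 22.0)),
        ),
        ProfileSpec(
            "adipic acid",
            ((0.0, 0.005, 100.0), (-0.016, 0.0026, 32.0), (0.013, 0.0028, 38.0)),
        ),
        # stilbenoids: apolar bulk within +-0.01 plus hb wings at -0.017
        # (phenolic OH) and +0.012 (acceptor oxygens); the dimer has the
        # same shape on a larger cavity surface
        ProfileSpec(
            "trans-resveratrol",
            ((0.0, 0.005, 195.0), (-0.017, 0.0025, 22.0), (0.012, 0.003, 26.0)),
        ),
        ProfileSpec(
            "trans-epsilon-viniferin",
            ((0.0, 0.005, 360.0), (-0.017, 0.0025, 40.0), (0.012, 0.003, 47.0)),
        ),
    ]
}


def _data_text(filename: str):
    return resources.files("stilbex.data").joinpath(filename)


def load_registry(with_profiles: bool = True) -> Dict[str, ComponentRecord]:
    """Component registry keyed by name, synthetic profiles attached."""
    df = pd.read_csv(_data_text("components.csv"))
    registry: Dict[str, ComponentRecord] = {}
    for row in df.itertuples(index=False):
        profile = None
        if with_profiles:
            spec = PROFILE_SPECS[row.name]
            # size the cavity volume consistently with the molar volume
            profile = dataclasses.replace(
                make_profile(spec),
                volume=float(row.liquid_molar_volume) * _CM3MOL_TO_A3,
            )
        registry[row.name] = ComponentRecord(
            name=row.name,
            molar_mass=float(row.molar_mass),
            liquid_molar_volume=float(row.liquid_molar_volume),
            density=None if pd.isna(row.density) else float(row.density),
            sigma_profile=profile,
        )
    return registry


def registry_by_abbrev(
    registry: Optional[Dict[str, ComponentRecord]] = None,
) -> Dict[str, ComponentRecord]:
    """The same registry keyed by the field abbreviations (Ch, B, Glu, ...)."""
    if registry is None:
        registry = load_registry()
    df = pd.read_csv(_data_text("components.csv"))
    return {
        row.abbrev: registry[row.name]
        for row in df.itertuples(index=False)
        if row.name in registry
    }


def hemwat_recipes(
    registry: Optional[Dict[str, ComponentRecord]] = None,
) -> Dict[str, SolventRecipe]:
    """The four HEMWat volumetric recipes, keyed by system id."""
    if registry is None:
        registry = load_registry()
    df = pd.read_csv(_data_text("hemwat_systems.csv"), dtype={"system_id": str})
    recipes = {}
    for sys_id, grp in df.groupby("system_id", sort=True):
        recipes[sys_id] = SolventRecipe(
            components=[registry[name] for name in grp["component"]],
            volume_parts=list(grp["part"]),
            T_lle=20.0,
        )
    return recipes


def hemwat_calculated_kd() -> PartitionTable:
    """Worked-example partition ratios for the four HEMWat systems.

    These are externally calculated reference values shipped as pipeline
    *inputs* for the selection worked example; they are not produced by
    the bundled engine.
    """
    df = pd.read_csv(_data_text("hemwat_kd_calculated.csv"), dtype={"system_id": str})
    return PartitionTable(
        rows=[(r.system_id, r.solute, float(r.K_D)) for r in df.itertuples(index=False)]
    )


def prepared_nades(
    registry: Optional[Dict[str, ComponentRecord]] = None,
) -> Dict[str, NADESSpec]:
    """The five experimentally prepared NADES formulations, keyed by label."""
    if registry is None:
        registry = load_registry()
    df = pd.read_csv(_data_text("nades_prepared.csv"))
    specs = {}
    for row in df.itertuples(index=False):
        ratio = (int(row.ratio_num), int(row.ratio_den))
        specs[row.label] = NADESSpec(
            hba=registry[row.hba],
            hbd=registry[row.hbd],
            ratio=ratio,
            water_wt_pct=float(row.water_wt_pct),
            nonstandard_ratio=True,
            preparable=bool(row.preparable),
        )
    return specs


def heatmap_specs(
    registry: Optional[Dict[str, ComponentRecord]] = None,
) -> List[NADESSpec]:
    """The canned heat-map slice: every registry HBD against every HBA.

    Choline chloride and betaine systems enter at molar ratio 3/1, the
    sugar HBAs (glucose, fructose) at 1/3, all anhydrous — the overview
    slice used to compare donor chemistries at a glance.
    """
    if registry is None:
        registry = load_registry()
    df = pd.read_csv(_data_text("components.csv"))
    hbas = list(df[df.role == "hba"]["name"])
    hbds = list(df[df.role == "hbd"]["name"])
    specs = []
    for hba in hbas:
        ratio = (1, 3) if hba in ("glucose", "fructose") else (3, 1)
        for hbd in hbds:
            specs.append(
                NADESSpec(
                    hba=registry[hba],
                    hbd=registry[hbd],
                    ratio=ratio,
                    water_wt_pct=0.0,
                )
            )
    return specs


def stilbenoid_mass_table() -> pd.DataFrame:
    """Candidate neutral monoisotopic masses for [M-H]- annotation."""
    return pd.read_csv(_data_text("stilbenoid_masses.csv"))


def grapevine_extract_ions() -> List[float]:
    """Representative negative-mode pseudo-molecular ions (m/z) of a
    grapevine-cane NADES extract, in elution order."""
    return [471.0, 469.0, 227.0, 453.0, 453.0, 453.0, 329.0, 565.0, 431.0]
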