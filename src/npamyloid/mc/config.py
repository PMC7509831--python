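"""Simulation configuration for the coarse-grained aggregation model.

All lengths are in reduced units sigma; ``sigma_nm`` records the physical
mapping (1 sigma = 1 nm by default, so one bead coarse-grains roughly five
Abeta42 residues and an 8-bead chain spans the peptide).  Energies are in kT.
"""

from __future__ import annotations

import math
from typing import Sequence

import yaml
from pydantic import BaseModel, Field, model_validator


class NanoparticleSpec(BaseModel):
    """A fixed spherical nanoparticle: hard core plus a square-well shell.

    ``adsorption_energy`` is the flat-surface well depth per bead (kT); the
    effective depth of a finite sphere is attenuated by curvature, see
    :meth:`effective_adsorption_energy`.
    """

    diameter: float = Field(gt=0)
    adsorption_energy: float = Field(default=8.0, ge=0)
    shell_thickness: float = Field(default=0.5, gt=0)

    def effective_adsorption_energy(self, curvature_length: float) -> float:
        """Curvature-attenuated well depth: eps * R / (R + l_c).

        A bead contacting a highly curved surface shares less contact area
        with it than on a flat wall; the attenuation length ``l_c`` sets how
        quickly the flat-surface limit is approached as the radius grows.
        """
        r = self.diameter / 2.0
        return self.adsorption_energy * r / (r + curvature_length)

    def effective_shell_thickness(self, shell_curvature_length: float) -> float:
        """Curvature-narrowed adsorption range: t * R / (R + l_s).

        The ligand-contact range a bead experiences narrows on a strongly
        curved surface for the same reason the well shallows: less of the
        particle surface is close enough to engage the bead.
        """
        r = self.diameter / 2.0
        return self.shell_thickness * r / (r + shell_curvature_length)


class SimulationConfig(BaseModel):
    """Full parameter set of one Monte Carlo system."""

    box_length: float = Field(gt=0)
    n_chains: int = Field(gt=0)
    chain_length: int = Field(default=8, ge=3)
    bead_diameter: float = Field(default=1.0, gt=0)
    bond_length: float = Field(default=1.0, gt=0)
    eps_hb: float = Field(default=4.0, ge=0)
    hb_cutoff: float = Field(default=1.2, gt=0)
    max_bonds_per_bead: int = Field(default=2, ge=1)
    nanoparticles: list[NanoparticleSpec] = Field(default_factory=list)
    move_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_relax_steps: int = Field(default=10_000, ge=0)
    n_production_steps: int = Field(default=100_000, gt=0)
    n_analysis_steps: int = Field(default=10_000, gt=0)
    n_replicates: int = Field(default=5, ge=1)
    seed: int = 0
    # model switches / numerics
    sigma_nm: float = Field(default=1.0, gt=0)
    curvature_length: float = Field(default=1.0, ge=0)
    shell_curvature_length: float = Field(default=0.0, ge=0)
    occlusion_radius: float = Field(default=1.25, gt=0)
    block_bonds_when_adsorbed: bool = True
    merge_np_contacts: bool = False
    snapshot_stride: int = Field(default=1_000, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if abs(sum(self.move_weights) - 1.0) > 1e-9:
            raise ValueError("move_weights must sum to 1")
        if any(w < 0 for w in self.move_weights):
            raise ValueError("move_weights must be non-negative")
        if self.n_analysis_steps > self.n_production_steps:
            raise ValueError("n_analysis_steps must be <= n_production_steps")
        if self.nanoparticles:
            dmax = max(np_.diameter for np_ in self.nanoparticles)
            if self.box_length <= 2.0 * dmax:
                raise ValueError(
                    "box_length must exceed twice the largest nanoparticle "
                    f"diameter ({dmax})")
        if self.hb_cutoff < self.bead_diameter:
            raise ValueError("hb_cutoff must be >= bead_diameter")
        if self.box_length < 2.0 * self.hb_cutoff:
            raise ValueError("box too small for minimum-image bonding")
        return self

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length

    @property
    def number_density(self) -> float:
        return self.n_chains / self.box_length ** 3

    # -- serialization ----------------------------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)

    def with_nanoparticles(self, diameter: float, count: int,
                           **np_kwargs) -> "SimulationConfig":
        nps = [NanoparticleSpec(diameter=diameter, **np_kwargs)
               for _ in range(count)]
        return self.model_copy(update={"nanoparticles": nps})


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def desk_preset(**overrides) -> SimulationConfig:
    """Small system for laptop-scale runs and tests.

    Denser than the full-scale system (1.25e-2 chains/sigma^3) so that
    hydrogen-bond driven aggregation develops within 1e5 attempted moves.
    """
    base = dict(
        box_length=20.0, n_chains=100,
        n_relax_steps=10_000, n_production_steps=100_000,
        n_analysis_steps=10_000, n_replicates=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def sweep_preset(**overrides) -> SimulationConfig:
    """Desk-scale box large enough for the full 2-15 nm diameter sweep.

    32 sigma satisfies box > 2 x the largest swept diameter (15 sigma).  The
    chain count (4.6e-3 chains/sigma^3) keeps the zero-NP control in the
    moderate-aggregation regime at this step budget, where the replicate
    variance of the cluster-size observable stays well below the
    nanoparticle effect size.
    """
    base = dict(
        box_length=32.0, n_chains=150,
        n_relax_steps=10_000, n_production_steps=300_000,
        n_analysis_steps=30_000, n_replicates=10,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def paper2020_preset(**overrides) -> SimulationConfig:
    """Full-scale system: 38.7 nm box, 1330 chains, 1e6 production steps.

    Provided for completeness; not the default (hours of CPU per replicate).
    """
    base = dict(
        box_length=38.7, n_chains=1330,
        n_relax_steps=10_000, n_production_steps=1_000_000,
        n_analysis_steps=100_000, n_replicates=10,
    )
    base.update(overrides)
    return SimulationConfig(**base)


PRESETS = {
    "desk": desk_preset,
    "sweep": sweep_preset,
    "paper2020": paper2020_preset,
}


def matched_np_counts(diameters: Sequence[float],
                      total_surface_area: float) -> list[int]:
    """Number of NPs per diameter at fixed total surface area.

    n = round(A / (pi d^2)), the dosing rule that equalizes available
    surface across sizes.
    """
    return [round(total_surface_area / (math.pi * d * d)) for d in diameters]
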