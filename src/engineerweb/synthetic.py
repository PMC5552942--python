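"""Synthetic study generator.

Emulates the statistical structure of a two-bay, three-habitat benthic
survey around an engineer species: organic-matter sources at the base,
prey guilds mixing those sources, predators mixing the prey guilds, one
trophic-enrichment step (TEF) per level, log-normal biomass, and
habitat-specific juvenile fish length distributions.  Every random draw
comes from a single seeded generator, so a study is reproducible
bit-for-bit, and all "true" quantities (diet proportions, modal lengths,
richness, biomass) are recorded in :class:`GroundTruth` for recovery
tests.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (CoefficientTable, CommunityMatrix, IsotopeTable,
                        RunConfig, ValidationError, check_habitat)

# Default marine source geometry (d13C, d15N, permil): particulate organic
# matter, sedimentary organic matter, microphytobenthos.  Spans ~6 permil in
# d13C and ~4 permil in d15N so the three-source mixing polygon is
# well-conditioned (collinear sources would make diet proportions
# unidentifiable).
DEFAULT_SOURCE_MEANS = ((-23.0, 4.0), (-20.0, 7.5), (-17.0, 3.5))
DEFAULT_SOURCE_SDS = ((0.5, 0.5), (0.5, 0.5), (0.5, 0.5))

# Source-mixture weights of the three prey guilds (rows sum to 1).
DEFAULT_GUILD_MIXTURES = ((0.7, 0.2, 0.1),
                          (0.2, 0.6, 0.2),
                          (0.1, 0.3, 0.6))

# Energetic profile per guild: (target E*pi*R in kJ/g/yr, accessibility A).
# Guild 1 is low-energy but accessible, guild 2 intermediate, guild 3
# high-energy and least accessible -- the pattern seen in engineered muds
# where the tube-building engineer itself is energy-rich but hard to reach.
DEFAULT_GUILD_ENERGY = ((1.5, 0.80), (4.0, 0.45), (8.0, 0.30))


@dataclass
class HabitatProfile:
    """Per-habitat generator settings."""

    n_prey: int
    n_predators: int
    n_hauls: int = 3
    biomass_factor: float = 1.0       # multiplies the log-normal median
    d15n_chain: float = 0.0           # permil added to predator d15N
    # centre of the juvenile length mode; at 2-cm binning this is the
    # midpoint of the intended modal bin (7 -> bin [6, 8), 9 -> [8, 10)),
    # keeping the planted mode off the bin edges
    modal_length_cm: float = 9.0


def _default_habitats() -> dict:
    return {
        "Haploops": HabitatProfile(n_prey=40, n_predators=18, n_hauls=6,
                                   biomass_factor=8.0, modal_length_cm=7.0),
        "Sternaspis": HabitatProfile(n_prey=26, n_predators=11, n_hauls=3,
                                     biomass_factor=1.5, modal_length_cm=9.0),
        "Amphiura_Owenia": HabitatProfile(n_prey=32, n_predators=14,
                                          n_hauls=3, biomass_factor=1.0,
                                          modal_length_cm=9.0),
    }


def _default_surfaces() -> dict:
    # km^2; engineered habitat largest, mirroring the field setting.
    return {
        ("BayA", "Amphiura_Owenia"): 68.7,
        ("BayA", "Sternaspis"): 2.9,
        ("BayA", "Haploops"): 81.1,
        ("BayB", "Amphiura_Owenia"): 23.8,
        ("BayB", "Sternaspis"): 96.3,
        ("BayB", "Haploops"): 173.0,
    }


@dataclass
class FoodWebSpec:
    """Parameters of the synthetic food web.

    ``tef`` is the per-trophic-step enrichment (d13C, d15N) applied from
    sources to prey and again from prey to predators; the default is the
    1.5 / 3.4 permil preset also used for fitting, so generator and mixing
    model share one forward model.  ``species_scatter_sd`` spreads species
    means around their guild mean; ``replicate_sd`` is analytical +
    individual noise per replicate.  ``true_diet`` is the diet composition
    (over the three prey guilds) given to every predator unless
    ``diet_dirichlet`` is set, in which case diets are drawn per predator.
    """

    bays: Sequence[str] = ("BayA", "BayB")
    habitats: dict = field(default_factory=_default_habitats)
    surfaces: dict = field(default_factory=_default_surfaces)
    source_means: Sequence = DEFAULT_SOURCE_MEANS
    source_sds: Sequence = DEFAULT_SOURCE_SDS
    guild_mixtures: Sequence = DEFAULT_GUILD_MIXTURES
    guild_energy: Sequence = DEFAULT_GUILD_ENERGY
    tef: tuple = (1.5, 3.4)
    species_scatter_sd: float = 0.5
    replicate_sd: float = 0.3
    n_replicates: int = 3
    true_diet: tuple = (0.2, 0.5, 0.3)
    diet_dirichlet: Optional[float] = None
    biomass_log_mu: float = 3.0       # log kg/km2, per-species median ~20
    biomass_log_sigma: float = 1.0
    haul_noise_sd: float = 0.3        # log-normal per-haul scatter
    presence_prob: float = 0.85       # per-haul occupancy of a species
    lengths_per_species: int = 12
    length_log_sd: float = 0.22
    juvenile_max_length: float = 20.0

    def __post_init__(self) -> None:
        for w in self.guild_mixtures:
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValidationError("guild mixture weights must sum to 1")
        for sd in np.ravel(self.source_sds):
            if sd < 0:
                raise ValidationError("source sds must be >= 0")
        for hab, prof in self.habitats.items():
            check_habitat(hab)
            if prof.n_prey < 3 or prof.n_predators < 3:
                raise ValidationError(
                    f"{hab}: need >= 3 prey and >= 3 predator species "
                    "(hull-based indices are undefined below that)")

    @property
    def n_sources(self) -> int:
        return len(self.source_means)


@dataclass
class GroundTruth:
    """Known truth of a generated study, for recovery tests.

    ``diet`` has one row per (bay, habitat, predator, guild) with the true
    proportion; ``modal_length``, ``richness`` and ``biomass_total`` are
    keyed by (bay, habitat).
    """

    diet: pd.DataFrame
    modal_length: dict
    richness: dict
    biomass_total: dict


@dataclass
class Study:
    """A complete synthetic (or loaded) study bundle."""

    community: CommunityMatrix
    isotopes: IsotopeTable
    coefficients: CoefficientTable
    lengths: pd.DataFrame
    registry: pd.DataFrame          # species metadata (role, mobility, ...)
    groundtruth: Optional[GroundTruth] = None
    spec: Optional[FoodWebSpec] = None


def _guild_mean(spec: FoodWebSpec, g: int) -> np.ndarray:
    """Noise-free signature of prey guild g: mixture of sources + one TEF."""
    mu = np.asarray(spec.source_means, dtype=float)
    w = np.asarray(spec.guild_mixtures[g], dtype=float)
    return w @ mu + np.asarray(spec.tef, dtype=float)


def generate_study(spec: FoodWebSpec, config: RunConfig) -> Study:
    """Generate one full study: community, isotopes, coefficients, lengths.

    Layout: 2 bays x 3 habitats, >= 3 hauls each.  Prey signatures are
    source mixtures plus one TEF step; predator signatures are prey-guild
    mixtures plus a second TEF step; both get Gaussian species- and
    replicate-level noise.  Biomasses are log-normal; juvenile fish lengths
    are log-normal truncated at the species' juvenile maximum length.
    """
    rng = config.stage_rng("synthetic")
    n_guilds = len(spec.guild_mixtures)
    tef = np.asarray(spec.tef, dtype=float)

    registry_rows = []
    community_rows = []
    isotope_rows = []
    coeff_rows = []
    length_rows = []
    diet_rows = []
    modal_length, richness, biomass_total = {}, {}, {}

    for bay in spec.bays:
        for hab, prof in spec.habitats.items():
            prey_codes = [f"{bay[-1]}{hab[:2].upper()}_P{i:02d}"
                          for i in range(prof.n_prey)]
            pred_codes = [f"{bay[-1]}{hab[:2].upper()}_F{i:02d}"
                          for i in range(prof.n_predators)]
            hauls = [f"{bay}_{hab}_h{j+1}" for j in range(prof.n_hauls)]

            # --- prey: guild membership, biomass, coefficients, isotopes
            guilds = np.arange(prof.n_prey) % n_guilds
            mean_b = np.exp(rng.normal(spec.biomass_log_mu,
                                       spec.biomass_log_sigma,
                                       prof.n_prey)) * prof.biomass_factor
            # individual wet mass (g) links biomass to density
            prey_mass = np.exp(rng.normal(0.0, 1.0, prof.n_prey))
            for i, code in enumerate(prey_codes):
                g = guilds[i]
                e_target, a_centre = spec.guild_energy[g]
                E = rng.uniform(3.0, 6.0)
                pi = rng.uniform(1.0, 2.5)
                epr = e_target * np.exp(rng.normal(0.0, 0.15))
                R = min(epr / (E * pi), 1.0)
                A = float(np.clip(a_centre + rng.normal(0.0, 0.04),
                                  0.01, 1.0))
                coeff_rows.append(dict(species=code, E_kJ_g=E, pi_per_yr=pi,
                                       R=R, A=A, mobility="",
                                       juv_max_len_cm=np.nan))
                registry_rows.append(dict(species=code, role="prey",
                                          guild=g, mobility=None,
                                          is_fish=False,
                                          juv_max_len_cm=np.nan,
                                          bay=bay, habitat=hab))
                sp_mean = (_guild_mean(spec, g)
                           + rng.normal(0.0, spec.species_scatter_sd, 2))
                for _ in range(spec.n_replicates):
                    rep = sp_mean + rng.normal(0.0, spec.replicate_sd, 2)
                    isotope_rows.append(dict(
                        bay=bay, habitat=hab, species=code, role="prey",
                        d13C=rep[0], d15N=rep[1],
                        biomass_kg_km2=mean_b[i]))
                for haul in hauls:
                    present = rng.random() < spec.presence_prob
                    b = (mean_b[i]
                         * np.exp(rng.normal(0.0, spec.haul_noise_sd))
                         if present else 0.0)
                    dens = b * 1000.0 / prey_mass[i]
                    community_rows.append(dict(
                        bay=bay, habitat=hab, haul=haul, species=code,
                        biomass_kg_km2=b, density_n_km2=dens))

            # --- predators: diets, isotopes, lengths, densities
            guild_means = np.array([_guild_mean(spec, g)
                                    for g in range(n_guilds)])
            pred_b = np.exp(rng.normal(spec.biomass_log_mu - 1.0,
                                       spec.biomass_log_sigma,
                                       prof.n_predators))
            pred_mass = np.exp(rng.normal(2.0, 0.8, prof.n_predators))
            for i, code in enumerate(pred_codes):
                # last two predators are mega-invertebrates (mobility M1)
                is_fish = i < prof.n_predators - 2
                mobility = ("M" + str(2 + i % 3)) if is_fish else "M1"
                if spec.diet_dirichlet is not None:
                    p = rng.dirichlet(np.full(n_guilds,
                                              spec.diet_dirichlet))
                else:
                    p = np.asarray(spec.true_diet, dtype=float)
                for g in range(n_guilds):
                    diet_rows.append(dict(bay=bay, habitat=hab,
                                          species=code, guild=g,
                                          true_p=p[g]))
                sp_mean = (p @ guild_means + tef
                           + np.array([0.0, prof.d15n_chain])
                           + rng.normal(0.0, spec.species_scatter_sd, 2))
                for _ in range(spec.n_replicates):
                    rep = sp_mean + rng.normal(0.0, spec.replicate_sd, 2)
                    isotope_rows.append(dict(
                        bay=bay, habitat=hab, species=code, role="predator",
                        d13C=rep[0], d15N=rep[1],
                        biomass_kg_km2=pred_b[i]))
                registry_rows.append(dict(
                    species=code, role="predator", guild=-1,
                    mobility=mobility, is_fish=is_fish,
                    juv_max_len_cm=(spec.juvenile_max_length if is_fish
                                    else np.nan),
                    bay=bay, habitat=hab))
                coeff_rows.append(dict(
                    species=code, E_kJ_g=np.nan, pi_per_yr=np.nan,
                    R=np.nan, A=np.nan, mobility=mobility,
                    juv_max_len_cm=(spec.juvenile_max_length if is_fish
                                    else np.nan)))
                for haul in hauls:
                    present = rng.random() < spec.presence_prob
                    b = (pred_b[i]
                         * np.exp(rng.normal(0.0, spec.haul_noise_sd))
                         if present else 0.0)
                    dens = b * 1000.0 / pred_mass[i]
                    community_rows.append(dict(
                        bay=bay, habitat=hab, haul=haul, species=code,
                        biomass_kg_km2=b, density_n_km2=dens))
                if is_fish:
                    # species-specific length medians around the habitat
                    # mode; the first species dominates the modal bin.
                    if i == 0:
                        median, n_len = prof.modal_length_cm, \
                            spec.lengths_per_species * 5
                    else:
                        median = prof.modal_length_cm * np.exp(
                            rng.normal(0.0, 0.10))
                        n_len = spec.lengths_per_species
                    for _ in range(n_len):
                        L = median * np.exp(
                            rng.normal(0.0, spec.length_log_sd))
                        L = min(L, spec.juvenile_max_length - 1e-6)
                        K = rng.normal(1.0, 0.05)
                        W = max(K, 0.5) * L ** 3 / 100.0
                        length_rows.append(dict(
                            bay=bay, habitat=hab,
                            haul=hauls[int(rng.integers(len(hauls)))],
                            species=code, length_cm=L, weight_g=W))
            modal_length[(bay, hab)] = prof.modal_length_cm

        # --- organic-matter sources: per bay, no biomass weight
        for k, (mu, sd) in enumerate(zip(spec.source_means,
                                         spec.source_sds)):
            code = f"SRC{k+1}"
            for hab in spec.habitats:
                for _ in range(spec.n_replicates):
                    rep = (np.asarray(mu, dtype=float)
                           + rng.normal(0.0, np.asarray(sd, dtype=float)))
                    isotope_rows.append(dict(
                        bay=bay, habitat=hab, species=code, role="source",
                        d13C=rep[0], d15N=rep[1], biomass_kg_km2=np.nan))

    community_df = pd.DataFrame(community_rows)
    idx = ["bay", "habitat", "haul"]
    biomass = (community_df.pivot_table(index=idx, columns="species",
                                        values="biomass_kg_km2",
                                        fill_value=0.0)
               .sort_index().sort_index(axis=1))
    density = (community_df.pivot_table(index=idx, columns="species",
                                        values="density_n_km2",
                                        fill_value=0.0)
               .sort_index().sort_index(axis=1))
    biomass.columns.name = None
    density.columns.name = None
    community = CommunityMatrix(biomass=biomass, density=density,
                                surface=dict(spec.surfaces))

    for bay, hab in community.groups():
        sub = community.hauls(bay, hab)
        richness[(bay, hab)] = int((sub.sum(axis=0) > 0).sum())
        biomass_total[(bay, hab)] = float(sub.mean(axis=0).sum())

    truth = GroundTruth(diet=pd.DataFrame(diet_rows),
                        modal_length=modal_length,
                        richness=richness, biomass_total=biomass_total)
    return Study(
        community=community,
        isotopes=IsotopeTable(pd.DataFrame(isotope_rows)),
        coefficients=CoefficientTable(pd.DataFrame(coeff_rows)),
        lengths=pd.DataFrame(length_rows),
        registry=pd.DataFrame(registry_rows),
        groundtruth=truth,
        spec=spec,
    )


@dataclass
class HabitatEffect:
    """A named perturbation applied to one habitat of an existing study."""

    d15n_chain: float = 0.0      # permil added to predator d15N
    biomass_factor: float = 1.0  # multiplies biomass (community + weights)
    modal_shift_cm: float = 0.0  # added to every fish length


def perturb_habitat(study: Study, habitat: str,
                    effect: HabitatEffect) -> Study:
    """Return a copy of ``study`` with only ``habitat``'s records changed.

    The d15N-chain effect moves predator replicates up the nitrogen axis,
    the biomass factor scales both community layers and the isotope-table
    weights, and the modal shift translates fish lengths (floored just
    above zero).  GroundTruth is updated to match.
    """
    check_habitat(habitat)
    if habitat not in {h for _, h in study.community.groups()}:
        raise ValidationError(f"habitat {habitat!r} not present in study")
    out = copy.deepcopy(study)

    mask = out.community.biomass.index.get_level_values("habitat") == habitat
    out.community.biomass.loc[mask] *= effect.biomass_factor
    out.community.density.loc[mask] *= effect.biomass_factor

    iso = out.isotopes.data
    hab_rows = iso["habitat"] == habitat
    pred = hab_rows & iso["role"].isin(["predator", "both"])
    iso.loc[pred, "d15N"] += effect.d15n_chain
    iso.loc[hab_rows, "biomass_kg_km2"] *= effect.biomass_factor

    ln = out.lengths
    lmask = ln["habitat"] == habitat
    ln.loc[lmask, "length_cm"] = np.maximum(
        ln.loc[lmask, "length_cm"] + effect.modal_shift_cm, 0.1)
    # weights follow isometrically so condition factor is preserved
    ln.loc[lmask, "weight_g"] = (
        ln.loc[lmask, "weight_g"]
        * (ln.loc[lmask, "length_cm"]
           / (ln.loc[lmask, "length_cm"] - effect.modal_shift_cm)) ** 3)

    if out.groundtruth is not None:
        gt = out.groundtruth
        for key in list(gt.modal_length):
            if key[1] == habitat:
                gt.modal_length[key] += effect.modal_shift_cm
                gt.biomass_total[key] *= effect.biomass_factor
    return out
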