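"""Available Benthic Energy Coefficient (ABEC) accounting.

ABEC_i = E_i * pi_i * R_i * A_i estimates the energetic value of prey
species *i* for benthic predators: mass energy (kJ/g wet mass) times
productivity (/yr), discounted by regeneration and accessibility
coefficients.  Scaling by mean biomass gives an areal energy supply
(kJ km^-2 yr^-1) and scaling again by habitat surface gives the habitat
total (kJ/yr).  Biomass arrives in kg/km^2, so a factor of 10^3 g/kg
bridges to E in kJ/g.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CoefficientTable, CommunityMatrix, ValidationError

log = logging.getLogger("engineerweb")

G_PER_KG = 1_000.0


@dataclass
class AbecResult:
    """Habitat-scale energy summary.

    ``per_habitat`` has one row per (bay, habitat) with columns
    ``surface_km2``, ``mean_biomass_kg_km2`` (summed over prey species),
    ``abec_x_b`` (kJ km^-2 yr^-1) and ``abec_x_b_x_s`` (kJ/yr).
    """

    per_species: pd.Series          # ABEC_i, kJ g^-1 yr^-1
    per_habitat: pd.DataFrame


def abec_species(coeffs: CoefficientTable,
                 prey_species=None) -> pd.Series:
    """Per-species ABEC_i = E_i * pi_i * R_i * A_i (kJ g^-1 yr^-1).

    Restricted to ``prey_species`` when given (the coefficient is defined
    for prey taxa only).  Species with any missing coefficient are skipped
    with a logged warning.
    """
    df = coeffs.indexed()
    if prey_species is not None:
        keep = [s for s in prey_species if s in df.index]
        absent = sorted(set(prey_species) - set(keep))
        if absent:
            log.warning("no coefficients for prey species %s; skipped",
                        absent)
        df = df.loc[keep]
    cols = ["E_kJ_g", "pi_per_yr", "R", "A"]
    incomplete = df[cols].isna().any(axis=1)
    if incomplete.any():
        log.warning("incomplete coefficients for %s; skipped",
                    sorted(df.index[incomplete]))
        df = df[~incomplete]
    abec = df["E_kJ_g"] * df["pi_per_yr"] * df["R"] * df["A"]
    abec.name = "abec_kJ_g_yr"
    return abec


def abec_habitat(community: CommunityMatrix, abec: pd.Series,
                 surface=None) -> AbecResult:
    """Scale species ABECs by mean biomass and habitat surface.

    For each (bay, habitat): ABECxB = sum_i ABEC_i * Bbar_i * 10^3 with
    Bbar_i the arithmetic mean biomass (kg/km^2) over the habitat's hauls
    (hauls are equally weighted: swept areas are near-equal), and
    ABECxBxS = ABECxB * S.  Species without an ABEC contribute nothing.
    """
    surface = dict(community.surface if surface is None else surface)
    rows = []
    species = [s for s in community.species if s in abec.index]
    a = abec.loc[species].to_numpy()
    for bay, hab in community.groups():
        sub = community.hauls(bay, hab)[species]
        b_bar = sub.mean(axis=0).to_numpy()
        if b_bar.sum() == 0:
            log.warning("(%s, %s): zero prey biomass; ABECxB = 0", bay, hab)
        abec_x_b = float((a * b_bar).sum() * G_PER_KG)
        s = surface.get((bay, hab), np.nan)
        rows.append(dict(bay=bay, habitat=hab,
                         surface_km2=s,
                         mean_biomass_kg_km2=float(b_bar.sum()),
                         abec_x_b=abec_x_b,
                         abec_x_b_x_s=abec_x_b * s))
    return AbecResult(per_species=abec,
                      per_habitat=pd.DataFrame(rows))


def cumulative_richness_subsample(community: CommunityMatrix, bay: str,
                                  habitat: str, k: int = 3,
                                  n_draws: int = 10_000,
                                  seed: int | None = None,
                                  rng: np.random.Generator | None = None
                                  ) -> tuple[float, float]:
    """Mean and sd of cumulative species richness over k-haul subsets.

    SR_cum of a draw is the number of species with biomass > 0 in the
    union of ``k`` hauls drawn without replacement.  With exactly ``k``
    hauls available the single possible subset is returned exactly
    (sd 0); otherwise the mean and sd over ``n_draws`` random subsets.
    """
    sub = community.hauls(bay, habitat)
    n = len(sub)
    if k > n:
        raise ValidationError(
            f"k={k} exceeds the {n} hauls of ({bay}, {habitat})")
    present = sub.to_numpy() > 0
    if k == n:
        return float(present.any(axis=0).sum()), 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = np.empty(n_draws)
    for j in range(n_draws):
        idx = rng.choice(n, size=k, replace=False)
        vals[j] = present[idx].any(axis=0).sum()
    return float(vals.mean()), float(vals.std(ddof=0))
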