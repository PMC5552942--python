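"""Core domain types shared by every analysis stage.

The study design is two bays, each containing three soft-bottom habitats:
one engineered by a tubiculous amphipod (``Haploops``) and two uncolonised
habitats (``Sternaspis`` muddy sand and ``Amphiura_Owenia`` sandy mud).
Each habitat is sampled by at least three beam-trawl hauls; biomass and
density are standardised per square kilometre of swept area.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical habitat labels accepted throughout the package.
HABITATS = ("Haploops", "Sternaspis", "Amphiura_Owenia")

#: Predator mobility classes: distance moved over the 3-4 week isotopic
#: integration window.  M1 <= 0.1 km, M2 0.1-1 km, M3 1-10 km, M4 > 10 km.
MOBILITY_CLASSES = ("M1", "M2", "M3", "M4")

ROLES = ("source", "prey", "predator", "both")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SpeciesRecord:
    """One taxon of the study registry.

    ``role`` may be ``both`` only for taxa that are prey in one habitat and
    predator in another.  Mega-invertebrate predators are always assigned the
    lowest mobility class (M1).  ``juvenile_max_length`` (cm) is the length a
    fish reaches at two years; absent for invertebrates.
    """

    code: str
    name: str = ""
    role: str = "prey"
    mobility: Optional[str] = None
    juvenile_max_length: Optional[float] = None
    is_fish: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"species {self.code!r}: role {self.role!r} not in {ROLES}")
        if self.mobility is not None and self.mobility not in MOBILITY_CLASSES:
            raise ValidationError(
                f"species {self.code!r}: mobility {self.mobility!r} "
                f"not in {MOBILITY_CLASSES}")


@dataclass
class CommunityMatrix:
    """Haul x species community data with aligned biomass and density layers.

    Both layers are DataFrames indexed by a ``(bay, habitat, haul)``
    MultiIndex with species codes as columns.  Cells are kg/km^2 (biomass)
    and individuals/km^2 (density); absence is an explicit zero, not a
    missing value.  ``surface`` maps ``(bay, habitat)`` to habitat area in
    km^2.
    """

    biomass: pd.DataFrame
    density: pd.DataFrame
    surface: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.biomass.index.equals(self.density.index):
            raise ValidationError("biomass and density hauls differ")
        if list(self.biomass.columns) != list(self.density.columns):
            raise ValidationError("biomass and density species differ")
        for layer_name, layer in (("biomass", self.biomass),
                                  ("density", self.density)):
            if (layer.to_numpy() < 0).any():
                bad = layer[(layer < 0).any(axis=1)].index[0]
                raise ValidationError(
                    f"negative {layer_name} in haul {bad}")
        for bay, habitat in self.biomass.index.droplevel("haul").unique():
            n = len(self.biomass.xs((bay, habitat),
                                    level=("bay", "habitat")))
            if n < 3:
                raise ValidationError(
                    f"({bay}, {habitat}) has {n} hauls; >= 3 required")
        for key, s in self.surface.items():
            if not s > 0:
                raise ValidationError(f"surface for {key} must be > 0")

    @property
    def species(self) -> list[str]:
        return list(self.biomass.columns)

    def hauls(self, bay: str, habitat: str) -> pd.DataFrame:
        """Biomass rows of one (bay, habitat) cell."""
        return self.biomass.xs((bay, habitat), level=("bay", "habitat"))

    def groups(self) -> list[tuple[str, str]]:
        return list(self.biomass.index.droplevel("haul").unique())


@dataclass
class IsotopeTable:
    """Per-replicate stable-isotope signatures.

    One row per analysed replicate: ``bay, habitat, species, role,
    d13C, d15N, biomass_kg_km2``.  Organic-matter sources carry no biomass
    weight (NaN).  delta values are in permil relative to the usual
    standards (VPDB for carbon, atmospheric N2 for nitrogen).
    """

    data: pd.DataFrame

    REQUIRED = ("bay", "habitat", "species", "role", "d13C", "d15N",
                "biomass_kg_km2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"isotope table missing columns {missing}")
        bad_role = set(self.data["role"]) - set(ROLES)
        if bad_role:
            raise ValidationError(f"unknown roles {sorted(bad_role)}")
        w = self.data["biomass_kg_km2"]
        if (w.dropna() < 0).any():
            raise ValidationError("negative biomass weight in isotope table")
        src = self.data["role"] == "source"
        if w[src].notna().any():
            raise ValidationError("sources must not carry biomass weights")

    def species_means(self, scope: str = "all") -> pd.DataFrame:
        """Species-level mean signatures per (bay, habitat).

        ``scope``: ``all`` keeps every role, ``prey`` keeps prey (and
        dual-role taxa), ``consumers`` drops sources.  Replicates are
        averaged unweighted.
        """
        df = self.data
        if scope == "prey":
            df = df[df["role"].isin(["prey", "both"])]
        elif scope == "consumers":
            df = df[df["role"] != "source"]
        elif scope != "all":
            raise ValueError(f"unknown scope {scope!r}")
        g = df.groupby(["bay", "habitat", "species"], sort=True)
        out = g.agg(d13C=("d13C", "mean"), d15N=("d15N", "mean"),
                    biomass_kg_km2=("biomass_kg_km2", "mean"),
                    role=("role", "first"))
        return out.reset_index()


@dataclass
class CoefficientTable:
    """Per-species energetic coefficients used by the ABEC calculation.

    ``E`` mass energy (kJ/g wet mass), ``pi`` productivity (/yr), ``R``
    regeneration and ``A`` accessibility coefficients (unitless in [0, 1]).
    ``mobility`` and ``juv_max_len_cm`` ride along for predator taxa.
    """

    data: pd.DataFrame

    REQUIRED = ("species", "E_kJ_g", "pi_per_yr", "R", "A")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(
                f"coefficient table missing columns {missing}")
        if self.data["species"].duplicated().any():
            dup = self.data["species"][self.data["species"].duplicated()]
            raise ValidationError(f"duplicate species {sorted(set(dup))}")
        num = self.data[["E_kJ_g", "pi_per_yr", "R", "A"]]
        if (num.to_numpy() < 0).any():
            raise ValidationError("coefficients must be >= 0")
        for col in ("R", "A"):
            bad = self.data[self.data[col] > 1]
            if len(bad):
                raise ValidationError(
                    f"{col} > 1 for species {list(bad['species'])}")

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("species")


@dataclass
class RunConfig:
    """Reproducibility and inference settings for a full run.

    Every randomised stage derives its own generator from ``seed`` via
    :meth:`stage_seed`, so a report can be regenerated bit-identically.
    """

    seed: int = 0
    n_permutations: int = 10_000
    alpha: float = 0.05
    tef_preset: str = "TEF3"
    size_bin_width: float = 2.0
    subsample_k: int = 3
    subsample_n: int = 10_000
    mcmc_iter: int = 40_000
    mcmc_burn: int = 20_000
    mcmc_thin: int = 10
    mcmc_chains: int = 4

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.size_bin_width <= 0:
            raise ValidationError("size_bin_width must be > 0")

    def stage_seed(self, stage: str) -> int:
        """Deterministic 31-bit seed for a named stage."""
        h = zlib.crc32(stage.encode("utf8"))
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, h])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.stage_seed(stage))


def check_habitat(label: str) -> str:
    """Validate a habitat label against the canonical set."""
    if label not in HABITATS:
        raise ValidationError(
            f"unknown habitat {label!r}; allowed: {list(HABITATS)}")
    return label
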