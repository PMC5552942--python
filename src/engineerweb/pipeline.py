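"""End-to-end study pipeline.

Stage order: prey energy accounting -> predator community structure ->
isotope clustering and functional indices (with pairwise permutation
tests) -> energy-group diet mixing -> juvenile size spectra.  Bays are
processed independently and never pooled: the two bays are separate
studies with their own species pools and cannot be compared directly.
Every randomised stage draws from a seed derived from the run seed, so
the report regenerates bit-identically from config + data.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import community as cs
from . import energy, ifi, io, mixing, sizespectra
from .datatypes import RunConfig, ValidationError
from .synthetic import FoodWebSpec, Study, generate_study

log = logging.getLogger("engineerweb")


@dataclass
class StudyReport:
    """Structured results of a full run, one block per stage."""

    energy: pd.DataFrame = None
    richness: pd.DataFrame = None
    diversity: pd.DataFrame = None
    permanova: pd.DataFrame = None
    ca_inertia: pd.DataFrame = None
    hac_groups: pd.DataFrame = None
    ifi_values: pd.DataFrame = None
    ifi_tests: pd.DataFrame = None
    mixing: pd.DataFrame = None
    spectra: pd.DataFrame = None
    modal_species: pd.DataFrame = None
    fulton: pd.DataFrame = None
    config: Optional[RunConfig] = None
    notices: list = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            if f.name in ("config", "notices"):
                continue
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        out["notices"] = pd.DataFrame({"notice": self.notices})
        return out


def _point_set(iso_means: pd.DataFrame, scope: str, label: str
               ) -> ifi.IsotopePointSet:
    pts = iso_means[["d13C", "d15N"]].to_numpy()
    if scope == "prey":
        w = iso_means["biomass_kg_km2"].to_numpy()
        weights = w / w.sum() if w.sum() > 0 else None
    else:
        weights = None
    return ifi.IsotopePointSet(points=pts, weights=weights,
                               species=list(iso_means["species"]),
                               scope=scope, label=label)


def run_pipeline(config: RunConfig, study: Optional[Study] = None,
                 data_dir: Optional[str] = None,
                 synthetic_spec: Optional[FoodWebSpec] = None,
                 out_dir: Optional[str] = None) -> StudyReport:
    """Run every stage on a study and assemble the report.

    Provide exactly one of ``study`` (an in-memory bundle), ``data_dir``
    (CSV files as written by :mod:`engineerweb.io`) or ``synthetic_spec``.
    When ``out_dir`` is given, the report and all stage tables are written
    there along with the config echo.
    """
    if sum(x is not None for x in (study, data_dir, synthetic_spec)) != 1:
        raise ValidationError(
            "provide exactly one of study, data_dir, synthetic_spec")
    if synthetic_spec is not None:
        study = generate_study(synthetic_spec, config)
    elif data_dir is not None:
        study = _load_study(data_dir)

    report = StudyReport(config=config)
    report.energy, report.richness = _stage_energy(study, config)
    (report.diversity, report.permanova,
     report.ca_inertia) = _stage_community(study, config, report.notices)
    (report.hac_groups, report.ifi_values,
     report.ifi_tests) = _stage_ifi(study, config, report.notices)
    report.mixing = _stage_mixing(study, config, report.notices)
    (report.spectra, report.modal_species,
     report.fulton) = _stage_spectra(study, config, report.notices)

    if out_dir is not None:
        io.write_report(report.as_dict(), out_dir, config=config)
    return report


def _load_study(data_dir: str) -> Study:
    import os

    def p(name):
        return os.path.join(data_dir, name)

    community = io.read_community(p("community.csv"),
                                  surfaces=p("surfaces.csv"))
    isotopes = io.read_isotopes(p("isotopes.csv"))
    coefficients = io.read_coefficients(p("coefficients.csv"))
    lengths = io.read_lengths(p("lengths.csv"))
    registry_path = p("registry.csv")
    registry = pd.read_csv(registry_path) if os.path.exists(registry_path) \
        else _registry_from_tables(isotopes, coefficients)
    return Study(community=community, isotopes=isotopes,
                 coefficients=coefficients, lengths=lengths,
                 registry=registry)


def _registry_from_tables(isotopes, coefficients) -> pd.DataFrame:
    roles = (isotopes.data.groupby("species")["role"]
             .agg(lambda s: s.iloc[0]))
    cdf = coefficients.indexed()
    rows = []
    for sp, role in roles.items():
        mob = cdf["mobility"].get(sp, None) if "mobility" in cdf else None
        jl = cdf["juv_max_len_cm"].get(sp, np.nan) \
            if "juv_max_len_cm" in cdf else np.nan
        rows.append(dict(species=sp, role=role,
                         mobility=mob if mob else None,
                         is_fish=bool(pd.notna(jl)),
                         juv_max_len_cm=jl))
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ stages

def _prey_species(study: Study) -> list[str]:
    reg = study.registry
    return sorted(set(reg.loc[reg["role"].isin(["prey", "both"]),
                              "species"]))


def _predator_species(study: Study) -> list[str]:
    reg = study.registry
    return sorted(set(reg.loc[reg["role"].isin(["predator", "both"]),
                              "species"]))


def _stage_energy(study: Study, config: RunConfig):
    prey = _prey_species(study)
    abec = energy.abec_species(study.coefficients, prey_species=prey)
    result = energy.abec_habitat(study.community, abec)
    rng = config.stage_rng("richness")
    rows = []
    for bay, hab in study.community.groups():
        prey_cols = [s for s in study.community.species if s in prey]
        sub_comm = study.community
        # richness restricted to prey taxa
        from .datatypes import CommunityMatrix
        prey_comm = CommunityMatrix(
            biomass=sub_comm.biomass[prey_cols],
            density=sub_comm.density[prey_cols],
            surface=sub_comm.surface)
        mean, sd = energy.cumulative_richness_subsample(
            prey_comm, bay, hab, k=config.subsample_k,
            n_draws=config.subsample_n, rng=rng)
        rows.append(dict(bay=bay, habitat=hab, sr_cum_mean=mean,
                         sr_cum_sd=sd, k=config.subsample_k))
    return result.per_habitat, pd.DataFrame(rows)


def _stage_community(study: Study, config: RunConfig, notices: list):
    rng = config.stage_rng("community")
    predators = [s for s in study.community.species
                 if s in set(_predator_species(study))]
    reg = study.registry.drop_duplicates("species").set_index("species")
    fish = [s for s in predators if bool(reg.loc[s, "is_fish"])]
    invert = [s for s in predators if not bool(reg.loc[s, "is_fish"])]

    div_rows, perm_rows, ca_rows = [], [], []
    for bay in study.community.biomass.index.get_level_values("bay").unique():
        dens = study.community.density.xs(bay, level="bay")[predators]
        habitats = dens.index.get_level_values("habitat")
        div = cs.diversity_indices(dens)
        for (hab, haul), row in div.iterrows():
            div_rows.append(dict(bay=bay, habitat=hab, haul=haul,
                                 SR=row["SR"], simpson=row["simpson"],
                                 pielou=row["pielou"]))
        # indices matrix: standardized Euclidean; Pielou NaN -> column mean
        idx_mat = div[["SR", "simpson", "pielou"]].to_numpy(dtype=float)
        col_mean = np.nanmean(idx_mat, axis=0)
        idx_mat = np.where(np.isnan(idx_mat), col_mean, idx_mat)
        res_idx = cs.permanova(idx_mat, habitats, distance="euclidean",
                               standardize=True,
                               n_perm=config.n_permutations, rng=rng)
        perm_rows.append(dict(bay=bay, matrix="diversity_indices",
                              pseudo_F=res_idx.pseudo_F, p=res_idx.p,
                              dispersion_p=res_idx.dispersion_p))
        # density matrix: Bray-Curtis
        res_dens = cs.permanova(dens.to_numpy(), habitats,
                                distance="bray-curtis",
                                n_perm=config.n_permutations, rng=rng)
        perm_rows.append(dict(bay=bay, matrix="predator_density",
                              pseudo_F=res_dens.pseudo_F, p=res_dens.p,
                              dispersion_p=res_dens.dispersion_p))
        if res_dens.p < config.alpha:
            pw = cs.pairwise_permanova(dens.to_numpy(), habitats,
                                       distance="bray-curtis",
                                       n_perm=config.n_permutations,
                                       alpha=config.alpha, rng=rng)
            for _, r in pw.iterrows():
                perm_rows.append(dict(bay=bay,
                                      matrix=f"posthoc_{r['group_a']}"
                                             f"_vs_{r['group_b']}",
                                      pseudo_F=r["pseudo_F"], p=r["p"],
                                      dispersion_p=np.nan))
        # CA: fish densities active, invertebrate densities supplementary;
        # species absent from this bay are dropped up front
        active = dens[fish].loc[:, dens[fish].sum(axis=0) > 0]
        occupied = active.sum(axis=1) > 0
        if not occupied.all():
            notices.append(f"{bay}: {int((~occupied).sum())} hauls with no "
                           "fish dropped from CA")
        try:
            supp = dens[invert].loc[:, dens[invert].sum(axis=0) > 0] \
                if invert else None
            ca = cs.correspondence_analysis(
                active[occupied],
                supplementary=supp[occupied] if supp is not None else None)
            for i, pct in enumerate(ca.percent_inertia[:2]):
                ca_rows.append(dict(bay=bay, axis=i + 1,
                                    percent_inertia=pct))
        except ValidationError as exc:
            notices.append(f"{bay}: CA skipped ({exc})")
    return (pd.DataFrame(div_rows), pd.DataFrame(perm_rows),
            pd.DataFrame(ca_rows))


def _stage_ifi(study: Study, config: RunConfig, notices: list):
    rng = config.stage_rng("ifi")
    means_all = study.isotopes.species_means(scope="all")
    means_prey = study.isotopes.species_means(scope="prey")
    hac_rows, ifi_rows, test_rows = [], [], []
    bays = sorted(means_all["bay"].unique())
    for bay in bays:
        prey_bay = means_prey[means_prey["bay"] == bay]
        prey_n = dict(prey_bay.groupby("habitat")["species"].size())
        prey_ok = all(n >= ifi.ACCURACY_THRESHOLD for n in prey_n.values())
        if not prey_ok:
            notices.append(
                f"{bay}: prey-level IFIs skipped (a habitat has fewer "
                f"than {ifi.ACCURACY_THRESHOLD} prey species: {prey_n})")
        sets = {}
        all_bay = means_all[means_all["bay"] == bay]
        for hab in sorted(all_bay["habitat"].unique()):
            sub_all = all_bay[all_bay["habitat"] == hab]
            # invertebrate-taxa clustering in isotope space
            inv = prey_bay[prey_bay["habitat"] == hab]
            if len(inv) >= 3:
                grouping = ifi.hac_ward(inv[["d13C", "d15N"]].to_numpy())
                hac_rows.append(dict(bay=bay, habitat=hab,
                                     n_groups=grouping.k,
                                     n_species=len(inv)))
            # food web: SEA/NR over every signature incl. sources;
            # the weighted trio excludes the (biomass-free) sources
            fw = _point_set(sub_all, "foodweb", f"{bay}/{hab}/foodweb")
            cons = sub_all[sub_all["role"] != "source"]
            fw_w = _point_set(cons.assign(), "prey",
                              f"{bay}/{hab}/foodweb-weighted")
            fw_w.scope = "foodweb"
            res = ifi.compute_ifi(fw)
            res_w = ifi.compute_ifi(fw_w)
            ifi_rows.append(dict(bay=bay, habitat=hab, scope="foodweb",
                                 SEA=res.SEA, NR=res.NR, IDiv=res_w.IDiv,
                                 IDis=res_w.IDis, IEve=res_w.IEve,
                                 n=res.n, sources_in_weighted=False))
            sets[("foodweb", hab)] = fw
            sets[("foodweb_w", hab)] = fw_w
            if prey_ok:
                pr = _point_set(inv, "prey", f"{bay}/{hab}/prey")
                scaled = ifi.scale_pooled(
                    [inv[["d13C", "d15N"]].to_numpy()])[0]
                resp = ifi.compute_ifi(pr, scaled_points=scaled)
                ifi_rows.append(dict(bay=bay, habitat=hab, scope="prey",
                                     **{k: getattr(resp, k) for k in
                                        ("SEA", "NR", "IDiv", "IDis",
                                         "IEve", "n")},
                                     sources_in_weighted=False))
                sets[("prey", hab)] = pr
        # pairwise permutation tests; Bonferroni divisor = pairs x indices.
        # Food-web tests permute consumer rows only: the organic-matter
        # sources are fixed endpoints common to every habitat, so they are
        # not exchangeable under the null and would inflate the permuted
        # NR/SEA variance.  Reported per-habitat SEA/NR stay source-inclusive.
        plans = [("foodweb", ("SEA", "NR", "IDiv"), "foodweb_w"),
                 ("prey", ("SEA", "NR", "IDiv", "IDis", "IEve"), "prey")]
        habs_by_key = {}
        for scope, indices, key in plans:
            habs_by_key[key] = sorted(h for (s, h) in sets if s == key)
        for scope, indices, key in plans:
            habs = habs_by_key[key]
            pairs = [(a, b) for i, a in enumerate(habs)
                     for b in habs[i + 1:]]
            if not pairs:
                continue
            n_idx = 3 if scope == "foodweb" else 5
            n_tests = len(pairs) * n_idx
            for a, b in pairs:
                comps = ifi.compare_ifi_permutation(
                    sets[(key, a)], sets[(key, b)], indices=indices,
                    n_perm=config.n_permutations, rng=rng,
                    alpha=config.alpha, n_tests=max(n_tests, 1))
                for c in comps:
                    test_rows.append(dict(bay=bay, scope=scope,
                                          habitat_a=a, habitat_b=b,
                                          index=c.index,
                                          delta_obs=c.delta_obs,
                                          pseudo_p=c.pseudo_p,
                                          significant=c.significant))
    return (pd.DataFrame(hac_rows), pd.DataFrame(ifi_rows),
            pd.DataFrame(test_rows))


def _stage_mixing(study: Study, config: RunConfig, notices: list):
    rng = config.stage_rng("mixing")
    iso = study.isotopes.data
    reg = study.registry.drop_duplicates("species").set_index("species")
    rows = []
    for bay in sorted(iso["bay"].unique()):
        for hab in sorted(iso.loc[iso["bay"] == bay, "habitat"].unique()):
            try:
                sources = mixing.abec_source_groups(
                    study.coefficients, study.isotopes, bay=bay,
                    habitat=hab)
            except ValidationError as exc:
                notices.append(f"{bay}/{hab}: mixing skipped ({exc})")
                continue
            preds = iso.query(
                "bay == @bay and habitat == @hab and "
                "role in ('predator', 'both')")
            mobility = preds["species"].map(
                reg["mobility"].to_dict()).fillna("M1")
            for mob in sorted(mobility.unique()):
                x = preds.loc[mobility == mob,
                              ["d13C", "d15N"]].to_numpy()
                if len(x) == 0:
                    continue
                post = mixing.fit_mixing(
                    x, sources, tef=config.tef_preset,
                    n_iter=config.mcmc_iter, burn_in=config.mcmc_burn,
                    thin=config.mcmc_thin, n_chains=config.mcmc_chains,
                    rng=rng)
                for j, lab in enumerate(post.labels):
                    rows.append(dict(
                        bay=bay, habitat=hab, mobility=mob, source=lab,
                        n_consumers=len(x),
                        p10=post.percentiles.loc["p10", lab],
                        p25=post.percentiles.loc["p25", lab],
                        p50=post.percentiles.loc["p50", lab],
                        p75=post.percentiles.loc["p75", lab],
                        p90=post.percentiles.loc["p90", lab],
                        mean=post.means[j],
                        preferred=post.preferred == lab,
                        highest_accessible_biomass=(
                            sources.flags["highest_accessible_biomass"]
                            == lab),
                        highest_energy=(sources.flags["highest_energy"]
                                        == lab),
                        converged=post.converged,
                        small_sample=post.small_sample))
    return pd.DataFrame(rows)


def _stage_spectra(study: Study, config: RunConfig, notices: list):
    reg = study.registry.drop_duplicates("species").set_index("species")
    max_len = reg["juv_max_len_cm"].dropna()
    juveniles = sizespectra.juvenile_filter(study.lengths, max_len)
    spec_rows, modal_rows, fulton_rows = [], [], []
    for bay in sorted(juveniles["bay"].unique()):
        sub = juveniles[juveniles["bay"] == bay]
        inside = sub[sub["habitat"] == "Haploops"]
        outside = sub[sub["habitat"] != "Haploops"]
        if len(inside) == 0 or len(outside) == 0:
            notices.append(f"{bay}: size spectra skipped (missing side)")
            continue
        sp_in = sizespectra.build_spectrum(inside, config.size_bin_width,
                                           group="Haploops")
        sp_out = sizespectra.build_spectrum(outside, config.size_bin_width,
                                            group="outside")
        comp = sizespectra.compare_spectra(sp_in, sp_out,
                                           alpha=config.alpha)
        spec_rows.append(dict(bay=bay, group="community",
                              mode_inside=sp_in.modal_midpoint,
                              mode_outside=sp_out.modal_midpoint,
                              chi2=comp.chi2, p=comp.p,
                              p_modal=comp.p_modal,
                              mode_differs=comp.mode_differs,
                              n_inside=sp_in.n, n_outside=sp_out.n))
        for where, sp in (("Haploops", sp_in), ("outside", sp_out)):
            shares = sizespectra.modal_contributions(sp)
            for species, share in shares.head(3).items():
                modal_rows.append(dict(bay=bay, group="community",
                                       where=where, species=species,
                                       share=share))
        # mobility-group spectra where data suffice
        mob = sub["species"].map(reg["mobility"].to_dict())
        for m in sorted(mob.dropna().unique()):
            msub_in = inside[mob.reindex(inside.index) == m]
            msub_out = outside[mob.reindex(outside.index) == m]
            if (len(msub_in) < sizespectra.MIN_GROUP_RECORDS
                    or len(msub_out) < sizespectra.MIN_GROUP_RECORDS):
                continue
            si = sizespectra.build_spectrum(msub_in, config.size_bin_width,
                                            group=m)
            so = sizespectra.build_spectrum(msub_out,
                                            config.size_bin_width, group=m)
            c = sizespectra.compare_spectra(si, so, alpha=config.alpha)
            spec_rows.append(dict(bay=bay, group=m,
                                  mode_inside=si.modal_midpoint,
                                  mode_outside=so.modal_midpoint,
                                  chi2=c.chi2, p=c.p, p_modal=c.p_modal,
                                  mode_differs=c.mode_differs,
                                  n_inside=si.n, n_outside=so.n))
        for hab in sorted(sub["habitat"].unique()):
            hsub = sub[sub["habitat"] == hab]
            k = sizespectra.fulton_k(hsub["weight_g"], hsub["length_cm"])
            fulton_rows.append(dict(bay=bay, habitat=hab,
                                    fulton_k_mean=float(np.mean(k)),
                                    fulton_k_sd=float(np.std(k, ddof=1)),
                                    n=len(hsub)))
    return (pd.DataFrame(spec_rows), pd.DataFrame(modal_rows),
            pd.DataFrame(fulton_rows))
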