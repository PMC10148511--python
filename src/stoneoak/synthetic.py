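"""Synthetic stone-oak study generator with known ground truth.

Produces, from one master seed, everything the analysis pipeline consumes:
a birth-death phylogeny (rescaled to unit height), a fruit-type history
evolved under an asymmetric two-state Mk model (acorn ancestors, repeated
independent origins of the enclosed-receptacle type with occasional
reversals), per-species fruit archetypes whose seed size follows Brownian
motion on the log scale with a type-dependent offset (ER species
stochastically larger-seeded), fruit-level measurement tables with
multiplicative lognormal noise (a shared latent fruit-size factor plus
independent per-dimension noise), and per-species locality MAT samples
drawn around zone centers with optional cold-tail skew.

What it deliberately does not emulate: cupule geometry, specimen imaging
artifacts, geographic range structure beyond MAT, and correlation between
fruit size and sample size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import phylo
from .classification import DIMENSIONS
from .fruit_profiles import make_archetype, exact_parameters
from .morphometry import compute_dimensions
from .phylo import MkModel, Phylogeny


class SyntheticStudyError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Generating conditions of a synthetic study (defaults = study scale)."""

    n_species: int = 80
    birth_rate: float = 1.0
    death_rate: float = 0.3
    # Mk rates per unit tree height: ER derived, occasionally reversing
    q_ac_to_er: float = 0.15
    q_er_to_ac: float = 0.05
    # log seed radial semi-axis: type-dependent mean + BM deviation on the tree
    log_seed_mean: dict = field(default_factory=lambda: {"AC": math.log(0.85), "ER": math.log(1.25)})
    bm_sigma: float = 0.25
    aspect_ratio: float = 1.25          # axial/radial seed semi-axis
    # shell thickness as a fraction of the seed radial semi-axis
    pericarp_thickness_frac: dict = field(default_factory=lambda: {"AC": 0.09, "ER": 0.05})
    receptacle_thickness_frac: dict = field(default_factory=lambda: {"AC": 0.15, "ER": 0.32})
    coverage_range: dict = field(default_factory=lambda: {
        "AC": (0.75, 0.95),  # f_p range for AC (f_r gets the complement share)
        "ER": (0.75, 0.95),  # f_r range for ER
    })
    minor_coverage_cap: float = 0.25
    # fruit-level noise: latent size factor (linear scale) + per-dimension
    size_cv: float = 0.1
    fruit_cv: float = 0.2
    # fruits per species ~ round(lognormal), clipped
    fruits_log_mean: float = math.log(4.0)
    fruits_log_sd: float = 1.1
    fruits_max: int = 250
    # thermal sampling
    zone_probs: dict = field(default_factory=lambda: {
        "tropical": 0.62, "subtropical": 0.08, "warm_temperate": 0.30})
    zone_centers: dict = field(default_factory=lambda: {
        "tropical": 25.5, "subtropical": 20.5, "warm_temperate": 16.0})
    zone_sd: float = 1.2
    localities_range: tuple[int, int] = (3, 30)
    cold_skew_prob: float = 0.15        # chance of a cold-outlier locality tail
    cold_skew_shift: float = -6.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_species < 4:
            problems.append("n_species must be >= 4")
        if not (self.birth_rate > self.death_rate >= 0):
            problems.append("need birth_rate > death_rate >= 0")
        for name in ("q_ac_to_er", "q_er_to_ac", "bm_sigma", "size_cv", "fruit_cv", "zone_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        lo, hi = self.localities_range
        if not (1 <= lo <= hi):
            problems.append("localities_range must satisfy 1 <= lo <= hi")
        if abs(sum(self.zone_probs.values()) - 1.0) > 1e-9:
            problems.append("zone_probs must sum to 1")
        if problems:
            raise SyntheticStudyError("invalid config: " + "; ".join(problems))


@dataclass
class SyntheticStudy:
    config: StudyConfig
    phylogeny: Phylogeny
    tip_types: dict[str, str]
    node_types: dict[str, str]
    true_changes: dict[str, int]
    species_truth: pd.DataFrame      # per-species true mean dimensions
    fruit_table: pd.DataFrame        # fruit-level noisy dimensions
    thermal_table: pd.DataFrame      # species, fruit_type, median/mean MAT, zone
    provenance: dict = field(default_factory=dict)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    s2 = math.log1p(cv * cv)
    return rng.lognormal(-s2 / 2.0, math.sqrt(s2), size)


def generate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a full synthetic study from the master seed.

    All randomness flows through named substreams of the master seed (tree,
    traits, fruits, thermal), so regenerating with the same config is
    bit-identical regardless of how the pieces are consumed downstream.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(("tree", "traits", "fruits", "thermal"), ss.spawn(4))}
    tree_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31 - 1))

    phy = phylo.simulate_birth_death(cfg.n_species, cfg.birth_rate, cfg.death_rate,
                                     seed=tree_seed)
    phylo.rescale_height(phy, 1.0)
    mk = MkModel(cfg.q_ac_to_er, cfg.q_er_to_ac, root_prior=(1.0, 0.0))  # AC-like ancestor
    rng_t = streams["traits"]
    node_states, jumps = phylo.simulate_mk_history(phy, mk, rng_t)
    bm_dev = phylo.simulate_bm(phy, cfg.bm_sigma, rng_t, 0.0)

    tip_types, node_types = {}, {}
    for nd in phy.tree.preorder_node_iter():
        name = nd.taxon.label if nd.is_leaf() else nd.label
        (tip_types if nd.is_leaf() else node_types)[name] = phylo.STATE_NAMES[node_states[id(nd)]]

    # per-species archetypes and true mean dimensions
    rng_f = streams["fruits"]
    truth_rows, fruit_rows = [], []
    for lf in phy.tree.leaf_node_iter():
        sp = lf.taxon.label
        ft = tip_types[sp]
        a = math.exp(cfg.log_seed_mean[ft] + bm_dev[id(lf)])
        axes = (a, a * cfg.aspect_ratio)
        thick = (cfg.pericarp_thickness_frac[ft] * a,
                 cfg.receptacle_thickness_frac[ft] * a)
        lo, hi = cfg.coverage_range[ft]
        major = rng_f.uniform(lo, hi)
        minor = rng_f.uniform(0.02, min(cfg.minor_coverage_cap, 1.0 - major))
        cover = (major, minor) if ft == "AC" else (minor, major)
        profile = make_archetype(ft, axes, thick, cover)
        dims = compute_dimensions(exact_parameters(profile)).as_dict()
        n_fruits = int(np.clip(round(rng_f.lognormal(cfg.fruits_log_mean, cfg.fruits_log_sd)),
                               1, cfg.fruits_max))
        truth_rows.append(dict(species=sp, fruit_type=ft, n=n_fruits, **dims))
        size = _lognormal_factor(rng_f, cfg.size_cv, n_fruits)
        for j in range(n_fruits):
            row = dict(fruit_id=f"{sp}_f{j + 1}", species=sp)
            for dim in DIMENSIONS:
                power = 2.0 if dim.startswith("S") else 3.0
                row[dim] = dims[dim] * size[j] ** power * _lognormal_factor(rng_f, cfg.fruit_cv)
            fruit_rows.append(row)

    species_truth = pd.DataFrame(truth_rows)
    fruit_table = pd.DataFrame(fruit_rows)

    # thermal sampling
    rng_th = streams["thermal"]
    zones = list(cfg.zone_probs)
    pz = np.array([cfg.zone_probs[z] for z in zones])
    thermal_rows = []
    for lf in phy.tree.leaf_node_iter():
        sp = lf.taxon.label
        zone = zones[rng_th.choice(len(zones), p=pz)]
        k = int(rng_th.integers(cfg.localities_range[0], cfg.localities_range[1] + 1))
        mats = rng_th.normal(cfg.zone_centers[zone], cfg.zone_sd, k)
        skewed = rng_th.random() < cfg.cold_skew_prob
        if skewed and k >= 3:
            n_out = max(1, k // 4)
            mats[:n_out] = mats[:n_out] + cfg.cold_skew_shift
        thermal_rows.append(dict(
            species=sp, fruit_type=tip_types[sp], true_zone=zone,
            median_mat=round(float(np.median(mats)), 1),
            mean_mat=round(float(np.mean(mats)), 1),
            n_localities=k, cold_skewed=bool(skewed and k >= 3),
        ))
    thermal_table = pd.DataFrame(thermal_rows)

    return SyntheticStudy(
        config=cfg, phylogeny=phy, tip_types=tip_types, node_types=node_types,
        true_changes=jumps, species_truth=species_truth, fruit_table=fruit_table,
        thermal_table=thermal_table,
        provenance=dict(seed=cfg.seed, tree_seed=tree_seed,
                        n_species=cfg.n_species),
    )


def export_tables(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write the study as pipeline-readable files plus a truth sidecar.

    Emits a species-mean table shaped like the published morphometric table
    (species means computed from the noisy fruit-level records), the
    fruit-level table itself, a thermal summary table, the tree in Newick,
    and a JSON sidecar holding every generating parameter and truth values.
    """
    if len(study.fruit_table) == 0:
        raise SyntheticStudyError("refusing to export an empty study")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    means = (study.fruit_table.groupby("species")[DIMENSIONS].mean().reset_index())
    means.insert(1, "fruit_type", means["species"].map(study.tip_types))
    counts = study.fruit_table.groupby("species").size()
    means.insert(2, "n", means["species"].map(counts))
    paths["species_table"] = str(out / "table1_species.csv")
    means.to_csv(paths["species_table"], index=False)

    paths["fruit_table"] = str(out / "fruit_dimensions.csv")
    study.fruit_table.to_csv(paths["fruit_table"], index=False)

    paths["thermal_table"] = str(out / "table3_thermal.csv")
    study.thermal_table.to_csv(paths["thermal_table"], index=False)

    paths["tree"] = str(out / "phylogeny.nwk")
    Path(paths["tree"]).write_text(phylo.write_newick(study.phylogeny) + "\n")

    truth = dict(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(study.config).items()},
        tip_types=study.tip_types,
        node_types=study.node_types,
        true_changes=study.true_changes,
        species_truth=study.species_truth.to_dict(orient="records"),
        provenance=study.provenance,
    )
    paths["truth"] = str(out / "truth.json")
    Path(paths["truth"]).write_text(json.dumps(truth, indent=1))
    return paths
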