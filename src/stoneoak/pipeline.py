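"""End-to-end orchestration: fixtures, staged analysis, JSON/text reports.

The packaged fixtures are the two published species-level tables: the
morphometric table (168 species: fruit type, sample n, and the six
dimensions) and the thermal table (72 species: median and mean MAT with
zone labels).  ``run_full_analysis`` chains classification, group
contrasts, allometry, the comparative stage (when a tree is supplied) and
thermal zoning, and reports every stage with provenance (input hashes and
seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from . import allometry, classification, phylo, thermal

log = logging.getLogger("stoneoak")

FIXTURES = {
    "table1": ("table1_species.csv", 168),
    "table3": ("table3_thermal.csv", 72),
    "demo_tree": ("demo_tree.nwk", None),
}

_SCHEMAS = {
    "table1": ["species", "fruit_type", "n", "S_p", "S_r", "S_s", "V_p", "V_r", "V_s"],
    "table3": ["species", "fruit_type", "median_mat", "median_zone", "mean_mat", "mean_zone"],
}


class PipelineError(ValueError):
    pass


def _fixture_path(fname: str):
    return resources.files("stoneoak.data").joinpath(fname)


def load_fixtures(name: str):
    """Load a packaged fixture: ``table1``, ``table3`` or ``demo_tree``."""
    if name not in FIXTURES:
        raise PipelineError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}")
    fname, nrows = FIXTURES[name]
    path = _fixture_path(fname)
    if name == "demo_tree":
        return phylo.read_newick(path.read_text())
    df = pd.read_csv(path)
    schema = _SCHEMAS[name]
    if list(df.columns) != schema:
        raise PipelineError(f"fixture {name}: column schema mismatch ({list(df.columns)})")
    if nrows is not None and len(df) != nrows:
        raise PipelineError(f"fixture {name}: expected {nrows} rows, found {len(df)}")
    return df


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_full_analysis(
    species_table: pd.DataFrame | None = None,
    fruit_table: pd.DataFrame | None = None,
    thermal_table: pd.DataFrame | None = None,
    tree: phylo.Phylogeny | None = None,
    min_n_allometry: int = 8,
    seed: int = 0,
    n_perm: int = 0,
) -> dict:
    """Run every stage for which inputs are available; return the report.

    ``species_table`` (species means) or ``fruit_table`` (per-fruit rows)
    feeds classification and allometry; ``thermal_table`` the thermal stage;
    ``tree`` the comparative stage (skipped, with a warning, when absent).
    The report is a plain dict, JSON-serializable via :func:`write_report`.
    """
    if species_table is None and fruit_table is None and thermal_table is None:
        raise PipelineError("no inputs: need a species, fruit or thermal table")
    report: dict = {"provenance": {"seed": seed, "inputs": {}}, "stages": {}}
    prov = report["provenance"]["inputs"]

    records = None
    if fruit_table is not None:
        prov["fruit_table"] = _hash_frame(fruit_table)
        records = classification.species_means(fruit_table)
    elif species_table is not None:
        prov["species_table"] = _hash_frame(species_table)
        records = classification.records_from_species_table(species_table)

    if records is not None:
        counts = {"AC": 0, "ER": 0, "unassigned": 0}
        for r in records:
            counts[r.fruit_type] += 1
        agreement = None
        if species_table is not None and "fruit_type" in species_table.columns:
            printed = dict(zip(species_table["species"], species_table["fruit_type"]))
            agreement = sum(printed.get(r.species) == r.fruit_type for r in records)
        report["stages"]["classification"] = {
            "n_species": len(records),
            "counts": counts,
            "total_fruits": int(sum(r.n for r in records)),
            "label_agreement": agreement,
        }
        contrasts = {}
        for dim in ("V_s", "defense_index", "V_h"):
            try:
                c = classification.group_contrast(records, dim)
            except classification.ClassificationError as exc:
                log.warning("contrast %s skipped: %s", dim, exc)
                continue
            contrasts[dim] = {
                "means": c.means, "statistic": c.statistic,
                "p_value": c.p_value, "er_exceeds_ac": c.er_exceeds_ac,
            }
        report["stages"]["contrasts"] = contrasts

        allo = allometry.fit_fruit_type_allometries(
            records, min_n=min_n_allometry, n_perm=n_perm, seed=seed)
        report["stages"]["allometry"] = {
            "min_n": allo["min_n"],
            "pairs": {
                pair: {
                    "slopes": {g: f.slope for g, f in entry["fits"].items()},
                    "intercepts": {g: f.intercept for g, f in entry["fits"].items()},
                    "constants": {g: f.allometric_constant for g, f in entry["fits"].items()},
                    "ci": {g: [f.ci_lower, f.ci_upper] for g, f in entry["fits"].items()},
                    "heterogeneity": (
                        {
                            "statistic": entry["heterogeneity"].statistic,
                            "df": entry["heterogeneity"].df,
                            "p_value": entry["heterogeneity"].p_value,
                            "common_slope": entry["heterogeneity"].common_slope,
                        }
                        if "heterogeneity" in entry else None
                    ),
                }
                for pair, entry in allo["pairs"].items()
            },
        }

    if tree is not None and records is not None:
        tip_types = {r.species: r.fruit_type for r in records}
        have = [l for l in tree.tip_labels if l in tip_types]
        if len(have) < tree.n_tips:
            log.warning("comparative stage: %d tips lack fruit-type data; skipped",
                        tree.n_tips - len(have))
            report["stages"]["comparative"] = {"skipped": "tips missing trait data"}
        else:
            fit = phylo.fit_mk(tree, tip_types, "ARD")
            asr = phylo.marginal_asr(tree, tip_types, fit.model)
            trans = phylo.count_transitions(tree, asr, tip_types)
            states01 = {l: 1.0 if s == "ER" else 0.0 for l, s in tip_types.items()}
            sig = phylo.blomberg_k(tree, states01, n_perm=max(n_perm, 199), seed=seed)
            report["stages"]["comparative"] = {
                "mk_rates": {"AC->ER": fit.model.q01, "ER->AC": fit.model.q10},
                "log_likelihood": fit.log_likelihood,
                "transitions": trans,
                "blomberg_K_fruit_type": sig.K,
                "blomberg_K_p": sig.p_value,
            }
    elif tree is None:
        log.warning("no tree supplied; comparative stage skipped")

    if thermal_table is not None:
        prov["thermal_table"] = _hash_frame(thermal_table)
        profiles = thermal.profiles_from_table(thermal_table)
        summary = thermal.zone_summary(profiles)
        agreement = None
        if "median_zone" in thermal_table.columns:
            agreement = int(sum(
                p.median_zone == z for p, z in zip(profiles, thermal_table["median_zone"])
            ) + sum(
                p.mean_zone == z for p, z in zip(profiles, thermal_table["mean_zone"])
            ))
        report["stages"]["thermal"] = {**summary, "printed_zone_agreement": agreement}

    return report


def write_report(report: dict, out_dir, stem: str = "report") -> dict[str, str]:
    """Write the report as canonical JSON plus a short human-readable text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / f"{stem}.json"
    jpath.write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
    lines = ["stone-oak analysis report", "=" * 25]
    for stage, content in report["stages"].items():
        lines.append(f"\n[{stage}]")
        lines.append(json.dumps(content, indent=1, sort_keys=True, default=float))
    tpath = out / f"{stem}.txt"
    tpath.write_text("\n".join(lines) + "\n")
    return {"json": str(jpath), "text": str(tpath)}
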