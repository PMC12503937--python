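"""End-to-end orchestration: simulate or load -> residuals -> modularity ->
divergence -> regime rates -> ecology -> composition, with reproducible
delimited-table reports.

Every stage writes its table into the output directory together with a
provenance header (tree hash, config hash, seeds), so any stage can be
re-run from persisted intermediates and compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import axes as axes_mod
from . import composition as comp_mod
from . import ecology as eco_mod
from . import modularity as mod_mod
from . import rates as rates_mod
from .allometry import fit_allometry
from .regimes import regime_path_lengths
from .simulate import GeneratorConfig, SyntheticDataset, make_dataset
from .tables import dev_binary, read_flight_table, read_trait_table
from .trees import Phylogeny, prune_to, read_newick, vcv

logger = logging.getLogger("wingleg")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "load_inputs"]


@dataclass
class PipelineConfig:
    """Inputs, toggles and thresholds for one pipeline run.

    Either the three input paths (tree/traits/flight) or a generator config
    must be present.  All randomness flows from the seeds recorded here.
    """

    tree_path: str | None = None
    traits_path: str | None = None
    flight_path: str | None = None
    generator: GeneratorConfig | None = None
    out_dir: str = "wingleg_out"
    n_maps: int = 100
    single_map: bool = False
    simmap_seed: int = 1
    alpha: float = 0.05
    pcoa_threshold: float = 0.05
    drop_species: tuple = ()
    min_divergence_myr: float = 0.0
    collapse_genera: bool = False
    stages: tuple = (
        "allometry",
        "modularity",
        "divergence",
        "rates",
        "ecology",
        "composition",
    )

    def __post_init__(self):
        has_paths = self.tree_path and self.traits_path
        if not has_paths and self.generator is None:
            raise ValueError(
                "config must provide input paths or a generator configuration"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = GeneratorConfig(**gen)
        for key in ("drop_species", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)


def _hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    header = "# " + json.dumps(provenance, sort_keys=True) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=True)


def validate_inputs(
    phy: Phylogeny,
    traits: pd.DataFrame,
    flight: pd.DataFrame | None,
    drop_species: tuple = (),
    min_divergence_myr: float = 0.0,
    collapse_genera: bool = False,
) -> dict:
    """Species-concordance checks plus the optional curation filters.

    Filters: caller-listed exclusions (e.g. flightless species), dropping
    one member of any pair diverging more recently than
    ``min_divergence_myr`` (the retained species is alphabetically first),
    and collapsing genera (label prefix before '_') to one species each.
    Returns the validation report with the retained species list.
    """
    issues: list[str] = []
    tree_sp = set(phy.tips)
    trait_sp = set(traits.index)
    missing_in_tree = sorted(trait_sp - tree_sp)
    missing_in_traits = sorted(tree_sp - trait_sp)
    if missing_in_tree:
        issues.append(f"species in traits missing from tree: {missing_in_tree}")
    if missing_in_traits:
        issues.append(f"species in tree missing from traits: {missing_in_traits}")
    keep = sorted(tree_sp & trait_sp)
    removed = {"listed": [], "recent_divergence": [], "genus_duplicates": []}

    listed = sorted(set(drop_species) & set(keep))
    removed["listed"] = listed
    keep = [s for s in keep if s not in set(listed)]

    if collapse_genera:
        by_genus: dict[str, list[str]] = {}
        for s in keep:
            by_genus.setdefault(s.split("_")[0], []).append(s)
        drop = [s for members in by_genus.values() for s in sorted(members)[1:]]
        removed["genus_duplicates"] = sorted(drop)
        keep = [s for s in keep if s not in set(drop)]

    if min_divergence_myr > 0 and len(keep) >= 2:
        sub = vcv(prune_to(phy, keep))
        T = sub.height
        drop = set()
        order = list(sub.tips)
        for i in range(len(order)):
            if order[i] in drop:
                continue
            for j in range(i + 1, len(order)):
                if order[j] in drop:
                    continue
                if T - sub.C[i, j] < min_divergence_myr:
                    drop.add(max(order[i], order[j]))
        removed["recent_divergence"] = sorted(drop)
        keep = [s for s in keep if s not in drop]

    if len(keep) < 10:
        raise ValueError(f"fewer than 10 species remain after filtering ({len(keep)})")
    if flight is not None:
        unknown = sorted(set(flight.index) - trait_sp)
        if unknown:
            issues.append(f"flight-style species missing from traits: {unknown}")
    return {"issues": issues, "removed": removed, "keep": keep}


def load_inputs(config: PipelineConfig):
    """Load real inputs or simulate synthetic ones per the config."""
    if config.generator is not None:
        ds = make_dataset(config.generator)
        return ds.phylogeny, ds.traits, ds.flight_styles, ds
    phy = read_newick(config.tree_path)
    traits = read_trait_table(config.traits_path)
    flight = read_flight_table(config.flight_path) if config.flight_path else None
    return phy, traits, flight, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage, write its tables, return the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phy, traits, flight, dataset = load_inputs(config)

    report = validate_inputs(
        phy,
        traits,
        flight,
        drop_species=config.drop_species,
        min_divergence_myr=config.min_divergence_myr,
        collapse_genera=config.collapse_genera,
    )
    keep = report["keep"]
    if set(keep) != set(phy.tips):
        phy = prune_to(phy, keep)
    traits = traits.loc[phy.tips]

    tree_newick = phy.to_newick()
    provenance = {
        "tree_hash": _hash(tree_newick),
        "config_hash": _hash(json.dumps(_config_dict(config), sort_keys=True)),
        "simmap_seed": config.simmap_seed,
    }
    if config.generator is not None:
        provenance["generator_seed"] = config.generator.seed
    with open(out / "tree.nwk", "w") as fh:
        fh.write(tree_newick + "\n")
    with open(out / "validation.json", "w") as fh:
        json.dump(report, fh, indent=1)

    results: dict = {"validation": report, "provenance": provenance, "phylogeny": phy}
    A = vcv(phy)

    def stage(name):
        return name in config.stages

    try:
        if stage("allometry"):
            logger.info("stage allometry")
            resid = fit_allometry(A, traits)
            results["allometry"] = resid
            _write(resid.residuals, out / "allometric_residuals.csv", provenance)
        if stage("modularity"):
            logger.info("stage modularity")
            grid = mod_mod.modularity_report(
                results["allometry"], traits, phy, alpha=config.alpha
            )
            results["modularity"] = grid
            _write(grid, out / "modularity.csv", provenance)
        if stage("divergence"):
            logger.info("stage divergence")
            evo, axes, scores = axes_mod.divergence_pipeline(A, results["allometry"])
            results["evolutionary_covariance"] = evo
            results["axes"] = axes
            results["scores"] = scores
            # Table-1 convention: blockwise-unit vectors (norm sqrt(2))
            axis_table = pd.DataFrame(
                [np.round(axes.g, 3), np.round(axes.d, 3)],
                index=["concordance", "divergence"],
                columns=results["allometry"].residuals.columns,
            )
            _write(axis_table, out / "axes.csv", provenance)
            _write(
                pd.DataFrame(
                    {"delta": scores.scores, "deviation": scores.deviation}
                ),
                out / "divergence_scores.csv",
                provenance,
            )
        if stage("rates"):
            logger.info("stage rates")
            results["rates"] = _rates_stage(phy, traits, results["scores"], config, A)
            _write(results["rates"]["table"], out / "rates.csv", provenance)
            _write(
                results["rates"]["ancestral"], out / "ancestral_scores.csv", provenance
            )
        if stage("ecology") and flight is not None:
            logger.info("stage ecology")
            results["ecology"] = _ecology_stage(
                flight, traits, results["scores"], config
            )
            _write(results["ecology"]["table"], out / "ecology_models.csv", provenance)
            _write(
                results["ecology"]["distinctiveness"],
                out / "flight_distinctiveness.csv",
                provenance,
            )
        if stage("composition"):
            logger.info("stage composition")
            comp = comp_mod.build_wing_composition(traits)
            overlay = comp_mod.deviation_overlay(
                results["scores"], comp, traits["dev_class"]
            )
            results["composition"] = comp
            results["overlay"] = overlay
            anc = comp_mod.ancestral_composition(A, comp.proportions)
            results["ancestral_composition"] = anc
            _write(overlay, out / "composition_overlay.csv", provenance)
            _write(
                pd.DataFrame(
                    [anc], columns=["p_hum", "p_rad", "p_cmc"], index=["ancestor"]
                ),
                out / "ancestral_composition.csv",
                provenance,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    return results


def _rates_stage(phy, traits, scores, config, A):
    dev = traits["dev_class"].map(dev_binary)
    tip_states = {s: d for s, d in dev.items() if d in ("altricial", "precocial")}
    if set(tip_states) != set(phy.tips):
        sub = prune_to(phy, sorted(tip_states))
    else:
        sub = phy
    y = scores.scores
    mk = rates_mod.fit_mk_er(sub, tip_states)
    n_maps = 1 if config.single_map else config.n_maps
    maps = rates_mod.sample_simmap(sub, tip_states, mk, n_maps, config.simmap_seed)
    A_sub = vcv(sub)
    single = rates_mod.fit_bm_single(y, A_sub)
    fits, ps = [], []
    for m in maps:
        paths = regime_path_lengths(m, sub)
        two = rates_mod.fit_bm_two_rate(y, paths)
        lam, p = rates_mod.likelihood_ratio_test(single, two)
        fits.append(two)
        ps.append(p)
    sa = float(np.median([f.sigma2_altricial for f in fits]))
    sp_ = float(np.median([f.sigma2_precocial for f in fits]))
    p_med = float(np.median(ps))
    table = pd.DataFrame(
        [
            {
                "model": "single",
                "sigma2_altricial": single.sigma2,
                "sigma2_precocial": single.sigma2,
                "logL": single.loglik,
                "LRT_p": np.nan,
            },
            {
                "model": "two_rate",
                "sigma2_altricial": sa,
                "sigma2_precocial": sp_,
                "logL": float(np.median([f.loglik for f in fits])),
                "LRT_p": p_med,
            },
        ]
    ).set_index("model")
    ancestral = rates_mod.ancestral_scores(sub, y)
    return {
        "mk": mk,
        "maps": maps,
        "single": single,
        "two_rate_fits": fits,
        "median_sigma2_altricial": sa,
        "median_sigma2_precocial": sp_,
        "median_lrt_p": p_med,
        "table": table,
        "ancestral": ancestral,
    }


def _ecology_stage(flight, traits, scores, config):
    fd = eco_mod.flight_distinctiveness(flight, threshold=config.pcoa_threshold)
    dev = traits["dev_class"].map(dev_binary)
    rows = []
    fits = {}
    for subset in ("altricial", "precocial"):
        members = dev.index[dev == subset]
        mf = fd.m_flight.loc[fd.m_flight.index.intersection(members)]
        mass = np.log10(traits.loc[traits.index.intersection(members), "mass_g"])
        for name, resp, formula in (
            ("flight", mf, "quadratic"),
            ("mass", mass, "linear"),
        ):
            fit = eco_mod.fit_ecology_models(resp, scores.scores, formula)
            fits[(subset, name)] = fit
            row = {
                "subset": subset,
                "model": name,
                "formula": formula,
                "adj_r2": fit.adj_r2,
                "n": fit.n,
            }
            for coef in fit.coefficients.index:
                row[f"b_{coef}"] = fit.coefficients[coef]
                row[f"p_{coef}"] = fit.pvalues[coef]
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["subset", "model"])
    dist = pd.DataFrame({"D2": fd.d2, "m_flight": fd.m_flight}).join(fd.scores)
    return {"distinctiveness_obj": fd, "distinctiveness": dist, "table": table, "fits": fits}


def _config_dict(config: PipelineConfig) -> dict:
    # out_dir is where results land, not what they are: keep it out of the
    # provenance hash so runs into different directories compare equal
    d = {
        k: v
        for k, v in config.__dict__.items()
        if k not in ("generator", "out_dir") and not isinstance(v, (pd.DataFrame,))
    }
    d["drop_species"] = list(config.drop_species)
    d["stages"] = list(config.stages)
    if config.generator is not None:
        d["generator"] = config.generator.to_dict()
    return d
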