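"""End-to-end orchestration of the full survey analysis.

``run_full_analysis`` executes: rarefaction -> alpha/beta diversity ->
PCoA/ANOSIM/PERMANOVA -> Mantel / partial-Mantel tables -> PCNM + forward
selection + variance partitioning -> betaNTI/RCbray/process classification
and per-stratum summaries -> ssOTU calling, co-occurrence network, modules
and module~environment regressions. Every stage draws its randomness from a
seed spawned deterministically from the master seed, and the run manifest
records the configuration so a rerun is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, diversity, multivariate, ssotu, synthetic
from . import data_model as dm

logger = logging.getLogger("assemblage")


@dataclass
class RunConfig:
    """All inputs, constants and seeds of a full analysis run.

    Either the three input paths or a scenario name must be given. The
    defaults carry the survey constants: rarefaction at 26,000 reads, 999
    null replicates and permutations, |betaNTI| threshold 2, |RCbray|
    threshold 0.95, network edge rule rho > 0.7 at p < 0.001, and the
    pooled relative-abundance filter at 0.01%.
    """

    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    scenario: str | None = None
    out_dir: str = "assemblage_out"
    rarefaction_depth: int = 26000
    n_null: int = 999
    n_perm: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    rho_min: float = 0.7
    p_max: float = 0.001
    abundance_threshold: float = 1e-4
    bnti_weighted: bool = False
    wuf_normalized: bool = False
    seed: int = 0
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if not 0 <= self.abundance_threshold < 1:
            raise ValueError("abundance threshold must be in [0, 1)")
        if not (self.rc_threshold > 0 and self.bnti_threshold > 0
                and 0 < self.rho_min < 1 and 0 < self.p_max < 1):
            raise ValueError("threshold outside its legal range")
        has_paths = all(p is not None for p in
                        (self.table_path, self.tree_path, self.metadata_path))
        if not has_paths and self.scenario is None:
            raise ValueError("give input paths or a scenario name")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _spawn_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


_STAGE_SEEDS = ["simulate", "rarefy", "anosim", "permanova", "mantel",
                "pmantel", "forward", "vpa", "bnti", "rcbray", "indicator"]


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write TSV/JSON reports plus a manifest.

    Returns a dict of in-memory results keyed by stage name. On a stage
    failure the exception is re-raised with the stage name; outputs written
    so far are preserved in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, _STAGE_SEEDS)
    results: dict = {}
    stage = "load_inputs"
    t0 = time.time()
    try:
        table, tree, metadata = _load_inputs(config, seeds)
        months = list(dict.fromkeys(metadata["month"]))
        env_vars = [v for v in dm.ENV_VARIABLES if v in metadata.columns]

        stage = "rarefy"
        table = dm.rarefy(table, config.rarefaction_depth,
                          seed=seeds["rarefy"])
        metadata = metadata.loc[table.sample_ids]
        dm.write_otu_table(table, out / "rarefied_table.tsv")

        stage = "alpha_diversity"
        alpha = diversity.alpha_diversity(table, tree)
        alpha.to_csv(out / "alpha.tsv", sep="\t")
        results["alpha"] = alpha
        corr = multivariate.alpha_env_correlation(alpha, metadata, env_vars)
        corr.to_csv(out / "alpha_env_correlation.tsv", sep="\t")
        results["alpha_env_correlation"] = corr
        if len(months) >= 2:
            letters = {
                idx: multivariate.group_difference_letters(
                    alpha[idx].to_numpy(), metadata["month"].to_numpy())
                for idx in diversity.ALPHA_INDICES
                if alpha[idx].notna().all()
            }
            letter_df = pd.concat(letters, names=["index", "group"])
            letter_df.to_csv(out / "alpha_group_letters.tsv", sep="\t")
            results["alpha_letters"] = letter_df

        stage = "beta_diversity"
        dms = {
            "bray": diversity.bray_curtis(table),
            "uuf": diversity.unweighted_unifrac(table, tree),
            "wuf": diversity.weighted_unifrac(
                table, tree, normalized=config.wuf_normalized),
        }
        for name, d in dms.items():
            dm.write_distance_matrix(d, out / f"distance_{name}.tsv")
        results["distances"] = dms

        stage = "ordination_tests"
        month_series = metadata["month"]
        ord_rows = []
        for name in ("uuf", "wuf"):
            ordn = multivariate.pcoa(dms[name])
            ordn.coordinates.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
            if len(months) >= 2:
                an = multivariate.anosim(dms[name], month_series,
                                         config.n_perm, seeds["anosim"])
                pm = multivariate.permanova(dms[name], month_series,
                                            config.n_perm, seeds["permanova"])
                ord_rows.append({
                    "distance": name, "anosim_r": an.statistic,
                    "anosim_p": an.p_value, "permanova_F": pm.statistic,
                    "permanova_R2": pm.extra["R2"], "permanova_p": pm.p_value,
                })
        if ord_rows:
            ord_df = pd.DataFrame(ord_rows).set_index("distance")
            ord_df.to_csv(out / "group_tests.tsv", sep="\t")
            results["group_tests"] = ord_df
        else:
            logger.info("single month design: ANOSIM/PERMANOVA skipped")

        stage = "mantel_tables"
        results["mantel"] = _mantel_tables(config, seeds, dms, metadata,
                                           env_vars, months, out)

        stage = "vpa"
        results["vpa"] = _vpa_tables(config, seeds, dms, metadata, env_vars,
                                     months, out)

        stage = "assembly"
        results.update(_assembly_stage(config, seeds, table, tree, metadata,
                                       out))

        stage = "ssotu_network"
        results.update(_ssotu_stage(config, seeds, table, metadata, env_vars,
                                    months, out))

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "stage_seeds": seeds,
            "months": months,
            "n_samples": table.n_samples,
            "n_taxa": table.n_taxa,
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        results["manifest"] = manifest
        results["elapsed_s"] = round(time.time() - t0, 2)
        logger.info("run complete in %.1f s", results["elapsed_s"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc
    return results


def _load_inputs(config: RunConfig, seeds: dict):
    if config.table_path is not None:
        table = dm.read_otu_table(config.table_path)
        tree = dm.read_newick(config.tree_path)
        metadata = dm.read_metadata(config.metadata_path)
    else:
        sc = synthetic.SyntheticConfig.scenario(
            config.scenario, seed=seeds["simulate"],
            **config.scenario_overrides)
        ds = synthetic.simulate_communities(sc)
        table, tree, metadata = ds.table, ds.tree, ds.metadata
    dm.check_tree_coverage(table, tree)
    dm.validate_metadata(table, metadata)
    return table, tree, metadata


def _mantel_tables(config, seeds, dms, metadata, env_vars, months, out):
    rows = []
    candidates: dict[str, object] = {}
    usable = [v for v in env_vars if metadata[v].std() > 0]
    for var in usable:
        candidates[var] = dm.euclidean_distance(metadata, [var])
    if usable:
        candidates["Env"] = dm.euclidean_distance(metadata, usable)
    candidates["Geo"] = dm.geographic_distance(metadata)
    for coord in ("longitude", "latitude"):
        if metadata[coord].std() > 0:
            candidates[coord.capitalize()] = dm.euclidean_distance(
                metadata, [coord], standardize=False)
    temporal = (multivariate.temporal_control_matrix(metadata)
                if len(months) >= 2 else None)
    if temporal is None:
        logger.info("single month design: partial Mantel (temporal) skipped")
    for name in ("wuf", "uuf"):
        for var, d_env in candidates.items():
            m = multivariate.mantel(dms[name], d_env, "spearman",
                                    config.n_perm, seeds["mantel"])
            row = {"distance": name, "variable": var, "r": m.statistic,
                   "p": m.p_value}
            if temporal is not None:
                pm = multivariate.partial_mantel(
                    dms[name], d_env, temporal, "spearman",
                    config.n_perm, seeds["pmantel"])
                row.update({"r_temporal": pm.statistic,
                            "p_temporal": pm.p_value})
            rows.append(row)
    df = pd.DataFrame(rows).set_index(["distance", "variable"])
    df.to_csv(out / "mantel_table.tsv", sep="\t")
    return df


def _vpa_tables(config, seeds, dms, metadata, env_vars, months, out):
    rows = []
    strata = ([("all", metadata.index)] if len(months) >= 2 else []) + [
        (m, metadata.index[metadata["month"] == m]) for m in months]
    for label, idx in strata:
        sub_meta = metadata.loc[idx]
        usable = [v for v in env_vars if sub_meta[v].std() > 0]
        env_X = ((sub_meta[usable] - sub_meta[usable].mean())
                 / sub_meta[usable].std())
        trend_X = sub_meta[["longitude", "latitude"]].astype(float)
        trend_X = (trend_X - trend_X.mean()) / trend_X.std(ddof=0).replace(0, 1)
        geo = dm.geographic_distance(sub_meta)
        try:
            pcnm_X = multivariate.pcnm_vectors(geo)
        except dm.ValidationError:
            pcnm_X = pd.DataFrame(index=sub_meta.index)
        for name in ("wuf", "uuf"):
            response = dms[name].filter(list(map(str, idx)))
            Y = multivariate.pcoa_embedding(response)
            sets = {}
            for set_name, X in (("env", env_X), ("trend", trend_X),
                                ("pcnm", pcnm_X)):
                if X.shape[1] == 0:
                    sets[set_name] = None
                    continue
                fs = multivariate.forward_select(
                    Y, X, alpha=0.05, n_perm=config.n_perm,
                    seed=seeds["forward"])
                sets[set_name] = X[fs.selected] if fs.selected else None
            vpa = multivariate.variance_partition(
                Y, sets["env"], sets["trend"], sets["pcnm"],
                n_perm=config.n_perm, seed=seeds["vpa"])
            row = {"stratum": label, "distance": name,
                   "testable": vpa.testable}
            if vpa.testable:
                row.update({k: vpa.displayed.get(k, np.nan)
                            for k in multivariate._VPA_KEYS})
                row.update({f"p_{k}": v for k, v in vpa.set_p_values.items()})
            rows.append(row)
    df = pd.DataFrame(rows).set_index(["stratum", "distance"])
    df.to_csv(out / "vpa_table.tsv", sep="\t")
    return df


def _assembly_stage(config, seeds, table, tree, metadata, out):
    bnti = assembly.beta_nti(table, tree, weighted=config.bnti_weighted,
                             n_null=config.n_null, seed=seeds["bnti"])
    rc = assembly.raup_crick_bray(table, n_null=config.n_null,
                                  seed=seeds["rcbray"])
    labels = assembly.classify_processes(bnti, rc, config.bnti_threshold,
                                         config.rc_threshold)
    long = bnti.to_long().merge(
        rc.to_long(), on=["sample_i", "sample_j"], suffixes=("_bmntd", "_bc"))
    long = long.merge(labels[["sample_i", "sample_j", "process"]],
                      on=["sample_i", "sample_j"], how="left")
    long.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
    summary = assembly.summarize_processes(labels, metadata)
    summary.to_csv(out / "process_summary.tsv", sep="\t")
    return {"bnti": bnti, "rcbray": rc, "process_labels": labels,
            "process_summary": summary}


def _ssotu_stage(config, seeds, table, metadata, env_vars, months, out):
    filtered = dm.filter_by_mean_relative_abundance(
        table, config.abundance_threshold)
    factors = ssotu.tmm_factors(filtered)
    cpm_df = ssotu.cpm(filtered, factors)
    results: dict = {"tmm_factors": factors, "cpm": cpm_df}
    month_series = metadata["month"]
    if len(months) >= 2:
        ind = ssotu.indicator_analysis(cpm_df, month_series,
                                       n_perm=config.n_perm,
                                       seed=seeds["indicator"])
        lrt = ssotu.nb_lrt(filtered, month_series, factors=factors)
        calls = ssotu.call_ssotus(ind, lrt)
        calls.to_csv(out / "ssotus.tsv", sep="\t")
        results["ssotus"] = calls
    else:
        logger.info("single month design: ssOTU calling skipped")
    net = ssotu.build_network(cpm_df, config.rho_min, config.p_max)
    net = ssotu.detect_modules(net)
    net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    net.modules.rename_axis("otu").to_frame().to_csv(
        out / "modules.tsv", sep="\t")
    ssotu.write_graphml(net, out / "network.graphml")
    reg = ssotu.module_env_regression(net, cpm_df, metadata, env_vars)
    reg.to_csv(out / "module_env_regression.tsv", sep="\t", index=False)
    results.update({"network": net, "module_env_regression": reg})
    return results
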