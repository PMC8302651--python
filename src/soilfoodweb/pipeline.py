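"""End-to-end orchestration: simulate/load -> assign -> abundance ->
metaweb -> local webs -> diversity -> effects -> MDMR.

Every stage is a pure function of (inputs, config, seed); a manifest
records inputs, seeds, versions and parameters so a rerun with the same
config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import SoilFoodWebError
from .io import (SampleMetadata, default_scheme, read_motu_table,
                 read_sample_metadata, write_metaweb, write_motu_table,
                 write_sample_metadata)
from .assign import assign_trophic_groups, assignment_summary
from .abundance import (class_abundance, group_relative_abundance,
                        hill_diversity_matrix, standardize_diversity)
from .diversity import alpha_diversity, network_dissimilarity
from .localweb import class_proportion_change, induce_class_web, induce_group_web
from .metaweb import aggregate_metaweb, build_metaweb, validate_metaweb
from .simulate import SimulationConfig, default_group_config, simulate_motu_table
from .stats import HierarchicalFitSpec, effect_table, mdmr_test


class StageError(SoilFoodWebError):
    """A pipeline stage failed; message names the stage."""


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def build_local_webs(metaweb, rel_abund, scheme):
    """Group- and class-level local webs for every sample column."""
    group_webs, class_webs = [], []
    for sample in rel_abund.values.columns:
        gw = induce_group_web(metaweb, rel_abund.values[sample], sample_id=sample)
        group_webs.append(gw)
        if gw.n_nodes:
            class_webs.append(induce_class_web(gw, scheme))
    return group_webs, class_webs


def alpha_table(webs, metadata: SampleMetadata, eta: float = 1.0) -> pd.DataFrame:
    """Alpha diversity of nodes and links per area x condition."""
    meta = metadata.table.set_index("sample_id")
    rows = []
    by_id = {w.sample_id: w for w in webs}
    for (area, cond), sub in meta.groupby(["area", "defoliation"]):
        sel = [by_id[s] for s in sub.index if s in by_id]
        sel_l = [w for w in sel if w.n_links > 0]
        rows.append({
            "area": area,
            "condition": "defoliated" if cond else "undamaged",
            "n_webs": len(sel),
            "alpha_nodes": alpha_diversity(sel, eta, "nodes") if sel else np.nan,
            "alpha_links": alpha_diversity(sel_l, eta, "links") if sel_l else np.nan,
        })
    return pd.DataFrame(rows)


def run_all(config: dict, outdir, quiet: bool = False) -> dict:
    """Execute the full pipeline; returns a dict of result objects.

    ``config`` keys (all optional): ``seed``, ``simulate`` (preset,
    retained_samples, design sizes...), ``inputs`` (motu_table, metadata
    paths), ``abundance`` (per_marker), ``effects`` (method, chains,
    iterations, interval_level), ``mdmr`` (n_permutations), ``eta``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    eta = float(config.get("eta", 1.0))
    scheme = default_scheme()
    results: dict = {}
    t0 = time.time()

    stage = "inputs"
    try:
        if "inputs" in config:
            inp = config["inputs"]
            if "motu_table" not in inp or "metadata" not in inp:
                raise StageError("inputs require motu_table and metadata paths")
            for key in ("motu_table", "metadata"):
                if not Path(inp[key]).exists():
                    raise StageError(f"missing input file {inp[key]!r}")
            table = read_motu_table(inp["motu_table"])
            metadata = read_sample_metadata(inp["metadata"])
        else:
            stage = "simulate"
            sim = dict(config.get("simulate", {}))
            preset = sim.pop("preset", "paper_signs")
            if preset is None:  # YAML 'null'
                preset = "null"
            sim_cfg = SimulationConfig(
                groups=default_group_config(scheme, preset=preset),
                seed=seed, **sim)
            table, truth, metadata = simulate_motu_table(sim_cfg, scheme=scheme)
            write_motu_table(table, outdir / "motu_table.tsv")
            write_sample_metadata(metadata, outdir / "metadata.csv")
            truth.groups.to_csv(outdir / "ground_truth.csv")
            results["truth"] = truth
        _log(quiet, f"[{stage}] {len(table.motu_ids)} MOTUs, "
                    f"{len(table.samples)} samples ({time.time() - t0:.1f}s)")

        stage = "assign"
        assigned = assign_trophic_groups(table, scheme)
        assignment_summary(assigned).to_csv(outdir / "assignment_summary.csv")

        stage = "abundance"
        per_marker = bool(config.get("abundance", {}).get("per_marker", True))
        hill = hill_diversity_matrix(assigned)
        std_div = standardize_diversity(hill)
        rel = group_relative_abundance(assigned, per_marker=per_marker)
        cls_ab = class_abundance(rel, scheme)
        for name, m in (("hill_diversity", hill), ("standardized_diversity", std_div),
                        ("relative_abundance", rel), ("class_abundance", cls_ab)):
            m.values.to_csv(outdir / f"{name}.csv")

        stage = "metaweb"
        web = build_metaweb(scheme)
        violations = validate_metaweb(web, scheme)
        if violations:
            raise StageError(f"metaweb has {len(violations)} rule violations")
        write_metaweb(web, outdir / "metaweb_groups.csv")
        write_metaweb(aggregate_metaweb(web, scheme), outdir / "metaweb_classes.csv")

        stage = "localwebs"
        group_webs, class_webs = build_local_webs(web, rel, scheme)
        node_change, link_change = class_proportion_change(class_webs, metadata)
        node_change.to_csv(outdir / "class_proportion_change.csv")
        link_change.to_csv(outdir / "class_link_change.csv")
        results.update(group_webs=group_webs, class_webs=class_webs,
                       node_change=node_change, link_change=link_change)

        stage = "diversity"
        alphas = alpha_table(group_webs, metadata, eta)
        alphas.to_csv(outdir / "alpha_diversity.csv", index=False)
        linked = [w for w in group_webs if w.n_links > 0]
        noded = [w for w in group_webs if w.n_nodes > 0]
        dis_nodes = network_dissimilarity(noded, eta, "nodes")
        dis_links = network_dissimilarity(linked, eta, "links")
        dis_nodes.to_csv(outdir / "dissimilarity_nodes.csv")
        dis_links.to_csv(outdir / "dissimilarity_links.csv")
        results.update(alpha=alphas, dis_nodes=dis_nodes, dis_links=dis_links)

        stage = "effects"
        eff_cfg = dict(config.get("effects", {}))
        spec = HierarchicalFitSpec(seed=seed + 1, **eff_cfg)
        div_eff = effect_table(std_div.values, metadata, spec)
        ab_eff = effect_table(rel.values, metadata, spec, transform="yeo-johnson")
        div_eff.insert(1, "response_kind", "diversity")
        ab_eff.insert(1, "response_kind", "relative_abundance")
        effects = pd.concat([div_eff, ab_eff], ignore_index=True)
        effects.to_csv(outdir / "effect_table.csv", index=False)
        results["effects"] = effects

        stage = "mdmr"
        n_perm = int(config.get("mdmr", {}).get("n_permutations", 999))
        mdmr_rows = []
        for name, dmat in (("nodes", dis_nodes), ("links", dis_links)):
            sub_meta = SampleMetadata(metadata.table[
                metadata.table["sample_id"].isin(dmat.index)].reset_index(drop=True))
            res = mdmr_test(dmat, sub_meta, n_permutations=n_perm, seed=seed + 2)
            mdmr_rows.append({"component": name, "statistic": res.statistic,
                              "p_value": res.p_value,
                              "n_permutations": res.n_permutations})
        mdmr = pd.DataFrame(mdmr_rows)
        mdmr.to_csv(outdir / "mdmr.csv", index=False)
        results["mdmr"] = mdmr
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__, "seed": seed, "eta": eta,
        "n_samples": len(table.samples), "n_motus": len(table.motu_ids),
        "config": repr(config), "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.txt", "w") as fh:
        for k, val in manifest.items():
            fh.write(f"{k} = {val}\n")
    _log(quiet, f"[done] outputs in {outdir} ({time.time() - t0:.1f}s)")
    results.update(table=table, metadata=metadata, assigned=assigned,
                   rel_abund=rel, std_div=std_div, metaweb=web)
    return results
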