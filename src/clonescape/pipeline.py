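"""End-to-end orchestration: simulate -> sample -> sequence -> tree ->
place -> forest -> expression -> signal -> ABC inference -> eQTL screen.

One :class:`RunConfig` (YAML/JSON-serializable) drives every enabled stage
with a single global seed fanned out to per-stage child seeds, so stages
are individually re-runnable and a rerun with the same config reproduces
identical outputs.  Each stage writes plain-text outputs (Newick, TSV,
JSON) into the run directory and registers them, with SHA-256 checksums,
in a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evo_inference, phylo_build, phylo_signal, synthetic_data
from .lowpass_placement import SamplePlacement, impute_leaf_forest
from .spatial_sim import SimParams, run_to_size, spatial_growth_mode, \
    true_sample_tree
from .synthetic_data import SamplingScheme
from .tree_metrics import intermixing_score, summary_labels, tree_summary

__all__ = ["RunConfig", "run_all", "report"]

STAGES = ("simulate", "sample", "tree", "place", "forest", "expression",
          "signal", "infer", "eqtl")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "clonescape_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulator
    sim: dict = field(default_factory=lambda: dict(
        N_end=500, m=1e-8, genome_size=3e9, D=2.0, d_push=3,
        lambda2=1.0, lambda3=1.0, t2=0, t3=0, death_rate=0.0))
    # sampling / sequencing
    scheme: dict = field(default_factory=lambda: dict(
        n_regions=4, glands_per_region=3, deep_per_region=1,
        cluster_radius=10, deep_depth=35.0, lowpass_depth=1.2))
    p0: float = 1e-3
    # tree building
    ccf_threshold: float = 0.25
    ratchet: dict = field(default_factory=lambda: dict(
        min_iter=20, max_iter=10_000, stop_no_improve=20))
    # forest / signal
    n_forest: int = 100
    expression: dict = field(default_factory=lambda: dict(
        n_heritable=30, n_plastic=30, heritable_sd=1.0, plastic_sd=1.0))
    # ABC
    abc: dict = field(default_factory=lambda: dict(
        n_end=400, n_particles=60, generations=3, nll_reps=60,
        models=("neutral", "selected")))
    # eQTL
    eqtl: dict = field(default_factory=lambda: dict(
        n_genes=120, mut_effect=1.0, cna_effect=0.3))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def _child_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {},
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    enabled = set(config.stages)
    ctx: dict = {}

    def register(stage, **files):
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha(Path(p))}
            for name, p in files.items()}

    if "simulate" in enabled:
        params = SimParams(seed=_child_seed(config.seed, "simulate"),
                           **config.sim)
        sim = run_to_size(params)
        ctx["sim"] = sim
        lat = out / "lattice.tsv"
        np.savetxt(lat, sim.lattice(), fmt="%d", delimiter="\t")
        growth = out / "growth.json"
        growth.write_text(json.dumps({
            "n_live": sim.n_live, "n_mutations": sim.n_mutations,
            "rim_fraction": spatial_growth_mode(sim),
            "subclone_freq": [sim.clone_frequency(1),
                              sim.clone_frequency(2)]}, indent=2))
        register("simulate", lattice=lat, growth=growth)

    if "sample" in enabled:
        scheme = SamplingScheme(**config.scheme)
        seed = _child_seed(config.seed, "sample")
        samples = synthetic_data.sample_tumour(ctx["sim"], scheme, seed=seed)
        vcs = synthetic_data.make_variant_call_set(
            ctx["sim"], samples, seed=seed + 1, p0=config.p0)
        ctx["samples"] = samples
        ctx["vcs"] = vcs
        counts = out / "allele_counts.tsv"
        vcs.to_tsv(counts)
        vcf = out / "variants.vcf"
        vcs.to_vcf(vcf)
        register("sample", allele_counts=counts, vcf=vcf)

    if "tree" in enabled:
        vcs = ctx["vcs"]
        deep = vcs.subset("deep")
        ccf = phylo_build.estimate_ccf(
            deep.y, deep.n, deep.purity[:, None], deep.c[None, :],
            deep.mult[None, :])
        mat = phylo_build.binarize(ccf, deep.sample_names,
                                   deep.mutation_ids,
                                   threshold=config.ccf_threshold)
        tree = phylo_build.ratchet_search(
            mat, seed=_child_seed(config.seed, "tree"), **config.ratchet)
        phylo_build.attach_edge_mutations(tree, mat)
        label_of = {s.name: s.region for s in ctx["samples"]}
        for tip in tree.tips():
            tip.label = label_of[tip.name]
        ctx["tree"] = tree
        ctx["matrix"] = mat
        nwk = out / "tree.nwk"
        nwk.write_text(tree.to_newick() + "\n")
        me = out / "edge_mutations.tsv"
        rows = []
        for i, e in enumerate(tree.edges()):
            for mid in sorted(e.muts or ()):
                rows.append((i, e.name or f"edge{i}", mid))
        pd.DataFrame(rows, columns=["edge_idx", "edge", "mutation_id"]
                     ).to_csv(me, sep="\t", index=False)
        stats_path = out / "tree_stats.tsv"
        pd.DataFrame({"stat": summary_labels(),
                      "value": tree_summary(tree)}
                     ).to_csv(stats_path, sep="\t", index=False)
        register("tree", newick=nwk, edge_mutations=me, stats=stats_path)

    if "place" in enabled:
        vcs = ctx["vcs"]
        tree = ctx["tree"]
        rows = []
        for i, s in enumerate(vcs.samples):
            if s.mode != "lowpass":
                continue
            model = SamplePlacement(tree, vcs.mutation_ids, vcs.y[i],
                                    vcs.n[i], c=vcs.c, mult=vcs.mult)
            res = model.fit()
            rows.append((s.name, s.region,
                         model._edge_name(res.edge), res.pi_m, res.rho,
                         res.p0, res.nll, res.status))
        placed = pd.DataFrame(rows, columns=[
            "sample", "region", "edge", "pi_m", "rho", "p0", "nll",
            "status"])
        ctx["placements"] = placed
        pth = out / "placements.tsv"
        placed.to_csv(pth, sep="\t", index=False)
        register("place", placements=pth)

    if "forest" in enabled:
        # graft each low-pass sample as a zero-length tip on its edge,
        # then impute terminal lengths from the deep samples per region
        from .lowpass_placement import edge_name
        from .trees import CloneNode
        tree = ctx["tree"].copy()
        by_name = {edge_name(e): e for e in tree.edges()}
        for row in ctx["placements"].itertuples(index=False):
            node = by_name.get(row.edge, tree.edges()[0])
            graft = CloneNode(name=row.sample, length=0.0, label=row.region)
            node.add_child(graft)
        region_counts: dict[str, list] = {}
        for tip in ctx["tree"].tips():
            region_counts.setdefault(tip.label, []).append(tip.length)
        lowpass = [s.name for s in ctx["samples"] if s.mode == "lowpass"]
        regions = {s.name: s.region for s in ctx["samples"]}
        forest = impute_leaf_forest(
            tree, region_counts, lowpass, regions,
            n_trees=config.n_forest,
            seed=_child_seed(config.seed, "forest"))
        ctx["forest"] = forest
        fpath = out / "forest.nwk"
        fpath.write_text("\n".join(t.to_newick() for t in forest) + "\n")
        register("forest", forest=fpath)

    if "expression" in enabled:
        forest = ctx["forest"]
        gt = synthetic_data.default_gene_table(**config.expression)
        expr, truth = synthetic_data.simulate_expression(
            forest[0], gt, seed=_child_seed(config.seed, "expression"))
        ctx["expression"] = expr
        epath = out / "expression.tsv"
        expr.to_csv(epath, sep="\t")
        tpath = out / "expression_truth.tsv"
        truth.to_csv(tpath, sep="\t", index=False)
        register("expression", matrix=epath, truth=tpath)

    if "signal" in enabled:
        tab = phylo_signal.forest_signal(ctx["forest"], ctx["expression"])
        ctx["signal"] = tab
        spath = out / "phylo_signal.tsv"
        tab.to_csv(spath, sep="\t")
        register("signal", table=spath)

    if "infer" in enabled:
        abc_cfg = dict(config.abc)
        models = abc_cfg.pop("models", ("neutral", "selected"))
        nll_reps = abc_cfg.pop("nll_reps", 60)
        cfg = evo_inference.ABCConfig(
            n_end=abc_cfg.pop("n_end", 400), **abc_cfg)
        target = evo_inference.simulate_one_summary(
            {"D": config.sim["D"], "log10_m": np.log10(config.sim["m"]),
             "d_push": float(config.sim["d_push"]),
             **({"lambda2": config.sim["lambda2"],
                 "log10_t2": np.log10(max(config.sim["t2"], 4))}
                if config.sim["lambda2"] > 1 else {})},
            cfg, seed=_child_seed(config.seed, "target"))
        tab, fits = evo_inference.fit_models(
            target, models, cfg, seed=_child_seed(config.seed, "infer"),
            nll_reps=nll_reps)
        ctx["aic"] = tab
        apath = out / "model_selection.tsv"
        tab.to_csv(apath, sep="\t", index=False)
        vpath = out / "verdict.json"
        vpath.write_text(json.dumps(
            {"best": tab.attrs["best"], "verdict": tab.attrs["verdict"]},
            indent=2))
        register("infer", aic_table=apath, verdict=vpath)

    if "eqtl" in enabled:
        from . import eqtl_stats
        cohort = synthetic_data.make_eqtl_cohort(
            seed=_child_seed(config.seed, "eqtl"), **config.eqtl)
        z, _ = eqtl_stats.zscore(cohort.expression)
        combos = eqtl_stats.eligible_combinations(cohort.mut, cohort.links)
        scr = eqtl_stats.screen(combos, z, cohort.mut, cohort.cna,
                                cohort.purity,
                                cohort.tumour_of != "normal")
        ctx["eqtl"] = scr
        qpath = out / "eqtl_screen.tsv"
        scr.table.to_csv(qpath, sep="\t", index=False)
        jpath = out / "eqtl_summary.json"
        jpath.write_text(json.dumps(scr.ratio_summary(), indent=2,
                                    default=float))
        register("eqtl", screen=qpath, summary=jpath)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable markdown summary of a completed run."""
    lines = ["# clonescape run report", ""]
    stages = manifest.get("stages", {})
    if not stages:
        return "\n".join(lines + ["(empty run: no stages executed)"])
    out = Path(manifest["config"]["out_dir"])
    if "infer" in stages:
        verdict = json.loads(Path(
            stages["infer"]["verdict"]["path"]).read_text())
        lines += [f"## Growth-model selection",
                  f"- best model: **{verdict['best']}** "
                  f"({verdict['verdict']} support)", ""]
    if "signal" in stages:
        tab = pd.read_csv(stages["signal"]["table"]["path"], sep="\t")
        n_sig = int(tab["signal"].sum())
        lines += ["## Phylogenetic signal",
                  f"- genes with signal (median p < 0.05): {n_sig} of "
                  f"{len(tab)}", ""]
    if "eqtl" in stages:
        summ = json.loads(Path(
            stages["eqtl"]["summary"]["path"]).read_text())
        lines += ["## Somatic eQTL screen",
                  f"- explained genes: {summ['n_explained_genes']} of "
                  f"{summ['n_genes']} ({summ['pct_explained_genes']:.1f}%)",
                  ""]
    missing = [s for s in STAGES if s not in stages]
    if missing:
        lines += [f"(stages not run: {', '.join(missing)})"]
    return "\n".join(lines)
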