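"""End-to-end workflow driver: wire the analysis stages together from a
single config mapping and write a reproducible report bundle.

Every stochastic stage draws from the single top-level seed; the JSON
summary embeds a hash of the config so outputs are traceable, and
re-running with the same config and seed reproduces it byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import alignments as aio
from . import amova as diff
from . import diversity as div
from . import imtests
from . import introgression as intro
from . import network as net
from . import simulate as sim

FIXTURES = {
    "taiwan_cp": sim.taiwan_cp_recipe,
    "taiwan_its": sim.taiwan_its_recipe,
    "philippines_cp": sim.philippines_cp_recipe,
    "philippines_its": sim.philippines_its_recipe,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: dict, outdir: Path):
    seed = int(config.get("seed", 0))
    src = config.get("input", {})
    if "fixture" in src:
        recipe = FIXTURES[src["fixture"]]()
        aln, smap, truth = sim.make_fixture(recipe, seed=seed)
        aio.write_alignment(aln, outdir / f"{src['fixture']}.fasta")
        aio.write_sample_map(smap, outdir / f"{src['fixture']}.samples.tsv")
        return aln, smap, truth
    if "fasta" in src:
        aln = aio.read_alignment(src["fasta"], src.get("ploidy_mode", "haploid"))
        smap = aio.read_sample_map(src["sample_map"])
        return aln, smap, None
    return None, None, None


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages and return the JSON-able summary.

    Recognised stages (all optional): ``stats``, ``diff``, ``network``,
    ``introgress``, ``lrt``, ``convert_im``.  Stage failures raise
    :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})
    summary: dict = {"config_hash": _config_hash(config), "seed": seed, "stages": {}}

    aln = smap = truth = None
    try:
        aln, smap, truth = _load_inputs(config, outdir)
    except Exception as e:                       # noqa: BLE001
        raise StageError("input", e) from e

    table = None
    if aln is not None and aln.records:
        table = aio.collapse_haplotypes(aln, smap, use_indel_chars=True)

    if "stats" in stages:
        try:
            summary["stages"]["stats"] = _run_stats(
                aln, smap, table, stages["stats"] or {}, seed, outdir)
        except Exception as e:                   # noqa: BLE001
            raise StageError("stats", e) from e
    if "diff" in stages:
        try:
            summary["stages"]["diff"] = _run_diff(
                aln, smap, stages["diff"] or {}, seed, outdir)
        except Exception as e:                   # noqa: BLE001
            raise StageError("diff", e) from e
    if "network" in stages:
        try:
            summary["stages"]["network"] = _run_network(
                aln, smap, table, stages["network"] or {}, outdir)
        except Exception as e:                   # noqa: BLE001
            raise StageError("network", e) from e
    if "introgress" in stages:
        try:
            summary["stages"]["introgress"] = _run_introgress(
                stages["introgress"] or {}, outdir)
        except Exception as e:                   # noqa: BLE001
            raise StageError("introgress", e) from e
    if "lrt" in stages:
        try:
            cfg = stages["lrt"] or {}
            rows = []
            for s in cfg.get("statistics", []):
                r = imtests.mixture_lrt_pvalue(float(s), alpha=cfg.get("alpha", 0.05))
                rows.append({"statistic": r.statistic,
                             "p_value": round(r.p_value, 3),
                             "critical_value": round(r.critical_value, 2),
                             "significant": bool(r.decision)})
            pd.DataFrame(rows).to_csv(outdir / "lrt.tsv", sep="\t", index=False)
            summary["stages"]["lrt"] = rows
        except Exception as e:                   # noqa: BLE001
            raise StageError("lrt", e) from e
    if "convert_im" in stages:
        try:
            cfg = stages["convert_im"] or {}
            scaling = imtests.ImScaling(
                mu_cp=cfg.get("mu_cp", 1.67e-6), mu_its=cfg.get("mu_its", 1.24e-6),
                generation_time=cfg.get("generation_time", 25.0))
            ne, years, meta = imtests.convert_im_estimates(
                cfg.get("q", []), cfg.get("t", []), scaling)
            summary["stages"]["convert_im"] = {"Ne": ne, "T_years": years, **meta}
        except Exception as e:                   # noqa: BLE001
            raise StageError("convert_im", e) from e

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    return summary


def _run_stats(aln, smap, table, cfg, seed, outdir):
    if aln is None:
        raise ValueError("stats stage needs input data")
    diploid = aln.ploidy_mode == "diploid_phased"
    pops = smap.set_index("sample_id")["population"]
    by_pop: dict[str, list[str]] = {}
    for rid, seq in aln.records:
        stem = aio.split_phase(rid)[0] if diploid else rid
        by_pop.setdefault(pops.loc[stem], []).append(seq)
    genotypes = div.genotypes_from_alignment(table, smap) if diploid else {}
    rows = []
    for pop in sorted(by_pop):
        seqs = by_pop[pop]
        hap_counts = table.counts[pop][table.counts[pop] > 0] if pop in table.counts else None
        res = div.diversity(seqs, list(hap_counts) if hap_counts is not None else None)
        row = {"population": pop, "n": len(seqs) if not diploid else len(seqs) // 2,
               "Hd": round(res.Hd, 3),
               "pi_x1000": round(1000 * res.pi_per_site, 3),
               "thetaW_x1000": round(1000 * res.thetaW_per_site, 3)}
        if diploid and pop in genotypes:
            hwe = div.hwe_exact_test(genotypes[pop],
                                     chain_steps=cfg.get("chain_steps", 200_000),
                                     burn_in=cfg.get("burn_in", 10_000),
                                     seed=seed)
            row["F_IS"] = None if hwe.F_IS is None else round(hwe.F_IS, 3)
            row["p_HWE"] = round(hwe.p_raw, 4)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if diploid and "p_HWE" in frame:
        adj = div.bonferroni(frame["p_HWE"].fillna(1.0), alpha=cfg.get("alpha", 0.05))
        frame["p_HWE_bonferroni"] = adj["p_adjusted"].round(4)
    frame.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    return json.loads(frame.to_json(orient="records"))


def _run_diff(aln, smap, cfg, seed, outdir):
    if aln is None:
        raise ValueError("diff stage needs input data")
    res = diff.amova(aln, smap, n_permutations=cfg.get("n_permutations", 2000),
                     seed=seed)
    res.table.to_csv(outdir / "amova.tsv", sep="\t", index=False)
    pm = diff.phist_matrix(aln, smap)
    pm.to_frame().to_csv(outdir / "phist.tsv", sep="\t")
    out = {"phi": {k: round(v, 4) for k, v in res.phi.items()},
           "p_values": res.p_values,
           "percent": [round(x, 1) for x in res.table["percent"]]}
    if len(pm.labels) >= 3:
        newick = diff.nj_tree(pm)
        (outdir / "nj.nwk").write_text(newick + "\n")
        out["nj_leaves"] = len(pm.labels)
    return out


def _run_network(aln, smap, table, cfg, outdir):
    if table is None:
        raise ValueError("network stage needs input data")
    limit = net.connection_limit(aln.length, cfg.get("p_threshold", 0.95),
                                 cfg.get("limit"))
    network = net.build_parsimony_network(table, limit)
    diploid = aln.ploidy_mode == "diploid_phased"
    assignment = net.classify_haplogroups(network, table, smap, diploid=diploid)
    network.to_edge_list().to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    assignment.sequence_table.to_csv(outdir / "haplogroups.tsv", sep="\t", index=False)
    out = {"limit": limit,
           "n_haplotypes": table.n_haplotypes,
           "n_components": len(network.components()),
           "haplogroup_sizes": assignment.sequence_table["haplogroup"]
           .value_counts().sort_index().to_dict()}
    counting = cfg.get("count_introgressed")
    if counting:
        count, total, percent = net.count_introgressed(
            assignment, counting["focal_taxon"], counting["donor_haplogroup"])
        out["introgressed"] = {"count": count, "total": total, "percent": percent}
    return out


def _run_introgress(cfg, outdir):
    params = intro.IntrogressionParams(
        mode=cfg.get("mode", "seed"), rate=float(cfg.get("rate", 0.01)),
        phi_e=float(cfg.get("phi_e", 0.5)), phi_l=float(cfg.get("phi_l", 0.5)),
        generations=int(cfg.get("generations", 40)))
    traj = intro.trajectory(params)
    traj.to_csv(outdir / "introgression_trajectory.tsv", sep="\t", index=False)
    end = traj.iloc[-1]
    return {"mode": params.mode, "rate": params.rate, "phi_e": params.phi_e,
            "generations": params.generations,
            "L_cp": round(float(end["L_cp"]), 6),
            "L_nuc": round(float(end["L_nuc"]), 6)}
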