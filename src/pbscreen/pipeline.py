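"""End-to-end orchestration: simulate -> trim -> call sites -> quantify ->
enrich -> survival -> DGE -> ORA/hubs -> report.

A single JSON config drives every stage; all thresholds default to the
study's (|log2FC| > 1, -log10 adjusted p > 2, adjusted p < 0.01) and every
random draw is derived from one seed, so a rerun with the same config is
bit-identical. Each stage writes plain-text artifacts into the run
directory; a manifest records seeds and SHA-256 checksums; stage failures
halt the run naming the stage, keeping partial outputs on disk.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pbscreen import dge, enrichment, pathway, sites, survival, synthetic, trim
from pbscreen.errors import PbscreenError, SchemaError

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "genome": {"n_genes": 150, "length": 300000, "gene_length": 1200},
    "library": {"n_clones": 5000, "abundance_scale": 20.0},
    "selection": {
        "doses": [0, 5, 10],
        "base_survival": {"0": 1.0, "5": 0.01, "10": 0.01},
        "n_resistance_genes": 20,
        "resistance_boost": 10.0,
    },
    "reads": {"read_len": 125, "depth": 1.0, "frag_min": 60, "frag_max": 300},
    "trim": {"max_tag_mismatches": 2, "min_flank_len": 20},
    "sites": {"snap_tolerance": 2},
    "thresholds": {"lfc": 1.0, "logp": 2.0, "alpha": 0.01},
    "survival": {
        "n_samples": 95,
        "signature_genes": ["ZNF720", "REEP3", "CNNM2", "CGREF1"],
        "true_beta": [0.4193, 0.1222, 0.1394, 0.291],
        "n_noise_genes": 16,
        "censor_frac": 0.4,
        "roc_horizon_years": 3.0,
    },
    "pathway": {"gmt": None, "ppi": None, "hub_method": "MCC"},
}


class PipelineError(PbscreenError):
    """A stage failed; the message names the stage."""


def validate_config(config: dict) -> dict:
    """Merge onto defaults, rejecting unknown keys with their dotted path."""

    def merge(defaults, user, path=""):
        if not isinstance(user, dict):
            raise SchemaError(f"config section {path or '<root>'} must be an object")
        out = copy.deepcopy(defaults)
        for key, val in user.items():
            if key not in defaults:
                raise SchemaError(f"unknown config key {path + key!r}")
            if isinstance(defaults[key], dict) and key != "base_survival":
                out[key] = merge(defaults[key], val, path + key + ".")
            else:
                out[key] = copy.deepcopy(val)
        return out

    return merge(DEFAULT_CONFIG, config or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seeds(seed: int, n: int = 16) -> list[int]:
    """Independent per-stage seeds below 2**31 from one root seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run every stage, returning a dict of headline results.

    Writes all stage artifacts plus ``results.json``, ``manifest.json`` and
    ``report.md`` under ``outdir``.
    """
    cfg = validate_config(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(int(cfg["seed"]))
    results: dict = {"config": cfg}
    artifacts: list[Path] = []
    stage = "setup"

    def register(path: Path) -> Path:
        artifacts.append(path)
        return path

    try:
        # ---------------- screen arm ----------------
        stage = "simulate_genome"
        g = cfg["genome"]
        genome = synthetic.generate_genome(
            g["n_genes"], g["length"], seeds[0], gene_length=g["gene_length"]
        )
        genome.to_fasta(register(out / "genome.fasta"))
        genome.genes_to_bed(register(out / "genes.bed"))

        stage = "simulate_library"
        rng = np.random.default_rng(seeds[1])
        gene_ids = [gm.gene_id for gm in genome.genes]
        n_res = cfg["selection"]["n_resistance_genes"]
        resistance = set(rng.choice(gene_ids, size=n_res, replace=False).tolist())
        sel_cfg = synthetic.SelectionConfig(
            doses=list(cfg["selection"]["doses"]),
            base_survival={
                int(k): float(v) for k, v in cfg["selection"]["base_survival"].items()
            },
            resistance_genes=resistance,
            resistance_boost=float(cfg["selection"]["resistance_boost"]),
            rng_seed=seeds[2],
        )
        sel_cfg.to_json(register(out / "selection_config.json"))
        library = synthetic.simulate_library(
            genome,
            cfg["library"]["n_clones"],
            seeds[3],
            abundance_scale=cfg["library"]["abundance_scale"],
        )

        stage = "simulate_reads"
        lib_names = {d: f"C{d}L" for d in sel_cfg.doses}
        tag_cfg = trim.TagLibraryConfig(
            max_tag_mismatches=cfg["trim"]["max_tag_mismatches"],
            min_flank_len=cfg["trim"]["min_flank_len"],
        )
        fastqs: dict[str, Path] = {}
        selected: dict[str, list[synthetic.Clone]] = {}
        for i, dose in enumerate(sel_cfg.doses):
            name = lib_names[dose]
            clones = synthetic.apply_selection(library, genome, sel_cfg, dose)
            selected[name] = clones
            synthetic.clones_to_tsv(clones, register(out / f"{name}.clones.tsv"))
            r1, r2 = synthetic.simulate_reads(
                clones,
                genome,
                seeds[4] + i,
                read_len=cfg["reads"]["read_len"],
                depth=cfg["reads"]["depth"],
                frag_min=cfg["reads"]["frag_min"],
                frag_max=cfg["reads"]["frag_max"],
            )
            p1 = register(out / f"{name}.R1.fastq")
            p2 = register(out / f"{name}.R2.fastq")
            synthetic.write_fastq(r1, p1)
            synthetic.write_fastq(r2, p2)
            fastqs[name] = p1

        stage = "trim"
        fragments: dict[str, list[trim.JunctionFragment]] = {}
        for name, fq in fastqs.items():
            frags, qc = trim.process_fastq_pair(fq, out / f"{name}.R2.fastq", tag_cfg)
            fragments[name] = frags
            qc.to_tsv(register(out / f"{name}.trim_qc.tsv"))

        stage = "call_sites"
        tol = cfg["sites"]["snap_tolerance"]
        all_sites: dict[str, list[sites.InsertionSite]] = {}
        library_sizes: dict[str, int] = {}
        for name, frags in fragments.items():
            alns, astats = sites.align_fragments(frags, genome)
            library_sizes[name] = astats.mapped
            side_of = {f.read_id: f.side for f in frags}
            per_side = []
            for side in ("PB5", "PB3"):
                side_alns = [a for a in alns if side_of[a.read_id] == side]
                called, _ = sites.call_sites(side_alns, genome, side, name, tol)
                per_side.append(called)
            all_sites[name] = sites.merge_sites(*per_side)
            sites.sites_to_bed(all_sites[name], register(out / f"{name}.sites.bed"))

        stage = "quantify"
        merged = sites.merge_sites(*all_sites.values())
        matrix = sites.assign_to_genes(merged, genome.genes, library_sizes)
        matrix.to_tsv(register(out / "gene_counts.tsv"))
        coverage = matrix.mutant_gene_counts()
        corr, order = sites.library_correlation(matrix)
        corr.to_csv(register(out / "library_correlation.tsv"), sep="\t")
        results["mutant_gene_counts"] = coverage.to_dict()
        results["library_sizes"] = library_sizes
        results["correlation_order"] = order

        stage = "enrich"
        ctrl = lib_names[sel_cfg.doses[0]]
        up_sets, labels = [], []
        results["enrichment"] = {}
        for dose in sel_cfg.doses[1:]:
            name = lib_names[dose]
            records = enrichment.enrichment_test(matrix, ctrl, name)
            records = enrichment.classify_volcano(
                records, cfg["thresholds"]["lfc"], cfg["thresholds"]["logp"]
            )
            frame = enrichment.records_to_frame(records)
            frame.to_csv(register(out / f"enrichment_{name}.tsv"), sep="\t", index=False)
            up = {r.gene_id for r in records if r.status == "up"}
            down = {r.gene_id for r in records if r.status == "down"}
            up_sets.append(up)
            labels.append(name)
            results["enrichment"][name] = {
                "n_tested": len(records),
                "n_up": len(up),
                "n_down": len(down),
                "n_planted_up": len(up & resistance),
                "n_planted_down": len(down & resistance),
            }
        overlap = enrichment.overlap_genes(*up_sets, labels=labels)
        pd.Series(overlap.intersection, name="gene_id").to_csv(
            register(out / "overlap_genes.tsv"), sep="\t", index=False
        )
        results["overlap_genes"] = overlap.intersection
        results["resistance_genes"] = sorted(resistance)
        planted_up = [gid for gid in sorted(resistance) if gid in set(overlap.intersection)]
        results["planted_recovered_in_overlap"] = planted_up
        results["planted_recovery_fraction"] = (
            len(planted_up) / len(resistance) if resistance else float("nan")
        )

        # ---------------- survival arm ----------------
        stage = "survival_cohort"
        sv = cfg["survival"]
        sig_genes = list(sv["signature_genes"])
        noise = [f"N{i + 1:03d}" for i in range(sv["n_noise_genes"])]
        cohort = synthetic.simulate_survival_cohort(
            sv["n_samples"],
            len(sig_genes) + len(noise),
            sv["true_beta"],
            sv["censor_frac"],
            seeds[8],
            gene_ids=sig_genes + noise,
        )
        expr = cohort.expression
        expr.rename_axis("gene_id").to_csv(register(out / "cohort_expression.tsv"), sep="\t")
        cohort.survival_frame().to_csv(
            register(out / "cohort_survival.tsv"), sep="\t", index=False
        )

        stage = "survival_model"
        model = survival.fit_cox(
            cohort.time_years, cohort.event, expr.loc[sig_genes].T
        )
        model.to_json(register(out / "cox_model.json"))
        scores, groups = survival.risk_score(model, expr)
        hi = groups == "high"
        chi2, logrank_p = survival.logrank_test(
            cohort.time_years[hi.to_numpy()],
            cohort.event[hi.to_numpy()],
            cohort.time_years[~hi.to_numpy()],
            cohort.event[~hi.to_numpy()],
        )
        auc = survival.td_roc_auc(
            cohort.time_years, cohort.event, scores, sv["roc_horizon_years"]
        )
        km_hi = survival.km_estimate(
            cohort.time_years[hi.to_numpy()], cohort.event[hi.to_numpy()]
        )
        km_lo = survival.km_estimate(
            cohort.time_years[~hi.to_numpy()], cohort.event[~hi.to_numpy()]
        )
        km_hi.to_frame().to_csv(register(out / "km_high.tsv"), sep="\t", index=False)
        km_lo.to_frame().to_csv(register(out / "km_low.tsv"), sep="\t", index=False)
        five = survival.five_group_assign(expr, sig_genes)
        pd.DataFrame(
            {"sample_id": scores.index, "risk_score": scores.values,
             "risk_group": groups.values, "five_group": five.values}
        ).to_csv(register(out / "risk_groups.tsv"), sep="\t", index=False)
        results["cox_model"] = model.to_dict()
        results["logrank"] = {"chi2": chi2, "p": logrank_p}
        results["td_auc"] = auc
        results["five_group_counts"] = five.value_counts().to_dict()

        stage = "dge"
        case, ctrl_grp = "Four_genes_high", "Low_group"
        n_case = int((five == case).sum())
        n_ctrl = int((five == ctrl_grp).sum())
        if n_case >= 2 and n_ctrl >= 2:
            mask = five.isin([case, ctrl_grp])
            deg_records = dge.moderated_de_test(
                expr.loc[:, mask.index[mask]], five[mask], case, ctrl_grp
            )
            deg_records = dge.classify_deg(
                deg_records, cfg["thresholds"]["lfc"], cfg["thresholds"]["logp"]
            )
            dge.records_to_frame(deg_records).to_csv(
                register(out / "dge.tsv"), sep="\t", index=False
            )
            deg_up = {r.gene_id for r in deg_records if r.status == "up"}
            deg_down = {r.gene_id for r in deg_records if r.status == "down"}
        else:
            deg_records, deg_up, deg_down = [], set(), set()
        results["dge"] = {
            "n_case": n_case,
            "n_control": n_ctrl,
            "n_up": len(deg_up),
            "n_down": len(deg_down),
        }

        stage = "pathway"
        universe = set(expr.index)
        if cfg["pathway"]["gmt"]:
            gene_sets = pathway.read_gmt(cfg["pathway"]["gmt"])
        else:
            gene_sets = _demo_gene_sets(sig_genes, noise)
        ora = pathway.ora_test(deg_up & universe, universe, gene_sets)
        pathway.ora_to_frame(ora).to_csv(
            register(out / "ora.tsv"), sep="\t", index=False
        )
        if cfg["pathway"]["ppi"]:
            graph = pathway.read_edge_list(cfg["pathway"]["ppi"])
        else:
            graph = _demo_ppi(sig_genes, noise, seeds[9])
        sub = pathway.extract_subnetwork(graph, deg_up | set(sig_genes))
        hubs = pathway.hub_scores(sub, cfg["pathway"]["hub_method"])
        hubs.rename("score").rename_axis("gene_id").to_csv(
            register(out / "hub_scores.tsv"), sep="\t"
        )
        results["top_terms"] = [r.term_id for r in ora[:3]]
        results["top_hubs"] = list(hubs.index[:5])
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "report"
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=str)
    artifacts.append(out / "results.json")
    manifest = {
        "seed": cfg["seed"],
        "derived_seeds": seeds,
        "stages_completed": True,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    write_report(out)
    return results


def _demo_gene_sets(sig_genes, noise) -> list[pathway.GeneSet]:
    """Synthetic annotation sets over the cohort's genes (no database)."""
    half = max(1, len(noise) // 2)
    return [
        pathway.GeneSet("SIG_MODULE", "signature module", set(sig_genes)),
        pathway.GeneSet(
            "SIG_PLUS", "signature plus neighbors", set(sig_genes) | set(noise[:half])
        ),
        pathway.GeneSet("BACKGROUND", "background genes", set(noise)),
    ]


def _demo_ppi(sig_genes, noise, seed: int):
    """Synthetic interaction network: signature clique plus sparse noise."""
    import itertools

    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(sig_genes)
    g.add_nodes_from(noise)
    g.add_edges_from(itertools.combinations(sig_genes, 2))
    for a in noise:
        for b in sig_genes:
            if rng.random() < 0.2:
                g.add_edge(a, b)
    return g


def write_report(run_dir) -> Path:
    """Assemble report.md from the stage artifacts in a run directory.

    Counts in the report are recomputed from the TSVs on disk so that the
    report always cross-foots with the stage outputs.
    """
    run = Path(run_dir)
    lines = ["# pbscreen run report", ""]
    res_path = run / "results.json"
    if not res_path.exists():
        lines.append("No data: results.json missing.")
        (run / "report.md").write_text("\n".join(lines) + "\n")
        return run / "report.md"
    results = json.loads(res_path.read_text())

    lines.append("## Library gene coverage")
    counts_path = run / "gene_counts.tsv"
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        for lib in counts.columns:
            lines.append(f"- {lib}: {(counts[lib] > 0).sum()} genes with insertions")
    else:
        lines.append("No data.")

    lines.append("")
    lines.append("## Library correlation (Pearson on log2 CPM)")
    corr_path = run / "library_correlation.tsv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, sep="\t", index_col=0)
        lines.append(corr.round(3).to_string())
    else:
        lines.append("No data.")

    lines.append("")
    lines.append("## Enrichment and overlap")
    n_over = None
    over_path = run / "overlap_genes.tsv"
    for f in sorted(run.glob("enrichment_*.tsv")):
        tab = pd.read_csv(f, sep="\t")
        lines.append(
            f"- {f.stem.removeprefix('enrichment_')}: "
            f"{(tab['status'] == 'up').sum()} up, "
            f"{(tab['status'] == 'down').sum()} down of {len(tab)} tested"
        )
    if over_path.exists():
        over = pd.read_csv(over_path, sep="\t")
        n_over = len(over)
        lines.append(f"- overlap: {n_over} genes up in every screened library")
    if n_over is None:
        lines.append("No data.")

    lines.append("")
    lines.append("## Survival model")
    cox_path = run / "cox_model.json"
    if cox_path.exists():
        cox = json.loads(cox_path.read_text())
        for gid, row in cox["genes"].items():
            lines.append(
                f"- {gid}: beta={row['beta']:.4f} (SE {row['se']:.4f}), "
                f"HR={row['hr']:.3f} [{row['ci95'][0]:.3f}, {row['ci95'][1]:.3f}]"
            )
        lines.append(f"- logPL={cox['log_partial_likelihood']:.4f}, AIC={cox['aic']:.4f}")
        lines.append(f"- log-rank high vs low risk: p={results['logrank']['p']:.3g}")
        if results.get("td_auc") is not None:
            lines.append(f"- time-dependent AUC: {results['td_auc']:.3f}")
        fg = results.get("five_group_counts", {})
        if fg:
            lines.append(
                "- five-group sizes: "
                + ", ".join(f"{k}={v}" for k, v in sorted(fg.items()))
            )
    else:
        lines.append("No data.")

    lines.append("")
    lines.append("## Differential expression, ORA, hubs")
    dge_path = run / "dge.tsv"
    if dge_path.exists():
        tab = pd.read_csv(dge_path, sep="\t")
        lines.append(
            f"- DEGs Four_genes_high vs Low_group: "
            f"{(tab['status'] == 'up').sum()} up, {(tab['status'] == 'down').sum()} down"
        )
    else:
        lines.append("- DEG comparison skipped (a group had < 2 samples).")
    ora_path = run / "ora.tsv"
    if ora_path.exists():
        tab = pd.read_csv(ora_path, sep="\t")
        if len(tab):
            top = tab.iloc[0]
            lines.append(
                f"- top ORA term: {top['term_id']} (k={top['k']}/{top['K']}, "
                f"p={top['p']:.3g})"
            )
    hubs_path = run / "hub_scores.tsv"
    if hubs_path.exists():
        tab = pd.read_csv(hubs_path, sep="\t")
        if len(tab):
            lines.append(
                "- top hubs: "
                + ", ".join(
                    f"{r.gene_id} ({r.score:.0f})" for r in tab.head(5).itertuples()
                )
            )

    path = run / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
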