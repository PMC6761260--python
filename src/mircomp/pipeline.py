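"""Pipeline stages over files.

Each stage reads the standard-format inputs under ``<out>/input`` plus the
TSV outputs of upstream stages, and writes its own TSV/JSON outputs into
``<out>``.  Stages are deterministic given the same configuration and
seed; all tables are written sorted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, catalog, clusters, expression, simulate, stats, targets
from .io import read_alignment, read_annotation, read_bed, read_fasta
from .tree import read_newick

log = logging.getLogger("mircomp")

STAGE_ORDER = [
    "simulate", "families", "conserve", "gainloss", "clusters", "targets",
    "spatial", "express", "correlate", "emerge", "enrich", "report",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": STAGE_ORDER,
    "simulate": {},  # SimulationConfig overrides
    "families": {"min_identity": 0.85, "min_cols": 16},
    "known": {"min_identity": 0.9},
    "clusters": {"max_gap": 5000},
    "spatial": {"lo": 0.1, "hi": 0.9, "n_grid": 512},
    "correlate": {"transform": "log2p1", "significant_only": False,
                  "alpha": 0.05},
    "emerge": {"top_fraction": 0.05},
}


class MissingUpstream(RuntimeError):
    pass


def merge_config(user: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingUpstream(
            f"missing {path.name}: run the '{produced_by}' stage first"
        )
    return path


def _log_stage(out: Path, stage: str, cfg: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pipeline.log", "a") as fh:
        fh.write(json.dumps({
            "stage": stage, "mircomp": __version__, "seed": cfg.get("seed"),
            "params": cfg.get(stage, {}),
        }, sort_keys=True) + "\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------


def stage_simulate(out: Path, cfg: dict) -> None:
    _log_stage(out, "simulate", cfg)
    overrides = dict(cfg.get("simulate") or {})
    overrides.setdefault("rng_seed", cfg["seed"])
    sim_cfg = simulate.SimulationConfig.from_dict(overrides)
    study = simulate.simulate_study(sim_cfg)
    simulate.write_study(study, out / "input")
    log.info("simulate: %d matures, %d genes", len(study.matures),
             len(study.truth.genes))


def _load_matures(input_dir: Path) -> list:
    mature_dir = _require(input_dir / "mature", "simulate")
    out = []
    for fa in sorted(mature_dir.glob("*.fa")):
        species = fa.stem
        for mid, seq in read_fasta(fa, alphabet="rna").items():
            out.append(catalog.MatureMiRNA(id=mid, species=species, sequence=seq))
    return out


def stage_families(out: Path, cfg: dict) -> None:
    _log_stage(out, "families", cfg)
    matures = _load_matures(out / "input")
    fp = cfg["families"]
    assignment = catalog.build_families(
        matures, min_identity=fp["min_identity"], min_cols=fp["min_cols"]
    )
    catalog.assign_isomirs(assignment, matures)
    by_id = {m.id: m for m in matures}
    rows = [
        {"mature_id": m.id, "species": m.species,
         "family_id": assignment.family_of[m.id],
         "gene_id": assignment.gene_of[m.id], "seed": m.seed,
         "variable": int(assignment.variable[assignment.gene_of[m.id]])}
        for m in sorted(matures, key=lambda m: m.id)
    ]
    pd.DataFrame(rows).to_csv(out / "families.tsv", sep="\t", index=False)
    ref_path = out / "input" / "reference.fa"
    if ref_path.exists():
        reference = read_fasta(ref_path, alphabet="rna")
        members = {}
        for mid, gid in assignment.gene_of.items():
            members.setdefault(gid, []).append(by_id[mid])
        status = catalog.annotate_known(
            members, reference, min_identity=cfg["known"]["min_identity"]
        )
        pd.DataFrame(
            sorted(status.items()), columns=["gene_id", "status"]
        ).to_csv(out / "known.tsv", sep="\t", index=False)


def _load_families(out: Path) -> pd.DataFrame:
    return pd.read_csv(_require(out / "families.tsv", "families"), sep="\t")


def stage_conserve(out: Path, cfg: dict) -> None:
    _log_stage(out, "conserve", cfg)
    fam = _load_families(out)
    tree = read_newick(_require(out / "input" / "tree.nwk", "simulate"))
    gene_species = {
        g: set(sub["species"]) for g, sub in fam.groupby("gene_id")
    }
    classes = catalog.classify_conservation(gene_species, tree)
    rows = [
        {"gene_id": g, "class": classes.class_of[g],
         "n_species": len(classes.presence[g]),
         "species": ",".join(sorted(classes.presence[g]))}
        for g in sorted(classes.class_of)
    ]
    pd.DataFrame(rows).to_csv(out / "conservation.tsv", sep="\t", index=False)

    variable_of = dict(zip(fam["gene_id"], fam["variable"].astype(bool)))
    assignment = catalog.FamilyAssignment(
        family_of={}, gene_of=dict(zip(fam["mature_id"], fam["gene_id"])),
        variable=variable_of,
    )
    table, pct = catalog.variability_table(classes, assignment)
    summary = {"class_counts": classes.counts(),
               "variability_table": table.tolist(),
               "variability_row_pct": [None if np.isnan(p) else p for p in pct]}
    if table.sum(axis=1).min() > 0 and np.asarray(table).sum(axis=0).min() > 0:
        res = stats.chi2_2x2(table, yates=True)
        summary["variability_chi2"] = {
            "statistic": res.statistic, "df": res.df, "p": res.p_value,
            "method": res.method,
        }
    known_path = out / "known.tsv"
    if known_path.exists():
        known = pd.read_csv(known_path, sep="\t")
        status = dict(zip(known["gene_id"], known["status"]))
        n_known, n_cons, pct = catalog.known_share(classes.class_of, status)
        summary["known_share_conserved"] = {
            "n_known": n_known, "n_conserved": n_cons, "pct": pct,
        }
    _write_json(summary, out / "conservation_summary.json")


def stage_gainloss(out: Path, cfg: dict) -> None:
    _log_stage(out, "gainloss", cfg)
    cons = pd.read_csv(_require(out / "conservation.tsv", "conserve"), sep="\t")
    tree = read_newick(_require(out / "input" / "tree.nwk", "simulate"))
    rows = []
    for _, rec in cons.sort_values("gene_id").iterrows():
        presence = {t: False for t in tree.tip_names}
        for sp in str(rec["species"]).split(","):
            presence[sp] = True
        gain, losses, n_events = catalog.dollo_gain_loss(tree, presence)
        rows.append({"gene_id": rec["gene_id"], "gain_branch": gain,
                     "loss_branches": ";".join(losses), "n_events": n_events})
    pd.DataFrame(rows).to_csv(out / "gainloss.tsv", sep="\t", index=False)


def stage_clusters(out: Path, cfg: dict) -> None:
    _log_stage(out, "clusters", cfg)
    input_dir = out / "input"
    coords_dir = _require(input_dir / "coords", "simulate")
    fam = _load_families(out)
    cons = pd.read_csv(_require(out / "conservation.tsv", "conserve"), sep="\t")
    class_of_gene = dict(zip(cons["gene_id"], cons["class"]))
    gene_of_mature = dict(zip(fam["mature_id"], fam["gene_id"]))
    pm = pd.read_csv(_require(input_dir / "premirna_matures.tsv", "simulate"),
                     sep="\t")
    class_of_pre = {}
    for _, rec in pm.iterrows():
        first = rec["mature_ids"].split(",")[0]
        class_of_pre[rec["premirna_id"]] = class_of_gene[gene_of_mature[first]]

    prems = []
    for bed in sorted(coords_dir.glob("*.bed")):
        species = bed.stem
        for name, iv in read_bed(bed):
            prems.append(catalog.PreMiRNA(id=name, species=species, interval=iv))
    cs = clusters.detect_clusters(prems, max_gap=cfg["clusters"]["max_gap"])
    clusters.label_clusters(cs, class_of_pre)
    rows = [
        {"cluster_id": f"cl{idx:04d}", "scaffold": c.scaffold,
         "strand": c.strand, "start": c.start, "end": c.end,
         "n": len(c.members), "density": c.density,
         "class_label": c.class_label, "members": ",".join(c.members)}
        for idx, c in enumerate(cs.clusters)
    ]
    pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)

    # conserved vs everything-else, as the cluster comparison pools
    # non-conserved with species-specific precursors
    two_way = {p: ("conserved" if c == "conserved" else "non-conserved")
               for p, c in class_of_pre.items()}
    tests: dict = {}
    try:
        table, res = clusters.clustered_fraction_test(two_way, cs)
        tests["clustered_fraction"] = {
            "table": table,
            "pct_conserved_clustered": round(100 * table[0][0] / sum(table[0]), 2),
            "pct_nonconserved_clustered": round(100 * table[1][0] / sum(table[1]), 2),
            "chi2": res.statistic, "p": res.p_value, "method": res.method,
        }
    except ValueError as exc:
        tests["clustered_fraction"] = {"error": str(exc)}
    dens = {"conserved": [], "non-conserved": []}
    for c in cs.clusters:
        if c.class_label in dens:
            dens[c.class_label].append(c.density)
    if len(dens["conserved"]) >= 2 and len(dens["non-conserved"]) >= 2:
        t = clusters.density_comparison(dens["conserved"], dens["non-conserved"])
        tests["density_comparison"] = {
            "mean_conserved": float(np.mean(dens["conserved"])),
            "mean_nonconserved": float(np.mean(dens["non-conserved"])),
            "t": t.statistic, "df": t.df, "p": t.p_value,
        }
    _write_json(tests, out / "cluster_tests.json")


def _mirnas_by_species(fam: pd.DataFrame, matures_seq: dict):
    """species -> sorted [(gene id, representative mature sequence)].

    Target match strings depend only on nucleotides 2-8, which isomiRs
    share, so the lexicographically first member is representative.
    """
    out: dict[str, list] = {}
    for (species, gene), sub in fam.groupby(["species", "gene_id"]):
        mid = sorted(sub["mature_id"])[0]
        out.setdefault(species, []).append((gene, matures_seq[mid]))
    for species in out:
        out[species].sort()
    return out


def stage_targets(out: Path, cfg: dict) -> None:
    _log_stage(out, "targets", cfg)
    input_dir = out / "input"
    utr_dir = _require(input_dir / "utr", "simulate")
    fam = _load_families(out)
    matures_seq = {
        m.id: m.sequence for m in _load_matures(input_dir)
    }
    by_species = _mirnas_by_species(fam, matures_seq)
    site_rows = []
    len_rows = []
    for fa in sorted(utr_dir.glob("*.fa")):
        gene = fa.stem
        aln = read_alignment(fa)
        sites = targets.scan_alignment(gene, aln, by_species)
        targets.call_site_conservation(sites, aln)
        for s in sites:
            site_rows.append({
                "gene_id": s.gene_id, "species": s.species, "mirna": s.mirna_id,
                "site_type": s.site_type, "start": s.start, "length": s.length,
                "col_first": s.alignment_cols[0], "col_last": s.alignment_cols[1],
                "relative_position": s.relative_position,
                "conserved_site": int(s.conserved_site),
            })
        for sp in aln.species:
            len_rows.append({"gene_id": gene, "species": sp,
                             "utr_length": aln.ungapped_length(sp)})
    pd.DataFrame(site_rows).sort_values(
        ["gene_id", "species", "mirna", "start"]
    ).to_csv(out / "sites.tsv", sep="\t", index=False)
    pd.DataFrame(len_rows).to_csv(out / "utr_lengths.tsv", sep="\t", index=False)


def stage_spatial(out: Path, cfg: dict) -> None:
    _log_stage(out, "spatial", cfg)
    sites = pd.read_csv(_require(out / "sites.tsv", "targets"), sep="\t")
    lengths = pd.read_csv(_require(out / "utr_lengths.tsv", "targets"), sep="\t")
    mean_len = lengths.groupby("gene_id")["utr_length"].mean().to_dict()
    long_set, short_set = targets.split_by_length(mean_len)
    sp = cfg["spatial"]
    result: dict = {}
    for site_set, sub in [
        ("all_sites", sites),
        ("conserved_sites", sites[sites["conserved_site"] == 1]),
    ]:
        for gene_set, genes_sel in [("all", None), ("long", long_set),
                                    ("short", short_set)]:
            data = sub if genes_sel is None else sub[sub["gene_id"].isin(genes_sel)]
            pos = data["relative_position"].to_numpy()
            key = f"{site_set}.{gene_set}"
            if np.unique(pos).size < 2:
                result[key] = None
                continue
            grid, density = targets.spatial_profile(pos, n_grid=sp["n_grid"])
            slope, intercept = targets.density_slope(
                grid, density, lo=sp["lo"], hi=sp["hi"]
            )
            result[key] = {"slope": slope, "intercept": intercept,
                           "n_sites": int(pos.size)}
    _write_json(result, out / "spatial.json")


def stage_express(out: Path, cfg: dict) -> None:
    _log_stage(out, "express", cfg)
    expr_dir = _require(out / "input" / "expr", "simulate")
    mirna = pd.read_csv(expr_dir / "mirna_counts.tsv", sep="\t", index_col=0)
    mrna = pd.read_csv(expr_dir / "mrna_counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(expr_dir / "mrna_lengths.tsv", sep="\t",
                          index_col=0)["length"].to_dict()
    expression.rpm_normalize(mirna).to_csv(out / "mirna_rpm.tsv", sep="\t")
    expression.tpm_normalize(mrna, lengths).to_csv(out / "mrna_tpm.tsv", sep="\t")


def _conserved_pairs(sites: pd.DataFrame, tips) -> list:
    """(miRNA gene, target gene) pairs with a site in every species."""
    need = set(tips)
    got: dict[tuple, set] = {}
    for rec in sites.itertuples():
        got.setdefault((rec.mirna, rec.gene_id), set()).add(rec.species)
    return sorted(p for p, sps in got.items() if need <= sps)


def stage_correlate(out: Path, cfg: dict) -> None:
    _log_stage(out, "correlate", cfg)
    mirna = pd.read_csv(_require(out / "mirna_rpm.tsv", "express"),
                        sep="\t", index_col=0)
    mrna = pd.read_csv(_require(out / "mrna_tpm.tsv", "express"),
                       sep="\t", index_col=0)
    sites = pd.read_csv(_require(out / "sites.tsv", "targets"), sep="\t")
    tree = read_newick(_require(out / "input" / "tree.nwk", "simulate"))
    samples = pd.read_csv(out / "input" / "expr" / "samples.tsv", sep="\t")
    species_of_sample = dict(zip(samples["sample"], samples["species"]))
    cc = cfg["correlate"]
    pairs = _conserved_pairs(sites, tree.tip_names)

    corr = expression.pair_correlations(mirna, mrna, pairs,
                                        transform=cc["transform"])
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    rs = corr["r"]
    if cc["significant_only"]:
        rs = corr.loc[corr["p"] < cc["alpha"], "r"]

    mirna_sp = expression.species_means(mirna, species_of_sample,
                                        transform=cc["transform"])
    mrna_sp = expression.species_means(mrna, species_of_sample,
                                       transform=cc["transform"])
    pic_corr = expression.pic_pair_correlations(mirna_sp, mrna_sp, pairs, tree)
    pic_corr.to_csv(out / "pic_correlations.tsv", sep="\t", index=False)

    def bias(values):
        try:
            n_neg, n_pos, res = expression.sign_bias_test(values)
        except ValueError as exc:
            return {"error": str(exc)}
        return {"n_negative": n_neg, "n_positive": n_pos,
                "chi2": res.statistic, "p": res.p_value}

    _write_json({
        "raw": bias(rs.tolist()),
        "pic": bias(pic_corr["r"].tolist()),
        "n_pairs": len(pairs),
    }, out / "sign_bias.json")


def stage_emerge(out: Path, cfg: dict) -> None:
    _log_stage(out, "emerge", cfg)
    sites = pd.read_csv(_require(out / "sites.tsv", "targets"), sep="\t")
    cons = pd.read_csv(_require(out / "conservation.tsv", "conserve"), sep="\t")
    lengths = pd.read_csv(_require(out / "utr_lengths.tsv", "targets"), sep="\t")
    class_of = dict(zip(cons["gene_id"], cons["class"]))
    utr_lengths: dict[str, dict[str, int]] = {}
    for rec in lengths.itertuples():
        utr_lengths.setdefault(rec.gene_id, {})[rec.species] = rec.utr_length
    site_objs = [
        targets.TargetSite(
            gene_id=r.gene_id, species=r.species, mirna_id=r.mirna,
            site_type=r.site_type, start=r.start, length=r.length,
        )
        for r in sites.itertuples()
    ]
    records = targets.emergence_rates(site_objs, class_of, utr_lengths)
    pd.DataFrame([
        {"gene_id": r.gene_id, "n_species_specific_sites": r.n_species_specific_sites,
         "total_utr_length": r.total_utr_length, "rate": r.rate}
        for r in records
    ]).to_csv(out / "emergence.tsv", sep="\t", index=False)
    top = targets.select_top_fraction(records, fraction=cfg["emerge"]["top_fraction"])
    (out / "top_genes.txt").write_text("\n".join(top) + "\n")


def stage_enrich(out: Path, cfg: dict) -> None:
    _log_stage(out, "enrich", cfg)
    top = _require(out / "top_genes.txt", "emerge").read_text().split()
    emergence = pd.read_csv(_require(out / "emergence.tsv", "emerge"), sep="\t")
    annotation = read_annotation(
        _require(out / "input" / "annotation.tsv", "simulate")
    )
    rows = stats.go_enrichment(top, emergence["gene_id"].tolist(), annotation)
    pd.DataFrame(rows).to_csv(out / "go_enrichment.tsv", sep="\t", index=False)


def stage_report(out: Path, cfg: dict) -> None:
    _log_stage(out, "report", cfg)
    report: dict = {}
    for name in ["conservation_summary.json", "cluster_tests.json",
                 "spatial.json", "sign_bias.json"]:
        path = out / name
        if path.exists():
            report[name.removesuffix(".json")] = json.loads(path.read_text())
    mirna_rpm = out / "mirna_rpm.tsv"
    if mirna_rpm.exists() and (out / "conservation.tsv").exists():
        expr = pd.read_csv(mirna_rpm, sep="\t", index_col=0)
        cons = pd.read_csv(out / "conservation.tsv", sep="\t")
        class_of = dict(zip(cons["gene_id"], cons["class"]))
        mean_expr = np.log2(expr + 1).mean(axis=1)
        groups = {"conserved": [], "species-specific": []}
        for gene, v in mean_expr.items():
            c = class_of.get(gene)
            if c in groups:
                groups[c].append(float(v))
        if all(len(v) >= 1 for v in groups.values()):
            res = stats.mann_whitney_u(groups["conserved"],
                                       groups["species-specific"],
                                       alternative="greater")
            report["expression_conserved_vs_specific"] = {
                "U": res.statistic, "p": res.p_value, "method": res.method,
                "n": list(res.n),
            }
        shares, _ = stats.pca(np.log2(expr + 1).to_numpy())
        report["mirna_expression_pca_pc1_share"] = float(shares[0])
    _write_json(report, out / "report.json")


STAGES = {
    "simulate": stage_simulate, "families": stage_families,
    "conserve": stage_conserve, "gainloss": stage_gainloss,
    "clusters": stage_clusters, "targets": stage_targets,
    "spatial": stage_spatial, "express": stage_express,
    "correlate": stage_correlate, "emerge": stage_emerge,
    "enrich": stage_enrich, "report": stage_report,
}


def run_pipeline(out, config: dict | None = None, stages=None) -> None:
    cfg = merge_config(config)
    out = Path(out)
    for stage in stages or cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        STAGES[stage](out, cfg)
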