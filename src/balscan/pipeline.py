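"""End-to-end orchestration: curation → counts → MK → diversity → HKA → trees.

``run_pipeline`` takes a manifest of candidate and control genes (file paths
or in-memory alignments), runs every analysis stage with seeds derived from
one master seed, and returns a result bundle that ``write_report`` renders as
a Table-1-style TSV, a full-precision JSON report, Newick trees and window
tracks.  Reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from . import diversity as dv
from . import haplostructure as hs
from . import hka as hkamod
from . import selection_tests as st
from .codon_counts import classify_variants
from .curation import GeneAlignment, RawAlignment, curate_strains, read_gene_alignment
from .exceptions import BalscanError, ConfigurationError


@dataclass
class GeneInput:
    gene_id: str
    role: str  # candidate | control
    path: Optional[str] = None
    alignment: Optional[GeneAlignment] = None
    raw: Optional[RawAlignment] = None
    min_length_fraction: float = 0.99


@dataclass
class RunConfig:
    genes: list
    reference_id: str = "S288C"
    outgroup_id: Optional[str] = "CBS432"
    window: int = 200
    step: int = 50
    chain_length: int = 100_000
    bootstrap_replicates: int = 1000
    seed: int = 0
    tree_genes: tuple = ()
    window_genes: tuple = ()
    run_hka: bool = True
    outdir: Optional[str] = None

    def __post_init__(self):
        cand = {g.gene_id for g in self.genes if g.role == "candidate"}
        ctrl = {g.gene_id for g in self.genes if g.role == "control"}
        if cand & ctrl:
            raise ConfigurationError(
                f"genes in both sets: {sorted(cand & ctrl)}"
            )


def _seeds(master: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(count)]


def run_pipeline(cfg: RunConfig) -> dict:
    results: dict = {
        "genes": {},
        "sets": {},
        "hka": {},
        "trees": {},
        "windows": {},
        "rm": {},
        "errors": [],
        "seed": cfg.seed,
    }
    curate_seeds = _seeds(cfg.seed, len(cfg.genes))
    by_role: dict = {"candidate": [], "control": []}
    alns: dict = {}

    # --- curation + per-gene statistics ----------------------------------
    for gene, cseed in zip(cfg.genes, curate_seeds):
        try:
            if gene.alignment is not None:
                aln = gene.alignment
            else:
                raw = gene.raw
                if raw is None:
                    raw = read_gene_alignment(
                        gene.path, cfg.reference_id, cfg.outgroup_id,
                        gene_id=gene.gene_id,
                    )
                aln = curate_strains(raw, gene.min_length_fraction, seed=cseed)
            alns[gene.gene_id] = aln
            calls, counts = classify_variants(aln)
            syn_stats = dv.diversity_stats(aln, "synonymous", calls=calls)
            k_syn = dv.divergence_K(aln, "synonymous")
            results["genes"][gene.gene_id] = {
                "role": gene.role,
                "counts": counts,
                "calls": calls,
                "syn_stats": syn_stats,
                "K_syn": k_syn,
                "n_strains": aln.n_strains,
            }
            by_role[gene.role].append(gene.gene_id)
        except BalscanError as exc:
            results["errors"].append(f"gene {gene.gene_id}: {exc}")

    # --- MK tests, Bonferroni within each gene set ------------------------
    for role, gids in by_role.items():
        m = len(gids)
        for gid in gids:
            counts = results["genes"][gid]["counts"]
            results["genes"][gid]["mk"] = st.mk_test(counts, m_tests=max(m, 1))
        if gids:
            try:
                wni = st.weighted_neutrality_index(
                    [results["genes"][g]["counts"] for g in gids]
                )
            except BalscanError:
                wni = None
            results["sets"][role] = {"genes": gids, "weighted_NI": wni}

    # --- HKA: each candidate against the control set ----------------------
    if cfg.run_hka and by_role["control"]:
        control_loci = [
            hkamod.locus_summary(
                alns[g],
                calls=results["genes"][g]["calls"],
                counts=results["genes"][g]["counts"],
            )
            for g in by_role["control"]
        ]
        hka_seeds = _seeds(cfg.seed + 1, max(len(by_role["candidate"]), 1))
        for gid, hseed in zip(by_role["candidate"], hka_seeds):
            try:
                cand_locus = hkamod.locus_summary(
                    alns[gid],
                    calls=results["genes"][gid]["calls"],
                    counts=results["genes"][gid]["counts"],
                )
                loci = control_loci + [cand_locus]
                stat, df, p_classic = hkamod.hka_chisq(loci)
                lrt = hkamod.mlhka_lrt(
                    loci, [gid], chain_length=cfg.chain_length, seeds=hseed,
                    keep_fits=True,
                )
                results["hka"][gid] = {
                    "classic": {"statistic": stat, "df": df, "p": p_classic},
                    "mlhka": lrt,
                }
            except BalscanError as exc:
                results["errors"].append(f"hka {gid}: {exc}")

    # --- trees, branch mapping, Rm ---------------------------------------
    tree_seeds = _seeds(cfg.seed + 2, max(len(cfg.tree_genes), 1))
    for gid, tseed in zip(cfg.tree_genes, tree_seeds):
        if gid not in alns:
            results["errors"].append(f"tree {gid}: gene not available")
            continue
        try:
            tree = hs.bootstrap_support(
                alns[gid], replicates=cfg.bootstrap_replicates, seed=tseed
            )
            mapping = hs.map_variants_to_branches(
                tree, results["genes"][gid]["calls"]
            )
            _, rm = hs.rm_min_recomb(alns[gid])
            results["trees"][gid] = {"tree": tree, "mapping": mapping}
            results["rm"][gid] = rm
        except BalscanError as exc:
            results["errors"].append(f"tree {gid}: {exc}")

    # --- sliding windows ---------------------------------------------------
    for gid in cfg.window_genes:
        if gid not in alns:
            results["errors"].append(f"window {gid}: gene not available")
            continue
        results["windows"][gid] = dv.sliding_window_pi_k(
            alns[gid], window=cfg.window, step=cfg.step
        )

    results["config"] = cfg
    return results


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if f.name not in ("calls", "counts", "fit_null", "fit_alt",
                              "alignment", "raw", "genes")
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def mk_table_rows(results: dict) -> list[dict]:
    """Table-1-style rows: per gene, then one summary row per gene set."""
    rows = []
    for role in ("candidate", "control"):
        gids = results["sets"].get(role, {}).get("genes", [])
        for gid in gids:
            g = results["genes"][gid]
            c = g["counts"]
            mk = g["mk"]
            rows.append(
                {
                    "gene": gid,
                    "set": role,
                    "n_sites": c.n_sites,
                    "Pn": c.Pn,
                    "Ps": c.Ps,
                    "Dn": c.Dn,
                    "Ds": c.Ds,
                    "mk_p": f"{mk.p_value:.6f}",
                    "mk_p_bonferroni": f"{mk.p_adjusted:.6f}",
                    "NI": "NA" if mk.NI is None else f"{mk.NI:.1f}",
                }
            )
        if gids:
            tot = {
                k: sum(getattr(results["genes"][g]["counts"], k) for g in gids)
                for k in ("n_sites", "Pn", "Ps", "Dn", "Ds")
            }
            wni = results["sets"][role]["weighted_NI"]
            rows.append(
                {
                    "gene": f"{len(gids)}_{role}_genes",
                    "set": role,
                    **tot,
                    "mk_p": "",
                    "mk_p_bonferroni": "",
                    "NI": "NA" if wni is None else f"{wni:.2f}",
                }
            )
    return rows


def write_report(results: dict, outdir: str) -> list[str]:
    """Write TSV/JSON/Newick outputs; returns the paths written."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    # Table-1-style TSV
    path = os.path.join(outdir, "mk_table.tsv")
    rows = mk_table_rows(results)
    cols = ["gene", "set", "n_sites", "Pn", "Ps", "Dn", "Ds",
            "mk_p", "mk_p_bonferroni", "NI"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    written.append(path)

    # full-precision JSON
    payload = {
        "seed": results["seed"],
        "genes": {
            gid: {
                "role": g["role"],
                "counts": _jsonable(g["counts"]),
                "mk": _jsonable(g.get("mk")),
                "syn_stats": _jsonable(g["syn_stats"]),
                "K_syn": g["K_syn"],
            }
            for gid, g in results["genes"].items()
        },
        "sets": _jsonable(results["sets"]),
        "hka": {
            gid: {
                "classic": _jsonable(h["classic"]),
                "mlhka": _jsonable(h["mlhka"]),
            }
            for gid, h in results["hka"].items()
        },
        "rm": _jsonable(results["rm"]),
        "errors": list(results["errors"]),
    }
    path = os.path.join(outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)

    # trees
    for gid, t in results["trees"].items():
        path = os.path.join(outdir, f"{gid}.nwk")
        with open(path, "w") as fh:
            fh.write(t["tree"].newick() + "\n")
        written.append(path)

    # window tracks (1-based inclusive coordinates in reports)
    for gid, track in results["windows"].items():
        path = os.path.join(outdir, f"{gid}.windows.tsv")
        with open(path, "w") as fh:
            fh.write("start\tend\tpi\tK\n")
            for s, e, pi, K in track.windows:
                fh.write(f"{s + 1}\t{e}\t{pi:.6f}\t{K:.6f}\n")
        written.append(path)

    # resolved configuration for provenance
    cfg = results.get("config")
    if cfg is not None:
        path = os.path.join(outdir, "run_config.yaml")
        cfgdict = _jsonable(cfg)
        cfgdict["genes"] = [
            {"gene_id": g.gene_id, "role": g.role, "path": g.path,
             "min_length_fraction": g.min_length_fraction}
            for g in cfg.genes
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(cfgdict, fh, sort_keys=True)
        written.append(path)
    return written
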