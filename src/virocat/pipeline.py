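"""Stage orchestration over a workspace directory.

A workspace has ``inputs/`` (contigs, evidence, placements, references,
bacteria, hosts, tables), ``derived/`` (per-stage TSVs) and ``catalogue/``
(final outputs).  A ``manifest.json`` records the config hash and completed
stages; stages only read ``inputs/`` and earlier stages' ``derived/``
files, so reruns are no-ops unless forced and outputs are byte-identical
for a fixed config, seed and inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import circular as circ_mod
from . import clades as clades_mod
from . import hosts as hosts_mod
from .clustering import build_graph, clusters_table, cluster_votus, mcl, rank_and_label
from .config import PipelineConfig, config_hash
from .homology import assign_source_group, dereplicate, find_hsps, novelty_vs_catalogues
from .identify import (CallResult, calls_table, decontaminate,
                       evaluate_criteria, evidence_from_row, call_virus,
                       length_filter, mask_prophages)
from .io import (Contig, ValidationError, log, read_fasta,
                 read_fasta_labelled, read_table, read_taxonomy, write_catalogue,
                 write_fasta, write_table)
from .quantify import (abundance_tables, bray_curtis, prevalence, rarefaction,
                       shannon, summarize_coverage, vc_abundance)

STAGES = ["identify", "circ", "derep", "novelty", "cluster", "clades",
          "quantify", "lifestyle", "hosts", "report"]


class PrerequisiteError(RuntimeError):
    """A stage was requested before the stage it depends on."""


class Workspace:
    def __init__(self, root: str | Path, cfg: PipelineConfig | None = None,
                 seed: int = 0):
        self.root = Path(root)
        self.cfg = cfg or PipelineConfig()
        self.seed = seed
        self.inputs = self.root / "inputs"
        self.derived = self.root / "derived"
        self.catalogue = self.root / "catalogue"
        self.manifest_path = self.root / "manifest.json"

    # -- manifest -----------------------------------------------------------
    def manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"config_hash": config_hash(self.cfg), "completed": []}

    def _mark_done(self, stage: str) -> None:
        m = self.manifest()
        if stage not in m["completed"]:
            m["completed"].append(stage)
        tmp = self.manifest_path.with_suffix(".tmp")
        tmp.write_text(json.dumps(m, indent=1, sort_keys=True))
        tmp.replace(self.manifest_path)

    def check_config(self, force: bool) -> None:
        m = self.manifest()
        if m["completed"] and m["config_hash"] != config_hash(self.cfg):
            if not force:
                raise ValidationError(
                    "config hash differs from the manifest; rerun with force "
                    "to overwrite earlier stage outputs")
            self.manifest_path.write_text(json.dumps(
                {"config_hash": config_hash(self.cfg), "completed": []}))

    def _require(self, stage: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists():
                raise PrerequisiteError(
                    f"stage {stage!r} needs {p}; run the producing stage first")

    # -- cached inputs --------------------------------------------------------
    def contigs(self) -> List[Contig]:
        cs = read_fasta(self.inputs / "contigs.fasta")
        meta = read_table(self.inputs / "contig_meta.tsv", schema="contig_meta")
        by_id = {str(r["contig_id"]): r for _, r in meta.iterrows()}
        for c in cs:
            if c.id in by_id:
                c.sample_id = str(by_id[c.id]["sample_id"])
                c.assembly_source = str(by_id[c.id]["assembly_source"])
        return cs

    def placements(self) -> pd.DataFrame:
        return read_table(self.inputs / "placements.tsv", schema="placements")

    def votus(self) -> List[Contig]:
        self._require("(votus)", self.derived / "votus.fasta")
        meta = {c.id: c for c in self.contigs()}
        out = []
        for c in read_fasta(self.derived / "votus.fasta"):
            src = meta.get(c.id)
            if src is not None:
                c.sample_id, c.assembly_source = src.sample_id, src.assembly_source
            out.append(c)
        return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_identify(ws: Workspace) -> pd.DataFrame:
    """Viral calling + decontamination + length filter -> derived/calls.tsv."""
    cfg = ws.cfg
    contigs = ws.contigs()
    evidence = read_table(ws.inputs / "evidence.tsv", schema="evidence")
    ev_by_id = {str(r["contig_id"]): evidence_from_row(r)
                for _, r in evidence.iterrows()}
    placements = ws.placements() if (ws.inputs / "placements.tsv").exists() else None

    masked_bacteria: List[Contig] = []
    bact_fa = ws.inputs / "bacteria" / "genomes.fasta"
    if bact_fa.exists():
        bacteria = read_fasta(bact_fa)
        intervals: Dict[str, list] = {}
        pro_path = ws.inputs / "bacteria" / "prophage_intervals.tsv"
        if pro_path.exists():
            pro = read_table(pro_path, schema="prophage-intervals")
            for _, r in pro.iterrows():
                intervals.setdefault(str(r["genome_id"]), []).append(
                    (int(r["start"]), int(r["end"])))
        masked_bacteria = [mask_prophages(b, intervals.get(b.id, []))
                           for b in bacteria]

    results: List[CallResult] = []
    for c in contigs:
        e = ev_by_id.get(c.id)
        if e is None:
            log.warning("no evidence row for contig %s; treating as silent", c.id)
            from .identify import EvidenceRecord
            e = EvidenceRecord(contig_id=c.id)
        crit = evaluate_criteria(e, c.length, cfg)
        circ = circ_mod.call_circularity(c, placements, cfg).is_circular
        is_virus = call_virus(crit, circ, e, cfg)
        hq = (len(crit) == 1 and not circ and is_virus)
        removed = False
        if is_virus and masked_bacteria:
            hits = []
            for b in masked_bacteria:
                hits.extend(find_hsps(c, b, min_identity=cfg.decontam_identity,
                                      min_len=100))
            removed = decontaminate(c, hits, cfg)
        results.append(CallResult(
            contig_id=c.id, satisfied_criteria=crit, circular=circ,
            hq_rescue=hq, is_virus=is_virus, removed_as_bacterial=removed,
            passed_length=c.length > cfg.min_contig_len))
    table = calls_table(results)
    write_table(table, ws.derived / "calls.tsv")
    kept_ids = {r.contig_id for r in results
                if r.is_virus and not r.removed_as_bacterial and r.passed_length}
    kept = length_filter([c for c in contigs if c.id in kept_ids], cfg)
    write_fasta(kept, ws.derived / "candidates.fasta")
    return table


def stage_circ(ws: Workspace) -> pd.DataFrame:
    ws._require("circ", ws.derived / "candidates.fasta")
    contigs = read_fasta(ws.derived / "candidates.fasta")
    placements = ws.placements() if (ws.inputs / "placements.tsv").exists() else None
    table = circ_mod.circularity_table(contigs, placements, ws.cfg)
    write_table(table, ws.derived / "circularity.tsv")
    return table


def stage_derep(ws: Workspace) -> pd.DataFrame:
    """Dereplicate candidates into vOTUs and attribute source groups."""
    ws._require("derep", ws.derived / "candidates.fasta")
    meta = {c.id: c for c in ws.contigs()}
    candidates = [meta[c.id] for c in read_fasta(ws.derived / "candidates.fasta")]
    clusters = dereplicate(candidates, ws.cfg)
    rows = [{"representative_id": cl.representative_id, "member_id": m,
             "identity_to_rep": cl.identity_to_rep[m]}
            for cl in clusters for m in cl.member_ids]
    table = pd.DataFrame(rows, columns=["representative_id", "member_id",
                                        "identity_to_rep"])
    write_table(table, ws.derived / "derep.tsv")
    reps = [next(c for c in candidates if c.id == cl.representative_id)
            for cl in clusters]
    write_fasta(reps, ws.derived / "votus.fasta")
    all_contigs = list(meta.values())
    groups = [{"contig_id": rep.id,
               "group": assign_source_group(rep, all_contigs, ws.cfg)}
              for rep in reps]
    gtable = pd.DataFrame(groups, columns=["contig_id", "group"])
    write_table(gtable, ws.derived / "groups.tsv")
    return table


def stage_novelty(ws: Workspace) -> pd.DataFrame:
    votus = ws.votus()
    refdir = ws.inputs / "references"
    catalogues = {p.stem: read_fasta(p)
                  for p in sorted(refdir.glob("*.fasta"))} if refdir.exists() else {}
    if not catalogues:
        raise PrerequisiteError("novelty stage needs inputs/references/*.fasta")
    table = novelty_vs_catalogues(votus, catalogues, ws.cfg)
    write_table(table, ws.derived / "novelty.tsv")
    return table


def stage_cluster(ws: Workspace) -> pd.DataFrame:
    votus = ws.votus()
    edges = build_graph(votus, ws.cfg)
    etable = pd.DataFrame(
        [{"a_id": e.a_id, "b_id": e.b_id, "cov_on_larger": e.cov_on_larger,
          "cov_on_smaller": e.cov_on_smaller, "passes": e.passes}
         for e in edges],
        columns=["a_id", "b_id", "cov_on_larger", "cov_on_smaller", "passes"])
    write_table(etable, ws.derived / "edges.tsv")
    comps = mcl([c.id for c in votus], edges, inflation=ws.cfg.mcl_inflation)
    table = clusters_table(rank_and_label(comps))
    write_table(table, ws.derived / "vcs.tsv")
    return table


def stage_clades(ws: Workspace) -> pd.DataFrame:
    votus = ws.votus()
    hits_path = ws.inputs / "crass_protein_hits.tsv"
    hits = read_table(hits_path, schema="crass-protein-hits") \
        if hits_path.exists() else None
    proto_path = ws.inputs / "references" / "crass_prototype.fasta"
    proto = read_fasta(proto_path)[0] if proto_path.exists() else None
    rows = []
    for v in votus:
        nt_id = nt_cov = None
        if proto is not None and v.length > ws.cfg.crass_min_len:
            from .homology import compute_ani
            r = compute_ani(v, proto, ws.cfg)
            nt_id, nt_cov = ws.cfg.crass_nt_identity, r.ani  # coverage at >=95% id
        call = clades_mod.call_crassphage(v, hits, nt_id, nt_cov, ws.cfg)
        rows.append({"contig_id": v.id, "is_crass": call.is_crass,
                     "crass_route": call.crass_route, "is_guba": False})
    table = pd.DataFrame(rows, columns=["contig_id", "is_crass",
                                        "crass_route", "is_guba"])
    guba_path = ws.inputs / "references" / "guba.fasta"
    if guba_path.exists():
        refs = read_fasta(guba_path)
        labels = {r.id: "Gubaphage" for r in refs}
        from .clustering import co_cluster_with_references
        guba = co_cluster_with_references(votus, labels, refs, ws.cfg)
        table["is_guba"] = table["contig_id"].map(lambda i: i in guba)
    write_table(table, ws.derived / "clades.tsv")
    return table


def stage_quantify(ws: Workspace) -> None:
    votus = ws.votus()
    lengths = {c.id: c.length for c in votus}
    placements = ws.placements()
    placements = placements[placements["contig_id"].isin(lengths)]
    coverage = summarize_coverage(placements, lengths)
    write_table(pd.DataFrame(
        [{"sample_id": cs.sample_id, "contig_id": cs.contig_id,
          "breadth": cs.breadth, "mean_depth": cs.mean_depth,
          "mapped_reads": cs.mapped_reads} for cs in coverage]),
        ws.derived / "coverage.tsv")
    rpkm_m, pres, rel = abundance_tables(coverage, lengths, ws.cfg)
    for name, frame in (("rpkm", rpkm_m), ("presence", pres),
                        ("relabund", rel)):
        out = frame.reset_index().rename(columns={"index": "sample_id"})
        write_table(out, ws.derived / f"{name}.tsv")
    prev = prevalence(pres).rename("prevalence").reset_index()
    prev.columns = ["contig_id", "prevalence"]
    write_table(prev, ws.derived / "prevalence.tsv")
    div = pd.DataFrame({"sample_id": rel.index,
                        "shannon": [shannon(rel.loc[s]) for s in rel.index]})
    write_table(div, ws.derived / "shannon.tsv")
    bc_rows = []
    idx = list(rel.index)
    for i, a in enumerate(idx):
        for b in idx[i + 1:]:
            if rel.loc[a].sum() == 0 and rel.loc[b].sum() == 0:
                continue
            bc_rows.append({"sample_a": a, "sample_b": b,
                            "bray_curtis": bray_curtis(rel.loc[a], rel.loc[b])})
    write_table(pd.DataFrame(bc_rows, columns=["sample_a", "sample_b",
                                               "bray_curtis"]),
                ws.derived / "bray_curtis.tsv")
    vcs_path = ws.derived / "vcs.tsv"
    if vcs_path.exists():
        vcs = read_table(vcs_path)
        members = {vc: grp["member_id"].tolist()
                   for vc, grp in vcs.groupby("vc_id")}
        vc_rel, vc_pres = vc_abundance(rel, pres, members)
        out = vc_rel.reset_index().rename(columns={"index": "sample_id"})
        write_table(out, ws.derived / "vc_relabund.tsv")
    sample_sets = {s: set(pres.columns[pres.loc[s]]) for s in pres.index}
    write_table(rarefaction(sample_sets, ws.seed),
                ws.derived / "rarefaction.tsv")


def stage_lifestyle(ws: Workspace) -> pd.DataFrame:
    votu_ids = {c.id for c in ws.votus()}
    scores = read_table(ws.inputs / "lifestyle.tsv", schema="lifestyle")
    scores = scores[scores["contig_id"].isin(votu_ids)]
    table = clades_mod.lifestyle_table(scores, ws.cfg)
    write_table(table, ws.derived / "lifestyle.tsv")
    return table


def stage_hosts(ws: Workspace) -> None:
    votus = ws.votus()
    hostdir = ws.inputs / "hosts"
    spacers = [(sid, host, seq) for sid, host, seq in
               read_fasta_labelled(hostdir / "spacers.fasta", "host")]
    viral_trnas = [(gid, owner, seq) for gid, owner, seq in
                   read_fasta_labelled(hostdir / "trnas_viral.fasta", "virus")]
    bact_trnas = [(gid, owner, seq) for gid, owner, seq in
                  read_fasta_labelled(hostdir / "trnas_bacterial.fasta", "host")]
    taxonomy = read_taxonomy(ws.inputs / "taxonomy.tsv")
    sp_matches = hosts_mod.match_spacers(spacers, votus, ws.cfg)
    votu_ids = {c.id for c in votus}
    viral_trnas = [t for t in viral_trnas if t[1] in votu_ids]
    tr_matches = hosts_mod.match_trnas(viral_trnas, bact_trnas, ws.cfg)
    evidence = hosts_mod.assign_hosts(
        sp_matches, tr_matches, {sid: seq for sid, _, seq in spacers})
    write_table(pd.DataFrame(
        [{"virus_id": ev.virus_id, "host_species_id": ev.host_species_id,
          "n_spacer_matches": ev.n_spacer_matches,
          "n_trna_matches": ev.n_trna_matches,
          "any_short_spacer_only": ev.any_short_spacer_only,
          "confidence": ev.confidence} for ev in evidence],
        columns=["virus_id", "host_species_id", "n_spacer_matches",
                 "n_trna_matches", "any_short_spacer_only", "confidence"]),
        ws.derived / "host_evidence.tsv")
    ranges = hosts_mod.host_range(evidence, taxonomy, high_only=True)
    write_table(pd.DataFrame(
        [{"virus_id": r.virus_id, "lca_rank": r.lca_rank,
          "lca_node": r.lca_node, "n_hosts": r.n_hosts} for r in ranges],
        columns=["virus_id", "lca_rank", "lca_node", "n_hosts"]),
        ws.derived / "host_range.tsv")
    vcs_path = ws.derived / "vcs.tsv"
    style_path = ws.derived / "lifestyle.tsv"
    if vcs_path.exists():
        vcs = read_table(vcs_path)
        members = {vc: grp["member_id"].tolist()
                   for vc, grp in vcs.groupby("vc_id")}
        lifestyle = {}
        if style_path.exists():
            st = read_table(style_path)
            lifestyle = dict(zip(st["contig_id"], st["category"]))
        edges, vc_attrs, host_attrs = hosts_mod.export_network(
            members, evidence, taxonomy, lifestyle)
        write_table(edges, ws.derived / "network_edges.tsv")
        write_table(vc_attrs, ws.derived / "network_vc_attrs.tsv")
        write_table(host_attrs, ws.derived / "network_host_attrs.tsv")
        # V/T ratio per host genus over high-confidence links
        by_genus: Dict[str, list] = {}
        for ev in evidence:
            if ev.confidence != "high" or ev.virus_id not in lifestyle:
                continue
            genus = taxonomy.ancestor_at_rank(ev.host_species_id, "genus")
            if genus:
                by_genus.setdefault(genus, []).append(lifestyle[ev.virus_id])
        vt_rows = []
        for genus, cats in sorted(by_genus.items()):
            ratio, defined = clades_mod.vt_ratio(cats)
            vt_rows.append({"host_genus": genus, "n_viruses": len(cats),
                            "vt_ratio": ratio if defined else float("nan"),
                            "defined": defined})
        write_table(pd.DataFrame(vt_rows, columns=["host_genus", "n_viruses",
                                                   "vt_ratio", "defined"]),
                    ws.derived / "vt_ratio.tsv")


def stage_report(ws: Workspace) -> dict:
    """Assemble the catalogue directory and a JSON summary of headline
    fractions, each recomputed from the catalogue tables alone."""
    votus = ws.votus()
    layers = {}
    for name, fname in (("circularity", "circularity.tsv"),
                        ("group", "groups.tsv"),
                        ("novelty", "novelty.tsv"),
                        ("vc", "vcs.tsv"),
                        ("clade", "clades.tsv"),
                        ("lifestyle", "lifestyle.tsv")):
        p = ws.derived / fname
        if p.exists():
            df = read_table(p)
            if "member_id" in df.columns:
                df = df.rename(columns={"member_id": "contig_id"})
            if "representative_id" in df.columns:
                df = df[df["contig_id"].isin({c.id for c in votus})]
            layers[name] = df[df["contig_id"].isin({c.id for c in votus})] \
                if "contig_id" in df.columns else df
    hosts_p = ws.derived / "host_evidence.tsv"
    if hosts_p.exists():
        he = read_table(hosts_p).rename(columns={"virus_id": "contig_id"})
        layers["hosts"] = he[he["contig_id"].isin({c.id for c in votus})]
    write_catalogue(votus, layers, ws.catalogue)

    n = len(votus)
    summary: dict = {"n_votus": n}
    if "circularity" in layers:
        summary["pct_circular"] = round(
            100.0 * layers["circularity"]["is_circular"].astype(bool).mean(), 2)
    if "group" in layers:
        counts = layers["group"]["group"].value_counts()
        for grp in ("long_read", "short_read", "both"):
            summary[f"pct_group_{grp}"] = round(
                100.0 * counts.get(grp, 0) / n, 2)
    if "novelty" in layers:
        counts = layers["novelty"]["class"].value_counts()
        for cls in ("identical", "partial", "novel"):
            summary[f"pct_novelty_{cls}"] = round(
                100.0 * counts.get(cls, 0) / n, 2)
    if "vc" in layers:
        sizes = layers["vc"].groupby("vc_id").size()
        summary["n_vcs"] = int(len(sizes))
        summary["n_nonsingleton_vcs"] = int((sizes > 1).sum())
    if "lifestyle" in layers:
        cats = layers["lifestyle"]["category"]
        summary["pct_virulent_side"] = round(
            100.0 * cats.isin(["virulent", "uncertain_virulent"]).mean(), 2)
        for cat in clades_mod.LIFESTYLE_CATEGORIES:
            summary[f"n_lifestyle_{cat}"] = int((cats == cat).sum())
    if "hosts" in layers:
        assigned = layers["hosts"]["contig_id"].nunique()
        summary["pct_host_assigned"] = round(100.0 * assigned / n, 2)
    out = ws.catalogue / "report.json"
    out.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary


_STAGE_FN = {"identify": stage_identify, "circ": stage_circ,
             "derep": stage_derep, "novelty": stage_novelty,
             "cluster": stage_cluster, "clades": stage_clades,
             "quantify": stage_quantify, "lifestyle": stage_lifestyle,
             "hosts": stage_hosts, "report": stage_report}

_PREREQ = {"circ": ["identify"], "derep": ["identify"],
           "novelty": ["derep"], "cluster": ["derep"], "clades": ["derep"],
           "quantify": ["derep", "cluster"], "lifestyle": ["derep"],
           "hosts": ["derep", "cluster", "lifestyle"],
           "report": ["derep"]}


def run_pipeline(workspace: str | Path, cfg: PipelineConfig | None = None,
                 stages: Sequence[str] | None = None, seed: int = 0,
                 force: bool = False) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    ws = Workspace(workspace, cfg, seed=seed)
    ws.check_config(force)
    wanted = list(STAGES) if stages is None else [s for s in STAGES
                                                 if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
    done = set(ws.manifest()["completed"])
    for stage in wanted:
        missing = [p for p in _PREREQ.get(stage, [])
                   if p not in done and p not in wanted[:wanted.index(stage)]]
        if missing:
            raise PrerequisiteError(
                f"stage {stage!r} requires earlier stage(s) {missing}")
        if stage in done and not force:
            log.info("stage %s already complete; skipping", stage)
            continue
        log.info("running stage %s", stage)
        _STAGE_FN[stage](ws)
        ws._mark_done(stage)
        done.add(stage)
    return ws.manifest()
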