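"""Synthetic community generator with known ground truth.

Everything the pipeline consumes — genomes, detector evidence, read
placements, reference catalogues, bacterial genomes with prophages,
CRISPR spacers, tRNA genes, taxonomy, lifestyle scores, protein COG
assignments — can be generated here from a single seed, together with
truth tables that record what was planted.  The generator emulates the
statistical shape of a real virome workspace (skewed lognormal
abundances, terminal redundancy on circular genomes, junction-spanning
reads, detector scores straddling their thresholds, exact spacer
protospacers); it does not model sequencing error, quality scores or
assembly artefacts.

All outputs are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .homology import revcomp
from .io import Contig, write_fasta, write_table

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationTruth:
    genome_id: str
    is_viral: bool
    is_circular: bool
    source_group: str            # short | long | both (expected group call)
    cluster_id: str
    divergence_from_parent: float
    novelty_class: str           # identical | partial | novel
    lifestyle_score: float
    planted_hosts: List[Tuple[str, str, int]] = field(default_factory=list)
    abundance: Dict[str, float] = field(default_factory=dict)
    present_in: Dict[str, bool] = field(default_factory=dict)
    removed_as_bacterial: bool = False
    below_length: bool = False
    expected_confidence: str = ""


# ---------------------------------------------------------------------------
# Sequence-level generators
# ---------------------------------------------------------------------------

def gen_genome(length: int, gc: float, seed: int, *, id: str = "g") -> Contig:
    """Random genome with i.i.d. bases at the requested GC content."""
    if length < 100:
        raise ValueError(f"genome length must be >= 100, got {length}")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(BASES, size=length, p=p).tobytes().decode()
    return Contig(id=id, sequence=seq)


def mutate(genome: Contig, divergence: float, seed: int,
           *, id: str | None = None) -> Contig:
    """Substitute each base independently with the given probability.

    Substitutions always change the base (no silent draws) and there are no
    indels, so the realised identity to the parent is analytically
    1 - (observed substitution count / length).
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError(f"divergence must be in [0, 0.5], got {divergence}")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < divergence)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return Contig(id=id or f"{genome.id}_mut", sequence=arr.tobytes().decode(),
                  sample_id=genome.sample_id,
                  assembly_source=genome.assembly_source)


def make_circular(genome: Contig, tr_len: int, *, id: str | None = None) -> Contig:
    """Append the first ``tr_len`` bases to the end — the terminal redundancy
    an assembler leaves on a circular genome."""
    if not 1 <= tr_len < genome.length:
        raise ValueError(f"tr_len must be in [1, length), got {tr_len}")
    return Contig(id=id or genome.id,
                  sequence=genome.sequence + genome.sequence[:tr_len],
                  sample_id=genome.sample_id,
                  assembly_source=genome.assembly_source)


def make_mosaic(donor: Contig, background: Contig, shared_fraction: float,
                seed: int, *, id: str = "mosaic") -> Contig:
    """A genome sharing a contiguous ``shared_fraction`` of the donor.

    The shared block (at ~99% identity) keeps its position inside a
    background of the donor's length, so the expected query-normalised ANI
    of the mosaic against the donor is ~100 x shared_fraction.
    """
    if not 0 < shared_fraction < 1:
        raise ValueError(f"shared_fraction must be in (0,1), got {shared_fraction}")
    L = donor.length
    if background.length < L:
        raise ValueError("background must be at least as long as the donor")
    S = int(round(shared_fraction * L))
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, L - S + 1))
    block = mutate(Contig(id="block", sequence=donor.sequence[start:start + S]),
                   0.01, seed + 1).sequence
    seq = background.sequence[:start] + block + background.sequence[start + S:L]
    return Contig(id=id, sequence=seq)


# ---------------------------------------------------------------------------
# Community-level generators
# ---------------------------------------------------------------------------

def gen_community(genomes: Sequence[Contig], n_samples: int, seed: int,
                  truths: Dict[str, SimulationTruth] | None = None,
                  circular_ids: Sequence[str] = (),
                  cfg: PipelineConfig | None = None,
                  *, read_len: int = 500, present_prob: float = 0.7,
                  sigma: float = 1.0, target_breadth: float = 0.88,
                  depth_range: Tuple[float, float] = (8.0, 30.0)) -> pd.DataFrame:
    """Per-sample read placements under lognormal(0, sigma) abundances.

    Present genomes are tiled to ``target_breadth`` with depth scaled to
    abundance inside ``depth_range`` (safely above the >4X presence cut);
    absent genomes get either no reads or sparse low-depth reads that stay
    below both presence thresholds.  Circular genomes additionally receive
    junction-spanning reads (two terminal segments per read, same strand).
    """
    cfg = cfg or PipelineConfig()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    circ = set(circular_ids)
    for s in range(n_samples):
        sample = f"S{s + 1:02d}"
        abund = rng.lognormal(0.0, sigma, size=len(genomes))
        present = rng.random(len(genomes)) < present_prob
        amax = abund.max() if abund.size else 1.0
        total = float((abund * present).sum()) or 1.0
        read_no = 0
        for g, a, pres in zip(genomes, abund, present):
            rl = min(read_len, g.length)
            if truths is not None:
                truths[g.id].abundance[sample] = float(a * pres / total)
                truths[g.id].present_in[sample] = bool(pres)
            if pres:
                depth = depth_range[0] + (depth_range[1] - depth_range[0]) * a / amax
                span = int(target_breadth * g.length)
                n_reads = max(math.ceil(depth * g.length / rl),
                              math.ceil(span / rl) + 1)
                for r in range(n_reads):
                    # tile first, then fill randomly inside the covered span
                    if r * rl + rl <= span:
                        start = r * rl
                    else:
                        start = int(rng.integers(0, max(1, span - rl + 1)))
                    read_no += 1
                    rows.append((sample, f"{sample}_r{read_no:06d}", g.id,
                                 start, start + rl, "+"))
                if g.id in circ:
                    for _ in range(int(rng.integers(2, 4))):
                        read_no += 1
                        rid = f"{sample}_r{read_no:06d}"
                        tail = int(rng.integers(60, min(cfg.circ_end_window, 95)))
                        front = int(rng.integers(60, min(cfg.circ_end_window, 95)))
                        rows.append((sample, rid, g.id,
                                     g.length - tail, g.length, "+"))
                        rows.append((sample, rid, g.id, 0, front, "+"))
            elif rng.random() < 0.5:
                # sparse background mapping: breadth ~0.3, depth ~1.5
                span = int(0.3 * g.length)
                n_reads = max(1, math.ceil(1.5 * span / rl))
                for _ in range(n_reads):
                    start = int(rng.integers(0, max(1, span - rl + 1)))
                    read_no += 1
                    rows.append((sample, f"{sample}_r{read_no:06d}", g.id,
                                 start, start + min(rl, g.length - start), "+"))
    return pd.DataFrame(rows, columns=["sample_id", "read_id", "contig_id",
                                       "start", "end", "strand"])


def gen_evidence(genomes: Sequence[Contig], viral: Dict[str, bool],
                 noise: float, seed: int,
                 cfg: PipelineConfig | None = None,
                 *, hq_rescue_ids: Sequence[str] = (),
                 circular_only_ids: Sequence[str] = ()) -> pd.DataFrame:
    """Detector-evidence table with scores straddling the calling thresholds.

    True viruses satisfy each planted criterion with probability 1 - noise;
    non-viruses satisfy each with probability noise.  ``hq_rescue_ids`` get
    exactly one criterion plus >=90% CheckV completeness (the single-
    criterion rescue path); ``circular_only_ids`` get no criteria at all and
    rely on circularity.
    """
    if not 0 <= noise <= 0.5:
        raise ValueError(f"noise must be in [0, 0.5], got {noise}")
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    rescue, circ_only = set(hq_rescue_ids), set(circular_only_ids)
    rows = []
    for g in genomes:
        is_v = viral.get(g.id, False)
        rec = {"contig_id": g.id, "virsorter_score": np.nan,
               "virfinder_score": np.nan, "pprmeta_score": np.nan,
               "refseq_hit_identity": np.nan, "refseq_hit_coverage": np.nan,
               "pog_hit_orfs": 0, "checkv_completeness": np.nan,
               "checkv_quality": "NA"}
        if is_v and g.id in circ_only:
            rows.append(rec)
            continue
        if is_v:
            k = 1 if g.id in rescue else int(rng.integers(2, 4))
            wanted = list(rng.choice(5, size=k, replace=False))
        else:
            wanted = []
        for c in range(5):
            hit = (c in wanted)
            if noise > 0 and rng.random() < noise:
                hit = not hit
            if c == 0:
                rec["virsorter_score"] = round(
                    rng.uniform(cfg.virsorter_min, 1.0) if hit
                    else rng.uniform(0.0, cfg.virsorter_min - 0.05), 3)
            elif c == 1:
                rec["virfinder_score"] = round(
                    rng.uniform(cfg.virfinder_min + 0.02, 1.0) if hit
                    else rng.uniform(0.0, cfg.virfinder_min), 3)
            elif c == 2:
                rec["pprmeta_score"] = round(
                    rng.uniform(cfg.pprmeta_min + 0.02, 1.0) if hit
                    else rng.uniform(0.0, cfg.pprmeta_min), 3)
            elif c == 3:
                if hit:
                    rec["refseq_hit_identity"] = round(rng.uniform(55, 100), 1)
                    rec["refseq_hit_coverage"] = round(rng.uniform(92, 100), 1)
                elif rng.random() < 0.3:
                    rec["refseq_hit_identity"] = round(rng.uniform(20, 49), 1)
                    rec["refseq_hit_coverage"] = round(rng.uniform(10, 88), 1)
            else:
                per10kb = g.length / 10000
                if hit:
                    rec["pog_hit_orfs"] = int(max(cfg.pog_min_orfs,
                                                  math.ceil(cfg.pog_min_per_10kb
                                                            * per10kb)))
                else:
                    rec["pog_hit_orfs"] = int(rng.integers(0, 2))
        if g.id in rescue and is_v:
            rec["checkv_completeness"] = round(
                rng.uniform(cfg.checkv_hq_completeness, 100.0), 1)
            rec["checkv_quality"] = "high-quality"
        elif rng.random() < 0.5:
            rec["checkv_completeness"] = round(rng.uniform(5, 85), 1)
            rec["checkv_quality"] = "medium-quality"
        rows.append(rec)
    return pd.DataFrame(rows)


def gen_taxonomy(n_species: int) -> pd.DataFrame:
    """Balanced seven-rank taxonomy over ``n_species`` species.

    Species i chains through genus i//2, family i//4, order i//8, class
    i//16 and phylum i//32 to a single domain root.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rows = [{"node_id": "D0", "parent_id": "", "rank": "domain",
             "name": "Bacteria"}]
    seen = {"D0"}

    def add(node, parent, rank):
        if node not in seen:
            rows.append({"node_id": node, "parent_id": parent, "rank": rank,
                         "name": node})
            seen.add(node)

    for i in range(n_species):
        add(f"P{i // 32}", "D0", "phylum")
        add(f"C{i // 16}", f"P{i // 32}", "class")
        add(f"O{i // 8}", f"C{i // 16}", "order")
        add(f"F{i // 4}", f"O{i // 8}", "family")
        add(f"G{i // 2}", f"F{i // 4}", "genus")
        add(f"S{i}", f"G{i // 2}", "species")
    return pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])


def gen_hosts(viral_genomes: Sequence[Contig], n_species: int, seed: int,
              cfg: PipelineConfig | None = None):
    """Bacterial genomes, spacers, tRNA genes, taxonomy and planted links.

    The first five viral genomes are linked to species S0..S4 with evidence
    patterns {2 spacers, 2 tRNAs, 1 spacer + 1 tRNA, 1 spacer, 1 short
    spacer}, expecting confidences {high, high, high, low, low}.  Decoy
    spacers and tRNAs with no viral origin exercise the no-match path.

    Returns (bacterial_genomes, spacers, viral_trnas, bacterial_trnas,
    taxonomy_df, truth_links) where spacers/trnas are (id, owner, sequence)
    tuples and truth_links rows are (virus_id, host_species_id, kind,
    count, expected_confidence).
    """
    cfg = cfg or PipelineConfig()
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    bacteria = [gen_genome(20000, 0.5, seed + 1000 + i, id=f"B{i}")
                for i in range(n_species)]
    spacers: List[Tuple[str, str, str]] = []
    viral_trnas: List[Tuple[str, str, str]] = []
    bact_trnas: List[Tuple[str, str, str]] = []
    links = []
    patterns = [("spacer", 2), ("trna", 2), ("mixed", 1), ("spacer", 1),
                ("short_spacer", 1)]
    expected = ["high", "high", "high", "low", "low"]
    for i, (kind, count) in enumerate(patterns):
        if i >= len(viral_genomes) or i >= n_species:
            break
        virus = viral_genomes[i]
        species = f"S{i}"
        n_spacers = n_trnas = 0
        if kind in ("spacer", "mixed", "short_spacer"):
            n = count if kind == "spacer" else 1
            for j in range(n):
                ln = 18 if kind == "short_spacer" else int(rng.integers(25, 46))
                pos = int(rng.integers(0, virus.length - ln))
                sp = virus.sequence[pos:pos + ln]
                if rng.random() < 0.5:
                    sp = revcomp(sp)
                spacers.append((f"sp_{species}_{j}", species, sp))
                n_spacers += 1
        if kind in ("trna", "mixed"):
            n = count if kind == "trna" else 1
            for j in range(n):
                ln = int(rng.integers(70, 91))
                pos = int(rng.integers(0, virus.length - ln))
                gene = virus.sequence[pos:pos + ln]
                viral_trnas.append((f"vt_{virus.id}_{j}", virus.id, gene))
                bact_trnas.append((f"bt_{species}_{j}", species, gene))
                n_trnas += 1
        links.append({"virus_id": virus.id, "host_species_id": species,
                      "kind": kind, "n_spacers": n_spacers,
                      "n_trnas": n_trnas,
                      "expected_confidence": expected[i]})
    # decoys with no planted origin
    for i in range(n_species):
        ln = int(rng.integers(25, 46))
        seq = gen_genome(max(100, ln), 0.5, seed + 2000 + i).sequence[:ln]
        spacers.append((f"sp_decoy_{i}", f"S{i % n_species}", seq))
    for i in range(3):
        gene = gen_genome(100, 0.5, seed + 3000 + i).sequence[:80]
        bact_trnas.append((f"bt_decoy_{i}", f"S{i % n_species}", gene))
    taxonomy = gen_taxonomy(n_species)
    return (bacteria, spacers, viral_trnas, bact_trnas, taxonomy,
            pd.DataFrame(links))


# ---------------------------------------------------------------------------
# Whole-workspace generation
# ---------------------------------------------------------------------------

def simulate_workspace(outdir: str | Path, n_genomes: int = 60,
                       n_samples: int = 5, seed: int = 1,
                       noise: float = 0.0,
                       cfg: PipelineConfig | None = None) -> Dict[str, SimulationTruth]:
    """Write a self-contained synthetic workspace under ``outdir``.

    Community composition (for the default 60 contigs): 20 viral cluster
    founders (6-15 kb; the last is a 72-kb crAssphage-like genome; the
    first five circular with planted terminal repeats), 10 within-cluster
    mutants at 1-3% divergence, 4 mosaics sharing 75% with reference-only
    donors, 3 sub-5-kb viral fragments, 3 bacterial contaminant contigs and
    20 non-viral random contigs.  The reference catalogue contains verbatim
    copies of founders 10-14 (identical class) and the mosaic donors
    (partial class); everything else is novel.
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    truthdir = outdir / "truth"
    inputs.mkdir(parents=True, exist_ok=True)
    truthdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths: Dict[str, SimulationTruth] = {}
    contigs: List[Contig] = []

    def record(c: Contig, **kw) -> Contig:
        truths[c.id] = SimulationTruth(genome_id=c.id, **kw)
        contigs.append(c)
        return c

    n_founders = max(6, min(20, n_genomes // 3))
    sources = ["long", "hybrid", "short"]
    founders: List[Contig] = []
    for i in range(n_founders):
        length = 72000 if i == n_founders - 1 else int(rng.integers(6000, 15001))
        g = gen_genome(length, float(rng.uniform(0.35, 0.6)),
                       seed * 1000 + i, id=f"v{i:02d}")
        g.sample_id = f"S{int(rng.integers(0, n_samples)) + 1:02d}"
        g.assembly_source = sources[i % 3]
        circular = i < 5
        if circular:
            g = make_circular(g, int(rng.integers(35, 91)), id=g.id)
        founders.append(g)
        # founders 10-14 are copied verbatim into the reference catalogue
        novelty = "identical" if 10 <= i <= 14 else "novel"
        record(g, is_viral=True, is_circular=circular,
               source_group="", cluster_id=f"cl{i:02d}",
               divergence_from_parent=0.0, novelty_class=novelty,
               lifestyle_score=0.0)

    # within-cluster mutants (founders 0-9), 1-3% divergence
    n_mutants = min(10, n_founders)
    for i in range(n_mutants):
        div = float(rng.uniform(0.01, 0.03))
        m = mutate(founders[i], div, seed * 2000 + i, id=f"v{i:02d}_m1")
        # mutants carry the opposite technology -> their clusters group "both"
        m.assembly_source = ("short" if founders[i].assembly_source != "short"
                             else "long")
        m.sample_id = f"S{int(rng.integers(0, n_samples)) + 1:02d}"
        record(m, is_viral=True, is_circular=False, source_group="",
               cluster_id=f"cl{i:02d}", divergence_from_parent=div,
               novelty_class=truths[founders[i].id].novelty_class,
               lifestyle_score=0.0)

    # expected source group of each cluster representative
    for i, f in enumerate(founders):
        cluster_sources = {c.assembly_source for c in contigs
                           if truths[c.id].cluster_id == f"cl{i:02d}"}
        if cluster_sources <= {"short"}:
            truths[f.id].source_group = "short"
        elif "short" in cluster_sources:
            truths[f.id].source_group = "both"
        else:
            truths[f.id].source_group = "long"

    # mosaics against reference-only donors: partial novelty class
    donors = []
    for j in range(4):
        donor = gen_genome(int(rng.integers(8000, 12001)), 0.5,
                           seed * 3000 + j, id=f"refdonor{j}")
        donors.append(donor)
        mz = make_mosaic(donor, gen_genome(donor.length, 0.5,
                                           seed * 3100 + j),
                         0.75, seed * 3200 + j, id=f"mz{j:02d}")
        mz.sample_id = f"S{int(rng.integers(0, n_samples)) + 1:02d}"
        mz.assembly_source = sources[j % 3]
        record(mz, is_viral=True, is_circular=False,
               source_group="short" if mz.assembly_source == "short" else "long",
               cluster_id=f"mzcl{j}", divergence_from_parent=0.25,
               novelty_class="partial", lifestyle_score=0.0)

    # short viral fragments, dropped by the >5 kb filter
    for j in range(3):
        g = gen_genome(int(rng.integers(2000, 4501)), 0.5,
                       seed * 4000 + j, id=f"short{j}")
        g.assembly_source = "short"
        record(g, is_viral=True, is_circular=False, source_group="short",
               cluster_id=f"shcl{j}", divergence_from_parent=0.0,
               novelty_class="novel", lifestyle_score=0.0, below_length=True)

    # bacterial genomes, prophages and contaminant contigs
    n_species = 10
    (bacteria, spacers, viral_trnas, bact_trnas, taxonomy_df,
     links) = gen_hosts(founders, n_species, seed * 5000, cfg)
    # bacterium B0 carries founder 0's first 60% as an annotated prophage:
    # masking must prevent the founder's false removal as bacterial
    pro_len = int(0.6 * founders[0].length)
    b0 = bacteria[0]
    bacteria[0] = Contig(id=b0.id, sequence=founders[0].sequence[:pro_len]
                         + b0.sequence[pro_len:])
    prophage_rows = [{"genome_id": "B0", "start": 0, "end": pro_len}]
    for j in range(3):
        src = bacteria[(j % (n_species - 1)) + 1]
        frag_len = int(rng.integers(7000, 9001))
        start = int(rng.integers(0, src.length - frag_len))
        frag = mutate(Contig(id=f"cont{j}",
                             sequence=src.sequence[start:start + frag_len]),
                      0.03, seed * 6000 + j, id=f"cont{j}")
        frag.assembly_source = "short"
        record(frag, is_viral=False, is_circular=False, source_group="",
               cluster_id=f"ctcl{j}", divergence_from_parent=0.03,
               novelty_class="novel", lifestyle_score=0.0,
               removed_as_bacterial=True)

    # plain non-viral contigs to fill the community
    n_filler = max(0, n_genomes - len(contigs))
    for j in range(n_filler):
        g = gen_genome(int(rng.integers(6000, 12001)), 0.5,
                       seed * 7000 + j, id=f"nv{j:02d}")
        g.assembly_source = sources[j % 3]
        record(g, is_viral=False, is_circular=False, source_group="",
               cluster_id=f"nvcl{j}", divergence_from_parent=0.0,
               novelty_class="novel", lifestyle_score=0.0)

    # detector evidence; contaminants look viral so decontamination, not the
    # calling rule, must remove them
    looks_viral = {c.id: (truths[c.id].is_viral
                          or truths[c.id].removed_as_bacterial)
                   for c in contigs}
    hq_ids = [founders[min(5, n_founders - 1)].id]
    circ_only = [founders[4].id] if n_founders > 4 else []
    evidence = gen_evidence(contigs, looks_viral, noise, seed * 11 + 7, cfg,
                            hq_rescue_ids=hq_ids,
                            circular_only_ids=circ_only)

    # lifestyle scores cycle through the four bins with a safety margin
    bins = [(0.02, 0.28), (0.32, 0.48), (0.52, 0.68), (0.72, 0.98)]
    styles = []
    for idx, c in enumerate(contigs):
        lo, hi = bins[idx % 4]
        score = round(float(rng.uniform(lo, hi)), 3)
        truths[c.id].lifestyle_score = score
        styles.append({"contig_id": c.id, "score": score})

    # protein COG categories, METABOLISM enriched among novel vOTUs
    cog_rows = []
    categories = ["INFORMATION STORAGE AND PROCESSING",
                  "CELLULAR PROCESSES AND SIGNALING", "METABOLISM",
                  "POORLY CHARACTERIZED"]
    for c in contigs:
        if not truths[c.id].is_viral:
            continue
        p_metab = 0.55 if truths[c.id].novelty_class == "novel" else 0.15
        for pnum in range(10):
            if rng.random() < p_metab:
                cat = "METABOLISM"
            else:
                cat = categories[int(rng.integers(0, 4)) % 3]
                if cat == "METABOLISM":
                    cat = "POORLY CHARACTERIZED"
            cog_rows.append({"protein_id": f"{c.id}_p{pnum}",
                             "contig_id": c.id, "category": cat})

    # crAssphage marker evidence for the long founder
    crass_id = founders[n_founders - 1].id
    crass_rows = [{"contig_id": crass_id, "target": "terminase",
                   "significant": 1}]

    placements = gen_community(contigs, n_samples, seed * 13 + 3, truths,
                               circular_ids=[f.id for f in founders[:5]],
                               cfg=cfg)

    for _, row in links.iterrows():
        t = truths[row["virus_id"]]
        t.planted_hosts.append((row["host_species_id"], row["kind"],
                                int(row["n_spacers"] + row["n_trnas"])))
        t.expected_confidence = row["expected_confidence"]

    # ---- write everything --------------------------------------------------
    write_fasta(contigs, inputs / "contigs.fasta")
    write_table(pd.DataFrame(
        [{"contig_id": c.id, "sample_id": c.sample_id,
          "assembly_source": c.assembly_source} for c in contigs]),
        inputs / "contig_meta.tsv")
    write_table(evidence, inputs / "evidence.tsv")
    write_table(placements, inputs / "placements.tsv")
    refdir = inputs / "references"
    ref_contigs = [Contig(id=f"ref_{founders[i].id}",
                          sequence=founders[i].sequence)
                   for i in range(10, min(15, n_founders))]
    ref_contigs += [Contig(id=f"ref_{d.id}", sequence=d.sequence)
                    for d in donors]
    write_fasta(ref_contigs, refdir / "public_catalogue.fasta")
    bactdir = inputs / "bacteria"
    write_fasta(bacteria, bactdir / "genomes.fasta")
    write_table(pd.DataFrame(prophage_rows),
                bactdir / "prophage_intervals.tsv")
    hostdir = inputs / "hosts"
    write_fasta([Contig(id=f"{sid}|host={host}", sequence=seq)
                 for sid, host, seq in spacers], hostdir / "spacers.fasta")
    write_fasta([Contig(id=f"{gid}|virus={owner}", sequence=seq)
                 for gid, owner, seq in viral_trnas],
                hostdir / "trnas_viral.fasta")
    write_fasta([Contig(id=f"{gid}|host={owner}", sequence=seq)
                 for gid, owner, seq in bact_trnas],
                hostdir / "trnas_bacterial.fasta")
    write_table(taxonomy_df, inputs / "taxonomy.tsv")
    write_table(pd.DataFrame(styles), inputs / "lifestyle.tsv")
    write_table(pd.DataFrame(cog_rows), inputs / "cog.tsv")
    write_table(pd.DataFrame(crass_rows), inputs / "crass_protein_hits.tsv")

    # truth tables
    write_table(pd.DataFrame(
        [{"genome_id": t.genome_id, "is_viral": t.is_viral,
          "is_circular": t.is_circular, "source_group": t.source_group,
          "cluster_id": t.cluster_id,
          "divergence": t.divergence_from_parent,
          "novelty_class": t.novelty_class,
          "lifestyle_score": t.lifestyle_score,
          "removed_as_bacterial": t.removed_as_bacterial,
          "below_length": t.below_length,
          "expected_confidence": t.expected_confidence}
         for t in truths.values()]), truthdir / "genomes.tsv")
    write_table(pd.DataFrame(
        [{"sample_id": s, "contig_id": t.genome_id, "present": p,
          "abundance": t.abundance.get(s, 0.0)}
         for t in truths.values() for s, p in sorted(t.present_in.items())]),
        truthdir / "presence.tsv")
    write_table(links, truthdir / "host_links.tsv")
    return truths
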