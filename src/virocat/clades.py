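"""Clade identification (crAssphage), lifestyle binning, V/T ratios and
COG-category enrichment.

crAssphage calls follow the marker rule: a contig longer than 70 kb with
either a significant protein hit to the prototypical crAssphage polymerase
or terminase, or >=95% nucleotide identity to the prototype genome over
>=80% of the contig length.  Lifestyle categories bin a continuous
virulence score at 0.3/0.5/0.7 (temperate <= 0.3 < uncertain temperate
<= 0.5 < uncertain virulent <= 0.7 < virulent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import chi2_contingency

from .config import PipelineConfig
from .io import Contig, log

LIFESTYLE_CATEGORIES = ("temperate", "uncertain_temperate",
                        "uncertain_virulent", "virulent")
VIRULENT_SIDE = {"virulent", "uncertain_virulent"}
TEMPERATE_SIDE = {"temperate", "uncertain_temperate"}


@dataclass
class CladeCall:
    contig_id: str
    is_crass: bool
    crass_route: str    # protein_hit | nucleotide_identity | none
    is_guba: bool = False


@dataclass
class LifestyleCall:
    contig_id: str
    score: float
    category: str


def call_crassphage(contig: Contig, protein_hits: pd.DataFrame | None,
                    nt_identity: Optional[float] = None,
                    nt_coverage: Optional[float] = None,
                    cfg: PipelineConfig | None = None) -> CladeCall:
    """Apply the crAssphage marker rule to one contig.

    ``protein_hits`` rows carry (contig_id, target in {polymerase,
    terminase}, significant); ``nt_identity``/``nt_coverage`` summarise the
    nucleotide comparison against the prototype genome (percent).  The
    protein route is preferred when both fire.
    """
    cfg = cfg or PipelineConfig()
    if contig.length <= cfg.crass_min_len:
        return CladeCall(contig.id, False, "none")
    protein = False
    if protein_hits is not None and len(protein_hits):
        rows = protein_hits[protein_hits["contig_id"] == contig.id]
        for r in rows.itertuples(index=False):
            if str(r.target) in ("polymerase", "terminase") and _truthy(r.significant):
                protein = True
    nucleotide = (nt_identity is not None and nt_coverage is not None
                  and nt_identity >= cfg.crass_nt_identity
                  and nt_coverage >= cfg.crass_nt_coverage)
    if protein:
        return CladeCall(contig.id, True, "protein_hit")
    if nucleotide:
        return CladeCall(contig.id, True, "nucleotide_identity")
    return CladeCall(contig.id, False, "none")


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def six_frame_translate(seq: str) -> List[str]:
    """Translate all six reading frames; stops rendered as ``*``."""
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    frames = []
    for template in (seq, rc):
        for off in range(3):
            sub = template[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()) if sub else "")
    return frames


def classify_lifestyle(score: float,
                       cfg: PipelineConfig | None = None) -> str:
    """Bin a virulence score into the four lifestyle categories."""
    cfg = cfg or PipelineConfig()
    if not 0 <= score <= 1:
        raise ValueError(f"lifestyle score must be in [0,1], got {score}")
    t, u, v = cfg.lifestyle_bins
    if score <= t:
        return "temperate"
    if score <= u:
        return "uncertain_temperate"
    if score <= v:
        return "uncertain_virulent"
    return "virulent"


def lifestyle_table(scores: pd.DataFrame,
                    cfg: PipelineConfig | None = None) -> pd.DataFrame:
    cfg = cfg or PipelineConfig()
    rows = [{"contig_id": str(r["contig_id"]), "score": float(r["score"]),
             "category": classify_lifestyle(float(r["score"]), cfg)}
            for _, r in scores.iterrows()]
    return pd.DataFrame(rows, columns=["contig_id", "score", "category"])


def vt_ratio(categories: Sequence[str],
             pooled: bool = True) -> Tuple[Optional[float], bool]:
    """Virulent-to-temperate ratio for one host taxon's viruses.

    Pooled mode (default) counts the uncertain bins with their side; strict
    mode counts only the unequivocal bins.  Returns (ratio, defined); an
    all-virulent taxon has an undefined ratio (zero denominator), never
    infinity.
    """
    if not categories:
        raise ValueError("V/T ratio requires at least one lifestyle call")
    if pooled:
        v = sum(1 for c in categories if c in VIRULENT_SIDE)
        t = sum(1 for c in categories if c in TEMPERATE_SIDE)
    else:
        v = sum(1 for c in categories if c == "virulent")
        t = sum(1 for c in categories if c == "temperate")
    if t == 0:
        return None, False
    return v / t, True


def virulent_side_percentage(counts: Dict[str, int],
                             catalogue_size: int) -> float:
    """Percentage of a catalogue on the virulent side of the lifestyle bins.

    Pools ``virulent`` with ``uncertain_virulent`` and divides by the
    catalogue size (not the category-count total, which can differ when the
    published per-category counts do not sum exactly to the catalogue),
    rounded to two decimals.
    """
    if catalogue_size <= 0:
        raise ValueError("catalogue size must be positive")
    v = sum(counts.get(c, 0) for c in VIRULENT_SIDE)
    return round(100.0 * v / catalogue_size, 2)


def published_lifestyle_reference() -> Dict:
    """Counts and catalogue size of the published gut-catalogue worked
    example shipped with the package."""
    import json
    from importlib import resources

    path = resources.files("virocat").joinpath(
        "data/gut_catalogue_lifestyle.json")
    return json.loads(path.read_text())


def cog_enrichment(novel_counts: Dict[str, int], other_counts: Dict[str, int],
                   n_novel: int, n_other: int,
                   cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-COG-category chi-square enrichment of novel vOTU proteins.

    For each category a 2x2 table (in-category vs not, novel vs other) is
    tested with Pearson's chi-square without continuity correction;
    enrichment requires p < 0.001 AND a higher in-category proportion among
    novel proteins.  Categories with a zero margin are skipped.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for cat in sorted(set(novel_counts) | set(other_counts)):
        a = novel_counts.get(cat, 0)          # novel, in category
        b = n_novel - a                        # novel, not in category
        c = other_counts.get(cat, 0)           # other, in category
        d = n_other - c
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            log.warning("COG category %s skipped: zero margin", cat)
            continue
        chi2, p, _, _ = chi2_contingency(table, correction=False)
        enriched = bool(p < cfg.enrich_alpha and (a / (a + b)) > (c / (c + d)))
        rows.append({"category": cat, "novel_in": a, "novel_out": b,
                     "other_in": c, "other_out": d, "chi2": float(chi2),
                     "p": float(p), "enriched": enriched})
    return pd.DataFrame(rows, columns=["category", "novel_in", "novel_out",
                                       "other_in", "other_out", "chi2", "p",
                                       "enriched"])
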