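"""Pipeline-wide threshold configuration.

Every numeric cutoff used by the catalogue-construction stages lives in one
:class:`PipelineConfig` so that a single flat key=value file controls the
whole pipeline.  Defaults are the published human-gut virome catalogue
settings (detector score cutoffs, 95% ANI dereplication, 30-bp terminal
repeats, 95/70 novelty classes, MCL inflation 4.0, >50% breadth / >4X depth
presence, 0.3/0.5/0.7 lifestyle bins, ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple


class ConfigError(ValueError):
    """Raised when a configuration file or value is invalid."""


@dataclass(frozen=True)
class PipelineConfig:
    # -- viral-calling criteria ------------------------------------------
    virsorter_min: float = 0.7        # criterion C1: score >= this
    virfinder_min: float = 0.6        # criterion C2: score strictly > this
    pprmeta_min: float = 0.7          # criterion C3: score strictly > this
    refseq_min_identity: float = 50.0   # C4: percent identity strictly >
    refseq_min_coverage: float = 90.0   # C4: percent coverage strictly >
    pog_min_orfs: int = 3             # C5: ORFs with phage-orthologue hits
    pog_min_per_10kb: float = 2.0     # C5: hits per 10 kb of contig
    checkv_hq_completeness: float = 90.0  # single-criterion rescue
    # -- decontamination & length filter ---------------------------------
    decontam_identity: float = 90.0   # percent, >= (inclusive)
    decontam_coverage: float = 50.0   # percent of contig length, >=
    min_contig_len: int = 5000        # keep strictly longer than this
    # -- dereplication ----------------------------------------------------
    derep_identity: float = 0.95      # global identity over shorter seq
    # -- circularity ------------------------------------------------------
    tr_min_len: int = 30              # exact terminal repeat, >= bp
    circ_min_reads: int = 2           # junction-spanning reads, >=
    circ_min_hit: int = 50            # bp per terminal segment, >=
    circ_end_window: int = 100        # bp window defining "front"/"tail"
    # -- novelty vs reference catalogues ---------------------------------
    novelty_hsp_identity: float = 95.0
    novelty_hsp_minlen: int = 500
    novelty_identical: float = 95.0   # ANI >= -> identical
    novelty_partial: float = 70.0     # ANI >= -> partial
    # -- viral-cluster graph ----------------------------------------------
    vc_hsp_identity: float = 90.0
    vc_cov_large: float = 70.0        # percent of larger genome, strictly >
    vc_cov_small: float = 90.0        # percent of smaller genome, strictly >
    mcl_inflation: float = 4.0
    # -- crAssphage -------------------------------------------------------
    crass_min_len: int = 70000        # strictly longer than
    crass_nt_identity: float = 95.0
    crass_nt_coverage: float = 80.0
    # -- presence / abundance ---------------------------------------------
    presence_breadth: float = 0.5     # fraction, strictly >
    presence_depth: float = 4.0       # x-fold, strictly >
    # -- lifestyle ---------------------------------------------------------
    lifestyle_bins: Tuple[float, float, float] = (0.3, 0.5, 0.7)
    # -- host assignment ---------------------------------------------------
    spacer_min_len: int = 20          # shorter spacers are low confidence
    trna_identity: float = 95.0       # percent over 100% of viral gene
    # -- enrichment --------------------------------------------------------
    enrich_alpha: float = 0.001

    def __post_init__(self) -> None:
        for name in ("refseq_min_identity", "refseq_min_coverage",
                     "checkv_hq_completeness", "decontam_identity",
                     "decontam_coverage", "novelty_hsp_identity",
                     "novelty_identical", "novelty_partial",
                     "vc_hsp_identity", "vc_cov_large", "vc_cov_small",
                     "crass_nt_identity", "crass_nt_coverage",
                     "trna_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigError(f"{name} must be a percentage in [0,100], got {v}")
        for name in ("derep_identity", "presence_breadth"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a fraction in [0,1], got {v}")
        b = self.lifestyle_bins
        if not (len(b) == 3 and b[0] < b[1] < b[2]):
            raise ConfigError(f"lifestyle_bins must be strictly increasing, got {b}")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ConfigError(f"{f.name} must be strictly positive, got {v}")


_INT_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)
               if f.type == "int"}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a flat ``key = value`` config file; absent keys take defaults.

    ``lifestyle_bins`` is written as three comma-separated numbers.  Lines
    starting with ``#`` and blank lines are ignored.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        for lineno, raw in enumerate(path.read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value, got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _parse_value(key, val)
    values.update(overrides)
    try:
        return PipelineConfig(**values)
    except TypeError as exc:  # pragma: no cover - unknown kw already caught
        raise ConfigError(str(exc)) from exc


def _parse_value(key: str, val: str):
    if key == "lifestyle_bins":
        parts = [p.strip() for p in val.split(",")]
        if len(parts) != 3:
            raise ConfigError(f"lifestyle_bins needs 3 comma-separated values, got {val!r}")
        try:
            return tuple(float(p) for p in parts)
        except ValueError:
            raise ConfigError(f"non-numeric lifestyle_bins value: {val!r}") from None
    try:
        return int(val) if key in _INT_FIELDS else float(val)
    except ValueError:
        raise ConfigError(f"non-numeric value for {key}: {val!r}") from None


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of every threshold, recorded in workspace manifests."""
    import hashlib

    payload = repr(sorted(dataclasses.asdict(cfg).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
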