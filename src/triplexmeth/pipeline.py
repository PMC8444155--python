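"""File-level pipeline runner and configuration.

:class:`PipelineConfig` collects input paths and stage parameters (every
default equals the protocol's published setting: FDR 0.05, delta 0.1,
pairing cutoff 0.1, triplex length 10 / error rate 20% / guanine rate 70%,
100-nt windows, 100 resamples, 3 kb flank); :func:`run_pipeline` builds a
:class:`~triplexmeth.model.TriplexProtectionModel` from the files, fits it
and writes every artifact plus a machine-readable JSON report.  Runs are
byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .coloc import ColocParams
from .methylation import ClassifierParams
from .model import TriplexProtectionModel, TriplexProtectionResults
from .stats import EnrichmentParams
from .structure import StructureParams
from .triplex import TriplexParams
from . import io as tio

__all__ = ["PipelineConfig", "run_pipeline", "simulate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one end-to-end run."""

    genome_fasta: str
    probes_bed: str
    beta_tsv: str
    groups_tsv: str
    rna_fasta: str
    outdir: str
    contacts_bedpe: str | None = None
    lunp: str | None = None
    rna_locus: str | None = None  # e.g. "chrL:1-800" (1-based inclusive)
    window_width: int = 100
    seed: int = 0
    log_level: str = "INFO"
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    structure: StructureParams = field(default_factory=StructureParams)
    triplex: TriplexParams = field(default_factory=TriplexParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    flank: int = 3000

    _INPUT_FIELDS = ("genome_fasta", "probes_bed", "beta_tsv", "groups_tsv",
                     "rna_fasta", "contacts_bedpe", "lunp")

    def validate(self) -> None:
        for name in self._INPUT_FIELDS:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config field '{name}': no such file: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword overrides beat file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        nested = {
            "classifier": ClassifierParams,
            "structure": StructureParams,
            "triplex": TriplexParams,
            "enrichment": EnrichmentParams,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                if "motifs" in value:
                    value = {**value, "motifs": tuple(value["motifs"])}
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["triplex"]["motifs"] = list(out["triplex"]["motifs"])
        return out


def run_pipeline(config: PipelineConfig) -> TriplexProtectionResults:
    """Run every stage on file inputs and write all artifacts.

    The JSON report under ``<outdir>/report.json`` is the machine-readable
    record of the run: all counts, test statistics, and the full parameter
    set actually used.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    coloc = ColocParams(
        flank=config.flank,
        rna_locus=tio.parse_region(config.rna_locus) if config.rna_locus else None,
    )
    model = TriplexProtectionModel.from_files(
        config.genome_fasta, config.probes_bed, config.beta_tsv,
        config.groups_tsv, config.rna_fasta,
        contacts_bedpe=config.contacts_bedpe, lunp=config.lunp,
        classifier_params=config.classifier,
        structure_params=config.structure,
        triplex_params=config.triplex,
        enrichment_params=config.enrichment,
        coloc_params=coloc,
        window_width=config.window_width,
    )
    logger.info("parameters: %s", config.to_dict())
    results = model.fit(seed=config.seed)
    paths = results.save_artifacts(config.outdir)
    # fold the effective config into the report for a complete audit trail
    report = results.to_report()
    report["config"] = config.to_dict()
    tio.write_json_report(paths["report"], report)
    logger.info("artifacts written to %s", config.outdir)
    return results


def simulate_inputs(cfg, outdir: str | Path,
                    structure_params: StructureParams = StructureParams(),
                    triplex_params: TriplexParams = TriplexParams()) -> dict:
    """Generate a complete synthetic input set (including contacts) on disk.

    Contact placement needs to know which windows are triplex-positive, so
    the folding/masking and triplex stages run here with the supplied
    parameters before the contact table is drawn.
    """
    from .structure import mask_paired, pair_probabilities, unpaired_profile
    from .synthetic import attach_contacts, simulate, write_inputs
    from .triplex import find_triplexes
    from .windows import build_windows, extract_window_sequences

    bundle = simulate(cfg)
    profile = unpaired_profile(pair_probabilities(bundle.rna, structure_params))
    masked = mask_paired(bundle.rna, profile, structure_params)
    wins = build_windows(bundle.probes, bundle.chrom_lengths, cfg.window_width)
    wins = extract_window_sequences(wins, bundle.genome)
    hits = find_triplexes(masked, wins, triplex_params)
    positive_ids = {h.region for h in hits}
    positive = wins[wins["probe_id"].astype(str).isin(positive_ids)]
    attach_contacts(bundle, positive, wins)
    return write_inputs(bundle, outdir)
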