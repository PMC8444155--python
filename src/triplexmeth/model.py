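"""Model/Results interface over the full protection analysis.

:class:`TriplexProtectionModel` bundles the inputs of the analysis — a
two-group beta matrix, CpG probe coordinates, a genome, the lncRNA and
(optionally) RNA-chromatin contacts — and :meth:`fit` runs the stages in
order:

1. classify probes into HM / NHM / OTHER;
2. fold the lncRNA (or ingest an accessibility track) and mask paired
   nucleotides;
3. build CpG-centered target windows and extract their sequences;
4. search the masked RNA against every window for triplex hits;
5. test hypermethylation against triplex positivity (Fisher) and compute
   per-DBD background-resampled enrichment;
6. when contacts are available, confirm predictions against them and test
   methylation protection at the validated sites.

The returned :class:`TriplexProtectionResults` carries every intermediate
table, the test statistics, a ``summary()`` text report and JSON/TSV
exporters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as tio
from .coloc import (ColocParams, filter_rna_contacts, protection_at_validated_sites,
                    validate_triplexes)
from .methylation import ClassifierParams, classify_cpgs
from .stats import (DBD, EnrichmentParams, cluster_dbds, dbds_to_frame,
                    enrich_dbds, hm_protection_table)
from .structure import StructureParams, mask_paired, pair_probabilities, unpaired_profile
from .triplex import TriplexHit, TriplexParams, find_triplexes, hits_to_frame
from .windows import build_windows, extract_window_sequences

__all__ = ["TriplexProtectionModel", "TriplexProtectionResults", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage of the analysis failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


class TriplexProtectionModel:
    """Genome-wide test of triplex-mediated protection from hypermethylation.

    Parameters
    ----------
    beta, groups
        Probes x samples beta matrix and per-sample 'mut'/'wt' labels.
    probes
        Frame with probe_id, chrom, pos (0-based position of the CpG's C).
    genome
        ``{chrom: sequence}`` on the same assembly as the probes.
    rna
        The lncRNA sequence (5'->3').
    contacts
        Optional BEDPE-like contact frame (see :mod:`triplexmeth.io`).
    unpaired_track
        Optional externally computed accessibility profile (e.g. from
        :func:`triplexmeth.io.read_lunp`); replaces the internal fold.
    n_background_windows
        Size of the random background window pool for DBD enrichment
        (default: twice the number of triplex-positive windows, >= 50).
    """

    def __init__(self, beta: pd.DataFrame, groups: pd.Series, probes: pd.DataFrame,
                 genome: Mapping[str, str], rna: str, *,
                 contacts: pd.DataFrame | None = None,
                 unpaired_track: pd.DataFrame | None = None,
                 classifier_params: ClassifierParams = ClassifierParams(),
                 structure_params: StructureParams = StructureParams(),
                 triplex_params: TriplexParams = TriplexParams(),
                 enrichment_params: EnrichmentParams = EnrichmentParams(),
                 coloc_params: ColocParams = ColocParams(),
                 window_width: int = 100,
                 n_background_windows: int | None = None):
        self.beta = beta
        self.groups = groups
        self.probes = probes.reset_index(drop=True)
        self.genome = dict(genome)
        self.rna = rna
        self.contacts = contacts
        self.unpaired_track = unpaired_track
        self.classifier_params = classifier_params
        self.structure_params = structure_params
        self.triplex_params = triplex_params
        self.enrichment_params = enrichment_params
        self.coloc_params = coloc_params
        self.window_width = window_width
        self.n_background_windows = n_background_windows
        self.chrom_lengths = {c: len(s) for c, s in self.genome.items()}

    @classmethod
    def from_files(cls, genome_fasta, probes_bed, beta_tsv, groups_tsv, rna_fasta,
                   contacts_bedpe=None, lunp=None, **kwargs) -> "TriplexProtectionModel":
        """Build the model from the standard file formats."""
        genome = tio.read_fasta(genome_fasta)
        bed = tio.read_bed(probes_bed)
        probes = pd.DataFrame({
            "probe_id": bed["name"], "chrom": bed["chrom"], "pos": bed["start"],
        })
        beta = tio.read_beta_matrix(beta_tsv)
        groups = tio.read_sample_groups(groups_tsv)
        rna_records = tio.read_fasta(rna_fasta)
        rna = next(iter(rna_records.values()))
        contacts = tio.read_contacts(contacts_bedpe) if contacts_bedpe else None
        track = tio.read_lunp(lunp) if lunp else None
        return cls(beta, groups, probes, genome, rna, contacts=contacts,
                   unpaired_track=track, **kwargs)

    # -- helpers ----------------------------------------------------------

    def _background_windows(self, windows: pd.DataFrame,
                            rng: np.random.Generator) -> pd.DataFrame:
        """Random genome windows disjoint from every probe window, used as
        the resampling pool for DBD enrichment."""
        n_pos = int(windows["triplex_positive"].sum())
        n_bg = self.n_background_windows or max(50, 2 * n_pos)
        width = self.window_width
        chroms = sorted(self.chrom_lengths)
        weights = np.array([self.chrom_lengths[c] - width for c in chroms], dtype=float)
        weights /= weights.sum()
        occupied = windows[["chrom", "start", "end"]]
        rows = []
        attempts = 0
        while len(rows) < n_bg and attempts < 50 * n_bg:
            attempts += 1
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            s = int(rng.integers(0, self.chrom_lengths[c] - width))
            sub = occupied[occupied["chrom"] == c]
            if ((sub["start"] < s + width) & (sub["end"] > s)).any():
                continue
            rows.append({"probe_id": f"bg_{len(rows):05d}", "chrom": c,
                         "start": s, "end": s + width})
        if len(rows) < n_bg:
            raise ValueError("could not place enough background windows")
        bg = pd.DataFrame(rows)
        return extract_window_sequences(bg, self.genome)

    # -- fitting ----------------------------------------------------------

    def fit(self, seed: int = 0) -> "TriplexProtectionResults":
        """Run all stages; deterministic for a fixed seed."""
        rng = np.random.default_rng([7, seed])

        def stage(name):
            class _Ctx:
                def __enter__(self_inner):
                    return None

                def __exit__(self_inner, exc_type, exc, tb):
                    if exc is not None and not isinstance(exc, PipelineError):
                        raise PipelineError(name, exc) from exc
                    return False
            return _Ctx()

        with stage("classify"):
            classification = classify_cpgs(
                self.beta, self.groups, self.probes.set_index("probe_id"),
                self.classifier_params,
            )

        with stage("structure"):
            if self.unpaired_track is not None:
                profile = self.unpaired_track
            else:
                P = pair_probabilities(self.rna, self.structure_params)
                profile = unpaired_profile(P)
            masked_rna = mask_paired(self.rna, profile, self.structure_params)

        with stage("windows"):
            wins = build_windows(classification, self.chrom_lengths, self.window_width)
            wins = extract_window_sequences(wins, self.genome)

        with stage("triplex"):
            hits = find_triplexes(masked_rna, wins, self.triplex_params)
            positive_ids = {h.region for h in hits}
            wins["triplex_positive"] = wins["probe_id"].astype(str).isin(positive_ids)

        with stage("enrichment"):
            protection = hm_protection_table(classification, wins)
            dbds = cluster_dbds(hits, self.enrichment_params)
            background = self._background_windows(wins, rng)
            background_hits = find_triplexes(masked_rna, background, self.triplex_params)
            target_ids = wins.loc[wins["triplex_positive"], "probe_id"].astype(str)
            dbds = enrich_dbds(dbds, hits, list(target_ids),
                               list(background["probe_id"]), background_hits,
                               self.enrichment_params, rng)

        colocalization = None
        validated_protection = None
        rna_contacts = None
        if self.contacts is not None:
            with stage("colocalization"):
                cparams = self.coloc_params
                rna_contacts = filter_rna_contacts(self.contacts, cparams)
                colocalization = validate_triplexes(wins, rna_contacts, cparams,
                                                    self.chrom_lengths)
                validated = colocalization["validated_windows"]
                other = wins[~wins["probe_id"].isin(validated["probe_id"])]
                if len(validated) and len(other):
                    validated_protection = protection_at_validated_sites(
                        classification, validated, other)

        return TriplexProtectionResults(
            model=self,
            seed=seed,
            classification=classification,
            profile=profile,
            masked_rna=masked_rna,
            windows=wins,
            hits=hits,
            protection=protection,
            dbds=dbds,
            background_pool=len(background) if background is not None else 0,
            rna_contacts=rna_contacts,
            colocalization=colocalization,
            validated_protection=validated_protection,
        )


@dataclass
class TriplexProtectionResults:
    """Estimates, diagnostics and exporters of a fitted protection model."""

    model: TriplexProtectionModel
    seed: int
    classification: pd.DataFrame
    profile: pd.DataFrame
    masked_rna: str
    windows: pd.DataFrame
    hits: list[TriplexHit]
    protection: dict
    dbds: list[DBD]
    background_pool: int
    rna_contacts: pd.DataFrame | None = None
    colocalization: dict | None = None
    validated_protection: dict | None = None

    # -- derived counts ---------------------------------------------------

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.classification["klass"].value_counts()
        return {k: int(counts.get(k, 0)) for k in ("HM", "NHM", "OTHER")}

    @property
    def n_positive(self) -> int:
        return int(self.windows["triplex_positive"].sum())

    @property
    def n_negative(self) -> int:
        return int((~self.windows["triplex_positive"]).sum())

    @property
    def significant_dbds(self) -> list[DBD]:
        return [d for d in self.dbds if d.q_value <= 0.05]

    def hits_frame(self) -> pd.DataFrame:
        return hits_to_frame(self.hits)

    def dbd_frame(self) -> pd.DataFrame:
        return dbds_to_frame(self.dbds)

    def window_summary(self) -> pd.DataFrame:
        """Per-window triplex summary (hit counts per window)."""
        frame = self.hits_frame()
        counts = frame.groupby("region").size() if len(frame) else pd.Series(dtype=int)
        out = self.windows[["probe_id", "chrom", "start", "end", "klass",
                            "triplex_positive"]].copy()
        out["n_hits"] = out["probe_id"].astype(str).map(counts).fillna(0).astype(int)
        return out

    # -- reporting --------------------------------------------------------

    def to_report(self) -> dict:
        """Machine-readable summary (stable content for a fixed seed)."""
        masked = sum(1 for c in self.masked_rna if c == "N")
        report = {
            "seed": self.seed,
            "parameters": {
                "classifier": vars(self.model.classifier_params).copy(),
                "structure": vars(self.model.structure_params).copy(),
                "triplex": {**vars(self.model.triplex_params),
                            "motifs": list(self.model.triplex_params.motifs)},
                "enrichment": vars(self.model.enrichment_params).copy(),
                "coloc": {"flank": self.model.coloc_params.flank,
                          "rna_locus": list(self.model.coloc_params.rna_locus)
                          if self.model.coloc_params.rna_locus else None},
                "window_width": self.model.window_width,
            },
            "classification": {**self.class_counts,
                               "n_tested": int(len(self.classification))},
            "structure": {"rna_length": len(self.masked_rna),
                          "masked_positions": masked},
            "triplex": {"n_hits": len(self.hits),
                        "positive_windows": self.n_positive,
                        "negative_windows": self.n_negative},
            "protection": {
                "table": vars(self.protection["table"]).copy(),
                "odds_ratio": self.protection["odds_ratio"],
                "p_value": self.protection["p_value"],
            },
            "dbds": {"n": len(self.dbds),
                     "n_significant": len(self.significant_dbds),
                     "background_pool": self.background_pool},
        }
        if self.colocalization is not None:
            report["colocalization"] = {
                "contacts_at_locus": int(len(self.rna_contacts)),
                "confirmed_contacts": int(len(self.colocalization["confirmed_contacts"])),
                "validated_windows": int(len(self.colocalization["validated_windows"])),
                "table": vars(self.colocalization["table"]).copy(),
                "odds_ratio": self.colocalization["odds_ratio"],
                "p_value": self.colocalization["p_value"],
            }
        if self.validated_protection is not None:
            report["validated_protection"] = dict(self.validated_protection)
        return report

    def summary(self) -> str:
        """Human-readable summary table."""
        cc = self.class_counts
        prot = self.protection
        t = prot["table"]
        lines = [
            "          Triplex methylation-protection analysis",
            "=" * 64,
            f"Probes tested        {len(self.classification):>8}    "
            f"HM {cc['HM']:>6}  NHM {cc['NHM']:>6}  OTHER {cc['OTHER']:>5}",
            f"RNA length           {len(self.masked_rna):>8}    "
            f"masked {self.masked_rna.count('N')} nt",
            f"Target windows       {len(self.windows):>8}    "
            f"triplex-positive {self.n_positive}, negative {self.n_negative}",
            f"Triplex hits         {len(self.hits):>8}",
            "-" * 64,
            "HM/NHM x triplex +/- contingency "
            f"[[{t.a}, {t.b}], [{t.c}, {t.d}]]",
            f"  odds ratio {prot['odds_ratio']:.4g}   "
            f"Fisher two-sided p {prot['p_value']:.3g}",
            f"DNA-binding domains  {len(self.dbds):>8}    "
            f"significant (q<=0.05): {len(self.significant_dbds)}",
        ]
        if self.colocalization is not None:
            c = self.colocalization
            ct = c["table"]
            lines += [
                "-" * 64,
                f"Contacts at RNA locus {len(self.rna_contacts):>7}    "
                f"confirmed {len(c['confirmed_contacts'])}",
                f"positive/negative x contacted/not "
                f"[[{ct.a}, {ct.b}], [{ct.c}, {ct.d}]]  p {c['p_value']:.3g}",
            ]
        if self.validated_protection is not None:
            v = self.validated_protection
            lines.append(
                f"Validated-site protection: mean delta {v['mean_delta_validated']:.4f} "
                f"vs {v['mean_delta_other']:.4f}, rank-sum p {v['p_value']:.3g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    # -- artifacts --------------------------------------------------------

    def save_artifacts(self, outdir: str | Path) -> dict[str, Path]:
        """Write every stage artifact in its standard text format."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["classification"] = outdir / "classification.tsv"
        self.classification.to_csv(paths["classification"], sep="\t", index=False)

        paths["profile"] = outdir / "structure_profile.tsv"
        prof = self.profile.copy()
        prof["masked"] = [c == "N" for c in self.masked_rna]
        prof.to_csv(paths["profile"], sep="\t", index=False)

        paths["masked_rna"] = outdir / "lncrna_masked.fa"
        tio.write_fasta(paths["masked_rna"], {"lncRNA_masked": self.masked_rna})

        paths["windows"] = outdir / "windows.bed"
        bed = self.windows.copy()
        bed["name"] = bed["probe_id"]
        bed["score"] = np.where(bed["triplex_positive"], 1, 0)
        tio.write_bed(paths["windows"], bed, columns=["name", "score"])

        paths["window_fasta"] = outdir / "windows.fa"
        tio.write_fasta(paths["window_fasta"], {
            str(r.probe_id): r.seq for r in self.windows.itertuples(index=False)
        })

        paths["hits"] = outdir / "triplex_hits.tsv"
        self.hits_frame().to_csv(paths["hits"], sep="\t", index=False)

        paths["window_summary"] = outdir / "window_summary.tsv"
        self.window_summary().to_csv(paths["window_summary"], sep="\t", index=False)

        paths["dbds"] = outdir / "dbds.tsv"
        self.dbd_frame().to_csv(paths["dbds"], sep="\t", index=False)

        if self.colocalization is not None:
            paths["validated_windows"] = outdir / "validated_windows.bed"
            vw = self.colocalization["validated_windows"].copy()
            vw["name"] = vw["probe_id"]
            tio.write_bed(paths["validated_windows"], vw, columns=["name"])
            paths["confirmed_contacts"] = outdir / "confirmed_contacts.tsv"
            tio.write_contacts(paths["confirmed_contacts"],
                               self.colocalization["confirmed_contacts"])

        paths["report"] = outdir / "report.json"
        tio.write_json_report(paths["report"], self.to_report())
        return paths
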