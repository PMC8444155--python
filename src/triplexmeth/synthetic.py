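"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure of the real study inputs
at desk scale: a small multi-chromosome genome carrying CpG probes whose
100-nt windows either do or do not contain a guanine-rich purine tract
(the triplex target signal); a two-group beta-value matrix with the
carrier group hypermethylated at planted probes *except* the protected
(tract-bearing) ones; a lncRNA with planted hairpins plus an unpaired
purine-rich 3' tract (the triplex-forming region); and RNA-chromatin
contacts split into true contacts (placed within the colocalization flank
of triplex-positive windows) and decoys (placed at least twice the flank
away from every probe window, so they confirm nothing).

Two layout choices keep downstream tests deterministic rather than
probabilistic:

* tract-bearing and plain probes are placed in separate strata of each
  chromosome, separated by a gap wide enough that decoy contacts can be
  spaced away from every triplex-positive window;
* windows of plain probes are sanitised so that no 10-mer contains >= 7
  guanines (or >= 7 cytosines, the minus-strand equivalent), making
  "contains a purine tract" an exact planted property instead of a
  high-probability one.

With a fixed seed every output is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as tio

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SimBundle",
    "generate_genome",
    "generate_methylation",
    "generate_lncrna",
    "generate_contacts",
    "simulate",
    "write_inputs",
]

logger = logging.getLogger(__name__)

_TTS_SCAN_LEN = 10   # minimum TTS length of the default triplex search
_TTS_SCAN_MIN_G = 7  # guanines in a scan window that make it a tract
_TRACT_HALF = 20     # planted DNA tract spans pos +/- 20
_ANCHOR_LEN = 200    # DNA anchor length of synthetic contacts
_RNA_ANCHOR_LEN = 150
_STEM_LEN = 14
_LOOP_LEN = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic inputs.

    Group sizes default to the 13 mutation-carrier / 173 wild-type split
    of the real cohort; contact counts default to the 29 triplex-supported
    / 128 other contacts of the interactome benchmark; effect size, noise
    and thresholds are on the beta scale.
    """

    n_chrom: int = 2
    chrom_length: int = 80_000
    gc_fraction: float = 0.5
    n_probes: int = 200
    n_mut_samples: int = 13
    n_wt_samples: int = 173
    frac_hyper: float = 0.35
    effect_delta: float = 0.2
    beta_noise_sd: float = 0.05
    baseline_range: tuple[float, float] = (0.2, 0.6)
    frac_protected: float = 0.3
    couple_protection: bool = True
    lnc_length: int = 800
    n_hairpins: int = 3
    tfo_tract: tuple[int, int] | None = None  # default: 3' tract at 77.5-92.5% of length
    tfo_tract_composition: tuple[tuple[str, float], ...] = (("G", 0.8), ("A", 0.2))
    n_true_contacts: int = 29
    n_decoy_contacts: int = 128
    n_offsite_contacts: int = 0
    window_width: int = 100
    probe_spacing: int = 400
    stratum_gap: int = 12_000
    contact_flank: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "frac_hyper", "frac_protected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_mut_samples + self.n_wt_samples < 4:
            raise ValueError("need at least 4 samples in total")
        if self.tfo_tract is None:
            object.__setattr__(self, "tfo_tract",
                               (round(0.775 * self.lnc_length),
                                round(0.925 * self.lnc_length)))
        ts, te = self.tfo_tract
        if not (0 <= ts < te <= self.lnc_length):
            raise ValueError("tfo_tract must lie within [0, lnc_length)")
        if not 0.0 <= self.beta_noise_sd <= 1.0:
            raise ValueError("beta_noise_sd must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels for recovery tests."""

    hyper_probe_ids: frozenset[str] = frozenset()
    protected_probe_ids: frozenset[str] = frozenset()
    planted_tfo_interval: tuple[int, int] = (0, 0)
    true_contact_ids: frozenset[str] = frozenset()
    hairpins: tuple[tuple[int, int], ...] = ()


@dataclass
class SimBundle:
    """All synthetic inputs of one simulation (contacts attach later,
    once triplex-positive windows are known)."""

    cfg: SyntheticConfig
    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    probes: pd.DataFrame
    beta: pd.DataFrame
    groups: pd.Series
    rna: str
    rna_locus: tuple[str, int, int]
    truth: SyntheticTruth
    contacts: pd.DataFrame | None = None


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


# ---------------------------------------------------------------------------
# Genome and probes

def _sliding_counts(flags: np.ndarray, width: int) -> np.ndarray:
    cum = np.concatenate(([0], np.cumsum(flags)))
    return cum[width:] - cum[:-width]


def _sanitize_window(seq: np.ndarray, lo: int, hi: int, protected: set[int],
                     base: str, repl: str) -> None:
    """Rewrite [lo, hi) so that no 10-mer holds >= 7 copies of ``base``."""
    while True:
        flags = seq[lo:hi] == base
        counts = _sliding_counts(flags, _TTS_SCAN_LEN)
        offending = np.flatnonzero(counts >= _TTS_SCAN_MIN_G)
        if offending.size == 0:
            return
        start = lo + int(offending[0])
        for t in range(start, start + _TTS_SCAN_LEN):
            if seq[t] == base and t not in protected:
                seq[t] = repl
                break
        else:  # pragma: no cover - >=7 bases minus <=2 protected always leaves one
            raise RuntimeError("window sanitisation failed")


def _densify_tract(seq: np.ndarray, lo: int, hi: int, protected: set[int]) -> None:
    """Guarantee the planted tract holds at least one 10-mer with >= 7 G."""
    while True:
        flags = seq[lo:hi] == "G"
        counts = _sliding_counts(flags, _TTS_SCAN_LEN)
        if counts.size and counts.max() >= _TTS_SCAN_MIN_G:
            return
        dense = lo + int(np.argmax(counts))
        for t in range(dense, dense + _TTS_SCAN_LEN):
            if seq[t] != "G" and t not in protected:
                seq[t] = "G"
                break


def generate_genome(cfg: SyntheticConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic chromosomes plus the CpG probe table.

    Every probe position is the C of a planted CpG.  Tract-bearing probes
    (fraction ``frac_protected``) carry a guanine-rich purine tract across
    their window; plain probes are sanitised to contain none.  Returns the
    genome as ``{chrom: sequence}`` and a probe frame with columns
    probe_id, chrom, pos (0-based), in_purine_tract.
    """
    rng = _rng(cfg, 1)
    bases = np.array(list("ACGT"))
    probs = np.array([
        (1 - cfg.gc_fraction) / 2, cfg.gc_fraction / 2,
        cfg.gc_fraction / 2, (1 - cfg.gc_fraction) / 2,
    ])
    if cfg.chrom_length < 200:
        raise ValueError("chrom_length must be >= 200")

    # blockwise probe assignment across chromosomes
    counts = [cfg.n_probes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_probes % cfg.n_chrom):
        counts[i] += 1
    n_protected = round(cfg.frac_protected * cfg.n_probes)
    prot_counts = [int(np.floor(cfg.frac_protected * m)) for m in counts]
    i = 0
    while sum(prot_counts) < n_protected:
        if prot_counts[i % cfg.n_chrom] < counts[i % cfg.n_chrom]:
            prot_counts[i % cfg.n_chrom] += 1
        i += 1

    comp_bases = [b for b, _ in cfg.tfo_tract_composition]
    comp_probs = np.array([p for _, p in cfg.tfo_tract_composition])
    comp_probs = comp_probs / comp_probs.sum()

    genome: dict[str, str] = {}
    rows = []
    probe_no = 0
    margin = 2000
    half = cfg.window_width // 2
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        m, k = counts[c], prot_counts[c]
        required = (margin + k * cfg.probe_spacing + cfg.stratum_gap
                    + (m - k) * cfg.probe_spacing + margin)
        if m and required > cfg.chrom_length:
            raise ValueError(
                f"chrom_length {cfg.chrom_length} too short for {m} probes "
                f"on {chrom} (needs {required})"
            )
        seq = rng.choice(bases, size=cfg.chrom_length, p=probs)
        positions = []
        flags = []
        pos = margin
        for t in range(m):
            tract = t < k
            positions.append(pos)
            flags.append(tract)
            if tract:
                lo, hi = pos - _TRACT_HALF, pos + _TRACT_HALF
                seq[lo:hi] = rng.choice(comp_bases, size=hi - lo, p=comp_probs)
            pos += cfg.probe_spacing
            if t + 1 == k:
                pos += cfg.stratum_gap
        for p, tract in zip(positions, flags):
            seq[p], seq[p + 1] = "C", "G"
        for p, tract in zip(positions, flags):
            keep = {p, p + 1}
            if tract:
                _densify_tract(seq, p - _TRACT_HALF, p + _TRACT_HALF, keep)
            else:
                lo, hi = max(p - half, 0), min(p + half, cfg.chrom_length)
                _sanitize_window(seq, lo, hi, keep, "G", "T")
                _sanitize_window(seq, lo, hi, keep, "C", "A")
        genome[chrom] = "".join(seq)
        for p, tract in zip(positions, flags):
            rows.append({
                "probe_id": f"cg{probe_no:05d}",
                "chrom": chrom,
                "pos": p,
                "in_purine_tract": tract,
            })
            probe_no += 1
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "in_purine_tract"])
    return genome, probes


# ---------------------------------------------------------------------------
# Methylation

def generate_methylation(cfg: SyntheticConfig, probes: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Two-group beta matrix with planted hypermethylation.

    Wild-type betas are a per-probe uniform baseline plus clipped Gaussian
    noise; the carrier group gains ``effect_delta`` at planted hyper
    probes.  When ``couple_protection`` is on, hyper probes are drawn from
    the non-protected pool, so tract-bearing (protected) probes keep their
    baseline; switching it off draws hyper probes from all probes, making
    methylation class independent of triplex positivity (the null for
    calibration runs).  ``effect_delta == 0`` plants nothing.
    """
    if len(probes) == 0:
        raise ValueError("probe table is empty")
    rng = _rng(cfg, 2)
    ids = probes["probe_id"].to_numpy()
    protected = probes["in_purine_tract"].to_numpy(dtype=bool)
    n = len(ids)

    n_hyper = round(cfg.frac_hyper * n) if cfg.effect_delta != 0 else 0
    pool = ids[~protected] if cfg.couple_protection else ids
    if n_hyper > pool.size:
        raise ValueError("frac_hyper exceeds the eligible (non-protected) pool")
    hyper = set(rng.choice(pool, size=n_hyper, replace=False)) if n_hyper else set()

    baseline = rng.uniform(*cfg.baseline_range, size=n)
    if cfg.baseline_range[1] + cfg.effect_delta > 1:
        logger.warning("baseline + effect_delta can exceed 1; clipping will "
                       "attenuate the planted effect")
    effect = np.array([cfg.effect_delta if pid in hyper else 0.0 for pid in ids])

    def draw(mean: np.ndarray, k: int) -> np.ndarray:
        vals = mean[:, None] + rng.normal(0.0, cfg.beta_noise_sd, size=(n, k))
        return np.clip(vals, 0.0, 1.0)

    mut = draw(baseline + effect, cfg.n_mut_samples)
    wt = draw(baseline, cfg.n_wt_samples)
    sample_ids = ([f"mut_{i + 1:03d}" for i in range(cfg.n_mut_samples)]
                  + [f"wt_{i + 1:03d}" for i in range(cfg.n_wt_samples)])
    beta = pd.DataFrame(np.hstack([mut, wt]), index=pd.Index(ids, name="probe_id"),
                        columns=sample_ids)
    groups = pd.Series(
        ["mut"] * cfg.n_mut_samples + ["wt"] * cfg.n_wt_samples,
        index=sample_ids, name="group",
    )
    truth = SyntheticTruth(
        hyper_probe_ids=frozenset(hyper),
        protected_probe_ids=frozenset(ids[protected]),
    )
    return beta, groups, truth


# ---------------------------------------------------------------------------
# lncRNA

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def generate_lncrna(cfg: SyntheticConfig) -> tuple[str, SyntheticTruth]:
    """Random lncRNA with planted hairpins and an unpaired TFO tract.

    The tract is purine-rich (guanine-heavy by default) so it cannot fold
    on itself; hairpins are perfect reverse-complement stems (14 bp, 4-nt
    loop) planted outside the tract, which the accessibility model should
    call paired and mask.  Stem words are rejection-sampled to have a
    unique pairing register (little self-similarity under small register
    shifts, no mononucleotide runs), otherwise probability mass spreads
    over shifted helices and no single pair dominates.
    """
    if cfg.lnc_length < 100:
        raise ValueError("lnc_length must be >= 100")
    rng = _rng(cfg, 3)
    seq = rng.choice(np.array(list("ACGU")), size=cfg.lnc_length)
    ts, te = cfg.tfo_tract
    comp_bases = [b.replace("T", "U") for b, _ in cfg.tfo_tract_composition]
    comp_probs = np.array([p for _, p in cfg.tfo_tract_composition])
    seq[ts:te] = rng.choice(comp_bases, size=te - ts, p=comp_probs / comp_probs.sum())

    footprint = 2 * _STEM_LEN + _LOOP_LEN
    taken = [(ts, te)]
    hairpins: list[tuple[int, int]] = []
    candidates = list(range(0, cfg.lnc_length - footprint))
    rng.shuffle(candidates)
    for _ in range(cfg.n_hairpins):
        slot = None
        for s in candidates:
            e = s + footprint
            if all(e + 2 <= lo or s >= hi + 2 for lo, hi in taken):
                slot = s
                break
        if slot is None:
            raise ValueError(
                f"cannot place {cfg.n_hairpins} hairpins outside the TFO tract"
            )
        while True:
            stem = "".join(rng.choice(list("ACGU"), size=_STEM_LEN))
            rc = stem.translate(_RNA_COMPLEMENT)[::-1]
            shifted_ok = all(
                sum(a == b for a, b in zip(stem[sh:], rc[:_STEM_LEN - sh]))
                <= 0.4 * (_STEM_LEN - sh)
                for sh in (1, 2, 3)
            )
            if shifted_ok and not any(b * 4 in stem for b in "ACGU"):
                break
        loop = "".join(rng.choice(list("ACGU"), size=_LOOP_LEN))
        word = stem + loop + rc
        seq[slot:slot + footprint] = list(word)
        taken.append((slot, slot + footprint))
        hairpins.append((slot, slot + footprint))

    truth = SyntheticTruth(planted_tfo_interval=(ts, te), hairpins=tuple(sorted(hairpins)))
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# RNA-chromatin contacts

def _interval_distances(starts: np.ndarray, ends: np.ndarray,
                        lo: int, hi: int) -> np.ndarray:
    """Gap between [lo, hi) and each [start, end); 0 when overlapping."""
    return np.maximum.reduce([starts - hi, lo - ends,
                              np.zeros_like(starts)])


def generate_contacts(cfg: SyntheticConfig,
                      rna_locus: tuple[str, int, int],
                      positive_windows: pd.DataFrame,
                      all_windows: pd.DataFrame,
                      chrom_lengths: Mapping[str, int],
                      ) -> tuple[pd.DataFrame, frozenset[str]]:
    """BEDPE-like contact table with planted true contacts and decoys.

    True contacts put their DNA anchor within ``contact_flank`` of a
    triplex-positive window (cycled round-robin); decoys go to free
    genomic space at least ``2 * contact_flank`` away from every probe
    window, so they are never confirmed; offsite contacts carry an RNA
    anchor outside the lncRNA locus and are dropped by the contact filter.
    Returns the table plus the ids of the true contacts.
    """
    rng = _rng(cfg, 4)
    if cfg.n_true_contacts > 0 and len(positive_windows) == 0:
        raise ValueError("true contacts requested but no triplex-positive windows")
    rna_chrom, rna_lo, rna_hi = rna_locus
    flank = cfg.contact_flank
    rows = []

    def rna_anchor() -> tuple[int, int]:
        span = max(rna_hi - rna_lo - _RNA_ANCHOR_LEN, 1)
        s = rna_lo + int(rng.integers(0, span))
        return s, min(s + _RNA_ANCHOR_LEN, rna_hi)

    pos = positive_windows.reset_index(drop=True)
    for k in range(cfg.n_true_contacts):
        win = pos.iloc[k % len(pos)]
        gap = int(rng.integers(0, max(flank - _ANCHOR_LEN, 1)))
        left = bool(rng.integers(0, 2))
        if left and win["start"] - gap - _ANCHOR_LEN >= 0:
            d_end = int(win["start"]) - gap
            d_start = d_end - _ANCHOR_LEN
        else:
            d_start = int(win["end"]) + gap
            d_end = d_start + _ANCHOR_LEN
            if d_end > chrom_lengths[win["chrom"]]:
                raise ValueError("no room for a true contact anchor")
        rs, re = rna_anchor()
        rows.append((rna_chrom, rs, re, win["chrom"], d_start, d_end,
                     f"true_{k + 1:04d}"))

    # decoys: free space >= 2*flank away from every probe window
    clearance = 2 * flank
    spacing = _ANCHOR_LEN + 50
    slots: list[tuple[str, int]] = []
    for chrom, length in chrom_lengths.items():
        sub = all_windows[all_windows["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = (int(ends.max()) if len(sub) else 0) + clearance
        p = lo
        while p + _ANCHOR_LEN <= length:
            d = _interval_distances(starts, ends, p, p + _ANCHOR_LEN)
            if len(sub) == 0 or d.min() >= clearance:
                slots.append((chrom, p))
            p += spacing
    if len(slots) < cfg.n_decoy_contacts:
        raise ValueError(
            f"insufficient genome space for {cfg.n_decoy_contacts} decoys "
            f"(found {len(slots)} slots)"
        )
    for k in range(cfg.n_decoy_contacts):
        chrom, p = slots[k]
        rs, re = rna_anchor()
        rows.append((rna_chrom, rs, re, chrom, p, p + _ANCHOR_LEN,
                     f"decoy_{k + 1:04d}"))

    for k in range(cfg.n_offsite_contacts):
        chrom = f"chr{int(rng.integers(0, cfg.n_chrom)) + 1}"
        s = int(rng.integers(0, chrom_lengths[chrom] - _RNA_ANCHOR_LEN))
        d = int(rng.integers(0, chrom_lengths[chrom] - _ANCHOR_LEN))
        rows.append((chrom, s, s + _RNA_ANCHOR_LEN, chrom, d, d + _ANCHOR_LEN,
                     f"offsite_{k + 1:04d}"))

    contacts = pd.DataFrame(rows, columns=tio.CONTACT_COLUMNS)
    true_ids = frozenset(f"true_{k + 1:04d}" for k in range(cfg.n_true_contacts))
    return contacts, true_ids


# ---------------------------------------------------------------------------
# Orchestration

def simulate(cfg: SyntheticConfig) -> SimBundle:
    """Genome, probes, methylation and lncRNA (contacts attach once the
    triplex-positive windows are known; see the pipeline runner)."""
    genome, probes = generate_genome(cfg)
    beta, groups, truth_m = generate_methylation(cfg, probes)
    rna, truth_r = generate_lncrna(cfg)
    truth = SyntheticTruth(
        hyper_probe_ids=truth_m.hyper_probe_ids,
        protected_probe_ids=truth_m.protected_probe_ids,
        planted_tfo_interval=truth_r.planted_tfo_interval,
        hairpins=truth_r.hairpins,
    )
    return SimBundle(
        cfg=cfg,
        genome=genome,
        chrom_lengths={c: len(s) for c, s in genome.items()},
        probes=probes,
        beta=beta,
        groups=groups,
        rna=rna,
        rna_locus=("chrL", 0, cfg.lnc_length),
        truth=truth,
    )


def attach_contacts(bundle: SimBundle, positive_windows: pd.DataFrame,
                    all_windows: pd.DataFrame) -> SimBundle:
    contacts, true_ids = generate_contacts(
        bundle.cfg, bundle.rna_locus, positive_windows, all_windows,
        bundle.chrom_lengths,
    )
    bundle.contacts = contacts
    bundle.truth = replace(bundle.truth, true_contact_ids=true_ids)
    return bundle


def write_inputs(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic input in its standard text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "probes": outdir / "probes.bed",
        "beta": outdir / "beta.tsv",
        "groups": outdir / "groups.tsv",
        "rna": outdir / "lncrna.fa",
        "truth": outdir / "truth.json",
    }
    tio.write_fasta(paths["genome"], bundle.genome)
    bed = pd.DataFrame({
        "chrom": bundle.probes["chrom"],
        "start": bundle.probes["pos"],
        "end": bundle.probes["pos"] + 2,
        "name": bundle.probes["probe_id"],
    })
    tio.write_bed(paths["probes"], bed)
    tio.write_beta_matrix(paths["beta"], bundle.beta)
    tio.write_sample_groups(paths["groups"], bundle.groups)
    tio.write_fasta(paths["rna"], {"lncRNA": bundle.rna})
    if bundle.contacts is not None:
        paths["contacts"] = outdir / "contacts.bedpe"
        tio.write_contacts(paths["contacts"], bundle.contacts)
    truth = bundle.truth
    tio.write_json_report(paths["truth"], {
        "hyper_probe_ids": sorted(truth.hyper_probe_ids),
        "protected_probe_ids": sorted(truth.protected_probe_ids),
        "planted_tfo_interval": list(truth.planted_tfo_interval),
        "true_contact_ids": sorted(truth.true_contact_ids),
        "hairpins": [list(h) for h in truth.hairpins],
    })
    return paths
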