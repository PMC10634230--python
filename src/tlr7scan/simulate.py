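"""Synthetic data with planted ground truth for every pipeline stage.

Three generators, all pure functions of (config, seed):

* ``gen_transcriptome`` — a pool of transcripts of heterogeneous length
  and composition containing one planted "XIST-like" transcript: a
  contiguous UU-dense block (emulating an A-repeat-like U-rich region
  near the 5' end), an embedded 5'-GUCCUUCAA-3' motif at a recorded
  position, and (via ``gen_counts``) extreme female expression bias and
  high abundance.  Some genes get a second, shorter variant to exercise
  longest-variant selection.
* ``gen_counts`` — negative-binomial counts across tissues with per-gene
  sex effects and 3-fold library-size variation.
* ``gen_sc`` — a multi-patient single-cell matrix in which an IFN gene
  module and one tracking gene shift with a per-patient IFN intensity;
  one patient contributes fewer than 10 cells to exercise the filter.

Stage seeds derive from the master seed as ``default_rng([seed, stage])``
with a fixed integer per stage, so stages are independent but jointly
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .seqio import TLR7_MOTIF, TranscriptRecord

_STAGE_TRANSCRIPTOME = 1
_STAGE_COUNTS = 2
_STAGE_SC = 3

BASES = np.array(list("ACGU"))


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


@dataclass
class XistLikeConfig:
    """Shape of the planted XIST-like transcript."""

    gene: str = "XIL1"
    length: int = 3000
    block_start: int = 181  # 1-based; mimics a 5' U-rich repeat region
    block_length: int = 820
    u_density: float = 0.8
    motif_position: int = 2000  # 1-based
    motif: str = TLR7_MOTIF


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset; round-trips via JSON."""

    planted_gene: str = ""
    block_start: int = 0
    block_length: int = 0
    u_density: float = 0.0
    motif_position: int = 0
    motif: str = ""
    gene_lengths: dict = field(default_factory=dict)  # longest variant per gene
    sex_log2fc: dict = field(default_factory=dict)
    tissues: list = field(default_factory=list)
    ifn_intensity: dict = field(default_factory=dict)  # patient -> intensity
    ifn_genes: list = field(default_factory=list)
    tracking_gene: str = ""

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_fasta(records: list[TranscriptRecord], path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_symbol}|{rec.transcript_id}\n")
            for i in range(0, rec.length, wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def _random_sequence(rng: np.random.Generator, length: int, base_freqs) -> str:
    return "".join(rng.choice(BASES, size=length, p=base_freqs))


def gen_transcriptome(
    n_genes: int = 500,
    length_range: tuple[int, int] = (300, 3000),
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    xist_like: XistLikeConfig | None = None,
    variant_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Generate a transcript pool with one planted XIST-like gene.

    Background sequences are i.i.d. draws from ``base_freqs``; the planted
    transcript carries a contiguous block of ``u_density`` uridines and an
    embedded motif copy at a recorded 1-based position.  A fraction of
    background genes get a shorter second variant.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    cfg = xist_like or XistLikeConfig()
    if cfg.block_start + cfg.block_length - 1 > cfg.length:
        raise ValueError("planted block extends beyond the transcript")
    if cfg.motif_position + len(cfg.motif) - 1 > cfg.length:
        raise ValueError("motif position beyond the transcript")
    rng = _rng(seed, _STAGE_TRANSCRIPTOME)

    records: list[TranscriptRecord] = []
    truth = SyntheticTruth(
        planted_gene=cfg.gene,
        block_start=cfg.block_start,
        block_length=cfg.block_length,
        u_density=cfg.u_density,
        motif_position=cfg.motif_position,
        motif=cfg.motif,
    )
    for i in range(n_genes - 1):
        gene = f"G{i + 1:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_sequence(rng, length, base_freqs)
        records.append(TranscriptRecord(f"T{i + 1:05d}.1", gene, seq))
        truth.gene_lengths[gene] = length
        if rng.random() < variant_fraction and length >= 2 * length_range[0]:
            # shorter second variant; longest-variant selection must drop it
            records.append(
                TranscriptRecord(f"T{i + 1:05d}.2", gene, seq[: length // 2])
            )

    base = list(_random_sequence(rng, cfg.length, base_freqs))
    b0 = cfg.block_start - 1
    for j in range(b0, b0 + cfg.block_length):
        base[j] = "U" if rng.random() < cfg.u_density else rng.choice(list("ACG"))
    m0 = cfg.motif_position - 1
    base[m0 : m0 + len(cfg.motif)] = list(cfg.motif)
    planted = "".join(base)
    records.append(TranscriptRecord("T90000.1", cfg.gene, planted))
    truth.gene_lengths[cfg.gene] = cfg.length
    return records, truth


def gen_counts(
    truth: SyntheticTruth,
    n_tissues: int = 3,
    n_per_sex: int = 20,
    dispersion: float = 0.1,
    base_meanlog: float = 7.5,
    base_sdlog: float = 1.2,
    tissue_sdlog: float = 0.3,
    lib_range: tuple[float, float] = (1 / 3, 3.0),
    planted_male_mean: float = 200.0,
    planted_ratio: float = 472.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with per-gene sex effects across tissues.

    Background genes have no sex effect; the planted gene's female:male
    mean ratio is ``planted_ratio`` (default the hundreds-fold regime of a
    female-specific lncRNA) at high absolute abundance.  Library sizes
    vary log-uniformly within ``lib_range`` to exercise TPM normalization.
    ``truth.sex_log2fc`` and ``truth.tissues`` are filled in.
    """
    if dispersion <= 0:
        raise ValueError("NB dispersion must be positive")
    rng = _rng(seed, _STAGE_COUNTS)
    genes = list(truth.gene_lengths)
    n_genes = len(genes)
    planted_idx = genes.index(truth.planted_gene) if truth.planted_gene in genes else -1

    base_mean = rng.lognormal(base_meanlog, base_sdlog, size=n_genes)
    sex_mult = np.ones((n_genes, 2))  # columns: female, male
    truth.sex_log2fc = {g: 0.0 for g in genes}
    if planted_idx >= 0:
        base_mean[planted_idx] = planted_male_mean
        sex_mult[planted_idx, 0] = planted_ratio
        truth.sex_log2fc[truth.planted_gene] = float(np.log2(planted_ratio))

    tissues = [f"tissue{k + 1}" for k in range(n_tissues)]
    truth.tissues = tissues
    columns: list[str] = []
    meta_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    inv_disp = 1.0 / dispersion
    for t_idx, tissue in enumerate(tissues):
        t_factor = rng.lognormal(0.0, tissue_sdlog, size=n_genes)
        if planted_idx >= 0:
            t_factor[planted_idx] = 1.0
        for s_idx, sex in enumerate(("female", "male")):
            for i in range(n_per_sex):
                lib = np.exp(rng.uniform(np.log(lib_range[0]), np.log(lib_range[1])))
                mean = base_mean * t_factor * sex_mult[:, s_idx] * lib
                p = inv_disp / (inv_disp + mean)
                blocks.append(rng.negative_binomial(inv_disp, p))
                sample = f"{tissue}_{sex[0].upper()}{i + 1:02d}"
                columns.append(sample)
                meta_rows.append(
                    {"sample_id": sample, "sex": sex, "tissue": tissue}
                )
    counts = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(genes, name="gene_symbol"),
        columns=columns,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, meta


def gen_sc(
    n_genes: int = 300,
    n_cells: int = 600,
    n_patients: int = 15,
    ifn_set_size: int = 20,
    ifn_effect: float = 1.0,
    baseline_range: tuple[float, float] = (0.1, 4.0),
    noise_sd: float = 0.5,
    small_patient_cells: int = 9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], SyntheticTruth]:
    """Multi-patient single-cell matrix with a planted IFN program.

    Each patient p has an IFN intensity drawn uniformly; IFN-module genes
    and one non-module tracking gene are up-shifted by
    ``ifn_effect * intensity_p`` in that patient's cells.  One patient is
    emitted with fewer than 10 cells to exercise the patient filter.
    Values are on a log-normalized-like scale (non-negative, unit-ish).
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    if n_cells < n_patients + small_patient_cells:
        raise ValueError("fewer cells than patients")
    rng = _rng(seed, _STAGE_SC)

    ifn_genes = [f"IFN{i + 1:03d}" for i in range(ifn_set_size)]
    tracking = "TRACKG"
    background = [f"SCG{i + 1:04d}" for i in range(n_genes - ifn_set_size - 1)]
    genes = ifn_genes + [tracking] + background

    cells_per = np.full(n_patients, (n_cells - small_patient_cells) // (n_patients - 1))
    cells_per[0] = small_patient_cells
    remainder = n_cells - cells_per.sum()
    cells_per[1 : 1 + remainder] += 1
    patients = [f"P{p + 1:02d}" for p in range(n_patients)]
    intensity = rng.uniform(0.2, 2.0, size=n_patients)

    mu = rng.uniform(baseline_range[0], baseline_range[1], size=len(genes))
    shifted = np.zeros(len(genes), dtype=bool)
    shifted[: ifn_set_size + 1] = True  # IFN module + tracking gene

    cols: list[str] = []
    meta_rows: list[dict] = []
    blocks: list[np.ndarray] = []
    cell_no = 0
    for p_idx, patient in enumerate(patients):
        shift = ifn_effect * intensity[p_idx]
        mean = mu + np.where(shifted, shift, 0.0)
        for _ in range(int(cells_per[p_idx])):
            cell_no += 1
            cell = f"C{cell_no:05d}"
            vals = np.clip(rng.normal(mean, noise_sd), 0.0, None)
            blocks.append(vals)
            cols.append(cell)
            meta_rows.append({"cell_id": cell, "patient_id": patient})

    expr = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(genes, name="gene_symbol"),
        columns=cols,
    )
    cell_meta = pd.DataFrame(meta_rows).set_index("cell_id")
    truth = SyntheticTruth(
        ifn_intensity={p: float(v) for p, v in zip(patients, intensity)},
        ifn_genes=ifn_genes,
        tracking_gene=tracking,
    )
    return expr, cell_meta, ifn_genes, truth
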