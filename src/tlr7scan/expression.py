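"""Counts-to-expression processing: filtering, TPM, sex fold-change.

Works on a genes x samples counts matrix (pandas DataFrame, gene symbols
as index) plus a per-sample metadata table (``sample_id``, ``sex`` in
{female, male}, ``tissue``).  Sex-specific tissues are excluded before any
female-vs-male comparison; low-count genes are dropped per tissue; TPM is
recomputed on the retained gene set so abundances stay comparable across
the analyzed universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Tissues with a single-sex anatomy, excluded from sex-bias comparisons.
SEX_SPECIFIC_TISSUES = (
    "uterus",
    "vagina",
    "breast",
    "ovary",
    "cervix uteri",
    "fallopian tube",
    "prostate",
    "testis",
)

VALID_SEXES = frozenset({"female", "male"})


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.empty:
        raise ValueError(f"counts file {path} is empty")
    return counts


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    bad = set(meta["sex"]) - VALID_SEXES
    if bad:
        raise ValueError(f"metadata has invalid sex values {sorted(bad)}")
    return meta.set_index("sample_id")


def exclude_sex_specific_tissues(
    sample_meta: pd.DataFrame, exclusion: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Drop samples from sex-specific tissues (case-insensitive match)."""
    if exclusion is None:
        exclusion = SEX_SPECIFIC_TISSUES
    excluded = {t.lower() for t in exclusion}
    keep = ~sample_meta["tissue"].str.lower().isin(excluded)
    return sample_meta.loc[keep]


def filter_low_counts(
    counts: pd.DataFrame, threshold: int = 25, fraction: float = 0.10
) -> pd.Index:
    """Genes retained after the low-count filter.

    A gene is excluded iff the proportion of samples with fewer than
    ``threshold`` reads is at least ``fraction`` (boundary inclusive on
    the fraction, strict on the read count).
    """
    if counts.shape[1] < 1:
        raise ValueError("counts matrix has no samples")
    low_frac = (counts < threshold).mean(axis=1)
    return counts.index[low_frac < fraction]


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and transcript lengths.

    Per sample: rate_g = count_g / (length_g / 1000);
    TPM_g = 1e6 * rate_g / sum_g rate_g.  Columns sum to 1e6.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"no length for genes {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero expression in sample(s) {zero}")
    return rate.div(totals, axis=1) * 1e6


def sex_mean_tpm(tpm: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean TPM in female and male samples."""
    meta = sample_meta.loc[tpm.columns]
    out = pd.DataFrame(index=tpm.index)
    for sex in ("female", "male"):
        cols = meta.index[meta["sex"] == sex]
        if len(cols) == 0:
            raise ValueError(f"no {sex} samples present")
        out[f"mean_tpm_{sex}"] = tpm[cols].mean(axis=1)
    return out


def log2fc_sex(
    tpm: pd.DataFrame, sample_meta: pd.DataFrame, pseudocount: float = 0.01
) -> pd.Series:
    """log2 fold-change of female over male mean TPM with a pseudocount.

    The pseudocount (default 0.01 TPM) bounds genes expressed in only one
    sex instead of producing infinities; it perturbs strong ratios (the
    hundreds-fold regime) by well under 1%.
    """
    means = sex_mean_tpm(tpm, sample_meta)
    fc = np.log2(
        (means["mean_tpm_female"] + pseudocount)
        / (means["mean_tpm_male"] + pseudocount)
    )
    fc.name = "log2fc_sex"
    return fc


@dataclass
class ExpressionSet:
    """Counts + metadata + lengths bundle, filtered and TPM-normalized.

    ``from_inputs`` applies the analysis order used throughout: restrict to
    the tissue's samples, drop low-count genes, then recompute TPM on the
    retained gene universe.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_lengths: pd.Series
    tpm: pd.DataFrame

    @classmethod
    def from_inputs(
        cls,
        counts: pd.DataFrame,
        sample_meta: pd.DataFrame,
        gene_lengths: pd.Series,
        threshold: int = 25,
        fraction: float = 0.10,
    ) -> "ExpressionSet":
        missing = counts.columns.difference(sample_meta.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        counts = counts[sample_meta.index.intersection(counts.columns)]
        kept = filter_low_counts(counts, threshold, fraction)
        counts = counts.loc[kept]
        if counts.empty:
            raise ValueError("no genes retained after low-count filtering")
        tpm = compute_tpm(counts, gene_lengths)
        meta = sample_meta.loc[counts.columns]
        return cls(counts=counts, sample_meta=meta, gene_lengths=gene_lengths.reindex(kept), tpm=tpm)

    def sex_stats(self, pseudocount: float = 0.01) -> pd.DataFrame:
        """Per-gene mean TPM by sex and female/male log2 fold-change."""
        stats = sex_mean_tpm(self.tpm, self.sample_meta)
        stats["log2fc_sex"] = log2fc_sex(self.tpm, self.sample_meta, pseudocount)
        return stats
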