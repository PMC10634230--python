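"""End-to-end bulk pipeline: profile -> expression -> DE -> ranking.

Given a transcriptome FASTA and a counts matrix with sample metadata, the
pipeline computes per-gene ligand profiles, per-tissue expression and sex
statistics, moderated differential expression, and per-tissue plus
cross-tissue ligation-score tables, writing everything as TSV together
with a JSON manifest (config, input checksums, output checksums) so a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import moderated_sex_test
from .expression import (
    SEX_SPECIFIC_TISSUES,
    ExpressionSet,
    exclude_sex_specific_tissues,
    read_counts,
    read_sample_meta,
)
from .ranking import ligation_score, normalize_and_average
from .seqio import TLR7_MOTIF, profile_transcripts, read_transcriptome, select_longest_variant


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Analysis parameters; defaults are the screen's standard values."""

    fasta: str = ""
    counts: str = ""
    metadata: str = ""
    out_dir: str = "tlr7scan_out"
    motif: str = TLR7_MOTIF
    window: int = 500
    mode: str = "nonoverlapping"
    threshold: int = 25
    fraction: float = 0.10
    pseudocount: float = 0.01
    alpha: float = 0.05
    excluded_tissues: tuple[str, ...] = SEX_SPECIFIC_TISSUES
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat key = value text config; unknown keys are rejected."""
        cfg = cls()
        valid = set(asdict(cfg))
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid:
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(cfg, key)
                if key == "excluded_tissues":
                    setattr(cfg, key, tuple(t.strip() for t in value.split(",") if t.strip()))
                elif isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_score_pipeline(config: RunConfig) -> Path:
    """Run the full screen; returns the output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        records = select_longest_variant(read_transcriptome(config.fasta))
        profiles = profile_transcripts(
            records, motif=config.motif, window=config.window, mode=config.mode
        )
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineError("profile", str(exc)) from exc
    _write(profiles, out_dir / "profile.tsv")
    lengths = profiles["length"].astype(float)

    try:
        counts = read_counts(config.counts)
        meta = read_sample_meta(config.metadata)
        meta = exclude_sex_specific_tissues(meta, config.excluded_tissues)
        counts = counts.loc[counts.index.intersection(profiles.index)]
        if counts.empty:
            raise ValueError("no counted genes match the transcriptome")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc

    tissue_tables: dict[str, pd.DataFrame] = {}
    for tissue in sorted(meta["tissue"].unique()):
        t_meta = meta.loc[meta["tissue"] == tissue]
        try:
            eset = ExpressionSet.from_inputs(
                counts[t_meta.index.intersection(counts.columns)],
                t_meta,
                lengths,
                threshold=config.threshold,
                fraction=config.fraction,
            )
            stats = eset.sex_stats(pseudocount=config.pseudocount)
        except Exception as exc:
            raise PipelineError("expression", f"tissue {tissue}: {exc}") from exc
        _write(stats, out_dir / f"expression_{tissue}.tsv")

        try:
            log_expr = np.log2(eset.tpm + config.pseudocount)
            de = moderated_sex_test(log_expr, eset.sample_meta["sex"], alpha=config.alpha)
        except Exception as exc:
            raise PipelineError("diffexpr", f"tissue {tissue}: {exc}") from exc
        _write(de, out_dir / f"diffexpr_{tissue}.tsv")

        try:
            genes = stats.index
            table = ligation_score(
                profiles.loc[genes],
                stats["mean_tpm_female"],
                stats["log2fc_sex"],
            )
        except Exception as exc:
            raise PipelineError("ranking", f"tissue {tissue}: {exc}") from exc
        _write(table, out_dir / f"score_{tissue}.tsv")
        tissue_tables[tissue] = table

    try:
        combined = normalize_and_average(tissue_tables)
    except Exception as exc:
        raise PipelineError("ranking", str(exc)) from exc
    _write(combined, out_dir / "score_combined.tsv")

    manifest = {
        "package_version": __version__,
        "config": {**asdict(config), "excluded_tissues": list(config.excluded_tissues)},
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("fasta", "counts", "metadata")
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(out_dir.glob("*.tsv"))
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir
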