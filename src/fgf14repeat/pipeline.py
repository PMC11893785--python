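"""End-to-end orchestration: FASTQ inputs -> calls -> cohort report.

All randomness flows from the single seed in the configuration (only the
simulator consumes randomness; calling is deterministic).  No stage reads
truth metadata from read ids.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import pandas as pd

from . import io as _io
from .classify import ClassificationThresholds, IndividualCall, call_individual
from .locus import LocusTemplate, default_template
from .profiling import waterfall_matrix
from .stats import DEFAULT_EXPANDED_MIN_UNITS, frequency_table, snp_association

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    tomllib = None

logger = logging.getLogger("fgf14repeat")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the calling pipeline, serializable to TOML."""

    max_mismatches: int = 0
    min_reads: int = 3
    split_gap_units: int = 10
    expanded_min_units: int = DEFAULT_EXPANDED_MIN_UNITS
    mode: str = "amplicon"
    seed: int = 0
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        thresholds_data = data.pop("thresholds", {})
        allowed = {f.name for f in fields(cls)} - {"thresholds"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        th_allowed = {f.name for f in fields(ClassificationThresholds)}
        th_unknown = set(thresholds_data) - th_allowed
        if th_unknown:
            raise ValueError(f"unknown threshold keys: {sorted(th_unknown)}")
        return cls(
            thresholds=ClassificationThresholds(**thresholds_data), **data
        )

    def to_dict(self) -> dict:
        return asdict(self)


def calls_to_frame(calls: list[IndividualCall]) -> pd.DataFrame:
    """Flatten individual calls to one row per sample (calls TSV shape)."""
    rows = []
    for call in calls:
        row: dict = {
            "sample": call.sample_id,
            "group": call.group,
            "rp_prediction": call.rp_pcr_prediction,
            "snp_genotype": call.snp_genotype,
            "flags": ";".join(call.flags),
        }
        for i in (1, 2):
            summary = call.alleles[i - 1] if len(call.alleles) >= i else None
            if summary is None:
                row[f"allele{i}_units"] = pd.NA
                row[f"allele{i}_class"] = ""
                row[f"allele{i}_band"] = ""
                row[f"allele{i}_run"] = pd.NA
                row[f"allele{i}_n_reads"] = pd.NA
            else:
                row[f"allele{i}_units"] = summary.call.unit_count_median
                row[f"allele{i}_class"] = summary.configuration_class.value
                row[f"allele{i}_band"] = summary.band.value
                row[f"allele{i}_run"] = summary.call.longest_run_units
                row[f"allele{i}_n_reads"] = summary.call.n_reads
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    calls: list[IndividualCall]
    calls_frame: pd.DataFrame
    cohort_table: pd.DataFrame
    snp_table: pd.DataFrame
    snp_discordance: int


def run_pipeline(
    sample_fastqs: dict[str, str | Path],
    manifest: dict[str, str],
    config: PipelineConfig | None = None,
    template: LocusTemplate | None = None,
    out_dir: str | Path | None = None,
    write_waterfalls: bool = False,
) -> PipelineResult:
    """Call every sample and aggregate the cohort report.

    ``sample_fastqs`` maps sample id to a FASTQ/FASTA path; ``manifest``
    maps sample id to group.  Every manifest sample must have a read file.
    When ``out_dir`` is given, calls.tsv, cohort_table.tsv and stats.json
    are written there (plus per-sample waterfall TSVs on request).
    """
    if config is None:
        config = PipelineConfig()
    if template is None:
        template = default_template()
    missing = sorted(set(manifest) - set(sample_fastqs))
    if missing:
        raise ValueError(f"manifest samples without reads: {missing}")
    calls: list[IndividualCall] = []
    for sample in sorted(manifest):
        reads = _io.read_seqs(sample_fastqs[sample])
        call = call_individual(
            sample,
            reads,
            template,
            thresholds=config.thresholds,
            group=manifest[sample],
            max_mismatches=config.max_mismatches,
            min_reads=config.min_reads,
            split_gap_units=config.split_gap_units,
        )
        logger.info(
            "sample %s: %s", sample,
            " ".join(f"{k}={v}" for k, v in call.stage_counts.items()),
        )
        calls.append(call)
    frame = calls_to_frame(calls)
    cohort = frequency_table(
        calls, expanded_min_units=config.expanded_min_units
    )
    snp_table, discordance = snp_association(
        calls, expanded_min_units=config.expanded_min_units
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _io.write_tsv(frame, out_dir / "calls.tsv")
        _io.write_tsv(cohort.reset_index(), out_dir / "cohort_table.tsv")
        _io.write_json(
            {
                "snp_association": {
                    "table": snp_table.to_dict(),
                    "discordance": discordance,
                },
                "config": config.to_dict(),
            },
            out_dir / "stats.json",
        )
        if write_waterfalls:
            wf_dir = out_dir / "waterfall"
            wf_dir.mkdir(exist_ok=True)
            for sample in sorted(manifest):
                reads = _io.read_seqs(sample_fastqs[sample])
                from .extraction import extract_repeat_reads
                from .profiling import profile_read

                anchored, _ = extract_repeat_reads(
                    reads, template, config.max_mismatches
                )
                profiles = [
                    p for p, _ in (profile_read(a, template) for a in anchored)
                    if p is not None
                ]
                _io.write_tsv(
                    waterfall_matrix(profiles), wf_dir / f"{sample}.tsv"
                )
    return PipelineResult(calls, frame, cohort, snp_table, discordance)
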