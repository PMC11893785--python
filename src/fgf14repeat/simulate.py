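"""Synthetic allele, read, and cohort generation.

Every downstream stage of the pipeline is testable without external data:
this module builds full-length locus sequences from ground-truth repeat
configurations, applies a HiFi-like uniform substitution/indel error model,
emulates the preparative-gel selection of long-range PCR products, and
writes whole cohorts (FASTQ per individual plus a truth table).

Randomness policy: every public entry point is deterministic given its
seed.  Cohort simulation derives one child RNG per individual via
``numpy.random.SeedSequence(seed, spawn_key=(group_index, individual_index))``
so that outputs do not depend on iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .locus import LocusTemplate, UnknownMotifError, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {ord(b): i for i, b in enumerate("ACGT")}


class CohortSpecError(ValueError):
    """A cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class RepeatBlock:
    """``count`` tandem copies of one lexicon motif."""

    motif: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("RepeatBlock count must be >= 1")


@dataclass(frozen=True)
class AlleleConfig:
    """Ground truth for one allele: ordered repeat blocks plus SNP phase.

    Blocks run upstream -> downstream in the transcription direction.
    ``total_units`` is the GAA-equivalent size of the whole tract
    (tract nt / 3); ``total_gaa_units`` counts only units inside pure-GAA
    blocks.
    """

    blocks: tuple[RepeatBlock, ...]
    snp_allele: str = "T"
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError("AlleleConfig needs at least one block")
        if self.snp_allele not in ("T", "A"):
            raise ValueError("snp_allele must be 'T' or 'A'")

    def tract(self, template: LocusTemplate) -> str:
        parts = []
        for block in self.blocks:
            if block.motif not in template.motif_lexicon:
                raise UnknownMotifError(f"unknown motif {block.motif!r}")
            parts.append(block.motif * block.count)
        return "".join(parts)

    @property
    def tract_nt(self) -> int:
        return sum(b.count * len(b.motif) for b in self.blocks)

    @property
    def total_units(self) -> int:
        return self.tract_nt // 3

    @property
    def total_gaa_units(self) -> int:
        return sum(b.count for b in self.blocks if b.motif == "GAA")

    def product_length(self, template: LocusTemplate) -> int:
        """Modeled LR-PCR product size in bp (tract plus both flanks)."""
        return self.tract_nt + template.flank_length()


def build_allele_sequence(template: LocusTemplate, config: AlleleConfig) -> str:
    """Full locus sequence of one allele: flanks around the repeat tract.

    The SNP allele is substituted at ``template.snp_offset`` in the upstream
    flank.  If the tract begins with a GAA unit the upstream junction 20-mer
    arises verbatim; if it ends with two GAA units so does the downstream
    one.
    """
    up = template.up_flank
    if config.snp_allele != template.snp_wt:
        up = up[: template.snp_offset] + config.snp_allele + up[template.snp_offset + 1 :]
    return up + config.tract(template) + template.down_flank


def gel_select(product_length_nt: int) -> bool:
    """Preparative-gel rule: keep products strictly longer than 750 bp.

    750 bp corresponds to a 200-unit tract plus the 150 bp of flank, the
    size below which long-range PCR products are not excised.
    """
    if product_length_nt < 0:
        raise ValueError("product length must be >= 0")
    return product_length_nt > 750


@dataclass(frozen=True)
class ErrorModel:
    """Uniform per-base error model for HiFi-like reads.

    Rates are independent per base, in [0, 0.1]; a read with all-zero rates
    is the exact allele sequence.  Order of operations per template base:
    deletion, then substitution, then insertion after the (surviving) base.
    No homopolymer weighting: HiFi-scale rates make uniform errors adequate.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1], got {rate}")

    @property
    def error_free(self) -> bool:
        return self.sub_rate == self.ins_rate == self.del_rate == 0.0


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """One noisy copy of ``seq`` under ``model`` using ``rng``."""
    if model.error_free:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(codes)
    keep = rng.random(n) >= model.del_rate
    subs = (rng.random(n) < model.sub_rate) & keep
    if subs.any():
        idx = np.array([_BASE_INDEX[c] for c in codes[subs]], dtype=np.int64)
        shift = rng.integers(1, 4, size=idx.size)
        codes[subs] = _BASES[(idx + shift) % 4]
    kept = codes[keep]
    slots = rng.random(kept.size + 1) < model.ins_rate
    if slots.any():
        where = np.flatnonzero(slots)
        bases = _BASES[rng.integers(0, 4, size=where.size)]
        kept = np.insert(kept, where, bases)
    return kept.tobytes().decode("ascii")


def simulate_reads(
    allele_seq: str,
    depth: int,
    error_model: ErrorModel,
    label: str = "allele",
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """``depth`` independent reads of the full allele sequence.

    Each read carries independent per-base errors and is reverse
    complemented with probability 0.5.  Read ids encode the allele label
    and strand after a ``|`` separator for truth tracking only; no pipeline
    stage may parse them.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if rng is None:
        rng = np.random.default_rng(error_model.seed)
    reads: list[tuple[str, str]] = []
    for i in range(depth):
        seq = apply_errors(allele_seq, error_model, rng)
        flip = bool(rng.random() < 0.5)
        if flip:
            seq = revcomp(seq)
        strand = "-" if flip else "+"
        reads.append((f"read{i:04d}|truth={label};strand={strand}", seq))
    return reads


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: name, size, and an allele-frequency table.

    ``allele_freqs`` maps config labels to frequencies summing to 1 over
    the group's 2n alleles.  ``allele_counts``, if given, fixes the exact
    allele counts used by exact-counts assignment (and implies the
    frequencies).
    """

    name: str
    n_individuals: int
    allele_freqs: dict[str, float] = field(default_factory=dict)
    allele_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise CohortSpecError("n_individuals must be >= 0")
        if self.allele_counts is not None:
            total = sum(self.allele_counts.values())
            if total != 2 * self.n_individuals:
                raise CohortSpecError(
                    f"group {self.name}: allele counts sum to {total}, "
                    f"expected {2 * self.n_individuals}"
                )
            if not self.allele_freqs:
                freqs = {
                    k: v / total for k, v in self.allele_counts.items()
                } if total else {}
                object.__setattr__(self, "allele_freqs", freqs)
        if self.n_individuals > 0:
            s = sum(self.allele_freqs.values())
            if abs(s - 1.0) > 1e-9:
                raise CohortSpecError(
                    f"group {self.name}: allele frequencies sum to {s}, not 1"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort description: groups, named allele configs, depth, errors."""

    groups: tuple[GroupSpec, ...]
    configs: dict[str, AlleleConfig]
    depth_range: tuple[int, int] = (20, 200)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        lo, hi = self.depth_range
        if not (0 <= lo <= hi):
            raise CohortSpecError("depth_range must satisfy 0 <= min <= max")
        for group in self.groups:
            for label in group.allele_freqs:
                if label not in self.configs:
                    raise CohortSpecError(
                        f"group {group.name} references unknown config {label!r}"
                    )


def _exact_allele_quota(group: GroupSpec) -> list[str]:
    """Deterministic allele multiset for exact-counts assignment.

    Counts come from ``allele_counts`` when given, otherwise from a
    largest-remainder apportionment of the frequencies over 2n alleles.
    The multiset is ordered rarest-config-first so that scarce (expanded)
    alleles are spread one per individual before common alleles fill the
    remaining slots.
    """
    total = 2 * group.n_individuals
    if group.allele_counts is not None:
        counts = dict(group.allele_counts)
    else:
        raw = {k: f * total for k, f in group.allele_freqs.items()}
        counts = {k: math.floor(v) for k, v in raw.items()}
        short = total - sum(counts.values())
        by_remainder = sorted(
            raw, key=lambda k: (raw[k] - counts[k], k), reverse=True
        )
        for k in by_remainder[:short]:
            counts[k] += 1
    ordered = sorted(counts, key=lambda k: (counts[k], k))
    quota: list[str] = []
    for label in ordered:
        quota.extend([label] * counts[label])
    return quota


def _draw_genotype(
    group: GroupSpec, rng: np.random.Generator
) -> tuple[str, str]:
    labels = sorted(group.allele_freqs)
    probs = np.array([group.allele_freqs[k] for k in labels])
    probs = probs / probs.sum()
    a1, a2 = rng.choice(len(labels), size=2, p=probs)
    return labels[a1], labels[a2]


@dataclass
class CohortResult:
    """Paths and truth produced by :func:`simulate_cohort`."""

    out_dir: Path
    fastq_paths: dict[str, Path]
    truth_path: Path
    manifest_path: Path
    truth_rows: list[dict]


def simulate_cohort(
    spec: CohortSpec,
    template: LocusTemplate,
    out_dir: str | Path,
    mode: str = "amplicon",
    exact_counts: bool = False,
) -> CohortResult:
    """Write one FASTQ per individual plus truth and manifest TSVs.

    In ``amplicon`` mode, reads for alleles whose modeled LR-PCR product
    fails :func:`gel_select` are omitted (emulating preparative gel
    excision); in ``wgs`` mode every allele's reads are retained, as for
    pre-extracted reads from PCR-free whole-genome sequencing.  Truth rows
    always record both alleles.
    """
    if mode not in ("amplicon", "wgs"):
        raise ValueError(f"mode must be 'amplicon' or 'wgs', got {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_cache = {
        label: build_allele_sequence(template, cfg)
        for label, cfg in spec.configs.items()
    }
    fastq_paths: dict[str, Path] = {}
    truth_rows: list[dict] = []
    for g_idx, group in enumerate(spec.groups):
        if exact_counts:
            quota = _exact_allele_quota(group)
            n = group.n_individuals
            genotypes = [(quota[i], quota[n + i]) for i in range(n)]
        else:
            genotypes = None
        for i_idx in range(group.n_individuals):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(g_idx, i_idx))
            rng = np.random.default_rng(ss)
            if genotypes is not None:
                lab1, lab2 = genotypes[i_idx]
            else:
                lab1, lab2 = _draw_genotype(group, rng)
            sample = f"{group.name}_{i_idx:04d}"
            reads: list[tuple[str, str]] = []
            for a_idx, lab in enumerate((lab1, lab2)):
                cfg = spec.configs[lab]
                if mode == "amplicon" and not gel_select(cfg.product_length(template)):
                    continue
                depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
                allele_reads = simulate_reads(
                    seq_cache[lab], depth, spec.error_model,
                    label=f"{sample}.a{a_idx + 1}.{lab}", rng=rng,
                )
                reads.extend(allele_reads)
            fastq = out_dir / f"{sample}.fastq"
            with fastq.open("w") as fh:
                for j, (rid, seq) in enumerate(reads):
                    fh.write(f"@{sample}.r{j:05d}|{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            fastq_paths[sample] = fastq
            cfg1, cfg2 = spec.configs[lab1], spec.configs[lab2]
            truth_rows.append(
                {
                    "sample": sample,
                    "group": group.name,
                    "allele1_config": lab1,
                    "allele1_units": cfg1.total_units,
                    "allele2_config": lab2,
                    "allele2_units": cfg2.total_units,
                    "snp_genotype": "/".join(
                        sorted((cfg1.snp_allele, cfg2.snp_allele), reverse=True)
                    ),
                }
            )
    truth_path = out_dir / "truth.tsv"
    cols = [
        "sample", "group", "allele1_config", "allele1_units",
        "allele2_config", "allele2_units", "snp_genotype",
    ]
    with truth_path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    manifest_path = out_dir / "manifest.tsv"
    with manifest_path.open("w") as fh:
        fh.write("sample\tgroup\n")
        for row in truth_rows:
            fh.write(f"{row['sample']}\t{row['group']}\n")
    return CohortResult(out_dir, fastq_paths, truth_path, manifest_path, truth_rows)
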