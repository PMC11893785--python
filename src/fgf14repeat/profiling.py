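"""Per-read repeat decomposition and diploid allele calling.

The repeat tract of each anchored read is located by exact search for the
two junction 20-mers, sized as the GAA-equivalent length of the span
between them, and decomposed into the six repeat motifs by a greedy
longest-match tokenizer (the "waterfall" decomposition).  Reads are then
filtered to the uniform-length population and clustered into at most two
alleles.

Coordinates are 0-based half-open throughout; ``junction_up_end`` is
exclusive.  The tract tiled by tokens is ``[junction_up_end - 3,
junction_down_start + 6)``: one repeat unit lies inside the upstream
junction 20-mer and two inside the downstream one, which is also why
``count_units`` adds 3 to the inter-junction gap divided by 3.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .extraction import AnchoredRead
from .locus import LocusTemplate

#: Token label for positions matching no motif.
NOISE = "NOISE"

#: Junction-location / profiling failure reasons.
PROFILE_FAILURES = (
    "no_upstream_junction",
    "no_downstream_junction",
    "no_junctions",
    "inverted_junctions",
)


@dataclass
class Token:
    """One motif (or 1-nt NOISE) occurrence; absolute read coordinates."""

    motif: str
    start: int
    end: int


@dataclass
class TractProfile:
    """Decomposition of one read's repeat tract."""

    read_id: str
    junction_up_end: int
    junction_down_start: int
    unit_count: int
    tokens: list[Token]
    purity: float
    upstream_run_units: int
    downstream_run_units: int
    longest_run_units: int
    noise_fraction: float

    @property
    def tract_start(self) -> int:
        return self.junction_up_end - 3

    @property
    def tract_end(self) -> int:
        return self.junction_down_start + 6

    @property
    def tract_nt(self) -> int:
        return self.tract_end - self.tract_start


@dataclass
class AlleleCall:
    """Consensus summary of one read cluster (one allele)."""

    allele_index: int
    n_reads: int
    unit_count_median: float
    unit_count_range: tuple[int, int]
    purity: float
    upstream_run_units: float
    downstream_run_units: float
    longest_run_units: float
    read_ids: list[str] = field(default_factory=list)
    snp_base: str = "unknown"


def locate_junctions(
    sequence: str, template: LocusTemplate
) -> tuple[tuple[int, int] | None, str | None]:
    """Exact search for the junction 20-mers in a normalized read.

    Returns ``((junction_up_end, junction_down_start), None)`` or
    ``(None, reason)``.  On multiple matches the *last* upstream and
    *first* downstream match are taken, maximizing the enclosed tract
    against spurious internal matches under sequencing errors (a clean
    pure tract cannot contain either 20-mer because motifs are T-free).
    """
    up_pos = sequence.rfind(template.junction_up)
    down_pos = sequence.find(template.junction_down)
    if up_pos < 0 and down_pos < 0:
        return None, "no_junctions"
    if up_pos < 0:
        return None, "no_upstream_junction"
    if down_pos < 0:
        return None, "no_downstream_junction"
    up_end = up_pos + len(template.junction_up)
    if down_pos < up_end:
        return None, "inverted_junctions"
    return (up_end, down_pos), None


def count_units(junction_up_end: int, junction_down_start: int) -> int:
    """GAA-equivalent repeat units of the junction-to-junction span.

    ``round(gap / 3) + 3`` with banker's rounding; the +3 restores the one
    unit inside the upstream junction and the two inside the downstream
    one.
    """
    gap = junction_down_start - junction_up_end
    if gap < 0:
        raise ValueError(f"negative junction gap {gap}")
    return round(gap / 3) + 3


def tokenize_tract(
    sequence: str, template: LocusTemplate, offset: int = 0
) -> list[Token]:
    """Greedy left-to-right longest-match decomposition of a tract.

    At each position the lexicon motifs are tried in order (longest first,
    (GCA)2GAA before GCA(GAA)2 among the 9-mers); positions matching no
    motif emit 1-nt NOISE tokens.  Tokens tile the input exactly.
    ``offset`` shifts reported coordinates (e.g. to read coordinates).
    """
    tokens: list[Token] = []
    pos = 0
    n = len(sequence)
    lexicon = template.motif_lexicon
    while pos < n:
        for motif in lexicon:
            if sequence.startswith(motif, pos):
                tokens.append(Token(motif, offset + pos, offset + pos + len(motif)))
                pos += len(motif)
                break
        else:
            tokens.append(Token(NOISE, offset + pos, offset + pos + 1))
            pos += 1
    return tokens


def terminal_runs(tokens: list[Token]) -> tuple[int, int, int]:
    """(upstream_run, downstream_run, longest_run) in GAA units.

    A run is a maximal stretch of GAA tokens in which isolated noise of at
    most 2 consecutive nt does not break the run (noise nt add no units).
    The upstream run counts only if it starts at the tract start (at most
    2 nt of leading noise); the downstream run only if it ends at the
    tract end likewise.
    """
    runs: list[dict] = []  # {units, first_idx, last_idx}
    current: dict | None = None
    pending_noise = 0
    for i, tok in enumerate(tokens):
        if tok.motif == "GAA":
            if current is not None and pending_noise > 2:
                current = None
            if current is None:
                current = {"units": 0, "first": i, "last": i}
                runs.append(current)
            current["units"] += 1
            current["last"] = i
            pending_noise = 0
        elif tok.motif == NOISE:
            pending_noise += tok.end - tok.start
        else:
            current = None
            pending_noise = 0
    if not runs:
        return 0, 0, 0
    longest = max(run["units"] for run in runs)
    first_run = runs[0]
    leading_nt = sum(
        t.end - t.start for t in tokens[: first_run["first"]]
    )
    upstream = first_run["units"] if leading_nt <= 2 else 0
    last_run = runs[-1]
    trailing_nt = sum(
        t.end - t.start for t in tokens[last_run["last"] + 1 :]
        if t.motif == NOISE
    )
    trailing_other = any(
        t.motif not in ("GAA", NOISE) for t in tokens[last_run["last"] + 1 :]
    )
    downstream = (
        last_run["units"] if (not trailing_other and trailing_nt <= 2) else 0
    )
    return upstream, downstream, longest


def profile_read(
    anchored: AnchoredRead, template: LocusTemplate
) -> tuple[TractProfile | None, str | None]:
    """Full tract profile of one anchored read, or a failure reason."""
    located, reason = locate_junctions(anchored.sequence, template)
    if located is None:
        return None, reason
    up_end, down_start = located
    units = count_units(up_end, down_start)
    tract_start, tract_end = up_end - 3, down_start + 6
    tract = anchored.sequence[tract_start:tract_end]
    tokens = tokenize_tract(tract, template, offset=tract_start)
    motif_nt = sum(t.end - t.start for t in tokens if t.motif != NOISE)
    gaa_nt = sum(t.end - t.start for t in tokens if t.motif == "GAA")
    noise_nt = len(tract) - motif_nt
    purity = gaa_nt / motif_nt if motif_nt else 0.0
    up_run, down_run, longest = terminal_runs(tokens)
    return (
        TractProfile(
            read_id=anchored.read_id,
            junction_up_end=up_end,
            junction_down_start=down_start,
            unit_count=units,
            tokens=tokens,
            purity=purity,
            upstream_run_units=up_run,
            downstream_run_units=down_run,
            longest_run_units=longest,
            noise_fraction=noise_nt / len(tract) if tract else 0.0,
        ),
        None,
    )


def _best_window(lengths: list[int], width: int) -> tuple[int, int]:
    """(lo, hi) bounds of the most populated window of given width.

    Candidate windows start at each observed length; ties prefer lower
    length variance, then shorter median, then lower start.
    """
    best = None
    for start in sorted(set(lengths)):
        inside = [x for x in lengths if start <= x <= start + width]
        var = statistics.pvariance(inside) if len(inside) > 1 else 0.0
        med = statistics.median(inside)
        key = (-len(inside), var, med, start)
        if best is None or key < best[0]:
            best = (key, (start, start + width))
    return best[1]


def select_uniform_region(
    profiles: list[TractProfile],
    min_reads: int = 3,
    coarse_gap_nt: int = 30,
) -> tuple[list[TractProfile], int]:
    """Select the uniform-read-length population(s).

    Sorted tract lengths are first split into candidate allele populations
    at gaps larger than ``coarse_gap_nt`` (10 units), so both alleles of a
    heterozygote survive.  Within each population a window of width
    ``max(12 nt, 1% of the population's median tract length)`` is slid
    over the lengths and the most populated window kept; populations whose
    window holds fewer than ``min_reads`` reads are discarded as shattered
    or artifactual.  Returns the selected profiles (input order preserved)
    and the number discarded.  Deterministic and order-independent.
    """
    if not profiles:
        return [], 0
    ordered = sorted(profiles, key=lambda p: (p.tract_nt, p.read_id))
    populations: list[list[TractProfile]] = [[ordered[0]]]
    for prof in ordered[1:]:
        if prof.tract_nt - populations[-1][-1].tract_nt > coarse_gap_nt:
            populations.append([prof])
        else:
            populations[-1].append(prof)
    keep: set[int] = set()
    for pop in populations:
        lengths = [p.tract_nt for p in pop]
        width = max(12, round(0.01 * statistics.median(lengths)))
        lo, hi = _best_window(lengths, width)
        inside = [p for p in pop if lo <= p.tract_nt <= hi]
        if len(inside) >= min_reads:
            keep.update(id(p) for p in inside)
    selected = [p for p in profiles if id(p) in keep]
    return selected, len(profiles) - len(selected)


def cluster_alleles(
    profiles: list[TractProfile],
    split_gap_units: int = 10,
    min_reads: int = 3,
) -> tuple[list[AlleleCall], int]:
    """Group selected reads into at most two allele calls.

    Unit counts are sorted and split at the largest inter-read gap when
    that gap reaches ``split_gap_units``; clusters with fewer than
    ``min_reads`` reads are dropped (returned as a warning count).
    Allele 1 is the smaller allele.
    """
    if not profiles:
        return [], 0
    ordered = sorted(profiles, key=lambda p: (p.unit_count, p.read_id))
    clusters: list[list[TractProfile]]
    if len(ordered) > 1:
        gaps = [
            ordered[i + 1].unit_count - ordered[i].unit_count
            for i in range(len(ordered) - 1)
        ]
        max_gap = max(gaps)
        if max_gap >= split_gap_units:
            cut = gaps.index(max_gap) + 1
            clusters = [ordered[:cut], ordered[cut:]]
        else:
            clusters = [ordered]
    else:
        clusters = [ordered]
    calls: list[AlleleCall] = []
    dropped = 0
    for cluster in clusters:
        if len(cluster) < min_reads:
            dropped += len(cluster)
            continue
        units = [p.unit_count for p in cluster]
        calls.append(
            AlleleCall(
                allele_index=len(calls) + 1,
                n_reads=len(cluster),
                unit_count_median=statistics.median(units),
                unit_count_range=(min(units), max(units)),
                purity=statistics.median(p.purity for p in cluster),
                upstream_run_units=statistics.median(
                    p.upstream_run_units for p in cluster
                ),
                downstream_run_units=statistics.median(
                    p.downstream_run_units for p in cluster
                ),
                longest_run_units=statistics.median(
                    p.longest_run_units for p in cluster
                ),
                read_ids=[p.read_id for p in cluster],
            )
        )
    return calls, dropped


def waterfall_matrix(profiles: list[TractProfile]):
    """Lossless token export: rows (read_id, start, end, motif).

    Coordinates are tract-relative; reads are ordered by ascending tract
    length, stable by read_id.  Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for prof in sorted(profiles, key=lambda p: (p.tract_nt, p.read_id)):
        for tok in prof.tokens:
            rows.append(
                {
                    "read_id": prof.read_id,
                    "start": tok.start - prof.tract_start,
                    "end": tok.end - prof.tract_start,
                    "motif": tok.motif,
                }
            )
    return pd.DataFrame(rows, columns=["read_id", "start", "end", "motif"])
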