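"""Identification of locus-spanning reads by flanking anchor sequences.

A read spans the repeat locus when it contains at least one of the three
upstream anchors AND at least one of the three downstream anchors, in the
correct relative order, in one orientation.  Three alternative anchors per
side tolerate sequencing errors without requiring mismatch-tolerant
matching; an optional Hamming-distance tolerance is available as well.

Reads are orientation-normalized (reverse complemented when the anchors are
found on the reverse strand); reads with full anchor signal in both
orientations are rejected rather than guessed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .locus import LocusTemplate, revcomp
from . import io as _io

#: Rejection categories, in reporting order.
REJECT_REASONS = (
    "empty",
    "ambiguous_orientation",
    "no_anchor",
    "no_upstream_anchor",
    "no_downstream_anchor",
    "anchor_disorder",
)


@dataclass
class AnchoredRead:
    """An orientation-normalized read confirmed to span the locus.

    Anchor hits are ``(anchor_index, start)`` pairs with 0-based starts in
    the normalized sequence; anchor indices are 1-based (1..3 per side).
    """

    read_id: str
    sequence: str
    was_reverse_complemented: bool
    up_anchor_hits: list[tuple[int, int]]
    down_anchor_hits: list[tuple[int, int]]


def _find_all(seq: str, pattern: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        hits = []
        start = 0
        while True:
            pos = seq.find(pattern, start)
            if pos < 0:
                return hits
            hits.append(pos)
            start = pos + 1
    # Hamming scan; 'N' in the read never matches an anchor position.
    m = len(pattern)
    hits = []
    for pos in range(len(seq) - m + 1):
        mm = 0
        window = seq[pos : pos + m]
        for a, b in zip(window, pattern):
            if a != b or a == "N":
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            hits.append(pos)
    return hits


def _scan_orientation(
    seq: str, template: LocusTemplate, max_mismatches: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    up_hits = []
    for idx, anchor in enumerate(template.up_anchors, start=1):
        up_hits.extend((idx, pos) for pos in _find_all(seq, anchor, max_mismatches))
    down_hits = []
    for idx, anchor in enumerate(template.down_anchors, start=1):
        down_hits.extend((idx, pos) for pos in _find_all(seq, anchor, max_mismatches))
    return up_hits, down_hits


def find_anchors(
    read_id: str,
    sequence: str,
    template: LocusTemplate,
    max_mismatches: int = 0,
) -> tuple[AnchoredRead | None, str | None]:
    """Anchor a read in locus-forward orientation, or reject it.

    Returns ``(AnchoredRead, None)`` on acceptance and ``(None, reason)``
    otherwise, with ``reason`` one of :data:`REJECT_REASONS`.
    """
    sequence = sequence.upper()
    if not sequence:
        return None, "empty"
    fwd = _scan_orientation(sequence, template, max_mismatches)
    rc_seq = revcomp(sequence)
    rev = _scan_orientation(rc_seq, template, max_mismatches)
    fwd_complete = bool(fwd[0]) and bool(fwd[1])
    rev_complete = bool(rev[0]) and bool(rev[1])
    if fwd_complete and rev_complete:
        return None, "ambiguous_orientation"
    if fwd_complete or rev_complete:
        if fwd_complete:
            seq, (up_hits, down_hits), flipped = sequence, fwd, False
        else:
            seq, (up_hits, down_hits), flipped = rc_seq, rev, True
        anchor_lens = {i: len(a) for i, a in enumerate(template.up_anchors, 1)}
        up_end = max(pos + anchor_lens[idx] for idx, pos in up_hits)
        down_start = min(pos for _, pos in down_hits)
        if up_end > down_start:
            return None, "anchor_disorder"
        return (
            AnchoredRead(read_id, seq, flipped, sorted(up_hits), sorted(down_hits)),
            None,
        )
    # incomplete in both orientations: categorize from the orientation with
    # more anchor signal (symmetric under reverse complement of the input)
    best = max((fwd, rev), key=lambda h: (len(h[0]) + len(h[1]), bool(h[0])))
    if best[0] and not best[1]:
        return None, "no_downstream_anchor"
    if best[1] and not best[0]:
        return None, "no_upstream_anchor"
    return None, "no_anchor"


def extract_repeat_reads(
    source: str | Path | list[tuple[str, str]],
    template: LocusTemplate,
    max_mismatches: int = 0,
) -> tuple[list[AnchoredRead], Counter]:
    """Apply :func:`find_anchors` to every record of a FASTQ/FASTA file.

    ``source`` may also be an in-memory list of ``(read_id, sequence)``
    pairs.  Returns the accepted reads and a Counter over rejection
    categories plus ``"accepted"``; accepted + rejected equals the input
    record count.
    """
    if isinstance(source, (str, Path)):
        records = _io.read_seqs(source)
    else:
        records = source
    accepted: list[AnchoredRead] = []
    summary: Counter = Counter({"accepted": 0, **{r: 0 for r in REJECT_REASONS}})
    for read_id, seq in records:
        anchored, reason = find_anchors(read_id, seq, template, max_mismatches)
        if anchored is not None:
            accepted.append(anchored)
            summary["accepted"] += 1
        else:
            summary[reason] += 1
    return accepted, summary
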